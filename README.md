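# thetaseq

Analysis of how slow (25–45 Hz) and fast (65–100 Hz) gamma rhythms
organize hippocampal CA1 place-cell firing into **theta sequences** —
compressed sweeps of represented position inside single 4–12 Hz theta
cycles. The package is aimed at systems neuroscientists working with
tetrode-style recordings (LFP at ~2 kHz, sorted spike trains, position
tracking) on a circular track, and at anyone who wants a fully testable,
ground-truth-validated implementation of this analysis chain.

It provides, as one pipeline over plain CSV/JSON/flat-binary session
files:

* zero-phase band filtering, Hilbert phase (trough = 0°), Morlet band
  power, gamma-episode detection (z ≥ 3, 160 ms, mutually exclusive
  between rhythms), theta-cycle segmentation;
* speed / head-direction estimation, 90-bin angular tuning curves, place
  field acceptance, Skaggs spatial information;
* **FG/NFG classification**: a place cell is an FG-cell when the Rayleigh
  test on its fast-gamma spike phases is significant (α = 0.05) and it
  fired ≥ 10 spikes in every lap;
* per-trial memoryless Bayesian decoding over 90 angle bins
  (P(x|n) ∝ Π_i λ_i(x)^{n_i} e^{−τλ_i(x)}, τ = 20 ms windows stepped by
  5 ms), plus exclusion decoders (exFG; exNFG with a count-matched NFG
  downsample);
* theta-sequence detection (optimal cutting phase, 100–200 ms duration,
  participation criteria) scored by the **weighted correlation**

  corr_w(t, p; prob) = cov(t, p; prob) / √(cov(t, t; prob) · cov(p, p; prob))

  over the ±35 cm × ±30 ms posterior window around the animal;
* **slow-gamma phase precession**: per cell and theta cycle, the mean
  wrapped phase difference across k ≥ 2 adjacent active slow-gamma cycles
  (negative = precession), with a within-cycle uniform-phase shuffle null,
  corrected empirical p-values (r+1)/(n+1), and the Q1 quadrant analysis
  of phase shift vs corr_w;
* a circular-statistics library (Rayleigh, Watson–Williams,
  Mardia–Watson–Wheeler, circular-linear regression);
* a **synthetic session generator** that produces ground-truth-annotated
  position, LFP and spikes with all of the above structure injected, so
  every stage is verifiable without real recordings.

## Worked example

Generate a session and run the full pipeline (the numbered scripts under
`analysis/` do the same in stages):

```bash
python analysis/01_simulate_session.py 1
python analysis/03_decode_sequences.py 1
python analysis/04_gamma_precession.py 1
```

which prints, for seed 1:

```
session written to results/session
  5 laps, 80.3 s, 14503 spikes from 45 cells (14 fast-gamma locked)
decoded 11598 windows; optimal cutting phase 300 deg
median decode error (spiking windows): 6.4 cm
276 theta sequences detected
mean weighted correlation by lap and decoder:
     corr_raw  corr_exfg  corr_exnfg
lap
0       0.362      0.359       0.281
...
83 (cell, theta-cycle) phase-shift records
observed sequence-level median shift: -69.3 deg
shuffle-null 95% CI: [-27.5, 27.0] deg; one-sided empirical p (precession) = 0.000999
```

Reading this: the decoder tracks the rat to within ~6 cm (bin width
≈ 3.5 cm); 276 theta cycles pass the sequence criteria and show a clear
forward-sweep structure (corr_w ≈ 0.3–0.37 per lap); and spikes inside
slow-gamma-event theta cycles arrive ~69° earlier on each successive
slow-gamma cycle — far outside the shuffle null — i.e. slow-gamma phase
precession, close to the −60°/cycle the generator injected.

The same operations are available from Python
(`thetaseq.simulate_session`, `thetaseq.analyze_session`) and from the
CLI (`thetaseq simulate|validate|run-all|decode|sequences|precession …`).

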