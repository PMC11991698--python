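# Methods

`thetaseq` reimplements, end to end, the analysis chain used to study how
slow- and fast-gamma rhythms organize hippocampal CA1 place-cell firing
into theta sequences: LFP band decomposition and gamma-episode detection,
place-cell characterization, FG/NFG classification by fast-gamma phase
locking, per-trial Bayesian position decoding, theta-sequence detection
with the weighted-correlation statistic, and the slow-gamma
phase-precession statistics with shuffle-based inference.  Because no real
recordings ship with the package, every stage is validated against a
ground-truth synthetic session generator that encodes the study design.
This note documents the models, the parameters that matter, and the
numerical choices.

## The synthetic session generator

### Behavior

A simulated rat runs `n_laps` (default 5) unidirectional laps on a
circular track of 90 cm inner diameter (running radius 45 cm, so one lap
is ~283 cm).  Speed is drawn per 25 Hz position sample from a clipped
normal distribution (default 25 +/- 3 cm/s) smoothed over ~0.5 s, and the
animal rests motionless at the track origin (the "rest box", angle 0) for
4 s between laps, which exercises every speed > 5 cm/s filter downstream.
Position is emitted as (x, y) so the speed and head-direction estimators
operate on the same inputs they would see from a tracking camera, but the
single behavioral coordinate is the track angle (matching the 90-angle-bin
analyses).

### LFP

The LFP is a sum of

* an 8 Hz theta sinusoid (200 uV) whose trough defines phase 0;
* a slow-gamma oscillator (center 37 Hz) and a fast-gamma oscillator
  (center 81 Hz), each with baseline amplitude (30 / 25 uV), and
  amplitude-modulated bursts;
* white noise (50 uV SD).

Both gamma oscillators carry slow AR(1) frequency drift (SD 4 Hz for slow,
14 Hz for fast, ~0.15 s correlation time).  The drift serves two purposes:
it prevents the oscillators from being commensurate with theta (a fixed
integer frequency ratio would make gamma phase predictable from theta
phase, and any theta-locked spike train would then show *spurious* gamma
phase locking), and it keeps the Rayleigh test approximately calibrated on
cells with no injected locking.  Fast gamma needs more drift than slow
gamma because spikes cluster within theta cycles on timescales comparable
to the fast-gamma phase correlation time; drift that is too small inflates
the Rayleigh false-positive rate well above alpha.  Residual inflation
remains visible at the session level because all cells share one
oscillator trajectory, so per-session false-positive rates fluctuate
somewhat beyond binomial expectations.

Bursts are placed per theta cycle (probability 0.2 per rhythm, only during
laps) at a fixed theta phase per rhythm -- slow gamma on the descending
phase (250 deg), fast gamma near the trough (20 deg); these placements are
conventional, not fitted.  Envelopes are Hann windows spanning a fraction
of the cycle (0.9 for slow, 0.35 for fast) with peak amplitude 4-7x the
baseline.  These amplitudes make strong bursts exceed the z >= 3 episode
threshold while keeping slow-gamma *events* (theta cycles whose mean
z-scored slow-gamma power is >= 1.5) a minority (~10-15% of cycles), which
is the regime the event-restricted analyses assume.  Because the z-score
is computed within-trial, the event rate is governed by burst duty cycle
and probability, not by absolute amplitude: stronger bursts also raise the
power variance they are normalized by.

### Spikes

Each of `n_cells` (default 45) place cells is an inhomogeneous Poisson
process sampled per 0.5-ms LFP sample (per-sample Poisson draws, one
independent RNG substream per cell).  The rate is a product of gains:

1. **Spatial/theta gain.** A von Mises bump (peak 35 Hz, full width at 10%
   of peak = 72 deg) evaluated at the *represented* position: the true
   position plus a sawtooth sweep running from 20 cm behind the animal at
   the theta trough to 20 cm ahead at the next trough.  This one mechanism
   yields theta phase precession, forward theta sequences, and the
   compressed look-ahead structure the decoder is meant to recover.  The
   20 cm half-span keeps the represented trajectory inside the +/-35 cm
   scoring window and keeps the median decode error well under the 10-cm
   acceptance bound (the sweep itself displaces the instantaneous decoded
   position by up to +/-20 cm).  With `sweep_fg_only` the sweep is given
   only to FG-labeled cells, so removing them destroys sequence structure
   while removing count-matched NFG cells does not.
2. **Fast-gamma gain** (FG cells only, default 30% of cells): von Mises in
   the ground-truth fast-gamma phase, concentration `fg_kappa` (default
   0.8), preferred phase 180 deg, normalized by I0(kappa) so the mean rate
   is unchanged.
3. **Slow-gamma precession gain**: von Mises in slow-gamma phase
   (concentration 8) whose preferred phase is `180 + slope * j` where `j`
   indexes slow-gamma cycles within the current theta cycle and `slope`
   defaults to -60 deg/cycle.  Spikes a cell emits in adjacent active
   cycles therefore advance (precess) by the slope on average.  Per-lap,
   per-class slope schedules (`sg_slope_fg_by_lap`, `sg_slope_nfg_by_lap`)
   support the lap-resolved experiments.  The gain applies only during
   laps; rest-box spikes carry no precession.

A 0.1 Hz space-independent baseline is added.  All outputs are
bit-reproducible from `(config, seed)`.

### What the generator does not emulate

No conductance-based dynamics, no spike waveforms (sorting is out of
scope), no multi-shank geometry, no theta frequency/amplitude modulation
by speed, no layer-dependent gamma, no cross-frequency amplitude coupling
beyond the theta-phase placement of bursts, and gamma amplitude does not
modulate firing rates (only phase does).  Passing tests therefore
demonstrate that the *analysis chain* recovers known structure under the
study's statistical assumptions -- not that those assumptions hold in any
particular real dataset.

## Analysis pipeline

### Signals

All filters are 4th-order Butterworth applied forward-backward
(zero-phase); bands are 4-12, 25-45 and 65-100 Hz.  Instantaneous phase is
the Hilbert-transform angle shifted so the trough maps to 0 deg and the
peak to 180 deg.  Time-varying band power uses an explicit 6-cycle complex
Morlet transform at 1 Hz-spaced center frequencies averaged across each
band, z-scored within trial (lap).  Gamma episodes are 160-ms windows
around local maxima of z >= 3; overlapping candidates are resolved
greedily by descending peak z, and an episode is vetoed when the other
rhythm's z reaches 3 anywhere in its window (mutual exclusivity).  The
unsmoothed averaged-band power is thresholded directly, and "amplitude"
in overlap resolution means peak z.  Theta cycles are successive upward
crossings of the cutting phase; durations outside 83-250 ms (the 4-12 Hz
band's physiological bounds) are flagged invalid.

### Place cells

Running speed is the central difference over flanking position samples
(elapsed time 2/25 s); head direction is the atan2 of the same
displacement (atan2, not a bare arctangent ratio, to resolve quadrants),
carried forward through zero-displacement samples.  Track angle is
measured from the midrange of the trajectory extent -- the centroid would
be biased toward the rest box, where dwell time is long.  Tuning curves
use 90 angle bins (~3.5 cm) and locomotion spikes only (> 5 cm/s),
unsmoothed by default.  Acceptance: peak > 1 Hz, main field (contiguous
bins above 10% of peak, circular wrap respected) > 3 bins, mean rate <=
15 Hz (putative interneurons excluded).  Spatial information is the
standard bits-per-spike score; unoccupied bins are dropped after
renormalizing occupancy so the score stays defined on partial coverage.

### FG/NFG classification

Each running spike takes the phase of the nearest LFP sample.
Classification applies the Rayleigh test (finite-n corrected p) to a
cell's pooled fast-gamma phases and requires >= 10 spikes in *every* lap;
cells failing the spike criterion stay unclassified and enter no
downstream pool.  Alpha is 0.05 per cell with no multiplicity correction.
Slow-gamma locking is computed and reported but never used for labels.

### Bayesian decoding

Per trial (lap), a memoryless Poisson decoder over 90 bins is trained on
that lap's locomotion spikes, with a flat prior, 20-ms windows stepped by
5 ms through the running intervals, computed in log space and normalized
per window.  Tuning curves are floored at 0.01 Hz before decoding: the
likelihood is degenerate at zero rate, and the floor's value only shifts
log-likelihoods by a bounded constant in unvisited bins.  The exFG decoder
drops all FG cells; the exNFG decoder drops a seeded pseudo-random NFG
subset matched in *cell count* to the FG pool (removed spike counts are
reported so spike parity can be checked).  Decode-error summaries use
windows containing at least one spike; zero-spike windows carry a flat
posterior and are flagged.

### Theta sequences

The cutting phase is chosen by segmenting at each of 0, 10, ..., 350 deg
and maximizing the mean weighted correlation of detected sequences (ties
toward the smallest phase).  A sequence is a valid theta cycle during
which the animal stays on the usable track segment (30-330 deg; the
spatial window must also fit inside it) at speed > 5 cm/s, lasting
100-200 ms, with >= 4 distinct accepted place cells firing and >= 5 total
spikes.  The participation sentence in the source protocol is ambiguous
("more than 3 place cells which emitted at least 5 spikes"); the reading
used here is >= 4 cells and >= 5 spikes in total, and a strict per-cell
>= 5-spike reading is available behind `strict_participation`.  The score
is the probability-weighted Pearson correlation between time and decoded
position over a 13 x 21 submatrix: +/-30 ms around the cycle mid-time at
the 5-ms step, +/-10 bins (~35 cm) around the animal's position, without
renormalizing probabilities inside the window (corr_w is scale
invariant).  Sequences whose temporal window would cross a running-gap
seam in the posterior, or whose spatial window would leave the usable
segment, are dropped and counted.  FG-cell sequences contain >= 1 FG cell
and some single cell firing across >= 3 slow-gamma cycles; NFG-cell
sequences satisfy the same span condition with no FG cell.

### Slow-gamma phase shift

Slow-gamma cycles run trough to trough.  Within slow-gamma-event theta
cycles (cycle-mean z >= 1.5), a cell's longest run of adjacent active
cycles (first run on ties) with k >= 2 gives one record: the arithmetic
mean of wrapped adjacent differences of per-cycle circular-mean phases,
in (-180, 180].  Records aggregate per sequence (mean across cells within
a theta cycle) or per cell (mean across cycles), stratified by lap and
FG/NFG label.  The shuffle null redraws each spike's phase uniformly
within its own cycle -- spike counts per cell and cycle are preserved
exactly -- 1000 times (scaled-down checks use 200), yielding the 95% CI
of the null statistic and corrected empirical p-values (r+1)/(n+1).  The
ensemble analysis orders complete slow-gamma cycles around the
maximal-spiking cycle (ties to the earliest; ordinals limited to -1..1)
and accumulates 40 x 40 gamma-phase x theta-phase histograms per ordinal,
smoothed with a circular 9-bin boxcar along each axis (a kernel choice;
the source protocol does not specify the smoother's shape).

### Quadrant analysis

Each FG- or NFG-cell sequence contributes a (phase shift, corr_w) point;
Quadrant 1 is shift < 0 and corr_w > 0.  Points with either coordinate
exactly zero belong to no quadrant and are excluded from the
normalization (measure-zero under continuous noise; the count is
reported).  The observed Q1 probability is compared against the same
within-cycle phase shuffle (corr_w fixed), one-sided.

## Statistical toolbox

Circular statistics are implemented in `thetaseq.circstats`: resultant
length, Rayleigh (Zar's finite-n correction), Watson-Williams (F with the
1 + 3/(8 kappa-hat) correction; a warning note, not an error, below the
concentration guideline), Mardia-Watson-Wheeler (uniform scores with
average ranks on ties, chi-square with 2(k-1) df, flagged below total
n = 10), the phase-precession circular-linear fit (resultant-length
maximization over a bounded slope window, grid scan plus bounded
refinement; significance from the circular-linear correlation z), and the
corrected empirical p.  Degrees at every API boundary, radians inside
kernels; wrapped differences in (-180, 180].

## Problem sizes and determinism

The reference synthetic session is 45 cells x 5 laps (~80 s, ~14,000
spikes); it runs through the full pipeline in a few seconds.  Multi-session
checks pool 3-10 seeded sessions; calibration checks use 200-2000
replicates with 200 shuffles where full 1000-shuffle nulls would be
redundant.  Every stochastic stage consumes a named substream of one
master seed (exNFG downsampling, shuffle nulls, the generator's per-cell
streams), so any stage can be rerun in isolation bit-for-bit.

## Known limitations

* The Rayleigh-based FG label inherits the test's sensitivity to serial
  dependence among spike phases; the generator controls this with
  oscillator drift, but real gamma is burstier still, and session-level
  false-positive rates fluctuate beyond binomial because cells share the
  LFP.
* Sequence detection assumes unidirectional running and a single usable
  track segment; bidirectional tracks would need directional tuning
  curves.
* The cutting-phase optimizer scores only the raw decoder; exFG/exNFG
  sequences reuse the same cycles by design (matching the exclusion
  comparison), not because the optimum is shared.
* Theta cycles are segmented from the same channel that provides gamma
  phases; no cross-channel referencing is modeled.
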