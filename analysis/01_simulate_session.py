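#!/usr/bin/env python
"""Generate the reference synthetic session and write it to disk.

One rat-session of the study design: 45 place cells, 5 unidirectional laps
on a 90-cm circular track, 2 kHz LFP with theta and nested slow/fast gamma
bursts, fast-gamma-locked FG cells (30%), within-cycle position sweeps and
slow-gamma phase precession at -60 deg/cycle.  Output goes to
results/session/ (position.csv, spikes.csv, lfp.bin/json, laps.csv,
ground_truth.json).
"""

import sys
from pathlib import Path

from thetaseq import SimConfig, simulate_session
from thetaseq.session_io import validate_session, write_session

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/session")


def main():
    cfg = SimConfig()
    session = simulate_session(cfg, seed=SEED)
    write_session(session, OUT)
    problems = validate_session(OUT)
    n_fg = int(session.cells["is_fg"].sum())
    print(f"session written to {OUT}")
    print(f"  {len(session.laps)} laps, {session.position.duration:.1f} s, "
          f"{len(session.spikes)} spikes from {cfg.n_cells} cells "
          f"({n_fg} fast-gamma locked)")
    print(f"  validation: {'PASS' if not problems else problems}")


if __name__ == "__main__":
    main()
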