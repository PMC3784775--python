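#!/usr/bin/env python
"""Quantify behavior from the kinematics of the demo session.

Computes smoothed head/tail speeds, detects stationary states with the
3-sigma / 10 s rule, and tabulates sucker-state occupancy; compares the
detected rest epochs with the generator's ground truth.
Writes results/stationary_intervals.csv and results/sucker_occupancy.csv.
"""

from pathlib import Path

import pandas as pd

from leechdendro.io import load_session
from leechdendro.kinematics import (
    detect_stationary,
    gaussian_velocity,
    occupancy_fractions,
    sucker_states,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    session = load_session(ROOT / "session_demo")
    hs, ts = gaussian_velocity(session.kinematics)
    detected = detect_stationary(hs, ts, session.kinematics.t)
    pd.DataFrame(
        [(iv.t_start, iv.t_end, iv.label) for iv in detected],
        columns=["t_start", "t_end", "label"],
    ).to_csv(ROOT / "stationary_intervals.csv", index=False)

    truth = [iv for iv in session.schedule
             if iv.label == "stationary" and iv.duration > 11.0]
    det_time = sum(iv.duration for iv in detected)
    truth_time = sum(iv.duration for iv in truth)
    overlap = sum(
        max(0.0, min(d.t_end, g.t_end) - max(d.t_start, g.t_start))
        for d in detected for g in truth
    )
    print(f"stationary detection: {len(detected)} intervals, "
          f"{det_time:.0f} s detected vs {truth_time:.0f} s ground truth, "
          f"overlap {overlap / truth_time:.1%} of truth")

    state, transitions = sucker_states(session.suckers)
    occ = occupancy_fractions(state)
    pd.DataFrame({"state": [0, 1, 2, 3], "fraction": occ}).to_csv(
        ROOT / "sucker_occupancy.csv", index=False
    )
    print("sucker-state occupancy (0: both attached ... 3: both detached): "
          + ", ".join(f"{f:.3f}" for f in occ)
          + f"; {len(transitions)} transitions")


if __name__ == "__main__":
    main()
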