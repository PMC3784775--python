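#!/usr/bin/env python
"""Generate the demonstration session used by the downstream analyses.

A 1200 s semi-intact recording with the full behavioral repertoire is
simulated (24 identified motoneurons on 8 electrodes, 25 Hz kinematics,
twin APs on the connectives) and written as a plain-text bundle under
results/session_demo/.
"""

from pathlib import Path

from leechdendro.io import write_session
from leechdendro.synth import SimulatorConfig, simulate_session

OUT = Path(__file__).resolve().parent.parent / "results" / "session_demo"

MIX = {
    "crawling": 0.25, "swimming": 0.15, "pseudo_swimming": 0.12,
    "exploring": 0.13, "stationary": 0.35,
}


def main() -> None:
    config = SimulatorConfig(session_duration=1200.0, seed=1)
    session = simulate_session(config, MIX)
    write_session(session, OUT)

    n_spikes = sum(len(st) for st in session.spikes.values())
    print(f"simulated {session.duration:.0f} s, {len(session.spikes)} units, "
          f"{n_spikes} spikes, {len(session.truth_twins)} injected twin APs")
    totals: dict[str, float] = {}
    for iv in session.schedule:
        totals[iv.label] = totals.get(iv.label, 0.0) + iv.duration
    for label, tot in sorted(totals.items(), key=lambda kv: -kv[1]):
        print(f"  {label:16s} {tot:7.1f} s")
    print(f"bundle written to {OUT}")


if __name__ == "__main__":
    main()
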