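#!/usr/bin/env python
"""Behavior dendrograms and their cross-experiment averages.

Builds Pearson-distance / complete-linkage dendrograms for crawling and
swimming from the demo session (checking that the crawling 2-cut
separates contractors from elongators), then averages crawling
dendrograms over 5 independent simulated experiments using the six
canonical cells (CV, L, 3, 109, 102, 119).  Writes Newick trees under
results/.
"""

from pathlib import Path

from leechdendro import dendro as DD
from leechdendro.io import load_session, write_dendrogram
from leechdendro.synth import SimulatorConfig, simulate_session

ROOT = Path(__file__).resolve().parent.parent / "results"


def describe_two_cut(dend, classes) -> str:
    lines = []
    for block in dend.cut(2).blocks:
        kinds = sorted({classes[u] for u in block})
        lines.append(f"  {len(block):2d} units ({', '.join(kinds)})")
    return "\n".join(lines)


def main() -> None:
    session = load_session(ROOT / "session_demo")
    classes = {uid: st.unit.functional_class
               for uid, st in session.spikes.items()}

    for behavior in ("crawling", "swimming"):
        dend = DD.behavior_dendrogram(session, behavior)
        write_dendrogram(dend, ROOT / f"dendrogram_{behavior}.nwk")
        print(f"{behavior} dendrogram ({dend.n_leaves} leaves), 2-cut:")
        print(describe_two_cut(dend, classes))

    sessions = [
        simulate_session(
            SimulatorConfig(session_duration=600.0, seed=60 + i),
            {"crawling": 0.5, "swimming": 0.2, "stationary": 0.3},
        )
        for i in range(5)
    ]
    for behavior in ("crawling", "swimming"):
        avg = DD.average_behavior_dendrogram(sessions, behavior)
        write_dendrogram(avg, ROOT / f"average_dendrogram_{behavior}.nwk")
        blocks = [sorted(b) for b in avg.cut(2).blocks]
        print(f"average {behavior} dendrogram over 5 experiments, "
              f"canonical cells, 2-cut: {blocks}")


if __name__ == "__main__":
    main()
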