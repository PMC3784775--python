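#!/usr/bin/env python
"""Twin APs on the connectives around head-sucker detachments.

Detects paired spikes on the rostral/caudal connectives (4-6 ms band),
scores them against the generator's ground truth, and aligns the twin
rate on head-sucker detachments (+- 30 s window).  Writes
results/twins.csv and results/twin_peri_event.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from leechdendro import twinap as TW
from leechdendro.io import load_session
from leechdendro.synth import head_detach_times

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    session = load_session(ROOT / "session_demo")
    events = TW.detect_twins(session.connectives["RC"], session.connectives["CC"])
    pd.DataFrame(
        [(e.t_rostral, e.t_caudal, e.delay_ms, e.direction) for e in events],
        columns=["t_rostral", "t_caudal", "delay_ms", "direction"],
    ).to_csv(ROOT / "twins.csv", index=False)

    truth = {(round(e.t_rostral, 6), round(e.t_caudal, 6))
             for e in session.truth_twins}
    det = {(round(e.t_rostral, 6), round(e.t_caudal, 6)) for e in events}
    tp = len(truth & det)
    counts = TW.direction_counts(events)
    print(f"{len(events)} twin events detected "
          f"(recall {tp / len(truth):.3f}, precision {tp / len(det):.3f}); "
          f"median |delay| {np.median([abs(e.delay_ms) for e in events]):.2f} ms; "
          f"tail->head {counts['tail_to_head']}, "
          f"head->tail {counts['head_to_tail']}")

    detaches = head_detach_times(session.suckers)
    rate = TW.twin_rate(events, span=(0.0, session.duration))
    rel, trace = TW.peri_event_average(rate, detaches)
    pd.DataFrame({"t_rel": rel, "rate_hz": trace}).to_csv(
        ROOT / "twin_peri_event.csv", index=False
    )
    baseline = trace[rel < -15].mean()
    lead = trace[(rel >= -8) & (rel < 0)].mean()
    burst = trace[(rel >= 0) & (rel < 2)].mean()
    print(f"peri-detachment twin rate over {detaches.size} events: "
          f"baseline {baseline:.2f} Hz, last 8 s before detach {lead:.2f} Hz, "
          f"burst at detach {burst:.2f} Hz")


if __name__ == "__main__":
    main()
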