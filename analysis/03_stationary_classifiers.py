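#!/usr/bin/env python
"""ROC comparison of rest-state classifiers: <rho_ij> versus <AFR_i>.

On repertoire sessions, nerve-level firing rates feed two threshold
classifiers of the stationary state: the mean windowed pairwise
covariance <rho_ij> (threshold swept over 0.01-1 Hz^2) and the mean
firing rate <AFR_i> (threshold 1-20 Hz), both with the "below threshold
= at rest" rule.  Windows fully inside / fully outside rest form the
ground truth.  Writes results/stationary_roc.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from leechdendro import classify as C
from leechdendro import rates as R
from leechdendro.synth import SimulatorConfig, simulate_session

ROOT = Path(__file__).resolve().parent.parent / "results"
MIX = {
    "crawling": 0.25, "swimming": 0.15, "pseudo_swimming": 0.12,
    "exploring": 0.13, "stationary": 0.35,
}


def window_truth(schedule, centers, label, width):
    full = np.zeros(len(centers), bool)
    none = np.zeros(len(centers), bool)
    for i, c in enumerate(centers):
        a, b = c - width / 2, c + width / 2
        ov = sum(max(0.0, min(b, iv.t_end) - max(a, iv.t_start))
                 for iv in schedule if iv.label == label)
        full[i] = ov >= (b - a) - 1e-6
        none[i] = ov < 1e-6
    return full, none


def main() -> None:
    rhos, afrs, truths = [], [], []
    for seed in (5, 6, 7):
        s = simulate_session(
            SimulatorConfig(session_duration=1200.0, seed=seed), MIX
        )
        nr = R.nerve_rates(s.spikes, 0.5, (0.0, s.duration))
        names = sorted(nr)
        centers, mats = R.covariance_matrix_series(
            [nr[x] for x in names], window_step=4
        )
        rho = R.mean_covariance(centers, mats, 50.0, 5).values
        afr = R.mean_afr([nr[x] for x in names]).values
        afr_w = np.array(
            [afr[int((c - 25) / 0.5): int((c + 25) / 0.5)].mean()
             for c in centers]
        )
        full, none = window_truth(s.schedule, centers, "stationary", 50.0)
        keep = full | none
        rhos.append(rho[keep])
        afrs.append(afr_w[keep])
        truths.append(full[keep])

    truth = np.concatenate(truths)
    curve_rho = C.roc_curve(np.concatenate(rhos), truth,
                            thresholds=np.linspace(0.01, 1.0, 100),
                            direction="less")
    curve_afr = C.roc_curve(np.concatenate(afrs), truth,
                            thresholds=np.linspace(1.0, 20.0, 100),
                            direction="less")
    rows = []
    for name, curve in (("mean_covariance", curve_rho),
                        ("mean_rate", curve_afr)):
        for T, fpr, tpr in zip(curve.thresholds, curve.fpr, curve.tpr):
            rows.append((name, T, fpr, tpr))
    pd.DataFrame(rows, columns=["classifier", "threshold", "fpr", "tpr"]).to_csv(
        ROOT / "stationary_roc.csv", index=False
    )
    print(f"stationary-state ROC over {truth.size} windows "
          f"({truth.sum()} at rest):")
    print(f"  AUC <rho_ij>  = {curve_rho.auc:.3f}")
    print(f"  AUC <AFR_i>   = {curve_afr.auc:.3f}")
    better = "covariance" if curve_rho.auc > curve_afr.auc else "rate"
    print(f"  the {better} classifier sits closer to the ideal (0, 1) corner")


if __name__ == "__main__":
    main()
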