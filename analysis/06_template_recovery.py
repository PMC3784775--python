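#!/usr/bin/env python
"""Recover behaviors from electrical activity by template matching.

Builds crawling and swimming template dendrograms from a training
session, slides a 100 s window (2 s step) over held-out sessions, and
scores each window against the templates (crawling: k=2 with NMI;
swimming: k=6 with Fowlkes-Mallows).  Windows fully inside / outside
ground-truth episodes give TPR and FPR at the 0.5 threshold.  Also
compares the dendrogram matcher with the covariance-feature discriminant
and the population-rate threshold via pooled ROC AUC.  Writes
results/template_similarity.csv and results/classifier_aucs.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from leechdendro import classify as C
from leechdendro import dendro as DD
from leechdendro import rates as R
from leechdendro.synth import SimulatorConfig, simulate_session

ROOT = Path(__file__).resolve().parent.parent / "results"
RECOVERY_MIX = {"crawling": 0.35, "swimming": 0.2, "stationary": 0.45}
REPERTOIRE_MIX = {
    "crawling": 0.25, "swimming": 0.15, "pseudo_swimming": 0.12,
    "exploring": 0.13, "stationary": 0.35,
}


def window_truth(schedule, centers, label, width=100.0):
    full = np.zeros(len(centers), bool)
    none = np.zeros(len(centers), bool)
    for i, c in enumerate(centers):
        a, b = c - width / 2, c + width / 2
        ov = sum(max(0.0, min(b, iv.t_end) - max(a, iv.t_start))
                 for iv in schedule if iv.label == label)
        full[i] = ov >= (b - a) - 1e-6
        none[i] = ov < 1e-6
    return full, none


def recovery_rates() -> None:
    train = simulate_session(
        SimulatorConfig(session_duration=2400.0, seed=900), RECOVERY_MIX
    )
    crawl_tpl = DD.behavior_dendrogram(train, "crawling")
    swim_tpl = DD.behavior_dendrogram(train, "swimming")
    tp = pos = fp = neg = 0
    rows = []
    nonswim_max = 0.0
    for seed in range(1, 6):
        s = simulate_session(
            SimulatorConfig(session_duration=1200.0, seed=seed), RECOVERY_MIX
        )
        c2, sc = C.match_behavior_template(s, crawl_tpl, "crawling")
        c6, ss = C.match_behavior_template(s, swim_tpl, "swimming")
        rows.extend(
            (seed, t, a, b) for t, a, b in zip(c2, sc, np.interp(c2, c6, ss))
        )
        full, none = window_truth(s.schedule, c2, "crawling")
        tp += (sc[full] > 0.5).sum()
        pos += full.sum()
        fp += (sc[none] > 0.5).sum()
        neg += none.sum()
        _, no_swim = window_truth(s.schedule, c6, "swimming")
        nonswim_max = max(nonswim_max, ss[no_swim].max())
    pd.DataFrame(rows, columns=["seed", "t_center", "s_crawling",
                                "s_swimming"]).to_csv(
        ROOT / "template_similarity.csv", index=False
    )
    print(f"crawling recovery over 5 held-out sessions: "
          f"TPR {100 * tp / pos:.1f}% ({pos} crawling windows), "
          f"FPR {100 * fp / neg:.2f}% ({neg} non-crawling windows)")
    print(f"swimming template never exceeds {nonswim_max:.3f} "
          f"outside swimming epochs")


def classifier_comparison() -> None:
    def features(s, label):
        ur = R.unit_rates(s.spikes, 0.5, (0.0, s.duration))
        uids = sorted(ur)
        centers, mats = R.covariance_matrix_series(
            [ur[u] for u in uids], N=200, window_step=4
        )
        X = C.covariance_features(mats)
        afr = R.mean_afr([ur[u] for u in uids]).values
        afr_w = np.array([afr[int((c - 50) / 0.5): int((c + 50) / 0.5)].mean()
                          for c in centers])
        full, none = window_truth(s.schedule, centers, label)
        return centers, X, afr_w, full, none

    trains = [simulate_session(SimulatorConfig(session_duration=1200.0, seed=sd),
                               REPERTOIRE_MIX) for sd in (101, 102)]
    Xs, ys = [], []
    for s in trains:
        _, X, _, full, none = features(s, "crawling")
        keep = full | none
        Xs.append(X[keep])
        ys.append(full[keep].astype(int))
    Xtr, ytr = np.vstack(Xs), np.concatenate(ys)
    Ztr, pca = C.pca_reduce(Xtr, 100)
    crawl_tpl = DD.behavior_dendrogram(trains[0], "crawling")

    kinds = ("linear", "diaglinear", "quadratic", "diagquadratic")
    cov_scores = {k: [] for k in kinds}
    dend_scores, rate_scores, truths = [], [], []
    for seed in (5, 6, 7):
        s = simulate_session(
            SimulatorConfig(session_duration=1200.0, seed=seed), REPERTOIRE_MIX
        )
        centers, X, afr_w, full, none = features(s, "crawling")
        keep = full | none
        Zte = pca.transform(X) if pca is not None else X
        for kind in kinds:
            _, sc = C.discriminant_classify(Ztr, ytr, Zte, kind,
                                            return_scores=True)
            cov_scores[kind].append(sc[keep])
        _, sim = C.match_behavior_template(s, crawl_tpl, "crawling")
        dend_scores.append(sim[keep])
        rate_scores.append(afr_w[keep])
        truths.append(full[keep])

    truth = np.concatenate(truths)
    rows = []
    for kind in kinds:
        rows.append((f"covariance_{kind}",
                     C.roc_curve(np.concatenate(cov_scores[kind]), truth).auc))
    rows.append(("dendrogram_matcher",
                 C.roc_curve(np.concatenate(dend_scores), truth).auc))
    rows.append(("rate_threshold",
                 C.roc_curve(np.concatenate(rate_scores), truth).auc))
    df = pd.DataFrame(rows, columns=["classifier", "auc"])
    df.to_csv(ROOT / "classifier_aucs.csv", index=False)
    print("crawling classifier AUCs (pooled over 3 repertoire sessions):")
    for name, auc in rows:
        print(f"  {name:24s} {auc:.4f}")


def main() -> None:
    recovery_rates()
    classifier_comparison()


if __name__ == "__main__":
    main()
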