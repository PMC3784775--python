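"""Behavior identification from electrical activity.

Three families of classifiers, all evaluated with ROC analysis:

* threshold classifiers on the population-mean firing rate <AFR_i> or the
  mean pairwise covariance <rho_ij> (used for stationary states, which
  show low, uncorrelated activity);
* sliding-window dendrogram template matching: a dendrogram is built in
  each window (default 100 s width, 2 s step) and compared to a behavior
  template at cut level k;
* Gaussian discriminant classifiers (linear / diaglinear / quadratic /
  diagquadratic) on the n(n-1)/2 windowed covariance coefficients,
  optionally PCA-reduced to at most 100 components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .containers import BehaviorInterval, SyntheticSession
from .dendro import Dendrogram, agglomerate, cut_tree, pearson_dissimilarity
from .rates import DEFAULT_BINWIDTH, RateSeries, unit_rates
from .simil import DEFAULT_CUT_K, DEFAULT_TEMPLATE_INDEX, similarity

DEFAULT_WINDOW = 100.0  # s
DEFAULT_STEP = 2.0  # s
DEFAULT_MATCH_THRESHOLD = 0.5
DEFAULT_PCA_COMPONENTS = 100
DISCRIMINANT_KINDS = ("linear", "diaglinear", "quadratic", "diagquadratic")


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    @property
    def auc(self) -> float:
        """Trapezoidal area under the curve, with (0,0) and (1,1) anchors."""
        order = np.argsort(self.fpr, kind="stable")
        fpr = np.concatenate([[0.0], self.fpr[order], [1.0]])
        tpr = np.concatenate([[0.0], self.tpr[order], [1.0]])
        return float(np.trapezoid(tpr, fpr))


def threshold_classify(
    scores: np.ndarray, T: float, direction: str = "greater"
) -> np.ndarray:
    """Binary labels: 1 where the score lies on the stated side of T."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if direction == "greater":
        return (scores > T).astype(int)
    if direction == "less":
        return (scores < T).astype(int)
    raise ValueError("direction must be 'greater' or 'less'")


def roc_curve(
    scores: np.ndarray,
    truth: np.ndarray,
    thresholds: np.ndarray | None = None,
    direction: str = "greater",
) -> ROCCurve:
    """One (FPR, TPR) point per threshold.

    TPR = TP / (TP + FN), FPR = FP / (FP + TN).  Raises on degenerate
    truth (all positive or all negative: the rates are undefined).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.size != truth.size:
        raise ValueError("scores and truth must have equal length")
    n_pos = int(truth.sum())
    n_neg = int(truth.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth labels are all one class; TPR/FPR undefined")
    if thresholds is None:
        thresholds = np.unique(scores)
    thresholds = np.asarray(thresholds, dtype=float)
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, T in enumerate(thresholds):
        pred = threshold_classify(scores, T, direction).astype(bool)
        tpr[i] = (pred & truth).sum() / n_pos
        fpr[i] = (pred & ~truth).sum() / n_neg
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr)


# --------------------------------------------------------------------------
# Dendrogram template matching
# --------------------------------------------------------------------------


def sliding_template_match(
    session: SyntheticSession,
    template: Dendrogram,
    k: int,
    window: float = DEFAULT_WINDOW,
    step: float = DEFAULT_STEP,
    index_kind: str = "nmi",
    binwidth: float = DEFAULT_BINWIDTH,
    method: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Similarity s(D_window, D_template) at cut k for each window position.

    Returns (window centers, similarity series).  Windows in which some
    template unit never fires (undefined correlation) score 0: the
    template's signature is absent there.
    """
    uids = list(template.leaves)
    missing = [u for u in uids if u not in session.spikes]
    if missing:
        raise KeyError(f"template units missing from the recording: {missing}")
    n_win_bins = int(round(window / binwidth))
    if n_win_bins < 10:
        raise ValueError("window must contain at least 10 bins")
    step_bins = max(1, int(round(step / binwidth)))
    method = method or template.linkage_method

    T = session.duration
    rate_map = unit_rates(
        {u: session.spikes[u] for u in uids}, binwidth, span=(0.0, T)
    )
    V = np.vstack([rate_map[u].values for u in uids])
    n_bins = V.shape[1]
    template_cut = cut_tree(template, k)

    centers, scores = [], []
    for start in range(0, n_bins - n_win_bins + 1, step_bins):
        block = V[:, start : start + n_win_bins]
        centers.append((start + n_win_bins / 2.0) * binwidth)
        if np.any(block.std(axis=1) == 0):
            scores.append(0.0)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            series = {
                u: RateSeries(t0=0.0, binwidth=binwidth, values=block[i])
                for i, u in enumerate(uids)
            }
            D = agglomerate(pearson_dissimilarity(series), method=method)
        scores.append(similarity(cut_tree(D, k), template_cut, index_kind))
    return np.asarray(centers), np.asarray(scores)


def match_behavior_template(
    session: SyntheticSession,
    template: Dendrogram,
    behavior: str,
    window: float = DEFAULT_WINDOW,
    step: float = DEFAULT_STEP,
    binwidth: float = DEFAULT_BINWIDTH,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding template match with the behavior's default cut level and
    index (k = 2 + NMI for crawling, k = 6 + Fowlkes-Mallows for swimming
    and pseudo-swimming)."""
    if behavior not in DEFAULT_CUT_K:
        raise ValueError(f"no template defaults for behavior {behavior!r}")
    return sliding_template_match(
        session, template,
        k=DEFAULT_CUT_K[behavior],
        window=window, step=step,
        index_kind=DEFAULT_TEMPLATE_INDEX[behavior],
        binwidth=binwidth,
    )


def detect_episodes(
    centers: np.ndarray,
    scores: np.ndarray,
    threshold: float = DEFAULT_MATCH_THRESHOLD,
    min_duration: float = 0.0,
    label: str = "crawling",
    erode: float = 0.0,
    merge_gap: float = 0.0,
) -> list[BehaviorInterval]:
    """Maximal runs of the similarity series above threshold; runs shorter
    than ``min_duration`` are discarded.  Interval bounds are half a step
    beyond the first/last window center of the run.

    Runs separated by gaps of at most ``merge_gap`` seconds are joined
    (brief dips of the index inside one episode).  A window whose extent
    only partially overlaps an episode can still carry the episode's
    signature, so raw runs overshoot episode bounds by up to half the
    window width; pass ``erode`` (typically window / 2) to shrink each
    run accordingly.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    centers = np.asarray(centers, dtype=float)
    scores = np.asarray(scores, dtype=float)
    above = scores > threshold
    if not above.any():
        return []
    step = float(np.median(np.diff(centers))) if centers.size > 1 else 0.0
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    runs = [
        (centers[i0] - step / 2, centers[i1 - 1] + step / 2)
        for i0, i1 in zip(starts, ends)
    ]
    merged = [runs[0]]
    for t0, t1 in runs[1:]:
        if t0 - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], t1)
        else:
            merged.append((t0, t1))
    out = []
    for t0, t1 in merged:
        t0, t1 = t0 + erode, t1 - erode
        if t1 > t0 and t1 - t0 >= min_duration:
            out.append(BehaviorInterval(t0, t1, label))
    return out


# --------------------------------------------------------------------------
# Discriminant analysis on covariance features
# --------------------------------------------------------------------------


def covariance_features(mats: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle of each M x M covariance matrix:
    one row per window, n(n-1)/2 columns."""
    mats = np.asarray(mats, dtype=float)
    if mats.ndim != 3 or mats.shape[1] != mats.shape[2]:
        raise ValueError("expected matrices of shape (n_windows, M, M)")
    iu = np.triu_indices(mats.shape[1], k=1)
    return mats[:, iu[0], iu[1]]


def pca_reduce(features: np.ndarray, n_components: int = DEFAULT_PCA_COMPONENTS):
    """Project features onto the leading principal components.

    Applied only when the feature count exceeds ``n_components``; returns
    (reduced features, fitted transform or None).
    """
    features = np.asarray(features, dtype=float)
    if n_components > min(features.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows, columns)={min(features.shape)}"
        )
    if features.shape[1] <= n_components:
        return features, None
    pca = PCA(n_components=n_components, svd_solver="full")
    return pca.fit_transform(features), pca


@dataclass
class _GaussianDiscriminant:
    classes: np.ndarray
    priors: np.ndarray
    means: np.ndarray
    covs: list  # one (pooled) or per-class covariance, full matrix or diag vector
    pooled: bool
    diagonal: bool

    def log_likelihood(self, X: np.ndarray) -> np.ndarray:
        n, d = X.shape
        ll = np.empty((n, self.classes.size))
        for c in range(self.classes.size):
            cov = self.covs[0] if self.pooled else self.covs[c]
            diff = X - self.means[c]
            if self.diagonal:
                if np.any(cov <= 0):
                    raise ValueError(
                        "singular (zero-variance) feature; reduce with PCA first"
                    )
                maha = ((diff**2) / cov).sum(axis=1)
                logdet = np.log(cov).sum()
            else:
                sign, logdet = np.linalg.slogdet(cov)
                if sign <= 0:
                    raise ValueError(
                        "singular pooled/class covariance; reduce the features "
                        "with PCA before classifying"
                    )
                maha = (diff * np.linalg.solve(cov, diff.T).T).sum(axis=1)
            ll[:, c] = -0.5 * (maha + logdet) + np.log(self.priors[c])
        return ll


def _fit_discriminant(X: np.ndarray, y: np.ndarray, kind: str) -> _GaussianDiscriminant:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    pooled = kind in ("linear", "diaglinear")
    diagonal = kind in ("diaglinear", "diagquadratic")
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    centered = [X[y == c] - means[i] for i, c in enumerate(classes)]
    if pooled:
        R = np.vstack(centered)
        denom = max(1, X.shape[0] - classes.size)
        cov = (R * R).sum(axis=0) / denom if diagonal else (R.T @ R) / denom
        covs = [cov]
    else:
        covs = []
        for Rc, nc in zip(centered, counts):
            denom = max(1, nc - 1)
            covs.append((Rc * Rc).sum(axis=0) / denom if diagonal else (Rc.T @ Rc) / denom)
    return _GaussianDiscriminant(
        classes=classes, priors=counts / counts.sum(), means=means,
        covs=covs, pooled=pooled, diagonal=diagonal,
    )


def discriminant_classify(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    kind: str = "linear",
    return_scores: bool = False,
):
    """Gaussian discriminant prediction on covariance features.

    ``kind``: linear (pooled full covariance), diaglinear (pooled
    diagonal, naive Bayes), quadratic (per-class full), diagquadratic
    (per-class diagonal).  Class priors are empirical from the training
    split.  With ``return_scores`` also returns the posterior log-odds of
    the highest class (useful for ROC sweeps in two-class problems).
    """
    if kind not in DISCRIMINANT_KINDS:
        raise ValueError(f"kind must be one of {DISCRIMINANT_KINDS}")
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    Xt = np.asarray(test_features, dtype=float)
    model = _fit_discriminant(X, y, kind)
    ll = model.log_likelihood(Xt)
    pred = model.classes[np.argmax(ll, axis=1)]
    if return_scores:
        if model.classes.size != 2:
            raise ValueError("scores are defined for two-class problems only")
        return pred, ll[:, 1] - ll[:, 0]
    return pred
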