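"""Dendrograms over units from firing-rate dissimilarity.

The metric is the Pearson distance d_ij = 1 - r_ij (one minus the sample
Pearson correlation between the two rate series), giving values in
[0, 2]: 0 for perfectly correlated units, 2 for perfect anti-correlation.
Trees are built agglomeratively; complete linkage is the default (less
sensitive to noise, valid for non-Euclidean dissimilarities), single
linkage is provided as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import BehaviorInterval, SyntheticSession, intervals_with_label
from .rates import DEFAULT_BINWIDTH, RateSeries, bin_rate
from .synth import CANONICAL_CELLS

LINKAGE_METHODS = ("complete", "single")


@dataclass
class DissimilarityMatrix:
    labels: list[str]
    d: np.ndarray  # (M, M), symmetric, zero diagonal, entries in [0, 2]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        M = len(self.labels)
        if self.d.shape != (M, M):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-9):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("dissimilarity matrix must be finite")


@dataclass
class Clustering:
    """Flat partition of leaves into k nonempty blocks."""

    blocks: list[frozenset]

    @property
    def k(self) -> int:
        return len(self.blocks)

    @property
    def elements(self) -> frozenset:
        return frozenset().union(*self.blocks)

    def labels_of(self, order: list[str]) -> np.ndarray:
        """Integer block labels in a given element order."""
        idx = {}
        for b, block in enumerate(self.blocks):
            for el in block:
                idx[el] = b
        return np.array([idx[el] for el in order])


@dataclass
class Dendrogram:
    """Agglomerative merge tree: scipy linkage matrix plus leaf names."""

    leaves: list[str]
    Z: np.ndarray  # scipy linkage matrix, (L-1, 4)
    linkage_method: str = "complete"

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        L = len(self.leaves)
        if self.Z.shape != (max(L - 1, 0), 4):
            raise ValueError(f"expected {L - 1} merges for {L} leaves")
        heights = self.Z[:, 2]
        if heights.size and np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be nondecreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def cut(self, k: int) -> Clustering:
        return cut_tree(self, k)


def pearson_dissimilarity(
    rate_list: dict[str, RateSeries] | list[RateSeries],
    labels: list[str] | None = None,
) -> DissimilarityMatrix:
    """Pearson-distance matrix over units; zero-variance units are dropped
    with a warning (their correlation is undefined)."""
    if isinstance(rate_list, dict):
        labels = list(rate_list.keys())
        series = list(rate_list.values())
    else:
        series = list(rate_list)
        if labels is None:
            labels = [str(i) for i in range(len(series))]
    if len(series) < 2:
        raise ValueError("need at least two units")
    n = series[0].values.size
    if n < 2:
        raise ValueError("rate series must have at least 2 samples")
    V = np.vstack([s.values for s in series])

    keep = V.std(axis=1) > 0
    if not np.all(keep):
        dropped = [lab for lab, k in zip(labels, keep) if not k]
        warnings.warn(f"dropping zero-variance units: {dropped}", stacklevel=2)
        V = V[keep]
        labels = [lab for lab, k in zip(labels, keep) if k]
    if V.shape[0] < 2:
        raise ValueError("fewer than two units with nonzero variance")

    r = np.corrcoef(V)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DissimilarityMatrix(labels=labels, d=d)


def agglomerate(D: DissimilarityMatrix, method: str = "complete") -> Dendrogram:
    """Standard agglomerative clustering of a dissimilarity matrix."""
    if method not in LINKAGE_METHODS:
        raise ValueError(f"method must be one of {LINKAGE_METHODS}")
    condensed = squareform(D.d, checks=True)
    Z = hierarchy.linkage(condensed, method=method)
    return Dendrogram(leaves=list(D.labels), Z=Z, linkage_method=method)


def cut_tree(dend: Dendrogram, k: int) -> Clustering:
    """Partition obtained by undoing the k-1 highest merges."""
    L = dend.n_leaves
    if not 1 <= k <= L:
        raise ValueError(f"k must lie in [1, {L}], got {k}")
    if L == 1:
        return Clustering(blocks=[frozenset(dend.leaves)])
    assignment = hierarchy.cut_tree(dend.Z, n_clusters=k).ravel()
    blocks: dict[int, set] = {}
    for leaf, b in zip(dend.leaves, assignment):
        blocks.setdefault(int(b), set()).add(leaf)
    return Clustering(blocks=[frozenset(s) for _, s in sorted(blocks.items())])


def episode_rates(
    session: SyntheticSession,
    intervals: list[BehaviorInterval],
    binwidth: float = DEFAULT_BINWIDTH,
    units: list[str] | None = None,
) -> dict[str, RateSeries]:
    """Per-unit rates restricted to the episodes, episodes concatenated raw.

    The concatenated series lives on a synthetic grid (t0 = 0); it is only
    meaningful for correlation structure, not for absolute timing.
    """
    if not intervals:
        raise ValueError("no episodes supplied")
    uids = list(session.spikes.keys()) if units is None else list(units)
    missing = [u for u in uids if u not in session.spikes]
    if missing:
        raise KeyError(f"units not present in the session: {missing}")
    out: dict[str, RateSeries] = {}
    for uid in uids:
        st = session.spikes[uid]
        pieces = [
            bin_rate(st.times, binwidth, span=(iv.t_start, iv.t_end)).values
            for iv in intervals
        ]
        out[uid] = RateSeries(t0=0.0, binwidth=binwidth, values=np.concatenate(pieces))
    return out


def behavior_dendrogram(
    session: SyntheticSession,
    behavior: str,
    binwidth: float = DEFAULT_BINWIDTH,
    method: str = "complete",
    units: list[str] | None = None,
) -> Dendrogram:
    """Dendrogram from all episodes of one behavior, grouped together."""
    intervals = intervals_with_label(session.schedule, behavior)
    if not intervals:
        raise ValueError(f"session has no {behavior!r} episodes")
    total_bins = sum(iv.duration for iv in intervals) / binwidth
    if total_bins < 10:
        raise ValueError(
            f"only {total_bins:.0f} bins of {behavior!r}; need at least 10"
        )
    rate_map = episode_rates(session, intervals, binwidth, units)
    D = pearson_dissimilarity(rate_map)
    return agglomerate(D, method=method)


def _celltype_mean_rates(
    session: SyntheticSession,
    intervals: list[BehaviorInterval],
    cells: tuple[str, ...],
    binwidth: float,
) -> dict[str, RateSeries]:
    """Average the rates of same-identity cells across sides and ganglia."""
    rate_map = episode_rates(session, intervals, binwidth)
    by_type: dict[str, list[RateSeries]] = {}
    for uid, series in rate_map.items():
        ct = session.spikes[uid].unit.cell_type
        if ct in cells:
            by_type.setdefault(ct, []).append(series)
    missing = [c for c in cells if c not in by_type]
    if missing:
        raise ValueError(f"sessions lack canonical cells: {missing}")
    return {
        ct: RateSeries(
            t0=0.0, binwidth=binwidth,
            values=np.vstack([s.values for s in group]).mean(axis=0),
        )
        for ct, group in by_type.items()
    }


def average_behavior_dendrogram(
    sessions: list[SyntheticSession],
    behavior: str,
    cells: tuple[str, ...] = CANONICAL_CELLS,
    binwidth: float = DEFAULT_BINWIDTH,
    method: str = "complete",
) -> Dendrogram:
    """Cross-experiment average dendrogram over the canonical cells.

    Per experiment, same-identity cells are averaged and a Pearson-distance
    matrix is computed over that experiment's episodes; the matrices are
    then averaged element-wise and agglomerated.
    """
    if not sessions:
        raise ValueError("need at least one session")
    mats = []
    for session in sessions:
        intervals = intervals_with_label(session.schedule, behavior)
        if not intervals:
            raise ValueError(f"a session has no {behavior!r} episodes")
        rate_map = _celltype_mean_rates(session, intervals, cells, binwidth)
        D = pearson_dissimilarity({c: rate_map[c] for c in cells})
        if D.labels != list(cells):
            raise ValueError(f"zero-variance canonical cell in a session: "
                             f"{sorted(set(cells) - set(D.labels))}")
        mats.append(D.d)
    avg = DissimilarityMatrix(labels=list(cells), d=np.mean(mats, axis=0))
    return agglomerate(avg, method=method)


def shift_control(
    session: SyntheticSession,
    channel: str,
    shift: float,
    behavior: str,
    binwidth: float = DEFAULT_BINWIDTH,
    method: str = "complete",
) -> Dendrogram:
    """Rebuild a behavior dendrogram after circularly shifting the spike
    times of one electrode's units (time-shuffling robustness control).

    ``channel`` is an electrode id such as ``DP_1L`` (one suction-pipette
    recording, the unit a shuffle displaces relative to the rest of the
    array) or a bare nerve name such as ``DP`` to shift every electrode
    of that nerve together.
    """
    T = session.duration
    if abs(shift) >= T:
        raise ValueError("shift must be smaller than the session duration")
    subset = [
        uid for uid, st in session.spikes.items()
        if channel in (st.unit.nerve, st.unit.nerve_id)
    ]
    if not subset:
        raise ValueError(f"no units recorded on channel {channel!r}")
    shifted = dict(session.spikes)
    for uid in subset:
        st = session.spikes[uid]
        new_times = np.sort(np.mod(st.times + shift, T))
        shifted[uid] = type(st)(unit=st.unit, times=new_times)
    twin = SyntheticSession(
        schedule=session.schedule,
        kinematics=session.kinematics,
        suckers=session.suckers,
        spikes=shifted,
        connectives=session.connectives,
        truth_twins=session.truth_twins,
        config=session.config,
    )
    return behavior_dendrogram(twin, behavior, binwidth=binwidth, method=method)
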