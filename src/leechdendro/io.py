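"""Session bundles on disk and dendrogram serialization.

A session directory holds plain-text tables: ``spikes.csv`` (unit_id,
time_s), ``kinematics.csv`` (t_s, x_head, y_head, x_tail, y_tail),
``suckers.csv`` (t_s, head_attached, tail_attached), ``connectives.csv``
(channel, time_s), ``schedule.csv`` (t_start, t_end, label; optional for
real data) and ``manifest.json`` (unit roster + generator config echo).
All quantities are spike times and low-rate traces, so CSV + JSON is
sufficient; adapting the readers to a community electrophysiology
container only requires replacing this module.

Dendrograms are serialized as Newick with branch lengths encoding merge
heights (leaves at height 0) and unit identifiers as leaf names.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    BehaviorInterval,
    CellIdentity,
    KinematicsTrace,
    SpikeTrain,
    SuckerTrace,
    SyntheticSession,
    TwinEvent,
)
from .dendro import Dendrogram


class SessionFormatError(ValueError):
    """A session bundle is missing files or violates an invariant."""


# --------------------------------------------------------------------------
# Session bundles
# --------------------------------------------------------------------------


def write_session(session: SyntheticSession, directory) -> Path:
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)

    rows = [
        (uid, t) for uid, st in session.spikes.items() for t in st.times
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
        out / "spikes.csv", index=False
    )

    kin = session.kinematics
    pd.DataFrame(
        {
            "t_s": kin.t,
            "x_head": kin.head_xy[:, 0],
            "y_head": kin.head_xy[:, 1],
            "x_tail": kin.tail_xy[:, 0],
            "y_tail": kin.tail_xy[:, 1],
        }
    ).to_csv(out / "kinematics.csv", index=False)

    suck = session.suckers
    pd.DataFrame(
        {
            "t_s": suck.t,
            "head_attached": suck.head_attached.astype(int),
            "tail_attached": suck.tail_attached.astype(int),
        }
    ).to_csv(out / "suckers.csv", index=False)

    conn_rows = [
        (ch, t) for ch, times in session.connectives.items() for t in times
    ]
    pd.DataFrame(conn_rows, columns=["channel", "time_s"]).to_csv(
        out / "connectives.csv", index=False
    )

    pd.DataFrame(
        [(iv.t_start, iv.t_end, iv.label) for iv in session.schedule],
        columns=["t_start", "t_end", "label"],
    ).to_csv(out / "schedule.csv", index=False)

    manifest = {
        "roster": [dataclasses.asdict(st.unit) for st in session.spikes.values()],
        "ref_point_M": list(kin.ref_point_M) if kin.ref_point_M else None,
        "truth_twins": [
            {"t_rostral": e.t_rostral, "t_caudal": e.t_caudal}
            for e in session.truth_twins
        ],
    }
    if session.config is not None and dataclasses.is_dataclass(session.config):
        manifest["config"] = dataclasses.asdict(session.config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_session(directory) -> SyntheticSession:
    """Load and validate a session bundle, with distinct diagnostics for a
    missing file, unsorted spike times, and unknown unit ids."""
    d = Path(directory)
    required = ["spikes.csv", "kinematics.csv", "suckers.csv", "connectives.csv",
                "manifest.json"]
    for name in required:
        if not (d / name).exists():
            raise SessionFormatError(f"missing session file: {name}")

    manifest = json.loads((d / "manifest.json").read_text())
    roster: dict[str, CellIdentity] = {}
    for u in manifest["roster"]:
        unit = CellIdentity(
            cell_type=u["cell_type"], side=u["side"], ganglion=u["ganglion"],
            nerve=u["nerve"], functional_class=u["functional_class"],
        )
        roster[unit.unit_id] = unit

    spikes_df = pd.read_csv(d / "spikes.csv")
    spikes: dict[str, SpikeTrain] = {}
    for uid, grp in spikes_df.groupby("unit_id", sort=False):
        uid = str(uid)
        if uid not in roster:
            raise SessionFormatError(
                f"spikes.csv contains unit id {uid!r} absent from the manifest roster"
            )
        times = grp["time_s"].to_numpy(dtype=float)
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise SessionFormatError(
                f"spike times of unit {uid!r} are not strictly ascending"
            )
        spikes[uid] = SpikeTrain(unit=roster[uid], times=times)
    for uid, unit in roster.items():
        spikes.setdefault(uid, SpikeTrain(unit=unit, times=np.empty(0)))

    kin_df = pd.read_csv(d / "kinematics.csv")
    M = manifest.get("ref_point_M")
    kinematics = KinematicsTrace(
        t=kin_df["t_s"].to_numpy(),
        head_xy=kin_df[["x_head", "y_head"]].to_numpy(),
        tail_xy=kin_df[["x_tail", "y_tail"]].to_numpy(),
        ref_point_M=tuple(M) if M else None,
    )

    suck_df = pd.read_csv(d / "suckers.csv")
    suckers = SuckerTrace(
        t=suck_df["t_s"].to_numpy(),
        head_attached=suck_df["head_attached"].to_numpy().astype(bool),
        tail_attached=suck_df["tail_attached"].to_numpy().astype(bool),
    )

    conn_df = pd.read_csv(d / "connectives.csv")
    connectives = {
        str(ch): np.sort(grp["time_s"].to_numpy(dtype=float))
        for ch, grp in conn_df.groupby("channel", sort=False)
    }

    schedule: list[BehaviorInterval] = []
    if (d / "schedule.csv").exists():
        sched_df = pd.read_csv(d / "schedule.csv")
        schedule = [
            BehaviorInterval(row.t_start, row.t_end, row.label)
            for row in sched_df.itertuples()
        ]
    truth = [
        TwinEvent(t_rostral=e["t_rostral"], t_caudal=e["t_caudal"])
        for e in manifest.get("truth_twins", [])
    ]

    session = SyntheticSession(
        schedule=schedule, kinematics=kinematics, suckers=suckers,
        spikes=spikes, connectives=connectives, truth_twins=truth,
    )
    if schedule:
        session.validate()
    return session


# --------------------------------------------------------------------------
# Newick dendrograms
# --------------------------------------------------------------------------

_SAFE_NAME = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _quote(name: str) -> str:
    return name if _SAFE_NAME.match(name) else "'" + name.replace("'", "''") + "'"


def write_dendrogram(dend: Dendrogram, path) -> Path:
    """Serialize as Newick; branch lengths encode merge heights (leaves at 0)."""
    L = dend.n_leaves
    heights = {i: 0.0 for i in range(L)}
    children: dict[int, tuple[int, int]] = {}
    for m, (a, b, h, _) in enumerate(dend.Z):
        node = L + m
        heights[node] = float(h)
        children[node] = (int(a), int(b))

    def render(node: int) -> str:
        if node < L:
            return _quote(dend.leaves[node])
        a, b = children[node]
        h = heights[node]
        return (
            f"({render(a)}:{h - heights[a]:.12g},"
            f"{render(b)}:{h - heights[b]:.12g})"
        )

    root = L + len(dend.Z) - 1 if len(dend.Z) else 0
    text = render(root) + ";\n"
    p = Path(path)
    p.write_text(text)
    return p


class NewickParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at character {position})")
        self.position = position


class _Node:
    __slots__ = ("name", "children", "branch", "height")

    def __init__(self):
        self.name = None
        self.children = []
        self.branch = 0.0
        self.height = 0.0


def _parse_newick(text: str) -> _Node:
    pos = 0
    n = len(text)

    def skip_ws():
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1

    def parse_name() -> str:
        nonlocal pos
        if pos < n and text[pos] == "'":
            pos += 1
            out = []
            while pos < n:
                if text[pos] == "'":
                    if pos + 1 < n and text[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(out)
                out.append(text[pos])
                pos += 1
            raise NewickParseError("unterminated quoted name", pos)
        start = pos
        while pos < n and text[pos] not in "(),:;":
            pos += 1
        return text[start:pos].strip()

    def parse_node() -> _Node:
        nonlocal pos
        skip_ws()
        node = _Node()
        if pos < n and text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                skip_ws()
                if pos >= n:
                    raise NewickParseError("unclosed '('", pos)
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise NewickParseError(f"unexpected character {text[pos]!r}", pos)
        name = parse_name()
        if name:
            node.name = name
        skip_ws()
        if pos < n and text[pos] == ":":
            pos += 1
            start = pos
            while pos < n and text[pos] not in "(),:;":
                pos += 1
            try:
                node.branch = float(text[start:pos])
            except ValueError:
                raise NewickParseError("malformed branch length", start)
        return node

    root = parse_node()
    skip_ws()
    if pos >= n or text[pos] != ";":
        raise NewickParseError("expected ';' at end of tree", pos)
    return root


def read_dendrogram(path, linkage_method: str = "complete") -> Dendrogram:
    """Parse a Newick dendrogram back into leaves + linkage matrix.

    Node heights are reconstructed bottom-up from branch lengths (leaves
    at 0); a parent lower than one of its children is a validation error.
    """
    text = Path(path).read_text()
    root = _parse_newick(text)

    leaves: list[str] = []
    internals: list[_Node] = []

    def walk(node: _Node) -> None:
        if not node.children:
            if node.name is None:
                raise NewickParseError("leaf without a name", 0)
            leaves.append(node.name)
            node.height = 0.0
            return
        if len(node.children) != 2:
            raise NewickParseError(
                f"dendrograms are binary; found a node with {len(node.children)} children", 0
            )
        for ch in node.children:
            walk(ch)
        h = [ch.height + ch.branch for ch in node.children]
        if abs(h[0] - h[1]) > 1e-6:
            raise SessionFormatError(
                f"inconsistent merge height: children reach {h[0]} vs {h[1]}"
            )
        node.height = float(np.mean(h))
        for ch in node.children:
            if node.height < ch.height - 1e-9:
                raise SessionFormatError(
                    f"merge height {node.height} below child height {ch.height}"
                )
        internals.append(node)

    walk(root)
    if len(leaves) != len(set(leaves)):
        raise SessionFormatError("duplicate leaf names")

    # scipy linkage matrix: merges sorted by height (the recorded
    # post-order already respects bottom-up dependencies for equal heights)
    internals.sort(key=lambda nd: nd.height)
    leaf_index = {name: i for i, name in enumerate(leaves)}
    node_id: dict[int, int] = {}
    sizes = {}
    Z = np.zeros((len(internals), 4))
    next_id = len(leaves)

    def ident(node: _Node) -> tuple[int, int]:
        if not node.children:
            return leaf_index[node.name], 1
        return node_id[id(node)], sizes[id(node)]

    for m, node in enumerate(internals):
        (ia, na), (ib, nb) = ident(node.children[0]), ident(node.children[1])
        Z[m] = [min(ia, ib), max(ia, ib), node.height, na + nb]
        node_id[id(node)] = next_id
        sizes[id(node)] = na + nb
        next_id += 1

    return Dendrogram(leaves=leaves, Z=Z, linkage_method=linkage_method)
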