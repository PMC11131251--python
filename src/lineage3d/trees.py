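"""Construction of 3D spatio-temporal lineage trees.

A lineage tree is drawn as straight line segments in (tissue-x, scaled-time,
tissue-y) space: each branch connects a cell's position at one sampled
snapshot to its position at the next, so clones show *where* they grew, not
just when. Four variants exist along two axes:

* scope — a single clone (:func:`build_full_tree` / :func:`build_alive_tree`)
  or all clones together (:func:`build_forest`);
* pruning — ``full`` trees include every cell ever recorded, ``alive`` trees
  keep only cells with at least one descendant surviving at the final index
  (dead branches and cells that left the domain are omitted).

Time is mapped linearly onto the vertical axis so that the drawn interval
[tmin, tmax] spans exactly the x-extent of the tissue, giving the three axes
comparable scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, Optional, Set, Tuple

from .io import (
    FOUNDER_SENTINEL,
    CellHistory,
    Snapshot,
    SnapshotSeries,
    TreeConfig,
)

__all__ = [
    "Branch",
    "BranchSet",
    "TimeScale",
    "sampled_indices",
    "time_to_y",
    "clone_root",
    "position_of",
    "build_full_tree",
    "build_alive_tree",
    "build_forest",
    "surviving_set",
]

Point3 = Tuple[float, float, float]  # (x, y_time, z)


@dataclass(frozen=True)
class Branch:
    """One line segment of a tree: clone label plus two (x, y_time, z) points.

    ``x``/``z`` are the tissue coordinates; ``y_time`` is scaled time, so a
    branch never points backward in time (``b[1] >= a[1]``).
    """

    clone_id: int
    a: Point3
    b: Point3

    def __post_init__(self) -> None:
        if self.b[1] < self.a[1]:
            raise ValueError(f"branch runs backward in time: {self.a} -> {self.b}")


@dataclass
class BranchSet:
    """A renderable tree: branches plus bookkeeping on mode and scope."""

    branches: List[Branch]
    mode: str  # "full" | "alive"
    scope: str  # "all" | "clone:<id>"

    @property
    def clones_present(self) -> Set[int]:
        return {br.clone_id for br in self.branches}

    def __len__(self) -> int:
        return len(self.branches)

    def as_set(self, ndigits: int = 9) -> FrozenSet[Tuple]:
        """Branches as a hashable set of rounded tuples (for comparisons)."""
        return frozenset(
            (br.clone_id, tuple(round(v, ndigits) for v in br.a),
             tuple(round(v, ndigits) for v in br.b))
            for br in self.branches
        )

    def to_text(self) -> str:
        """Serialize as ``x1 y1 z1 x2 y2 z2 clone`` lines."""
        lines = []
        for br in self.branches:
            coords = " ".join("%.6g" % v for v in (*br.a, *br.b))
            lines.append(f"{coords} {br.clone_id}")
        return "\n".join(lines)


@dataclass(frozen=True)
class TimeScale:
    """Vertical-axis scaling: y-units of plot per file_step of drawn time."""

    time_step: float

    @classmethod
    def from_config(cls, config: TreeConfig) -> "TimeScale":
        return cls((config.xmax - config.xmin) * config.file_step / (config.tmax - config.tmin))


def sampled_indices(tmin: int, tmax: int, file_step: int, stride: int) -> List[int]:
    """File indices at which branches are drawn: tmin, tmin+file_step, ...

    ``tmax`` is always included, appended when the stepping misses it, so the
    final state of the tree is drawn regardless of divisibility. ``file_step``
    must address indices that actually exist on disk, i.e. be a positive
    multiple of the dataset's save stride.
    """
    if file_step < 1:
        raise ValueError(f"file_step must be >= 1, got {file_step}")
    if file_step % stride != 0:
        raise ValueError(
            f"file_step ({file_step}) must be a multiple of the dataset save "
            f"stride ({stride}); intermediate indices are not on disk"
        )
    out = list(range(tmin, tmax + 1, file_step))
    if out[-1] != tmax:
        out.append(tmax)
    return out


def time_to_y(file_index: int, config: TreeConfig, scale: Optional[TimeScale] = None) -> float:
    """Map a file index onto the vertical axis.

    Linear with y(tmin) = 0 and y(tmax) = xmax - xmin exactly, so the time
    axis spans the same length as the tissue's x-extent.
    """
    if scale is None:
        scale = TimeScale.from_config(config)
    return (file_index - config.tmin) / config.file_step * scale.time_step


def clone_root(history: CellHistory, clone_id: int) -> int:
    """The founding cell of a clone.

    For the initial clone this is the cell with the founder-sentinel mother;
    for a mutated clone, the first daughter whose mother belongs to a
    different clone. Earliest birth wins; ties break to the smallest id.
    """
    candidates = []
    for rec in history:
        if rec.clone_id != clone_id:
            continue
        if rec.mother_id == FOUNDER_SENTINEL:
            candidates.append(rec)
        elif history[rec.mother_id].clone_id != clone_id:
            candidates.append(rec)
    if not candidates:
        present = history.clone_ids
        raise ValueError(f"clone {clone_id} not present in history (clones: {present})")
    return min(candidates, key=lambda r: (r.birth_iter, r.cell_id)).cell_id


def position_of(
    series: SnapshotSeries,
    history: CellHistory,
    cell_id: int,
    file_index: int,
) -> Optional[Tuple[float, float]]:
    """A cell's coordinates at a saved index, falling back to its ancestry.

    If the cell is not yet recorded at ``file_index`` (born at or after it),
    the nearest ancestor's position there is returned instead — this is what
    anchors a daughter's first branch at its mother. Returns ``None`` when
    the cell's whole lineage is absent (already dead, left the domain, or the
    line did not exist yet).
    """
    snap = series[file_index]
    pos = snap.position(cell_id)
    if pos is not None:
        return pos
    rec = history[cell_id]
    if rec.birth_iter >= file_index and rec.mother_id != FOUNDER_SENTINEL:
        return position_of(series, history, rec.mother_id, file_index)
    return None


def _build_tree(
    history: CellHistory,
    series: SnapshotSeries,
    clone_id: int,
    config: TreeConfig,
    keep: Optional[Set[int]],
    mode: str,
) -> BranchSet:
    """Shared traversal: one branch per clone member present at the later of
    each consecutive sampled-index pair, anchored via ancestor fallback."""
    scale = TimeScale.from_config(config)
    indices = sampled_indices(config.tmin, config.tmax, config.file_step, series.stride)
    members = set(history.clone_members(clone_id))
    if keep is not None:
        members &= keep
    branches: List[Branch] = []
    for k, k2 in zip(indices, indices[1:]):
        snap = series[k2]
        y_a, y_b = time_to_y(k, config, scale), time_to_y(k2, config, scale)
        for cid in snap.ids:
            if cid not in members:
                continue
            start = position_of(series, history, cid, k)
            end = snap.position(cid)
            if start is None or end is None:
                continue
            branches.append(
                Branch(clone_id, (start[0], y_a, start[1]), (end[0], y_b, end[1]))
            )
    return BranchSet(branches, mode=mode, scope=f"clone:{clone_id}")


def build_full_tree(
    history: CellHistory,
    series: SnapshotSeries,
    clone_id: int,
    config: TreeConfig,
) -> BranchSet:
    """Tree of *all* cells of one clone, including branches that later die.

    The clone's entry segment (mutated daughter anchored at its mother in the
    parent clone) belongs to this clone, so single-clone plots are
    self-contained.
    """
    clone_root(history, clone_id)  # raises if the clone is absent
    return _build_tree(history, series, clone_id, config, keep=None, mode="full")


def surviving_set(
    history: CellHistory,
    final_snapshot: Snapshot,
    clone_id: Optional[int] = None,
) -> Set[int]:
    """Cells with at least one descendant (or themselves) alive at the end.

    Walks mother links upward from every cell listed in the final snapshot;
    every ancestor touched survives in the pruned sense. With ``clone_id``
    the walk starts only from alive cells *of that clone* and the result is
    restricted to its members: a clone none of whose own cells reached the
    end is pruned away entirely, even if the clones it spawned live on —
    survival does not flow back across the mutation boundary.
    """
    if clone_id is None:
        seeds = list(final_snapshot.ids)
    else:
        seeds = [c for c in final_snapshot.ids if history[c].clone_id == clone_id]
    survivors: Set[int] = set()
    for cid in seeds:
        cur = cid
        while cur != FOUNDER_SENTINEL and cur not in survivors:
            survivors.add(cur)
            cur = history[cur].mother_id
    if clone_id is not None:
        survivors = {c for c in survivors if history[c].clone_id == clone_id}
    return survivors


def build_alive_tree(
    history: CellHistory,
    series: SnapshotSeries,
    clone_id: int,
    config: TreeConfig,
) -> BranchSet:
    """Survivor-pruned tree of one clone: dead branches omitted.

    The result is always a subset of the full tree's branches; a clone whose
    cells all died (e.g. the drug-sensitive initial clone after treatment)
    yields an empty tree, which is a valid outcome, not an error.
    """
    clone_root(history, clone_id)
    keep = surviving_set(history, series[config.tmax], clone_id=clone_id)
    return _build_tree(history, series, clone_id, config, keep=keep, mode="alive")


def build_forest(
    history: CellHistory,
    series: SnapshotSeries,
    num_clones: int,
    mode: str,
    config: TreeConfig,
) -> BranchSet:
    """All-clone tree: the disjoint union of per-clone trees for ids
    0..num_clones (clones are numbered from 0; absent ids are skipped)."""
    if mode not in ("full", "alive"):
        raise ValueError(f"mode must be 'full' or 'alive', got {mode!r}")
    present = set(history.clone_ids)
    branches: List[Branch] = []
    build = build_full_tree if mode == "full" else build_alive_tree
    for clone_id in range(num_clones + 1):
        if clone_id not in present:
            continue
        branches.extend(build(history, series, clone_id, config).branches)
    return BranchSet(branches, mode=mode, scope="all")
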