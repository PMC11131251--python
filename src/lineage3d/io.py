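"""Reading, writing and validating the plain-text lineage dataset format.

A dataset directory holds a ``data/`` subdirectory with four kinds of
whitespace-separated text files:

``cell_history.txt``
    One cell per row: ``cell_id  clone_id  mother_id  birth_iter  end_iter``.
    ``mother_id == 0`` marks the founding cell; ``end_iter == 0`` marks a cell
    that is still alive and has not divided; otherwise ``end_iter`` is the
    iteration at which the cell divided (it then has exactly two daughters
    born at that iteration) or died / left the domain (no daughters).
``cellID_<k>.txt`` / ``cellXY_<k>.txt``
    For every saved iteration ``k``: the ids of the cells present, and their
    x/y coordinates, row-aligned — row ``i`` of both files describes the same
    cell.
``drug.txt``
    Optional 2D matrix of a microenvironmental factor (drug, oxygen, ...)
    sampled on a regular grid spanning the tissue rectangle.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "FormatError",
    "ValidationError",
    "CellRecord",
    "CellHistory",
    "Snapshot",
    "SnapshotSeries",
    "DrugField",
    "TreeConfig",
    "ValidationReport",
    "CheckResult",
    "read_cell_history",
    "read_snapshot",
    "read_drug_map",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
]

FOUNDER_SENTINEL = 0  # mother_id of a cell with no recorded mother

_SNAP_ID_RE = re.compile(r"cellID_(\d+)\.txt$")


class FormatError(ValueError):
    """A text file does not conform to the dataset format."""


class ValidationError(ValueError):
    """A dataset parses but violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellRecord:
    """One row of ``cell_history.txt``.

    ``end_iter == 0`` means alive and undivided; a positive ``end_iter`` is the
    iteration of division (two daughters) or death/exit (no daughters).
    """

    cell_id: int
    clone_id: int
    mother_id: int
    birth_iter: int
    end_iter: int

    def __post_init__(self) -> None:
        if self.cell_id < 1:
            raise ValidationError(f"cell_id must be >= 1, got {self.cell_id}")
        if self.clone_id < 0:
            raise ValidationError(f"clone_id must be >= 0, got {self.clone_id}")
        if self.mother_id < 0:
            raise ValidationError(f"mother_id must be >= 0, got {self.mother_id}")
        if self.birth_iter < 0:
            raise ValidationError(f"birth_iter must be >= 0, got {self.birth_iter}")
        if self.end_iter != 0 and self.end_iter < self.birth_iter:
            raise ValidationError(
                f"cell {self.cell_id}: end_iter {self.end_iter} precedes "
                f"birth_iter {self.birth_iter}"
            )

    @property
    def alive_and_undivided(self) -> bool:
        return self.end_iter == 0


class CellHistory:
    """The full genealogy: records keyed by cell id plus a daughter index.

    Construction validates referential integrity (every non-founder mother id
    resolves), time ordering (a daughter is not born before its mother), and
    the binary-division contract: a cell has either 0 or 2 daughters, and the
    daughters' birth iteration equals the mother's end iteration.
    """

    def __init__(self, records: Iterable[CellRecord]):
        self.records: Dict[int, CellRecord] = {}
        for rec in records:
            if rec.cell_id in self.records:
                raise ValidationError(f"duplicate cell_id {rec.cell_id}")
            self.records[rec.cell_id] = rec

        self.children: Dict[int, List[int]] = {cid: [] for cid in self.records}
        for rec in self.records.values():
            if rec.mother_id == FOUNDER_SENTINEL:
                continue
            mother = self.records.get(rec.mother_id)
            if mother is None:
                raise ValidationError(
                    f"cell {rec.cell_id}: mother {rec.mother_id} not in history"
                )
            if rec.birth_iter < mother.birth_iter:
                raise ValidationError(
                    f"cell {rec.cell_id} born at {rec.birth_iter}, before its "
                    f"mother {mother.cell_id} (born {mother.birth_iter})"
                )
            self.children[rec.mother_id].append(rec.cell_id)

        for cid, kids in self.children.items():
            kids.sort()
            if not kids:
                continue
            mother = self.records[cid]
            if len(kids) != 2:
                raise ValidationError(
                    f"cell {cid} has {len(kids)} daughter(s); divisions are binary"
                )
            for kid in kids:
                if self.records[kid].birth_iter != mother.end_iter:
                    raise ValidationError(
                        f"daughter {kid} born at {self.records[kid].birth_iter} "
                        f"but mother {cid} ended at {mother.end_iter}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, cell_id: int) -> bool:
        return cell_id in self.records

    def __getitem__(self, cell_id: int) -> CellRecord:
        return self.records[cell_id]

    def __iter__(self):
        return iter(self.records.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, CellHistory) and self.records == other.records

    @property
    def clone_ids(self) -> List[int]:
        return sorted({rec.clone_id for rec in self})

    def clone_members(self, clone_id: int) -> List[int]:
        return sorted(r.cell_id for r in self if r.clone_id == clone_id)

    def is_division(self, cell_id: int) -> bool:
        """End-of-record disambiguation: division iff the cell has daughters."""
        return bool(self.children[cell_id])

    def descendants(self, cell_id: int) -> List[int]:
        """All strict descendants, by breadth-first walk of the daughter index."""
        out: List[int] = []
        frontier = list(self.children[cell_id])
        while frontier:
            out.extend(frontier)
            frontier = [g for c in frontier for g in self.children[c]]
        return out


@dataclass
class Snapshot:
    """Ids and row-aligned coordinates of the cells present at one saved index."""

    file_index: int
    ids: List[int]
    xy: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(len(self.ids), 2)
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError(
                f"snapshot {self.file_index}: duplicate cell ids"
            )
        self._row_of = {cid: i for i, cid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, cell_id: int) -> bool:
        return cell_id in self._row_of

    def position(self, cell_id: int) -> Optional[Tuple[float, float]]:
        row = self._row_of.get(cell_id)
        if row is None:
            return None
        return float(self.xy[row, 0]), float(self.xy[row, 1])


@dataclass
class SnapshotSeries:
    """Snapshots keyed by file index, saved at a fixed stride."""

    snapshots: Dict[int, Snapshot]

    def __post_init__(self) -> None:
        self.snapshots = dict(sorted(self.snapshots.items()))
        for idx, snap in self.snapshots.items():
            if snap.file_index != idx:
                raise ValidationError(
                    f"series key {idx} != snapshot file_index {snap.file_index}"
                )

    @property
    def indices(self) -> List[int]:
        return list(self.snapshots)

    @property
    def stride(self) -> int:
        """Save stride inferred from the file indices (gcd of the gaps)."""
        idx = self.indices
        if len(idx) < 2:
            return 1
        return math.gcd(*[b - a for a, b in zip(idx, idx[1:])])

    def __getitem__(self, file_index: int) -> Snapshot:
        try:
            return self.snapshots[file_index]
        except KeyError:
            raise KeyError(
                f"no snapshot saved at index {file_index}; "
                f"available: {self.indices[:5]}..{self.indices[-1:]}"
            ) from None

    def __contains__(self, file_index: int) -> bool:
        return file_index in self.snapshots


@dataclass
class DrugField:
    """A microenvironmental factor sampled on a regular grid over the tissue."""

    values: np.ndarray  # shape (ny, nx), row i <-> y level i
    extent: Tuple[float, float, float, float]  # (xmin, xmax, ymin, ymax)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("drug field contains non-finite values")
        if np.any(self.values < 0):
            raise ValidationError("drug field contains negative concentrations")
        xmin, xmax, ymin, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ValidationError(f"degenerate extent {self.extent}")


@dataclass
class TreeConfig:
    """User arguments shared by the four tree routines.

    ``tmin``/``tmax`` bound the saved-file indices drawn; ``file_step`` is the
    sampling stride over saved indices (larger values straighten branches by
    skipping intermediate positions). ``num_clones`` applies to all-clone
    routines, ``clone_num`` to single-clone ones.
    """

    path_data: str = "."
    xmin: float = -100.0
    xmax: float = 100.0
    ymin: float = -100.0
    ymax: float = 100.0
    tmin: int = 0
    tmax: int = 0
    file_step: int = 1
    is_gradient: bool = False
    to_print: bool = False
    num_clones: Optional[int] = None
    clone_num: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.xmax > self.xmin:
            raise ValidationError(f"xmax ({self.xmax}) must exceed xmin ({self.xmin})")
        if not self.ymax > self.ymin:
            raise ValidationError(f"ymax ({self.ymax}) must exceed ymin ({self.ymin})")
        if not self.tmax > self.tmin:
            raise ValidationError(f"tmax ({self.tmax}) must exceed tmin ({self.tmin})")
        if self.file_step < 1:
            raise ValidationError(f"file_step must be >= 1, got {self.file_step}")
        if self.tmin < 0:
            raise ValidationError(f"tmin must be >= 0, got {self.tmin}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _numbered_rows(path: Path) -> Iterable[Tuple[int, List[str]]]:
    """Non-blank lines of a whitespace-separated file with 1-based numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if fields:
                yield lineno, fields


def _parse_int(token: str, path: Path, lineno: int) -> int:
    try:
        value = float(token)
    except ValueError:
        raise FormatError(f"{path}, line {lineno}: non-numeric field {token!r}") from None
    if value != int(value):
        raise FormatError(f"{path}, line {lineno}: expected integer, got {token!r}")
    return int(value)


def read_cell_history(path) -> CellHistory:
    """Parse ``cell_history.txt`` into a validated :class:`CellHistory`."""
    path = Path(path)
    records = []
    for lineno, fields in _numbered_rows(path):
        if len(fields) != 5:
            raise FormatError(
                f"{path}, line {lineno}: expected 5 fields "
                f"(cell clone mother birth end), got {len(fields)}"
            )
        vals = [_parse_int(tok, path, lineno) for tok in fields]
        try:
            records.append(CellRecord(*vals))
        except ValidationError as exc:
            raise ValidationError(f"{path}, line {lineno}: {exc}") from None
    return CellHistory(records)


def read_snapshot(id_path, xy_path, file_index: int) -> Snapshot:
    """Read a row-aligned ``cellID_<k>.txt`` / ``cellXY_<k>.txt`` pair.

    The two files must list the same cells in the same order; a length
    mismatch is a hard alignment error. Empty files form a valid empty
    snapshot (all cells dead or gone).
    """
    id_path, xy_path = Path(id_path), Path(xy_path)
    ids: List[int] = []
    for lineno, fields in _numbered_rows(id_path):
        if len(fields) != 1:
            raise FormatError(
                f"{id_path}, line {lineno}: expected 1 field, got {len(fields)}"
            )
        ids.append(_parse_int(fields[0], id_path, lineno))
    xy: List[Tuple[float, float]] = []
    for lineno, fields in _numbered_rows(xy_path):
        if len(fields) != 2:
            raise FormatError(
                f"{xy_path}, line {lineno}: expected 2 fields, got {len(fields)}"
            )
        try:
            xy.append((float(fields[0]), float(fields[1])))
        except ValueError:
            raise FormatError(
                f"{xy_path}, line {lineno}: non-numeric coordinate"
            ) from None
    if len(ids) != len(xy):
        raise ValidationError(
            f"snapshot {file_index}: {id_path.name} lists {len(ids)} cells but "
            f"{xy_path.name} lists {len(xy)}; the two files must be row-aligned"
        )
    return Snapshot(file_index, ids, np.array(xy, dtype=float).reshape(len(ids), 2))


def read_drug_map(path, extent: Tuple[float, float, float, float]) -> DrugField:
    """Read ``drug.txt`` (rectangular whitespace-separated matrix)."""
    path = Path(path)
    rows: List[List[float]] = []
    width: Optional[int] = None
    for lineno, fields in _numbered_rows(path):
        if width is None:
            width = len(fields)
        elif len(fields) != width:
            raise FormatError(
                f"{path}, line {lineno}: ragged matrix — row has "
                f"{len(fields)} values, expected {width}"
            )
        try:
            rows.append([float(tok) for tok in fields])
        except ValueError:
            raise FormatError(f"{path}, line {lineno}: non-numeric value") from None
    if not rows:
        raise FormatError(f"{path}: empty matrix")
    return DrugField(np.array(rows, dtype=float), extent)


def snapshot_indices_on_disk(data_dir) -> List[int]:
    """Saved file indices present in a ``data/`` directory, sorted."""
    data_dir = Path(data_dir)
    out = []
    for p in data_dir.glob("cellID_*.txt"):
        m = _SNAP_ID_RE.search(p.name)
        if m:
            out.append(int(m.group(1)))
    return sorted(out)


def read_dataset(
    root,
    indices: Optional[Sequence[int]] = None,
    extent: Optional[Tuple[float, float, float, float]] = None,
) -> Tuple[CellHistory, SnapshotSeries, Optional[DrugField]]:
    """Read a whole dataset directory (``<root>/data/``).

    ``indices`` restricts which snapshots are loaded (all on disk by default).
    ``drug.txt`` is read when present and ``extent`` is given.
    """
    data_dir = Path(root) / "data"
    history = read_cell_history(data_dir / "cell_history.txt")
    if indices is None:
        indices = snapshot_indices_on_disk(data_dir)
    snaps = {}
    for k in indices:
        snaps[k] = read_snapshot(
            data_dir / f"cellID_{k}.txt", data_dir / f"cellXY_{k}.txt", k
        )
    drug = None
    drug_path = data_dir / "drug.txt"
    if drug_path.exists() and extent is not None:
        drug = read_drug_map(drug_path, extent)
    return history, SnapshotSeries(snaps), drug


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

_COORD_FMT = "%.6g"  # 6 significant digits on write


def write_dataset(
    history: CellHistory,
    series: SnapshotSeries,
    drug: Optional[DrugField],
    root,
) -> Dict[str, List[Path]]:
    """Write a dataset under ``<root>/data/``; returns a manifest of paths.

    Integer fields round-trip bit-for-bit through :func:`read_dataset`;
    coordinates are written with 6 significant digits.
    """
    data_dir = Path(root) / "data"
    data_dir.mkdir(parents=True, exist_ok=True)

    hist_path = data_dir / "cell_history.txt"
    with open(hist_path, "w") as fh:
        for rec in sorted(history, key=lambda r: r.cell_id):
            fh.write(
                f"{rec.cell_id} {rec.clone_id} {rec.mother_id} "
                f"{rec.birth_iter} {rec.end_iter}\n"
            )

    manifest: Dict[str, List[Path]] = {"history": [hist_path], "snapshots": [], "drug": []}
    for k, snap in series.snapshots.items():
        id_path = data_dir / f"cellID_{k}.txt"
        xy_path = data_dir / f"cellXY_{k}.txt"
        with open(id_path, "w") as fh:
            for cid in snap.ids:
                fh.write(f"{cid}\n")
        with open(xy_path, "w") as fh:
            for x, y in snap.xy:
                fh.write(f"{_COORD_FMT % x} {_COORD_FMT % y}\n")
        manifest["snapshots"] += [id_path, xy_path]

    if drug is not None:
        drug_path = data_dir / "drug.txt"
        np.savetxt(drug_path, drug.values, fmt=_COORD_FMT)
        manifest["drug"].append(drug_path)
    return manifest


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    hard: bool  # hard failure vs advisory warning
    message: str = ""


@dataclass
class ValidationReport:
    checks: List[CheckResult] = field(default_factory=list)

    def add(self, name: str, passed: bool, hard: bool = True, message: str = "") -> None:
        self.checks.append(CheckResult(name, passed, hard, message))

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks if c.hard)

    def failures(self) -> List[CheckResult]:
        return [c for c in self.checks if not c.passed]

    def __str__(self) -> str:
        lines = []
        for c in self.checks:
            tag = "ok  " if c.passed else ("FAIL" if c.hard else "warn")
            lines.append(f"[{tag}] {c.name}" + (f": {c.message}" if c.message else ""))
        return "\n".join(lines)


def validate_dataset(root, config: TreeConfig) -> ValidationReport:
    """Check a dataset directory against the format's structural contracts.

    Never raises for a bad dataset — every problem becomes a failed check in
    the report. Out-of-bounds coordinates are advisory only (cells that left
    the domain are legitimately *absent*; a *present* cell outside the stated
    rectangle is suspicious but not fatal).
    """
    report = ValidationReport()
    data_dir = Path(root) / "data"
    if not data_dir.is_dir():
        report.add("data directory", False, message=f"{data_dir} not found")
        return report
    report.add("data directory", True)

    try:
        history = read_cell_history(data_dir / "cell_history.txt")
        report.add("history parses and is internally consistent", True)
    except (OSError, FormatError, ValidationError) as exc:
        report.add("history parses and is internally consistent", False, message=str(exc))
        return report

    on_disk = snapshot_indices_on_disk(data_dir)
    if not on_disk:
        report.add("snapshot files present", False, message="no cellID_*.txt files")
        return report
    report.add("snapshot files present", True)

    stride = math.gcd(*[b - a for a, b in zip(on_disk, on_disk[1:])]) if len(on_disk) > 1 else 1
    wanted = [k for k in range(config.tmin, config.tmax + 1, stride)]
    missing = sorted(set(wanted) - set(on_disk))
    report.add(
        f"indices {config.tmin}..{config.tmax} at stride {stride} all saved",
        not missing,
        message=f"missing {missing[:10]}" if missing else "",
    )

    aligned = True
    ids_ok = True
    bounds_ok = True
    membership_ok = True
    for k in on_disk:
        if not (config.tmin <= k <= config.tmax):
            continue
        try:
            snap = read_snapshot(
                data_dir / f"cellID_{k}.txt", data_dir / f"cellXY_{k}.txt", k
            )
        except (OSError, FormatError, ValidationError) as exc:
            aligned = False
            report.add(f"snapshot {k} row-aligned", False, message=str(exc))
            continue
        for cid in snap.ids:
            rec = history.records.get(cid)
            if rec is None:
                ids_ok = False
                report.add(
                    "snapshot ids resolve in history", False,
                    message=f"cell {cid} at index {k} not in history",
                )
                break
            if rec.birth_iter > k or (rec.end_iter != 0 and rec.end_iter < k):
                membership_ok = False
                report.add(
                    "snapshot membership consistent with history", False,
                    message=f"cell {cid} listed at {k} outside [{rec.birth_iter}, "
                    f"{rec.end_iter or 'alive'}]",
                )
                break
        if len(snap) and (
            snap.xy[:, 0].min() < config.xmin or snap.xy[:, 0].max() > config.xmax
            or snap.xy[:, 1].min() < config.ymin or snap.xy[:, 1].max() > config.ymax
        ):
            bounds_ok = False
    if aligned:
        report.add("snapshots row-aligned", True)
    if ids_ok:
        report.add("snapshot ids resolve in history", True)
    if membership_ok:
        report.add("snapshot membership consistent with history", True)
    report.add(
        "coordinates within stated domain", bounds_ok, hard=False,
        message="" if bounds_ok else "some listed cells fall outside the rectangle",
    )
    return report
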