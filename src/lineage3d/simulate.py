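"""Agent-based tumor-evolution simulator emitting conforming datasets.

A 2D tissue patch contains a handful of point vessels. A single founder cell
(clone 0) proliferates off-lattice; daughters are placed beside the mother and
local overlaps are relaxed by pairwise repulsion, so division is effectively
blocked in crowded regions and the colony expands from its rim. From
``drug_start`` on, a cytotoxic drug diffuses out of the vessels (explicit
finite-difference diffusion with decay and per-cell uptake, no-flux walls) and
cells accumulate dose from their surroundings; a sensitive cell dies once its
accumulated dose exceeds a threshold. At division each daughter mutates with
probability ``p_mut``, founding a new sequentially-numbered clone; mutated
clones are fully drug-resistant, so treatment selects for them. Cells may
also die at random or wander out of the domain (both recorded like deaths:
an end iteration with no daughters).

The emitted :class:`SimOutput` carries the genealogy, the saved snapshots
(state *entering* each saved iteration — a cell dividing or dying at a saved
index is still listed there, its daughters appear from the next one), and the
final drug field, and can be written to disk in the package's text format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .io import (
    CellHistory,
    CellRecord,
    DrugField,
    Snapshot,
    SnapshotSeries,
    TreeConfig,
    write_dataset,
)

__all__ = [
    "SimParams",
    "SimOutput",
    "simulate",
    "update_drug",
    "resolve_crowding",
    "make_fixture",
    "load_params",
    "small_colony_params",
    "FIXTURE_KINDS",
]

_CFL_LIMIT = 0.25  # stability bound D*dt/h^2 for the explicit 5-point stencil


@dataclass(frozen=True)
class SimParams:
    """Tunable rates and scales of the tumor model.

    Iterations are the time unit; tissue coordinates share the units of
    ``domain``. ``save_stride`` controls how often snapshots are written;
    history records carry raw iteration numbers, so file indices and
    iteration numbers coincide.
    """

    domain: Tuple[float, float, float, float] = (-100.0, 100.0, -100.0, 100.0)
    n_vessels: int = 5
    p_mut: float = 0.005          # mutation probability per daughter per division
    n_iters: int = 5000
    drug_start: int = 2500        # first iteration of drug injection (>= n_iters: never)
    save_stride: int = 50
    grid_h: float = 4.0           # drug-grid spacing, tissue units
    diffusion_coeff: float = 2.0  # tissue-units^2 per iteration
    decay_rate: float = 0.0005    # fractional decay per iteration
    uptake_rate: float = 0.002    # fractional removal per resident cell per iteration
    vessel_conc: float = 1.0      # concentration clamped at vessel nodes
    death_threshold: float = 3.0  # accumulated dose lethal to sensitive cells
    division_age: float = 150.0   # mean iterations between divisions
    crowding_radius: float = 6.0  # min free distance to divide / overlap target
    random_death_prob: float = 2e-4  # per cell per iteration
    motility_step: float = 0.05   # std of the random displacement per iteration
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_mut", "random_death_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")
        if self.save_stride < 1 or self.n_iters % self.save_stride:
            raise ValueError(
                f"save_stride ({self.save_stride}) must divide n_iters ({self.n_iters})"
            )
        xmin, xmax, ymin, ymax = self.domain
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"degenerate domain {self.domain}")
        if self.crowding_radius <= 0 or self.division_age <= 0:
            raise ValueError("crowding_radius and division_age must be positive")
        cfl = self.diffusion_coeff * self.dt / self.grid_h**2
        if cfl > _CFL_LIMIT:
            raise ValueError(
                f"unstable drug stencil: D*dt/h^2 = {cfl:.3g} exceeds {_CFL_LIMIT}"
            )

    @property
    def grid_shape(self) -> Tuple[int, int]:
        xmin, xmax, ymin, ymax = self.domain
        nx = round((xmax - xmin) / self.grid_h) + 1
        ny = round((ymax - ymin) / self.grid_h) + 1
        return ny, nx


def load_params(path) -> SimParams:
    """Read :class:`SimParams` from a YAML mapping (missing keys -> defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of parameter names")
    if "domain" in raw:
        raw["domain"] = tuple(raw["domain"])
    return SimParams(**raw)


@dataclass
class SimOutput:
    """Everything a simulation emits, ready for the tree routines."""

    history: CellHistory
    series: SnapshotSeries
    drug: Optional[DrugField]
    clone_count: int
    params: SimParams
    vessels: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    drug_death_ids: Set[int] = field(default_factory=set)

    def tree_config(self, file_step: Optional[int] = None, **kw) -> TreeConfig:
        """A TreeConfig spanning this run's domain and saved index range."""
        xmin, xmax, ymin, ymax = self.params.domain
        idx = self.series.indices
        return TreeConfig(
            xmin=xmin, xmax=xmax, ymin=ymin, ymax=ymax,
            tmin=idx[0], tmax=idx[-1],
            file_step=file_step or self.series.stride, **kw,
        )

    def write(self, root) -> Dict[str, List[Path]]:
        return write_dataset(self.history, self.series, self.drug, root)


# ---------------------------------------------------------------------------
# drug field
# ---------------------------------------------------------------------------


def _node_indices(
    positions: np.ndarray, params: SimParams
) -> Tuple[np.ndarray, np.ndarray]:
    """Nearest grid node (iy, ix) for each cell position, clipped to the grid."""
    xmin, _, ymin, _ = params.domain
    ny, nx = params.grid_shape
    ix = np.clip(np.rint((positions[:, 0] - xmin) / params.grid_h).astype(int), 0, nx - 1)
    iy = np.clip(np.rint((positions[:, 1] - ymin) / params.grid_h).astype(int), 0, ny - 1)
    return iy, ix


def _drug_step(
    values: np.ndarray,
    occupancy: Optional[np.ndarray],
    vessel_nodes: Optional[Tuple[np.ndarray, np.ndarray]],
    params: SimParams,
) -> np.ndarray:
    """One explicit update: diffusion (no-flux walls) - decay - uptake + source."""
    coef = params.diffusion_coeff * params.dt / params.grid_h**2
    p = np.pad(values, 1, mode="edge")
    lap = p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * values
    new = values + coef * lap
    if params.decay_rate:
        new *= 1.0 - params.decay_rate * params.dt
    if occupancy is not None and params.uptake_rate:
        new *= np.clip(1.0 - params.uptake_rate * params.dt * occupancy, 0.0, None)
    if vessel_nodes is not None:
        new[vessel_nodes] = params.vessel_conc
    np.clip(new, 0.0, None, out=new)
    if not np.all(np.isfinite(new)):
        raise FloatingPointError(
            f"drug field diverged; the explicit stencil requires "
            f"D*dt/h^2 <= {_CFL_LIMIT} (got {coef:.3g})"
        )
    return new


def update_drug(
    drug: DrugField,
    cell_positions: Optional[np.ndarray],
    vessels: Optional[np.ndarray],
    params: SimParams,
) -> DrugField:
    """Advance the drug field by one time step.

    Vessels act as constant-concentration sources (clamped nodes); each cell
    removes a fixed fraction of the concentration at its grid node; decay is
    uniform. With no vessels, uptake or decay the update is pure no-flux
    diffusion and conserves total mass to rounding error.
    """
    values = drug.values
    if values.shape != params.grid_shape:
        raise ValueError(
            f"field shape {values.shape} does not match grid {params.grid_shape} "
            f"for domain {params.domain} at h={params.grid_h}"
        )
    occupancy = None
    if cell_positions is not None and len(cell_positions):
        occupancy = np.zeros(params.grid_shape)
        iy, ix = _node_indices(np.asarray(cell_positions, float), params)
        np.add.at(occupancy, (iy, ix), 1.0)
    vessel_nodes = None
    if vessels is not None and len(vessels):
        vessel_nodes = _node_indices(np.asarray(vessels, float), params)
    new = _drug_step(values, occupancy, vessel_nodes, params)
    return DrugField(new, drug.extent)


# ---------------------------------------------------------------------------
# mechanics
# ---------------------------------------------------------------------------


def resolve_crowding(
    positions: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
    passes: int = 8,
) -> np.ndarray:
    """Relax pairwise overlaps by symmetric repulsion.

    Each pass pushes every pair closer than ``crowding_radius`` apart by half
    the overlap on each side (coincident cells separate along a random
    direction). A fixed small number of passes is used, so dense interiors
    stay compressed — which is what throttles proliferation there.
    """
    pos = np.array(positions, dtype=float).reshape(-1, 2)
    r = params.crowding_radius
    for _ in range(passes):
        if len(pos) < 2:
            break
        pairs = cKDTree(pos).query_pairs(r, output_type="ndarray")
        if not len(pairs):
            break
        i, j = pairs[:, 0], pairs[:, 1]
        dv = pos[j] - pos[i]
        dist = np.hypot(dv[:, 0], dv[:, 1])
        zero = dist < 1e-12
        if np.any(zero):
            ang = rng.uniform(0, 2 * np.pi, int(zero.sum()))
            dv[zero] = np.c_[np.cos(ang), np.sin(ang)]
            dist[zero] = 1.0
        unit = dv / dist[:, None]
        shift = 0.5 * (r - np.minimum(dist, r))[:, None] * unit
        np.add.at(pos, j, shift)
        np.add.at(pos, i, -shift)
    return pos


def _crowded_mask(positions: np.ndarray, radius: float) -> np.ndarray:
    """True for cells with a neighbor strictly closer than ``radius``."""
    n = len(positions)
    mask = np.zeros(n, dtype=bool)
    if n >= 2:
        pairs = cKDTree(positions).query_pairs(radius * (1 - 1e-9), output_type="ndarray")
        if len(pairs):
            mask[pairs.ravel()] = True
    return mask


# ---------------------------------------------------------------------------
# the simulation loop
# ---------------------------------------------------------------------------


def simulate(params: SimParams) -> SimOutput:
    """Run the tumor model; identical params + seed give identical output.

    Per-iteration order: snapshot (at save indices), drug update and dose
    accumulation, drug/random deaths, random motility, divisions (mature and
    uncrowded cells only), overlap relaxation, out-of-domain removal.
    """
    rng = np.random.default_rng(params.seed)
    xmin, xmax, ymin, ymax = params.domain

    # non-uniform vessel layout, fixed for the run
    vessels = np.c_[
        rng.uniform(xmin + 0.1 * (xmax - xmin), xmax - 0.1 * (xmax - xmin), params.n_vessels),
        rng.uniform(ymin + 0.1 * (ymax - ymin), ymax - 0.1 * (ymax - ymin), params.n_vessels),
    ]
    vessel_nodes = _node_indices(vessels, params) if params.n_vessels else None

    # state arrays (struct-of-arrays over the living cells)
    ids = np.array([1], dtype=int)
    pos = np.array([[0.5 * (xmin + xmax), 0.5 * (ymin + ymax)]], dtype=float)
    birth = np.array([0], dtype=int)
    dose = np.array([0.0])
    resistant = np.array([False])
    next_div = np.array([params.division_age * rng.uniform(0.7, 1.3)])

    clone_of: Dict[int, int] = {1: 0}
    mother_of: Dict[int, int] = {1: 0}
    birth_of: Dict[int, int] = {1: 0}
    end_of: Dict[int, int] = {1: 0}
    drug_death_ids: Set[int] = set()
    next_id = 2
    next_clone = 1

    field_vals = np.zeros(params.grid_shape)
    snapshots: Dict[int, Snapshot] = {}

    def clone_arr() -> np.ndarray:
        return np.array([clone_of[i] for i in ids], dtype=int)

    for t in range(params.n_iters + 1):
        if t % params.save_stride == 0:
            snapshots[t] = Snapshot(t, [int(i) for i in ids], pos.copy())
        if t == params.n_iters:
            break
        n = len(ids)

        # --- drug transport and accumulation ---
        if t >= params.drug_start:
            occupancy = None
            if n:
                occupancy = np.zeros(params.grid_shape)
                iy, ix = _node_indices(pos, params)
                np.add.at(occupancy, (iy, ix), 1.0)
            field_vals = _drug_step(field_vals, occupancy, vessel_nodes, params)
            if n:
                dose = dose + field_vals[iy, ix] * params.dt

        if n:
            # --- deaths ---
            dying = (~resistant) & (dose > params.death_threshold)
            drug_death_ids.update(int(i) for i in ids[dying])
            dying |= rng.random(n) < params.random_death_prob
            if np.any(dying):
                for cid in ids[dying]:
                    end_of[int(cid)] = t
                keep = ~dying
                ids, pos, birth = ids[keep], pos[keep], birth[keep]
                dose, resistant, next_div = dose[keep], resistant[keep], next_div[keep]
                n = len(ids)

        if n:
            # --- motility ---
            pos = pos + params.motility_step * rng.standard_normal((n, 2))

            # --- divisions ---
            mature = (t - birth) >= next_div
            dividing = mature & ~_crowded_mask(pos, params.crowding_radius)
            if np.any(dividing):
                new_rows = []
                for k in np.flatnonzero(dividing):
                    mid = int(ids[k])
                    end_of[mid] = t
                    ang = rng.uniform(0, 2 * np.pi)
                    off = 0.55 * params.crowding_radius * np.array(
                        [math.cos(ang), math.sin(ang)]
                    )
                    for sign in (+1, -1):
                        did = next_id
                        next_id += 1
                        if rng.random() < params.p_mut:
                            dclone, dres = next_clone, True
                            next_clone += 1
                        else:
                            dclone, dres = clone_of[mid], bool(resistant[k])
                        clone_of[did] = dclone
                        mother_of[did] = mid
                        birth_of[did] = t
                        end_of[did] = 0
                        new_rows.append(
                            (did, pos[k] + sign * off, t, dres,
                             params.division_age * rng.uniform(0.7, 1.3))
                        )
                keep = ~dividing
                ids, pos, birth = ids[keep], pos[keep], birth[keep]
                dose, resistant, next_div = dose[keep], resistant[keep], next_div[keep]
                ids = np.concatenate([ids, [r[0] for r in new_rows]]).astype(int)
                pos = np.vstack([pos, [r[1] for r in new_rows]])
                birth = np.concatenate([birth, [r[2] for r in new_rows]]).astype(int)
                dose = np.concatenate([dose, np.zeros(len(new_rows))])
                resistant = np.concatenate([resistant, [r[3] for r in new_rows]])
                next_div = np.concatenate([next_div, [r[4] for r in new_rows]])
                n = len(ids)

            # --- overlap relaxation ---
            pos = resolve_crowding(pos, params, rng, passes=4)

            # --- out-of-domain removal ---
            outside = (
                (pos[:, 0] < xmin) | (pos[:, 0] > xmax)
                | (pos[:, 1] < ymin) | (pos[:, 1] > ymax)
            )
            if np.any(outside):
                for cid in ids[outside]:
                    end_of[int(cid)] = t
                keep = ~outside
                ids, pos, birth = ids[keep], pos[keep], birth[keep]
                dose, resistant, next_div = dose[keep], resistant[keep], next_div[keep]

    records = [
        CellRecord(cid, clone_of[cid], mother_of[cid], birth_of[cid], end_of[cid])
        for cid in sorted(clone_of)
    ]
    history = CellHistory(records)
    drug = DrugField(field_vals, params.domain) if params.drug_start < params.n_iters else None
    return SimOutput(
        history=history,
        series=SnapshotSeries(snapshots),
        drug=drug,
        clone_count=len(set(clone_of.values())),
        params=params,
        vessels=vessels,
        drug_death_ids=drug_death_ids,
    )


def small_colony_params(seed: int, drug: bool = False) -> SimParams:
    """A miniature preset (~tens to ~150 cells, 120 iterations, 9 snapshots).

    Useful for quick demos and for generating many random genealogies cheaply;
    ``drug=True`` switches treatment on halfway through the run.
    """
    return SimParams(
        domain=(-40.0, 40.0, -40.0, 40.0), n_vessels=2, p_mut=0.02,
        n_iters=120, drug_start=60 if drug else 10**6, save_stride=15,
        division_age=15.0, crowding_radius=3.0, random_death_prob=0.01,
        death_threshold=0.3, decay_rate=0.001, uptake_rate=0.002,
        motility_step=0.05, seed=seed,
    )


# ---------------------------------------------------------------------------
# hand-built oracle fixtures
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("one_cell", "one_division", "dying_branch", "two_clones", "drug_extinction")

_FIXTURE_DOMAIN = (-10.0, 10.0, -10.0, 10.0)


def _fixture_output(
    records: List[CellRecord],
    snaps: Dict[int, Tuple[List[int], List[Tuple[float, float]]]],
    drug: Optional[DrugField] = None,
    drug_death_ids: Optional[Set[int]] = None,
) -> SimOutput:
    series = SnapshotSeries(
        {k: Snapshot(k, cids, np.array(xy, float).reshape(len(cids), 2))
         for k, (cids, xy) in snaps.items()}
    )
    history = CellHistory(records)
    n_iters = max(series.indices)
    params = SimParams(
        domain=_FIXTURE_DOMAIN, n_vessels=0, n_iters=n_iters, drug_start=n_iters + 1,
        save_stride=1, grid_h=5.0, diffusion_coeff=2.0,
    )
    return SimOutput(
        history=history, series=series, drug=drug,
        clone_count=len({r.clone_id for r in records}), params=params,
        drug_death_ids=drug_death_ids or set(),
    )


def make_fixture(kind: str) -> SimOutput:
    """Tiny hand-constructed datasets with exactly known trees.

    These encode the snapshot-timing convention of :func:`simulate`: a cell
    dividing or dying at a saved index is still listed at that index, its
    daughters appear from the next saved index on.

    * ``one_cell`` — one immortal motionless founder over 3 snapshots.
    * ``one_division`` — the founder divides at the middle snapshot; its full
      tree has exactly 3 branches (1 mother + 2 daughters).
    * ``dying_branch`` — one daughter dies: the pruned tree is the surviving
      path, the full tree adds the dead stub.
    * ``two_clones`` — one daughter mutates into clone 1.
    * ``drug_extinction`` — clone 0 dies of accumulated drug, the resistant
      mutated clone survives; includes a drug field.
    """
    R = CellRecord
    if kind == "one_cell":
        return _fixture_output(
            [R(1, 0, 0, 0, 0)],
            {0: ([1], [(0.0, 0.0)]), 1: ([1], [(0.0, 0.0)]), 2: ([1], [(0.0, 0.0)])},
        )
    if kind == "one_division":
        return _fixture_output(
            [R(1, 0, 0, 0, 1), R(2, 0, 1, 1, 0), R(3, 0, 1, 1, 0)],
            {
                0: ([1], [(0.0, 0.0)]),
                1: ([1], [(0.0, 1.0)]),
                2: ([2, 3], [(-1.0, 2.0), (1.0, 2.0)]),
            },
        )
    if kind == "dying_branch":
        return _fixture_output(
            [R(1, 0, 0, 0, 1), R(2, 0, 1, 1, 0), R(3, 0, 1, 1, 3)],
            {
                0: ([1], [(0.0, 0.0)]),
                1: ([1], [(0.0, 0.5)]),
                2: ([2, 3], [(-1.0, 1.0), (1.0, 1.0)]),
                3: ([2, 3], [(-2.0, 1.5), (2.0, 1.5)]),
                4: ([2], [(-3.0, 2.0)]),
            },
        )
    if kind == "two_clones":
        return _fixture_output(
            [R(1, 0, 0, 0, 1), R(2, 0, 1, 1, 0), R(3, 1, 1, 1, 0)],
            {
                0: ([1], [(0.0, 0.0)]),
                1: ([1], [(0.0, 0.0)]),
                2: ([2, 3], [(-1.5, 0.0), (1.5, 0.0)]),
            },
        )
    if kind == "drug_extinction":
        drug = DrugField(
            np.linspace(0.0, 1.0, 25).reshape(5, 5), _FIXTURE_DOMAIN
        )
        return _fixture_output(
            [R(1, 0, 0, 0, 1), R(2, 0, 1, 1, 3), R(3, 1, 1, 1, 0)],
            {
                0: ([1], [(0.0, 0.0)]),
                1: ([1], [(0.0, 0.0)]),
                2: ([2, 3], [(-2.0, 0.0), (2.0, 0.0)]),
                3: ([2, 3], [(-2.5, 0.5), (3.0, 0.5)]),
                4: ([3], [(4.0, 1.0)]),
            },
            drug=drug,
            drug_death_ids={2},
        )
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
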