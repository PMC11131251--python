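import matplotlib

matplotlib.use("Agg", force=True)

from typing import Optional, Set

import pytest

from lineage3d import (
    CellHistory,
    Snapshot,
    make_fixture,
    simulate,
    small_colony_params,
)


@pytest.fixture(scope="session")
def small_run():
    """One cached miniature simulation with drug, for read-only assertions."""
    return simulate(small_colony_params(seed=7, drug=True))


@pytest.fixture(scope="session")
def fixture_outputs():
    return {k: make_fixture(k) for k in
            ("one_cell", "one_division", "dying_branch", "two_clones", "drug_extinction")}


def brute_force_survivors(
    history: CellHistory, final: Snapshot, clone_id: Optional[int] = None
) -> Set[int]:
    """Independent pruning oracle: descendants(c) (incl. c) intersect the
    alive set — restricted to the clone's members for single-clone scope."""
    alive = set(final.ids)
    if clone_id is not None:
        alive = {c for c in alive if history[c].clone_id == clone_id}
    out = set()
    for rec in history:
        desc = {rec.cell_id, *history.descendants(rec.cell_id)}
        if desc & alive:
            out.add(rec.cell_id)
    if clone_id is not None:
        out = {c for c in out if history[c].clone_id == clone_id}
    return out
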