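"""3D rendering of lineage trees with matplotlib.

Branches are drawn as line segments in (x, time, y) axes, one
``Line3DCollection`` per clone so large forests stay fast while the scene
remains introspectable (``segment_count``). Colors come from a deterministic
clone palette. Figures are interactive when a GUI backend is active (drag to
rotate); under a headless backend the same figure can still be exported to
JPEG, which is how ``to_print = 1`` is honored.
"""

from __future__ import annotations

import colorsys
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import matplotlib.figure
import matplotlib.pyplot as plt
from mpl_toolkits.mplot3d.art3d import Line3DCollection

from .gradient import BackgroundPlane
from .io import TreeConfig
from .trees import BranchSet

__all__ = ["clone_color", "render", "export_jpeg", "segment_count"]

_CLONE0_PINK = (1.0, 0.412, 0.706)  # hot pink, the customary initial-clone color
_GOLDEN = 0.6180339887498949  # golden-ratio hue stepping: distinct, stable hues


def clone_color(clone_id: int) -> Tuple[float, float, float]:
    """Deterministic RGB for a clone id; identical across runs and figures.

    Clone 0 is fixed to pink; other clones take golden-ratio-spaced hues,
    which stay pairwise distinct for any realistic clone count.
    """
    if clone_id == 0:
        return _CLONE0_PINK
    hue = (0.12 + clone_id * _GOLDEN) % 1.0
    sat = 0.85 if clone_id % 2 else 0.65
    val = 0.9 if clone_id % 3 else 0.7
    return colorsys.hsv_to_rgb(hue, sat, val)


def render(
    branches: BranchSet,
    config: TreeConfig,
    background: Optional[BackgroundPlane] = None,
) -> matplotlib.figure.Figure:
    """Draw a branch set (plus optional backdrop) into a new 3D figure.

    An empty branch set renders empty axes — a clone with no survivors is a
    legitimate result, not an error. Axis extents follow the config rectangle
    and the scaled time span.
    """
    fig = plt.figure(figsize=(7, 7))
    ax = fig.add_subplot(projection="3d")

    if background is not None:
        xe, ze = background.x_edges, background.z_edges
        X, Z = np.meshgrid(xe, ze)
        Y = np.full_like(X, background.y_time)
        ax.plot_surface(
            X, Y, Z,
            facecolors=background.facecolors,
            rstride=1, cstride=1, shade=False,
            alpha=0.5, zorder=0, label="_background",
        )

    by_clone: Dict[int, List] = {}
    for br in branches.branches:
        by_clone.setdefault(br.clone_id, []).append([br.a, br.b])
    for clone_id in sorted(by_clone):
        coll = Line3DCollection(
            by_clone[clone_id],
            colors=[clone_color(clone_id)],
            linewidths=0.8,
            label=f"clone {clone_id}",
        )
        coll.set_gid(f"clone-{clone_id}")
        ax.add_collection3d(coll)

    span = config.xmax - config.xmin
    ax.set_xlim(config.xmin, config.xmax)
    ax.set_ylim(0, span)
    ax.set_zlim(config.ymin, config.ymax)
    ax.set_xlabel("x")
    ax.set_ylabel("time")
    ax.set_zlabel("y")
    ax.set_title(f"{branches.mode} lineage tree ({branches.scope})")
    ax.view_init(elev=20, azim=-60)
    return fig


def segment_count(fig: matplotlib.figure.Figure) -> int:
    """Number of branch segments in a rendered figure's scene graph."""
    total = 0
    for ax in fig.axes:
        for coll in ax.collections:
            gid = coll.get_gid() or ""
            if gid.startswith("clone-"):
                # 3D segments live in _segments3d until the first draw projects
                # them; fall back to the public 2D accessor if that ever moves.
                segs = getattr(coll, "_segments3d", None)
                total += len(segs) if segs is not None else len(coll.get_segments())
    return total


def export_jpeg(fig: matplotlib.figure.Figure, path) -> Path:
    """Save a rendered figure as a JPEG file; returns the written path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, format="jpg", dpi=150)
    return path
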