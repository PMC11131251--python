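"""Quantized microenvironment backdrop.

The drug (or oxygen, ...) field is split into four equal-width concentration
bands between its min and max and projected onto the tissue plane of the 3D
scene, colored highest-to-lowest red — yellow — cyan — blue. Four flat colors
keep the backdrop legible behind the tree; equal-width (not quartile) bins
make the split deterministic on spiky fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .io import DrugField, TreeConfig

__all__ = ["BandMap", "BackgroundPlane", "BAND_COLORS", "quantize_field", "background_plane"]

# band 0 = lowest concentration .. band 3 = highest
BAND_COLORS: Tuple[str, str, str, str] = ("blue", "cyan", "yellow", "red")

_BAND_RGBA = np.array(
    [
        (0.0, 0.0, 1.0, 1.0),  # blue
        (0.0, 1.0, 1.0, 1.0),  # cyan
        (1.0, 1.0, 0.0, 1.0),  # yellow
        (1.0, 0.0, 0.0, 1.0),  # red
    ]
)


@dataclass
class BandMap:
    """Field quantized to integer bands {0..3} with the 3 inner thresholds."""

    band: np.ndarray  # 2D int matrix, values in {0,1,2,3}
    thresholds: Tuple[float, float, float]
    extent: Tuple[float, float, float, float]

    def __post_init__(self) -> None:
        bad = set(np.unique(self.band)) - {0, 1, 2, 3}
        if bad:
            raise ValueError(f"band values outside 0..3: {sorted(bad)}")

    @property
    def bands_used(self) -> List[int]:
        return sorted(int(b) for b in np.unique(self.band))


def quantize_field(field: DrugField) -> BandMap:
    """Split a field into 4 equal-width bands on [min, max].

    Value v maps to ``floor(4 * (v - min) / (max - min))`` clipped to 3, so
    the maximum itself lands in the top band and other boundary values fall
    upward. A constant field degenerates to a single lowest band.
    """
    v = field.values
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        band = np.zeros_like(v, dtype=int)
        thresholds = (lo, lo, lo)
    else:
        band = np.clip(np.floor(4.0 * (v - lo) / (hi - lo)).astype(int), 0, 3)
        step = (hi - lo) / 4.0
        thresholds = (lo + step, lo + 2 * step, lo + 3 * step)
    return BandMap(band=band, thresholds=thresholds, extent=field.extent)


@dataclass
class BackgroundPlane:
    """A colored plane spanning the tissue rectangle at a fixed scene time.

    ``x_edges``/``z_edges`` delimit the band cells; ``facecolors`` holds one
    RGBA per cell. The plane sits at ``y_time`` (the tmin face, so the tree
    grows away from its environment map).
    """

    x_edges: np.ndarray  # shape (nx + 1,)
    z_edges: np.ndarray  # shape (ny + 1,)
    facecolors: np.ndarray  # shape (ny, nx, 4)
    y_time: float = 0.0

    @property
    def n_colors(self) -> int:
        flat = self.facecolors.reshape(-1, 4)
        return len(np.unique(flat, axis=0))


def background_plane(bands: Optional[BandMap], config: TreeConfig) -> Optional[BackgroundPlane]:
    """Build the backdrop plane, or ``None`` when gradients are switched off
    (or no band map is available)."""
    if not config.is_gradient or bands is None:
        return None
    ny, nx = bands.band.shape
    xmin, xmax, ymin, ymax = bands.extent
    return BackgroundPlane(
        x_edges=np.linspace(xmin, xmax, nx + 1),
        z_edges=np.linspace(ymin, ymax, ny + 1),
        facecolors=_BAND_RGBA[bands.band],
        y_time=0.0,
    )
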