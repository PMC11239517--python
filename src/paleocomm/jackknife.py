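"""Spatial jackknife resampling of bedding-plane surfaces.

Each replicate subsamples a surface to a fixed fraction (default 66%) of
its mapped area with a square box grown around a randomly seeded centre
point.  When a side of the growing box reaches the surface edge that side
freezes while the others keep expanding, so the captured region is the
growing square clipped to the mapped rectangle.  Replicates are drawn
independently and may overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import SurfaceMap


@dataclass(frozen=True)
class JackknifeConfig:
    fraction: float = 0.66
    n_samples: int = 1000
    seed: int = 0
    area_tolerance: float = 1e-6  # relative, on the captured area fraction

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must be in (0, 1)")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class JackknifeSample:
    surface_id: str
    sample_index: int
    centre: tuple[float, float]
    box: tuple[float, float, float, float]  # (x0, y0, x1, y1)
    captured_area_fraction: float
    indices: np.ndarray = field(repr=False)  # positional rows into specimens
    specimen_ids: np.ndarray = field(repr=False)


def _clipped_box(
    cx: float, cy: float, t: float,
    extent: tuple[float, float, float, float],
) -> tuple[float, float, float, float]:
    x0, y0, x1, y1 = extent
    return (max(x0, cx - t), max(y0, cy - t), min(x1, cx + t), min(y1, cy + t))


def _box_for_fraction(
    cx: float, cy: float, fraction: float,
    extent: tuple[float, float, float, float],
) -> tuple[float, float, float, float]:
    """Half-size of the clipped square capturing the target area fraction.

    The captured area is continuous and strictly increasing in the nominal
    half-size until the box covers the whole rectangle, so the halt point
    of the discrete expansion is the root of ``area(t) - fraction * A``.
    """
    x0, y0, x1, y1 = extent
    total = (x1 - x0) * (y1 - y0)

    def frac(t: float) -> float:
        bx0, by0, bx1, by1 = _clipped_box(cx, cy, t, extent)
        return (bx1 - bx0) * (by1 - by0) / total - fraction

    tmax = max(x1 - x0, y1 - y0)
    t = brentq(frac, 0.0, tmax, xtol=1e-12, rtol=1e-14)
    return _clipped_box(cx, cy, t, extent)


def generate_jackknife_samples(
    surface: SurfaceMap, cfg: JackknifeConfig
) -> list[JackknifeSample]:
    """Draw ``cfg.n_samples`` independent expanding-box subsamples.

    Deterministic under a fixed ``cfg.seed``; specimens on a box boundary
    are included (closed intervals).
    """
    x0, y0, x1, y1 = surface.extent
    if not (x1 > x0 and y1 > y0):
        raise ValueError(
            f"surface {surface.surface_id!r}: degenerate extent, cannot jackknife")
    rng = np.random.default_rng(cfg.seed)
    xs = surface.specimens["x"].to_numpy(float)
    ys = surface.specimens["y"].to_numpy(float)
    ids = surface.specimens["specimen_id"].to_numpy()
    total = (x1 - x0) * (y1 - y0)

    samples: list[JackknifeSample] = []
    centres = rng.uniform((x0, y0), (x1, y1), size=(cfg.n_samples, 2))
    for i, (cx, cy) in enumerate(centres):
        box = _box_for_fraction(cx, cy, cfg.fraction, surface.extent)
        bx0, by0, bx1, by1 = box
        captured = (bx1 - bx0) * (by1 - by0) / total
        if abs(captured - cfg.fraction) > cfg.area_tolerance * cfg.fraction:
            raise RuntimeError(
                f"captured fraction {captured:.6f} outside tolerance")
        mask = (xs >= bx0) & (xs <= bx1) & (ys >= by0) & (ys <= by1)
        idx = np.flatnonzero(mask)
        samples.append(
            JackknifeSample(
                surface_id=surface.surface_id,
                sample_index=i,
                centre=(float(cx), float(cy)),
                box=box,
                captured_area_fraction=float(captured),
                indices=idx,
                specimen_ids=ids[idx],
            )
        )
    return samples


def membership_table(samples: Sequence[JackknifeSample]) -> pd.DataFrame:
    """Long-format (surface_id, sample_index, specimen_id) membership table."""
    recs = [
        (s.surface_id, s.sample_index, sid)
        for s in samples
        for sid in s.specimen_ids
    ]
    return pd.DataFrame(recs, columns=["surface_id", "sample_index", "specimen_id"])
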