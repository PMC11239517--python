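"""Census-map data model, validation, derived geometry and retrodeformation.

A *surface* is one mapped bedding plane: every sessile specimen on it with
its position (metres), part measurements (millimetres) and a taxonomic
label.  Specimens are held as a :class:`pandas.DataFrame` inside a
:class:`SurfaceMap`; all downstream modules (jackknife, composition,
succession, tiering) consume that frame.

Derived per-specimen quantities follow fixed morphological conventions:

* height — reclining forms rest on the substrate, so their vertical reach
  is one-third of the (frond) width; erect forms reach
  ``stem_length + frond_length``.
* uptake interval — the vertical band occupied by the branching
  (feeding/exchange) part: ``[0, height]`` for recliners,
  ``[stem_length, height]`` for erect forms.
* areal coverage — a biomass proxy assembled from the tabulated
  measurements: ellipse areas ``pi/4 * length * width`` for disc and
  frond plus a ``stem_length * stem_width`` rectangle.

Tectonically sheared surfaces are restored ("retrodeformed") by an
area-preserving inverse pure shear calibrated on elongated holdfast discs
larger than 10 mm mean diameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TAX_LEVELS = ("species", "genus", "morphocategory", "taphomorph")
MORPHOGROUPS = ("reclining", "bradgatia", "pectinifrons", "upright_frond", "other")

#: columns every census CSV must provide
REQUIRED_COLUMNS = ("specimen_id", "x", "y", "taxon")

#: optional measurement columns, all millimetres except the orientation
MEASUREMENT_COLUMNS = (
    "disc_length",
    "disc_width",
    "stem_length",
    "stem_width",
    "frond_length",
    "frond_width",
)

OPTIONAL_COLUMNS = MEASUREMENT_COLUMNS + (
    "disc_orientation",
    "tax_level",
    "effaced_frond",
    "morphogroup",
    "true_taxon",
)

DERIVED_COLUMNS = ("height", "uptake_lo", "uptake_hi", "areal_coverage")


class SchemaError(ValueError):
    """A required column is absent or a column has an unusable dtype."""


class ValidationError(ValueError):
    """Row-level contract violation (duplicate ids, negative lengths...)."""


@dataclass(frozen=True)
class RetrodeformationParams:
    """Pure-shear calibration recovered from elongated holdfast discs.

    theta_deg is the mean long-axis orientation of the elongated discs
    (degrees anticlockwise from the map x-axis, axial, in [0, 180)),
    axial_ratio the mean long/short ratio (>= 1) of the qualifying discs
    and n_discs how many discs entered the calibration.
    """

    theta_deg: float
    axial_ratio: float
    n_discs: int

    def __post_init__(self) -> None:
        if self.axial_ratio < 1.0:
            raise ValueError("axial_ratio must be >= 1")


@dataclass
class SurfaceMap:
    """One bedding-plane community: specimen table plus mapped extent."""

    surface_id: str
    specimens: pd.DataFrame
    extent: tuple[float, float, float, float]  # (x0, y0, x1, y1), metres
    area_m2: float
    retrodeformed: bool = False
    retro_params: RetrodeformationParams | None = None
    flags: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_specimens(self) -> int:
        return len(self.specimens)

    @property
    def extent_area(self) -> float:
        x0, y0, x1, y1 = self.extent
        return (x1 - x0) * (y1 - y0)

    def copy(self) -> "SurfaceMap":
        return replace(
            self,
            specimens=self.specimens.copy(),
            flags=list(self.flags),
            meta=dict(self.meta),
        )


def _coerce_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Fill optional columns with defaults and coerce dtypes in place."""
    df = df.copy()
    for col in MEASUREMENT_COLUMNS + ("disc_orientation",):
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "tax_level" not in df.columns:
        df["tax_level"] = "species"
    df["tax_level"] = df["tax_level"].fillna("species")
    if "effaced_frond" not in df.columns:
        df["effaced_frond"] = False
    df["effaced_frond"] = (
        df["effaced_frond"].map(
            {True: True, False: False, "True": True, "False": False,
             "true": True, "false": False, 1: True, 0: False, "1": True, "0": False}
        ).astype("boolean").fillna(False).astype(bool)
    )
    if "morphogroup" not in df.columns:
        df["morphogroup"] = "other"
    df["morphogroup"] = df["morphogroup"].fillna("other")
    df["specimen_id"] = df["specimen_id"].astype(str)
    df["taxon"] = df["taxon"].astype(str)
    df["x"] = pd.to_numeric(df["x"], errors="raise")
    df["y"] = pd.to_numeric(df["y"], errors="raise")
    return df


def _validate(df: pd.DataFrame, surface_id: str) -> None:
    dup = df["specimen_id"][df["specimen_id"].duplicated()]
    if len(dup):
        raise ValidationError(
            f"surface {surface_id!r}: duplicate specimen_id(s): "
            + ", ".join(sorted(dup.unique())[:10])
        )
    bad_level = ~df["tax_level"].isin(TAX_LEVELS)
    if bad_level.any():
        raise ValidationError(
            f"surface {surface_id!r}: unknown tax_level values "
            f"{sorted(df.loc[bad_level, 'tax_level'].unique())}"
        )
    bad_group = ~df["morphogroup"].isin(MORPHOGROUPS)
    if bad_group.any():
        raise ValidationError(
            f"surface {surface_id!r}: unknown morphogroup values "
            f"{sorted(df.loc[bad_group, 'morphogroup'].unique())}"
        )
    for col in MEASUREMENT_COLUMNS:
        neg = df[col] < 0
        if neg.any():
            rows = df.loc[neg, "specimen_id"].tolist()[:10]
            raise ValidationError(
                f"surface {surface_id!r}: negative {col} for specimen(s) {rows}"
            )
    if df["x"].isna().any() or df["y"].isna().any():
        rows = df.loc[df["x"].isna() | df["y"].isna(), "specimen_id"].tolist()[:10]
        raise ValidationError(
            f"surface {surface_id!r}: missing coordinates for specimen(s) {rows}"
        )


def read_surface_map(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    surface_id: str | None = None,
    extent: tuple[float, float, float, float] | None = None,
    area_m2: float | None = None,
) -> SurfaceMap:
    """Read and validate one census-map CSV.

    Parameters
    ----------
    path
        CSV with a header row; empty cells are missing values.
    schema
        Optional mapping ``{canonical_name: column_name_in_file}`` for files
        whose headers differ from the canonical schema.
    surface_id
        Defaults to the file stem.
    extent, area_m2
        The mapped rectangle (metres) and its area.  By default the extent
        is the bounding box of the specimen positions and ``area_m2`` the
        extent area.

    Derived geometry columns are *not* computed here; call
    :func:`derive_geometry` on the result.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    df = _coerce_frame(df)
    sid = surface_id or path.stem
    _validate(df, sid)
    if extent is None:
        if len(df):
            extent = (
                float(df["x"].min()),
                float(df["y"].min()),
                float(df["x"].max()),
                float(df["y"].max()),
            )
        else:
            extent = (0.0, 0.0, 1.0, 1.0)
    x0, y0, x1, y1 = extent
    inside = (df["x"] >= x0) & (df["x"] <= x1) & (df["y"] >= y0) & (df["y"] <= y1)
    if not inside.all():
        rows = df.loc[~inside, "specimen_id"].tolist()[:10]
        raise ValidationError(f"surface {sid!r}: specimen(s) outside extent: {rows}")
    if area_m2 is None:
        area_m2 = (x1 - x0) * (y1 - y0)
    if not area_m2 > 0:
        raise ValidationError(f"surface {sid!r}: non-positive area")
    return SurfaceMap(surface_id=sid, specimens=df.reset_index(drop=True),
                      extent=extent, area_m2=float(area_m2))


def surface_from_frame(
    df: pd.DataFrame,
    surface_id: str,
    extent: tuple[float, float, float, float],
    area_m2: float | None = None,
) -> SurfaceMap:
    """Build a validated SurfaceMap from an in-memory specimen table."""
    df = _coerce_frame(df)
    _validate(df, surface_id)
    x0, y0, x1, y1 = extent
    if area_m2 is None:
        area_m2 = (x1 - x0) * (y1 - y0)
    return SurfaceMap(surface_id=surface_id, specimens=df.reset_index(drop=True),
                      extent=extent, area_m2=float(area_m2))


def derive_geometry(surface: SurfaceMap) -> SurfaceMap:
    """Populate height, uptake interval and areal coverage (idempotent).

    Conventions: reclining forms have ``height = width / 3`` (frond width,
    falling back to disc width) and uptake interval ``[0, height]``; all
    other forms have ``height = stem_length + frond_length`` and uptake
    interval ``[stem_length, height]`` (a missing part contributes 0).
    Areal coverage sums the disc and frond ellipses and the stem rectangle.
    Specimens with no measurable part get height 0 and coverage 0 and are
    counted in the surface flags.
    """
    out = surface.copy()
    df = out.specimens
    m = {c: df[c].fillna(0.0).to_numpy(float) for c in MEASUREMENT_COLUMNS}

    reclining = (df["morphogroup"] == "reclining").to_numpy()
    rec_width = np.where(m["frond_width"] > 0, m["frond_width"], m["disc_width"])
    height = np.where(reclining, rec_width / 3.0,
                      m["stem_length"] + m["frond_length"])
    lo = np.where(reclining, 0.0, m["stem_length"])
    hi = np.where(reclining, height, m["stem_length"] + m["frond_length"])

    coverage = (
        np.pi / 4.0 * (m["disc_length"] * m["disc_width"]
                       + m["frond_length"] * m["frond_width"])
        + m["stem_length"] * m["stem_width"]
    )

    unmeasured = ~np.any([m[c] > 0 for c in MEASUREMENT_COLUMNS], axis=0)
    n_unmeasured = int(unmeasured.sum())
    if n_unmeasured:
        logger.warning(
            "surface %s: %d specimen(s) with no measurable part (height and "
            "coverage set to 0)", surface.surface_id, n_unmeasured)
        flag = f"unmeasured_specimens={n_unmeasured}"
        if flag not in out.flags:
            out.flags.append(flag)

    df["height"] = height
    df["uptake_lo"] = lo
    df["uptake_hi"] = hi
    df["areal_coverage"] = coverage
    return out


# ---------------------------------------------------------------------------
# retrodeformation
# ---------------------------------------------------------------------------

def _transform_ellipses(
    M: np.ndarray,
    lengths: np.ndarray,
    widths: np.ndarray,
    angles_deg: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply a 2x2 linear map to ellipses given as (long, short, angle).

    Returns the transformed (long, short, angle_deg) arrays.  Uses the
    closed-form SVD of the 2x2 composite map per ellipse.
    """
    phi = np.radians(angles_deg)
    a = lengths / 2.0
    b = widths / 2.0
    c, s = np.cos(phi), np.sin(phi)
    # B = M @ Rot(phi) @ diag(a, b), columns are the mapped semi-axes
    b11 = M[0, 0] * c * a + M[0, 1] * s * a
    b21 = M[1, 0] * c * a + M[1, 1] * s * a
    b12 = -M[0, 0] * s * b + M[0, 1] * c * b
    b22 = -M[1, 0] * s * b + M[1, 1] * c * b
    # singular values of B from trace/determinant of B B^T
    t = b11**2 + b12**2 + b21**2 + b22**2
    d = b11 * b22 - b12 * b21
    disc = np.sqrt(np.maximum(t**2 - 4.0 * d**2, 0.0))
    s1 = np.sqrt((t + disc) / 2.0)
    s2 = np.sqrt(np.maximum((t - disc) / 2.0, 0.0))
    p = b11**2 + b12**2
    r = b21**2 + b22**2
    q = b11 * b21 + b12 * b22
    theta = 0.5 * np.arctan2(2.0 * q, p - r)
    return 2.0 * s1, 2.0 * s2, np.degrees(theta) % 180.0


def _qualifying_discs(df: pd.DataFrame, min_diameter_mm: float) -> pd.DataFrame:
    """Discs with both axes measured and mean diameter above the cutoff."""
    ok = (
        df["disc_length"].notna()
        & df["disc_width"].notna()
        & (df["disc_length"] > 0)
        & (df["disc_width"] > 0)
        & ((df["disc_length"] + df["disc_width"]) / 2.0 > min_diameter_mm)
        & df["disc_orientation"].notna()
    )
    return df.loc[ok]


def disc_axial_stats(
    surface: SurfaceMap, min_diameter_mm: float = 10.0
) -> tuple[float, float, int]:
    """Mean long-axis orientation and mean axial ratio of qualifying discs.

    Orientation is the axial circular mean over discs more elongated than
    1.01 (doubling the angles so 0 and 180 degrees coincide); the ratio is
    the mean long/short ratio over all qualifying discs.
    """
    discs = _qualifying_discs(surface.specimens, min_diameter_mm)
    if discs.empty:
        return 0.0, 1.0, 0
    long_ax = np.maximum(discs["disc_length"], discs["disc_width"]).to_numpy(float)
    short_ax = np.minimum(discs["disc_length"], discs["disc_width"]).to_numpy(float)
    ang = discs["disc_orientation"].to_numpy(float)
    # where the recorded width exceeds the length the long axis is rotated 90 deg
    ang = np.where(discs["disc_width"] > discs["disc_length"], ang + 90.0, ang)
    ratio = long_ax / short_ax
    elong = ratio > 1.01
    if elong.any():
        dbl = np.radians(2.0 * ang[elong])
        theta = 0.5 * np.degrees(np.arctan2(np.sin(dbl).mean(), np.cos(dbl).mean()))
    else:
        theta = 0.0
    return float(theta % 180.0), float(ratio.mean()), int(len(discs))


def retrodeform(
    surface: SurfaceMap,
    n_min: int = 10,
    min_diameter_mm: float = 10.0,
) -> SurfaceMap:
    """Restore a tectonically sheared surface using holdfast-disc ellipticity.

    Elongated discs larger than ``min_diameter_mm`` mean diameter calibrate
    the strain: their mean long-axis orientation ``theta`` and mean axial
    ratio ``R``.  An area-preserving inverse pure shear — rotate by
    ``-theta``, scale by ``(1/sqrt(R), sqrt(R))``, rotate back — is applied
    to specimen coordinates and to the disc ellipses (whose orientations
    are recorded); stem and frond measurements carry no orientation and are
    left unchanged.  After the transform the mean qualifying-disc axial
    ratio is ~1.

    With fewer than ``n_min`` qualifying discs the surface is returned
    unchanged with a ``retrodeformation_skipped`` flag.
    """
    theta_deg, ratio, n_discs = disc_axial_stats(surface, min_diameter_mm)
    out = surface.copy()
    if n_discs < n_min:
        logger.warning(
            "surface %s: only %d qualifying disc(s) (< %d); not retrodeformed",
            surface.surface_id, n_discs, n_min)
        out.flags.append("retrodeformation_skipped")
        return out

    th = np.radians(theta_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    scale = np.diag([1.0 / np.sqrt(ratio), np.sqrt(ratio)])
    M = rot @ scale @ rot.T  # det == 1: area preserving

    df = out.specimens
    cx = (surface.extent[0] + surface.extent[2]) / 2.0
    cy = (surface.extent[1] + surface.extent[3]) / 2.0
    xy = df[["x", "y"]].to_numpy(float) - (cx, cy)
    df[["x", "y"]] = xy @ M.T + (cx, cy)

    has_disc = (
        df["disc_length"].notna() & df["disc_width"].notna()
        & df["disc_orientation"].notna()
        & (df["disc_length"] > 0) & (df["disc_width"] > 0)
    ).to_numpy()
    if has_disc.any():
        ln = df.loc[has_disc, "disc_length"].to_numpy(float)
        wd = df.loc[has_disc, "disc_width"].to_numpy(float)
        an = df.loc[has_disc, "disc_orientation"].to_numpy(float)
        an = np.where(wd > ln, an + 90.0, an)
        long_ax, short_ax = np.maximum(ln, wd), np.minimum(ln, wd)
        nl, nw, na = _transform_ellipses(M, long_ax, short_ax, an)
        df.loc[has_disc, "disc_length"] = nl
        df.loc[has_disc, "disc_width"] = nw
        df.loc[has_disc, "disc_orientation"] = na

    # extent: bounding box of the transformed mapped rectangle
    x0, y0, x1, y1 = surface.extent
    corners = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]]) - (cx, cy)
    tc = corners @ M.T + (cx, cy)
    out.extent = (float(tc[:, 0].min()), float(tc[:, 1].min()),
                  float(tc[:, 0].max()), float(tc[:, 1].max()))
    out.retrodeformed = True
    out.retro_params = RetrodeformationParams(theta_deg, ratio, n_discs)
    if "height" in df.columns:
        out = derive_geometry(out)
    return out


def write_specimens_csv(surface: SurfaceMap, path: str | Path) -> None:
    """Write the (possibly derived) specimen table as CSV."""
    surface.specimens.to_csv(path, index=False)
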