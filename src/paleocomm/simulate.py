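"""Synthetic bedding-plane communities for testing the analysis pipeline.

The generator emulates the statistical structure the analyses assume:
multinomial per-taxon abundances, uniform-Poisson or Thomas-cluster
spatial point patterns, lognormal part sizes with fixed width allometry,
a controllable covariance between abundance rank and body size (the
successional state), optional tectonic forward shear for retrodeformation
tests, and an effaced-frond recording probability.  Effaced specimens
keep their true identity in a hidden ``true_taxon`` column so relabelling
treatments can be scored against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SurfaceMap, _transform_ellipses, derive_geometry, surface_from_frame

SUCCESSION_STATES = ("early", "intermediate", "late")


@dataclass(frozen=True)
class TaxonSpec:
    """Generative description of one taxon.

    Size distributions are lognormal, given as (median mm, log-sd); widths
    follow the fixed allometry ``width = a * length``.  ``spatial`` is
    either ``uniform`` (Poisson) or ``thomas`` (cluster process with
    Poisson parents, Gaussian offspring displacement).
    """

    name: str
    morphogroup: str = "upright_frond"
    abundance_weight: float = 1.0
    spatial: str = "uniform"
    parents_per_m2: float = 0.3
    cluster_radius_m: float = 0.4
    frond_length: tuple[float, float] = (60.0, 0.3)
    width_allometry: float = 0.5
    stem_length: tuple[float, float] | None = None
    disc_diameter: tuple[float, float] | None = None

    @property
    def reclining(self) -> bool:
        return self.morphogroup == "reclining"

    def __post_init__(self) -> None:
        if self.abundance_weight <= 0:
            raise ValueError("abundance_weight must be positive")
        if not 0 < self.width_allometry <= 1:
            raise ValueError("width_allometry must be in (0, 1]")
        if self.spatial not in ("uniform", "thomas"):
            raise ValueError(f"unknown spatial mode {self.spatial!r}")


@dataclass(frozen=True)
class SyntheticSurfaceConfig:
    surface_id: str
    taxa: tuple[TaxonSpec, ...]
    total_n: int = 500
    extent: tuple[float, float, float, float] = (0.0, 0.0, 10.0, 10.0)
    succession_state: str | None = None
    shear: tuple[float, float] | None = None  # (factor >= 1, orientation deg)
    effaced_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_n < 1:
            raise ValueError("total_n must be >= 1")
        if not 0.0 <= self.effaced_fraction < 1.0:
            raise ValueError("effaced_fraction must be in [0, 1)")
        x0, y0, x1, y1 = self.extent
        if not (x1 > x0 and y1 > y0):
            raise ValueError("zero-area extent")
        if self.succession_state is not None \
                and self.succession_state not in SUCCESSION_STATES:
            raise ValueError(f"unknown succession_state {self.succession_state!r}")


def _apply_succession_state(taxa: Sequence[TaxonSpec],
                            state: str | None) -> list[TaxonSpec]:
    """Couple abundance rank and body size to plant a successional signal.

    Per-specimen areal coverage scales with the square of frond length, so
    setting frond-length medians proportional to ``1 / sqrt(weight)``
    spreads biomass evenly across taxa while abundance stays uneven: the
    most abundant taxon is the smallest, a rare large frond joins the
    community, and abundance dominance (W > 0) is expected.  ``late``
    mirrors this (medians proportional to ``sqrt(weight)``) so biomass
    concentrates in the dominant taxon and W < 0 is expected.
    ``intermediate`` leaves sizes as configured.  The overall size scale
    (geometric mean of the configured medians) is preserved.
    """
    taxa = list(taxa)
    if state in (None, "intermediate"):
        return taxa
    total_w = sum(t.abundance_weight for t in taxa)
    extreme = "Rare large frond" if state == "early" else "Rare small frond"
    taxa.append(TaxonSpec(
        name=extreme, morphogroup="upright_frond",
        abundance_weight=0.03 * total_w,
        frond_length=(np.exp(np.mean([np.log(t.frond_length[0])
                                      for t in taxa])), 0.25)))
    w = np.array([t.abundance_weight for t in taxa])
    w = w / w.sum()
    base = np.exp(np.mean([np.log(t.frond_length[0]) for t in taxa]))
    g = np.exp(np.mean(np.log(w)))
    expo = -0.5 if state == "early" else 0.5
    medians = base * (w / g) ** expo
    return [replace(t, frond_length=(float(m), t.frond_length[1]))
            for t, m in zip(taxa, medians)]


def _lognormal(rng: np.random.Generator, median: float, sigma: float,
               n: int) -> np.ndarray:
    return median * np.exp(sigma * rng.standard_normal(n))


def _positions(rng: np.random.Generator, spec: TaxonSpec, n: int,
               extent: tuple[float, float, float, float]) -> np.ndarray:
    x0, y0, x1, y1 = extent
    if spec.spatial == "uniform" or n == 0:
        return rng.uniform((x0, y0), (x1, y1), size=(n, 2))
    area = (x1 - x0) * (y1 - y0)
    n_parents = max(1, int(rng.poisson(spec.parents_per_m2 * area)))
    parents = rng.uniform((x0, y0), (x1, y1), size=(n_parents, 2))
    pts = np.empty((n, 2))
    for i in range(n):
        for _ in range(200):  # redraw offspring falling off the map
            p = parents[rng.integers(n_parents)]
            cand = p + rng.normal(0.0, spec.cluster_radius_m, size=2)
            if x0 <= cand[0] <= x1 and y0 <= cand[1] <= y1:
                pts[i] = cand
                break
        else:
            pts[i] = rng.uniform((x0, y0), (x1, y1))
    return pts


def generate_surface(cfg: SyntheticSurfaceConfig) -> SurfaceMap:
    """Draw one synthetic surface; deterministic under ``cfg.seed``.

    The returned :class:`SurfaceMap` has derived geometry populated and a
    ``meta['truth']`` record of the generating configuration.
    """
    rng = np.random.default_rng(cfg.seed)
    taxa = _apply_succession_state(cfg.taxa, cfg.succession_state)
    weights = np.array([t.abundance_weight for t in taxa], float)
    counts = rng.multinomial(cfg.total_n, weights / weights.sum())

    frames = []
    for spec, n in zip(taxa, counts):
        if n == 0:
            continue
        pos = _positions(rng, spec, n, cfg.extent)
        fl = _lognormal(rng, *spec.frond_length, n)
        fw = spec.width_allometry * fl
        rec = {
            "taxon": spec.name,
            "tax_level": "species",
            "morphogroup": spec.morphogroup,
            "x": pos[:, 0],
            "y": pos[:, 1],
            "frond_length": fl,
            "frond_width": fw,
        }
        if spec.stem_length is not None:
            sl = _lognormal(rng, *spec.stem_length, n)
            rec["stem_length"] = sl
            rec["stem_width"] = 0.15 * sl
        if spec.disc_diameter is not None:
            dd = _lognormal(rng, *spec.disc_diameter, n)
            ecc = np.exp(0.02 * rng.standard_normal(n))
            rec["disc_length"] = dd * ecc
            rec["disc_width"] = dd / ecc
            rec["disc_orientation"] = rng.uniform(0.0, 180.0, n)
        frames.append(pd.DataFrame(rec))
    df = pd.concat(frames, ignore_index=True)
    df["true_taxon"] = df["taxon"]

    frondose = df["morphogroup"] != "reclining"
    if cfg.effaced_fraction > 0:
        effaced = frondose & (rng.random(len(df)) < cfg.effaced_fraction)
        df.loc[effaced, "taxon"] = "effaced_frond"
        df.loc[effaced, "tax_level"] = "morphocategory"
        df["effaced_frond"] = effaced

    if cfg.shear is not None:
        factor, orient = cfg.shear
        df = _forward_shear(df, cfg.extent, factor, orient)

    df.insert(0, "specimen_id", [f"{cfg.surface_id}-{i:05d}"
                                 for i in range(len(df))])
    extent = cfg.extent
    if cfg.shear is not None:
        xs, ys = df["x"], df["y"]
        extent = (float(xs.min()), float(ys.min()),
                  float(xs.max()), float(ys.max()))
    surface = surface_from_frame(df, cfg.surface_id, extent)
    surface = derive_geometry(surface)
    surface.meta["truth"] = {
        "taxa": [t.name for t in taxa],
        "counts": {t.name: int(c) for t, c in zip(taxa, counts)},
        "succession_state": cfg.succession_state,
        "effaced_fraction": cfg.effaced_fraction,
        "shear": cfg.shear,
        "seed": cfg.seed,
    }
    return surface


def _forward_shear(df: pd.DataFrame, extent, factor: float,
                   orientation_deg: float) -> pd.DataFrame:
    """Area-preserving pure shear stretching the orientation axis.

    Initially near-circular discs acquire axial ratio ~``factor`` aligned
    with the shear orientation, as on a tectonically deformed surface.
    """
    th = np.radians(orientation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    M = rot @ np.diag([np.sqrt(factor), 1.0 / np.sqrt(factor)]) @ rot.T
    df = df.copy()
    cx = (extent[0] + extent[2]) / 2.0
    cy = (extent[1] + extent[3]) / 2.0
    xy = df[["x", "y"]].to_numpy(float) - (cx, cy)
    df[["x", "y"]] = xy @ M.T + (cx, cy)
    if "disc_length" in df.columns:
        has = df["disc_length"].notna().to_numpy()
        if has.any():
            ln = df.loc[has, "disc_length"].to_numpy(float)
            wd = df.loc[has, "disc_width"].to_numpy(float)
            an = df.loc[has, "disc_orientation"].to_numpy(float)
            nl, nw, na = _transform_ellipses(M, np.maximum(ln, wd),
                                             np.minimum(ln, wd),
                                             np.where(wd > ln, an + 90, an))
            df.loc[has, "disc_length"] = nl
            df.loc[has, "disc_width"] = nw
            df.loc[has, "disc_orientation"] = na
    return df


# ---------------------------------------------------------------------------
# canned community types and the study-shaped fixture
# ---------------------------------------------------------------------------

def _taxa_for_type(ctype: str) -> tuple[TaxonSpec, ...]:
    """Realistic Avalon-style community templates, one dominant per type."""
    charnia = dict(stem_length=(25.0, 0.3), disc_diameter=(18.0, 0.25))
    if ctype == "fractofusus_misrai":
        return (
            TaxonSpec("Fractofusus misrai", "reclining", 0.65, "thomas",
                      frond_length=(90.0, 0.35), width_allometry=0.35),
            TaxonSpec("Charnia masoni", "upright_frond", 0.12,
                      frond_length=(110.0, 0.35), **charnia),
            TaxonSpec("Bradgatia sp", "bradgatia", 0.10,
                      frond_length=(55.0, 0.3), width_allometry=0.8),
            TaxonSpec("Charniodiscus procerus", "upright_frond", 0.08,
                      frond_length=(95.0, 0.3), stem_length=(40.0, 0.3),
                      disc_diameter=(22.0, 0.25)),
            TaxonSpec("Thectardis avalonensis", "other", 0.05,
                      frond_length=(70.0, 0.3)),
        )
    if ctype == "fractofusus_andersoni":
        return (
            TaxonSpec("Fractofusus andersoni", "reclining", 0.78, "thomas",
                      frond_length=(65.0, 0.35), width_allometry=0.45),
            TaxonSpec("Pectinifrons abyssalis", "pectinifrons", 0.08,
                      frond_length=(120.0, 0.3), width_allometry=0.3),
            TaxonSpec("Charnia masoni", "upright_frond", 0.07,
                      frond_length=(110.0, 0.35), **charnia),
            TaxonSpec("Primocandelabrum sp", "upright_frond", 0.07,
                      frond_length=(60.0, 0.3), stem_length=(35.0, 0.3),
                      disc_diameter=(25.0, 0.25)),
        )
    if ctype == "bradgatia":
        return (
            TaxonSpec("Bradgatia sp", "bradgatia", 0.70, "thomas",
                      frond_length=(60.0, 0.35), width_allometry=0.8),
            TaxonSpec("Fractofusus misrai", "reclining", 0.10,
                      frond_length=(90.0, 0.35), width_allometry=0.35),
            TaxonSpec("Charniodiscus spinosus", "upright_frond", 0.10,
                      frond_length=(85.0, 0.3), stem_length=(45.0, 0.3),
                      disc_diameter=(20.0, 0.25)),
            TaxonSpec("Culmofrons plumosa", "upright_frond", 0.10,
                      frond_length=(75.0, 0.3), stem_length=(55.0, 0.3),
                      disc_diameter=(16.0, 0.25)),
        )
    if ctype == "frond":
        return (
            TaxonSpec("Charnia masoni", "upright_frond", 0.35,
                      frond_length=(110.0, 0.35), **charnia),
            TaxonSpec("Charniodiscus procerus", "upright_frond", 0.25,
                      frond_length=(95.0, 0.3), stem_length=(40.0, 0.3),
                      disc_diameter=(22.0, 0.25)),
            TaxonSpec("Primocandelabrum sp", "upright_frond", 0.20,
                      frond_length=(60.0, 0.3), stem_length=(35.0, 0.3),
                      disc_diameter=(25.0, 0.25)),
            TaxonSpec("Culmofrons plumosa", "upright_frond", 0.12,
                      frond_length=(75.0, 0.3), stem_length=(55.0, 0.3),
                      disc_diameter=(16.0, 0.25)),
            TaxonSpec("Beothukis mistakensis", "upright_frond", 0.08,
                      frond_length=(50.0, 0.3)),
        )
    raise ValueError(f"unknown community type {ctype!r}")


COMMUNITY_TYPES = ("fractofusus_misrai", "fractofusus_andersoni",
                   "bradgatia", "frond")


@dataclass
class FixtureSurface:
    surface: SurfaceMap
    community_type: str
    succession_state: str


def generate_study_fixture(
    seed: int = 0,
    sizes: Sequence[int] = (1500, 600, 250),
    effaced_fractions: Sequence[float] = (0.0, 0.15, 0.35),
) -> list[FixtureSurface]:
    """Twelve surfaces spanning four Community Types x three stages.

    Surface sizes span a few hundred to a couple of thousand specimens and
    effaced-frond fractions range up to 0.35, mirroring census maps where
    poorly preserved fronds can exceed 30% of a community.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(COMMUNITY_TYPES) * len(SUCCESSION_STATES))
    fixture = []
    k = 0
    for ti, ctype in enumerate(COMMUNITY_TYPES):
        for si, state in enumerate(SUCCESSION_STATES):
            cfg = SyntheticSurfaceConfig(
                surface_id=f"SYN-{ctype}-{state}",
                taxa=_taxa_for_type(ctype),
                total_n=int(sizes[(ti + si) % len(sizes)]),
                succession_state=state,
                effaced_fraction=float(effaced_fractions[(ti + si)
                                                         % len(effaced_fractions)]),
                seed=int(seeds[k] % (2**31)),
            )
            fixture.append(FixtureSurface(generate_surface(cfg), ctype, state))
            k += 1
    return fixture


def generate_planted_w_surface(
    target_w: float,
    surface_id: str,
    total_n: int = 1500,
    p_abundant: float = 0.7,
    seed: int = 0,
    extent: tuple[float, float, float, float] = (0.0, 0.0, 10.0, 10.0),
) -> SurfaceMap:
    """Two-taxon surface whose full-surface W is planted at ``target_w``.

    With two taxa only the first rank separates the ABC curves, so
    ``W = (A1 - B1) / 50`` with ``A1 = 100 * p_abundant``.  The rare
    taxon's per-specimen coverage is scaled to hit the biomass split that
    yields the target; positions are uniform so spatial jackknifing
    preserves the composition in expectation.  |target_w| must be at most
    ``2 * p_abundant - 1``.
    """
    if not 0.5 < p_abundant < 1.0:
        raise ValueError("p_abundant must be in (0.5, 1)")
    a1 = 100.0 * p_abundant
    b1 = a1 - 50.0 * target_w
    if not 50.0 <= b1 <= 100.0:
        raise ValueError(f"target_w {target_w} unreachable at p={p_abundant}")
    q_rare = b1 if target_w <= 0 else 100.0 - b1
    if target_w > 0 and b1 >= 50.0:
        # abundant taxon holds the top biomass share b1 < a1
        q_rare = 100.0 - b1

    rng = np.random.default_rng(seed)
    n1 = int(round(p_abundant * total_n))
    n2 = total_n - n1
    # per-specimen coverage ratio needed for the rare taxon
    cov_ratio = (q_rare / (100.0 - q_rare)) * (n1 / n2)
    base_len, base_wid = 30.0, 15.0
    scale = np.sqrt(cov_ratio)
    frames = []
    for name, n, ln, wd in (
        ("Abundant small taxon", n1, base_len, base_wid),
        ("Rare large taxon", n2, base_len * scale, base_wid * scale),
    ):
        noise = np.exp(0.05 * rng.standard_normal(n))
        frames.append(pd.DataFrame({
            "taxon": name,
            "tax_level": "species",
            "morphogroup": "upright_frond",
            "x": rng.uniform(extent[0], extent[2], n),
            "y": rng.uniform(extent[1], extent[3], n),
            "frond_length": ln * noise,
            "frond_width": wd * noise,
        }))
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "specimen_id", [f"{surface_id}-{i:05d}" for i in range(len(df))])
    surface = derive_geometry(surface_from_frame(df, surface_id, extent))
    surface.meta["truth"] = {"target_w": target_w, "seed": seed}
    return surface


def write_fixture(fixture: Sequence[FixtureSurface], outdir: str | Path) -> Path:
    """Write fixture CSVs, a surfaces manifest (YAML) and a truth sidecar."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"surfaces": []}
    truth = {}
    for fs in fixture:
        s = fs.surface
        fname = f"{s.surface_id}.csv"
        s.specimens.to_csv(outdir / fname, index=False)
        x0, y0, x1, y1 = s.extent
        manifest["surfaces"].append({
            "surface_id": s.surface_id,
            "file": fname,
            "extent": [float(x0), float(y0), float(x1), float(y1)],
            "area_m2": float(s.area_m2),
            "jackknife": True,
        })
        truth[s.surface_id] = {
            "community_type": fs.community_type,
            "succession_state": fs.succession_state,
            **s.meta.get("truth", {}),
        }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    return outdir / "manifest.yaml"
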