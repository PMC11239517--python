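"""Vertical tiering metrics: distinct vertical stratification (DVS) scores.

Sessile epifauna partition the water column; DVS quantifies how exclusive
each taxon's vertical occupation is within a community.

* DVS^u — the proportion of a taxon's uptake zone (the union of its
  specimens' uptake intervals, in mm above the substrate) that overlaps no
  other taxon's uptake zone.  Computed with exact interval arithmetic.
* DVS^h — the proportion of a taxon's specimens whose height is matched
  by no other taxon, where "matched" means the height falls inside the
  closed [min, max] height envelope of at least one other taxon.

Community scores are means over per-taxon scores, either unweighted or
abundance-weighted (weights n_t / N over the scored taxa).  Communities
are classed high (> 0.70), medium (0.40-0.70) or low (< 0.40) tiering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .composition import EffacedTreatment, STANDARD, apply_treatment, taxon_labels
from .io import SurfaceMap
from .succession import RegressionResult, ols_regression

logger = logging.getLogger(__name__)

TIER_HIGH = 0.70
TIER_LOW = 0.40

#: morphogroups entering the morphogroup-level tiering analysis
TIERING_MORPHOGROUPS = ("reclining", "bradgatia", "pectinifrons", "upright_frond")

Interval = tuple[float, float]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of closed intervals as a sorted list of disjoint intervals.

    Zero-length intervals are kept only if isolated (they have measure 0
    either way); touching intervals are merged.
    """
    ints = sorted((float(lo), float(hi)) for lo, hi in intervals if hi >= lo)
    merged: list[Interval] = []
    for lo, hi in ints:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def interval_measure(intervals: Iterable[Interval]) -> float:
    return float(sum(hi - lo for lo, hi in merge_intervals(intervals)))


def intersect_measure(a: Sequence[Interval], b: Sequence[Interval]) -> float:
    """Measure of the intersection of two disjoint-interval unions."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    total = 0.0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


@dataclass
class TaxonTierProfile:
    taxon: str
    n: int
    heights: np.ndarray = field(repr=False)
    zone: list[Interval] = field(default_factory=list)

    @property
    def zone_measure(self) -> float:
        return interval_measure(self.zone)

    @property
    def height_envelope(self) -> Interval:
        return float(self.heights.min()), float(self.heights.max())


def build_profiles(
    surface: SurfaceMap,
    level: str = "species",
    treatment: EffacedTreatment = STANDARD,
    min_n: int | None = None,
) -> list[TaxonTierProfile]:
    """Per-taxon tier profiles (heights + merged uptake zone) for a surface."""
    df = apply_treatment(surface.specimens, treatment)
    if "uptake_lo" not in df.columns:
        raise ValueError("derive_geometry must run before tiering analysis")
    labels = taxon_labels(df, level)
    profiles = []
    for taxon, sub in df.groupby(labels.to_numpy()):
        if min_n is not None and len(sub) < min_n:
            continue
        zone = merge_intervals(zip(sub["uptake_lo"], sub["uptake_hi"]))
        profiles.append(TaxonTierProfile(
            taxon=str(taxon), n=len(sub),
            heights=sub["height"].to_numpy(float), zone=zone))
    return profiles


def taxon_dvs_u(target: TaxonTierProfile,
                others: Sequence[TaxonTierProfile]) -> float:
    """Fraction of the target's uptake zone overlapping no other taxon."""
    m = target.zone_measure
    if m <= 0:
        raise ValueError(f"taxon {target.taxon!r}: zero-measure uptake zone")
    union_others = merge_intervals(
        iv for o in others for iv in o.zone)
    return 1.0 - intersect_measure(target.zone, union_others) / m


def taxon_dvs_h(target: TaxonTierProfile,
                others: Sequence[TaxonTierProfile]) -> float:
    """Fraction of target specimens whose height no other taxon matches."""
    if target.n < 1:
        raise ValueError("empty taxon profile")
    h = target.heights
    matched = np.zeros(len(h), dtype=bool)
    for o in others:
        lo, hi = o.height_envelope
        matched |= (h >= lo) & (h <= hi)
    return float((~matched).mean())


@dataclass
class TieringResult:
    surface_id: str
    per_taxon: pd.DataFrame  # taxon, n, dvs_h, dvs_u
    dvs_h: float
    dvs_u: float
    weighted_dvs_h: float
    weighted_dvs_u: float
    stem_proportion: float
    n_excluded: int = 0

    def tier_class(self, metric: str = "weighted_dvs_u") -> str:
        return classify_tier(getattr(self, metric))


def classify_tier(score: float) -> str:
    if score > TIER_HIGH:
        return "high"
    if score < TIER_LOW:
        return "low"
    return "medium"


def _dvs_from_profiles(profiles: Sequence[TaxonTierProfile],
                       surface_id: str,
                       stem_proportion: float) -> TieringResult:
    if len(profiles) < 2:
        raise ValueError(
            f"surface {surface_id!r}: need >= 2 eligible taxa for DVS")
    rows = []
    excluded = 0
    for i, p in enumerate(profiles):
        others = [o for j, o in enumerate(profiles) if j != i]
        h_score = taxon_dvs_h(p, others)
        if p.zone_measure > 0:
            u_score = taxon_dvs_u(p, others)
        else:
            u_score = np.nan
            excluded += 1
            logger.info("taxon %r: zero-measure uptake zone, excluded from "
                        "DVS^u", p.taxon)
        rows.append((p.taxon, p.n, h_score, u_score))
    per_taxon = pd.DataFrame(rows, columns=["taxon", "n", "dvs_h", "dvs_u"])

    def mean_of(col: str, weighted: bool) -> float:
        sub = per_taxon.dropna(subset=[col])
        if sub.empty:
            return float("nan")
        if weighted:
            w = sub["n"].to_numpy(float)
            return float(np.average(sub[col], weights=w))
        return float(sub[col].mean())

    return TieringResult(
        surface_id=surface_id,
        per_taxon=per_taxon,
        dvs_h=mean_of("dvs_h", False),
        dvs_u=mean_of("dvs_u", False),
        weighted_dvs_h=mean_of("dvs_h", True),
        weighted_dvs_u=mean_of("dvs_u", True),
        stem_proportion=stem_proportion,
        n_excluded=excluded,
    )


def stem_proportion(surface: SurfaceMap, level: str = "species",
                    treatment: EffacedTreatment = STANDARD) -> float:
    """Specimen-weighted fraction belonging to stemmed taxa.

    A taxon is stemmed when its mean recorded stem length is positive.
    """
    df = apply_treatment(surface.specimens, treatment)
    labels = taxon_labels(df, level)
    stems = df["stem_length"].fillna(0.0)
    mean_stem = stems.groupby(labels.to_numpy()).mean()
    stemmed = set(mean_stem.index[mean_stem > 0])
    return float(labels.isin(stemmed).mean())


def community_dvs(
    surface: SurfaceMap,
    level: str = "species",
    min_n: int | None = None,
    treatment: EffacedTreatment = STANDARD,
) -> TieringResult:
    """Community DVS scores (weighted and unweighted) with tier classes.

    ``min_n`` restricts scoring to abundant taxa (the earlier-literature
    N > 30 convention uses ``min_n=31``); by default every taxon with at
    least one specimen is scored, which the abundance-weighted mean is
    designed to accommodate.
    """
    profiles = build_profiles(surface, level, treatment, min_n=min_n)
    return _dvs_from_profiles(profiles, surface.surface_id,
                              stem_proportion(surface, level, treatment))


def morphogroup_dvs(
    surface: SurfaceMap,
    min_n: int = 31,
    treatment: EffacedTreatment = STANDARD,
) -> TieringResult:
    """DVS over gross morphogroups, each treated as a single taxon-unit.

    Only the reclining, bushy (Bradgatia), comb-like (Pectinifrons) and
    upright-frond groups enter; a surface qualifies when at least three of
    them are abundant (n >= ``min_n``, i.e. N > 30 by default).
    """
    profiles = [
        p for p in build_profiles(surface, "morphogroup", treatment)
        if p.taxon in TIERING_MORPHOGROUPS and p.n >= min_n
    ]
    if len(profiles) < 3:
        raise ValueError(
            f"surface {surface.surface_id!r}: fewer than 3 abundant "
            f"morphogroups (have {len(profiles)}); excluded from "
            "morphogroup tiering")
    return _dvs_from_profiles(profiles, surface.surface_id,
                              stem_proportion(surface, "morphogroup", treatment))


@dataclass
class CorrelationResult:
    method: str
    rho: float
    n: int
    p: float


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input to correlation")
    rho, p = spearmanr(x, y)
    return CorrelationResult("spearman", float(rho), len(x), float(p))


def tiering_table(results: Sequence[TieringResult]) -> pd.DataFrame:
    """Per-surface tiering summary with tier classes for each metric."""
    recs = []
    for r in results:
        recs.append({
            "surface_id": r.surface_id,
            "dvs_h": r.dvs_h, "dvs_u": r.dvs_u,
            "weighted_dvs_h": r.weighted_dvs_h,
            "weighted_dvs_u": r.weighted_dvs_u,
            "class_dvs_u": classify_tier(r.dvs_u),
            "class_weighted_dvs_u": classify_tier(r.weighted_dvs_u),
            "stem_proportion": r.stem_proportion,
        })
    return pd.DataFrame(recs).set_index("surface_id")


def tiering_succession_association(
    table: pd.DataFrame,
) -> tuple[dict[str, RegressionResult], dict[str, CorrelationResult]]:
    """Associations between tiering, succession and stems across surfaces.

    ``table`` needs columns mean_w, dvs_u, weighted_dvs_u, dvs_h and
    stem_proportion.  Returns OLS fits of each DVS metric on mean W, and
    Spearman correlations of stem proportion vs weighted DVS^u and of
    DVS^h vs DVS^u.
    """
    regressions = {}
    for col in ("dvs_u", "weighted_dvs_u", "dvs_h", "weighted_dvs_h"):
        if col in table.columns:
            sub = table[[col, "mean_w"]].dropna()
            regressions[col] = ols_regression(
                sub[col].to_numpy(), sub["mean_w"].to_numpy(), col, "mean_w")
    correlations = {
        "stem_vs_weighted_dvs_u": spearman(table["stem_proportion"],
                                           table["weighted_dvs_u"]),
        "dvs_h_vs_dvs_u": spearman(table["dvs_h"], table["dvs_u"]),
    }
    return regressions, correlations
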