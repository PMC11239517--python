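"""Abundance-biomass comparison (ABC) curves, the W statistic and staging.

An ABC curve ranks the taxa of one community twice — by count abundance
and, independently, by biomass (areal coverage as proxy) — and accumulates
percentages along each ranking.  The W statistic summarises the separation
of the two dominance curves,

    W = sum_i (A_i - B_i) / (50 * (S - 1)),

with A and B the cumulative percent abundance and biomass at ranks
1..S.  The orientation used here makes abundance dominance positive:
communities of many small individuals (recently disturbed / earlier
succession) score W > 0, communities dominated by a few large individuals
(later succession) score W < 0.  Some ABC literature uses the mirrored
sign; the orientation is a module constant.

Surfaces are placed into earlier / intermediate / later successional
stages by comparing per-replicate W values across spatial jackknife
distributions with percentile confidence intervals on replicate-wise
differences.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .composition import EffacedTreatment, STANDARD, apply_treatment, taxon_labels
from .io import SurfaceMap
from .jackknife import JackknifeSample

logger = logging.getLogger(__name__)

#: +1: abundance dominance gives W > 0 (convention used throughout);
#: -1 mirrors the sign as in some ABC formulations.
ABUNDANCE_POSITIVE = 1

STAGES = ("earlier", "intermediate", "later")


@dataclass
class ABCCurve:
    S: int
    A: np.ndarray  # cumulative % abundance at ranks 1..S
    B: np.ndarray  # cumulative % biomass at ranks 1..S
    W: float
    abundance_rank: list = field(default_factory=list)
    biomass_rank: list = field(default_factory=list)


def abc_w(
    counts: Mapping[str, float] | pd.Series,
    biomass: Mapping[str, float] | pd.Series,
    orientation: int = ABUNDANCE_POSITIVE,
) -> ABCCurve:
    """ABC curves and W from per-taxon counts and biomasses.

    Taxa with zero count are dropped; at least two must remain.  Rank ties
    are broken by taxon label so the result is deterministic (the
    cumulative curves make exact ties W-neutral).
    """
    counts = pd.Series(counts, dtype=float)
    biomass = pd.Series(biomass, dtype=float).reindex(counts.index).fillna(0.0)
    keep = counts > 0
    counts, biomass = counts[keep], biomass[keep]
    S = len(counts)
    if S < 2:
        raise ValueError(f"ABC curve needs >= 2 taxa with positive counts, got {S}")
    if biomass.sum() <= 0:
        raise ValueError("total biomass must be positive")

    def cum_percent(v: pd.Series) -> tuple[np.ndarray, list]:
        order = sorted(v.index, key=lambda t: (-v[t], str(t)))
        shares = v.loc[order].to_numpy() / v.sum() * 100.0
        return np.cumsum(shares), order

    A, a_order = cum_percent(counts)
    B, b_order = cum_percent(biomass)
    w = float(orientation * np.sum(A - B) / (50.0 * (S - 1)))
    return ABCCurve(S=S, A=A, B=B, W=w, abundance_rank=a_order,
                    biomass_rank=b_order)


def surface_abc(
    surface: SurfaceMap,
    level: str = "species",
    treatment: EffacedTreatment = STANDARD,
) -> ABCCurve:
    """ABC curve of a full surface (counts and summed areal coverage)."""
    df = apply_treatment(surface.specimens, treatment)
    if "areal_coverage" not in df.columns:
        raise ValueError("derive_geometry must run before ABC analysis")
    labels = taxon_labels(df, level)
    counts = labels.value_counts()
    biomass = df.groupby(labels.to_numpy())["areal_coverage"].sum()
    return abc_w(counts, biomass)


@dataclass
class WDistribution:
    surface_id: str
    values: np.ndarray
    n_dropped: int = 0

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    def quantile(self, q) -> np.ndarray:
        return np.quantile(self.values, q)


def w_jackknife_distribution(
    surface: SurfaceMap,
    samples: Sequence[JackknifeSample],
    level: str = "species",
    treatment: EffacedTreatment = STANDARD,
) -> WDistribution:
    """Per-replicate W values over the jackknife samples of one surface.

    Replicates with fewer than two taxa are dropped (and counted); more
    than half dropped raises, as the community is too sparse to resample.
    """
    df = apply_treatment(surface.specimens, treatment)
    if "areal_coverage" not in df.columns:
        raise ValueError("derive_geometry must run before ABC analysis")
    labels = taxon_labels(df, level)
    codes, taxa = pd.factorize(labels, sort=True)
    coverage = df["areal_coverage"].to_numpy(float)
    n_taxa = len(taxa)
    # map jackknife indices (positions in the untreated frame) to rows here
    pos_of = pd.Series(np.arange(len(df)), index=df.index)

    values = []
    dropped = 0
    for s in samples:
        rows = pos_of.reindex(s.indices).dropna().to_numpy(int)
        if len(rows) == 0:
            dropped += 1
            continue
        c = np.bincount(codes[rows], minlength=n_taxa).astype(float)
        b = np.bincount(codes[rows], weights=coverage[rows], minlength=n_taxa)
        present = c > 0
        if present.sum() < 2 or b[present].sum() <= 0:
            dropped += 1
            continue
        curve = abc_w(pd.Series(c[present], index=taxa[present]),
                      pd.Series(b[present], index=taxa[present]))
        values.append(curve.W)
    if dropped > len(samples) / 2:
        raise ValueError(
            f"surface {surface.surface_id!r}: {dropped}/{len(samples)} "
            "replicates dropped (community too sparse)")
    if dropped:
        logger.info("surface %s: dropped %d sparse jackknife replicate(s)",
                    surface.surface_id, dropped)
    return WDistribution(surface.surface_id, np.asarray(values), dropped)


@dataclass
class WComparison:
    pair: tuple[str, str]
    diffs: np.ndarray = field(repr=False)
    ci_low: float = 0.0
    ci_high: float = 0.0
    significant: bool = False

    @property
    def mean_diff(self) -> float:
        return float(self.diffs.mean())


def compare_w(
    dist_a: WDistribution,
    dist_b: WDistribution,
    alpha: float = 0.05,
) -> WComparison:
    """Replicate-wise W difference (a - b) with a percentile CI.

    Replicates are paired by index; the longer vector is truncated.  The
    difference is significant when the CI excludes zero.
    """
    a, b = dist_a.values, dist_b.values
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty W distribution")
    m = min(len(a), len(b))
    diffs = a[:m] - b[:m]
    lo, hi = np.quantile(diffs, [alpha / 2.0, 1.0 - alpha / 2.0])
    sig = not (lo <= 0.0 <= hi)
    return WComparison(pair=(dist_a.surface_id, dist_b.surface_id),
                       diffs=diffs, ci_low=float(lo), ci_high=float(hi),
                       significant=bool(sig))


@dataclass
class StageAssignment:
    surface_id: str
    mean_w: float
    stage: str
    resolution: str  # "significant" or "by_mean_w"


def _stage_from_signs(has_pos: bool, has_neg: bool) -> str:
    if has_pos and not has_neg:
        return "earlier"
    if has_neg and not has_pos:
        return "later"
    return "intermediate"


def assign_stages(
    distributions: Mapping[str, WDistribution],
    full_surface_w: Mapping[str, float] | None = None,
    alpha: float = 0.05,
) -> list[StageAssignment]:
    """Categorical successional stage for every surface.

    Jackknifed surfaces whose significant pairwise comparisons are all
    positive are *earlier*, all negative *later*, mixed *intermediate*.
    A surface with no significant comparison joins the resolved group
    whose mean-W range is nearest (resolution ``by_mean_w``), as do
    unjackknifed surfaces supplied through ``full_surface_w`` (placed by
    their total-surface W).  With no significant structure at all, every
    surface is flagged ``by_mean_w`` and rated intermediate.
    """
    sids = list(distributions)
    comparisons = {
        (a, b): compare_w(distributions[a], distributions[b], alpha)
        for a, b in itertools.combinations(sids, 2)
    }

    resolved: dict[str, str] = {}
    unresolved: list[str] = []
    for sid in sids:
        signs = []
        for (a, b), cmp_ in comparisons.items():
            if not cmp_.significant:
                continue
            if a == sid:
                signs.append(np.sign(cmp_.mean_diff))
            elif b == sid:
                signs.append(-np.sign(cmp_.mean_diff))
        if signs:
            resolved[sid] = _stage_from_signs(any(s > 0 for s in signs),
                                              any(s < 0 for s in signs))
        else:
            unresolved.append(sid)

    mean_w = {sid: distributions[sid].mean for sid in sids}
    ranges: dict[str, tuple[float, float]] = {}
    for stage in STAGES:
        ws = [mean_w[s] for s, st in resolved.items() if st == stage]
        if ws:
            ranges[stage] = (min(ws), max(ws))

    def nearest_stage(w: float) -> str:
        if not ranges:
            return "intermediate"
        best, best_d = None, np.inf
        for stage in STAGES:  # tie-break: earlier < intermediate < later order
            if stage not in ranges:
                continue
            lo, hi = ranges[stage]
            d = 0.0 if lo <= w <= hi else min(abs(w - lo), abs(w - hi))
            if d < best_d:
                best, best_d = stage, d
        return best

    if not resolved:
        logger.warning("no significant W comparisons anywhere; all surfaces "
                       "placed by mean W")

    out = [
        StageAssignment(sid, mean_w[sid], resolved[sid], "significant")
        for sid in resolved
    ]
    out += [
        StageAssignment(sid, mean_w[sid], nearest_stage(mean_w[sid]), "by_mean_w")
        for sid in unresolved
    ]
    for sid, w in (full_surface_w or {}).items():
        out.append(StageAssignment(sid, float(w), nearest_stage(w), "by_mean_w"))
    order = {sid: i for i, sid in enumerate(list(sids) + list(full_surface_w or {}))}
    out.sort(key=lambda a: order[a.surface_id])
    return out


def stage_table(assignments: Sequence[StageAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.surface_id, a.mean_w, a.stage, a.resolution) for a in assignments],
        columns=["surface_id", "mean_w", "stage", "resolution"],
    )


@dataclass
class RegressionResult:
    response: str
    covariate: str
    n: int
    F: float
    df: tuple[int, int]
    p: float
    adj_r2: float
    slope: float


def ols_regression(y: np.ndarray, x: np.ndarray, response: str,
                   covariate: str) -> RegressionResult:
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {covariate!r} is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        response=response, covariate=covariate, n=len(y),
        F=float(model.fvalue), df=(int(model.df_model), int(model.df_resid)),
        p=float(model.f_pvalue), adj_r2=float(model.rsquared_adj),
        slope=float(model.params[1]),
    )


def regress_w_covariates(
    table: pd.DataFrame,
    covariates: Sequence[str] = ("specimen_density", "areal_coverage",
                                 "mean_height", "max_height"),
    response: str = "mean_w",
) -> dict[str, RegressionResult]:
    """OLS of mean W on each surface-level covariate."""
    out = {}
    for cov in covariates:
        sub = table[[response, cov]].dropna()
        out[cov] = ols_regression(sub[response].to_numpy(), sub[cov].to_numpy(),
                                  response, cov)
    return out


def surface_covariates(surfaces: Sequence[SurfaceMap]) -> pd.DataFrame:
    """Specimen density, total coverage and height summaries per surface."""
    recs = []
    for s in surfaces:
        df = s.specimens
        recs.append({
            "surface_id": s.surface_id,
            "specimen_density": len(df) / s.area_m2,
            "areal_coverage": float(df["areal_coverage"].sum()),
            "mean_height": float(df["height"].mean()),
            "max_height": float(df["height"].max()),
        })
    return pd.DataFrame(recs).set_index("surface_id")
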