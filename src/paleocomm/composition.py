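"""Community composition: count tables, Bray-Curtis, NMDS, clustering, LDA.

Composition tables are pandas DataFrames with one row per community (a
full surface or one jackknife replicate) and one column per taxon label
at the requested taxonomic level.  Records that cannot be identified at
that level keep their finest available label as their own column.

Poorly preserved ("effaced") frondose specimens are handled through four
treatments: drop them (standard), keep them as a pseudo-taxon, relabel
them at random in proportion to the identified composition of the same
community, or relabel them to a best-guess identity and drop the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.manifold import MDS

from .io import SurfaceMap
from .jackknife import JackknifeSample

LEVELS = ("species", "genus", "morphogroup")

TREATMENT_MODES = ("standard", "effaced_as_taxon", "proportional_relabel",
                   "best_guess")

EFFACED_LABEL = "effaced_frond"


@dataclass(frozen=True)
class EffacedTreatment:
    """How effaced fronds enter a composition table.

    ``proportional_relabel`` draws a label for each effaced frond from the
    community's identified-taxon relative abundances (so a community that
    is half *Charnia* relabels on average half of its effaced fronds as
    *Charnia*); it conserves the total specimen count.  ``best_guess``
    maps effaced records through ``best_guess_map`` (specimen_id -> taxon,
    or the sentinel column name ``"true_taxon"``) and drops the rest.
    Taphomorph records are excluded under every mode.
    """

    mode: str = "standard"
    relabel_seed: int | None = None
    best_guess_map: Mapping[str, str] | str | None = None

    def __post_init__(self) -> None:
        if self.mode not in TREATMENT_MODES:
            raise ValueError(f"unknown treatment mode {self.mode!r}")


STANDARD = EffacedTreatment("standard")


def taxon_labels(df: pd.DataFrame, level: str) -> pd.Series:
    """Label each record at the requested level.

    species: the recorded taxon (already the finest available label);
    genus: the first token of the taxon name for species/genus-level
    records, the recorded label otherwise; morphogroup: the morphogroup.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    if level == "species":
        return df["taxon"].copy()
    if level == "genus":
        at_named = df["tax_level"].isin(["species", "genus"])
        genus = df["taxon"].str.split().str[0]
        return genus.where(at_named, df["taxon"])
    return df["morphogroup"].copy()


def apply_treatment(
    df: pd.DataFrame,
    treatment: EffacedTreatment = STANDARD,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Resolve effaced fronds within one community table."""
    df = df[df["tax_level"] != "taphomorph"]
    effaced = df["effaced_frond"].to_numpy(bool)
    if treatment.mode == "standard":
        return df.loc[~effaced]
    if treatment.mode == "effaced_as_taxon":
        out = df.copy()
        out.loc[effaced, "taxon"] = EFFACED_LABEL
        out.loc[effaced, "tax_level"] = "morphocategory"
        return out
    if treatment.mode == "proportional_relabel":
        out = df.copy()
        ident = out.loc[~effaced, "taxon"]
        if effaced.any():
            if ident.empty:
                raise ValueError(
                    "proportional_relabel: no identified specimens to draw from")
            props = ident.value_counts(normalize=True)
            if rng is None:
                rng = np.random.default_rng(treatment.relabel_seed)
            draws = rng.choice(props.index.to_numpy(), size=int(effaced.sum()),
                               p=props.to_numpy())
            out.loc[effaced, "taxon"] = draws
            out.loc[effaced, "tax_level"] = "species"
        return out
    # best_guess
    out = df.copy()
    bg = treatment.best_guess_map
    if isinstance(bg, str):
        guess = out[bg].where(out[bg].notna()) if bg in out.columns else None
    elif bg is not None:
        guess = out["specimen_id"].map(bg)
    else:
        guess = None
    if guess is None:
        return out.loc[~effaced]
    has_guess = effaced & guess.notna().to_numpy()
    out.loc[has_guess, "taxon"] = guess[has_guess]
    out.loc[has_guess, "tax_level"] = "species"
    return out.loc[~effaced | has_guess]


def _counts(df: pd.DataFrame, level: str) -> pd.Series:
    return taxon_labels(df, level).value_counts()


def composition_table(
    surfaces: Sequence[SurfaceMap],
    level: str = "species",
    treatment: EffacedTreatment = STANDARD,
    relative: bool = False,
) -> pd.DataFrame:
    """Full-surface composition table (one row per surface)."""
    rng = np.random.default_rng(treatment.relabel_seed)
    rows = {}
    for s in surfaces:
        rows[s.surface_id] = _counts(apply_treatment(s.specimens, treatment, rng),
                                     level)
    table = pd.DataFrame(rows).T.fillna(0.0).sort_index(axis=1)
    table.index.name = "surface_id"
    return relative_abundance(table) if relative else table


def jackknife_composition_table(
    surface: SurfaceMap,
    samples: Sequence[JackknifeSample],
    level: str = "species",
    treatment: EffacedTreatment = STANDARD,
) -> pd.DataFrame:
    """Composition table over jackknife replicates of one surface.

    Rows are indexed by (surface_id, sample_index); the treatment is
    applied per replicate community.
    """
    rng = np.random.default_rng(treatment.relabel_seed)
    rows = {}
    for s in samples:
        sub = surface.specimens.iloc[s.indices]
        rows[(s.surface_id, s.sample_index)] = _counts(
            apply_treatment(sub, treatment, rng), level)
    table = pd.DataFrame(rows).T.fillna(0.0).sort_index(axis=1)
    table.index.names = ["surface_id", "sample_index"]
    return table


def combine_tables(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Stack composition tables, unioning taxon columns (absent -> 0)."""
    return pd.concat(tables).fillna(0.0).sort_index(axis=1)


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    totals = table.sum(axis=1)
    if (totals <= 0).any():
        bad = table.index[totals <= 0].tolist()
        raise ValueError(f"zero-total composition row(s): {bad}")
    return table.div(totals, axis=0)


def bray_curtis(a: np.ndarray, b: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b) over a shared column set."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("rows must share the same column set")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("composition rows must be non-negative")
    denom = (a + b).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero rows")
    return float(np.abs(a - b).sum() / denom)


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis distance matrix over table rows."""
    if (table.sum(axis=1) <= 0).any():
        raise ValueError("all rows need a positive total")
    d = squareform(pdist(table.to_numpy(float), metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


@dataclass
class OrdinationResult:
    k: int
    coordinates: pd.DataFrame
    stress: float  # Kruskal stress-1
    n_restarts: int
    seed: int | None


def nmds(
    table: pd.DataFrame,
    k: int = 2,
    seed: int | None = 0,
    n_restarts: int = 20,
    max_iter: int = 300,
    eps: float = 1e-7,
) -> OrdinationResult:
    """Non-metric multidimensional scaling of the Bray-Curtis matrix.

    Rank-based stress minimisation (Kruskal stress-1); the lowest-stress
    solution over ``n_restarts`` random starts is kept.  Deterministic for
    a fixed seed.
    """
    if len(table) < k + 1:
        raise ValueError(f"need at least {k + 1} rows for a {k}-D ordination")
    d = bray_curtis_matrix(table).to_numpy()
    kwargs = dict(
        n_components=k,
        n_init=n_restarts,
        max_iter=max_iter,
        eps=eps,
        random_state=seed,
        normalized_stress=True,
    )
    try:  # keywords renamed across scikit-learn releases
        model = MDS(metric_mds=False, metric="precomputed", init="random",
                    **kwargs)
    except TypeError:
        model = MDS(metric=False, dissimilarity="precomputed", **kwargs)
    coords = model.fit_transform(d)
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        k=k,
        coordinates=pd.DataFrame(coords, index=table.index, columns=cols),
        stress=float(model.stress_),
        n_restarts=n_restarts,
        seed=seed,
    )


@dataclass
class ClusteringResult:
    linkage: np.ndarray
    labels: list
    method: str

    def cut(self, n_clusters: int) -> pd.Series:
        assign = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(assign, index=pd.Index(self.labels), name="cluster")

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return str(self.labels[node.id]).replace(" ", "_")
            length_l = node.dist - node.left.dist
            length_r = node.dist - node.right.dist
            return (f"({rec(node.left)}:{length_l:.6f},"
                    f"{rec(node.right)}:{length_r:.6f})")

        return rec(tree) + ";"


def hierarchical_cluster(
    table: pd.DataFrame,
    method: str = "average",
    relative: bool = True,
) -> ClusteringResult:
    """Agglomerative (default UPGMA) clustering on Bray-Curtis distances.

    By default rows are converted to relative abundances first, matching
    clustering of whole-surface compositions.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to cluster")
    data = relative_abundance(table) if relative else table
    cond = pdist(data.to_numpy(float), metric="braycurtis")
    z = hierarchy.linkage(cond, method=method)
    return ClusteringResult(linkage=z, labels=list(table.index), method=method)


@dataclass
class LDAStageReport:
    median_correct: float
    per_repeat: np.ndarray
    confusions: list[pd.DataFrame] = field(repr=False, default_factory=list)


def lda_stage_prediction(
    table: pd.DataFrame,
    stages: Mapping[str, str],
    n_repeats: int = 100,
    n_test_surfaces: int = 3,
    seed: int | None = 0,
) -> LDAStageReport:
    """Predict successional stage from composition with a linear discriminant.

    ``table`` holds jackknife-replicate compositions indexed by
    (surface_id, sample_index); ``stages`` maps each surface to its stage.
    Each repeat holds out every replicate of ``n_test_surfaces`` randomly
    chosen surfaces, fits the discriminant on relative abundances of the
    rest and scores the held-out replicates; the median correct fraction
    over repeats is reported.  Repeats whose training fold misses a stage
    are redrawn.
    """
    surfaces = list(table.index.get_level_values(0).unique())
    stage_of = {s: stages[s] for s in surfaces}
    all_stages = sorted(set(stage_of.values()))
    if len(all_stages) < 2:
        raise ValueError("need at least 2 stages")
    rel = relative_abundance(table)
    X = rel.to_numpy(float)
    y = np.array([stage_of[s] for s in table.index.get_level_values(0)])
    surf_arr = table.index.get_level_values(0).to_numpy()

    rng = np.random.default_rng(seed)
    accs = np.empty(n_repeats)
    confusions: list[pd.DataFrame] = []
    for r in range(n_repeats):
        for _attempt in range(1000):
            test_surf = rng.choice(surfaces, size=n_test_surfaces, replace=False)
            train_mask = ~np.isin(surf_arr, test_surf)
            if set(y[train_mask]) == set(all_stages):
                break
        else:
            raise ValueError("could not draw a training fold covering all stages")
        model = LinearDiscriminantAnalysis()
        model.fit(X[train_mask], y[train_mask])
        pred = model.predict(X[~train_mask])
        truth = y[~train_mask]
        accs[r] = float((pred == truth).mean())
        conf = pd.crosstab(pd.Series(truth, name="true"),
                           pd.Series(pred, name="predicted"))
        confusions.append(conf.reindex(index=all_stages, columns=all_stages,
                                       fill_value=0))
    return LDAStageReport(median_correct=float(np.median(accs)),
                          per_repeat=accs, confusions=confusions)


def lda_permutation_null(
    table: pd.DataFrame,
    stages: Mapping[str, str],
    n_permutations: int = 20,
    n_repeats_per: int = 10,
    n_test_surfaces: int = 3,
    seed: int | None = 0,
) -> LDAStageReport:
    """Chance-level reference for :func:`lda_stage_prediction`.

    Stage labels are shuffled across surfaces afresh for each of
    ``n_permutations`` permutations and the prediction experiment is
    repeated under each; the pooled accuracies estimate the null
    distribution (median ~ 1/k for k balanced stages).
    """
    rng = np.random.default_rng(seed)
    sids = list(table.index.get_level_values(0).unique())
    labels = np.array([stages[s] for s in sids])
    pooled = []
    for _ in range(n_permutations):
        perm = dict(zip(sids, rng.permutation(labels)))
        rep = lda_stage_prediction(
            table, perm, n_repeats=n_repeats_per,
            n_test_surfaces=n_test_surfaces,
            seed=int(rng.integers(2**31)))
        pooled.append(rep.per_repeat)
    accs = np.concatenate(pooled)
    return LDAStageReport(median_correct=float(np.median(accs)),
                          per_repeat=accs)
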