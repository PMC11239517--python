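# paleocomm

Community-ecology analyses for *census-mapped* palaeocommunities —
bedding-plane surfaces (such as the Ediacaran Avalon assemblages of
Newfoundland and Charnwood Forest) on which every sessile specimen's
position, part measurements and taxonomic identity have been digitised.
The package is aimed at palaeoecologists who have per-surface specimen
tables and want reproducible answers to three questions:

1. **Composition** — do surfaces fall into distinct Community Types?
   Bray–Curtis dissimilarity, non-metric multidimensional scaling (NMDS)
   and UPGMA hierarchical clustering over spatial-jackknife replicates.
2. **Succession** — how recently was each community disturbed?
   Abundance–biomass comparison (ABC) curves summarised by the W
   statistic,

       W = Σᵢ (Aᵢ − Bᵢ) / (50 (S − 1)),

   where A and B are cumulative percent abundance and biomass over taxon
   ranks 1..S.  Here W > 0 means abundance dominance (many small
   individuals, earlier succession) and W < 0 biomass dominance (later
   succession).  Surfaces are staged earlier / intermediate / later by
   percentile confidence intervals on replicate-wise W differences
   across 1,000 spatial jackknife subsamples of 66% of each surface.
3. **Tiering** — do co-occurring taxa partition the vertical space?
   Distinct-vertical-stratification scores per taxon: DVS^u (fraction of
   a taxon's uptake zone overlapping no other taxon, by exact interval
   arithmetic) and DVS^h (fraction of specimens matched in height by no
   other taxon), combined into unweighted and abundance-weighted
   community means and classed high (> 0.70) / medium (0.40–0.70) /
   low (< 0.40).

Supporting machinery: census-CSV reading and validation, derived
geometry (height, uptake interval, areal coverage as a biomass proxy),
retrodeformation of tectonically sheared surfaces from holdfast-disc
ellipticity, effaced-frond sensitivity treatments, linear-discriminant
stage prediction, W-vs-covariate regressions, and a synthetic community
generator with planted Community Types, successional states and tiering
structure so that every stage of the pipeline is testable without access
to field data.  See `docs/methods.md` for conventions and assumptions.

## Worked example

```python
import numpy as np
from paleocomm import (abc_w, generate_planted_w_surface,
                       generate_jackknife_samples, JackknifeConfig,
                       w_jackknife_distribution, assign_stages)
from paleocomm.succession import stage_table

# ABC curves and W from per-taxon counts and biomasses
curve = abc_w({"Fractofusus": 70, "Charnia": 20, "Bradgatia": 10},
              {"Fractofusus": 10, "Charnia": 30, "Bradgatia": 60})
print("W =", round(curve.W, 3))

# stage three synthetic surfaces with planted W of 0.2 / 0.0 / -0.2
dists = {}
for i, (sid, w) in enumerate([("A", 0.2), ("B", 0.0), ("C", -0.2)]):
    s = generate_planted_w_surface(w, sid, total_n=1500, seed=10 + i)
    samples = generate_jackknife_samples(
        s, JackknifeConfig(n_samples=1000, seed=20 + i))
    dists[sid] = w_jackknife_distribution(s, samples)
print(stage_table(assign_stages(dists)).to_string(index=False))
```

prints

```
W = 0.1
surface_id    mean_w        stage  resolution
         A  0.205104      earlier significant
         B -0.014769 intermediate significant
         C -0.164920        later significant
```

The W of 0.1 reflects the cumulative abundance curve running above the
biomass curve (70/90/100 vs 60/90/100 at ranks 1–3): the community is
numerically dominated by a taxon that holds little of the biomass, the
signature of an early-successional community.  The three planted
surfaces are recovered in the right stages, each resolved by
significant pairwise comparisons rather than by the mean-W fallback.

Tiering of a two-taxon community whose uptake bands are disjoint — a
recliner at the substrate and a stemmed frond higher up:

```python
from paleocomm import (SyntheticSurfaceConfig, TaxonSpec,
                       generate_surface, community_dvs)

taxa = (TaxonSpec("Fractofusus misrai", "reclining", 0.6,
                  frond_length=(90.0, 0.2), width_allometry=0.35),
        TaxonSpec("Charnia masoni", "upright_frond", 0.4,
                  frond_length=(80.0, 0.2), stem_length=(60.0, 0.1)))
s = generate_surface(SyntheticSurfaceConfig("demo", taxa, total_n=400, seed=1))
r = community_dvs(s)
print(r.per_taxon.round(3).to_string(index=False))
print("unweighted DVS^u =", round(r.dvs_u, 3),
      "| weighted =", round(r.weighted_dvs_u, 3),
      "->", r.tier_class("weighted_dvs_u"), "tiering")
```

prints

```
             taxon   n  dvs_h  dvs_u
    Charnia masoni 158    1.0    1.0
Fractofusus misrai 242    1.0    1.0
unweighted DVS^u = 1.0 | weighted = 1.0 -> high tiering
```

— the recliners' uptake zone (0 to ~10 mm above the substrate) never
meets the fronds' (≳55 mm up), so every taxon scores 1 and the community
is fully tiered.

## Command line

A thin CLI wraps the library for shell-driven runs:

```sh
paleocomm simulate --seed 0 --out fixture/          # synthetic study fixture
paleocomm run --manifest fixture/manifest.yaml --seed 0 --out results_dir/
paleocomm succession --manifest fixture/manifest.yaml --out stages.csv
paleocomm tiering --manifest fixture/manifest.yaml --out tiering.csv
```

`run` executes the whole pipeline (read → retrodeform → jackknife →
composition/NMDS/clustering → W staging → regressions → tiering) and
writes CSV/JSON artifacts plus a run log; identical configurations and
seeds reproduce every file byte for byte.

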