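import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from paleocomm.composition import (EffacedTreatment, apply_treatment,
                                   bray_curtis, bray_curtis_matrix,
                                   composition_table, hierarchical_cluster,
                                   jackknife_composition_table, nmds,
                                   relative_abundance, taxon_labels)
from paleocomm.jackknife import JackknifeConfig, generate_jackknife_samples
from paleocomm.simulate import generate_surface, SyntheticSurfaceConfig, TaxonSpec

from conftest import make_surface


def community(counts: dict, effaced: int = 0) -> pd.DataFrame:
    rows = []
    for taxon, n in counts.items():
        for i in range(n):
            rows.append({"specimen_id": f"{taxon}-{i}", "x": 1.0, "y": 1.0,
                         "taxon": taxon, "tax_level": "species",
                         "true_taxon": taxon})
    for i in range(effaced):
        rows.append({"specimen_id": f"eff-{i}", "x": 1.0, "y": 1.0,
                     "taxon": "effaced_frond", "tax_level": "morphocategory",
                     "effaced_frond": True, "true_taxon": "Charnia masoni"})
    return pd.DataFrame(rows)


class TestTreatments:
    def test_standard_drops_effaced(self):
        df = community({"Charnia masoni": 5, "Fractofusus misrai": 5},
                       effaced=4)
        out = apply_treatment(make_surface(df, derive=False).specimens,
                              EffacedTreatment("standard"))
        assert len(out) == 10
        assert not out["effaced_frond"].any()

    def test_effaced_as_taxon_adds_one_column_only(self):
        df = community({"Charnia masoni": 5, "Fractofusus misrai": 5},
                       effaced=4)
        s = make_surface(df, derive=False)
        std = composition_table([s], treatment=EffacedTreatment("standard"))
        eff = composition_table([s],
                                treatment=EffacedTreatment("effaced_as_taxon"))
        for taxon in std.columns:
            assert std.loc["test", taxon] == eff.loc["test", taxon]
        assert set(eff.columns) - set(std.columns) == {"effaced_frond"}
        assert eff.loc["test", "effaced_frond"] == 4

    def test_proportional_relabel_conserves_counts_and_proportions(self):
        df = community({"Charnia masoni": 500, "Fractofusus misrai": 500},
                       effaced=400)
        s = make_surface(df, derive=False)
        t = EffacedTreatment("proportional_relabel", relabel_seed=3)
        tab = composition_table([s], treatment=t)
        assert tab.sum(axis=1).iloc[0] == 1400  # total conserved
        # relabelled specimens split ~50/50 following identified composition
        assert tab.loc["test", "Charnia masoni"] == pytest.approx(700, abs=60)

    def test_best_guess_uses_true_identity_column(self):
        df = community({"Fractofusus misrai": 6}, effaced=4)
        s = make_surface(df, derive=False)
        t = EffacedTreatment("best_guess", best_guess_map="true_taxon")
        tab = composition_table([s], treatment=t)
        assert tab.loc["test", "Charnia masoni"] == 4

    def test_single_taxon_relative_abundance(self):
        s = make_surface(community({"Charnia masoni": 10}), derive=False)
        tab = composition_table([s], relative=True)
        assert tab.shape == (1, 1)
        assert tab.iloc[0, 0] == 1.0


class TestLabels:
    def test_genus_level_bins_species_by_first_token(self):
        df = community({"Fractofusus misrai": 1, "Fractofusus andersoni": 1})
        labels = taxon_labels(df, "genus")
        assert set(labels) == {"Fractofusus"}

    def test_morphocategory_record_keeps_own_label_at_genus_level(self):
        df = community({"Charnia masoni": 1})
        df.loc[1] = {"specimen_id": "m0", "x": 0, "y": 0,
                     "taxon": "Rangeomorph indet", "tax_level": "morphocategory",
                     "true_taxon": "Rangeomorph indet"}
        labels = taxon_labels(df, "genus")
        assert "Rangeomorph indet" in set(labels)


class TestBrayCurtis:
    def test_worked_example(self):
        assert bray_curtis(np.array([6, 4, 0]),
                           np.array([2, 4, 4])) == pytest.approx(0.4)

    def test_identity_and_disjoint_bounds(self):
        a = np.array([3.0, 7.0, 0.0])
        assert bray_curtis(a, a) == 0.0
        assert bray_curtis(np.array([5.0, 0.0]), np.array([0.0, 9.0])) == 1.0

    def test_matches_scipy_and_is_symmetric(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.integers(0, 20, size=6).astype(float)
            b = rng.integers(0, 20, size=6).astype(float)
            if (a + b).sum() == 0:
                continue
            assert bray_curtis(a, b) == pytest.approx(scipy_braycurtis(a, b))
            assert bray_curtis(a, b) == pytest.approx(bray_curtis(b, a))
            assert 0.0 <= bray_curtis(a, b) <= 1.0

    def test_all_zero_rows_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(np.zeros(3), np.zeros(3))


class TestNMDS:
    def test_equidistant_triplet_embeds_with_near_zero_stress(self):
        t = pd.DataFrame(np.eye(3) * 10, index=list("abc"),
                         columns=["t1", "t2", "t3"])
        r = nmds(t, k=2, seed=0, n_restarts=8)
        assert r.stress < 0.01

    def test_extra_dimension_never_fits_worse(self, study_fixture):
        surfaces = [f.surface for f in study_fixture]
        comp = composition_table(surfaces)
        r2 = nmds(comp, k=2, seed=3, n_restarts=10)
        r3 = nmds(comp, k=3, seed=3, n_restarts=10)
        assert r3.stress <= r2.stress + 0.02
        assert 0.0 <= r3.stress <= 1.0

    def test_planted_types_separate_in_ordination(self, study_fixture):
        surfaces = [f.surface for f in study_fixture]
        comp = composition_table(surfaces)
        r = nmds(comp, k=2, seed=0, n_restarts=10)
        xy = r.coordinates.to_numpy()
        types = np.array([f.community_type for f in study_fixture])
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
        same = types[:, None] == types[None, :]
        off = ~np.eye(len(xy), dtype=bool)
        assert d[same & off].mean() < d[~same].mean()


class TestClustering:
    def test_identical_communities_merge_at_zero(self):
        t = pd.DataFrame([[5, 5], [10, 10], [1, 9]], index=list("abc"),
                         columns=["t1", "t2"])
        cl = hierarchical_cluster(t)
        assert cl.merge_heights()[0] == pytest.approx(0.0, abs=1e-12)

    def test_planted_four_types_recovered_exactly(self, study_fixture):
        surfaces = [f.surface for f in study_fixture]
        comp = composition_table(surfaces)
        cut = hierarchical_cluster(comp).cut(4)
        truth = pd.Series({f.surface.surface_id: f.community_type
                           for f in study_fixture})
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth[cut.index], cut) == pytest.approx(1.0)

    def test_duplicated_surface_leaves_other_merges_unchanged(self):
        t = pd.DataFrame([[10, 0, 0], [8, 2, 0], [0, 10, 0], [0, 0, 10]],
                         index=list("abcd"), columns=["t1", "t2", "t3"])
        base = sorted(hierarchical_cluster(t).merge_heights())
        t2 = pd.concat([t, t.loc[["d"]].rename(index={"d": "d2"})])
        dup = sorted(hierarchical_cluster(t2).merge_heights())
        # the duplicate joins at height 0; existing merge heights persist
        assert dup[0] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(dup[1:], base, atol=1e-12)

    def test_newick_export_contains_all_leaves(self, study_fixture):
        surfaces = [f.surface for f in study_fixture[:5]]
        comp = composition_table(surfaces)
        nwk = hierarchical_cluster(comp).to_newick()
        assert nwk.endswith(";")
        for sid in comp.index:
            assert sid.replace(" ", "_") in nwk

    def test_single_row_errors(self):
        t = pd.DataFrame([[1, 2]], index=["a"], columns=["t1", "t2"])
        with pytest.raises(ValueError):
            hierarchical_cluster(t)


def test_jackknife_composition_rows_match_sample_sizes():
    taxa = (TaxonSpec("A", abundance_weight=0.6),
            TaxonSpec("B", abundance_weight=0.4))
    s = generate_surface(SyntheticSurfaceConfig("jk", taxa, total_n=400,
                                                seed=2))
    samples = generate_jackknife_samples(
        s, JackknifeConfig(n_samples=20, seed=1))
    tab = jackknife_composition_table(s, samples)
    assert len(tab) == 20
    for smp in samples:
        assert tab.loc[("jk", smp.sample_index)].sum() == len(smp.indices)


def test_relative_abundance_rows_sum_to_one(study_fixture):
    comp = composition_table([f.surface for f in study_fixture])
    rel = relative_abundance(comp)
    np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-9)
    with pytest.raises(ValueError, match="zero-total"):
        relative_abundance(pd.DataFrame([[0, 0]], columns=["a", "b"]))
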