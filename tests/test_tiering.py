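import numpy as np
import pandas as pd
import pytest

from paleocomm.simulate import SyntheticSurfaceConfig, TaxonSpec, generate_surface
from paleocomm.tiering import (TaxonTierProfile, classify_tier, community_dvs,
                               intersect_measure, interval_measure,
                               merge_intervals, morphogroup_dvs, spearman,
                               stem_proportion, taxon_dvs_h, taxon_dvs_u,
                               tiering_succession_association, tiering_table)

from conftest import make_surface


def profile(name, n, heights, zone):
    return TaxonTierProfile(name, n, np.asarray(heights, float), list(zone))


def grid_dvs_u(target, others, step=0.01):
    """Brute-force DVS^u on a discretized occupancy grid (independent oracle)."""
    hi = max(iv[1] for p in [target, *others] for iv in p.zone) + step
    centres = np.arange(step / 2, hi, step)

    def occupied(p):
        occ = np.zeros(len(centres), dtype=bool)
        for lo, h in p.zone:
            occ |= (centres >= lo) & (centres <= h)
        return occ

    t_occ = occupied(target)
    o_occ = np.zeros_like(t_occ)
    for o in others:
        o_occ |= occupied(o)
    return 1.0 - (t_occ & o_occ).sum() / t_occ.sum()


class TestIntervalArithmetic:
    def test_merge_and_measure(self):
        merged = merge_intervals([(0, 5), (3, 8), (10, 12)])
        assert merged == [(0.0, 8.0), (10.0, 12.0)]
        assert interval_measure(merged) == 10.0

    def test_intersect_measure(self):
        a = [(0.0, 10.0), (20.0, 30.0)]
        b = [(5.0, 25.0)]
        assert intersect_measure(a, b) == pytest.approx(10.0)


class TestTaxonDVS:
    def test_disjoint_zones_fully_tiered(self):
        t = profile("a", 5, [5], [(0, 10)])
        o = profile("b", 5, [30], [(20, 50)])
        assert taxon_dvs_u(t, [o]) == 1.0

    def test_identical_zones_untired(self):
        t = profile("a", 5, [5], [(0, 10)])
        o = profile("b", 5, [5], [(0, 10)])
        assert taxon_dvs_u(t, [o]) == 0.0
        assert taxon_dvs_h(t, [o]) == 0.0

    def test_partial_overlap_worked_example(self):
        t = profile("a", 1, [5], [(0, 10)])
        o = profile("b", 3, [12, 13, 14], [(5, 20)])
        assert taxon_dvs_u(t, [o]) == pytest.approx(0.5)
        assert taxon_dvs_u(o, [t]) == pytest.approx(1 - 5 / 15)

    def test_height_envelope_matching(self):
        t = profile("a", 3, [5, 15, 25], [(0, 30)])
        o = profile("b", 2, [10, 20], [(0, 30)])
        assert taxon_dvs_h(t, [o]) == pytest.approx(2 / 3)
        assert taxon_dvs_h(o, [t]) == 0.0  # inside [5, 25]

    def test_heights_above_all_others_fully_distinct(self):
        t = profile("a", 4, [40, 45, 50, 60], [(40, 60)])
        o = profile("b", 2, [5, 10], [(0, 10)])
        assert taxon_dvs_h(t, [o]) == 1.0

    def test_zero_measure_zone_raises(self):
        t = profile("a", 1, [0.0], [(0.0, 0.0)])
        with pytest.raises(ValueError, match="zero-measure"):
            taxon_dvs_u(t, [])

    def test_grid_oracle_agreement_small(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            profiles = _random_profiles(rng)
            for i, t in enumerate(profiles):
                others = profiles[:i] + profiles[i + 1:]
                exact = taxon_dvs_u(t, others)
                assert exact == pytest.approx(grid_dvs_u(t, others), abs=0.02)


def _random_profiles(rng, max_taxa=5, max_specimens=50):
    n_taxa = rng.integers(2, max_taxa + 1)
    profiles = []
    for ti in range(n_taxa):
        n = int(rng.integers(1, max_specimens // n_taxa + 2))
        lo = rng.uniform(0, 60, n)
        length = rng.uniform(5, 40, n)
        ivs = list(zip(lo, lo + length))
        heights = lo + length
        profiles.append(profile(f"t{ti}", n, heights, merge_intervals(ivs)))
    return profiles


class TestCommunityDVS:
    def _surface(self, spec_rows):
        df = pd.DataFrame(spec_rows)
        df["specimen_id"] = [f"s{i}" for i in range(len(df))]
        df["x"] = np.linspace(1, 9, len(df))
        df["y"] = np.linspace(1, 9, len(df))
        return make_surface(df)

    def test_disjoint_tiers_score_one_any_weighting(self):
        rows = [{"taxon": "Fractofusus misrai", "morphogroup": "reclining",
                 "frond_length": 90.0, "frond_width": 30.0}] * 10
        rows += [{"taxon": "Charnia masoni", "morphogroup": "upright_frond",
                  "stem_length": 20.0, "stem_width": 3.0,
                  "frond_length": 30.0, "frond_width": 12.0}] * 5
        r = community_dvs(self._surface(rows))
        assert r.dvs_u == r.weighted_dvs_u == 1.0
        assert r.tier_class("weighted_dvs_u") == "high"

    def test_weighted_vs_unweighted_worked_example(self):
        # zones [0,10] (n=1) and [5,20] (n=3) built from real specimens
        rows = [{"taxon": "Lowlier zona", "morphogroup": "reclining",
                 "frond_length": 60.0, "frond_width": 30.0}]  # height 10
        rows += [{"taxon": "Upper zona", "morphogroup": "upright_frond",
                  "stem_length": 5.0, "stem_width": 1.0,
                  "frond_length": 15.0, "frond_width": 6.0}] * 3  # [5, 20]
        r = community_dvs(self._surface(rows))
        assert r.dvs_u == pytest.approx((0.5 + 2 / 3) / 2)
        assert r.weighted_dvs_u == pytest.approx((1 * 0.5 + 3 * (2 / 3)) / 4)

    def test_equal_abundances_make_weighting_a_noop(self):
        rows = [{"taxon": "A", "morphogroup": "reclining",
                 "frond_length": 60.0, "frond_width": 30.0}] * 4
        rows += [{"taxon": "B", "morphogroup": "upright_frond",
                  "stem_length": 5.0, "stem_width": 1.0,
                  "frond_length": 15.0, "frond_width": 6.0}] * 4
        r = community_dvs(self._surface(rows))
        assert r.weighted_dvs_u == pytest.approx(r.dvs_u)
        assert r.weighted_dvs_h == pytest.approx(r.dvs_h)

    def test_translation_invariance_of_dvs_u(self):
        rng = np.random.default_rng(5)
        profiles = _random_profiles(rng)
        shifted = [profile(p.taxon, p.n, p.heights,
                           [(lo + 7.5, hi + 7.5) for lo, hi in p.zone])
                   for p in profiles]
        for i in range(len(profiles)):
            assert taxon_dvs_u(profiles[i], profiles[:i] + profiles[i + 1:]) \
                == pytest.approx(
                    taxon_dvs_u(shifted[i], shifted[:i] + shifted[i + 1:]))

    def test_removing_a_taxon_never_decreases_dvs_u(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            profiles = _random_profiles(rng, max_taxa=4)
            t = profiles[0]
            full = taxon_dvs_u(t, profiles[1:])
            reduced = taxon_dvs_u(t, profiles[2:])
            assert reduced >= full - 1e-12

    def test_uniform_height_scaling_preserves_dvs_h(self):
        rng = np.random.default_rng(8)
        profiles = _random_profiles(rng)
        scaled = [profile(p.taxon, p.n, p.heights * 3.0, p.zone)
                  for p in profiles]
        for i in range(len(profiles)):
            assert taxon_dvs_h(profiles[i], profiles[:i] + profiles[i + 1:]) \
                == pytest.approx(
                    taxon_dvs_h(scaled[i], scaled[:i] + scaled[i + 1:]))

    def test_single_taxon_errors(self):
        rows = [{"taxon": "A", "morphogroup": "reclining",
                 "frond_length": 60.0, "frond_width": 30.0}] * 3
        with pytest.raises(ValueError, match=">= 2 eligible"):
            community_dvs(self._surface(rows))


class TestMorphogroupDVS:
    def _surface(self, groups):
        rows = []
        for g, n, stem, frond in groups:
            for _ in range(n):
                rows.append({"taxon": f"{g} taxon", "morphogroup": g,
                             "stem_length": stem, "stem_width": stem * 0.1,
                             "frond_length": frond, "frond_width": frond / 2})
        df = pd.DataFrame(rows)
        df["specimen_id"] = [f"m{i}" for i in range(len(df))]
        rng = np.random.default_rng(0)
        df["x"] = rng.uniform(0, 10, len(df))
        df["y"] = rng.uniform(0, 10, len(df))
        return make_surface(df)

    def test_two_abundant_groups_excluded(self):
        s = self._surface([("reclining", 40, 0.0, 60.0),
                           ("upright_frond", 40, 30.0, 60.0),
                           ("bradgatia", 5, 0.0, 40.0)])
        with pytest.raises(ValueError, match="fewer than 3"):
            morphogroup_dvs(s)

    def test_three_disjoint_groups_fully_tiered(self):
        s = self._surface([("reclining", 40, 0.0, 30.0),   # zone [0, 10]
                           ("bradgatia", 40, 0.0, 15.0),   # zone [0, 15] !
                           ("upright_frond", 40, 30.0, 60.0)])  # [30, 90]
        # bradgatia overlaps the recliner band; fronds are clear of both
        r = morphogroup_dvs(s)
        per = r.per_taxon.set_index("taxon")
        assert per.loc["upright_frond", "dvs_u"] == 1.0
        assert per.loc["reclining", "dvs_u"] < 1.0

    def test_matches_interval_oracle(self):
        s = self._surface([("reclining", 35, 0.0, 30.0),
                           ("bradgatia", 45, 0.0, 15.0),
                           ("upright_frond", 50, 5.0, 60.0)])
        r = morphogroup_dvs(s)
        per = r.per_taxon.set_index("taxon")
        # recliner zone [0,10]; others' union [0,15] u [5,65] = [0,65]
        assert per.loc["reclining", "dvs_u"] == pytest.approx(0.0)
        # bradgatia zone [0,15]; others [0,10] u [5,65] -> overlap 15
        assert per.loc["bradgatia", "dvs_u"] == pytest.approx(0.0)
        # fronds zone [5,65]; others [0,15] -> overlap 10/60
        assert per.loc["upright_frond", "dvs_u"] == pytest.approx(1 - 10 / 60)


class TestAssociations:
    def test_identity_and_inverse_correlations(self):
        rng = np.random.default_rng(9)
        w = rng.normal(0, 0.1, 18)
        tab = pd.DataFrame({
            "mean_w": w, "dvs_u": w, "dvs_h": w,
            "weighted_dvs_u": np.linspace(0.2, 0.9, 18),
            "weighted_dvs_h": w,
        })
        tab["stem_proportion"] = 1 - tab["weighted_dvs_u"]
        regs, corrs = tiering_succession_association(tab)
        assert corrs["dvs_h_vs_dvs_u"].rho == pytest.approx(1.0)
        assert corrs["stem_vs_weighted_dvs_u"].rho == pytest.approx(-1.0)
        assert regs["dvs_u"].adj_r2 == pytest.approx(1.0)

    def test_independent_vectors_uncorrelated_on_average(self):
        rng = np.random.default_rng(10)
        rhos = [spearman(rng.normal(size=18), rng.normal(size=18)).rho
                for _ in range(1000)]
        assert abs(np.mean(rhos)) < 0.1

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(5), np.arange(5.0))


def test_classify_tier_thresholds():
    assert classify_tier(0.71) == "high"
    assert classify_tier(0.70) == "medium"
    assert classify_tier(0.40) == "medium"
    assert classify_tier(0.39) == "low"


def test_stem_proportion_specimen_weighted():
    rows = [{"taxon": "Stalked", "morphogroup": "upright_frond",
             "stem_length": 20.0, "frond_length": 30.0,
             "frond_width": 10.0}] * 3
    rows += [{"taxon": "Prostrate", "morphogroup": "reclining",
              "frond_length": 60.0, "frond_width": 30.0}] * 9
    df = pd.DataFrame(rows)
    df["specimen_id"] = [f"s{i}" for i in range(len(df))]
    df["x"] = df["y"] = 1.0
    assert stem_proportion(make_surface(df)) == pytest.approx(0.25)


def test_tiering_table_classes(study_fixture):
    results = [community_dvs(f.surface) for f in study_fixture[:4]]
    tab = tiering_table(results)
    assert {"dvs_u", "weighted_dvs_u", "class_weighted_dvs_u"} <= \
        set(tab.columns)
    assert tab["class_weighted_dvs_u"].isin(["high", "medium", "low"]).all()
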