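"""Per-plot metric computations: basal area, biomass, carbon, dominance,
richness, trait imputation, Rao's Q and the climate score."""

import math

import numpy as np
import pandas as pd
import pytest

from mycoforest import (climate_score, impute_traits, mycorrhizal_dominance,
                        plot_tree_carbon, rao_q, species_richness,
                        stem_basal_area, stem_biomass)
from mycoforest.errors import (DegenerateInputError, DomainError,
                               ImputationError)
from mycoforest.metrics import gower_distance, trait_distance

from conftest import make_stems


class TestBasalArea:
    @pytest.mark.parametrize("dbh, expected", [
        (20.0, math.pi * 0.1 ** 2),          # d = 0.2 m circle
        (3.0, math.pi * 0.015 ** 2),         # 7.0686e-4 m^2
        (200.0, math.pi),
    ])
    def test_circle_area(self, dbh, expected):
        assert stem_basal_area(dbh) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            stem_basal_area(0.0)


class TestBiomass:
    def test_identity_coefficients(self):
        assert stem_biomass(1.0, 1.0, (0.0, 1.0)) == pytest.approx(1.0)

    def test_zero_exponent_gives_constant(self):
        assert stem_biomass(50.0, 30.0, (1.5, 0.0)) == pytest.approx(math.exp(1.5))

    def test_default_allometry_hand_value(self):
        # exp(-2.5 + 0.95*ln(10^2 * 8)) evaluated directly
        expected = math.exp(-2.5 + 0.95 * math.log(800))
        assert stem_biomass(10.0, 8.0, (-2.5, 0.95)) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(47.011, abs=0.001)

    def test_monotone_in_both_arguments(self):
        base = stem_biomass(10.0, 8.0)
        assert stem_biomass(11.0, 8.0) > base
        assert stem_biomass(10.0, 9.0) > base


class TestPlotTreeCarbon:
    def test_half_carbon_per_area(self):
        # one stem of exactly 1000 kg biomass in 0.09 ha -> 0.5/0.09 Mg C/ha
        stems = make_stems([("p", 1, "A", 10.0, 10.0)])
        h = 1000.0 / math.exp(-2.5 + 0.95 * math.log(100.0 * 1.0)) # solve c1=... easier: use c0=ln(1000),c1=0
        tc = plot_tree_carbon(stems, coeffs=(math.log(1000.0), 0.0), area_ha=0.09)
        assert tc == pytest.approx(0.5 / 0.09)

    def test_additive_and_linear(self):
        one = make_stems([("p", 1, "A", 12.0, 9.0)])
        two = make_stems([("p", 1, "A", 12.0, 9.0), ("p", 2, "B", 12.0, 9.0)])
        assert plot_tree_carbon(two) == pytest.approx(2 * plot_tree_carbon(one))

    def test_empty_plot_is_zero_with_warning(self, caplog):
        stems = make_stems([])
        with caplog.at_level("WARNING", logger="mycoforest"):
            assert plot_tree_carbon(stems) == 0.0
        assert "empty" in caplog.text


class TestDominance:
    def test_pure_ecm(self, toy_species):
        stems = make_stems([("p", 1, "A", 10.0, 8.0), ("p", 2, "A", 15.0, 9.0)])
        ecmd, amd = mycorrhizal_dominance(stems, toy_species)
        assert ecmd == 1.0 and amd == 0.0

    def test_single_dual_stem_splits_evenly(self, toy_species):
        stems = make_stems([("p", 1, "C", 10.0, 8.0)])
        ecmd, amd = mycorrhizal_dominance(stems, toy_species)
        assert ecmd == pytest.approx(0.5) and amd == pytest.approx(0.5)

    def test_hand_mixture(self, toy_species):
        # choose DBH so basal areas are 1:1:2 (EcM:dual:AM) -> ecmd = 1.5/4
        d = 20.0
        stems = make_stems([
            ("p", 1, "A", d, 8.0),
            ("p", 1, "C", d, 8.0),
            ("p", 1, "B", d * math.sqrt(2), 8.0),
        ])
        ecmd, amd = mycorrhizal_dominance(stems, toy_species)
        assert ecmd == pytest.approx(0.375)
        assert ecmd + amd == pytest.approx(1.0, abs=1e-12)

    def test_ratio_preserved_under_uniform_dbh_scaling(self, toy_species):
        stems = make_stems([("p", 1, "A", 10.0, 8.0), ("p", 1, "B", 17.0, 8.0),
                            ("p", 1, "C", 6.0, 8.0)])
        before = mycorrhizal_dominance(stems, toy_species)
        scaled = stems.assign(dbh=stems["dbh"] * 3.7)
        after = mycorrhizal_dominance(scaled, toy_species)
        assert before == pytest.approx(after, rel=1e-12)

    def test_empty_raises(self, toy_species):
        with pytest.raises(DomainError):
            mycorrhizal_dominance(make_stems([]), toy_species)


class TestRichness:
    @pytest.mark.parametrize("species_ids, expected", [
        (["A"] * 5, 1),
        (["A", "B", "C"], 3),
        (["A", "B", "C", "B", "C", "D", "E"], 5),  # union over subplots
    ])
    def test_distinct_count(self, species_ids, expected):
        stems = make_stems([("p", 1 + i % 9, s, 10.0, 8.0)
                            for i, s in enumerate(species_ids)])
        assert species_richness(stems) == expected


class TestImputation:
    def test_identity_when_complete(self, toy_species):
        out = impute_traits(toy_species)
        assert not out.isna().any().any()
        assert out.loc["A", "SLA"] == 10.0

    def test_mean_fill(self, toy_species):
        toy_species.loc[0, "SLA"] = np.nan  # others hold 20, 30, 40
        out = impute_traits(toy_species)
        assert out.loc["A", "SLA"] == pytest.approx(30.0)

    def test_species_level_average_before_fill(self, toy_species):
        dup = pd.concat([toy_species, toy_species.iloc[[0]].assign(SLA=30.0)])
        out = impute_traits(dup)
        assert out.loc["A", "SLA"] == pytest.approx(20.0)  # mean(10, 30)

    def test_all_missing_trait_errors(self, toy_species):
        toy_species["Pmass"] = np.nan
        with pytest.raises(ImputationError, match="Pmass"):
            impute_traits(toy_species)


class TestRaoQ:
    def test_single_species_zero(self):
        assert rao_q([1.0], [[0.0]]) == 0.0

    def test_two_species_hand_value(self):
        D = np.array([[0.0, 0.8], [0.8, 0.0]])
        assert rao_q([0.5, 0.5], D) == pytest.approx(0.4)

    def test_matches_brute_force_double_loop(self, rng):
        for n in [2, 5, 10]:
            p = rng.dirichlet(np.ones(n))
            D = rng.random((n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            brute = sum(p[i] * p[j] * D[i, j] for i in range(n) for j in range(n))
            assert rao_q(p, D) == pytest.approx(brute, rel=1e-12)

    def test_permutation_invariant(self, rng):
        p = rng.dirichlet(np.ones(6))
        D = rng.random((6, 6)); D = (D + D.T) / 2; np.fill_diagonal(D, 0)
        perm = rng.permutation(6)
        assert rao_q(p[perm], D[np.ix_(perm, perm)]) == pytest.approx(rao_q(p, D))

    def test_unnormalized_abundances_rejected(self):
        with pytest.raises(DomainError):
            rao_q([0.5, 0.6], np.zeros((2, 2)))


class TestTraitDistance:
    def test_gower_symmetric_zero_diagonal(self, toy_species):
        D = gower_distance(impute_traits(toy_species))
        arr = D.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)
        assert (arr >= 0).all() and (arr <= 1).all()

    def test_unknown_metric_rejected(self, toy_species):
        with pytest.raises(DomainError):
            trait_distance(impute_traits(toy_species), metric="cosine")


class TestClimateScore:
    def test_collinear_pair_explains_everything(self, rng):
        ts = rng.normal(100, 10, 50)
        scores, var1 = climate_score(ts, ts * 2.0 + 5.0)
        assert var1 == pytest.approx(1.0)

    def test_uncorrelated_pair_splits_variance(self):
        # exactly orthogonal standardized pair
        ts = np.array([1.0, 1.0, -1.0, -1.0])
        ps = np.array([1.0, -1.0, 1.0, -1.0])
        _, var1 = climate_score(ts, ps)
        assert var1 == pytest.approx(0.5)

    def test_sign_convention_max_seasonality_max_score(self, rng):
        ts = rng.normal(100, 15, 80)
        ps = 0.6 * ts + rng.normal(0, 8, 80)
        ts[3], ps[3] = ts.max() + 50, ps.max() + 50
        scores, _ = climate_score(ts, ps)
        assert scores.argmax() == 3

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            climate_score([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
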