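import numpy as np
import pandas as pd
import pytest

from conftest import effects_from, make_map, random_dh_case

from crossvar.core import GenotypeMatrix, MatingScheme
from crossvar.cross_metrics import (
    CrossParentEffects,
    cross_mean,
    cross_parent_effects,
    cross_variance,
    pair_covariance,
    predict_all_crosses,
    selection_intensity,
    superior_progeny_value,
    usefulness,
)
from crossvar.sim_oracle import exhaustive_dh_variance

DH0 = MatingScheme("DH", 0)


class TestCrossMean:
    def test_identical_parents_give_parental_value(self):
        cpe = CrossParentEffects(beta0=2.0, markers=["a", "b"],
                                 g=np.array([1.0, -0.5]), h=np.array([1.0, -0.5]))
        assert cross_mean(cpe) == pytest.approx(2.0 + 0.5)

    def test_symmetric_effects_cancel(self):
        cpe = CrossParentEffects(beta0=10.0, markers=["a"],
                                 g=np.array([1.0]), h=np.array([-1.0]))
        assert cross_mean(cpe) == pytest.approx(10.0)

    def test_equals_midparent_value(self):
        rng = np.random.default_rng(2)
        _, cpe, (d1, d2), u = random_dh_case(rng, 20, beta0=5.0)
        parent1_value = 5.0 + float(d1 @ u)
        parent2_value = 5.0 + float(d2 @ u)
        assert cross_mean(cpe) == pytest.approx((parent1_value + parent2_value) / 2)


class TestPairCovariance:
    def test_monomorphic_locus_contributes_nothing(self):
        assert pair_covariance(1.0, 1.0, 2.0, -2.0, 0.9) == 0.0

    def test_linkage_equilibrium_gives_zero(self):
        assert pair_covariance(1.0, -1.0, 2.0, -2.0, 0.5) == pytest.approx(0.0)

    def test_perfect_coupling(self):
        # two perfectly linked gametes: values (g_j+g_k) or (h_j+h_k), each 1/2
        assert pair_covariance(1.0, -1.0, 1.0, -1.0, 1.0) == pytest.approx(1.0)

    def test_q_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pair_covariance(1.0, 0.0, 1.0, 0.0, 1.2)


class TestCrossVariance:
    def test_monomorphic_cross_has_zero_variance(self):
        lmap = make_map([0.0, 10.0])
        cpe = CrossParentEffects(beta0=0.0, markers=lmap.markers,
                                 g=np.array([1.0, 2.0]), h=np.array([1.0, 2.0]))
        assert cross_variance(cpe, lmap, DH0) == 0.0

    def test_single_locus_diagonal_term(self):
        lmap = make_map([0.0])
        cpe = CrossParentEffects(beta0=0.0, markers=lmap.markers,
                                 g=np.array([1.0]), h=np.array([-1.0]))
        # two DH outcomes, values +-1 with probability 1/2 -> variance 1
        assert cross_variance(cpe, lmap, DH0) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        lmap, cpe, _, _ = random_dh_case(rng, 8, beta0=1.5)
        mu_e, var_e = exhaustive_dh_variance(cpe, lmap)
        assert cross_mean(cpe) == pytest.approx(mu_e, abs=1e-10)
        assert cross_variance(cpe, lmap, DH0) == pytest.approx(var_e, abs=1e-10)

    @pytest.mark.parametrize("kind,t", [("DH", 0), ("DH", 3), ("SSD", 0), ("SSD", 2)])
    def test_unlinked_limit_is_sum_of_single_locus_variances(self, kind, t):
        rng = np.random.default_rng(9)
        g = rng.normal(size=6)
        h = rng.normal(size=6)
        lmap = make_map(np.arange(6) * 1e7)  # effectively unlinked
        cpe = CrossParentEffects(beta0=0.0, markers=lmap.markers, g=g, h=h)
        expected = np.sum((g - h) ** 2) / 4
        assert cross_variance(cpe, lmap, MatingScheme(kind, t)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_parent_swap_leaves_moments_unchanged(self):
        rng = np.random.default_rng(10)
        lmap, cpe, _, _ = random_dh_case(rng, 12)
        swapped = CrossParentEffects(beta0=cpe.beta0, markers=cpe.markers,
                                     g=cpe.h.copy(), h=cpe.g.copy())
        assert cross_mean(swapped) == pytest.approx(cross_mean(cpe))
        for scheme in (DH0, MatingScheme("SSD", 1)):
            assert cross_variance(swapped, lmap, scheme) == pytest.approx(
                cross_variance(cpe, lmap, scheme)
            )

    def test_variance_ignores_intercept(self):
        rng = np.random.default_rng(12)
        lmap, cpe, _, _ = random_dh_case(rng, 10, beta0=0.0)
        shifted = CrossParentEffects(beta0=100.0, markers=cpe.markers, g=cpe.g, h=cpe.h)
        assert cross_variance(shifted, lmap, DH0) == pytest.approx(
            cross_variance(cpe, lmap, DH0)
        )

    def test_marker_missing_from_map_rejected(self):
        lmap = make_map([0.0])
        cpe = CrossParentEffects(beta0=0.0, markers=["mX"],
                                 g=np.array([1.0]), h=np.array([0.0]))
        with pytest.raises(ValueError, match="mX"):
            cross_variance(cpe, lmap, DH0)


class TestSelectionMetrics:
    @pytest.mark.parametrize(
        "p,expected,tol",
        [(1.0, 0.0, 0), (0.5, 2 / np.sqrt(2 * np.pi), 1e-12), (0.05, 2.0627128, 1e-6)],
    )
    def test_selection_intensity(self, p, expected, tol):
        assert selection_intensity(p) == pytest.approx(expected, abs=tol)

    def test_selection_intensity_monotone_decreasing(self):
        ps = [0.01, 0.05, 0.2, 0.5, 1.0]
        vals = [selection_intensity(p) for p in ps]
        assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.1])
    def test_selection_intensity_domain(self, p):
        with pytest.raises(ValueError):
            selection_intensity(p)

    def test_superior_progeny_value(self):
        assert superior_progeny_value(100.0, 2.0, 2.0627) == pytest.approx(104.1254)
        assert superior_progeny_value(5.0, 0.0, 2.0) == 5.0
        assert superior_progeny_value(5.0, 2.0, 0.0) == 5.0

    def test_usefulness(self):
        assert usefulness(100.0, 2.0, 2.0627, 0.5) == pytest.approx(102.0627)
        assert usefulness(100.0, 2.0, 2.0627, 1.0) == superior_progeny_value(100.0, 2.0, 2.0627)
        assert usefulness(100.0, 2.0, 2.0627, 0.0) == 100.0
        with pytest.raises(ValueError):
            usefulness(100.0, 2.0, 2.0, 1.5)


class TestPredictAllCrosses:
    def _parents(self, dosage, markers):
        return GenotypeMatrix(
            [f"P{i}" for i in range(len(dosage))], markers, np.asarray(dosage, dtype=float)
        )

    def test_pair_counts(self):
        lmap = make_map([0.0, 10.0])
        eff = effects_from([0.5, -0.5], lmap.markers)
        for n, expected in [(2, 1), (5, 10)]:
            rng = np.random.default_rng(n)
            parents = self._parents(2 * rng.integers(0, 2, size=(n, 2)), lmap.markers)
            preds = predict_all_crosses(parents, eff, lmap, DH0)
            assert len(preds) == expected

    def test_complementary_coupling_pair_ranks_first(self):
        """Parents fixed for opposite alleles in coupling phase at every
        locus maximize the segregation variance and rank first by s; the
        ranking is confirmed by exhaustive enumeration of all 6 crosses."""
        lmap = make_map([0.0, 30.0, 60.0, 90.0])
        u = np.ones(4)
        eff = effects_from(u, lmap.markers)
        dosages = {
            "P0": np.array([2.0, 2.0, 2.0, 2.0]),
            "P1": np.array([0.0, 0.0, 0.0, 0.0]),  # P0 x P1 fully coupling
            "P2": np.array([2.0, 0.0, 2.0, 0.0]),
            "P3": np.array([0.0, 2.0, 0.0, 2.0]),
        }
        parents = self._parents(list(dosages.values()), lmap.markers)
        parents.line_ids = list(dosages)
        preds = predict_all_crosses(parents, eff, lmap, DH0, p=0.05)
        assert {preds[0].parent1, preds[0].parent2} == {"P0", "P1"}
        assert sorted((p.s for p in preds), reverse=True) == [p.s for p in preds]
        # independent oracle: exhaustive enumeration per cross
        i = selection_intensity(0.05)
        s_exhaustive = {}
        for a, b in [("P0", "P1"), ("P0", "P2"), ("P0", "P3"),
                     ("P1", "P2"), ("P1", "P3"), ("P2", "P3")]:
            cpe = CrossParentEffects(
                beta0=0.0, markers=lmap.markers,
                g=dosages[a] * u, h=dosages[b] * u,
            )
            mean_e, var_e = exhaustive_dh_variance(cpe, lmap)
            s_exhaustive[(a, b)] = mean_e + i * np.sqrt(var_e)
        best = max(s_exhaustive, key=s_exhaustive.get)
        assert set(best) == {"P0", "P1"}
        for p in preds:
            assert p.s == pytest.approx(s_exhaustive[(p.parent1, p.parent2)], abs=1e-10)

    def test_heterozygous_parent_rejected(self):
        lmap = make_map([0.0, 10.0])
        eff = effects_from([0.5, -0.5], lmap.markers)
        parents = self._parents([[2, 0], [1, 2]], lmap.markers)
        with pytest.raises(ValueError, match="P1.*m0"):
            predict_all_crosses(parents, eff, lmap, DH0)

    def test_prediction_fields_consistent(self):
        lmap = make_map([0.0, 25.0])
        eff = effects_from([0.7, -0.3], lmap.markers, beta0=70.0)
        parents = self._parents([[2, 0], [0, 2]], lmap.markers)
        (pred,) = predict_all_crosses(parents, eff, lmap, DH0, p=0.1, h=0.8)
        assert pred.sigma == pytest.approx(np.sqrt(pred.sigma2))
        assert pred.s == pytest.approx(pred.mu + pred.i_used * pred.sigma)
        assert pred.U == pytest.approx(pred.mu + pred.i_used * pred.sigma * 0.8)
        assert pred.i_used == pytest.approx(selection_intensity(0.1))

    def test_missing_parental_dosage_drops_marker_from_both_sums(self):
        lmap = make_map([0.0, 10.0])
        eff = effects_from([0.5, -0.5], lmap.markers, beta0=1.0)
        cpe = cross_parent_effects(
            np.array([2.0, np.nan]), np.array([0.0, 2.0]), eff, lmap.markers
        )
        assert cpe.markers == ["m0"]
        assert cross_mean(cpe) == pytest.approx(1.0 + 0.5 * (2 * 0.5 + 0.0))
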