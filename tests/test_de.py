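"""DE-core tests: size factors, blind dispersion, exact test, BH, VST."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

import vernalseq as vs
from vernalseq.de import vst_raw, vst_values

from conftest import simulate_null_counts


def _df(arr, prefix="s"):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = _df(np.tile([[5], [10], [200]], (1, 4)))
        np.testing.assert_allclose(vs.size_factors(counts), 1.0)

    def test_three_fold_column(self):
        """Second column = 3x first -> factors {1/sqrt3, sqrt3}."""
        base = np.array([[10], [40], [100], [7]])
        counts = _df(np.hstack([base, 3 * base]))
        sf = vs.size_factors(counts)
        np.testing.assert_allclose(
            sf, [1 / math.sqrt(3), math.sqrt(3)], rtol=1e-12
        )

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        counts = _df(rng.integers(1, 1000, (50, 4)))
        sf = vs.size_factors(counts)
        scaled = counts.copy()
        c = 5
        scaled["s2"] = scaled["s2"] * c
        sf2 = vs.size_factors(scaled)
        # the scaled column's factor grows by c modulo the geometric-mean
        # renormalization shared by all columns
        ratio = sf2 / sf
        np.testing.assert_allclose(ratio["s2"] / ratio["s0"], c, rtol=1e-12)

    def test_no_all_positive_gene_errors(self):
        counts = _df([[0, 5], [3, 0]])
        with pytest.raises(ValueError, match="positive"):
            vs.size_factors(counts)


class TestBlindDispersion:
    def test_constant_counts_zero_dispersion(self):
        counts = _df(np.tile([[50], [400]], (1, 5)))
        fit = vs.estimate_dispersion_blind(counts, np.ones(5))
        np.testing.assert_allclose(fit.per_gene_alpha, 0.0, atol=1e-12)

    def test_parameter_recovery_within_50pct(self):
        """Planted (a0, a1) = (0.02, 2) recovered from 5000 genes x 5 samples."""
        counts, sf, _ = simulate_null_counts(5000, 5, 0.02, 2.0, seed=7)
        fit = vs.estimate_dispersion_blind(counts, sf)
        assert 0.01 <= fit.a0 <= 0.03
        assert 1.0 <= fit.a1 <= 3.0

    def test_poisson_null_fit_is_small(self):
        """Poisson counts: fitted dispersion <= 0.01 at mu >= 100."""
        counts, sf, _ = simulate_null_counts(5000, 5, 0.0, 0.0, seed=8)
        fit = vs.estimate_dispersion_blind(counts, sf)
        mu = np.logspace(2, 6, 20)
        assert np.all(fit.alpha(mu) <= 0.01)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            vs.estimate_dispersion_blind(_df([[5], [6]]), np.ones(1))


def exact_test_oracle(k_a, k_b, s_a, s_b, alpha):
    """Brute-force conditional NB test via direct lgamma arithmetic.

    Independent of the package path: per-split probabilities are
    computed in plain Python from the NB pmf definition and summed.
    """
    total = k_a + k_b
    if total == 0:
        return 1.0
    q = (k_a / s_a + k_b / s_b) / 2.0

    def pmf(k, mean):
        if alpha <= 0:
            return math.exp(k * math.log(mean) - mean - math.lgamma(k + 1))
        r = 1.0 / alpha
        p = r / (r + mean)
        return math.exp(
            math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
            + r * math.log(p) + k * math.log(1 - p)
        )

    probs = [pmf(a, q * s_a) * pmf(total - a, q * s_b) for a in range(total + 1)]
    p_obs = probs[k_a]
    return sum(p for p in probs if p <= p_obs * (1 + 1e-12)) / sum(probs)


class TestNBExactTest:
    def test_equal_counts_equal_factors_p_one(self):
        alpha_fn = lambda mu: 0.1
        for k in (1, 7, 40):
            assert vs.nb_exact_test(k, k, 1.0, 1.0, alpha_fn) == pytest.approx(1.0)

    def test_zero_pair_returns_one(self):
        assert vs.nb_exact_test(0, 0, 1.0, 2.0, lambda m: 0.1) == 1.0

    def test_matches_enumeration_oracle(self):
        alpha_fn = lambda mu: 0.1
        p = vs.nb_exact_test(0, 10, 1.0, 1.0, alpha_fn)
        assert p == pytest.approx(exact_test_oracle(0, 10, 1.0, 1.0, 0.1), rel=1e-10)

    @pytest.mark.parametrize("ka,kb,sa,sb,alpha", [
        (3, 25, 1.0, 1.0, 0.05),
        (12, 4, 0.7, 1.4, 0.2),
        (0, 55, 1.2, 0.8, 0.0),
        (100, 80, 2.1, 1.9, 0.01),
    ])
    def test_oracle_agreement_varied_inputs(self, ka, kb, sa, sb, alpha):
        p = vs.nb_exact_test(ka, kb, sa, sb, lambda m: alpha)
        assert p == pytest.approx(exact_test_oracle(ka, kb, sa, sb, alpha), rel=1e-10)

    def test_swap_invariance(self):
        alpha_fn = lambda mu: 0.08
        p1 = vs.nb_exact_test(6, 19, 0.9, 1.3, alpha_fn)
        p2 = vs.nb_exact_test(19, 6, 1.3, 0.9, alpha_fn)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            vs.nb_exact_test(-1, 3, 1.0, 1.0, lambda m: 0.1)
        with pytest.raises(ValueError):
            vs.nb_exact_test(1, 3, 0.0, 1.0, lambda m: 0.1)


class TestBHAdjust:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            vs.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_identical_and_singleton(self):
        np.testing.assert_allclose(vs.bh_adjust([0.2, 0.2, 0.2]), 0.2)
        np.testing.assert_allclose(vs.bh_adjust([0.37]), [0.37])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_padj_bounds_and_order_invariance(self, pvals):
        p = np.array(pvals)
        adj = vs.bh_adjust(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1 + 1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(vs.bh_adjust(p[perm]), adj[perm], rtol=1e-12)

    def test_monotone_in_p(self):
        p = np.array([0.001, 0.01, 0.2, 0.9])
        adj = vs.bh_adjust(p)
        assert np.all(np.diff(adj) >= -1e-12)


class TestVST:
    def test_closed_form_value(self):
        # (2/sqrt(0.1)) * asinh(sqrt(1)) at mu = 10, a0 = 0.1, a1 = 0
        assert vst_raw(10.0, 0.1, 0.0) == pytest.approx(
            (2 / math.sqrt(0.1)) * math.asinh(1.0), rel=1e-12
        )
        assert vst_raw(10.0, 0.1, 0.0) == pytest.approx(5.5743, abs=1e-4)

    def test_matches_numeric_quadrature(self):
        """Closed form equals int dmu / sqrt(v(mu)) to 1e-6 relative."""
        a0, a1 = 0.05, 1.5
        f = lambda mu: 1.0 / np.sqrt((1 + a1) * mu + a0 * mu**2)
        grid = np.logspace(0, 6, 25)
        for mu in grid:
            num, _ = integrate.quad(f, 1.0, mu, limit=200)
            closed = vst_raw(mu, a0, a1) - vst_raw(1.0, a0, a1)
            assert closed == pytest.approx(num, rel=1e-6, abs=1e-9)

    def test_poisson_limit_quadrature(self):
        a1 = 2.0
        f = lambda mu: 1.0 / np.sqrt((1 + a1) * mu)
        for mu in (10.0, 1e3, 1e6):
            num, _ = integrate.quad(f, 1.0, mu, limit=200)
            closed = vst_raw(mu, 0.0, a1) - vst_raw(1.0, 0.0, a1)
            assert closed == pytest.approx(num, rel=1e-6)

    def test_log2_like_calibration(self):
        """For large mu a doubling adds 1 and values approach log2(mu)."""
        a0, a1 = 0.02, 2.0
        mu = 1e9
        assert vst_values(2 * mu, a0, a1) - vst_values(mu, a0, a1) == pytest.approx(
            1.0, abs=1e-6
        )
        assert vst_values(mu, a0, a1) == pytest.approx(np.log2(mu), abs=1e-4)

    def test_monotone_in_counts(self):
        fit = vs.DispersionFit(pd.Series(dtype=float), a0=0.05, a1=1.0)
        counts = _df(np.arange(0, 40).reshape(-1, 1))
        out = vs.vst(counts, np.ones(1), fit)
        assert np.all(np.diff(out.to_numpy()[:, 0]) > 0)

    def test_replicate_sd_stable_across_means(self):
        """SD of transformed replicate counts varies < 20% over 2^4..2^14."""
        a0, a1 = 0.02, 2.0
        rng = np.random.default_rng(0)
        sds = []
        for e in range(4, 15):
            mu = 2.0**e
            alpha = a0 + a1 / mu
            r = 1 / alpha
            k = rng.negative_binomial(r, r / (r + mu), 4000)
            sds.append(np.std(vst_values(k, a0, a1)))
        assert max(sds) / min(sds) < 1.2


class TestPairwiseDE:
    def test_comparison_counts(self, leaf_de, leaf, meristem):
        results, _, _ = leaf_de
        assert len(results) == 10  # C(5,2)
        times = {(r.time_a, r.time_b) for r in results}
        assert len(times) == 10

    def test_meristem_three_comparisons(self):
        cfg = vs.SimulationConfig(
            grid=vs.meristem_grid(),
            n_genes=200,
            archetype_mix={"null_flat": 0.7, "long_day_up": 0.3},
            seed=6,
        )
        counts, samples, _ = vs.generate_timecourse(cfg)
        cm = vs.CountMatrix(counts=counts, samples=samples)
        results, _, _ = vs.pairwise_de(cm, vs.meristem_grid())
        assert len(results) == 3  # C(3,2)

    def test_padj_dominates_p_and_flag_consistent(self, leaf_de):
        results, _, info = leaf_de
        for r in results:
            t = r.table
            assert (t["padj"] >= t["pval"] - 1e-12).all()
            assert (t["significant"] == (t["padj"] < info["alpha"])).all()

    def test_union_matches_tables(self, leaf_de):
        results, union, _ = leaf_de
        rebuilt = set()
        for r in results:
            rebuilt |= r.significant_genes
        assert rebuilt == union

    def test_grid_sample_mismatch_rejected(self, leaf_scenario):
        _, counts, samples, _ = leaf_scenario
        cm = vs.CountMatrix(counts=counts, samples=samples)
        with pytest.raises(ValueError, match="grid"):
            vs.pairwise_de(cm, vs.TimeGrid(
                (0.0, 2.0, 28.0, 63.0, 99.0),
                ("pre_induction", "early_cold", "mid_cold", "late_cold", "long_day"),
                "leaf",
            ))

    def test_technical_replicates_summed(self):
        """Two replicate columns per time point behave like their sum."""
        cfg = vs.SimulationConfig(
            n_genes=150, n_replicates=2, seed=12,
            archetype_mix={"null_flat": 1.0},
        )
        counts, samples, _ = vs.generate_timecourse(cfg)
        cm = vs.CountMatrix(counts=counts, samples=samples)
        results, _, _ = vs.pairwise_de(cm, cfg.grid)
        assert len(results) == 10
        for r in results:
            assert ((r.table["pval"] > 0) & (r.table["pval"] <= 1)).all()
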