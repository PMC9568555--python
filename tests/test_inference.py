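import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metfref as m
from metfref.core_model import METF_COLUMNS


class TestWelch:
    def test_hand_computed_example(self):
        """Equal-variance samples make the Welch df exactly n1+n2−2."""
        res = m.welch_t([1, 2, 3, 4, 5], [3, 4, 5, 6, 7])
        assert res.t == pytest.approx(-2.0)
        assert res.df == pytest.approx(8.0)
        assert res.p == pytest.approx(0.0805, abs=5e-4)
        assert res.mean_diff == pytest.approx(-2.0)

    def test_identical_samples(self):
        res = m.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a, b = [1.0, 2.5, 3.0, 4.5], [2.0, 2.2, 5.1]
        fwd, rev = m.welch_t(a, b), m.welch_t(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p == pytest.approx(rev.p)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="n >= 2"):
            m.welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero variance"):
            m.welch_t([2.0, 2.0], [3.0, 3.0])


class TestHolm:
    def test_worked_example(self):
        adj = m.holm_adjust([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert m.holm_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert m.holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            m.holm_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_dominates_raw_and_bonferroni(self, ps):
        """Step-down formula from first principles: sort ascending,
        running max of (m−i)·p_(i), capped at 1 — the independent oracle
        for the library-backed implementation."""
        adj = m.holm_adjust(ps)
        order = np.argsort(ps)
        oracle = np.empty(len(ps))
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (len(ps) - rank) * ps[idx])
            oracle[idx] = min(1.0, running)
        assert adj == pytest.approx(oracle)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        bonf = np.minimum(1.0, np.asarray(ps) * len(ps))
        assert np.all(adj <= bonf + 1e-12)

    def test_permutation_equivariant(self):
        ps = [0.01, 0.2, 0.04, 0.8, 0.04]
        perm = [3, 0, 4, 1, 2]
        direct = m.holm_adjust(ps)
        permuted = m.holm_adjust([ps[i] for i in perm])
        assert permuted == pytest.approx([direct[i] for i in perm])


class TestMoments:
    def test_symmetric_sample(self):
        res = m.moments([-2, -1, 0, 1, 2])
        assert res.skewness == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_moments_near_zero(self):
        rng = np.random.default_rng(6)
        v = rng.standard_normal(100_000)
        res = m.moments(v)
        assert abs(res.skewness) < 3 * np.sqrt(6 / len(v))
        assert abs(res.kurtosis_excess) < 3 * np.sqrt(24 / len(v))
        assert res.kurtosis_raw == pytest.approx(res.kurtosis_excess + 3)

    def test_left_skewed_generator_output(self):
        spec = m.PopulationSpec(n_groups=1, n_methods=1,
                                n_tb_per_cell=500, sigma_tb=0,
                                sigma_method=0, sigma_group=0,
                                skew_shape=-5.0, seed=2)
        table, truth = m.sample_population(spec)
        merged = table.df.merge(truth.noise_free,
                                on=["tb_id", "frequency_hz"])
        res = m.moments((merged["metf_db"] - merged["truth_db"]).to_numpy())
        assert res.skewness < 0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            m.moments([1.0, 2.0, 3.0])


class TestPairwise:
    def test_shifted_groups_always_significant(self):
        """10 dB offset at σ=4 dB, n=30/group: power ≈ 1 everywhere."""
        rng = np.random.default_rng(8)
        rows = []
        for g, offset in (("Dresden", 0.0), ("Hannover", 10.0)):
            for i in range(30):
                for f in (500.0, 1000.0, 2000.0):
                    rows.append((f"{g}{i}", g, "A", f,
                                 rng.normal(-40 + offset, 4.0),
                                 "displacement", np.nan, False))
        table = m.METFTable(pd.DataFrame(rows, columns=METF_COLUMNS))
        comps = m.pairwise_by_frequency(table, "group", alpha=0.05)
        assert len(comps) == 3
        assert all(c.significant for c in comps)
        assert all(abs(c.mean_diff_db + 10) < 3 for c in comps)

    def test_single_level_yields_no_tests(self, small_population):
        table, _ = small_population
        one = m.METFTable(table.df[table.df["group"] == "Dresden"])
        assert m.pairwise_by_frequency(one, "group") == []

    def test_adjusted_p_dominates_raw(self, small_population):
        table, _ = small_population
        comps = m.pairwise_by_frequency(table, "group")
        # 4 groups -> 6 pairs at each of 8 frequencies
        assert len(comps) == 48
        for c in comps:
            assert c.p <= c.p_adj <= 1.0

    def test_global_family_is_stricter(self, small_population):
        table, _ = small_population
        per_f = m.pairwise_by_frequency(table, "group",
                                        holm_family="frequency")
        glob = m.pairwise_by_frequency(table, "group",
                                       holm_family="global")
        for a, b in zip(per_f, glob):
            assert b.p_adj >= a.p_adj - 1e-12


class TestLmm:
    def test_zero_variance_reduces_to_ols(self):
        spec = m.PopulationSpec(n_groups=2, n_methods=2, n_tb_per_cell=5,
                                sigma_tb=0, sigma_method=0, sigma_group=0,
                                sigma_resid=1.0, seed=1)
        table, truth = m.sample_population(spec)
        d = m.fit_lmm(table)
        assert d.converged
        for comp in ("sigma2_tb", "sigma2_method", "sigma2_group"):
            assert getattr(d, comp) < 0.05
        assert d.beta == pytest.approx(truth.mean_curve, abs=0.5)

    def test_matches_independent_mixed_model_solver(self):
        """Variance components and fixed effects agree with the
        general-purpose REML solver in statsmodels on the same data."""
        import statsmodels.formula.api as smf
        spec = m.PopulationSpec(n_groups=4, n_methods=2, n_tb_per_cell=6,
                                seed=11)
        table, _ = m.sample_population(spec)
        d = m.fit_lmm(table)
        df = table.df.copy()
        df["z"] = m.standardize_log_frequency(df["frequency_hz"],
                                              m.AUDIOLOGICAL_GRID)
        df["one"] = 1
        fit = smf.mixedlm(
            "metf_db ~ z + I(z**2) + I(z**3)", df, groups="one",
            vc_formula={"tb": "0 + C(tb_id)", "method": "0 + C(method)",
                        "group": "0 + C(group)"}).fit(reml=True)
        sm_group, sm_method, sm_tb = fit.vcomp  # alphabetical order
        assert d.sigma2_tb == pytest.approx(sm_tb, rel=1e-2)
        assert d.sigma2_method == pytest.approx(sm_method, rel=1e-2)
        assert d.sigma2_group == pytest.approx(sm_group, rel=2e-2)
        assert d.sigma2_resid == pytest.approx(fit.scale, rel=1e-2)
        assert d.beta == pytest.approx(fit.fe_params.values, abs=1e-3)

    def test_bitwise_reproducible(self):
        spec = m.PopulationSpec(n_groups=3, n_methods=2, n_tb_per_cell=5,
                                seed=23)
        table, _ = m.sample_population(spec)
        d1, d2 = m.fit_lmm(table), m.fit_lmm(table)
        assert d1.beta == d2.beta
        assert (d1.sigma2_tb, d1.sigma2_resid) == (d2.sigma2_tb,
                                                   d2.sigma2_resid)

    def test_single_level_factor_dropped_with_zero_variance(self):
        spec = m.PopulationSpec(n_groups=1, n_methods=1, n_tb_per_cell=20,
                                seed=31)
        table, _ = m.sample_population(spec)
        d = m.fit_lmm(table)
        assert set(d.dropped_factors) == {"method", "group"}
        assert d.sigma2_method == d.sigma2_group == 0.0
        assert d.sd("tb") == pytest.approx(4.2, rel=0.4)

    def test_higher_poly_order_adds_little(self):
        """Beyond the cubic, extra polynomial terms raise marginal R²
        by less than one percentage point on generator data."""
        spec = m.PopulationSpec(n_groups=4, n_methods=2, n_tb_per_cell=10,
                                seed=37)
        table, _ = m.sample_population(spec)
        r2_3 = m.fit_lmm(table, poly_order=3).r2_marginal
        for order in (4, 5):
            r2_h = m.fit_lmm(table, poly_order=order).r2_marginal
            assert r2_h - r2_3 < 0.01


class TestR2:
    def test_plug_in_values(self):
        d = m.VarianceDecomposition(
            beta=(0.0,), sigma2_tb=1.0, sigma2_method=0.0,
            sigma2_group=0.0, sigma2_resid=1.0, sigma2_fixed=2.0,
            r2_marginal=0.5, r2_conditional=0.75, loglik=0.0,
            converged=True, n_obs=10, poly_order=3)
        assert m.r2_nakagawa(d) == pytest.approx((0.5, 0.75))

    def test_pure_fixed_model_r2_one(self):
        d = m.VarianceDecomposition(
            beta=(0.0,), sigma2_tb=0.0, sigma2_method=0.0,
            sigma2_group=0.0, sigma2_resid=0.0, sigma2_fixed=3.0,
            r2_marginal=1.0, r2_conditional=1.0, loglik=0.0,
            converged=True, n_obs=10, poly_order=3)
        assert m.r2_nakagawa(d) == pytest.approx((1.0, 1.0))

    def test_printed_sds_square_to_printed_variances(self):
        """The published SD line (4.2, 3.4, 1.4 dB) squares to the
        published variance line (17.6, 11.5, 1.98 dB²) within print
        rounding."""
        assert 4.2 ** 2 == pytest.approx(17.6, abs=0.1)
        assert 3.4 ** 2 == pytest.approx(11.5, abs=0.1)
        assert 1.4 ** 2 == pytest.approx(1.98, abs=0.03)

    def test_marginal_never_exceeds_conditional(self, small_population):
        table, _ = small_population
        d = m.fit_lmm(table)
        r2m, r2c = m.r2_nakagawa(d)
        assert 0 <= r2m <= r2c <= 1
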