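import itertools

import numpy as np
import pytest
from scipy import stats as spstats

from trrkit import design as dsg
from trrkit import stats as st
from trrkit import synthdata as sd
from trrkit.hrf import canonical_hrf


def _simple_design(n, rng, k=3):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k))])
    labels = ["intercept"] + [f"x{i}" for i in range(k)]
    return dsg.DesignMatrix(X, labels, 1.5)


class TestMixedModel:
    def test_exact_recovery_zero_noise(self, rng):
        dm = _simple_design(200, rng)
        beta = np.array([1.0, 2.0, -0.5, 0.3])
        y = dm.matrix @ beta
        groups = np.repeat(["a", "b"], 100)
        spec = st.MixedModelSpec(dm, groups, random_labels=("intercept",))
        # zero noise makes the RE covariance singular; the floor is expected
        with pytest.warns(RuntimeWarning, match="variance floored"):
            fit = st.fit_mixed_model(spec, y)
        np.testing.assert_allclose(fit.coefficients.to_numpy(), beta, atol=1e-6)

    def test_ols_equivalence_without_random_effects(self, rng):
        dm = _simple_design(150, rng)
        y = rng.normal(size=150)
        groups = np.repeat(["a", "b", "c"], 50)
        spec = st.MixedModelSpec(dm, groups, random_labels=None)
        fit = st.fit_mixed_model(spec, y)
        beta_ols, *_ = np.linalg.lstsq(dm.matrix, y, rcond=None)
        np.testing.assert_allclose(fit.coefficients.to_numpy(), beta_ols,
                                   atol=1e-6)
        np.testing.assert_allclose(fit.residuals + fit.fitted, y, atol=1e-10)

    def test_random_slopes_recover_observer_scalings(self):
        # recovery study: per-observer slope BLUPs track the true scalings
        rs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n_obs, n_per = 9, 200
            t = np.arange(n_per)
            x = np.sin(2 * np.pi * t / 25) + 0.3 * np.sin(2 * np.pi * t / 7)
            scales = np.exp(rng.normal(0, 0.4, n_obs))
            ys, groups = [], []
            for i, s in enumerate(scales):
                ys.append(s * x + rng.normal(0, 0.3, n_per))
                groups.append(np.repeat(f"o{i}", n_per))
            X = np.column_stack([np.ones(n_obs * n_per), np.tile(x, n_obs)])
            dm = dsg.DesignMatrix(X, ["intercept", "x"], 1.5)
            spec = st.MixedModelSpec(dm, np.concatenate(groups),
                                     random_labels=("intercept", "x"))
            fit = st.fit_mixed_model(spec, np.concatenate(ys))
            slopes = np.array([fit.random_effects[f"o{i}"][1]
                               for i in range(n_obs)])
            rs.append(np.corrcoef(slopes, scales)[0, 1])
        assert min(rs) > 0.9

    def test_length_mismatch_rejected(self, rng):
        dm = _simple_design(50, rng)
        spec = st.MixedModelSpec(dm, np.repeat("a", 50), random_labels=None)
        with pytest.raises(ValueError):
            st.fit_mixed_model(spec, np.zeros(49))

    def test_unknown_random_label_rejected(self, rng):
        dm = _simple_design(50, rng)
        with pytest.raises(ValueError):
            st.MixedModelSpec(dm, np.repeat("a", 50), random_labels=("nope",))


class TestContrastFtest:
    def test_null_pvalues_uniform(self):
        # KS calibration oracle: 1,000 null OLS simulations
        pvals = []
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            dm = _simple_design(60, rng)
            y = rng.normal(size=60)
            spec = st.MixedModelSpec(dm, np.repeat("a", 60), random_labels=None)
            fit = st.fit_mixed_model(spec, y)
            _, p = st.contrast_ftest(fit, [0.0, 1.0, 0.0, 0.0])
            pvals.append(p)
        assert spstats.kstest(pvals, "uniform").pvalue > 0.001

    def test_duplicated_row_invariance(self, rng):
        dm = _simple_design(80, rng)
        y = rng.normal(size=80)
        spec = st.MixedModelSpec(dm, np.repeat("a", 80), random_labels=None)
        fit = st.fit_mixed_model(spec, y)
        row = np.array([0.0, 1.0, 1.0, 0.0])
        f1, p1 = st.contrast_ftest(fit, row)
        f2, p2 = st.contrast_ftest(fit, np.vstack([row, row]))
        assert f1 == pytest.approx(f2, rel=1e-9)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_zero_contrast_rejected(self, rng):
        dm = _simple_design(30, rng)
        spec = st.MixedModelSpec(dm, np.repeat("a", 30), random_labels=None)
        fit = st.fit_mixed_model(spec, rng.normal(size=30))
        with pytest.raises(ValueError):
            st.contrast_ftest(fit, np.zeros(4))

    def test_wrong_width_rejected(self, rng):
        dm = _simple_design(30, rng)
        spec = st.MixedModelSpec(dm, np.repeat("a", 30), random_labels=None)
        fit = st.fit_mixed_model(spec, rng.normal(size=30))
        with pytest.raises(ValueError):
            st.contrast_ftest(fit, np.zeros(5))


class TestExactP:
    def test_printed_floor_value(self):
        p = st.exact_p(0, 100_000)
        assert p == pytest.approx(9.9999e-6, rel=1e-4)
        # truncating to three significant digits gives the printed floor
        from decimal import Decimal
        mantissa = int(Decimal(p).scaleb(8))  # p * 1e8 truncated
        assert mantissa / 100.0 == pytest.approx(9.99)

    def test_b_equals_m(self):
        assert st.exact_p(5, 5) == 1.0

    def test_arithmetic(self):
        assert st.exact_p(7, 100_000) == pytest.approx(7.9999e-5, rel=1e-4)
        assert st.exact_p(4999, 9999) == 0.5

    def test_never_zero(self):
        assert st.exact_p(0, 1) == 0.5
        assert st.exact_p(0, 10**6) > 0

    def test_invalid(self):
        with pytest.raises(ValueError):
            st.exact_p(5, 4)
        with pytest.raises(ValueError):
            st.exact_p(0, 0)


class TestPermutationTest:
    def test_all_equal_ties_give_p_one(self):
        values = np.ones(10)
        labels = np.repeat([0, 1], 5)
        res = st.permutation_test(values, labels, m=200, seed=1)
        assert res.exceed_count == 200
        assert res.p_exact == 1.0

    def test_enumeration_oracle_small_n(self):
        # brute-force enumeration over all C(10,5) label assignments
        rng = np.random.default_rng(3)
        values = rng.normal(size=10)
        labels = np.repeat([0, 1], 5)
        m = 20_000
        res = st.permutation_test(values, labels, m=m, seed=4)
        obs = values[5:].mean() - values[:5].mean()
        stats = []
        idx = set(range(10))
        for comb in itertools.combinations(range(10), 5):
            rest = list(idx - set(comb))
            stats.append(values[list(comb)].mean() - values[rest].mean())
        stats = np.array(stats)
        p_enum = np.mean(stats >= obs - 1e-12)
        assert abs(res.p_exact - p_enum) < 2 / (m + 1) + 0.01

    def test_left_tail(self, rng):
        values = np.concatenate([np.zeros(6) + 1.0, np.zeros(6)])
        labels = np.repeat([0, 1], 6)
        right = st.permutation_test(values, labels, m=500, tail="right", seed=5)
        left = st.permutation_test(values, labels, m=500, tail="left", seed=5)
        assert left.p_exact < right.p_exact

    def test_reproducible(self, rng):
        values = rng.normal(size=20)
        labels = np.repeat([0, 1], 10)
        r1 = st.permutation_test(values, labels, m=300, seed=6)
        r2 = st.permutation_test(values, labels, m=300, seed=6)
        np.testing.assert_array_equal(r1.null_stats, r2.null_stats)

    def test_invalid_args(self, rng):
        values = rng.normal(size=10)
        with pytest.raises(ValueError):
            st.permutation_test(values, np.zeros(10), m=100)
        with pytest.raises(ValueError):
            st.permutation_test(values, np.repeat([0, 1], 5), m=0)

    def test_type_one_error_calibrated(self):
        # 2,000 null datasets x 500 permutations; rejection rate within the
        # 95% binomial interval of the attainable level 25/501
        m, n_sims, alpha = 500, 2000, 0.05
        level = np.floor(alpha * (m + 1)) / (m + 1)
        rng = np.random.default_rng(7)
        labels = np.repeat([0, 1], 10)
        rejections = 0
        for i in range(n_sims):
            values = rng.normal(size=20)
            res = st.permutation_test(values, labels, m=m, seed=int(i))
            rejections += res.p_exact <= alpha
        rate = rejections / n_sims
        half = 1.96 * np.sqrt(level * (1 - level) / n_sims)
        assert level - half <= rate <= level + half


class TestBorderTest:
    def _map(self, values):
        return st.VisualFieldMap(values)

    def test_constant_map_p_one(self):
        vmap = self._map(np.full((40, 70), 3.3))
        res = st.border_test(vmap, st.BorderSpec(n_draws=300), seed=0)
        assert res.p_exact == 1.0

    def test_edge_concentrated_map_minimal_p(self):
        ny, nx = 40, 70
        amp = np.zeros((ny, nx))
        t = 7.2
        px = 70.0 / nx
        py = 39.5 / ny
        xs = -35 + (np.arange(nx) + 0.5) * px
        ys = -19.75 + (np.arange(ny) + 0.5) * py
        inner = (np.abs(xs[None, :]) <= 35 - t) & (np.abs(ys[:, None]) <= 19.75 - t)
        amp[~inner] = 10.0
        m = 500
        res = st.border_test(self._map(amp), st.BorderSpec(n_draws=m), seed=1)
        assert res.p_exact == pytest.approx(1 / (m + 1))

    def test_gaussian_map_null_valid(self):
        # null calibration: clipped off-field bands have fewer pixels and
        # higher-variance means, so the p distribution is hump-shaped rather
        # than exactly uniform; the test must still be valid (conservative)
        pvals = []
        rng = np.random.default_rng(2)
        for rep in range(500):
            vmap = self._map(rng.normal(size=(20, 35)))
            res = st.border_test(vmap, st.BorderSpec(n_draws=200), seed=rep)
            pvals.append(res.p_exact)
        pvals = np.array(pvals)
        assert 0.45 < pvals.mean() < 0.55
        for alpha in (0.05, 0.1, 0.25):
            assert np.mean(pvals <= alpha) <= alpha + 0.03

    def test_shift_invariance(self, rng):
        amp = rng.normal(size=(20, 35))
        r1 = st.border_test(self._map(amp), st.BorderSpec(n_draws=400), seed=3)
        r2 = st.border_test(self._map(amp + 7.0), st.BorderSpec(n_draws=400), seed=3)
        assert r1.p_exact == r2.p_exact

    def test_oversized_thickness_rejected(self):
        with pytest.raises(ValueError):
            st.border_test(self._map(np.zeros((20, 35))),
                           st.BorderSpec(thickness_deg=50.0, n_draws=10), seed=0)

    def test_extent_matches_screen(self):
        vmap = self._map(np.zeros((20, 35)))
        assert vmap.x_extent_deg == (-35.0, 35.0)
        assert vmap.y_extent_deg == (-19.75, 19.75)


def _fdr_oracle(pvals, alpha):
    """Literal two-stage step-up, written independently of the package."""
    p = np.asarray(pvals)
    m = p.size
    q = alpha / (1 + alpha)

    def bh(p, q):
        order = np.argsort(p)
        thresh = q * np.arange(1, m + 1) / m
        passed = p[order] <= thresh
        if not passed.any():
            return np.zeros(m, bool)
        k = np.max(np.nonzero(passed)[0])
        rej = np.zeros(m, bool)
        rej[order[: k + 1]] = True
        return rej

    stage1 = bh(p, q)
    r1 = stage1.sum()
    if r1 == 0:
        return np.zeros(m, bool)
    if r1 == m:
        return np.ones(m, bool)
    return bh(p, q * m / (m - r1))


class TestTwoStageFDR:
    def test_all_ones_no_rejections(self):
        crit, rej = st.two_stage_fdr(np.ones(20), 0.05)
        assert not rej.any()

    def test_all_tiny_all_rejected(self):
        n = 16
        crit, rej = st.two_stage_fdr(np.full(n, 0.05 / n / 2), 0.05)
        assert rej.all()

    def test_matches_stepwise_oracle_on_mixed_vector(self):
        rng = np.random.default_rng(8)
        # 128 p-values: nulls uniform, alternatives concentrated near zero
        pvals = np.concatenate([
            rng.uniform(size=96),
            rng.uniform(0, 0.002, size=32),
        ])
        pvals = np.clip(pvals, 1e-12, 1.0)
        crit, rej = st.two_stage_fdr(pvals, 0.05)
        np.testing.assert_array_equal(rej, _fdr_oracle(pvals, 0.05))

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(9)
        for _ in range(5):
            pvals = np.clip(np.concatenate([
                rng.uniform(size=40), rng.uniform(0, 0.01, size=10),
            ]), 1e-12, 1.0)
            _, rej = st.two_stage_fdr(pvals, 0.05)
            ref = multipletests(pvals, alpha=0.05, method="fdr_tsbky")[0]
            np.testing.assert_array_equal(rej, ref)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            st.two_stage_fdr(np.array([]), 0.05)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.two_stage_fdr(np.array([0.0, 0.5]), 0.05)


class TestRtModulationSim:
    @pytest.fixture(scope="class")
    @staticmethod
    def behavior():
        proto = sd.ProtocolParams(n_runs=4,
                                  difficulty_schedule=("easy", "hard") * 2)
        obs = sd.ObserverModel(lapse_prob_easy=0.0, lapse_prob_hard=0.0)
        beh, _ = sd.simulate_behavior(proto, obs, sd.StaircaseSpec(), 60)
        return beh, proto

    def test_tot_amplitude_increases_with_rt(self, behavior):
        beh, proto = behavior
        out = st.rt_modulation_sim(beh, canonical_hrf(), proto)
        for (diff, corr) in {(k[0], k[1]) for k in out["ToT"]}:
            fast = out["ToT"].get((diff, corr, "fast"))
            slow = out["ToT"].get((diff, corr, "slow"))
            if fast is not None and slow is not None:
                assert slow > fast

    def test_to_bp_amplitude_decreases_with_rt(self, behavior):
        beh, proto = behavior
        out = st.rt_modulation_sim(beh, canonical_hrf(), proto)
        for (diff, corr) in {(k[0], k[1]) for k in out["TO+BP"]}:
            fast = out["TO+BP"].get((diff, corr, "fast"))
            slow = out["TO+BP"].get((diff, corr, "slow"))
            if fast is not None and slow is not None:
                assert slow < fast

    def test_zero_rt_limit(self, behavior):
        beh, proto = behavior
        beh0 = beh.copy()
        beh0["rt_s"] = 1e-9
        out = st.rt_modulation_sim(beh0, canonical_hrf(), proto)
        # ToT amplitude vanishes; TO+BP is exactly twice one impulse response
        from trrkit.events import convolve_stream, hrf_kernel
        rate = 50.0
        n = int(round(proto.trial_duration_s * rate))
        imp = np.zeros(n)
        imp[0] = rate
        single = convolve_stream(imp, hrf_kernel(canonical_hrf(), rate))
        expected = 2 * (single.max() - single.min())
        for key, amp in out["ToT"].items():
            assert amp == pytest.approx(0.0, abs=1e-6)
        for key, amp in out["TO+BP"].items():
            assert amp == pytest.approx(expected, rel=1e-6)

    def test_missing_rt_rejected(self, behavior):
        beh, proto = behavior
        bad = beh.copy()
        bad.loc[bad.index[2], "rt_s"] = np.nan
        with pytest.raises(ValueError):
            st.rt_modulation_sim(bad, canonical_hrf(), proto)
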