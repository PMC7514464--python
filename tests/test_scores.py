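import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats

from sqrkit import _engine
from sqrkit.calibration import slr_sigma
from sqrkit.order_statistics import UniformizedSample, sos_reference
from sqrkit.scores import (
    BlockScheme,
    reference_point,
    score_ad,
    score_ll,
    score_lr,
    score_p,
    score_rmslr,
    score_var,
    shifted_scores,
)


def classical_a_squared(u: np.ndarray) -> float:
    """Independent textbook Anderson-Darling A² for uniform(0,1) input.

    Uses the one-sided arrangement A² = -n - (1/n) sum_k [(2k-1) ln u_k +
    (2(n-k)+1) ln(1-u_k)], algebraically distinct from the package's
    paired-index form.
    """
    n = u.size
    k = np.arange(1, n + 1)
    return -n - np.mean((2 * k - 1) * np.log(u) + (2 * (n - k) + 1) * np.log1p(-u))


class TestAD:
    def test_single_point_value(self):
        u = UniformizedSample(np.array([0.5]))
        # (1-2) * (ln .5 + ln .5) / 1 = 2 ln 2
        assert score_ad(u).value == pytest.approx(1.386294, abs=1e-6)

    def test_equals_classical_a2_plus_n(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 200))
            u = UniformizedSample(np.sort(rng.random(n)))
            assert score_ad(u).value - n == pytest.approx(
                classical_a_squared(u.r), abs=1e-10
            )

    def test_reference_point_gives_zero_shift(self):
        ref = sos_reference(25)
        u = UniformizedSample(ref.mu)
        assert score_ad(u).value == pytest.approx(reference_point("AD", 25).value)
        sad, sll = shifted_scores(u)
        assert sad.value == pytest.approx(0.0, abs=1e-12)
        assert sll.value == pytest.approx(0.0, abs=1e-12)


class TestLL:
    def test_single_point_uniform_density(self):
        # beta(1, 1) is the standard uniform: log-density 0 everywhere
        u = UniformizedSample(np.array([0.5]))
        assert score_ll(u).value == pytest.approx(0.0, abs=1e-12)

    def test_equals_mean_beta_logpdf(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 200))
            u = UniformizedSample(np.sort(rng.random(n)))
            k = np.arange(1, n + 1)
            oracle = np.mean(stats.beta.logpdf(u.r, k, n - k + 1))
            assert score_ll(u).value == pytest.approx(oracle, abs=1e-10)

    def test_reference_point_n3(self):
        ref = sos_reference(3)
        u = UniformizedSample(ref.mu)
        assert score_ll(u).value == pytest.approx(reference_point("LL", 3).value)


class TestShifted:
    def test_shifted_ad_std_near_limit(self, rng):
        # large-N sd of S'_AD approaches sd[A²] = sqrt(2(pi²-9)/3) ≈ 0.7614
        vals = _engine.batch_ad(_engine.batch_surd(4000, 2000, rng))
        vals -= _engine.ad_reference(2000)
        target = np.sqrt(2 * (np.pi**2 - 9) / 3)
        assert vals.std(ddof=1) == pytest.approx(target, abs=0.04)

    def test_ad_ll_data_collapse(self, rng):
        # the -2-scaled shifted LL shares the shifted AD distribution
        r = _engine.batch_surd(8000, 1000, rng)
        sad = _engine.batch_ad(r) - _engine.ad_reference(1000)
        sll = -2.0 * (_engine.batch_ll(r) - _engine.ll_reference(1000))
        d = stats.ks_2samp(sad, sll).statistic
        assert d < 0.03


class TestVarAndP:
    def test_zero_at_mean_quantiles(self):
        ref = sos_reference(11)
        u = UniformizedSample(ref.mu)
        assert score_var(u).value == pytest.approx(0.0, abs=1e-20)

    def test_single_point_arithmetic(self):
        u = UniformizedSample(np.array([0.75]))
        assert score_var(u).value == pytest.approx(0.75, abs=1e-12)

    def test_expectation_is_one(self, rng):
        # E[S_VAR] = 1 exactly (unit-variance z by the beta law)
        vals = _engine.batch_var(_engine.batch_surd(20_000, 100, rng))
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - 1.0) < 3 * se

    def test_constant_z_power_mean_identity(self):
        ref = sos_reference(50)
        u = UniformizedSample(ref.mu + 0.1 * ref.sigma)
        vals = [score_p(u, p).value for p in (0.5, 1, 2, 3, 4)]
        assert np.allclose(vals, 0.1, atol=1e-12)

    def test_rejects_nonpositive_exponent(self, surd_1000):
        with pytest.raises(ValueError):
            score_p(surd_1000, 0.0)

    @given(seed=hst.integers(0, 2**16))
    @settings(max_examples=30, deadline=None)
    def test_power_mean_monotone_in_p(self, seed):
        r = np.sort(np.random.default_rng(seed).random(64))
        u = UniformizedSample(np.clip(r, 1e-12, 1 - 1e-12))
        vals = [score_p(u, p).value for p in (0.5, 1, 2, 3, 4)]
        assert np.all(np.diff(vals) >= -1e-12)


class TestLR:
    def test_identical_spacings_give_zero(self):
        r = np.linspace(0.1, 0.9, 12)  # all spacings equal
        u = UniformizedSample(r)
        m = score_lr(u, BlockScheme(nb=3, m=4))
        assert np.allclose(m.slr, 0.0)

    def test_antisymmetry_and_zero_diagonal(self, surd_1000):
        m = score_lr(surd_1000, BlockScheme.for_sample(1000))
        assert np.allclose(m.slr + m.slr.T, 0.0)
        assert np.allclose(np.diag(m.slr), 0.0)

    def test_block_scheme_validation(self):
        with pytest.raises(ValueError):
            BlockScheme(nb=1, m=10)
        with pytest.raises(ValueError):
            BlockScheme(nb=3, m=1)
        with pytest.raises(ValueError):
            BlockScheme.for_sample(10, nb=8)

    def test_scheme_blocks_disjoint_ordered_equal(self):
        sch = BlockScheme.for_sample(1000)
        ranges = sch.index_ranges()
        for (lo1, hi1), (lo2, hi2) in zip(ranges[:-1], ranges[1:]):
            assert hi1 == lo2 and hi1 - lo1 == hi2 - lo2

    def test_slr_centered_and_normal(self, rng):
        # S_LR(i, j) under SURD: mean 0, approximately normal
        r = _engine.batch_surd(20_000, 2500, rng)
        nb, m, start = _engine.rmslr_blocks(2500)
        ml = _engine.batch_block_meanlog(r, nb, m, start)
        slr = ml[:, 0] - ml[:, 1]
        assert abs(slr.mean()) < 5 * slr.std() / np.sqrt(slr.size)
        assert abs(stats.skew(slr)) < 0.1

    def test_slr_sigma_formula_matches_simulation(self, rng):
        # empirical sd of S_LR vs the calibrated sigma_LR(m, x=1), within 3%
        r = _engine.batch_surd(6000, 10_000, rng)
        nb, m, start = _engine.rmslr_blocks(10_000)
        ml = _engine.batch_block_meanlog(r, nb, m, start)
        slr = ml[:, 0] - ml[:, 1]
        assert slr.std(ddof=1) == pytest.approx(
            slr_sigma(m, 10_000, 10_000), rel=0.03
        )


class TestRMSLR:
    def test_two_blocks_reduces_to_single_pair(self, rng):
        r = np.sort(rng.random(40))
        u = UniformizedSample(r)
        val = score_rmslr(u, nb=2)
        sch = BlockScheme.for_sample(40, nb=2)
        ml = _engine.batch_block_meanlog(r[None, :], sch.nb, sch.m, sch.start)[0]
        expected = abs(ml[0] - ml[1]) / slr_sigma(sch.m, 40, 40)
        assert val.value == pytest.approx(expected, abs=1e-12)

    def test_distribution_invariant_across_n(self, rng):
        sizes = [1000, 5000, 20_000]
        samples = {
            n: _engine.batch_rmslr(_engine.batch_surd(2500, n, rng)) for n in sizes
        }
        for a, b in zip(sizes[:-1], sizes[1:]):
            assert stats.ks_2samp(samples[a], samples[b]).statistic < 0.05

    def test_uncorrelated_with_zvar(self, rng):
        # RMSLR measures spacing structure, not dispersion
        from sqrkit.calibration import default_model

        r = _engine.batch_surd(1500, 5000, rng)
        rm = _engine.batch_rmslr(r)
        mod = default_model("VAR")
        zv = np.abs((_engine.batch_var(r) - mod.mu(5000)) / mod.sigma(5000))
        assert abs(np.corrcoef(rm, zv)[0, 1]) < 0.1
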