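import json

import numpy as np
import pytest
from click.testing import CliRunner
from scipy import stats

from sqrkit import _engine, generate_surd, make_distribution, sample_distribution
from sqrkit.cli import main
from sqrkit.order_statistics import uniformize
from sqrkit.workbench import (
    TEST_SET,
    null_scores,
    read_cdf_spec,
    read_sample,
    simulate_null_moments,
    simulate_sqr_coverage,
)


class TestGenerateSurd:
    def test_deterministic_per_seed(self):
        a = generate_surd(100, 12)
        b = generate_surd(100, 12)
        assert np.array_equal(a.r, b.r)

    def test_large_sample_uniformity(self, rng):
        u = generate_surd(100_000, rng)
        assert u.r.mean() == pytest.approx(0.5, abs=0.005)
        assert stats.kstest(u.r, "uniform").pvalue > 0.001

    def test_order_statistic_means(self, rng):
        # mean of r_k over many trials -> k/(N+1)
        n, reps = 10, 30_000
        r = _engine.batch_surd(reps, n, rng)
        mu = np.arange(1, n + 1) / (n + 1)
        se = np.sqrt(mu * (1 - mu) / (n + 2) / reps)
        assert np.all(np.abs(r.mean(axis=0) - mu) < 5 * se)


class TestDistributions:
    def test_uniform_midpoint(self):
        d = make_distribution("uniform", lower=4, upper=8)
        assert d.cdf(6.0) == pytest.approx(0.5)

    def test_bimodal_normal_cdf_limits(self):
        name, params = TEST_SET[3]
        d = make_distribution(name, **params)
        assert d.cdf(1e6) == pytest.approx(1.0)
        assert d.cdf(-1e6) == pytest.approx(0.0, abs=1e-12)
        # mixture density integrates the weighted components
        assert d.pdf(2.0) > d.pdf(4.0)

    def test_bad_mixture_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            make_distribution(
                "bimodal_normal", mus=(0, 1), sigmas=(1, 1), ps=(0.7, 0.5)
            )

    def test_unknown_family_lists_supported(self):
        with pytest.raises(ValueError, match="supported"):
            make_distribution("zipf")

    def test_sample_is_sorted_and_reproducible(self):
        d = make_distribution("weibull", a=1.0, b=2.0)
        s1 = sample_distribution(d, 50, 5)
        s2 = sample_distribution(d, 50, 5)
        assert np.array_equal(s1.values, s2.values)
        assert np.all(np.diff(s1.values) >= 0)

    @pytest.mark.parametrize(
        "name,params",
        [t for t in TEST_SET if not t[0].startswith("stable")][::3],
        ids=lambda v: v if isinstance(v, str) else "",
    )
    def test_own_cdf_yields_surd(self, name, params, rng):
        # universality: scoring a sample under its own true cdf is scoring SURD
        d = make_distribution(name, **params)
        s = sample_distribution(d, 2000, rng)
        u = uniformize(s, d)
        assert stats.kstest(u.r, "uniform").pvalue > 1e-4

    def test_stable_sampler_and_cdf_consistent(self, rng):
        # the numerically integrated stable cdf matches its own sampler
        d = make_distribution("stable", alpha=0.5, beta=0.05, gamma=1.0, delta=4.0)
        x = np.sort(np.asarray(d.rvs(300, rng)))
        r = d.cdf(x)
        assert stats.kstest(r, "uniform").pvalue > 1e-4

    def test_universality_of_z_scores_across_distributions(self, rng):
        # Z_VAR null distributions coincide whatever generated the data
        from sqrkit.calibration import default_model

        n, trials = 1000, 2500
        model = default_model("VAR")
        zs = {}
        for name, params in [
            ("normal", {"mu": 1.0, "sigma": 1.0}),
            ("exponential", {"mu": 1.0}),
            ("beta", {"a": 0.5, "b": 0.5}),
        ]:
            d = make_distribution(name, **params)
            x = np.sort(np.asarray(d.rvs(trials * n, rng)).reshape(trials, n), axis=1)
            r = np.clip(d.cdf(x), 1e-12, 1 - 1e-12)
            s = _engine.batch_var(r)
            zs[name] = (s - model.mu(n)) / model.sigma(n)
        names = list(zs)
        for a in names:
            for b in names:
                if a < b:
                    assert stats.ks_2samp(zs[a], zs[b]).statistic < 0.05


class TestSimulationHelpers:
    def test_coverage_levels(self, rng):
        cov = simulate_sqr_coverage(200, 300, [1.0, 2.58, 1e9], rng)
        assert cov[1.0] < cov[2.58] < cov[1e9] == 1.0

    def test_null_moments_shapes(self, rng):
        out = simulate_null_moments(100, 400, rng)
        assert 0 < out["std_var"] < 2
        assert out["mean_p4"] > out["mean_p05"]

    def test_null_scores_measures(self, rng):
        out = null_scores(100, 300, ["Z_VAR", "CS"], rng)
        assert set(out) == {"Z_VAR", "CS"}
        assert out["CS"].min() >= 0


class TestIO:
    def test_sample_roundtrip(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("3.0\n1.0\n2.0\n")
        s = read_sample(p)
        assert np.array_equal(s.values, [1.0, 2.0, 3.0])

    def test_cdf_spec_json(self, tmp_path):
        p = tmp_path / "cdf.json"
        p.write_text(json.dumps({"name": "normal", "params": {"mu": 0, "sigma": 1}}))
        d = read_cdf_spec(p)
        assert d.cdf(0.0) == pytest.approx(0.5)

    def test_cdf_spec_tabulated(self, tmp_path):
        p = tmp_path / "cdf.csv"
        p.write_text("0,0\n1,1\n")
        cdf = read_cdf_spec(p)
        assert cdf(np.array([0.5]))[0] == pytest.approx(0.5)


class TestCli:
    def test_score_command_reports_measures(self, tmp_path, rng):
        sample = tmp_path / "s.txt"
        np.savetxt(sample, generate_surd(200, rng).r)
        res = CliRunner().invoke(main, ["score", str(sample)])
        assert res.exit_code == 0, res.output
        report = json.loads(res.output)
        assert report["n"] == 200
        assert "Z_VAR" in report["standardized"]

    def test_sqr_command_reproduces_worked_example(self, tmp_path):
        sample = tmp_path / "s.txt"
        sample.write_text("0.2\n0.8\n")
        out = tmp_path / "sqr.csv"
        res = CliRunner().invoke(main, ["sqr", str(sample), "--out", str(out)])
        assert res.exit_code == 0, res.output
        import pandas as pd

        tab = pd.read_csv(out)
        assert np.allclose(tab["sqr_k"], [-0.26667, 0.26667], atol=1e-4)

    def test_decoy_command_identity(self, tmp_path):
        spec = tmp_path / "d.json"
        spec.write_text(json.dumps({"family": "sine", "params": {"A": 0.0, "m": 1}}))
        out = tmp_path / "decoy.txt"
        res = CliRunner().invoke(
            main, ["decoy", str(spec), "-n", "100", "--seed", "1", "--out", str(out)]
        )
        assert res.exit_code == 0, res.output
        vals = np.loadtxt(out)
        assert np.array_equal(vals, generate_surd(100, 1).r)

    def test_roc_command_identity_decoy(self, tmp_path):
        suite = tmp_path / "suite.json"
        suite.write_text(
            json.dumps({"decoys": [{"family": "sine", "params": {"A": 0.0, "m": 1}}]})
        )
        out = tmp_path / "auc.csv"
        res = CliRunner().invoke(
            main,
            ["roc", "--suite", str(suite), "--measures", "|Z_VAR|",
             "--sizes", "100", "--trials", "400", "--seed", "2", "--out", str(out)],
        )
        assert res.exit_code == 0, res.output
        import pandas as pd

        tab = pd.read_csv(out)
        assert tab["auc"].iloc[0] == pytest.approx(0.5, abs=0.1)

    def test_partitions_command(self, tmp_path, rng):
        sample = tmp_path / "s.txt"
        np.savetxt(sample, generate_surd(800, rng).r)
        out = tmp_path / "parts.csv"
        res = CliRunner().invoke(
            main, ["partitions", str(sample), "--out", str(out)]
        )
        assert res.exit_code == 0, res.output
        import pandas as pd

        tab = pd.read_csv(out)
        assert list(tab["Np"]) == [800]

    def test_malformed_input_nonzero_exit(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("0,0\n1,0.5\n0.5,0.2\n")  # non-monotone x
        res = CliRunner().invoke(main, ["score", str(bad)])
        assert res.exit_code != 0
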