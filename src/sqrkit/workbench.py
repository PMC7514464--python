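"""Fixture generation, the distribution test set, file I/O and run plumbing.

Sampling any of the test-set distributions and uniformizing with its *own*
cdf produces sampled uniform random data (SURD) — the universality behind
all the scores: their null distributions do not depend on which continuous
distribution generated the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _engine
from .order_statistics import SortedSample, TabulatedCdf, UniformizedSample

__all__ = [
    "generate_surd",
    "DistributionSpec",
    "make_distribution",
    "sample_distribution",
    "TEST_SET",
    "RunConfig",
    "read_sample",
    "read_cdf_spec",
    "write_sqr_csv",
    "null_scores",
]


def generate_surd(
    n: int, rng: np.random.Generator | int | None = None
) -> UniformizedSample:
    """Sort-ordered i.i.d. uniforms on (0, 1); deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    r = np.clip(_engine.batch_surd(1, n, rng)[0], 1e-12, 1 - 1e-12)
    return UniformizedSample(r)


class _Mixture:
    """Finite mixture of frozen distributions; weighted cdf/pdf, component draw."""

    def __init__(self, components: Sequence, weights: Sequence[float]):
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be non-negative and sum to 1")
        self.components = list(components)
        self.weights = w

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return sum(w * c.cdf(x) for w, c in zip(self.weights, self.components))

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        return sum(w * c.pdf(x) for w, c in zip(self.weights, self.components))

    def rvs(self, size: int, random_state: np.random.Generator):
        counts = random_state.multinomial(size, self.weights)
        draws = np.concatenate(
            [
                np.atleast_1d(c.rvs(size=k, random_state=random_state))
                for c, k in zip(self.components, counts)
                if k > 0
            ]
        )
        random_state.shuffle(draws)
        return draws


@dataclass(frozen=True)
class DistributionSpec:
    """A named distribution with sampler, pdf and cdf."""

    name: str
    params: dict
    frozen: object = field(repr=False)

    def cdf(self, x):
        return self.frozen.cdf(x)

    def pdf(self, x):
        return self.frozen.pdf(x)

    def rvs(self, size: int, rng: np.random.Generator):
        return self.frozen.rvs(size=size, random_state=rng)


def _norm_mix(mus, sigmas, ps):
    return _Mixture([stats.norm(m, s) for m, s in zip(mus, sigmas)], ps)


def _uniform_mix(lowers, uppers, ps):
    return _Mixture(
        [stats.uniform(lo, hi - lo) for lo, hi in zip(lowers, uppers)], ps
    )


def _stable(alpha, beta, gamma, delta):
    return stats.levy_stable(alpha, beta, loc=delta, scale=gamma)


_BUILDERS = {
    "beta": lambda a, b: stats.beta(a, b),
    "bimodal_normal": _norm_mix,
    "birnbaum_saunders": lambda gamma, beta: stats.fatiguelife(gamma, scale=beta),
    "burr": lambda c, k, alpha=1.0: stats.burr12(c, k, scale=alpha),
    "exponential": lambda mu: stats.expon(scale=mu),
    # Gumbel for minima (the classical extreme-value convention for minima)
    "extreme_value": lambda sigma, mu: stats.gumbel_l(loc=mu, scale=sigma),
    "gamma": lambda k, sigma, mu=0.0: stats.gamma(k, scale=sigma, loc=mu),
    # shape sign: positive k = heavy upper tail (Frechet-type)
    "gev": lambda shape, scale, loc: stats.genextreme(-shape, loc=loc, scale=scale),
    "generalized_pareto": lambda k, sigma, theta: stats.genpareto(
        k, loc=theta, scale=sigma
    ),
    "half_normal": lambda sigma, mu: stats.halfnorm(loc=mu, scale=sigma),
    "inverse_gaussian": lambda lam, mu: stats.invgauss(mu / lam, scale=lam),
    "normal": lambda mu, sigma: stats.norm(mu, sigma),
    "normal_mix": _norm_mix,
    "stable": _stable,
    "stable_mix": lambda alphas, betas, gammas, deltas, ps: _Mixture(
        [_stable(a, b, g, d) for a, b, g, d in zip(alphas, betas, gammas, deltas)],
        ps,
    ),
    "t_location_scale": lambda nu, sigma, mu: stats.t(nu, loc=mu, scale=sigma),
    "uniform": lambda lower, upper: stats.uniform(lower, upper - lower),
    "uniform_mix": _uniform_mix,
    "weibull": lambda a, b: stats.weibull_min(b, scale=a),
}


def make_distribution(name: str, **params) -> DistributionSpec:
    """Build a test-set distribution by name; raises listing the known set."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unsupported distribution {name!r}; supported: {sorted(_BUILDERS)}"
        ) from None
    return DistributionSpec(name=name, params=params, frozen=builder(**params))


#: the distribution test set: monomodal shapes, sharp peaks, heavy tails and
#: mixtures (stable laws carry a numerically integrated cdf and are slow)
TEST_SET: tuple[tuple[str, dict], ...] = (
    ("beta", {"a": 0.5, "b": 1.5}),
    ("beta", {"a": 2.0, "b": 0.5}),
    ("beta", {"a": 0.5, "b": 0.5}),
    ("bimodal_normal", {"mus": (2, 6), "sigmas": (0.8, 0.3), "ps": (0.65, 0.35)}),
    ("birnbaum_saunders", {"gamma": 0.5, "beta": 1.5}),
    ("burr", {"c": 2.0, "k": 2.0, "alpha": 1.0}),
    ("exponential", {"mu": 1.0}),
    ("extreme_value", {"sigma": 2.0, "mu": 1.0}),
    ("gamma", {"k": 1.0, "sigma": 2.0, "mu": 2.0}),
    ("gev", {"shape": 2.0, "scale": 2.0, "loc": 2.0}),
    ("generalized_pareto", {"k": 2.0, "sigma": 1.0, "theta": 0.0}),
    ("half_normal", {"sigma": 1.0, "mu": 0.0}),
    ("inverse_gaussian", {"lam": 1.0, "mu": 5.0}),
    ("normal", {"mu": 1.0, "sigma": 1.0}),
    (
        "normal_mix",
        {"mus": (5, 5), "sigmas": (2.0, 0.25), "ps": (0.5, 0.5)},
    ),  # contaminated normal
    ("stable", {"alpha": 0.5, "beta": 0.05, "gamma": 1.0, "delta": 4.0}),
    ("stable", {"alpha": 0.2, "beta": 0.05, "gamma": 1.0, "delta": 4.0}),
    (
        "stable_mix",
        {
            "alphas": (0.5, 0.5),
            "betas": (0.05, 0.05),
            "gammas": (1.0, 1.0),
            "deltas": (2.0, 5.0),
            "ps": (0.25, 0.75),
        },
    ),
    (
        "stable_mix",
        {
            "alphas": (0.5, 0.5, 0.5),
            "betas": (0.05, 0.05, 0.05),
            "gammas": (1.0, 1.0, 1.0),
            "deltas": (2.0, 5.0, 8.0),
            "ps": (0.25, 0.5, 0.25),
        },
    ),
    (
        "normal_mix",
        {"mus": (4, 5, 6), "sigmas": (0.5, 0.25, 0.5), "ps": (1 / 3, 1 / 3, 1 / 3)},
    ),  # trimodal normal
    ("t_location_scale", {"nu": 1.0, "sigma": 0.5, "mu": 4.0}),
    ("uniform", {"lower": 4.0, "upper": 8.0}),
    (
        "uniform_mix",
        {
            "lowers": (1.0, 3.5, 7.0),
            "uppers": (2.0, 5.5, 9.0),
            "ps": (1 / 6, 4 / 6, 1 / 6),
        },
    ),
    (
        "uniform_mix",
        {
            "lowers": (1.0, 2.5, 4.0, 5.5, 7.0, 8.5),
            "uppers": (2.0, 3.5, 5.0, 6.5, 8.0, 9.5),
            "ps": (1 / 6,) * 6,
        },
    ),  # uniform periodic
    ("weibull", {"a": 1.0, "b": 2.0}),
)


def sample_distribution(
    spec: DistributionSpec, n: int, rng: np.random.Generator | int | None = None
) -> SortedSample:
    """Sorted random sample from a test-set distribution (true cdf on spec)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = np.sort(np.asarray(spec.rvs(n, rng), dtype=float))
    return SortedSample(x)


@dataclass
class RunConfig:
    """Run plumbing: seed and sizes recorded into every output."""

    seed: int = 0
    trials: int = 1000
    n_grid: tuple[int, ...] = (1000,)
    measures: tuple[str, ...] = ("|Z_VAR|", "|Z_4|", "CS")
    output_dir: str = "."

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def stamp(self) -> dict:
        return {"seed": self.seed, "trials": self.trials, "n_grid": list(self.n_grid)}


def read_sample(path: str | Path) -> SortedSample:
    """Plain text / single-column CSV, one real per line; sorts the values."""
    vals = (
        pd.read_csv(path, header=None, comment="#")
        .iloc[:, 0]
        .to_numpy(dtype=float)
    )
    return SortedSample.from_values(vals)


def read_cdf_spec(path: str | Path):
    """Candidate cdf: JSON {"name", "params"} or two-column CSV (x, F)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        d = json.loads(path.read_text())
        return make_distribution(d["name"], **d.get("params", {}))
    tab = pd.read_csv(path, header=None, comment="#").to_numpy(dtype=float)
    if tab.shape[1] != 2:
        raise ValueError("tabulated cdf must have exactly two columns (x, F)")
    return TabulatedCdf(tab[:, 0], tab[:, 1])


def write_sqr_csv(series, path: str | Path, x: np.ndarray | None = None) -> None:
    """SQR series as CSV with columns (k, mu_k, x_k, sqr_k)."""
    k = np.arange(1, series.n + 1)
    xcol = series.x if series.x is not None else (x if x is not None else np.full(series.n, np.nan))
    pd.DataFrame(
        {"k": k, "mu_k": series.mu, "x_k": xcol, "sqr_k": series.value}
    ).to_csv(path, index=False)


def simulate_sqr_coverage(
    n: int,
    realizations: int,
    sfs: Sequence[float],
    rng: np.random.Generator | int | None = None,
    chunk_budget: int = 20_000_000,
) -> dict[float, float]:
    """Pooled SQR contour coverage under SURD.

    Simulates ``realizations`` SURD samples of size n, pools all scaled
    quantile residuals, and returns the fraction inside the contour
    ``+- sf sqrt(mu (1 - mu))`` for each scale factor.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mu, sig = _engine.sos_mu_sigma(n)
    counts = {float(sf): 0 for sf in sfs}
    total = 0
    chunk = max(1, min(realizations, chunk_budget // n))
    for done in range(0, realizations, chunk):
        r = _engine.batch_surd(min(chunk, realizations - done), n, rng)
        # |SQR| <= sf sqrt(mu(1-mu))  <=>  |z| <= sf
        z = np.abs((r - mu) / sig)
        for sf in counts:
            counts[sf] += int(np.sum(z <= sf))
        total += z.size
    return {sf: c / total for sf, c in counts.items()}


def simulate_null_moments(
    n: int,
    trials: int,
    rng: np.random.Generator | int | None = None,
    chunk_budget: int = 20_000_000,
) -> dict[str, float]:
    """Monte-Carlo moments of the raw scores under SURD at size n.

    Returns the standard deviation of the shifted AD score and of S_VAR, and
    the means of S_4 and S_0.5 (the quantities whose large-N limits calibrate
    the finite-size corrections), all from one shared SURD stream.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ad_ref = _engine.ad_reference(n)
    sad, svar, s4, s05 = [], [], [], []
    chunk = max(1, min(trials, chunk_budget // n))
    for done in range(0, trials, chunk):
        r = _engine.batch_surd(min(chunk, trials - done), n, rng)
        sad.append(_engine.batch_ad(r) - ad_ref)
        svar.append(_engine.batch_var(r))
        s4.append(_engine.batch_p(r, 4.0))
        s05.append(_engine.batch_p(r, 0.5))
    return {
        "std_ad_shifted": float(np.std(np.concatenate(sad), ddof=1)),
        "std_var": float(np.std(np.concatenate(svar), ddof=1)),
        "mean_p4": float(np.mean(np.concatenate(s4))),
        "mean_p05": float(np.mean(np.concatenate(s05))),
        "trials": trials,
        "n": n,
    }


def null_scores(
    n: int,
    trials: int,
    measures: Sequence[str],
    rng: np.random.Generator | int | None = None,
    chunk_budget: int = 20_000_000,
) -> dict[str, np.ndarray]:
    """Null (SURD) distributions of standardized measures by simulation."""
    from .roc import _batch_measures

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    acc: dict[str, list] = {m: [] for m in measures}
    chunk = max(1, min(trials, chunk_budget // n))
    for done in range(0, trials, chunk):
        r = _engine.batch_surd(min(chunk, trials - done), n, rng)
        for m, v in _batch_measures(r, measures).items():
            acc[m].append(v)
    return {m: np.concatenate(v) for m, v in acc.items()}
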