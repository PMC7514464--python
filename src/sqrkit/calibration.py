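"""Finite-size corrections, Z-standardization and the composite score.

Raw scores S_t drift with sample size; empirical mean and standard-deviation
functions ``mu_t(N)``, ``sigma_t(N)`` standardize them into

    Z_t = (S_t - mu_t(N)) / sigma_t(N)

which is sample-size invariant to a good approximation for N >= 9.  The
correction functions follow the ladder form ``a + b/sqrt(N) + c/N +
d/N**1.5``.  The AD, VAR, S_0.5 and S_4 coefficients are the published
Monte-Carlo fits (each quoted with an uncertainty of 3 in the last digit); the
LL and p in {1, 2, 3} generalized-moment corrections ship as this package's
own Monte-Carlo refits (see ``data/corrections_fitted.json``, provenance
embedded), produced by :func:`fit_corrections`.

The pairwise spacing score S_LR needs a scale that also depends on the
sub-sampling fraction ``x = (N_p - 1)/(N - 1)`` of a partition:

    sigma_LR(m, x) = sqrt(2 x / m) * poly(x)

with a piecewise quintic/quartic polynomial switching at x = 1/2 (and
poly(x) ~ sqrt(trigamma(1/x)/x), its small-x theory).  The composite score

    CS = |Z_VAR + 0.666| + [max(2.5, |Z_4|, RMSLR) - 2.5]

uses the most probable Z_VAR value (-0.666) as baseline and adds an outlier
penalty only when |Z_4| or RMSLR exceeds 2.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import numpy as np

from . import _engine
from .order_statistics import UniformizedSample
from .scores import RawScore

__all__ = [
    "CorrectionModel",
    "StandardScore",
    "CompositeScore",
    "TABLE_COEFFICIENTS",
    "default_model",
    "z_transform",
    "slr_sigma",
    "composite_score",
    "fit_corrections",
    "standard_scores",
]

#: minimum sample size for which the corrections are calibrated
MIN_CALIBRATED_N = 9

#: published correction coefficients (a, b, c, d) of a + b/sqrt(n) + c/n + d/n^1.5
TABLE_COEFFICIENTS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "AD": {
        "mu": (1.0, -0.250, -0.667, 0.0),
        "sigma": (0.761, 0.0, 0.025, 0.0),
    },
    "VAR": {
        "mu": (1.0, 0.0, -0.003, 0.0),
        "sigma": (0.757, 0.312, 0.406, 0.0),
    },
    "P0.5": {
        "mu": (0.704, -0.008, 0.009, 0.52),
        "sigma": (0.302, 0.000, 0.313, 0.0),
    },
    "P4": {
        "mu": (1.153, 0.129, -1.630, 2.20),
        "sigma": (0.345, 0.303, 0.762, -2.56),
    },
}

#: sigma_LR polynomial, branch switching at x = 1/2
_SLR_POLY_LO = (1.0, 0.1888, 1.754, -13.71, 44.49, -47.01)
_SLR_POLY_HI = (-4.952, 29.12, -50.52, 38.95, -11.32)


@dataclass(frozen=True)
class CorrectionModel:
    """mu_t(n) and sigma_t(n) for one score family."""

    kind: str
    mu_coeffs: tuple[float, ...]
    sigma_coeffs: tuple[float, ...]
    fit_meta: dict | None = None

    def mu(self, n: int | np.ndarray) -> float | np.ndarray:
        return _ladder(self.mu_coeffs, n)

    def sigma(self, n: int | np.ndarray) -> float | np.ndarray:
        s = _ladder(self.sigma_coeffs, n)
        if np.any(np.asarray(s) <= 0):
            raise ValueError(f"sigma_{self.kind} non-positive at n={n}")
        return s

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "form": "a + b/sqrt(n) + c/n + d/n^1.5",
                "mu": list(self.mu_coeffs),
                "sigma": list(self.sigma_coeffs),
                "fit_meta": self.fit_meta,
            },
            indent=1,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "CorrectionModel":
        return cls(
            kind=d["kind"],
            mu_coeffs=tuple(d["mu"]),
            sigma_coeffs=tuple(d["sigma"]),
            fit_meta=d.get("fit_meta"),
        )


@dataclass(frozen=True)
class StandardScore:
    """Finite-size-corrected score Z_t; under SURD, mean -> 0 and std -> 1."""

    kind: str
    z: float
    n: int


@dataclass(frozen=True)
class CompositeScore:
    """CS = |Z_VAR + 0.666| + [max(2.5, |Z_4|, RMSLR) - 2.5]."""

    cs: float
    zvar: float
    z4: float
    rmslr: float


def _ladder(coeffs: Sequence[float], n: int | np.ndarray) -> float | np.ndarray:
    n = np.asarray(n, dtype=float)
    out = coeffs[0] + coeffs[1] / np.sqrt(n) + coeffs[2] / n
    if len(coeffs) > 3:
        out = out + coeffs[3] / n**1.5
    return float(out) if out.ndim == 0 else out


_FITTED_CACHE: dict[str, CorrectionModel] | None = None


def _fitted_models() -> dict[str, CorrectionModel]:
    global _FITTED_CACHE
    if _FITTED_CACHE is None:
        path = resources.files("sqrkit").joinpath("data/corrections_fitted.json")
        raw = json.loads(path.read_text())
        _FITTED_CACHE = {d["kind"]: CorrectionModel.from_dict(d) for d in raw["models"]}
    return _FITTED_CACHE


def default_model(kind: str, p: float | None = None) -> CorrectionModel:
    """Correction model for a score family.

    ``kind`` in {'AD', 'LL', 'VAR', 'P'}; the P family needs ``p``.  AD, VAR,
    P0.5, P4 use the published coefficients; LL, P1, P2, P3 use the shipped
    refits.
    """
    if kind == "P":
        if p is None:
            raise ValueError("P family needs the exponent p")
        kind = f"P{p:g}"
    if kind in TABLE_COEFFICIENTS:
        c = TABLE_COEFFICIENTS[kind]
        return CorrectionModel(kind=kind, mu_coeffs=c["mu"], sigma_coeffs=c["sigma"])
    fitted = _fitted_models()
    if kind in fitted:
        return fitted[kind]
    raise ValueError(f"no correction model for score kind {kind!r}")


_KIND_TO_MODEL = {"AD'": "AD", "LL'": "LL", "VAR": "VAR"}


def z_transform(raw: RawScore, model: CorrectionModel | None = None) -> StandardScore:
    """Standardize a raw score: Z = (S - mu(n)) / sigma(n).

    AD and LL enter through their shifted forms (kinds ``AD'`` and ``LL'``).
    Sizes below 9 are outside the calibrated regime and only warn.
    """
    if model is None:
        if raw.kind in _KIND_TO_MODEL:
            model = default_model(_KIND_TO_MODEL[raw.kind])
        elif raw.kind == "P":
            model = default_model("P", p=raw.p)
        elif raw.kind in ("AD", "LL"):
            raise ValueError(
                f"kind {raw.kind!r} must be shifted to its reference point first "
                "(use shifted_scores)"
            )
        else:
            raise ValueError(f"no default correction for kind {raw.kind!r}")
    if raw.n < MIN_CALIBRATED_N:
        warnings.warn(
            f"n={raw.n} is below the calibrated regime (N >= {MIN_CALIBRATED_N})",
            stacklevel=2,
        )
    z = (raw.value - model.mu(raw.n)) / model.sigma(raw.n)
    return StandardScore(kind=model.kind, z=float(z), n=raw.n)


def slr_poly(x: float | np.ndarray) -> np.ndarray:
    """Piecewise polynomial factor of sigma_LR, switching branches at x = 1/2."""
    x = np.asarray(x, dtype=float)
    lo = np.polynomial.polynomial.polyval(x, _SLR_POLY_LO)
    hi = np.polynomial.polynomial.polyval(x, _SLR_POLY_HI)
    return np.where(x < 0.5, lo, hi)


def slr_sigma(m: int, np_: int, n: int) -> float:
    """Null scale of S_LR(i, j) for block size ``m`` inside a partition.

    ``x = (np_ - 1)/(n - 1)`` is the sub-sampled fraction; x = 1 is the full
    sample.  sigma_LR = sqrt(2 x / (m - 1)) * poly(x) — the m - 1 accounts
    for the number of spacings actually averaged per block (it matters only
    for small blocks; simulation at m = 15 confirms the m - 1 form).
    """
    if m < 2:
        raise ValueError("block size m must be >= 2")
    x = (np_ - 1.0) / (n - 1.0)
    if x <= 0 or x > 1:
        raise ValueError(f"sub-sample fraction x={x} outside (0, 1]")
    return float(np.sqrt(2.0 * x / (m - 1.0)) * slr_poly(x))


def composite_score(
    zvar: StandardScore | float,
    z4: StandardScore | float,
    rmslr: RawScore | float,
) -> CompositeScore:
    """Composite score of one realization (all inputs from the same sample)."""
    zv = zvar.z if isinstance(zvar, StandardScore) else float(zvar)
    z4v = z4.z if isinstance(z4, StandardScore) else float(z4)
    rm = rmslr.value if isinstance(rmslr, RawScore) else float(rmslr)
    cs = abs(zv + 0.666) + (max(2.5, abs(z4v), rm) - 2.5)
    return CompositeScore(cs=cs, zvar=zv, z4=z4v, rmslr=rm)


_BATCH_FNS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "AD": lambda r: _engine.batch_ad(r) - _engine.ad_reference(r.shape[-1]),
    "LL": lambda r: -2.0 * (_engine.batch_ll(r) - _engine.ll_reference(r.shape[-1])),
    "VAR": _engine.batch_var,
    "P0.5": lambda r: _engine.batch_p(r, 0.5),
    "P1": lambda r: _engine.batch_p(r, 1.0),
    "P2": lambda r: _engine.batch_p(r, 2.0),
    "P3": lambda r: _engine.batch_p(r, 3.0),
    "P4": lambda r: _engine.batch_p(r, 4.0),
}


def fit_corrections(
    score_fn: str | Callable[[np.ndarray], np.ndarray],
    n_grid: Sequence[int],
    trials: int = 10_000,
    seed: int | np.random.Generator = 0,
    chunk_budget: int = 20_000_000,
) -> tuple[CorrectionModel, dict]:
    """Empirically refit mu_t(n) and sigma_t(n) by SURD simulation.

    For each n in ``n_grid`` (which should span at least two decades),
    ``trials`` SURD realizations are scored and the per-n mean and standard
    deviation are fit by least squares to the ladder
    ``a + b/sqrt(n) + c/n + d/n^1.5``.  Returns the model plus a diagnostics
    dict with the raw moments and fit residuals.
    """
    if isinstance(score_fn, str):
        kind = score_fn
        try:
            fn = _BATCH_FNS[score_fn]
        except KeyError:
            raise ValueError(
                f"unknown score kind {score_fn!r}; one of {sorted(_BATCH_FNS)}"
            ) from None
    else:
        kind, fn = getattr(score_fn, "__name__", "custom"), score_fn
    n_grid = sorted(int(n) for n in n_grid)
    if len(n_grid) < 5:
        raise ValueError("n_grid too small to constrain a 4-term fit")
    if n_grid[-1] < 100 * n_grid[0]:
        warnings.warn("n_grid spans less than two decades", stacklevel=2)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    means, stds = [], []
    for n in n_grid:
        chunk = max(1, min(trials, chunk_budget // n))
        vals = np.concatenate(
            [
                fn(_engine.batch_surd(min(chunk, trials - done), n, rng))
                for done in range(0, trials, chunk)
            ]
        )
        means.append(vals.mean())
        stds.append(vals.std(ddof=1))
    means = np.asarray(means)
    stds = np.asarray(stds)
    narr = np.asarray(n_grid, dtype=float)
    basis = np.column_stack(
        [np.ones_like(narr), narr**-0.5, 1.0 / narr, narr**-1.5]
    )
    mu_c, mu_res = _lstsq(basis, means)
    sg_c, sg_res = _lstsq(basis, stds)
    meta = {
        "n_grid": n_grid,
        "trials": trials,
        "seed": None if isinstance(seed, np.random.Generator) else int(seed),
        "mean_residual_rms": mu_res,
        "sigma_residual_rms": sg_res,
    }
    model = CorrectionModel(
        kind=kind, mu_coeffs=tuple(mu_c), sigma_coeffs=tuple(sg_c), fit_meta=meta
    )
    diagnostics = {"n": narr, "mean": means, "std": stds, **meta}
    return model, diagnostics


def _lstsq(basis: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    resid = y - basis @ coef
    return coef, float(np.sqrt(np.mean(resid**2)))


def standard_scores(u: UniformizedSample) -> dict[str, float]:
    """All standardized scores plus CS for one realization."""
    from .scores import score_p, score_rmslr, score_var, shifted_scores

    sad, sll = shifted_scores(u)
    out = {
        "Z_AD": z_transform(sad).z,
        "Z_LL": z_transform(sll).z,
        "Z_VAR": z_transform(score_var(u)).z,
    }
    for p in (0.5, 1.0, 2.0, 3.0, 4.0):
        out[f"Z_{p:g}"] = z_transform(score_p(u, p)).z
    rm = score_rmslr(u)
    out["RMSLR"] = rm.value
    out["CS"] = composite_score(out["Z_VAR"], out["Z_4"], rm).cs
    return out
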