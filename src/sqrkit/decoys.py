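"""Decoy-SURD generation: controlled perturbations of uniform order statistics.

A decoy cdf ``F_d(r) = r + Delta(r)`` deterministically distorts sampled
uniform random data (SURD) into decoy-SURD (dSURD), mimicking a wrong or
over-fitted density estimate.  Validity requires ``1 + Delta'(r) >= 0``
(monotone F_d) and ``Delta(0) = Delta(1) = 0``.

Families (perturbation shapes):

=========  ==================================================  =============
dimple     A exp(-(r - r_o)^2 / (2 sigma^2))                   A, r_o, sigma
pulse      A (r_o - r)/sigma^2 exp(-(r - r_o)^2/(2 sigma^2))   A, r_o, sigma
wavelet    A sin(m pi r) exp(-(r - r_o)^2/(2 sigma^2))         A, r_o, sigma, m
sine       A sin(m pi r)                                       A, m
beta       F_beta(r | alpha, beta) - r                         alpha, beta
reduced    r_d = r - p (r - mu_k)  (fluctuation shrinkage)     p
=========  ==================================================  =============

A decoy with ``max |Delta| = 1/sqrt(N_d)`` is marginally detectable at sample
size N_d: hard to distinguish from SURD for N < N_d, obvious for N >> N_d.
The reduced-fluctuation decoy is the exception — it suppresses fluctuations
by a fixed fraction p, so its difficulty does not depend on N.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy import stats

from .order_statistics import EPS, UniformizedSample

__all__ = [
    "DecoySpec",
    "DecoyCDF",
    "make_decoy",
    "calibrate_amplitude",
    "apply_decoy",
    "apply_reduced_fluctuations",
    "default_suite",
    "FAMILIES",
]

FAMILIES = ("dimple", "pulse", "wavelet", "sine", "beta", "reduced")

#: default grid resolution for tabulating F_d
GRID_POINTS = 100_001

#: default shape parameters where a family needs them
DEFAULT_SHAPES = {"r_o": 0.5, "sigma": 0.05, "m_wavelet": 8, "m_sine": 16}


@dataclass(frozen=True)
class DecoySpec:
    """A decoy family plus its parameters and (optionally) the difficulty N_d."""

    family: str
    params: dict = field(default_factory=dict)
    target_nd: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown decoy family {self.family!r}")
        if self.family == "reduced":
            p = self.params.get("p")
            if p is None or not (0.0 <= p < 1.0):
                raise ValueError("reduced decoy needs 0 <= p < 1")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": dict(self.params),
            "target_nd": self.target_nd,
        }


@dataclass(frozen=True)
class DecoyCDF:
    """Dense-grid tabulation of a valid decoy cdf F_d(r) = r + Delta(r)."""

    grid: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        g, f = self.grid, self.f
        if abs(f[0]) > 1e-9 or abs(f[-1] - 1.0) > 1e-9:
            raise ValueError("decoy cdf must satisfy F_d(0)=0, F_d(1)=1")
        df = np.diff(f)
        if np.any(df < 0):
            k = int(np.argmax(df < 0))
            raise ValueError(
                f"decoy cdf not monotone: negative slope near r={g[k]:.6g} "
                "(1 + Delta'(r) < 0)"
            )

    @property
    def delta(self) -> np.ndarray:
        return self.f - self.grid

    def __call__(self, r: np.ndarray) -> np.ndarray:
        return np.interp(r, self.grid, self.f)


def _raw_delta(family: str, params: dict, r: np.ndarray) -> np.ndarray:
    a = params.get("A", 0.0)
    if family == "dimple":
        ro, s = params["r_o"], params["sigma"]
        return a * np.exp(-((r - ro) ** 2) / (2 * s**2))
    if family == "pulse":
        ro, s = params["r_o"], params["sigma"]
        return a * (ro - r) / s**2 * np.exp(-((r - ro) ** 2) / (2 * s**2))
    if family == "wavelet":
        ro, s, m = params["r_o"], params["sigma"], params["m"]
        return a * np.sin(m * np.pi * r) * np.exp(-((r - ro) ** 2) / (2 * s**2))
    if family == "sine":
        return a * np.sin(params["m"] * np.pi * r)
    if family == "beta":
        al, be = params["alpha"], params["beta"]
        return stats.beta.cdf(r, al, be) - r
    raise ValueError(f"family {family!r} has no closed-form Delta(r)")


def make_decoy(spec: DecoySpec, grid_points: int = GRID_POINTS) -> DecoyCDF:
    """Tabulate F_d = r + Delta(r) on a uniform grid and validate it.

    The Gaussian-windowed families only satisfy Delta(0) = Delta(1) = 0
    approximately; when the residual boundary value exceeds 1e-6 the
    perturbation is multiplied by the taper 4 r (1 - r), renormalized to
    preserve max |Delta|.
    """
    if spec.family == "reduced":
        raise ValueError(
            "the reduced-fluctuation decoy is a map on realizations, not a "
            "cdf; use apply_reduced_fluctuations"
        )
    r = np.linspace(0.0, 1.0, grid_points)
    delta = _raw_delta(spec.family, spec.params, r)
    boundary = max(abs(delta[0]), abs(delta[-1]))
    if boundary > 1e-6:
        peak = np.max(np.abs(delta))
        delta = delta * (4.0 * r * (1.0 - r))
        new_peak = np.max(np.abs(delta))
        if new_peak > 0:
            delta *= peak / new_peak
    delta[0] = delta[-1] = 0.0
    return DecoyCDF(grid=r, f=r + delta)


def calibrate_amplitude(
    family: str,
    shape_params: dict | None = None,
    nd: float = 10_000.0,
    grid_points: int = GRID_POINTS,
) -> DecoySpec:
    """Scale a decoy's amplitude so that ``max |Delta| = 1/sqrt(nd)``.

    For the amplitude families (dimple/pulse/wavelet/sine) the amplitude A is
    solved directly (Delta is linear in A).  For the beta family, (alpha,
    beta) are moved along a log-space ray away from the uniform (1, 1) by
    bisection.  The reduced family has no N-dependent difficulty and is
    rejected.
    """
    if nd <= 0:
        raise ValueError("nd must be positive")
    target = 1.0 / np.sqrt(nd)
    shape_params = dict(shape_params or {})
    if family == "reduced":
        raise ValueError(
            "reduced-fluctuation difficulty is sample-size independent; "
            "choose the shrinkage fraction p directly"
        )
    if family in ("dimple", "pulse", "wavelet", "sine"):
        params = _fill_shapes(family, shape_params)
        params["A"] = 1.0
        r = np.linspace(0.0, 1.0, grid_points)
        unit_peak = np.max(np.abs(_raw_delta(family, params, r)))
        if unit_peak == 0:
            raise ValueError("degenerate shape: Delta vanishes identically")
        params["A"] = target / unit_peak
        spec = DecoySpec(family, params, target_nd=nd)
        make_decoy(spec, grid_points)  # validity check at this amplitude
        return spec
    if family == "beta":
        a0 = shape_params.get("alpha", 1.3)
        b0 = shape_params.get("beta", 0.8)
        la, lb = np.log(a0), np.log(b0)
        if la == 0.0 and lb == 0.0:
            raise ValueError("beta direction must differ from (1, 1)")
        r = np.linspace(0.0, 1.0, grid_points)

        def peak(t: float) -> float:
            d = stats.beta.cdf(r, np.exp(t * la), np.exp(t * lb)) - r
            return float(np.max(np.abs(d)))

        hi = 1.0
        while peak(hi) < target:
            hi *= 2.0
            if hi > 64:
                raise ValueError("beta grid search exhausted: target too hard")
        lo = 0.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            lo, hi = (mid, hi) if peak(mid) < target else (lo, mid)
        t = 0.5 * (lo + hi)
        params = {"alpha": float(np.exp(t * la)), "beta": float(np.exp(t * lb))}
        return DecoySpec("beta", params, target_nd=nd)
    raise ValueError(f"unknown decoy family {family!r}")


def _fill_shapes(family: str, params: dict) -> dict:
    out = dict(params)
    if family in ("dimple", "pulse", "wavelet"):
        out.setdefault("r_o", DEFAULT_SHAPES["r_o"])
        out.setdefault("sigma", DEFAULT_SHAPES["sigma"])
    if family == "wavelet":
        out.setdefault("m", DEFAULT_SHAPES["m_wavelet"])
    if family == "sine":
        out.setdefault("m", DEFAULT_SHAPES["m_sine"])
    return out


def apply_decoy(surd: UniformizedSample, decoy: DecoyCDF) -> UniformizedSample:
    """Map a SURD realization through the decoy cdf: r_d = F_d(r)."""
    rd = np.clip(decoy(surd.r), EPS, 1.0 - EPS)
    return UniformizedSample(rd)


def apply_reduced_fluctuations(surd: UniformizedSample, p: float) -> UniformizedSample:
    """Shrink fluctuations toward the mean quantiles: r_d = r - p (r - mu_k).

    p = 0 leaves the sample unchanged; p -> 1 collapses it onto the mean
    quantiles (no fluctuations left), mimicking extreme over-fitting.
    """
    if not (0.0 <= p < 1.0):
        raise ValueError("need 0 <= p < 1")
    k = np.arange(1, surd.n + 1, dtype=float)
    mu = k / (surd.n + 1.0)
    rd = np.clip(surd.r - p * (surd.r - mu), EPS, 1.0 - EPS)
    return UniformizedSample(np.sort(rd))


def default_suite() -> list[DecoySpec]:
    """The shipped decoy benchmark suite (~60 specs across all families)."""
    path = resources.files("sqrkit").joinpath("data/decoy_suite.json")
    raw = json.loads(path.read_text())
    return [
        DecoySpec(d["family"], d.get("params", {}), d.get("target_nd"))
        for d in raw["decoys"]
    ]


def suite_to_json(specs: Sequence[DecoySpec]) -> str:
    return json.dumps({"decoys": [s.to_dict() for s in specs]}, indent=1)
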