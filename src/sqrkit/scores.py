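"""The seven raw scoring functions on uniformized order statistics.

All scores consume a :class:`~sqrkit.order_statistics.UniformizedSample`
(sorted values strictly inside (0, 1), e.g. a sample mapped through a
candidate cdf) and quantify how far it departs from sampled uniform random
data (SURD):

============  ================================================================
``S_AD``      the sample-size-relevant part of the Anderson-Darling statistic;
              ``S_AD - N`` is the classical A-squared
``S_LL``      quasi log-likelihood: mean Beta(k, N-k+1) log-density at r_k
``S_VAR``     mean squared z-value, z_k = (r_k - mu_k)/sigma_k
``S_p``       generalized moment (mean |z_k|^p)^(1/p), p in {1/2, 1, 2, 3, 4}
``S_LR``      mean log-ratio of nearest-neighbour spacings between two equal
              disjoint index blocks (double order statistics)
``RMSLR``     root-mean-square of standardized S_LR over all distinct block
              pairs; sensitive to localized distortions
============  ================================================================

``S_AD`` and ``S_LL`` are used through their shifted forms, referenced to the
score at the mean quantiles (and, for LL, scaled by -2 to collapse onto the
AD distribution).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _engine
from .order_statistics import UniformizedSample, sos_reference

__all__ = [
    "RawScore",
    "ReferencePoint",
    "BlockScheme",
    "LogRatioMatrix",
    "score_ad",
    "score_ll",
    "reference_point",
    "shifted_scores",
    "score_var",
    "score_p",
    "score_lr",
    "score_rmslr",
    "P_EXPONENTS",
]

#: exponents of the generalized-moment family
P_EXPONENTS = (0.5, 1.0, 2.0, 3.0, 4.0)


@dataclass(frozen=True)
class RawScore:
    """A raw score value S_t for one realization.

    ``kind`` is one of ``AD``, ``AD'``, ``LL``, ``LL'``, ``VAR``, ``P``,
    ``RMSLR`` (the primed kinds are the shifted/scaled forms entering the
    Z-transform).  ``p`` is set for the P family only.
    """

    kind: str
    value: float
    n: int
    p: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"non-finite {self.kind} score")
        if self.kind in ("VAR", "P", "RMSLR") and self.value < 0:
            raise ValueError(f"{self.kind} score must be non-negative")


@dataclass(frozen=True)
class ReferencePoint:
    """S_AD or S_LL evaluated at the mean quantiles (deterministic in n)."""

    kind: str
    value: float
    n: int


@dataclass(frozen=True)
class BlockScheme:
    """Equal, disjoint, ordered consecutive index blocks for the LR scores."""

    nb: int
    m: int
    start: int = 0  #: 0-based offset of the first block

    def __post_init__(self) -> None:
        if self.nb < 2:
            raise ValueError("need at least 2 blocks")
        if self.m < 2:
            raise ValueError("blocks need m >= 2 indices (m-1 spacings)")
        if self.start < 0:
            raise ValueError("start must be non-negative")

    @classmethod
    def for_sample(cls, n: int, nb: int | None = None) -> "BlockScheme":
        """Default scheme: a fixed block count (16 at most 64) -- see
        the engine notes -- with remainder indices dropped symmetrically."""
        if nb is None:
            nb_, m, start = _engine.rmslr_blocks(n)
            return cls(nb=nb_, m=m, start=start)
        m = n // nb
        if m < 2:
            raise ValueError("too many blocks for this sample size")
        rem = n - nb * m
        return cls(nb=nb, m=m, start=rem // 2)

    def index_ranges(self) -> list[tuple[int, int]]:
        """Half-open 0-based (lo, hi) index range per block."""
        return [
            (self.start + i * self.m, self.start + (i + 1) * self.m)
            for i in range(self.nb)
        ]


@dataclass(frozen=True)
class LogRatioMatrix:
    """Antisymmetric matrix of S_LR(i, j) over all ordered block pairs."""

    slr: np.ndarray
    nb: int

    def __post_init__(self) -> None:
        s = np.asarray(self.slr, dtype=float)
        if s.shape != (self.nb, self.nb):
            raise ValueError("slr must be (nb, nb)")
        object.__setattr__(self, "slr", s)


def score_ad(u: UniformizedSample) -> RawScore:
    """Anderson-Darling-type score; ``value - N`` equals the classical A²."""
    _check_open_interval(u)
    return RawScore("AD", float(_engine.batch_ad(u.r)[0]), u.n)


def score_ll(u: UniformizedSample) -> RawScore:
    """Quasi log-likelihood score (mean field over Beta order-statistic pdfs)."""
    _check_open_interval(u)
    return RawScore("LL", float(_engine.batch_ll(u.r)[0]), u.n)


def reference_point(kind: str, n: int) -> ReferencePoint:
    """Natural reference point: the score evaluated at the mean quantiles."""
    if kind == "AD":
        return ReferencePoint("AD", _engine.ad_reference(n), n)
    if kind == "LL":
        return ReferencePoint("LL", _engine.ll_reference(n), n)
    raise ValueError("reference points exist for kinds 'AD' and 'LL' only")


def shifted_scores(u: UniformizedSample) -> tuple[RawScore, RawScore]:
    """Shifted scores ``S'_AD = S_AD(r) - S_AD(mu)`` and
    ``S'_LL = -2 [S_LL(r) - S_LL(mu)]``.

    The -2 factor on the LL deviation was determined empirically to collapse
    the S'_LL distribution onto the S'_AD one.
    """
    sad = score_ad(u).value - _engine.ad_reference(u.n)
    sll = -2.0 * (score_ll(u).value - _engine.ll_reference(u.n))
    return RawScore("AD'", sad, u.n), RawScore("LL'", sll, u.n)


def score_var(u: UniformizedSample) -> RawScore:
    """Mean squared z-value; expectation exactly 1 under SURD."""
    return RawScore("VAR", float(_engine.batch_var(u.r)[0]), u.n)


def score_p(u: UniformizedSample, p: float) -> RawScore:
    """Generalized moment of |z|; non-decreasing in p (power-mean inequality)."""
    if p <= 0:
        raise ValueError("exponent p must be positive")
    return RawScore("P", float(_engine.batch_p(u.r, p)[0]), u.n, p=p)


def score_lr(u: UniformizedSample, blocks: BlockScheme) -> LogRatioMatrix:
    """Mean log-ratio of spacings for all distinct ordered block pairs.

    The m-1 spacings ``delta_k = r_{k+1} - r_k`` are computed within each
    block only, the block mean logs once per block, and
    ``S_LR(i, j) = <log delta^(i)> - <log delta^(j)>``.
    """
    if blocks.start + blocks.nb * blocks.m > u.n:
        raise ValueError("block scheme does not fit the sample")
    ml = _engine.batch_block_meanlog(u.r, blocks.nb, blocks.m, blocks.start)[0]
    return LogRatioMatrix(slr=ml[:, None] - ml[None, :], nb=blocks.nb)


def score_rmslr(u: UniformizedSample, nb: int | None = None) -> RawScore:
    """Root-mean-square standardized log-ratio score.

    Blocks default to a fixed count (64) with size proportional to N, which
    keeps the null distribution sample-size invariant; each S_LR(i, j) is
    divided by its null scale ``sigma_LR(m, x)`` before squaring so the
    result is comparable with the 2.5 outlier threshold of the composite
    score.
    """
    if nb is None:
        value = float(_engine.batch_rmslr(u.r)[0])
        return RawScore("RMSLR", value, u.n)
    from .calibration import slr_sigma

    scheme = BlockScheme.for_sample(u.n, nb)
    ml = _engine.batch_block_meanlog(u.r, scheme.nb, scheme.m, scheme.start)[0]
    sig = slr_sigma(scheme.m, u.n, u.n)
    diffs = (ml[:, None] - ml[None, :]) / sig
    iu = np.triu_indices(scheme.nb, k=1)
    return RawScore("RMSLR", float(np.sqrt(np.mean(diffs[iu] ** 2))), u.n)


def all_raw_scores(u: UniformizedSample, p_values: Sequence[float] = P_EXPONENTS
                   ) -> dict[str, RawScore]:
    """Every raw score for one realization, keyed by report name."""
    sad, sll = shifted_scores(u)
    out: dict[str, RawScore] = {
        "AD": score_ad(u),
        "AD'": sad,
        "LL": score_ll(u),
        "LL'": sll,
        "VAR": score_var(u),
        "RMSLR": score_rmslr(u),
    }
    for p in p_values:
        out[f"P{p:g}"] = score_p(u, p)
    return out


def _check_open_interval(u: UniformizedSample) -> None:
    if u.r[0] <= 0.0 or u.r[-1] >= 1.0:
        raise ValueError("r values must lie strictly inside (0, 1)")
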