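"""Single-order-statistics reference quantities and scaled quantile residuals.

For a sorted sample of ``N`` i.i.d. draws from a continuous distribution with
cdf ``F``, the probability integral transform ``r_k = F(x_k)`` maps the order
statistics onto uniform order statistics on (0, 1).  Each ``r_k`` is then
Beta(k, N+1-k) distributed, with mean quantile ``mu_k = k/(N+1)`` and standard
deviation ``sigma_k = sqrt(mu_k (1-mu_k) / (N+2))``.

The *scaled quantile residual* (SQR)

    SQR_k = sqrt(N+2) * (r_k - mu_k)

has a pointwise spread ``sqrt(mu_k (1-mu_k))`` that does not depend on the
sample size, which makes SQR plots directly comparable across N.  Contours
``+- sf * sqrt(mu (1-mu))`` enclose a fixed fraction of SQR points: scale
factors 1.65, 1.96, 2.58 and 3.40 correspond to roughly 90%, 95%, 99% and
99.9% coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np

__all__ = [
    "EPS",
    "SortedSample",
    "UniformizedSample",
    "SOSReference",
    "SQRSeries",
    "ContourSpec",
    "TabulatedCdf",
    "uniformize",
    "sos_reference",
    "sqr",
    "coverage_fraction",
]

#: clip bound keeping transformed quantiles strictly inside (0, 1); protects
#: the logarithms used by the scoring functions
EPS = 1e-12


@dataclass(frozen=True)
class SortedSample:
    """A sort-ordered univariate sample ``{x_k}``, k = 1..N."""

    values: np.ndarray
    n: int = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("sample must be a non-empty 1-D array")
        if np.any(np.diff(v) < 0):
            raise ValueError("sample values must be sorted ascending")
        if not np.all(np.isfinite(v)):
            raise ValueError("sample values must be finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "n", int(v.size))

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "SortedSample":
        """Build from an unordered iterable (stable sort keeps duplicates)."""
        return cls(np.sort(np.asarray(values, dtype=float), kind="stable"))


@dataclass(frozen=True)
class UniformizedSample:
    """Probability-integral-transformed order statistics ``0 < r_k <= r_{k+1} < 1``."""

    r: np.ndarray
    n: int = field(init=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 1 or r.size < 1:
            raise ValueError("r must be a non-empty 1-D array")
        if r[0] <= 0.0 or r[-1] >= 1.0:
            raise ValueError("r must lie strictly inside (0, 1)")
        if np.any(np.diff(r) < 0):
            raise ValueError("r must be sorted ascending")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "n", int(r.size))


@dataclass(frozen=True)
class SOSReference:
    """Mean quantiles and their standard deviations for sample size ``n``."""

    mu: np.ndarray
    sigma: np.ndarray
    n: int


@dataclass(frozen=True)
class SQRSeries:
    """Scaled quantile residuals ``sqrt(N+2) (r_k - mu_k)`` with their positions."""

    mu: np.ndarray
    value: np.ndarray
    n: int
    x: np.ndarray | None = None  #: original sample values when available

    @property
    def position(self) -> np.ndarray:
        """Plot abscissa: original x when attached, else the mean quantile."""
        return self.mu if self.x is None else self.x


@dataclass(frozen=True)
class ContourSpec:
    """Coverage contour ``+- sf * sqrt(mu (1 - mu))`` on the SQR plot."""

    sf: float
    target_coverage: float | None = None

    def __post_init__(self) -> None:
        if self.sf <= 0:
            raise ValueError("scale factor must be positive")

    def boundary(self, mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        return self.sf * np.sqrt(mu * (1.0 - mu))


#: default contours and the coverage levels they were simulated to enclose
STANDARD_CONTOURS = (
    ContourSpec(1.65, 0.90),
    ContourSpec(1.96, 0.95),
    ContourSpec(2.58, 0.99),
    ContourSpec(3.40, 0.999),
)


class TabulatedCdf:
    """Monotone piecewise-linear cdf given as (x, F) knots.

    Constant extrapolation outside the tabulated range; a strictly decreasing
    step anywhere in ``F`` is rejected because the probability integral
    transform requires a monotone map.
    """

    def __init__(self, x: Sequence[float], f: Sequence[float]):
        x = np.asarray(x, dtype=float)
        f = np.asarray(f, dtype=float)
        if x.ndim != 1 or x.shape != f.shape or x.size < 2:
            raise ValueError("need matching 1-D x and F arrays with >= 2 knots")
        if np.any(np.diff(x) <= 0):
            raise ValueError("tabulated x knots must be strictly increasing")
        df = np.diff(f)
        if np.any(df < 0):
            k = int(np.argmax(df < 0))
            raise ValueError(
                f"tabulated cdf is not monotone non-decreasing at x={x[k + 1]!r}"
            )
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("tabulated F values must lie in [0, 1]")
        self.x = x
        self.f = f

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.interp(x, self.x, self.f, left=self.f[0], right=self.f[-1])


CdfLike = Union[Callable[[np.ndarray], np.ndarray], TabulatedCdf]


def _as_cdf_callable(cdf: object) -> Callable[[np.ndarray], np.ndarray]:
    if callable(cdf):
        return cdf  # includes TabulatedCdf
    if hasattr(cdf, "cdf"):
        return cdf.cdf  # scipy frozen distribution or DistributionSpec
    raise TypeError("cdf must be callable, have a .cdf method, or be a TabulatedCdf")


def uniformize(sample: SortedSample, cdf: object, eps: float = EPS) -> UniformizedSample:
    """Map a sorted sample through a candidate cdf: ``r_k = F(x_k)``.

    The output is clipped into ``(eps, 1 - eps)`` so downstream logarithms are
    finite.  A monotone map of sorted input stays sorted; a decreasing ``r``
    indicates a non-monotone candidate cdf and is rejected.  Runs of ties in
    ``r`` (beyond 0.1% of consecutive differences below ``eps``) trigger a
    warning because the scores assume continuous data.
    """
    fn = _as_cdf_callable(cdf)
    r = np.asarray(fn(sample.values), dtype=float)
    if r.shape != sample.values.shape:
        raise ValueError("cdf returned a shape different from the input sample")
    if np.any(np.diff(r) < 0):
        k = int(np.argmax(np.diff(r) < 0))
        raise ValueError(
            f"candidate cdf is not monotone over the sample (decrease after "
            f"x={sample.values[k]!r})"
        )
    r = np.clip(r, eps, 1.0 - eps)
    d = np.diff(r)
    if d.size and np.mean(d < eps) > 1e-3:
        warnings.warn(
            "more than 0.1% of consecutive transformed values are tied; the "
            "continuity assumption behind the SQR scores is violated",
            stacklevel=2,
        )
    return UniformizedSample(r)


def sos_reference(n: int) -> SOSReference:
    """Exact single-order-statistics reference: ``mu_k``, ``sigma_k`` for size n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    k = np.arange(1, n + 1, dtype=float)
    mu = k / (n + 1.0)
    sigma = np.sqrt(mu * (1.0 - mu) / (n + 2.0))
    return SOSReference(mu=mu, sigma=sigma, n=int(n))


def sqr(
    u: UniformizedSample,
    positions: str = "mean-quantile",
    x: np.ndarray | None = None,
) -> SQRSeries:
    """Scaled quantile residual series ``sqrt(N+2) (r_k - mu_k)``.

    ``positions='original-x'`` attaches the raw sample values so the series
    can be plotted against x instead of the mean quantile.
    """
    ref = sos_reference(u.n)
    value = np.sqrt(u.n + 2.0) * (u.r - ref.mu)
    if positions == "mean-quantile":
        return SQRSeries(mu=ref.mu, value=value, n=u.n)
    if positions == "original-x":
        if x is None:
            raise ValueError("positions='original-x' requires the x array")
        x = np.asarray(x, dtype=float)
        if x.shape != u.r.shape:
            raise ValueError("x must match the sample length")
        return SQRSeries(mu=ref.mu, value=value, n=u.n, x=x)
    raise ValueError("positions must be 'mean-quantile' or 'original-x'")


def coverage_fraction(s: SQRSeries, sf: float) -> float:
    """Fraction of SQR points inside the contour ``+- sf sqrt(mu(1-mu))``."""
    if sf <= 0:
        raise ValueError("scale factor must be positive")
    if s.value.size == 0:
        raise ValueError("empty SQR series")
    bound = sf * np.sqrt(s.mu * (1.0 - s.mu))
    return float(np.mean(np.abs(s.value) <= bound))
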