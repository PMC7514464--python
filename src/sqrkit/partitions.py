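"""Hierarchical mirror-symmetric sub-sampling (partitions) of a sorted sample.

Large samples are scored on a ladder of nested sub-samples ("partitions") of
odd sizes 3, 5, 9, 17, ..., 1 + 2**k, capped by the full size N.  A partition
always contains the first index, the last index and the median index, and its
index set is symmetric under k -> N + 1 - k — the Anderson-Darling score is
sensitive to breaking this mirror symmetry, the other scores are not.

The ladder is built as a nested family of uniformly random index subsets:
the largest sub-partition draws its lower-half interior indices uniformly at
random (then mirrors them), and each coarser partition is a symmetric random
thinning of the finer one, so every partition is a superset of the previous
— the refinement pattern read top-down.  The randomness matters: any
deterministic or stratified evenly spaced rank selection suppresses the
fluctuations of the sub-sampled values (they stop behaving like uniform
order statistics of the partition size, e.g. S_VAR collapses to roughly
(N_p-1)/(N-1) instead of 1) and destroys the size invariance of the scores.
A uniformly random subset of i.i.d. uniforms is itself an i.i.d. uniform
sample, so under this rule each partition behaves like SURD of its own size
N_p and every score keeps its N_p-calibrated null distribution — including
the spacing-based LR scores, whose scale is therefore taken at the
partition's own size (the x-dependent scale sigma_LR(m, x) in
:func:`sqrkit.calibration.slr_sigma` describes evenly spread sub-samples
instead, where spacing fluctuations really are suppressed by x).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from . import _engine
from .calibration import StandardScore, default_model, slr_sigma
from .order_statistics import EPS, UniformizedSample

__all__ = [
    "PartitionScheme",
    "partition_sizes",
    "build_partitions",
    "score_partitions",
    "is_valid_partition_index_set",
]

#: partitions are only used above this size (1 + 2**10)
DEFAULT_MIN_SIZE = 1025


@dataclass(frozen=True)
class PartitionScheme:
    """Nested ladder of mirror-symmetric index sets (1-based, sorted)."""

    full_n: int
    sizes: tuple[int, ...]
    index_sets: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        for size, idx in zip(self.sizes, self.index_sets):
            if idx.size != size:
                raise ValueError("index set size mismatch")


def partition_sizes(n: int, min_size: int = DEFAULT_MIN_SIZE) -> list[int]:
    """The ladder 1+2**k (>= min_size, < n) followed by the full size n."""
    if n < 3:
        raise ValueError("need n >= 3")
    if n <= min_size:
        return [n]
    sizes = []
    s = 3
    while s < n:
        if s >= min_size:
            sizes.append(s)
        s = 2 * s - 1  # 1 + 2**k doubling
    sizes.append(n)
    return sizes


def _mirror(lower: np.ndarray, n: int, c: int) -> np.ndarray:
    """Symmetric index set from its lower half (centre index unpaired)."""
    upper = n + 1 - lower[lower < c][::-1]
    return np.unique(np.concatenate([lower, upper]))


def build_partitions(
    n: int,
    min_size: int = DEFAULT_MIN_SIZE,
    rng: np.random.Generator | int | None = None,
) -> PartitionScheme:
    """Build the nested random partition ladder for a sample of size n.

    For n <= min_size a single full partition is returned.  Indices are
    1-based.  ``rng`` may be a Generator or a seed.  The largest sub-partition
    takes a uniformly random mirror-symmetric index subset (always containing
    1, the median index and n); each smaller ladder size is a symmetric random
    thinning of the next larger one, giving nested supersets.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    sizes = partition_sizes(n, min_size)
    if sizes == [n]:
        return PartitionScheme(n, (n,), (np.arange(1, n + 1),))
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    c = (n + 1) // 2
    ladder = sizes[:-1]  # 1 + 2**k sizes, largest first below
    # lower-half interior pool: indices strictly between 1 and the median
    top = ladder[-1]
    k_interior = (top + 1) // 2 - 2  # lower-half count minus the forced {1, c}
    pool = rng.choice(np.arange(2, c), size=k_interior, replace=False)
    lowers = {top: np.sort(np.concatenate([[1], pool, [c]]))}
    for smaller, larger in zip(ladder[-2::-1], ladder[::-1]):
        interior = lowers[larger][1:-1]
        keep = (smaller + 1) // 2 - 2
        sub = rng.choice(interior, size=keep, replace=False)
        lowers[smaller] = np.sort(np.concatenate([[1], sub, [c]]))
    sets = [_mirror(lowers[s], n, c) for s in ladder]
    sets.append(np.arange(1, n + 1))
    return PartitionScheme(n, tuple(sizes), tuple(sets))


def is_valid_partition_index_set(n: int, indices: Sequence[int]) -> bool:
    """Check the partition invariants: sorted, contains 1, N and the median
    index, and is symmetric under k -> N + 1 - k (exact for odd n)."""
    idx = np.asarray(sorted(indices), dtype=int)
    if idx.size == n:
        return True  # the full sample is trivially a valid partition
    if idx[0] != 1 or idx[-1] != n:
        return False
    c = (n + 1) // 2
    if c not in idx:
        return False
    if n % 2 == 1:
        return bool(np.array_equal(idx, np.sort(n + 1 - idx)))
    # even n: the centre index has no integer mirror; all others must pair up
    rest = idx[idx != c]
    return bool(np.array_equal(rest, np.sort(n + 1 - rest)))


def conditional_uniformize(r: np.ndarray, ranks: np.ndarray, n: int) -> np.ndarray:
    """Exact SURD of the sub-sample via the conditional spacing transform.

    Given the values of a sorted uniform sample at known ranks
    ``k_1 < ... < k_Np`` (1-based), the normalized gap
    ``(r_j - r_{j-1}) / (1 - r_{j-1})`` is Beta(k_j - k_{j-1}, n - k_j + 1)
    distributed independently of everything to its left (and the first value
    is Beta(k_1, n - k_1 + 1)).  Mapping each through its beta cdf yields
    i.i.d. uniforms, whose sort is an exact uniform order-statistics sample of
    the partition size — for *any* rank pattern, mirror-symmetric or not.
    This is what makes every score exactly size-invariant per partition: an
    affine moment correction cannot do it, because freezing the index pattern
    (in particular the number of points below the median) distorts the
    *shape* of the score null, not just its first two moments.
    """
    vals = r[ranks - 1]
    gaps = np.diff(ranks)
    a = np.concatenate([[ranks[0]], gaps]).astype(float)
    b = (n - ranks + 1).astype(float)
    s = np.empty_like(vals)
    s[0] = vals[0]
    denom = 1.0 - vals[:-1]
    s[1:] = np.diff(vals) / np.where(denom > 0, denom, 1.0)
    u = stats.beta.cdf(np.clip(s, 0.0, 1.0), a, b)
    return np.sort(np.clip(u, EPS, 1.0 - EPS))


def score_partitions(
    u: UniformizedSample,
    scheme: PartitionScheme,
    measure: str = "VAR",
    method: str = "conditional",
    table: "PartitionMomentTable | None" = None,
) -> list[StandardScore]:
    """Score every partition with corrections evaluated at its own size N_p.

    The sub-sample is re-ranked within the partition (local index k, local
    N_p).  ``measure`` is 'AD', 'LL', 'VAR', 'P<p>' or 'RMSLR'.

    ``method='conditional'`` (default) first maps the sub-sample through the
    exact conditional spacing transform (:func:`conditional_uniformize`), so
    each partition is scored as a genuine uniform order-statistics sample of
    its own size and every score keeps its standard N_p-calibrated null —
    invariance is exact by construction.  ``method='affine'`` scores the raw
    sub-sample and standardizes with empirical two-argument moment
    corrections mu_t(N_p, N), sigma_t(N_p, N) from a
    :class:`PartitionMomentTable` (build one with
    :func:`calibrate_partition_moments`); this matches the historical
    description but only aligns the first two moments — the null *shape*
    still varies with the sub-sampled fraction.  The full partition is always
    scored directly (it is the plain sample).
    """
    if scheme.full_n != u.n:
        raise ValueError("scheme was built for a different sample size")
    if method not in ("conditional", "affine"):
        raise ValueError("method must be 'conditional' or 'affine'")
    if method == "affine" and table is None and len(scheme.sizes) > 1:
        raise ValueError(
            "affine partition scoring needs a PartitionMomentTable; build one "
            "with calibrate_partition_moments"
        )
    out: list[StandardScore] = []
    for np_, idx in zip(scheme.sizes, scheme.index_sets):
        if np_ == u.n:
            sub = u.r[None, :]
        elif method == "conditional":
            sub = conditional_uniformize(u.r, idx, u.n)[None, :]
        else:
            sub = u.r[idx - 1][None, :]
        if measure == "RMSLR":
            nb, m, _ = _engine.rmslr_blocks(np_)
            val = float(
                _engine.batch_rmslr(sub, sigma_lr=slr_sigma(m, np_, np_))[0]
            )
            out.append(StandardScore(kind="RMSLR", z=val, n=np_))
            continue
        if measure == "AD":
            s = float(_engine.batch_ad(sub)[0]) - _engine.ad_reference(np_)
            model = default_model("AD")
        elif measure == "LL":
            s = -2.0 * (float(_engine.batch_ll(sub)[0]) - _engine.ll_reference(np_))
            model = default_model("LL")
        elif measure == "VAR":
            s = float(_engine.batch_var(sub)[0])
            model = default_model("VAR")
        elif measure.startswith("P"):
            p = float(measure[1:])
            s = float(_engine.batch_p(sub, p)[0])
            model = default_model("P", p=p)
        else:
            raise ValueError(f"unknown measure {measure!r}")
        if method == "affine" and np_ < u.n:
            mu_, sg_ = table.moments(measure, np_)
            z = (s - mu_) / sg_
        else:
            z = (s - model.mu(np_)) / model.sigma(np_)
        out.append(StandardScore(kind=model.kind, z=float(z), n=np_))
    return out


@dataclass(frozen=True)
class PartitionMomentTable:
    """Empirical two-argument corrections mu_t(N_p, N), sigma_t(N_p, N).

    Calibrated for one full size N and the ladder sizes of its scheme.
    """

    full_n: int
    sizes: tuple[int, ...]
    mu: dict  # measure -> {np: mean}
    sigma: dict  # measure -> {np: std}
    trials: int = 0

    def moments(self, measure: str, np_: int) -> tuple[float, float]:
        try:
            return self.mu[measure][np_], self.sigma[measure][np_]
        except KeyError:
            raise KeyError(
                f"no calibrated moments for measure={measure!r}, Np={np_}"
            ) from None


def calibrate_partition_moments(
    n: int,
    measures: Sequence[str] = ("VAR",),
    trials: int = 2000,
    min_size: int = DEFAULT_MIN_SIZE,
    rng: np.random.Generator | int | None = None,
) -> PartitionMomentTable:
    """Monte-Carlo calibration of raw partition-score moments under SURD.

    Simulates SURD of size n, builds a fresh random partition scheme per
    realization, and records the mean and standard deviation of each raw
    measure at every ladder size.  This is the two-argument finite-size
    correction the affine partition-scoring path standardizes with.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sizes = tuple(partition_sizes(n, min_size)[:-1])
    acc: dict[str, dict[int, list]] = {m: {s: [] for s in sizes} for m in measures}
    for _ in range(trials):
        r = _engine.batch_surd(1, n, rng)[0]
        scheme = build_partitions(n, min_size, rng)
        for np_, idx in zip(scheme.sizes[:-1], scheme.index_sets[:-1]):
            sub = r[idx - 1][None, :]
            for m in measures:
                acc[m][np_].append(_raw_measure(sub, np_, m))
    mu = {
        m: {s: float(np.mean(v)) for s, v in acc[m].items()} for m in measures
    }
    sigma = {
        m: {s: float(np.std(v, ddof=1)) for s, v in acc[m].items()}
        for m in measures
    }
    return PartitionMomentTable(n, sizes, mu, sigma, trials)


def _raw_measure(sub: np.ndarray, np_: int, measure: str) -> float:
    if measure == "AD":
        return float(_engine.batch_ad(sub)[0]) - _engine.ad_reference(np_)
    if measure == "LL":
        return -2.0 * (float(_engine.batch_ll(sub)[0]) - _engine.ll_reference(np_))
    if measure == "VAR":
        return float(_engine.batch_var(sub)[0])
    if measure.startswith("P"):
        return float(_engine.batch_p(sub, float(measure[1:]))[0])
    raise ValueError(f"unknown measure {measure!r}")
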