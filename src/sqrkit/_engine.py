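"""Vectorized batch evaluation of the scoring functions.

Everything here operates on a matrix ``R`` of shape (trials, N) whose rows are
independent sorted sequences on (0, 1).  The public per-sample API in
:mod:`sqrkit.scores` delegates to these kernels with a single row; the
simulation-heavy routines (finite-size calibration, ROC benchmarks, the
acceptance checks) call them directly so that tens of thousands of trials stay
in numpy.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = [
    "sos_mu_sigma",
    "ad_reference",
    "ll_reference",
    "batch_ad",
    "batch_ll",
    "batch_var",
    "batch_p",
    "batch_rmslr",
    "rmslr_blocks",
    "batch_surd",
]


def sos_mu_sigma(n: int) -> tuple[np.ndarray, np.ndarray]:
    k = np.arange(1, n + 1, dtype=float)
    mu = k / (n + 1.0)
    return mu, np.sqrt(mu * (1.0 - mu) / (n + 2.0))


def ad_reference(n: int) -> float:
    """S_AD evaluated at the mean quantiles (the natural AD reference point)."""
    mu, _ = sos_mu_sigma(n)
    k = np.arange(1, n + 1, dtype=float)
    w = 1.0 - 2.0 * k
    return float(np.mean(w * (np.log(mu) + np.log1p(-mu)[::-1])))


def _ll_log_binom(n: int) -> np.ndarray:
    k = np.arange(1, n + 1, dtype=float)
    return gammaln(n + 1.0) - gammaln(k) - gammaln(n - k + 1.0)


def ll_reference(n: int) -> float:
    """S_LL evaluated at the mean quantiles."""
    mu, _ = sos_mu_sigma(n)
    k = np.arange(1, n + 1, dtype=float)
    lb = _ll_log_binom(n)
    return float(np.mean(lb + (k - 1.0) * np.log(mu) + (n - k) * np.log1p(-mu)))


def batch_ad(r: np.ndarray) -> np.ndarray:
    """S_AD = (1/N) sum_k (1-2k) [ln r_k + ln(1 - r_{N+1-k})] per row."""
    r = np.atleast_2d(r)
    n = r.shape[-1]
    k = np.arange(1, n + 1, dtype=float)
    w = 1.0 - 2.0 * k
    return np.mean(w * (np.log(r) + np.log1p(-r)[..., ::-1]), axis=-1)


def batch_ll(r: np.ndarray) -> np.ndarray:
    """Quasi log-likelihood: mean Beta(k, N-k+1) log-density at r_k per row.

    Computed entirely in log-gamma space; this is a mean-field likelihood that
    ignores correlations between order statistics.
    """
    r = np.atleast_2d(r)
    n = r.shape[-1]
    k = np.arange(1, n + 1, dtype=float)
    lb = _ll_log_binom(n)
    return np.mean(lb + (k - 1.0) * np.log(r) + (n - k) * np.log1p(-r), axis=-1)


def batch_var(r: np.ndarray) -> np.ndarray:
    """S_VAR = mean z_k^2 with z_k = (r_k - mu_k)/sigma_k, per row."""
    r = np.atleast_2d(r)
    mu, sig = sos_mu_sigma(r.shape[-1])
    z = (r - mu) / sig
    return np.mean(z * z, axis=-1)


def batch_p(r: np.ndarray, p: float) -> np.ndarray:
    """Generalized moment S_p = (mean |z_k|^p)^(1/p) per row."""
    if p <= 0:
        raise ValueError("exponent p must be positive")
    r = np.atleast_2d(r)
    mu, sig = sos_mu_sigma(r.shape[-1])
    z = np.abs((r - mu) / sig)
    return np.mean(z**p, axis=-1) ** (1.0 / p)


DEFAULT_RMSLR_BLOCKS = 64


def rmslr_blocks(n: int) -> tuple[int, int, int]:
    """Default RMSLR block partition of 1..n.

    The number of blocks is held fixed (64, fewer for tiny samples) while the
    block size grows proportionally to N.  This keeps the computation O(N)
    and — crucially — makes the standardized RMSLR distribution sample-size
    invariant: RMSLR² is approximately chi-square with nb-1 degrees of
    freedom over nb, so its spread is set by the block *count*; a block count
    growing with N would concentrate the distribution instead.  The
    ``n - nb*m`` remainder indices are split between the two ends.  Returns
    ``(nb, m, start)`` with ``start`` the 0-based offset of block 1.
    """
    nb = min(DEFAULT_RMSLR_BLOCKS, n // 2)
    if nb < 2:
        raise ValueError("sample too small for RMSLR (need >= 2 blocks)")
    m = n // nb
    rem = n - nb * m
    return nb, m, rem // 2


def batch_block_meanlog(r: np.ndarray, nb: int, m: int, start: int,
                        floor: float = 1e-15) -> np.ndarray:
    """Mean log nearest-neighbour spacing per block, shape (trials, nb).

    Spacings are taken only within a block (m-1 per block); zero spacings are
    floored at ``floor`` to guard the logarithm.
    """
    r = np.atleast_2d(r)
    blocks = r[:, start:start + nb * m].reshape(r.shape[0], nb, m)
    d = np.diff(blocks, axis=-1)
    np.maximum(d, floor, out=d)
    return np.mean(np.log(d), axis=-1)


def batch_rmslr(r: np.ndarray, sigma_lr: float | None = None) -> np.ndarray:
    """Root-mean-square of standardized S_LR(i, j) over all distinct block pairs.

    Each pairwise mean-log-spacing difference is divided by the null scale
    ``sigma_lr`` before squaring, so RMSLR is on the same standardized footing
    as |Z_4| in the composite score.  ``sigma_lr=None`` uses the full-sample
    calibration (x = 1).
    """
    from .calibration import slr_sigma  # local import, no cycle at module load

    r = np.atleast_2d(r)
    n = r.shape[-1]
    nb, m, start = rmslr_blocks(n)
    if sigma_lr is None:
        sigma_lr = slr_sigma(m, n, n)
    ml = batch_block_meanlog(r, nb, m, start)
    # sum over distinct pairs of (ml_i - ml_j)^2 via moment identity
    s1 = np.sum(ml, axis=-1)
    s2 = np.sum(ml * ml, axis=-1)
    pair_sq_sum = nb * s2 - s1 * s1  # = sum_{i<j} (ml_i - ml_j)^2 * ... see below
    # sum_{i<j} (a_i-a_j)^2 = nb * sum a^2 - (sum a)^2
    r_pairs = nb * (nb - 1) / 2.0
    return np.sqrt(pair_sq_sum / r_pairs) / sigma_lr


def batch_surd(trials: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """``trials`` independent sorted uniform rows of length ``n``."""
    r = rng.random((trials, n))
    r.sort(axis=-1)
    return r
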