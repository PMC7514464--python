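"""ROC evaluation of score discrimination between SURD and decoy-SURD.

Convention: the *positive* class is true SURD, and a realization is predicted
SURD when its score falls below the threshold.  Sweeping the threshold over
all observed score values traces the fraction of true positives
FTP = TP/(TP + FN) against the fraction of false positives
FFP = FP/(FP + TN); the area under that curve (trapezoid rule, ties sharing
one threshold step) summarizes discrimination: 0.5 is chance, 1.0 perfect.

Note the inversion effect: an over-fitting decoy (reduced fluctuations) makes
*signed* Z scores smaller than the null, so their ROC dips below the
diagonal; taking |Z| removes the inversion because both over- and
under-fitting then raise the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _engine
from .calibration import default_model
from .decoys import DecoySpec, apply_reduced_fluctuations, make_decoy

__all__ = ["ScoreSamples", "ROCCurve", "roc_curve", "auc", "benchmark"]


@dataclass(frozen=True)
class ScoreSamples:
    """Scores of matched SURD and decoy realizations for one measure."""

    surd_scores: np.ndarray
    decoy_scores: np.ndarray
    measure: str = ""
    n: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.surd_scores, dtype=float)
        d = np.asarray(self.decoy_scores, dtype=float)
        if s.size == 0 or d.size == 0:
            raise ValueError("both score lists must be non-empty")
        if not (np.all(np.isfinite(s)) and np.all(np.isfinite(d))):
            raise ValueError("scores must be finite")
        object.__setattr__(self, "surd_scores", s)
        object.__setattr__(self, "decoy_scores", d)


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    ffp: np.ndarray
    ftp: np.ndarray
    auc: float


def roc_curve(s: ScoreSamples) -> ROCCurve:
    """Full threshold sweep; predicted SURD when score < threshold."""
    pooled = np.unique(np.concatenate([s.surd_scores, s.decoy_scores]))
    if pooled.size == 1:
        warnings.warn("all scores identical; degenerate ROC", stacklevel=2)
        return ROCCurve(
            thresholds=np.array([pooled[0], np.inf]),
            ffp=np.array([0.0, 1.0]),
            ftp=np.array([0.0, 1.0]),
            auc=0.5,
        )
    thr = np.concatenate([pooled, [np.inf]])
    # P(score < t): strict inequality; ties share a single threshold step
    ftp = np.searchsorted(np.sort(s.surd_scores), thr, side="left") / s.surd_scores.size
    ffp = np.searchsorted(np.sort(s.decoy_scores), thr, side="left") / s.decoy_scores.size
    a = float(np.trapezoid(ftp, ffp))
    return ROCCurve(thresholds=thr, ffp=ffp, ftp=ftp, auc=a)


def auc(surd_scores: np.ndarray, decoy_scores: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney) identity, ties counted half.

    Equals the trapezoid area of :func:`roc_curve`; positive class = SURD,
    predicted SURD below threshold, so AUC > 0.5 when SURD scores are the
    smaller ones.
    """
    s = np.asarray(surd_scores, dtype=float)
    d = np.asarray(decoy_scores, dtype=float)
    ds = np.sort(d)
    less = np.searchsorted(ds, s, side="left")   # decoys strictly below s
    leq = np.searchsorted(ds, s, side="right")
    greater = d.size - leq                        # decoys strictly above s
    return float((greater + 0.5 * (leq - less)).sum() / (s.size * d.size))


#: measures available to the benchmark; signed variants keep the sign
BENCH_MEASURES = (
    "Z_VAR", "|Z_VAR|", "Z_AD", "|Z_AD|", "Z_LL", "|Z_LL|", "Z_4", "|Z_4|",
    "RMSLR", "CS",
)


def _batch_measures(r: np.ndarray, measures: Sequence[str]) -> dict[str, np.ndarray]:
    """Evaluate the requested standardized measures on rows of r."""
    n = r.shape[-1]
    need = {m.strip("|") for m in measures}
    vals: dict[str, np.ndarray] = {}
    if {"Z_VAR", "CS"} & need:
        mod = default_model("VAR")
        vals["Z_VAR"] = (_engine.batch_var(r) - mod.mu(n)) / mod.sigma(n)
    if "Z_AD" in need:
        mod = default_model("AD")
        s = _engine.batch_ad(r) - _engine.ad_reference(n)
        vals["Z_AD"] = (s - mod.mu(n)) / mod.sigma(n)
    if "Z_LL" in need:
        mod = default_model("LL")
        s = -2.0 * (_engine.batch_ll(r) - _engine.ll_reference(n))
        vals["Z_LL"] = (s - mod.mu(n)) / mod.sigma(n)
    if {"Z_4", "CS"} & need:
        mod = default_model("P", p=4)
        vals["Z_4"] = (_engine.batch_p(r, 4.0) - mod.mu(n)) / mod.sigma(n)
    if {"RMSLR", "CS"} & need:
        vals["RMSLR"] = _engine.batch_rmslr(r)
    if "CS" in need:
        vals["CS"] = np.abs(vals["Z_VAR"] + 0.666) + (
            np.maximum(2.5, np.maximum(np.abs(vals["Z_4"]), vals["RMSLR"])) - 2.5
        )
    out = {}
    for m in measures:
        base = m.strip("|")
        out[m] = np.abs(vals[base]) if m.startswith("|") else vals[base]
    return out


def benchmark(
    measures: Sequence[str],
    decoy_suite: Sequence[DecoySpec],
    n_list: Sequence[int],
    trials: int = 1000,
    seed: int | np.random.Generator = 0,
    chunk_budget: int = 20_000_000,
) -> pd.DataFrame:
    """AUC of each measure against each decoy at each sample size.

    Matched SURD/dSURD pairs: every SURD realization is mapped through the
    decoy to produce its decoy twin.  Returns a tidy DataFrame with columns
    (decoy, measure, n, auc, trials).
    """
    if trials < 100:
        raise ValueError("need trials >= 100 for a stable AUC")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rows = []
    for spec in decoy_suite:
        fd = None if spec.family == "reduced" else make_decoy(spec)
        for n in n_list:
            chunk = max(1, min(trials, chunk_budget // n))
            surd_acc: dict[str, list] = {m: [] for m in measures}
            dec_acc: dict[str, list] = {m: [] for m in measures}
            for done in range(0, trials, chunk):
                r = _engine.batch_surd(min(chunk, trials - done), n, rng)
                if fd is None:
                    p = spec.params["p"]
                    mu = np.arange(1, n + 1) / (n + 1.0)
                    rd = r - p * (r - mu)
                else:
                    rd = np.clip(fd(r), 1e-12, 1 - 1e-12)
                for m, v in _batch_measures(r, measures).items():
                    surd_acc[m].append(v)
                for m, v in _batch_measures(rd, measures).items():
                    dec_acc[m].append(v)
            label = _decoy_label(spec)
            for m in measures:
                rows.append(
                    {
                        "decoy": label,
                        "measure": m,
                        "n": n,
                        "auc": auc(
                            np.concatenate(surd_acc[m]), np.concatenate(dec_acc[m])
                        ),
                        "trials": trials,
                    }
                )
    return pd.DataFrame(rows)


def _decoy_label(spec: DecoySpec) -> str:
    ps = ",".join(f"{k}={v:.4g}" for k, v in sorted(spec.params.items()))
    return f"{spec.family}({ps})"
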