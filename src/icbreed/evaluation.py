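"""Comparison metrics: genetic gain, genetic variance, prediction accuracy.

Programs are compared by genetic gain in intercrop performance: the mean
true intercrop genetic value of the two crops' new DH cohorts, centered at
the end of the shared burn-in so all arms start from zero. Arms are
compared as *ratios* of their final gains, estimated replicate-by-replicate
on seed-paired runs (each replicate shares one burn-in across arms) and
combined on the log scale, which keeps the estimate symmetric in the two
arms and matches how "times higher" results are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)

__all__ = [
    "mean_intercrop_value",
    "intercrop_variance",
    "prediction_accuracy",
    "RatioEstimate",
    "gain_ratio",
    "summarize_metrics",
]


def mean_intercrop_value(a_ic_A: np.ndarray, a_ic_B: np.ndarray) -> float:
    """Population mean intercrop value: average of the two crop means."""
    return float(0.5 * (np.mean(a_ic_A) + np.mean(a_ic_B)))


def intercrop_variance(a_ic_A: np.ndarray, a_ic_B: np.ndarray) -> float:
    """Genetic variance of the pooled intercrop values (divide-by-n)."""
    return float(np.var(np.concatenate([np.ravel(a_ic_A), np.ravel(a_ic_B)])))


def prediction_accuracy(predicted: np.ndarray, true: np.ndarray) -> float:
    """Pearson correlation of a selection criterion with true values.

    Returns NaN (with a warning) when either side has zero variance,
    rather than a spurious correlation.
    """
    predicted = np.asarray(predicted, float)
    true = np.asarray(true, float)
    if predicted.shape != true.shape:
        raise ValueError("predicted and true values must have the same shape")
    if predicted.size < 2:
        raise ValueError("need at least 2 individuals for an accuracy")
    if np.std(predicted) == 0 or np.std(true) == 0:
        logger.warning("zero variance in accuracy computation; returning NaN")
        return float("nan")
    return float(np.corrcoef(predicted, true)[0, 1])


@dataclass(frozen=True)
class RatioEstimate:
    """Geometric-mean ratio of paired per-replicate gains with a t CI."""

    ratio: float
    ci_low: float
    ci_high: float
    n: int


def gain_ratio(
    gains_x: np.ndarray, gains_y: np.ndarray, confidence: float = 0.95
) -> RatioEstimate:
    """Ratio of program X's gain to program Y's on seed-paired replicates.

    Per replicate the log-ratio log(x_i) - log(y_i) is formed; the
    estimate is the back-transformed mean log-ratio (the geometric mean of
    the per-replicate ratios) with a paired-t confidence interval. All
    gains must be positive -- the ratio of mean *gains from a common
    burn-in baseline* is only meaningful when both programs actually
    gained.
    """
    x = np.asarray(gains_x, float)
    y = np.asarray(gains_y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired gain vectors must be 1-D and equal length")
    if x.size < 2:
        raise ValueError("need at least 2 replicates for a ratio estimate")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("gain ratios require positive gains in both programs")
    d = np.log(x) - np.log(y)
    n = d.size
    mean = d.mean()
    se = d.std(ddof=1) / math.sqrt(n)
    tcrit = scipy.stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    return RatioEstimate(
        ratio=float(np.exp(mean)),
        ci_low=float(np.exp(mean - tcrit * se)),
        ci_high=float(np.exp(mean + tcrit * se)),
        n=n,
    )


def summarize_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-program final-year summary of replicate-level metric trajectories.

    Expects tidy rows with columns (rep, corr, program, year, gain,
    var_ic, acc_A, acc_B); returns one row per (corr, program) with the
    across-replicate mean and standard error of the final-year gain,
    variance, and accuracy.
    """
    final_year = metrics["year"].max()
    last = metrics[metrics["year"] == final_year]
    rows = []
    for (corr, program), grp in last.groupby(["corr", "program"], sort=True):
        n = len(grp)
        acc = grp[["acc_A", "acc_B"]].to_numpy().mean(axis=1)
        rows.append({
            "corr": corr, "program": program, "year": final_year, "n_reps": n,
            "gain_mean": grp["gain"].mean(),
            "gain_se": grp["gain"].std(ddof=1) / math.sqrt(n) if n > 1 else float("nan"),
            "var_mean": grp["var_ic"].mean(),
            "acc_mean": float(np.nanmean(acc)),
        })
    return pd.DataFrame(rows)
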