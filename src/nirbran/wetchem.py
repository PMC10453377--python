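"""Method-validation statistics for the wet-chemistry reference assay.

The reference cellulose values behind any NIR calibration come from a
potassium dichromate oxidation (PDO) assay; before the spectroscopy is
trusted, the assay's precision is characterised with relative standard
deviations and the optimised protocol is compared against the original
one with paired t-tests and Pearson correlation.

* RSD = SD / mean x 100 % (sample SD, n-1 denominator) — intra-day
  repeatability (RSDr) uses one day's replicates, inter-day repeatability
  (RSDR) pools all replicates across days.
* Method comparison on paired per-sample results uses the paired t
  statistic ``t = mean(d) / (sd(d)/sqrt(n))`` with df = n-1, one- or
  two-tailed, plus the product-moment correlation of the per-sample means.

Two small datasets from the assay-validation study ship with the module:
:func:`load_repeatability_study` (3 days x 6 replicate determinations on
one rice bran layer sample) and :func:`load_method_comparison_study`
(15 samples measured in triplicate by both protocol variants).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PrecisionContext",
    "PrecisionReport",
    "MethodComparison",
    "rsd",
    "interday_rsd",
    "paired_t",
    "pearson",
    "critical_t",
    "load_repeatability_study",
    "load_method_comparison_study",
]


class PrecisionContext(str, enum.Enum):
    INTRA_DAY = "RSDr"
    INTER_DAY = "RSDR"
    REPLICATE = "RSD"


@dataclass(frozen=True)
class PrecisionReport:
    """Mean, SD and relative SD of a set of replicate determinations."""

    mean: float
    sd: float
    rsd: float  # percent
    n: int
    context: PrecisionContext = PrecisionContext.REPLICATE


@dataclass(frozen=True)
class MethodComparison:
    """Paired t-test (and optionally correlation) between two methods."""

    t: float
    df: int
    p: float
    tails: int
    r: float | None = None


def rsd(
    values, context: PrecisionContext = PrecisionContext.REPLICATE
) -> PrecisionReport:
    """Relative standard deviation of replicate measurements, in percent.

    Uses the sample (n-1) SD; requires a strictly positive mean.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("RSD needs at least 2 replicates")
    mean = float(v.mean())
    if mean <= 0:
        raise ValueError("RSD undefined for non-positive mean")
    sd = float(v.std(ddof=1))
    return PrecisionReport(mean=mean, sd=sd, rsd=sd / mean * 100.0,
                           n=v.size, context=context)


def interday_rsd(groups) -> PrecisionReport:
    """Inter-day precision: pool all days' replicates into one RSD."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("inter-day precision needs >= 2 replicate groups")
    pooled = np.concatenate(groups)
    report = rsd(pooled, context=PrecisionContext.INTER_DAY)
    return report


def paired_t(x, y, tails: int = 2) -> MethodComparison:
    """Paired t-test on per-sample differences d = x - y.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with df = n - 1; the p-value uses
    the stated number of tails (one-tailed p is for the observed
    direction).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:  # identical pairs: t = 0/0 taken as the null value
            return MethodComparison(
                t=0.0, df=n - 1, p=1.0 if tails == 2 else 0.5, tails=tails
            )
        raise ValueError("zero-variance differences: t undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    if tails == 2:
        p = 2.0 * float(stats.t.sf(abs(t), df))
    else:
        p = float(stats.t.sf(abs(t), df))
    return MethodComparison(t=t, df=df, p=p, tails=tails)


def pearson(x, y) -> float:
    """Product-moment correlation between paired determinations."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson needs >= 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def critical_t(df: int, alpha: float, tails: int = 2) -> float:
    """Critical value of Student's t for the given df, alpha and tails."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    q = 1.0 - alpha / tails
    return float(stats.t.ppf(q, df))


# ---------------------------------------------------------------------------
# packaged validation datasets (assay-validation study measurements)

def load_repeatability_study() -> pd.DataFrame:
    """Replicate cellulose determinations (%, w/w) on one rice bran layer
    sample: six consecutive measurements on each of three days, by the
    optimised PDO protocol.  Rows are days, columns replicates."""
    data = {
        "Day1": [3.86, 3.89, 3.80, 3.91, 3.86, 3.86],
        "Day2": [3.84, 3.86, 3.82, 3.83, 3.87, 3.86],
        "Day3": [3.88, 3.84, 3.81, 3.82, 3.84, 3.84],
    }
    return pd.DataFrame(data).T.rename(columns=lambda c: f"rep{c + 1}")


def load_method_comparison_study() -> pd.DataFrame:
    """Per-sample triplicate summaries (mean %, SD %, RSD %) of fifteen
    rice bran layer samples measured by both the original and the
    optimised PDO protocol."""
    rows = [
        # sample, orig mean, orig sd, orig rsd, opt mean, opt sd, opt rsd
        ("A", 3.57, 0.097, 2.73, 3.38, 0.058, 1.73),
        ("B", 3.62, 0.161, 4.45, 3.54, 0.057, 1.61),
        ("C", 3.73, 0.144, 3.86, 3.57, 0.075, 2.10),
        ("D", 3.69, 0.061, 1.65, 3.74, 0.054, 1.45),
        ("E", 4.58, 0.051, 1.12, 4.38, 0.061, 1.39),
        ("F", 4.30, 0.155, 3.60, 4.52, 0.011, 0.25),
        ("G", 4.63, 0.092, 1.99, 4.75, 0.080, 1.69),
        ("H", 3.00, 0.116, 3.85, 2.98, 0.030, 1.00),
        ("I", 4.16, 0.087, 2.10, 4.08, 0.065, 1.60),
        ("J", 3.59, 0.046, 1.28, 3.60, 0.070, 1.95),
        ("K", 4.33, 0.125, 2.88, 4.41, 0.059, 1.33),
        ("L", 4.19, 0.155, 3.71, 4.15, 0.047, 1.14),
        ("M", 4.06, 0.114, 2.80, 4.16, 0.035, 0.84),
        ("N", 4.08, 0.110, 2.70, 4.04, 0.041, 1.01),
        ("O", 4.36, 0.145, 3.33, 4.41, 0.059, 1.33),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "original_mean", "original_sd", "original_rsd",
            "optimized_mean", "optimized_sd", "optimized_rsd",
        ],
    ).set_index("sample")
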