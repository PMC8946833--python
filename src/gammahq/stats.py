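"""Replicate-level statistics for the co-stress readout.

The experimental readout is one fold change per (experiment, arm, treatment):
percent gamma-H2AX-positive cells in a treated condition divided by the
untreated condition of the same arm.  Across replicate experiments those fold
changes are screened for outliers with an iterated two-sided Grubbs test,
checked for normality (Shapiro-Wilk), and compared between arms with a paired
t-test, pairing by experiment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .classify import PositivitySummary

__all__ = [
    "FoldChangeResult",
    "GrubbsResult",
    "PairedTestResult",
    "fold_change",
    "grubbs_critical_value",
    "grubbs_exclude",
    "normality_test",
    "paired_t_test",
]


@dataclass(frozen=True)
class FoldChangeResult:
    """Treated-vs-untreated ratio of percent positive cells within one arm."""

    experiment: str
    arm: str
    treatment: str
    fc: float
    undefined: bool = False
    reason: str = ""


@dataclass(frozen=True)
class GrubbsResult:
    values: tuple[float, ...]
    alpha: float
    excluded_indices: tuple[int, ...]
    g_statistics: tuple[float, ...]
    critical_values: tuple[float, ...]

    @property
    def retained(self) -> tuple[float, ...]:
        excl = set(self.excluded_indices)
        return tuple(v for i, v in enumerate(self.values) if i not in excl)


@dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    df: int
    p_value: float
    normality_w: float
    normality_p: float
    n_pairs: int
    degenerate: bool = False


def fold_change(
    treated: PositivitySummary, untreated: PositivitySummary
) -> FoldChangeResult:
    """Ratio of percent-positive cells, treated over untreated, within one arm.

    A zero untreated percentage makes the ratio undefined; the result is
    flagged (and excluded downstream) rather than raising, so one empty
    condition does not abort a whole run.
    """
    if treated.experiment != untreated.experiment:
        raise ValueError(
            f"experiment mismatch: {treated.experiment!r} vs {untreated.experiment!r}"
        )
    if treated.arm != untreated.arm:
        raise ValueError(f"arm mismatch: {treated.arm!r} vs {untreated.arm!r}")
    if untreated.n_cells == 0 or untreated.pct_positive == 0:
        warnings.warn(
            f"undefined fold change for {treated.experiment}/{treated.arm}/"
            f"{treated.treatment}: untreated percentage is zero",
            stacklevel=2,
        )
        return FoldChangeResult(
            experiment=treated.experiment,
            arm=treated.arm,
            treatment=treated.treatment,
            fc=math.nan,
            undefined=True,
            reason="untreated pct_positive is zero",
        )
    return FoldChangeResult(
        experiment=treated.experiment,
        arm=treated.arm,
        treatment=treated.treatment,
        fc=treated.pct_positive / untreated.pct_positive,
    )


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided single-outlier Grubbs critical value.

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_exclude(values, alpha: float = 0.05) -> GrubbsResult:
    """Iterated two-sided single-outlier Grubbs screening.

    At each pass the maximum studentized deviation G = max|x_i - mean| / sd
    (sample sd, ddof=1) is compared with the critical value; the most extreme
    point is removed while G exceeds it, re-testing on the reduced sample.
    Iteration stops when G is not significant or fewer than 3 points remain,
    so at most n - 3 points are ever removed.  Zero-variance samples are left
    untouched (G is undefined).
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size and not np.all(np.isfinite(vals)):
        raise ValueError("values must be finite")
    excluded: list[int] = []
    gs: list[float] = []
    crits: list[float] = []
    if vals.size < 3:
        warnings.warn(
            f"Grubbs test skipped: n={vals.size} < 3", stacklevel=2
        )
        return GrubbsResult(tuple(vals), alpha, (), (), ())
    active = list(range(vals.size))
    while len(active) >= 3:
        sub = vals[active]
        mean = sub.mean()
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - mean)
        imax = int(np.argmax(dev))
        g = dev[imax] / sd
        crit = grubbs_critical_value(len(active), alpha)
        if g > crit and len(active) > 3:
            gs.append(float(g))
            crits.append(float(crit))
            excluded.append(active.pop(imax))
        else:
            # either not significant, or removal would leave fewer than the
            # 3 points the test itself needs — never exclude past n = 3
            break
    return GrubbsResult(
        tuple(vals), alpha, tuple(excluded), tuple(gs), tuple(crits)
    )


def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk test. Returns (W, p); raises for n < 3 or zero variance."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 3:
        raise ValueError("normality test requires n >= 3")
    if np.ptp(vals) == 0:
        raise ValueError("normality test undefined for constant values")
    w, p = sps.shapiro(vals)
    return float(w), float(p)


def paired_t_test(x, y) -> PairedTestResult:
    """Two-sided paired t-test on per-experiment pairs.

    t = mean(d) / (sd(d)/sqrt(n)) on differences d = x - y, with n-1 degrees
    of freedom.  Normality of the differences is assessed with Shapiro-Wilk
    first; a significant departure is reported with a warning but does not
    abort the t-test.  Zero-variance differences yield a degenerate result
    (flagged) rather than a division by zero.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 2:
        raise ValueError("paired t-test requires at least 2 pairs")
    d = xa - ya
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else math.copysign(math.inf, d.mean())
        p = math.nan if d.mean() == 0 else 0.0
        return PairedTestResult(t, df, p, math.nan, math.nan, n, degenerate=True)
    try:
        w, norm_p = normality_test(d)
    except ValueError:
        w, norm_p = math.nan, math.nan
    else:
        if norm_p < 0.05:
            warnings.warn(
                f"differences depart from normality (Shapiro-Wilk p={norm_p:.3g}); "
                "paired t-test reported anyway",
                stacklevel=2,
            )
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return PairedTestResult(float(t), df, float(p), w, norm_p, n)
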