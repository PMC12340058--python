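"""Normality-routed correlation with grip strength, effect sizes, and the
a priori sample-size computation for a correlation test.

Each gait statistic (per-subject mean or CV of one parameter) is paired
with grip strength; Shapiro-Wilk normality of *both* variables routes the
pair to Pearson's product-moment correlation, otherwise to Spearman's rank
correlation.  Effect size is Cohen's r = |r| with the conventional
negligible/small/medium/large cuts at 0.1 / 0.3 / 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DataError, ValidationError

__all__ = [
    "CorrelationResult",
    "PowerSpec",
    "shapiro_wilk",
    "choose_method",
    "correlate",
    "classify_effect",
    "required_sample_size",
    "build_results_table",
]

ALPHA = 0.05


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the a priori power analysis for a two-sided correlation test."""

    r_effect: float = 0.37
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.r_effect < 1):
            raise ValidationError("r_effect must be in (0, 1)")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValidationError("alpha and power must be in (0, 1)")


@dataclass
class CorrelationResult:
    variable: str
    statistic_kind: str        # "mean" or "cv"
    method: str                # "pearson" or "spearman"
    r: float
    p: float
    mean: float                # cohort mean of the statistic
    sd: float
    n: int

    @property
    def effect_size(self) -> float:
        return abs(self.r)

    @property
    def effect_class(self) -> str:
        return classify_effect(self.r)

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston approximation, via scipy)."""
    x = np.asarray(x, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise DataError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={len(x)}")
    if np.ptp(x) == 0:
        raise DataError("Shapiro-Wilk undefined for a constant sample")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def choose_method(x, y, alpha: float = ALPHA) -> str:
    """Pearson iff both samples pass Shapiro-Wilk at ``alpha``, else Spearman."""
    if len(x) != len(y) or len(x) < 4:
        raise DataError("x and y must have equal length >= 4")
    _, px = shapiro_wilk(x)
    _, py = shapiro_wilk(y)
    return "pearson" if (px >= alpha and py >= alpha) else "spearman"


def correlate(x, y, method: str) -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value.

    Pearson uses the exact t test (df = n - 2); Spearman uses average ranks
    for ties and the t approximation for p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise DataError("x and y must have equal length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation undefined for zero-variance input")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def classify_effect(r: float) -> str:
    """Cohen's r category on |r|: <0.1 negligible, <0.3 small, <0.5 medium."""
    a = abs(r)
    if a > 1:
        raise ValidationError(f"|r| = {a} > 1")
    if a < 0.1:
        return "negligible"
    if a < 0.3:
        return "small"
    if a < 0.5:
        return "medium"
    return "large"


def _power_two_sided(n: float, r: float, alpha: float) -> float:
    """Power of the two-sided correlation test at real-valued sample size n.

    Fisher-z approximation with the small-sample mean correction
    z_r = atanh(r) + r / (2(n-1)); the critical correlation comes from the
    t quantile at n - 2 df.
    """
    tq = stats.t.ppf(1.0 - alpha / 2.0, n - 2.0)
    r_crit = np.sqrt(tq**2 / (tq**2 + n - 2.0))
    z_c = np.arctanh(r_crit)
    z_r = np.arctanh(r) + r / (2.0 * (n - 1.0))
    se = np.sqrt(n - 3.0)
    return float(stats.norm.cdf((z_r - z_c) * se) + stats.norm.cdf((-z_r - z_c) * se))


def required_sample_size(spec: PowerSpec = PowerSpec(), rounding: str = "floor") -> int:
    """Minimum n for the correlation test to reach the requested power.

    The real-valued root of ``power(n) = target`` is found numerically and
    rounded per ``rounding`` ("floor" by default, "ceil" and "nearest"
    available).  The result is never below 4.
    """
    f = lambda n: _power_two_sided(n, spec.r_effect, spec.alpha) - spec.power
    lo, hi = 4.0 + 1e-9, 1e7
    if f(lo) >= 0:
        return 4
    if f(hi) < 0:
        raise DataError("no root of the power equation in (4, 1e7)")
    root = optimize.brentq(f, lo, hi, xtol=1e-10)
    if rounding == "floor":
        n = int(np.floor(root))
    elif rounding == "ceil":
        n = int(np.ceil(root))
    elif rounding == "nearest":
        n = int(np.round(root))
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return max(n, 4)


def build_results_table(
    summaries: pd.DataFrame,
    statistic_kind: str,
    parameters: list[str] | None = None,
    alpha: float = ALPHA,
    max_missing_frac: float = 0.2,
) -> list[CorrelationResult]:
    """Correlate each gait statistic with grip strength across subjects.

    ``summaries`` is a per-subject table with a ``grip_strength`` column and
    ``mean_<param>`` / ``cv_<param>`` columns (see
    :meth:`footgait.parameters.SubjectSummary.to_row`).
    """
    if statistic_kind not in ("mean", "cv"):
        raise ValueError("statistic_kind must be 'mean' or 'cv'")
    if len(summaries) < 5:
        raise DataError("need at least 5 subjects")
    if summaries["grip_strength"].isna().any():
        raise DataError("grip strength missing for some subjects")
    if parameters is None:
        prefix = statistic_kind + "_"
        parameters = [c[len(prefix):] for c in summaries.columns if c.startswith(prefix)]

    grip = summaries["grip_strength"].to_numpy(dtype=float)
    results = []
    for name in parameters:
        col = summaries[f"{statistic_kind}_{name}"]
        mask = col.notna()
        if (~mask).mean() > max_missing_frac:
            import warnings

            warnings.warn(f"{name}: missing for >20% of subjects, dropped", stacklevel=2)
            continue
        x = col[mask].to_numpy(dtype=float)
        g = grip[mask.to_numpy()]
        if np.ptp(x) == 0:
            import warnings

            warnings.warn(f"{name}: constant across subjects, dropped", stacklevel=2)
            continue
        method = choose_method(x, g, alpha)
        r, p = correlate(x, g, method)
        results.append(
            CorrelationResult(
                variable=name,
                statistic_kind=statistic_kind,
                method=method,
                r=r,
                p=p,
                mean=float(np.mean(x)),
                sd=float(np.std(x, ddof=1)),
                n=int(mask.sum()),
            )
        )
    return results


def results_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Render correlation results in the reporting column order."""
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "statistic": r.statistic_kind,
                "mean": r.mean,
                "sd": r.sd,
                "p_value": r.p,
                "r": r.r,
                "effect_size": r.effect_size,
                "interpretation": r.effect_class,
                "method": r.method,
                "significant": r.significant,
                "n": r.n,
            }
            for r in results
        ]
    )
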