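"""Two-group statistical evaluation of game outcomes.

Small behavioural samples (n ≈ 8 per group) cannot be assumed normal, so the
pipeline follows the standard gated procedure for such data:

1. **Levene test** (mean-centred) for equality of variances; variances are
   called equal when p > 0.05, and a p in (0.05, 0.10] is flagged *weak*.
2. **Pooled-variance Student t** (two groups) and **one-way ANOVA**; for two
   groups the identity ``F = t²`` holds exactly and is used as an internal
   cross-check.  Both tests are available from raw samples or from published
   summary statistics (mean, SD, n).
3. **Kruskal–Wallis** (chi-square approximation, mid-ranked ties with
   correction) as a distribution-free corroboration, reported as p(chi-sq).

The group verdict is "different" when the two-sided t-test p-value is below
0.05; the Kruskal–Wallis agreement is reported alongside as corroboration.
Percent differences are reported as integers relative to the control mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "MetricComparison",
    "ComparisonReport",
    "pooled_t_from_summary",
    "pooled_t",
    "levene_test",
    "anova_oneway",
    "kruskal_wallis",
    "percent_difference",
    "critical_values",
    "compare_groups",
]

ALPHA = 0.05
WEAK_LEVENE = 0.10


@dataclass
class GroupSummary:
    """Published summary of one group: mean ± SD with sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("need n >= 2")

    @classmethod
    def from_sample(cls, x: np.ndarray) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)), n=len(x))


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def pooled_t_from_summary(a: GroupSummary, b: GroupSummary
                          ) -> tuple[float, int, float, float]:
    """Pooled-variance Student t from summary statistics.

    Returns ``(t, df, p_two_sided, F)`` with ``df = n_a + n_b − 2`` and
    ``F = t²`` (the one-way ANOVA statistic for two groups).  Two identical
    constant groups give t = 0 by convention.
    """
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    if se == 0:
        t = 0.0 if a.mean == b.mean else np.inf * np.sign(b.mean - a.mean)
    else:
        t = (b.mean - a.mean) / se
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return float(t), df, p, float(t * t) if np.isfinite(t) else np.inf


def pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float, float]:
    """Pooled t from raw samples; equals the summary path on their summaries."""
    return pooled_t_from_summary(GroupSummary.from_sample(x),
                                 GroupSummary.from_sample(y))


def levene_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mean-centred (classic) Levene test for equality of variances.

    Two identical constant samples are degenerate: W = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per sample")
    if np.ptp(np.abs(x - np.mean(x))) == 0 and np.ptp(np.abs(y - np.mean(y))) == 0:
        return 0.0, 1.0
    w, p = stats.levene(x, y, center="mean")
    return float(w), float(p)


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA; identical groups give F = 0, p = 1."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups of >= 2 observations")
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H via the chi-square approximation (tie-corrected)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups of >= 2 observations")
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def percent_difference(control_mean: float, target_mean: float) -> int:
    """Integer percent deviation of the target from the control mean."""
    if control_mean == 0:
        raise ZeroDivisionError("control mean is zero; percent difference undefined")
    return int(round(100.0 * (target_mean - control_mean) / control_mean))


def critical_values(alpha: float, df_num: int, df_den: int
                    ) -> tuple[float, float]:
    """Upper-tail critical values: one-tailed t (df_den) and F (df_num, df_den)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df_num < 1 or df_den < 1:
        raise ValueError("degrees of freedom must be >= 1")
    t_crit = float(stats.t.isf(alpha, df_den))
    f_crit = float(stats.f.isf(alpha, df_num, df_den))
    return t_crit, f_crit


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class MetricComparison:
    metric: str
    control: GroupSummary
    target: GroupSummary
    percent_difference: int
    levene_w: float
    levene_p: float
    variances_equal: bool
    levene_weak: bool
    t: float
    df: int
    p_t: float
    f: float
    h: float
    p_chisq: float
    different: bool
    kw_corroborates: bool

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["control"] = self.control.__dict__
        d["target"] = self.target.__dict__
        return d

    def display(self) -> dict:
        """Report-style rounding: p and F to 2 decimals, percent as integer."""
        return {
            "metric": self.metric,
            "control": f"{self.control.mean:.2f} ± {self.control.sd:.2f}",
            "target": f"{self.target.mean:.2f} ± {self.target.sd:.2f}",
            "difference": f"{self.percent_difference:+d}%",
            "levene": round(self.levene_p, 2),
            "variances": "Equal" if self.variances_equal else "Diff",
            "p_t": round(self.p_t, 2),
            "F": round(self.f, 2),
            "p_chisq": round(self.p_chisq, 2),
            "groups": "Diff" if self.different else "Equal",
        }


@dataclass
class ComparisonReport:
    metrics: dict[str, MetricComparison] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {m: c.to_dict() for m, c in self.metrics.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.display() for c in self.metrics.values()])


def compare_groups(outcomes: pd.DataFrame,
                   control_label: str = "control",
                   target_label: str = "target") -> ComparisonReport:
    """Table-style report over a long-format outcomes table.

    ``outcomes`` columns: ``subject, group, metric, value``.  Each metric
    needs at least two subjects per group.
    """
    required = {"subject", "group", "metric", "value"}
    missing = required - set(outcomes.columns)
    if missing:
        raise ValueError(f"outcomes table missing columns {sorted(missing)}")
    report = ComparisonReport()
    for metric, sub in outcomes.groupby("metric"):
        x = sub.loc[sub["group"] == control_label, "value"].to_numpy(dtype=float)
        y = sub.loc[sub["group"] == target_label, "value"].to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"metric {metric!r}: need >= 2 subjects per group")
        w, p_lev = levene_test(x, y)
        t, df, p_t, f = pooled_t(x, y)
        f_anova, _ = anova_oneway([x, y])
        assert (not np.isfinite(f)
                or abs(f_anova - f) <= 1e-6 * max(1.0, abs(f))), "F = t^2 cross-check"
        h, p_kw = kruskal_wallis([x, y])
        ctrl = GroupSummary.from_sample(x)
        tgt = GroupSummary.from_sample(y)
        report.metrics[str(metric)] = MetricComparison(
            metric=str(metric),
            control=ctrl, target=tgt,
            percent_difference=percent_difference(ctrl.mean, tgt.mean),
            levene_w=w, levene_p=p_lev,
            variances_equal=p_lev > ALPHA,
            levene_weak=ALPHA < p_lev <= WEAK_LEVENE,
            t=t, df=df, p_t=p_t, f=f, h=h, p_chisq=p_kw,
            different=p_t < ALPHA,
            kw_corroborates=(p_kw < ALPHA) == (p_t < ALPHA),
        )
    return report
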