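"""One-way ANOVA and Dunnett many-to-one comparisons against a control.

Both tests work either from raw replicates or from summary triples
(mean, SD, n), since published tables usually report only the latter;
between- and within-group sums of squares reconstruct exactly from
summaries.

Dunnett's test compares every group against one control using the ANOVA
pooled variance.  Adjusted p-values are computed from the null
distribution of the maximum |t| over the comparisons, where the t
statistics share the control mean and the pooled variance estimate:
T_i = lam_i * Z_0 + sqrt(1 - lam_i**2) * Z_i, all divided by a common
sqrt(chi2_df/df), with lam_i = sqrt(n_i / (n_i + n_0)) (correlation 1/2
between comparisons in a balanced design).  The max-|t| distribution is
sampled by seeded Monte Carlo rather than taken from printed tables, so
accuracy is controlled by the number of draws and is verified against an
independent brute-force oracle in the test suite.

Tests are run on raw EC50 values by default to mirror common practice in
TEVC dose-response work; pass log-transformed values for the (better
behaved) log-scale variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupData",
    "AnovaResult",
    "one_way_anova",
    "dunnett_vs_control",
    "dunnett_critical_value",
    "sample_max_abs_t",
]


@dataclass(frozen=True)
class GroupData:
    """One group: raw replicate values, or the (mean, sd, n) summary."""

    label: str
    values: np.ndarray | None = None
    mean: float | None = None
    sd: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.values is not None:
            v = np.asarray(self.values, dtype=float)
            if v.ndim != 1 or v.size < 1:
                raise ValueError(f"group {self.label!r}: values must be a 1-D vector")
            object.__setattr__(self, "values", v)
            object.__setattr__(self, "mean", float(v.mean()))
            object.__setattr__(self, "sd", float(v.std(ddof=1)) if v.size > 1 else 0.0)
            object.__setattr__(self, "n", int(v.size))
        else:
            if self.mean is None or self.sd is None or self.n is None:
                raise ValueError(
                    f"group {self.label!r}: provide values or (mean, sd, n)"
                )
            if self.n < 2:
                raise ValueError(
                    f"group {self.label!r}: summary-based tests need n >= 2"
                )
            if self.sd < 0:
                raise ValueError(f"group {self.label!r}: sd must be non-negative")


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    pooled_variance: float


def one_way_anova(groups: Sequence[GroupData]) -> AnovaResult:
    """Fixed-effects one-way ANOVA from replicates or summary triples."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    n_total = ns.sum()
    grand = float(np.sum(ns * means) / n_total)
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds**2))
    df_between = len(groups) - 1
    df_within = int(n_total) - len(groups)
    if df_within < 1:
        raise ValueError("no within-group degrees of freedom")
    ms_within = ss_within / df_within
    if ms_within == 0:
        f = math.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f = (ss_between / df_between) / ms_within
        p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(f, df_between, df_within, p, ms_within)


def sample_max_abs_t(
    lambdas: np.ndarray, df: int, n_draws: int, seed: int
) -> np.ndarray:
    """Seeded draws of max_i |T_i| for the Dunnett null (see module docstring)."""
    rng = np.random.default_rng(seed)
    lambdas = np.asarray(lambdas, dtype=float)
    m = lambdas.size
    z0 = rng.standard_normal(n_draws)
    zi = rng.standard_normal((n_draws, m))
    numer = lambdas * z0[:, None] + np.sqrt(1.0 - lambdas**2) * zi
    denom = np.sqrt(rng.chisquare(df, n_draws) / df)
    return np.max(np.abs(numer / denom[:, None]), axis=1)


def dunnett_critical_value(
    lambdas: np.ndarray, df: int, alpha: float, n_draws: int = 200_000, seed: int = 0
) -> float:
    """Two-sided Dunnett critical value by Monte Carlo (1-alpha quantile)."""
    draws = sample_max_abs_t(lambdas, df, n_draws, seed)
    return float(np.quantile(draws, 1.0 - alpha))


def dunnett_vs_control(
    groups: Sequence[GroupData],
    control_label: str,
    alpha: float = 0.05,
    n_draws: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Dunnett's many-to-one comparisons against ``control_label``.

    Returns a DataFrame with one row per non-control group: the t
    statistic against the control (pooled-variance SE), the unadjusted
    two-sided p, the Dunnett-adjusted p, and a significance flag at
    ``alpha``.  With a single comparison the adjusted p equals the
    unadjusted one; in general it is clamped to be no smaller (the
    max-|t| null is stochastically larger than a single |t|).
    """
    labels = [g.label for g in groups]
    if control_label not in labels:
        raise ValueError(f"control group {control_label!r} not present")
    if len(groups) < 2:
        raise ValueError("need at least one comparison group")
    anova = one_way_anova(groups)
    s2, df = anova.pooled_variance, anova.df_within
    control = groups[labels.index(control_label)]
    others = [g for g in groups if g.label != control_label]

    lambdas = np.array([math.sqrt(g.n / (g.n + control.n)) for g in others])
    ts = np.array(
        [
            (g.mean - control.mean) / math.sqrt(s2 * (1.0 / g.n + 1.0 / control.n))
            for g in others
        ]
    )
    p_unadj = 2.0 * stats.t.sf(np.abs(ts), df)
    if len(others) == 1:
        p_adj = p_unadj.copy()
    else:
        draws = sample_max_abs_t(lambdas, df, n_draws, seed)
        p_adj = np.array([np.mean(draws >= abs(t)) for t in ts])
        p_adj = np.maximum(p_adj, p_unadj)  # Dunnett p can never undercut unadjusted
    return pd.DataFrame(
        {
            "group": [g.label for g in others],
            "mean_diff": [g.mean - control.mean for g in others],
            "t": ts,
            "p_unadjusted": p_unadj,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        }
    )
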