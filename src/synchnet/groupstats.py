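"""ROI degree aggregation, condition contrasts and group-level statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatResult",
    "roi_mean_degree",
    "relative_change",
    "welch_t",
    "paired_t",
    "mixed_anova",
    "multi_density_rule",
    "degree_tmap",
]


@dataclass
class StatResult:
    effect: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    test: str
    k: int | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def roi_mean_degree(
    degrees: np.ndarray, labels: list[str], roi: tuple[str, ...] | list[str]
) -> float:
    """Arithmetic mean of node degree over the ROI channels."""
    if len(roi) == 0:
        raise ValueError("ROI is empty")
    index = {ch: i for i, ch in enumerate(labels)}
    missing = [ch for ch in roi if ch not in index]
    if missing:
        raise KeyError(f"ROI labels not in graph: {missing}")
    return float(np.mean([degrees[index[ch]] for ch in roi]))


def relative_change(a: float, b: float, mode: str = "symmetric") -> float:
    """Percent change from b to a.

    ``symmetric``: 100 * (a - b) / ((a + b) / 2) — antisymmetric in its
    arguments and bounded in [-200, 200] for nonnegative inputs.
    ``simple``: 100 * (a - b) / b.
    """
    if mode == "symmetric":
        denom = (a + b) / 2.0
    elif mode == "simple":
        denom = b
    else:
        raise ValueError(f"unknown relative-change mode {mode!r}")
    if denom == 0:
        raise ZeroDivisionError("zero denominator in relative change")
    return 100.0 * (a - b) / denom


def welch_t(x, y, effect: str = "group difference") -> StatResult:
    """Two-tailed unequal-variance two-sample t-test (Welch-Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    res = stats.ttest_ind(x, y, equal_var=False)
    return StatResult(
        effect=effect,
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        test="welch_t",
    )


def paired_t(x, y, effect: str = "condition difference") -> StatResult:
    """Two-tailed paired-samples t-test (one-sample t on differences)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need n >= 2 pairs")
    d = x - y
    if np.var(d, ddof=1) == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    res = stats.ttest_rel(x, y)
    return StatResult(
        effect=effect,
        statistic=float(res.statistic),
        df=float(x.size - 1),
        p_value=float(res.pvalue),
        test="paired_t",
    )


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "condition",
    between: str = "group",
    subject: str = "subject",
) -> list[StatResult]:
    """Two-way mixed-design ANOVA (within x between) by sums of squares.

    Every subject must contribute exactly one observation per within level
    (balanced within factor; group sizes may differ).  The between effect is
    tested against subject-within-group error; the within effect and the
    interaction against the within-subject residual.
    """
    cols = {dv, within, between, subject}
    missing = cols - set(data.columns)
    if missing:
        raise KeyError(f"missing columns: {sorted(missing)}")
    counts = data.groupby([subject, within], observed=True)[dv].count()
    if (counts != 1).any():
        raise ValueError("each subject needs exactly one value per within level")
    levels_w = data[within].nunique()
    per_subject = data.groupby(subject, observed=True)[within].nunique()
    if (per_subject != levels_w).any():
        raise ValueError("missing within-level cells for some subjects")
    group_of = data.groupby(subject, observed=True)[between].nunique()
    if (group_of != 1).any():
        raise ValueError("subject assigned to multiple groups")

    y = data[dv].to_numpy(dtype=float)
    grand = y.mean()
    t = levels_w
    a = data[between].nunique()
    n_subjects = data[subject].nunique()

    subj_means = data.groupby(subject, observed=True)[dv].mean()
    group_means = data.groupby(between, observed=True)[dv].mean()
    cond_means = data.groupby(within, observed=True)[dv].mean()
    cell_means = data.groupby([between, within], observed=True)[dv].mean()
    group_sizes = data.groupby(between, observed=True)[subject].nunique()

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(t * ((subj_means - grand) ** 2).sum())
    ss_a = float(t * (group_sizes * (group_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_a
    ss_t = float(n_subjects * ((cond_means - grand) ** 2).sum())
    ss_cells = 0.0
    for (g, w), m in cell_means.items():
        ss_cells += group_sizes[g] * (m - grand) ** 2
    ss_at = float(ss_cells) - ss_a - ss_t
    ss_err_within = ss_total - ss_between_subj - ss_t - ss_at

    df_a = a - 1
    df_subj = n_subjects - a
    df_t = t - 1
    df_at = df_a * df_t
    df_err = df_subj * df_t
    if df_subj <= 0 or df_err <= 0:
        raise ValueError("not enough subjects for the design")

    ms_subj = ss_subj_within / df_subj
    ms_err = ss_err_within / df_err

    def _f(ss: float, df: int, ms_denom: float, df_denom: int, name: str) -> StatResult:
        if ms_denom <= 0:
            f_val, p = (0.0, 1.0) if ss <= 1e-12 else (np.inf, 0.0)
        else:
            f_val = (ss / df) / ms_denom
            f_val = max(f_val, 0.0)
            p = float(stats.f.sf(f_val, df, df_denom))
        return StatResult(
            effect=name,
            statistic=float(f_val),
            df=(float(df), float(df_denom)),
            p_value=p,
            test="mixed_anova",
        )

    return [
        _f(ss_t, df_t, ms_err, df_err, within),
        _f(ss_a, df_a, ms_subj, df_subj, between),
        _f(ss_at, df_at, ms_err, df_err, f"{within} * {between}"),
    ]


def multi_density_rule(
    p_values, alpha: float = 0.05, min_levels: int = 3
) -> bool:
    """Significant only if p < alpha at >= ``min_levels`` density levels."""
    p_values = list(p_values)
    if len(p_values) == 0:
        raise ValueError("empty p-value list")
    return sum(p < alpha for p in p_values) >= min_levels


def degree_tmap(
    degrees: pd.DataFrame,
    contrast: tuple[str, str],
    dv: str = "degree",
    subject: str = "subject",
    condition: str = "condition",
    channel: str = "channel",
) -> pd.DataFrame:
    """Per-channel paired t between two conditions across subjects.

    ``degrees`` is long-format (subject, condition, channel, degree).
    Channels with zero-variance differences get NaN t/p with a flag rather
    than an error.
    """
    cond_a, cond_b = contrast
    wide = degrees.pivot_table(
        index=[subject, channel], columns=condition, values=dv
    ).reset_index()
    for cond in contrast:
        if cond not in wide.columns:
            raise KeyError(f"condition {cond!r} absent from degree table")
    rows = []
    for ch, grp in wide.groupby(channel):
        x = grp[cond_a].to_numpy(dtype=float)
        y = grp[cond_b].to_numpy(dtype=float)
        if np.any(np.isnan(x)) or np.any(np.isnan(y)):
            raise ValueError(f"unpaired subjects for channel {ch!r}")
        try:
            res = paired_t(x, y)
            rows.append(
                {
                    "channel": ch,
                    "t": res.statistic,
                    "df": res.df,
                    "p": res.p_value,
                    "degenerate": False,
                }
            )
        except ValueError:
            rows.append(
                {"channel": ch, "t": np.nan, "df": np.nan, "p": np.nan,
                 "degenerate": True}
            )
    return pd.DataFrame(rows)
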