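"""Group-level statistics: repeated-measures ANOVA with generalized
eta-squared, paired t-tests with Hedges g_av, and within-subject-corrected
SEM (Cousineau-Morey).

All p-values are two-tailed and uncorrected.  No sphericity correction is
applied to the ANOVA degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = ["EffectReport", "rm_anova", "paired_t_gav", "within_subject_sem"]


@dataclass
class EffectReport:
    """One test statistic with effect size."""

    name: str
    statistic: float  # F or t
    df: tuple
    p: float
    effect_size: float
    effect_size_name: str  # "eta_g_squared" or "g_av"

    def __str__(self):
        df = ",".join(f"{d:g}" for d in self.df)
        return (f"{self.name}: stat({df}) = {self.statistic:.3f}, "
                f"p = {self.p:.4g}, {self.effect_size_name} = "
                f"{self.effect_size:.3f}")


def _check_balanced(df: pd.DataFrame, subject: str, within) -> None:
    counts = df.groupby([subject, *within], observed=True).size()
    if counts.nunique() != 1 or counts.iloc[0] != 1:
        raise ValueError("design must be balanced with one value per cell")
    per_subject = df.groupby(subject, observed=True).size()
    if per_subject.nunique() != 1:
        raise ValueError("design must be balanced across subjects")


def rm_anova(
    df: pd.DataFrame,
    dv: str = "value",
    within="array",
    subject: str = "subject",
) -> list[EffectReport]:
    """Repeated-measures ANOVA (one- or two-way) with generalized
    eta-squared effect sizes.

    ``within`` is one factor name or a list of two.  Returns one
    EffectReport per effect (main effects, then the interaction for
    two-way designs).  Uncorrected degrees of freedom.
    """
    import pingouin as pg

    within_list = [within] if isinstance(within, str) else list(within)
    if len(within_list) not in (1, 2):
        raise ValueError("only one- and two-way designs are supported")
    _check_balanced(df, subject, within_list)
    res = pg.rm_anova(
        data=df, dv=dv,
        within=within_list if len(within_list) > 1 else within_list[0],
        subject=subject, effsize="ng2", correction=False, detailed=True,
    )
    # column names vary across pingouin versions / designs
    p_col = "p_unc" if "p_unc" in res.columns else "p-unc"
    error_df = None
    if "ddof1" not in res.columns:
        err = res[res["Source"].isin(["Error", "Within"])]
        if len(err):
            error_df = float(err.iloc[0]["DF"])
    reports = []
    for _, row in res.iterrows():
        if row["Source"] in ("Error", "Within"):
            continue
        if "ddof1" in res.columns:
            df = (float(row["ddof1"]), float(row["ddof2"]))
        else:
            df = (float(row["DF"]), error_df)
        reports.append(
            EffectReport(
                name=str(row["Source"]),
                statistic=float(row["F"]),
                df=df,
                p=float(row[p_col]),
                effect_size=float(row["ng2"]),
                effect_size_name="eta_g_squared",
            )
        )
    return reports


def paired_t_gav(a, b, name: str = "paired") -> EffectReport:
    """Two-tailed paired t-test with the Hedges g_av effect size.

    g_av divides the mean difference by the average of the two condition
    standard deviations and applies the small-sample (Hedges) correction
    J = 1 - 3 / (4 (n - 1) - 1).  With zero-variance zero-mean differences
    the statistic is undefined and reported as NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D arrays")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        t = np.nan if np.allclose(diff.mean(), 0.0) else np.inf * np.sign(diff.mean())
        p = np.nan
    else:
        res = sstats.ttest_rel(a, b)
        t, p = float(res.statistic), float(res.pvalue)
    sd_avg = (a.std(ddof=1) + b.std(ddof=1)) / 2.0
    if sd_avg == 0:
        g = 0.0 if np.allclose(diff.mean(), 0.0) else np.nan
    else:
        J = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
        g = float(diff.mean() / sd_avg * J)
    return EffectReport(name=name, statistic=t, df=(n - 1,), p=p,
                        effect_size=g, effect_size_name="g_av")


def within_subject_sem(
    df: pd.DataFrame,
    dv: str = "value",
    within: str = "array",
    subject: str = "subject",
) -> pd.Series:
    """Cousineau-Morey within-subject standard error per condition.

    Each subject's mean is subtracted and the grand mean added back
    (removing pure between-subject variance); the SEM of the normalized
    values is then scaled by the Morey factor sqrt(k / (k - 1)) for k
    conditions.
    """
    _check_balanced(df, subject, [within])
    wide = df.pivot(index=subject, columns=within, values=dv)
    k = wide.shape[1]
    if k < 2:
        raise ValueError("need at least 2 conditions")
    normalized = wide.sub(wide.mean(axis=1), axis=0) + wide.to_numpy().mean()
    sem = normalized.std(ddof=1) / np.sqrt(wide.shape[0])
    return sem * np.sqrt(k / (k - 1.0))
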