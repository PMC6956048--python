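"""Relative qPCR quantification and group-comparison statistics.

Fold changes use the comparative-Ct model: per sample,
``dCt = Ct_target - Ct_housekeeping``; per gene, ``ddCt = dCt - mean(dCt)``
over the control group; ``fold = 2**(-ddCt)``. Under this construction the
control group's geometric-mean fold is exactly 1 and the housekeeping gene's
fold is exactly 1 for every sample. Group summaries are geometric means
(arithmetic mean of log2 fold), the appropriate central tendency for ratio
data.

The two-sample t tests (pooled-variance Student and Welch) and the one-way
ANOVA are computed from their defining formulas, with two-sided p-values via
the regularized incomplete beta function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "FoldChangeResult",
    "TestResult",
    "validate_ct_table",
    "delta_delta_ct",
    "two_sample_t",
    "two_sample_t_from_summary",
    "one_way_anova",
    "holm_adjust",
]

CT_COLUMNS = ("sample_id", "group", "gene", "ct")


@dataclass
class FoldChangeResult:
    per_sample: pd.DataFrame  # sample_id, group, gene, dct, ddct, fold_change
    group_summary: pd.DataFrame  # group, gene, geo_mean_fold, sd_log2_fold, n
    housekeeping: str
    control_group: str


@dataclass
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_two_sided: float
    test_name: Literal["student_t", "welch_t", "anova_F"]


class DegenerateStatisticError(ValueError):
    """The test statistic is undefined (zero variance, zero difference)."""


def validate_ct_table(table: pd.DataFrame, housekeeping: str) -> None:
    """Raise ``ValueError`` on schema, duplication or missing-housekeeping faults."""
    missing_cols = set(CT_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValueError(f"Ct table missing columns {sorted(missing_cols)}")
    if not np.isfinite(table["ct"].to_numpy(dtype=float)).all():
        raise ValueError("Ct table contains non-finite Ct values")
    dup = table.duplicated(subset=["sample_id", "gene"])
    if dup.any():
        pairs = table.loc[dup, ["sample_id", "gene"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (sample, gene) measurements: {pairs[:5]}")
    has_hk = table.groupby("sample_id")["gene"].apply(lambda g: housekeeping in set(g))
    if not has_hk.all():
        lacking = sorted(has_hk.index[~has_hk])
        raise ValueError(f"samples missing housekeeping gene {housekeeping!r}: {lacking}")


def delta_delta_ct(
    table: pd.DataFrame,
    housekeeping: str = "Gapdh",
    control_group: str = "control",
) -> FoldChangeResult:
    """Comparative-Ct fold changes normalized to a housekeeping gene and a
    control group. See the module docstring for the model."""
    validate_ct_table(table, housekeeping)
    if control_group not in set(table["group"]):
        raise ValueError(f"control group {control_group!r} absent from table")
    df = table.copy()
    hk_ct = (
        df[df["gene"] == housekeeping].set_index("sample_id")["ct"].rename("hk_ct")
    )
    df = df.join(hk_ct, on="sample_id")
    df["dct"] = df["ct"] - df["hk_ct"]
    control_mean = (
        df[df["group"] == control_group].groupby("gene")["dct"].mean().rename("control_dct")
    )
    df = df.join(control_mean, on="gene")
    df["ddct"] = df["dct"] - df["control_dct"]
    df["fold_change"] = np.exp2(-df["ddct"])
    per_sample = df[["sample_id", "group", "gene", "dct", "ddct", "fold_change"]]
    grp = df.groupby(["group", "gene"], sort=False)
    summary = grp.agg(
        geo_mean_fold=("ddct", lambda v: float(np.exp2(-np.mean(v)))),
        sd_log2_fold=("ddct", lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0),
        n=("ddct", "size"),
    ).reset_index()
    return FoldChangeResult(
        per_sample=per_sample.reset_index(drop=True),
        group_summary=summary,
        housekeeping=housekeeping,
        control_group=control_group,
    )


def _t_p_two_sided(t: float, df: float) -> float:
    """P(|T_df| >= |t|) via the regularized incomplete beta function."""
    if not np.isfinite(t):
        return 0.0
    return float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    variant: Literal["student", "welch"] = "student",
) -> TestResult:
    """Two-sample t test from raw observations (each sample n >= 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample must contain at least 2 observations")
    return two_sample_t_from_summary(
        (x.mean(), x.std(ddof=1), len(x)),
        (y.mean(), y.std(ddof=1), len(y)),
        variant=variant,
    )


def two_sample_t_from_summary(
    x: tuple[float, float, int],
    y: tuple[float, float, int],
    variant: Literal["student", "welch"] = "student",
) -> TestResult:
    """Two-sample t test from (mean, sd, n) summaries.

    Student: pooled variance, df = n1 + n2 - 2. Welch: unpooled variance with
    Welch-Satterthwaite df. Zero variance in both samples with equal means is
    an undefined statistic and raises :class:`DegenerateStatisticError`.
    """
    m1, s1, n1 = float(x[0]), float(x[1]), int(x[2])
    m2, s2, n2 = float(y[0]), float(y[1]), int(y[2])
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample must have n >= 2")
    if s1 == 0.0 and s2 == 0.0 and m1 == m2:
        raise DegenerateStatisticError("zero variance in both samples with equal means")
    if variant == "student":
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df: float = n1 + n2 - 2
        name: Literal["student_t", "welch_t"] = "student_t"
    elif variant == "welch":
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)) if se > 0 else 1.0
        name = "welch_t"
    else:
        raise ValueError(f"unknown variant {variant!r}")
    t = (m1 - m2) / se if se > 0 else np.inf * np.sign(m1 - m2)
    return TestResult(
        statistic=float(t),
        df=float(df),
        p_two_sided=_t_p_two_sided(float(t), float(df)),
        test_name=name,
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Classic one-way fixed-effects ANOVA (between/within decomposition).

    F = MSB / MSW with df (k-1, N-k); p from the F distribution via the
    regularized incomplete beta function. All-identical data (both sums of
    squares zero) raise :class:`DegenerateStatisticError`.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"group {i} has n={len(g)} < 2")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    n_total = len(all_values)
    k = len(arrays)
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df1, df2 = k - 1, n_total - k
    if ssb == 0.0 and ssw == 0.0:
        raise DegenerateStatisticError("all groups identical constants; F undefined")
    msb, msw = ssb / df1, ssw / df2
    f = msb / msw if msw > 0 else np.inf
    if np.isfinite(f):
        p = float(special.betainc(df2 / 2.0, df1 / 2.0, df2 / (df2 + df1 * f)))
    else:
        p = 0.0
    return TestResult(statistic=float(f), df=(float(df1), float(df2)), p_two_sided=p, test_name="anova_F")


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment (off by default in the reporting pipeline)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
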