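"""Statistical layer for subject-level tables.

Covers the tests used on n = 3-4 subject designs: one-sample, paired and
unpaired Student t tests (two-sided, alpha = 0.05); one- and two-way
repeated-measures ANOVA on complete balanced within-subject tables (no
sphericity correction); and Tukey HSD post-hoc comparisons built on the
studentized-range distribution with the repeated-measures error mean square.

The ANOVA sums of squares are computed in closed form for balanced designs,
which keeps null-calibration simulations with thousands of replicates cheap;
degrees of freedom are (levels - 1, (levels - 1)(n_subjects - 1)) per
within-subject factor.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sst

from .errors import StatsError

ALPHA = 0.05  # two-sided significance threshold used throughout

DfLike = Union[float, tuple[float, float]]


@dataclass(frozen=True)
class StatResult:
    """Outcome of one test: statistic, df, p, direction, optional extras.

    ``direction`` is the sign of the headline effect (+1 / 0 / -1).  For
    ANOVAs ``effects`` holds the per-effect F table and the headline
    statistic/df/p refer to the effect named in ``test_name``.
    ``degenerate`` marks zero-variance inputs (infinite or undefined t).
    """

    test_name: str
    statistic: float
    df: DfLike
    p_value: float
    direction: int = 0
    n: int = 0
    effects: Optional[pd.DataFrame] = None
    posthoc: Optional[pd.DataFrame] = None
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        d = {"test": self.test_name, "statistic": self.statistic, "df": self.df,
             "p_value": self.p_value, "direction": self.direction, "n": self.n,
             "significant": bool(self.significant), "degenerate": self.degenerate}
        if self.effects is not None:
            d["effects"] = self.effects.to_dict(orient="records")
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), default=float, **kw)

    def __str__(self) -> str:
        df = self.df if np.isscalar(self.df) else ", ".join(f"{d:g}" for d in self.df)
        return (f"{self.test_name}: statistic = {self.statistic:.4g}, "
                f"df = {df}, p = {self.p_value:.4g}")


def _as_array(values, name: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if len(arr) < min_n:
        raise StatsError(f"{name}: need at least {min_n} values, got {len(arr)}")
    if not np.all(np.isfinite(arr)):
        raise StatsError(f"{name}: non-finite values")
    return arr


def _t_from_mean_sd(mean: float, sd: float, n: int, df: int,
                    test_name: str) -> StatResult:
    if sd == 0.0:
        # Zero-variance input: t is 0 (mean on target) or infinite.
        stat = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
        p = 1.0 if mean == 0.0 else 0.0
        return StatResult(test_name, stat, float(df), p,
                          direction=int(np.sign(mean)), n=n, degenerate=True)
    stat = mean / (sd / math.sqrt(n))
    p = 2.0 * sst.t.sf(abs(stat), df)
    return StatResult(test_name, float(stat), float(df), float(p),
                      direction=int(np.sign(mean)), n=n)


def one_sample_t(values, mu0: float = 0.0) -> StatResult:
    """Two-sided one-sample Student t test against ``mu0`` (df = n - 1)."""
    arr = _as_array(values, "one_sample_t")
    diff = arr - mu0
    return _t_from_mean_sd(float(diff.mean()), float(diff.std(ddof=1)),
                           len(arr), len(arr) - 1, "one_sample_t")


def paired_t(a, b=None) -> StatResult:
    """Two-sided paired t test (df = n - 1).

    Accepts either two equal-length sequences or a single sequence of
    differences.
    """
    if b is None:
        diff = _as_array(a, "paired_t")
    else:
        x = _as_array(a, "paired_t a")
        y = _as_array(b, "paired_t b")
        if len(x) != len(y):
            raise StatsError("paired_t: unequal lengths")
        diff = x - y
    res = _t_from_mean_sd(float(diff.mean()), float(diff.std(ddof=1)),
                          len(diff), len(diff) - 1, "paired_t")
    return res


def unpaired_t(group_a, group_b) -> StatResult:
    """Two-sided Student t test with pooled variance (df = n_a + n_b - 2)."""
    a = _as_array(group_a, "unpaired_t a")
    b = _as_array(group_b, "unpaired_t b")
    na, nb = len(a), len(b)
    df = na + nb - 2
    ssq = (na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)
    mean = float(a.mean() - b.mean())
    if ssq == 0.0:
        stat = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
        return StatResult("unpaired_t", stat, float(df),
                          1.0 if mean == 0.0 else 0.0,
                          direction=int(np.sign(mean)), n=na + nb, degenerate=True)
    se = math.sqrt(ssq / df * (1.0 / na + 1.0 / nb))
    stat = mean / se
    p = 2.0 * sst.t.sf(abs(stat), df)
    return StatResult("unpaired_t", float(stat), float(df), float(p),
                      direction=int(np.sign(mean)), n=na + nb)


# --------------------------------------------------------------------------
# Repeated-measures ANOVA (balanced, all-within designs)


def _f_p(ss_eff: float, df_eff: int, ss_err: float, df_err: int) -> tuple[float, float]:
    if ss_eff <= 0.0:
        return 0.0, 1.0
    if ss_err <= 0.0:
        return math.inf, 0.0
    f = (ss_eff / df_eff) / (ss_err / df_err)
    return float(f), float(sst.f.sf(f, df_eff, df_err))


def _to_wide(table, index: str, columns: str, values: str = "auc_mean"):
    """subject x condition wide matrix from a tidy or already-wide table."""
    if isinstance(table, pd.DataFrame):
        if {index, columns}.issubset(table.columns):
            vcol = values if values in table.columns else (
                "auc" if "auc" in table.columns else None)
            if vcol is None:
                raise StatsError(f"tidy table needs a '{values}' or 'auc' column")
            wide = table.pivot_table(index=index, columns=columns, values=vcol,
                                     aggfunc="mean")
            if wide.isna().any().any():
                missing = [(i, c) for i in wide.index for c in wide.columns
                           if pd.isna(wide.at[i, c])]
                raise StatsError(f"missing cells (no imputation): {missing[:10]}")
            return wide
        return table  # already wide (subjects x conditions)
    return pd.DataFrame(np.asarray(table, dtype=float))


def one_way_rm_anova(table) -> StatResult:
    """One-way repeated-measures ANOVA on a subject x condition table.

    Accepts a 2-d array (rows = subjects), a wide DataFrame, or a tidy frame
    with ``subject``/``condition`` columns.  F = MS_condition / MS_error with
    df = (k - 1, (k - 1)(n - 1)); the subject main effect is removed from the
    error term.  Missing cells are an error.
    """
    wide = _to_wide(table, "subject", "condition")
    x = wide.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise StatsError("missing or non-finite cells (no imputation)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise StatsError(f"need >= 2 subjects and >= 2 conditions, got {n} x {k}")
    grand = x.mean()
    ss_cond = n * float(((x.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((x.mean(axis=1) - grand) ** 2).sum())
    ss_tot = float(((x - grand) ** 2).sum())
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond, df_err = k - 1, (k - 1) * (n - 1)
    f, p = _f_p(ss_cond, df_cond, ss_err, df_err)
    effects = pd.DataFrame([{"effect": "condition", "F": f, "df1": df_cond,
                             "df2": df_err, "p": p,
                             "ms_error": ss_err / df_err if df_err else np.nan}])
    return StatResult("one_way_rm_anova[condition]", f, (float(df_cond), float(df_err)),
                      p, n=n, effects=effects)


def two_way_rm_anova(table, factor_a: str = "session",
                     factor_b: str = "trial_type") -> StatResult:
    """Two-way repeated-measures ANOVA (both factors within-subject).

    Accepts a 3-d array ``(n_subjects, a_levels, b_levels)`` or a tidy
    DataFrame with ``subject``, ``factor_a``, ``factor_b`` columns and an
    ``auc_mean``/``auc``/``value`` column.  Each effect is tested against its
    own factor x subject interaction: df = (a-1, (a-1)(n-1)) for A,
    (b-1, (b-1)(n-1)) for B, ((a-1)(b-1), (a-1)(b-1)(n-1)) for A x B.  The
    headline statistic is the interaction.  Missing cells are an error.
    """
    if isinstance(table, pd.DataFrame):
        vcol = next((c for c in ("auc_mean", "auc", "value") if c in table.columns), None)
        if vcol is None or not {"subject", factor_a, factor_b}.issubset(table.columns):
            raise StatsError(
                f"tidy table needs columns subject/{factor_a}/{factor_b} and a value")
        wide = table.pivot_table(index="subject", columns=[factor_a, factor_b],
                                 values=vcol, aggfunc="mean")
        a_levels = wide.columns.get_level_values(0).unique()
        b_levels = wide.columns.get_level_values(1).unique()
        if wide.shape[1] != len(a_levels) * len(b_levels) or wide.isna().any().any():
            raise StatsError("incomplete subject x factor table (no imputation)")
        x = (wide.reindex(columns=pd.MultiIndex.from_product([a_levels, b_levels]))
             .to_numpy(dtype=float).reshape(len(wide), len(a_levels), len(b_levels)))
    else:
        x = np.asarray(table, dtype=float)
        if x.ndim != 3:
            raise StatsError("array input must be (n_subjects, a_levels, b_levels)")
    if not np.all(np.isfinite(x)):
        raise StatsError("missing or non-finite cells (no imputation)")
    n, a, b = x.shape
    if n < 2 or a < 2 or b < 2:
        raise StatsError(f"need >= 2 levels everywhere, got {n} x {a} x {b}")

    g = x.mean()
    m_s = x.mean(axis=(1, 2))           # subject means
    m_a = x.mean(axis=(0, 2))           # factor-A means
    m_b = x.mean(axis=(0, 1))
    m_sa = x.mean(axis=2)               # (n, a)
    m_sb = x.mean(axis=1)               # (n, b)
    m_ab = x.mean(axis=0)               # (a, b)

    ss_a = n * b * float(((m_a - g) ** 2).sum())
    ss_b = n * a * float(((m_b - g) ** 2).sum())
    ss_s = a * b * float(((m_s - g) ** 2).sum())
    ss_sa = b * float(((m_sa - m_a[None, :] - m_s[:, None] + g) ** 2).sum())
    ss_sb = a * float(((m_sb - m_b[None, :] - m_s[:, None] + g) ** 2).sum())
    ss_ab = n * float(((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2).sum())
    ss_tot = float(((x - g) ** 2).sum())
    ss_sab = ss_tot - ss_a - ss_b - ss_s - ss_sa - ss_sb - ss_ab

    rows = []
    for name, ss_eff, df_eff, ss_err, df_err in [
        (factor_a, ss_a, a - 1, ss_sa, (a - 1) * (n - 1)),
        (factor_b, ss_b, b - 1, ss_sb, (b - 1) * (n - 1)),
        ("interaction", ss_ab, (a - 1) * (b - 1), ss_sab, (a - 1) * (b - 1) * (n - 1)),
    ]:
        f, p = _f_p(ss_eff, df_eff, max(ss_err, 0.0), df_err)
        rows.append({"effect": name, "F": f, "df1": df_eff, "df2": df_err, "p": p})
    effects = pd.DataFrame(rows)
    inter = rows[-1]
    return StatResult("two_way_rm_anova[interaction]", inter["F"],
                      (float(inter["df1"]), float(inter["df2"])), inter["p"],
                      n=n, effects=effects)


def tukey_posthoc(table) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons after a one-way RM ANOVA.

    q = |mean_i - mean_j| / sqrt(MS_error / n) with the repeated-measures
    error mean square and df; p from the studentized-range distribution.
    """
    wide = _to_wide(table, "subject", "condition")
    x = wide.to_numpy(dtype=float)
    anova = one_way_rm_anova(wide)
    n, k = x.shape
    df_err = float(anova.df[1])
    ms_err = float(anova.effects["ms_error"].iloc[0])
    means = x.mean(axis=0)
    names = list(wide.columns)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        if ms_err <= 0.0:
            q = 0.0 if diff == 0.0 else math.inf
            p = 1.0 if diff == 0.0 else 0.0
        else:
            q = abs(diff) / math.sqrt(ms_err / n)
            p = float(sst.studentized_range.sf(q, k, df_err))
        rows.append({"group_a": names[i], "group_b": names[j],
                     "mean_diff": float(diff), "q": float(q),
                     "p_value": min(1.0, p), "significant": p < ALPHA})
    return pd.DataFrame(rows)


def one_way_rm_anova_with_tukey(table) -> StatResult:
    """One-way RM ANOVA plus Tukey HSD table attached as ``posthoc``."""
    res = one_way_rm_anova(table)
    posthoc = tukey_posthoc(table)
    return StatResult(res.test_name, res.statistic, res.df, res.p_value,
                      direction=res.direction, n=res.n, effects=res.effects,
                      posthoc=posthoc)
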