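"""First-principles statistical machinery used throughout the pipeline.

Implements the unpaired t-test (pooled and Welch), the balanced fixed-effects
two-way ANOVA, the split-plot (two-way mixed) ANOVA with one between-subjects
and one repeated (within-subjects) factor, and Bonferroni adjustment.  These
are authored from the sums-of-squares decompositions rather than delegated to a
statistics package so that every downstream report is traceable to an explicit
formula; scipy supplies only the t and F distribution tails.

Conventions
-----------
* t statistics are signed as ``mean(x) - mean(y)`` over the standard error.
* All p-values are two-sided.
* Degenerate zero-variance designs yield statistic 0 / p 1 with a
  ``degenerate`` flag instead of NaN, so pipelines never propagate NaN.
* ANOVA supports balanced (and for the mixed model, complete-repeated-measures)
  designs only; anything else raises :class:`IncompleteDesignError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "TestResult",
    "ANOVATable",
    "InsufficientDataError",
    "IncompleteDesignError",
    "unpaired_t_test",
    "paired_t_test",
    "two_way_anova_fixed",
    "mixed_anova_2x2plus",
    "bonferroni_adjust",
]


class InsufficientDataError(ValueError):
    """Raised when a test is asked for with fewer observations than it needs."""


class IncompleteDesignError(ValueError):
    """Raised when an ANOVA design has missing cells or subjects."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``df`` is a float (Welch df is fractional).  ``degenerate`` marks
    zero-variance inputs where the statistic was defined by convention.
    """

    statistic: float
    df: float
    p: float
    method: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value out of range: {self.p}")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "method": self.method,
            "degenerate": self.degenerate,
        }


@dataclass
class ANOVATable:
    """Tidy ANOVA decomposition: one row per effect or error stratum.

    ``rows`` maps effect name -> dict with SS, df, MS, F, p.  Error strata have
    F and p set to NaN.  ``degenerate`` flags designs where every value was
    equal (all SS zero) and F values are reported as 0 by convention.
    """

    rows: "dict[str, dict]" = field(default_factory=dict)
    method: str = ""
    degenerate: bool = False

    def add(self, effect: str, ss: float, df: float, f: float | None = None,
            p: float | None = None) -> None:
        ms = ss / df if df > 0 else np.nan
        self.rows[effect] = {
            "SS": float(ss),
            "df": float(df),
            "MS": float(ms),
            "F": np.nan if f is None else float(f),
            "p": np.nan if p is None else float(p),
        }

    def __getitem__(self, effect: str) -> dict:
        return self.rows[effect]

    @property
    def effects(self) -> list:
        return list(self.rows)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.rows, orient="index")
        df.index.name = "effect"
        return df

    def to_tsv(self, path) -> None:
        frame = self.to_frame().reset_index()
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "degenerate": self.degenerate,
            "effects": self.rows,
        }


def _as_clean_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise InsufficientDataError(f"{name} needs at least 2 values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def unpaired_t_test(x, y, equal_variance: bool = True) -> TestResult:
    """Two-sample t-test; statistic sign follows ``mean(x) - mean(y)``.

    Student's pooled-variance form when ``equal_variance`` (the default, which
    yields the integer dfs reported in group comparisons, e.g. t(10) for two
    groups of 6), Welch with Satterthwaite df otherwise.
    """
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    n1, n2 = x.size, y.size
    d = x.mean() - y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if equal_variance:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        method = "student-t"
    else:
        se2_1, se2_2 = v1 / n1, v2 / n2
        se = np.sqrt(se2_1 + se2_2)
        if se > 0:
            df = (se2_1 + se2_2) ** 2 / (
                se2_1 ** 2 / (n1 - 1) + se2_2 ** 2 / (n2 - 1)
            )
        else:
            df = n1 + n2 - 2
        method = "welch-t"
    if se == 0:
        # zero variance in both groups: equal means -> no evidence at all
        stat = 0.0 if d == 0 else np.sign(d) * np.inf
        p = 1.0 if d == 0 else 0.0
        return TestResult(stat, float(df), p, method, degenerate=True)
    t = d / se
    p = 2.0 * _st.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), method)


def paired_t_test(x, y) -> TestResult:
    """Paired t-test on the within-pair differences (x - y)."""
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    if x.size != y.size:
        raise ValueError("paired test needs equal-length series")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        stat = 0.0 if d.mean() == 0 else np.sign(d.mean()) * np.inf
        p = 1.0 if d.mean() == 0 else 0.0
        return TestResult(stat, float(n - 1), p, "paired-t", degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * _st.t.sf(abs(t), n - 1)
    return TestResult(float(t), float(n - 1), float(p), "paired-t")


def _f_p(ss_num: float, df_num: float, ss_den: float, df_den: float,
         degenerate_total: bool):
    """F and p for one effect; returns (F, p) with the 0-by-convention rule."""
    if df_num <= 0 or df_den <= 0:
        return np.nan, np.nan
    ms_num = ss_num / df_num
    ms_den = ss_den / df_den
    if ms_den == 0:
        if ms_num == 0 or degenerate_total:
            return 0.0, 1.0
        return np.inf, 0.0
    f = ms_num / ms_den
    return float(f), float(_st.f.sf(f, df_num, df_den))


def two_way_anova_fixed(table: pd.DataFrame, factor_a: str = "factorA",
                        factor_b: str = "factorB", value: str = "value",
                        ) -> ANOVATable:
    """Fixed-effects two-way ANOVA with interaction (Type-I SS).

    Computed by sequential nested least-squares fits (grand mean, +A, +B,
    +A:B), which on balanced data equals the classical cell-mean
    decomposition.  Every (A, B) cell must be observed.
    """
    df = table[[factor_a, factor_b, value]].copy()
    y = np.asarray(df[value], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("values contain non-finite entries")
    a_codes, a_levels = pd.factorize(df[factor_a], sort=True)
    b_codes, b_levels = pd.factorize(df[factor_b], sort=True)
    na, nb = len(a_levels), len(b_levels)
    if na < 2 or nb < 2:
        raise IncompleteDesignError("each factor needs >= 2 levels")
    counts = np.zeros((na, nb), dtype=int)
    np.add.at(counts, (a_codes, b_codes), 1)
    if np.any(counts == 0):
        raise IncompleteDesignError("empty cell(s) in the two-way design")

    def dummies(codes, k):
        m = np.zeros((codes.size, k))
        m[np.arange(codes.size), codes] = 1.0
        return m

    one = np.ones((y.size, 1))
    xa = dummies(a_codes, na)
    xb = dummies(b_codes, nb)
    cell = a_codes * nb + b_codes
    xab = dummies(cell, na * nb)

    def rss(design):
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        return float(resid @ resid)

    rss0 = rss(one)
    rss_a = rss(np.hstack([one, xa]))
    rss_ab = rss(np.hstack([one, xa, xb]))
    rss_full = rss(xab)  # cell-mean model

    tol = 1e-12 * max(rss0, 1.0)     # exact zeros survive lstsq round-off
    ss_a = max(rss0 - rss_a, 0.0)
    ss_b = max(rss_a - rss_ab, 0.0)
    ss_int = max(rss_ab - rss_full, 0.0)
    ss_err = max(rss_full, 0.0)
    ss_a, ss_b, ss_int, ss_err = (0.0 if s < tol else s
                                  for s in (ss_a, ss_b, ss_int, ss_err))
    df_a, df_b = na - 1, nb - 1
    df_int = df_a * df_b
    df_err = y.size - na * nb

    degenerate = rss0 == 0.0
    out = ANOVATable(method="two-way fixed ANOVA (Type-I SS)",
                     degenerate=degenerate)
    fa, pa = _f_p(ss_a, df_a, ss_err, df_err, degenerate)
    fb, pb = _f_p(ss_b, df_b, ss_err, df_err, degenerate)
    fi, pi = _f_p(ss_int, df_int, ss_err, df_err, degenerate)
    out.add(factor_a, ss_a, df_a, fa, pa)
    out.add(factor_b, ss_b, df_b, fb, pb)
    out.add(f"{factor_a}:{factor_b}", ss_int, df_int, fi, pi)
    out.add("residual", ss_err, df_err)
    return out


def mixed_anova_2x2plus(table: pd.DataFrame, subject: str = "subject",
                        group: str = "group", level: str = "level",
                        value: str = "value") -> ANOVATable:
    """Split-plot (two-way mixed) ANOVA.

    ``group`` is the between-subjects factor, ``level`` the repeated
    within-subjects factor.  Every subject must be observed exactly once at
    every within-level (complete repeated measures); groups may have unequal
    numbers of subjects.  The between-subjects stratum is partitioned into the
    group effect and subjects-within-groups (the error term for group); the
    within-subjects stratum into the level effect, the group x level
    interaction and the residual.
    """
    df = table[[subject, group, level, value]].copy()
    y_all = np.asarray(df[value], dtype=float)
    if not np.all(np.isfinite(y_all)):
        raise ValueError("values contain non-finite entries")
    levels = sorted(df[level].unique())
    b = len(levels)
    if b < 2:
        raise IncompleteDesignError("need >= 2 within-subject levels")
    # subject -> group must be unique, and each subject complete
    subj_groups = df.groupby(subject)[group].nunique()
    if (subj_groups > 1).any():
        raise IncompleteDesignError("a subject appears in more than one group")
    counts = df.groupby([subject, level]).size()
    if (counts != 1).any():
        raise IncompleteDesignError(
            "design incomplete: every subject needs exactly one value per level")
    wide = df.pivot_table(index=[group, subject], columns=level, values=value)
    if wide.isna().any().any():
        raise IncompleteDesignError("missing cell(s) in the mixed design")
    groups = wide.index.get_level_values(0)
    group_names = sorted(set(groups))
    if len(group_names) < 2:
        raise IncompleteDesignError("need >= 2 between-subject groups")
    n_per_group = {g: int((groups == g).sum()) for g in group_names}
    if min(n_per_group.values()) < 2:
        raise IncompleteDesignError("need >= 2 subjects per group")

    y = wide.to_numpy()            # subjects x levels
    grand = y.mean()
    subj_means = y.mean(axis=1)
    level_means = y.mean(axis=0)   # unweighted only if balanced; recompute below
    n_subj = y.shape[0]

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(b * ((subj_means - grand) ** 2).sum())
    # group effect (weighted by group size)
    ss_group = 0.0
    for g in group_names:
        mask = groups == g
        gm = y[mask].mean()
        ss_group += mask.sum() * b * (gm - grand) ** 2
    ss_subj_within = ss_between_subj - ss_group
    df_group = len(group_names) - 1
    df_subj_within = sum(n - 1 for n in n_per_group.values())

    ss_within = ss_total - ss_between_subj
    ss_level = float(n_subj * ((level_means - grand) ** 2).sum())
    # interaction from cell means (group x level)
    ss_cells = 0.0
    for g in group_names:
        mask = groups == g
        cell_means = y[mask].mean(axis=0)
        gm = y[mask].mean()
        ss_cells += mask.sum() * ((cell_means - gm - level_means + grand) ** 2).sum()
    ss_inter = float(ss_cells)
    ss_resid = ss_within - ss_level - ss_inter
    tol = 1e-12 * max(ss_total, 1.0)    # exact zeros survive round-off
    ss_group, ss_subj_within, ss_level, ss_inter, ss_resid = (
        0.0 if s < tol else s
        for s in (ss_group, ss_subj_within, ss_level, ss_inter, ss_resid))
    df_level = b - 1
    df_inter = df_group * df_level
    df_resid = df_subj_within * df_level

    degenerate = ss_total <= 1e-300
    out = ANOVATable(method="split-plot (two-way mixed) ANOVA",
                     degenerate=degenerate)
    fg, pg = _f_p(ss_group, df_group, ss_subj_within, df_subj_within, degenerate)
    fl, pl = _f_p(ss_level, df_level, ss_resid, df_resid, degenerate)
    fi, pi = _f_p(ss_inter, df_inter, ss_resid, df_resid, degenerate)
    out.add(group, ss_group, df_group, fg, pg)
    out.add("subjects-within-groups", ss_subj_within, df_subj_within)
    out.add(level, ss_level, df_level, fl, pl)
    out.add(f"{group}:{level}", ss_inter, df_inter, fi, pi)
    out.add("residual", max(ss_resid, 0.0), df_resid)
    return out


def bonferroni_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni adjustment: each p times the family size, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)
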