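"""Cell-type-specific differential-expression screen on TPM matrices.

The screen follows the study's published criteria: per-gene unpaired t-test
between condition groups, fold change as the ratio of group means, and a
three-part gate (fold change >= 2 or <= 0.5, p < 0.01, mean abundance
TPM >= 30).  Marker panels check cell-type purity (expected-population
transcripts enriched, neighboring-population transcripts depleted), and a
declared gene panel (e.g. the AMP-related kinase family) can be compared with
Bonferroni correction over the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .stats_core import TestResult, bonferroni_adjust, unpaired_t_test

__all__ = [
    "DECriteria",
    "MarkerPanel",
    "compute_tpm",
    "differential_test",
    "apply_criteria",
    "marker_purity",
    "panel_compare",
]


@dataclass(frozen=True)
class DECriteria:
    """Screen gates.  ``tpm_min`` is inclusive (>= 30); the fold-change gates
    are inclusive too, so a gene at exactly 0.50 passes the down gate."""

    fc_up: float = 2.0
    fc_down: float = 0.5
    p_max: float = 0.01
    tpm_min: float = 30.0

    def __post_init__(self) -> None:
        if min(self.fc_up, self.fc_down, self.p_max, self.tpm_min) <= 0:
            raise ValueError("criteria gates must be positive")


@dataclass
class MarkerPanel:
    """Named gene set with an enrichment expectation and a TPM cutoff."""

    label: str
    genes: "tuple[str, ...]"
    expectation: str             # "enriched" | "depleted"
    tpm_cutoff: float = 10.0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("marker panel must be non-empty")
        if self.expectation not in ("enriched", "depleted"):
            raise ValueError("expectation must be 'enriched' or 'depleted'")


def compute_tpm(counts: pd.DataFrame, lengths_bp) -> pd.DataFrame:
    """Transcripts-per-million from read counts and gene lengths.

    Per sample: rate_g = count_g / length_kb_g, TPM_g = rate_g / sum(rates)
    * 1e6; every column sums to 1e6.
    """
    lengths = np.asarray(lengths_bp, dtype=float)
    if lengths.shape[0] != counts.shape[0]:
        raise ValueError("lengths must match the number of genes")
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be >= 0")
    rate = counts.div(lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"sample(s) with zero total rate: {bad}")
    return rate.div(totals, axis=1) * 1e6


def _group_columns(matrix: pd.DataFrame, groups: pd.Series,
                   group_a: str, group_b: str) -> "tuple[list, list]":
    ga = [c for c in matrix.columns if groups.get(c) == group_a]
    gb = [c for c in matrix.columns if groups.get(c) == group_b]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("need >= 2 samples per group")
    return ga, gb


def _vectorized_pooled_t(a: np.ndarray, b: np.ndarray
                         ) -> "tuple[np.ndarray, np.ndarray]":
    """Row-wise pooled-variance t statistic and two-sided p."""
    n1, n2 = a.shape[1], b.shape[1]
    df = n1 + n2 - 2
    d = a.mean(axis=1) - b.mean(axis=1)
    sp2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d / se
    p = 2.0 * _st.t.sf(np.abs(t), df)
    # zero variance in both groups: equal means -> t 0, p 1
    degen = se == 0
    t[degen & (d == 0)] = 0.0
    p[degen & (d == 0)] = 1.0
    p[degen & (d != 0)] = 0.0
    return t, p


def differential_test(matrix: pd.DataFrame, groups: pd.Series,
                      group_a: str = "CTA", group_b: str = "control",
                      log: bool = False) -> pd.DataFrame:
    """Per-gene screen table: fold change, p, mean TPM, direction.

    ``fold_change`` is mean(group_a) / mean(group_b) on linear TPM (infinite
    with an exclusion flag when the control mean is zero); the t-test runs on
    linear TPM by default or on log2(TPM + 1) with ``log=True``.  ``mean_tpm``
    is the grand mean across all samples of both groups.
    """
    ga, gb = _group_columns(matrix, groups, group_a, group_b)
    a_lin = matrix[ga].to_numpy(dtype=float)
    b_lin = matrix[gb].to_numpy(dtype=float)
    if log:
        t, p = _vectorized_pooled_t(np.log2(a_lin + 1.0), np.log2(b_lin + 1.0))
        method = "pooled-t on log2(TPM+1)"
    else:
        t, p = _vectorized_pooled_t(a_lin, b_lin)
        method = "pooled-t on TPM"
    mean_a, mean_b = a_lin.mean(axis=1), b_lin.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_b > 0, mean_a / mean_b, np.inf)
    out = pd.DataFrame({
        "fold_change": fc,
        "p": p,
        "t": t,
        "mean_tpm": np.hstack([a_lin, b_lin]).mean(axis=1),
        "direction": np.where(fc >= 1.0, "up", "down"),
        "zero_control": mean_b == 0,
    }, index=matrix.index)
    out.attrs["method"] = method
    out.attrs["groups"] = (group_a, group_b)
    return out


def apply_criteria(de_table: pd.DataFrame,
                   criteria: Optional[DECriteria] = None,
                   tpm_mode: str = "grand_mean", matrix: pd.DataFrame = None,
                   groups: pd.Series = None,
                   ) -> "tuple[pd.DataFrame, pd.DataFrame]":
    """Split the screen into (up, down) tables passing all three gates.

    ``tpm_mode='grand_mean'`` gates on the grand-mean TPM (default);
    ``'either_group'`` requires at least one group's mean to clear the gate
    (needs ``matrix`` and ``groups``).  Lists are sorted by ascending p.
    """
    criteria = criteria or DECriteria()
    zero_ok = ~de_table["zero_control"].astype(bool)
    if tpm_mode == "grand_mean":
        abundant = de_table["mean_tpm"] >= criteria.tpm_min
    elif tpm_mode == "either_group":
        if matrix is None or groups is None:
            raise ValueError("either_group mode needs matrix and groups")
        ga, gb = _group_columns(matrix, groups, *de_table.attrs["groups"])
        abundant = ((matrix[ga].mean(axis=1) >= criteria.tpm_min) |
                    (matrix[gb].mean(axis=1) >= criteria.tpm_min))
    else:
        raise ValueError(f"unknown tpm_mode {tpm_mode}")
    sig = (de_table["p"] < criteria.p_max) & abundant & zero_ok
    up = de_table[sig & (de_table["fold_change"] >= criteria.fc_up)]
    down = de_table[sig & (de_table["fold_change"] <= criteria.fc_down)]
    return up.sort_values("p"), down.sort_values("p")


def marker_purity(matrix: pd.DataFrame, panels: Sequence[MarkerPanel]
                  ) -> pd.DataFrame:
    """Mean abundance per marker panel and enrichment/depletion verdicts.

    Panels with no genes present in the matrix are skipped with a warning row
    (verdict 'skipped'); missing genes are reported per panel.
    """
    rows = []
    for panel in panels:
        present = [g for g in panel.genes if g in matrix.index]
        missing = [g for g in panel.genes if g not in matrix.index]
        if not present:
            rows.append((panel.label, panel.expectation, 0, len(missing),
                         np.nan, np.nan, "skipped"))
            continue
        sub = matrix.loc[present]
        mean_tpm = float(sub.to_numpy().mean())
        frac_above = float((sub.mean(axis=0) > panel.tpm_cutoff).mean())
        if panel.expectation == "enriched":
            verdict = "pass" if mean_tpm >= panel.tpm_cutoff else "fail"
        else:
            verdict = "pass" if mean_tpm < panel.tpm_cutoff else "fail"
        rows.append((panel.label, panel.expectation, len(present), len(missing),
                     mean_tpm, frac_above, verdict))
    return pd.DataFrame(rows, columns=["panel", "expectation", "n_present",
                                       "n_missing", "mean_tpm",
                                       "frac_samples_above_cutoff", "verdict"])


def panel_compare(matrix: pd.DataFrame, panel_genes: Sequence[str],
                  groups: pd.Series, group_a: str = "CTA",
                  group_b: str = "control", alpha: float = 0.05
                  ) -> pd.DataFrame:
    """Per-gene t-tests over a declared panel, Bonferroni family = panel size."""
    panel_genes = list(panel_genes)
    if not panel_genes:
        raise ValueError("empty panel")
    missing = [g for g in panel_genes if g not in matrix.index]
    if missing:
        raise KeyError(f"panel genes absent from matrix: {missing}")
    ga, gb = _group_columns(matrix, groups, group_a, group_b)
    rows = []
    for g in panel_genes:
        res: TestResult = unpaired_t_test(matrix.loc[g, ga], matrix.loc[g, gb])
        mean_b = float(matrix.loc[g, gb].mean())
        fc = float(matrix.loc[g, ga].mean()) / mean_b if mean_b > 0 else np.inf
        rows.append((g, fc, res.statistic, res.df, res.p))
    out = pd.DataFrame(rows, columns=["gene", "fold_change", "t", "df", "p_raw"]
                       ).set_index("gene")
    out["p_adj"] = bonferroni_adjust(out["p_raw"])
    out["significant"] = out["p_adj"] < alpha
    return out
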