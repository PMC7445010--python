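"""Conditioned-taste-aversion memory-strength metrics and group statistics.

Input is an animal-level consumption table: fluid volume (ml) drunk by each
animal during the CTA training session, the test session, and optionally a
water session 8 h after the test.  Memory strength is the per-animal
test/training consumption ratio (lower ratio = stronger aversion).  The group
analysis runs the split-plot ANOVA (treatment between animals, session within
animals), Bonferroni-corrected post-hoc comparisons of the four
treatment x session cells, an unpaired t-test on the ratios and another on
the water-control volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .stats_core import (ANOVATable, TestResult, bonferroni_adjust,
                         mixed_anova_2x2plus, paired_t_test, unpaired_t_test)

__all__ = [
    "ConsumptionValidationError",
    "validate_consumption",
    "read_consumption",
    "memory_ratio",
    "cta_effect_analysis",
    "CTAReport",
]

SESSIONS = ("training", "test")
WATER_SESSION = "water8h"

#: group labels conventionally treated as the control / reference arm
CONTROL_ALIASES = ("control", "vehicle", "gfp", "wt")

DEFAULT_DIALECT = {
    "format": "long",            # "long" or "wide"
    "animal": "animal",
    "group": "group",
    "session": "session",
    "volume": "volume_ml",
    # wide-format column names
    "training": "training",
    "test": "test",
    "water8h": None,
    "sheet": 0,
    "session_map": {},           # raw session label -> canonical
}


class ConsumptionValidationError(ValueError):
    """Consumption table violates the expected schema."""


def validate_consumption(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema, units and completeness; returns the validated table."""
    required = {"animal", "group", "session", "volume_ml"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ConsumptionValidationError(f"missing columns: {sorted(missing_cols)}")
    t = table.copy()
    t["volume_ml"] = pd.to_numeric(t["volume_ml"])
    if (t["volume_ml"] < 0).any():
        raise ConsumptionValidationError("volumes must be >= 0 ml")
    dup = t.duplicated(["animal", "session"])
    if dup.any():
        raise ConsumptionValidationError(
            f"duplicate animal/session rows: "
            f"{t.loc[dup, ['animal', 'session']].to_records(index=False).tolist()}")
    for sess in SESSIONS:
        have = set(t.loc[t["session"] == sess, "animal"])
        everyone = set(t["animal"])
        lacking = sorted(everyone - have)
        if lacking:
            raise ConsumptionValidationError(
                f"animals missing a '{sess}' row: {lacking}")
    return t


def read_consumption(path, dialect: Optional[dict] = None) -> pd.DataFrame:
    """Read a consumption table from CSV/TSV or a spreadsheet workbook.

    ``dialect`` maps the file's layout onto the canonical schema (long rows of
    animal/group/session/volume, or wide per-animal rows with one column per
    session); source-data layouts vary, so the mapping is configuration, not
    code.
    """
    d = {**DEFAULT_DIALECT, **(dialect or {})}
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path, sheet_name=d["sheet"])
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        raw = pd.read_csv(path, sep=sep)
    if d["format"] == "long":
        t = raw.rename(columns={d["animal"]: "animal", d["group"]: "group",
                                d["session"]: "session", d["volume"]: "volume_ml"})
        if d["session_map"]:
            t["session"] = t["session"].map(lambda s: d["session_map"].get(s, s))
    elif d["format"] == "wide":
        rows = []
        for _, r in raw.iterrows():
            rows.append((r[d["animal"]], r[d["group"]], "training",
                         r[d["training"]]))
            rows.append((r[d["animal"]], r[d["group"]], "test", r[d["test"]]))
            if d["water8h"] and d["water8h"] in raw.columns:
                rows.append((r[d["animal"]], r[d["group"]], WATER_SESSION,
                             r[d["water8h"]]))
        t = pd.DataFrame(rows, columns=["animal", "group", "session",
                                        "volume_ml"])
    else:
        raise ValueError(f"unknown dialect format {d['format']}")
    return validate_consumption(t[["animal", "group", "session", "volume_ml"]])


def _control_first(groups: "list[str]", control_group: Optional[str]) -> "list[str]":
    if control_group is not None:
        if control_group not in groups:
            raise ValueError(f"control group {control_group!r} not in table")
        return [control_group] + [g for g in groups if g != control_group]
    for g in groups:
        if str(g).lower() in CONTROL_ALIASES:
            return [g] + [x for x in groups if x != g]
    return groups


def memory_ratio(table: pd.DataFrame, control_group: Optional[str] = None
                 ) -> "tuple[pd.DataFrame, pd.DataFrame]":
    """Per-animal test/training ratios and a per-group summary.

    Animals with zero training volume are flagged and excluded from the
    ratios.  A lower ratio means a stronger aversive memory.
    """
    t = validate_consumption(table)
    wide = t[t["session"].isin(SESSIONS)].pivot_table(
        index=["group", "animal"], columns="session", values="volume_ml")
    ratios = []
    for (group, animal), row in wide.iterrows():
        if row["training"] <= 0:
            ratios.append((group, animal, np.nan, True))
        else:
            ratios.append((group, animal, row["test"] / row["training"], False))
    per_animal = pd.DataFrame(ratios, columns=["group", "animal", "ratio",
                                               "excluded_zero_training"])
    ok = per_animal[~per_animal["excluded_zero_training"]]
    order = _control_first(sorted(t["group"].unique()), control_group)
    summary = (ok.groupby("group")["ratio"]
               .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)),
                    n="count")
               .reindex(order).reset_index())
    return per_animal, summary


@dataclass
class CTAReport:
    """Bundle of the behavioral statistics for one experiment."""

    anova: ANOVATable
    posthoc: pd.DataFrame
    ratio_summary: pd.DataFrame
    ratio_test: TestResult
    water_test: Optional[TestResult] = None
    group_order: "list[str]" = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "anova": self.anova.to_dict(),
            "posthoc": self.posthoc.to_dict(orient="records"),
            "ratio_summary": self.ratio_summary.to_dict(orient="records"),
            "ratio_test": self.ratio_test.to_dict(),
            "group_order": self.group_order,
        }
        if self.water_test is not None:
            d["water_test"] = self.water_test.to_dict()
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         default=float) + "\n")


def _posthoc_cells(wide: pd.DataFrame, order: "list[str]",
                   include_diagonal: bool) -> pd.DataFrame:
    """Pairwise comparisons of the treatment x session cells.

    Within-group training-vs-test comparisons are paired (same animals);
    between-group comparisons at a session are unpaired.  The Bonferroni
    family is the number of comparisons computed.
    """
    rows = []
    for g in order:
        sub = wide.xs(g, level="group")
        res = paired_t_test(sub["training"], sub["test"])
        rows.append((f"{g}: training vs test", "paired", res.statistic,
                     res.df, res.p))
    for sess in SESSIONS:
        a = wide.xs(order[0], level="group")[sess]
        b = wide.xs(order[1], level="group")[sess]
        res = unpaired_t_test(a, b)
        rows.append((f"{sess}: {order[0]} vs {order[1]}", "unpaired",
                     res.statistic, res.df, res.p))
    if include_diagonal:
        for ga, sa, gb, sb in ((order[0], "training", order[1], "test"),
                               (order[0], "test", order[1], "training")):
            a = wide.xs(ga, level="group")[sa]
            b = wide.xs(gb, level="group")[sb]
            res = unpaired_t_test(a, b)
            rows.append((f"{ga} {sa} vs {gb} {sb}", "unpaired",
                         res.statistic, res.df, res.p))
    out = pd.DataFrame(rows, columns=["comparison", "kind", "t", "df", "p_raw"])
    out["p_adj"] = bonferroni_adjust(out["p_raw"])
    return out


def cta_effect_analysis(table: pd.DataFrame, control_group: Optional[str] = None,
                        include_diagonal: bool = False) -> CTAReport:
    """Full behavioral statistics pipeline for a 2-group, 2-session design.

    Runs the split-plot ANOVA on the training/test volumes (treatment between,
    session within), Bonferroni post-hoc cell comparisons, the unpaired t-test
    on the per-animal test/training ratios (control group first, so the sign
    convention of the reported statistics is reproducible), and, if an 8-h
    water session is present, the same unpaired t-test on water volumes.
    """
    t = validate_consumption(table)
    groups = sorted(t["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    order = _control_first(groups, control_group)

    long = t[t["session"].isin(SESSIONS)].rename(
        columns={"animal": "subject", "session": "level", "volume_ml": "value"})
    anova = mixed_anova_2x2plus(long, subject="subject", group="group",
                                level="level", value="value")
    wide = t[t["session"].isin(SESSIONS)].pivot_table(
        index=["group", "animal"], columns="session", values="volume_ml")
    posthoc = _posthoc_cells(wide, order, include_diagonal)

    per_animal, summary = memory_ratio(t, control_group=order[0])
    ok = per_animal[~per_animal["excluded_zero_training"]]
    r0 = ok.loc[ok["group"] == order[0], "ratio"]
    r1 = ok.loc[ok["group"] == order[1], "ratio"]
    ratio_test = unpaired_t_test(r0, r1)

    water_test = None
    water = t[t["session"] == WATER_SESSION]
    if not water.empty:
        w0 = water.loc[water["group"] == order[0], "volume_ml"]
        w1 = water.loc[water["group"] == order[1], "volume_ml"]
        if len(w0) >= 2 and len(w1) >= 2:
            water_test = unpaired_t_test(w0, w1)

    return CTAReport(anova=anova, posthoc=posthoc, ratio_summary=summary,
                     ratio_test=ratio_test, water_test=water_test,
                     group_order=list(order))
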