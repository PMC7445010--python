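"""Moving-window palatability coding of gustatory-cortex spike trains.

For every single unit, firing rates are computed in 250 ms windows stepped by
25 ms across the response, and each window's rates (one value per trial, all
tastes pooled) are Spearman-correlated with the trials' palatability ranks.
Population time courses average the correlation magnitude |rho| across units;
two populations (e.g. genotypes) are compared by a two-way ANOVA on the
unit-level correlations across genotype and time window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .stats_core import ANOVATable, bonferroni_adjust, two_way_anova_fixed, _f_p
from .synthetic import SpikeTrainSet, SpikeTrial  # containers shared with the generator

__all__ = [
    "PalatabilityMap",
    "CorrelationTimecourse",
    "WINDOW_MS",
    "STEP_MS",
    "window_starts",
    "window_rates",
    "palatability_timecourse",
    "population_timecourse",
    "compare_genotypes",
    "taste_responsiveness",
]

WINDOW_MS = 250.0
STEP_MS = 25.0


@dataclass(frozen=True)
class PalatabilityMap:
    """Taste label -> hedonic rank (1..4, higher = more palatable)."""

    ranks: "dict[str, int]"

    def __post_init__(self) -> None:
        if sorted(self.ranks.values()) != list(range(1, len(self.ranks) + 1)):
            raise ValueError("ranks must be a permutation of 1..n_tastes")

    def __getitem__(self, taste: str) -> int:
        return self.ranks[taste]

    def __contains__(self, taste: str) -> bool:
        return taste in self.ranks


def window_starts(duration_ms: float, window_ms: float = WINDOW_MS,
                  step_ms: float = STEP_MS) -> np.ndarray:
    """Window start times tiling [0, T - window] in steps of ``step_ms``."""
    if window_ms <= 0 or step_ms <= 0:
        raise ValueError("window and step must be positive")
    if window_ms > duration_ms + 1e-9:
        raise ValueError("window longer than the trial")
    n = int(np.floor((duration_ms - window_ms) / step_ms + 1e-9)) + 1
    return np.arange(n) * step_ms


def window_rates(trials: Sequence[SpikeTrial], window_ms: float = WINDOW_MS,
                 step_ms: float = STEP_MS) -> "tuple[np.ndarray, np.ndarray]":
    """Per-trial firing-rate matrix.

    Returns (rates, starts): ``rates[i, j]`` is the rate (Hz) of trial ``i``
    in the half-open window [starts[j], starts[j] + window) ms post-stimulus.
    """
    duration_ms = trials[0].duration_s * 1000.0
    starts = window_starts(duration_ms, window_ms, step_ms)
    rates = np.empty((len(trials), starts.size))
    for i, tr in enumerate(trials):
        t_ms = tr.spikes_s * 1000.0
        lo = np.searchsorted(t_ms, starts, side="left")
        hi = np.searchsorted(t_ms, starts + window_ms, side="left")
        rates[i] = (hi - lo) / (window_ms / 1000.0)
    return rates, starts


def palatability_timecourse(trials: Sequence[SpikeTrial], ranks: PalatabilityMap,
                            window_ms: float = WINDOW_MS,
                            step_ms: float = STEP_MS,
                            ) -> "tuple[np.ndarray, np.ndarray, np.ndarray]":
    """Per-window Spearman rho between trial rates and palatability ranks.

    All trials are pooled per window (each contributes its rate and its
    taste's rank).  Windows where the rates are constant across trials yield
    rho 0 with the degeneracy flag set.  Returns (rho, degenerate, starts).
    """
    for tr in trials:
        if tr.taste not in ranks:
            raise KeyError(f"taste {tr.taste!r} has no palatability rank")
    if len({tr.taste for tr in trials}) < 2:
        raise ValueError("need >= 2 tastes for a palatability correlation")
    rates, starts = window_rates(trials, window_ms, step_ms)
    rank_vec = np.array([ranks[tr.taste] for tr in trials], dtype=float)
    rho = np.zeros(starts.size)
    degenerate = np.zeros(starts.size, dtype=bool)
    for j in range(starts.size):
        col = rates[:, j]
        if np.ptp(col) == 0:
            degenerate[j] = True
            continue
        rho[j] = _st.spearmanr(col, rank_vec).statistic
    return rho, degenerate, starts


@dataclass
class CorrelationTimecourse:
    """Population moving-window correlation summary."""

    window_start_ms: np.ndarray
    window_ms: float
    unit_rho: np.ndarray              # units x windows, signed
    mean_abs_rho: np.ndarray = field(init=False)
    sem_abs_rho: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        ar = np.abs(self.unit_rho)
        self.mean_abs_rho = ar.mean(axis=0)
        n = ar.shape[0]
        self.sem_abs_rho = (ar.std(axis=0, ddof=1) / np.sqrt(n) if n > 1
                            else np.zeros(ar.shape[1]))

    @property
    def window_center_ms(self) -> np.ndarray:
        return self.window_start_ms + self.window_ms / 2.0

    @property
    def n_units(self) -> int:
        return self.unit_rho.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_center_ms": self.window_center_ms,
            "mean_abs_rho": self.mean_abs_rho,
            "sem": self.sem_abs_rho,
            "n_units": self.n_units,
        })


def population_timecourse(spikes: SpikeTrainSet, ranks: PalatabilityMap,
                          window_ms: float = WINDOW_MS, step_ms: float = STEP_MS,
                          ) -> CorrelationTimecourse:
    """Unit-by-unit time courses aggregated as mean +- SEM of |rho|."""
    rhos = []
    starts = None
    for uid in sorted(spikes.units):
        rho, _, starts = palatability_timecourse(spikes.units[uid], ranks,
                                                 window_ms, step_ms)
        rhos.append(rho)
    if not rhos:
        raise ValueError("no units")
    return CorrelationTimecourse(window_start_ms=starts, window_ms=window_ms,
                                 unit_rho=np.vstack(rhos))


def compare_genotypes(tc_a: CorrelationTimecourse, tc_b: CorrelationTimecourse,
                      labels: "tuple[str, str]" = ("A", "B"),
                      layout: str = "unit_window") -> ANOVATable:
    """Two-way ANOVA of |rho| across genotype and time window.

    ``unit_window``: every unit x window |rho| is an observation in a
    genotype x window fixed two-way ANOVA.  ``unit_mean``: each unit's mean
    |rho| across windows is one observation in a one-way genotype ANOVA
    (error df = total units - 2, the layout matching unit-level df reporting).
    """
    if tc_a.n_units == 0 or tc_b.n_units == 0:
        raise ValueError("both groups need at least one unit")
    if layout == "unit_window":
        rows = []
        for label, tc in ((labels[0], tc_a), (labels[1], tc_b)):
            ar = np.abs(tc.unit_rho)
            for u in range(ar.shape[0]):
                for j, w in enumerate(tc.window_start_ms):
                    rows.append((label, float(w), ar[u, j]))
        df = pd.DataFrame(rows, columns=["genotype", "window", "value"])
        return two_way_anova_fixed(df, "genotype", "window")
    if layout == "unit_mean":
        a = np.abs(tc_a.unit_rho).mean(axis=1)
        b = np.abs(tc_b.unit_rho).mean(axis=1)
        grand = np.concatenate([a, b]).mean()
        ss_between = a.size * (a.mean() - grand) ** 2 + \
            b.size * (b.mean() - grand) ** 2
        ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        df_b, df_w = 1, a.size + b.size - 2
        degenerate = ss_between + ss_within == 0
        table = ANOVATable(method="one-way genotype ANOVA on unit mean |rho|",
                           degenerate=degenerate)
        f, p = _f_p(ss_between, df_b, ss_within, df_w, degenerate)
        table.add("genotype", ss_between, df_b, f, p)
        table.add("residual", ss_within, df_w)
        return table
    raise ValueError(f"unknown layout {layout}")


def taste_responsiveness(trials: Sequence[SpikeTrial],
                         evoked_window_s: "tuple[float, float]" = (0.0, 2.0),
                         alpha: float = 0.05) -> "dict[str, dict]":
    """Per-taste responsiveness: evoked vs baseline rate across trials.

    Wilcoxon signed-rank on per-trial (evoked - baseline) rates, Bonferroni
    corrected over the tastes tested.  Trials need a pre-stimulus baseline.
    """
    tastes = sorted({tr.taste for tr in trials})
    raw: dict[str, float] = {}
    for taste in tastes:
        diffs = []
        for tr in trials:
            if tr.taste != taste:
                continue
            if tr.pre_s <= 0:
                raise ValueError("trials carry no pre-stimulus baseline")
            t = tr.spikes_s
            base = np.sum((t >= -tr.pre_s) & (t < 0)) / tr.pre_s
            lo, hi = evoked_window_s
            hi = min(hi, tr.duration_s)
            ev = np.sum((t >= lo) & (t < hi)) / (hi - lo)
            diffs.append(ev - base)
        d = np.asarray(diffs)
        if np.all(d == 0):
            raw[taste] = 1.0
        else:
            raw[taste] = float(_st.wilcoxon(d, zero_method="wilcox").pvalue)
    adj = bonferroni_adjust([raw[t] for t in tastes])
    return {t: {"p_raw": raw[t], "p_adj": float(adj[i]),
                "responsive": bool(adj[i] < alpha)}
            for i, t in enumerate(tastes)}
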