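"""Seeded generators for every input the pipeline consumes, with ground truth.

Each generator returns its data object together with a JSON-serializable
ground-truth sidecar that records the parameters the analysis is later asked
to recover.  Analysis modules never read the sidecars.  Identical parameters
plus seed give bit-identical output.

The neuron generator is a leaky integrate-and-fire model with an optional
first-order hyperpolarization-activated (sag) conductance and a slow
spike-triggered adaptation current.  Action potentials are rendered by
stamping a stereotyped triangular waveform into the trace the moment the
membrane reaches threshold: the subthreshold approach always has dV/dt below
10 V/s while the stamp rises well above it starting exactly at the threshold
voltage, so AP threshold, amplitude, half-width and the post-spike trough all
have closed-form true values.  Stamp rise/fall durations are snapped to the
sample grid so that the sampled waveform attains the nominal peak exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .ephys import Sweep, SweepSet

__all__ = [
    "NeuronSimParams",
    "StepProtocol",
    "TasteSimParams",
    "ExprSimParams",
    "GroupConsumption",
    "ConsumptionSimParams",
    "simulate_neuron_sweeps",
    "simulate_population",
    "sag_ratio_oracle",
    "simulate_taste_units",
    "expected_null_abs_rho",
    "simulate_expression",
    "simulate_consumption",
]

MAX_DT_MS = 0.1   # coarser sampling cannot resolve the 10 V/s crossing


class ResolutionError(ValueError):
    """dt too coarse for faithful threshold-crossing rendering."""


# ---------------------------------------------------------------------------
# electrophysiology

@dataclass
class StepProtocol:
    """Square-step protocol: a 25 pA seal test in the baseline, then the step.

    Default amplitudes are 0..450 pA in 50 pA increments plus the -100 pA sag
    step.  Step duration defaults to 1000 ms; firing rate is spikes per step
    duration.
    """

    dt_ms: float = 0.1
    baseline_ms: float = 400.0
    step_duration_ms: float = 1000.0
    tail_ms: float = 150.0
    seal_onset_ms: float = 25.0
    seal_duration_ms: float = 150.0
    seal_pa: float = 25.0
    amplitudes_pa: "tuple[float, ...]" = (
        -100.0, 0.0, 50.0, 100.0, 150.0, 200.0, 250.0,
        300.0, 350.0, 400.0, 450.0)

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if not all(np.isfinite(self.amplitudes_pa)):
            raise ValueError("step amplitudes must be finite")
        if self.seal_onset_ms + self.seal_duration_ms > self.baseline_ms:
            raise ValueError("seal test must end before the step onset")

    @property
    def total_ms(self) -> float:
        return self.baseline_ms + self.step_duration_ms + self.tail_ms

    @property
    def n_samples(self) -> int:
        return int(round(self.total_ms / self.dt_ms))


@dataclass
class NeuronSimParams:
    """Ground-truth parameters of one simulated neuron.

    Voltages in mV, resistances in MOhm, times in ms, slopes in V/s.
    ``sag_g_ratio`` is the maximal sag conductance relative to the leak
    conductance; 0 disables the sag entirely, in which case the noiseless
    subthreshold steady-state deflection is exactly R_m * I.
    """

    e_leak_mv: float = -70.0
    r_m_mohm: float = 100.0
    tau_m_ms: float = 20.0
    v_threshold_mv: float = -45.0
    spike_peak_mv: float = 30.0
    spike_rise_v_per_s: float = 200.0
    spike_fall_v_per_s: float = 100.0
    trough_depth_mv: float = 8.0          # post-spike trough below threshold
    sahp_increment_mv: float = 0.8        # per-spike slow-AHP increment
    sahp_tau_ms: float = 500.0
    sag_g_ratio: float = 0.0
    sag_v_half_mv: float = -82.0
    sag_k_mv: float = 6.0
    sag_tau_ms: float = 50.0
    sag_e_rev_mv: float = -30.0
    noise_sd_mv: float = 0.0
    series_resistance_mohm: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_m_mohm <= 0 or self.tau_m_ms <= 0:
            raise ValueError("R_m and tau_m must be positive")
        if self.spike_peak_mv <= self.v_threshold_mv:
            raise ValueError("spike peak must exceed threshold")
        if self.trough_depth_mv < 0 or self.sahp_increment_mv < 0:
            raise ValueError("trough depth and sAHP increment must be >= 0")

    @property
    def rheobase_pa(self) -> float:
        """Analytic LIF rheobase (sag-free): (V_T - E_L) / R_m."""
        return (self.v_threshold_mv - self.e_leak_mv) / self.r_m_mohm * 1000.0

    def stamp_shape(self, dt_ms: float) -> "tuple[int, int, float, float]":
        """Grid-aligned stamp: (rise samples, fall samples, eff. slopes V/s)."""
        amp_up = self.spike_peak_mv - self.v_threshold_mv
        amp_down = self.spike_peak_mv - (self.v_threshold_mv - self.trough_depth_mv)
        n_rise = max(int(round(amp_up / self.spike_rise_v_per_s / dt_ms)), 1)
        n_fall = max(int(round(amp_down / self.spike_fall_v_per_s / dt_ms)), 1)
        return (n_rise, n_fall,
                amp_up / (n_rise * dt_ms), amp_down / (n_fall * dt_ms))

    def true_ap_metrics(self, dt_ms: float) -> dict:
        """Closed-form AP truth for the grid-aligned stamp."""
        n_rise, n_fall, rise, fall = self.stamp_shape(dt_ms)
        amp = self.spike_peak_mv - self.v_threshold_mv
        half_width_ms = amp / 2.0 / rise + amp / 2.0 / fall
        return {
            "threshold_mv": self.v_threshold_mv,
            "peak_mv": self.spike_peak_mv,
            "amplitude_mv": amp,
            "half_width_ms": half_width_ms,
            "mahp_mv": self.trough_depth_mv,
        }


def _simulate_traces(params: NeuronSimParams, protocol: StepProtocol,
                     amplitudes: np.ndarray, rng: np.random.Generator,
                     per_trace: Optional[dict] = None,
                     ) -> "tuple[np.ndarray, list[list[float]]]":
    """Vectorized Euler integration of a batch of sweeps.

    ``per_trace`` may override scalar parameters with per-trace arrays (used
    by the population generator).  Returns the voltage matrix (traces x
    samples) and per-trace spike onset times in ms.
    """
    if protocol.dt_ms > MAX_DT_MS + 1e-12:
        raise ResolutionError(
            f"dt={protocol.dt_ms} ms too coarse; need <= {MAX_DT_MS} ms")
    dt = protocol.dt_ms
    n_tr = amplitudes.size
    n_s = protocol.n_samples

    def par(name):
        if per_trace and name in per_trace:
            return np.asarray(per_trace[name], dtype=float)
        return np.full(n_tr, getattr(params, name), dtype=float)

    e_l, r_m, tau_m = par("e_leak_mv"), par("r_m_mohm"), par("tau_m_ms")
    v_t = par("v_threshold_mv")
    peak = par("spike_peak_mv")
    trough = v_t - par("trough_depth_mv")
    sahp_inc_pa = par("sahp_increment_mv") / r_m * 1000.0
    sahp_tau = par("sahp_tau_ms")
    g_sag, v_half, k_sag = par("sag_g_ratio"), par("sag_v_half_mv"), par("sag_k_mv")
    sag_tau, e_sag = par("sag_tau_ms"), par("sag_e_rev_mv")
    noise = par("noise_sd_mv")

    # grid-aligned stamp geometry per trace
    amp_up = peak - v_t
    amp_down = peak - trough
    n_rise = np.maximum(np.round(amp_up / par("spike_rise_v_per_s") / dt), 1
                        ).astype(int)
    n_fall = np.maximum(np.round(amp_down / par("spike_fall_v_per_s") / dt), 1
                        ).astype(int)
    stamp_len = n_rise + n_fall
    rise_per_samp = amp_up / n_rise
    fall_per_samp = amp_down / n_fall

    t_axis = np.arange(n_s) * dt
    in_seal = (t_axis >= protocol.seal_onset_ms) & \
              (t_axis < protocol.seal_onset_ms + protocol.seal_duration_ms)
    step_on = protocol.baseline_ms
    step_off = protocol.baseline_ms + protocol.step_duration_ms
    in_step = (t_axis >= step_on) & (t_axis < step_off)

    def h_inf(v):
        return 1.0 / (1.0 + np.exp((v - v_half) / k_sag))

    v = e_l.copy()
    h = h_inf(v)
    a_pa = np.zeros(n_tr)                  # adaptation current, pA
    phase = np.full(n_tr, -1, dtype=int)   # -1 = not in stamp
    V = np.empty((n_tr, n_s))
    V[:, 0] = v
    spikes: list[list[float]] = [[] for _ in range(n_tr)]
    noisy = bool(np.any(noise > 0))
    noise_scale = noise * np.sqrt(2.0 * dt / tau_m)

    for i in range(1, n_s):
        i_inj = amplitudes * in_step[i] + protocol.seal_pa * in_seal[i]
        active = phase < 0
        if active.any():
            drive = (e_l - v + r_m * (i_inj - a_pa) / 1000.0
                     + g_sag * h * (e_sag - v))
            v_new = v + dt / tau_m * drive
            if noisy:
                v_new = v_new + noise_scale * rng.standard_normal(n_tr)
            h = h + dt / sag_tau * (h_inf(v) - h)
            a_pa = a_pa * (1.0 - dt / sahp_tau)
            crossed = active & (v_new >= v_t)
            v = np.where(active, v_new, v)
            if crossed.any():
                v[crossed] = v_t[crossed]
                phase[crossed] = 0
                t_i = i * dt
                for j in np.flatnonzero(crossed):
                    spikes[j].append(t_i)
        stamped = phase >= 0
        if stamped.any():
            ph = phase + 1  # advance within stamp
            rising = stamped & (ph <= n_rise)
            falling = stamped & (ph > n_rise) & (ph < stamp_len)
            ending = stamped & (ph >= stamp_len)
            v = np.where(rising, v_t + rise_per_samp * ph, v)
            v = np.where(falling, peak - fall_per_samp * (ph - n_rise), v)
            if ending.any():
                v = np.where(ending, trough, v)
                a_pa = np.where(ending, a_pa + sahp_inc_pa, a_pa)
                h = np.where(ending, h_inf(v), h)
            phase = np.where(stamped, np.where(ending, -1, ph), phase)
        V[:, i] = v
    return V, spikes


def _sweepset_from_traces(cell_id: str, genotype: str, params: NeuronSimParams,
                          protocol: StepProtocol, V: np.ndarray,
                          amplitudes: np.ndarray) -> SweepSet:
    step_on = protocol.baseline_ms
    step_off = protocol.baseline_ms + protocol.step_duration_ms
    sweeps = [
        Sweep(dt_ms=protocol.dt_ms, voltage_mv=V[k], step_pa=float(amplitudes[k]),
              step_onset_ms=step_on, step_offset_ms=step_off,
              seal_pa=protocol.seal_pa, seal_onset_ms=protocol.seal_onset_ms,
              seal_offset_ms=protocol.seal_onset_ms + protocol.seal_duration_ms,
              baseline_start_ms=step_on - 50.0, baseline_end_ms=step_on)
        for k in range(amplitudes.size)
    ]
    return SweepSet(cell_id=cell_id, sweeps=sweeps, genotype=genotype,
                    series_resistance_mohm=params.series_resistance_mohm)


def simulate_neuron_sweeps(params: NeuronSimParams,
                           protocol: Optional[StepProtocol] = None,
                           cell_id: str = "cell-0", genotype: str = "",
                           ) -> "tuple[SweepSet, dict]":
    """Simulate one cell's full step family; returns (SweepSet, ground truth)."""
    protocol = protocol or StepProtocol()
    rng = np.random.default_rng(params.seed)
    amplitudes = np.asarray(protocol.amplitudes_pa, dtype=float)
    V, spikes = _simulate_traces(params, protocol, amplitudes, rng)
    sweeps = _sweepset_from_traces(cell_id, genotype, params, protocol, V,
                                   amplitudes)
    truth = {
        "cell_id": cell_id,
        "params": asdict(params),
        "rheobase_pa": params.rheobase_pa,
        "v_rest_reported_mv": params.e_leak_mv - 10.0,
        "input_resistance_mohm": params.r_m_mohm,
        "ap": params.true_ap_metrics(protocol.dt_ms),
        "spike_times_ms": {f"{a:g}": s for a, s in zip(amplitudes, spikes)},
    }
    if params.sag_g_ratio > 0:
        truth["sag_ratio"] = sag_ratio_oracle(params, protocol)
    return sweeps, truth


def sag_ratio_oracle(params: NeuronSimParams, protocol: Optional[StepProtocol]
                     = None, refine: int = 4, long_step_ms: float = 2000.0
                     ) -> float:
    """Ground-truth sag ratio from a noiseless dt-refined long simulation.

    Uses the same (V_ss - V_min) / (V_base - V_min) formula as the extractor,
    with V_ss read at the true steady state of an extended -100 pA step.
    """
    protocol = protocol or StepProtocol()
    fine = StepProtocol(dt_ms=protocol.dt_ms / refine,
                       baseline_ms=protocol.baseline_ms,
                       step_duration_ms=long_step_ms,
                       tail_ms=protocol.tail_ms,
                       seal_onset_ms=protocol.seal_onset_ms,
                       seal_duration_ms=protocol.seal_duration_ms,
                       seal_pa=protocol.seal_pa, amplitudes_pa=(-100.0,))
    quiet = NeuronSimParams(**{**asdict(params), "noise_sd_mv": 0.0})
    rng = np.random.default_rng(0)
    V, _ = _simulate_traces(quiet, fine, np.array([-100.0]), rng)
    v = V[0]
    a = int(round(fine.baseline_ms / fine.dt_ms))
    b = int(round((fine.baseline_ms + fine.step_duration_ms) / fine.dt_ms))
    base = v[a - int(round(50.0 / fine.dt_ms)):a].mean()
    v_min = v[a:b].min()
    v_ss = v[b - 1]
    if v_min >= base:
        return 0.0
    return float(max((v_ss - v_min) / (base - v_min), 0.0))


def simulate_population(genotype_a: NeuronSimParams, genotype_b: NeuronSimParams,
                        n_per_genotype: int, protocol: Optional[StepProtocol] = None,
                        seed: int = 0, jitter_cv: float = 0.08,
                        labels: "tuple[str, str]" = ("A", "B"),
                        ) -> "tuple[list[SweepSet], dict]":
    """Simulate two genotypes of cells with per-cell parameter jitter.

    Per-cell passive parameters (R_m, tau_m, E_L offset, V_T offset) are
    jittered log-normally/normally around each genotype's means with the
    stated coefficient of variation.  All cells of both genotypes integrate in
    one vectorized batch; deterministic under ``seed``.
    """
    if n_per_genotype < 2:
        raise ValueError("need >= 2 cells per genotype for group statistics")
    protocol = protocol or StepProtocol()
    rng = np.random.default_rng(seed)
    amplitudes = np.asarray(protocol.amplitudes_pa, dtype=float)
    n_sw = amplitudes.size
    cells = []
    for geno, base, label in ((0, genotype_a, labels[0]),
                              (1, genotype_b, labels[1])):
        for c in range(n_per_genotype):
            r_m = base.r_m_mohm * rng.lognormal(0.0, jitter_cv)
            tau = base.tau_m_ms * rng.lognormal(0.0, jitter_cv)
            e_l = base.e_leak_mv + rng.normal(0.0, jitter_cv * 10.0)
            v_t = base.v_threshold_mv + rng.normal(0.0, jitter_cv * 10.0)
            cells.append((label, base, dict(r_m_mohm=r_m, tau_m_ms=tau,
                                            e_leak_mv=e_l, v_threshold_mv=v_t)))
    n_cells = len(cells)
    per_trace: dict = {}
    scalar_names = ["e_leak_mv", "r_m_mohm", "tau_m_ms", "v_threshold_mv",
                    "spike_peak_mv", "spike_rise_v_per_s", "spike_fall_v_per_s",
                    "trough_depth_mv", "sahp_increment_mv", "sahp_tau_ms",
                    "sag_g_ratio", "sag_v_half_mv", "sag_k_mv", "sag_tau_ms",
                    "sag_e_rev_mv", "noise_sd_mv"]
    for name in scalar_names:
        vals = []
        for label, base, over in cells:
            v = over.get(name, getattr(base, name))
            vals.extend([v] * n_sw)
        per_trace[name] = np.array(vals)
    amps_all = np.tile(amplitudes, n_cells)
    V, _ = _simulate_traces(genotype_a, protocol, amps_all, rng, per_trace)

    out: list[SweepSet] = []
    truth_cells = []
    for ci, (label, base, over) in enumerate(cells):
        block = V[ci * n_sw:(ci + 1) * n_sw]
        cell_params = NeuronSimParams(**{**asdict(base), **over})
        ss = _sweepset_from_traces(f"{label}-{ci:03d}", label, cell_params,
                                   protocol, block, amplitudes)
        out.append(ss)
        truth_cells.append({"cell_id": ss.cell_id, "genotype": label,
                            **{k: float(v) for k, v in over.items()},
                            "rheobase_pa": cell_params.rheobase_pa})
    truth = {"seed": seed, "jitter_cv": jitter_cv, "n_per_genotype": n_per_genotype,
             "genotype_means": {labels[0]: asdict(genotype_a),
                                labels[1]: asdict(genotype_b)},
             "cells": truth_cells}
    return out, truth


# ---------------------------------------------------------------------------
# taste spike trains

#: hedonic ranking of the four-taste battery (4 = most palatable)
DEFAULT_PALATABILITY = {"sucrose": 4, "nacl": 3, "citric_acid": 2, "quinine": 1}

#: centered, unit-max contrast coding of the palatability ranks
_RANK_COEF = {r: (r - 2.5) / 1.5 for r in (1, 2, 3, 4)}
_MOD_DEPTH = 0.75   # rate modulation at full coupling


@dataclass
class TasteSimParams:
    """Inhomogeneous-Poisson taste-trial generator parameters.

    Before ``onset_ms`` each taste carries a small identity gain uncorrelated
    with its rank; after the onset+ramp the across-taste rate ordering follows
    the palatability ranks with a strength set by ``rho_target`` (0 = none,
    1 = maximal modulation; the achieved trial-level Spearman correlation is
    an empirical, monotone function of it).  ``mode='regular'`` replaces
    Poisson sampling with deterministic evenly spaced spikes.
    """

    n_units: int = 20
    palatability: "dict[str, int]" = field(
        default_factory=lambda: dict(DEFAULT_PALATABILITY))
    trials_per_taste: int = 15
    duration_s: float = 2.5
    pre_s: float = 0.5
    baseline_rate_hz: float = 10.0
    identity_gain_sd: float = 0.05
    rho_target: float = 0.7
    onset_ms: float = 600.0
    ramp_ms: float = 300.0
    mode: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if sorted(self.palatability.values()) != [1, 2, 3, 4]:
            raise ValueError("palatability ranks must be a permutation of 1..4")
        if self.trials_per_taste < 2:
            raise ValueError("need >= 2 trials per taste")
        if self.baseline_rate_hz < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class SpikeTrial:
    taste: str
    spikes_s: np.ndarray
    duration_s: float
    pre_s: float


@dataclass
class SpikeTrainSet:
    """Per-unit taste trials; spike times in s relative to stimulus onset."""

    units: "dict[str, list[SpikeTrial]]"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for uid, trials in self.units.items():
            for k, tr in enumerate(trials):
                if tr.spikes_s.size == 0:
                    rows.append((uid, tr.taste, k, np.nan, tr.duration_s, tr.pre_s))
                for s in tr.spikes_s:
                    rows.append((uid, tr.taste, k, s, tr.duration_s, tr.pre_s))
        return pd.DataFrame(rows, columns=["unit_id", "taste", "trial",
                                           "spike_time_s", "trial_duration_s",
                                           "pre_s"])


def _unit_rate_profile(taste: str, rank: int, gains: dict, p: TasteSimParams,
                       bin_edges_ms: np.ndarray) -> "tuple[np.ndarray, bool]":
    """Mean rate (Hz) per time bin for one taste, from the coupling model."""
    centers = 0.5 * (bin_edges_ms[:-1] + bin_edges_ms[1:])
    m = np.clip((centers - p.onset_ms) / max(p.ramp_ms, 1e-9), 0.0, 1.0)
    m[centers < 0] = 0.0          # pre-stimulus: pure baseline
    identity = np.where(centers >= 0, gains[taste], 0.0) * (1.0 - m)
    pal = _MOD_DEPTH * p.rho_target * _RANK_COEF[rank] * m
    raw = p.baseline_rate_hz * (1.0 + identity + pal)
    return np.clip(raw, 0.0, None), bool(np.any(raw < 0))


def simulate_taste_units(params: TasteSimParams) -> "tuple[SpikeTrainSet, dict]":
    """Simulate a population of taste-responsive units; returns (set, truth)."""
    rng = np.random.default_rng(params.seed)
    bin_ms = 5.0
    edges = np.arange(-params.pre_s * 1000.0, params.duration_s * 1000.0 + bin_ms,
                      bin_ms)
    units: dict[str, list[SpikeTrial]] = {}
    clipped = False
    for u in range(params.n_units):
        gains = {t: rng.normal(0.0, params.identity_gain_sd)
                 for t in params.palatability}
        trials: list[SpikeTrial] = []
        for taste, rank in params.palatability.items():
            rate, was_clipped = _unit_rate_profile(taste, rank, gains, params,
                                                   edges)
            clipped = clipped or was_clipped
            lam = rate * bin_ms / 1000.0
            for _ in range(params.trials_per_taste):
                if params.mode == "poisson":
                    counts = rng.poisson(lam)
                    times = []
                    for b, c in enumerate(counts):
                        if c:
                            times.append(edges[b] + rng.random(c) * bin_ms)
                    sp = (np.sort(np.concatenate(times)) / 1000.0
                          if times else np.array([]))
                elif params.mode == "regular":
                    sp = _regular_train(rate, edges) / 1000.0
                else:
                    raise ValueError(f"unknown mode {params.mode}")
                trials.append(SpikeTrial(taste, sp, params.duration_s,
                                         params.pre_s))
        order = rng.permutation(len(trials))
        units[f"unit-{u:03d}"] = [trials[k] for k in order]
    if clipped:
        import warnings
        warnings.warn("negative rates after gain composition were clipped at 0",
                      RuntimeWarning, stacklevel=2)
    truth = {"params": asdict(params), "clipped": clipped}
    return SpikeTrainSet(units), truth


def _regular_train(rate_hz_per_bin: np.ndarray, edges_ms: np.ndarray
                   ) -> np.ndarray:
    """Deterministic spikes: piecewise-constant rate integrated; a spike is
    emitted whenever the accumulated intensity crosses an integer."""
    bin_ms = edges_ms[1] - edges_ms[0]
    out = []
    acc = 0.0
    for b, r in enumerate(rate_hz_per_bin):
        lam = r * bin_ms / 1000.0
        new_acc = acc + lam
        k = int(math.floor(new_acc)) - int(math.floor(acc))
        for j in range(k):
            target = math.floor(acc) + j + 1
            frac = (target - acc) / lam if lam > 0 else 0.0
            out.append(edges_ms[b] + frac * bin_ms)
        acc = new_acc
    return np.asarray(out)


def expected_null_abs_rho(n_trials_per_taste: int = 15, n_tastes: int = 4,
                          n_sims: int = 2000, seed: int = 12345,
                          ) -> "tuple[float, float]":
    """Monte-Carlo mean and SD of |Spearman rho| under taste-independent rates.

    Matches the tie structure of the analysis: ``n_trials_per_taste`` trials
    share each taste's palatability rank while rates are i.i.d. continuous.
    """
    from scipy.stats import spearmanr
    rng = np.random.default_rng(seed)
    ranks = np.repeat(np.arange(1, n_tastes + 1), n_trials_per_taste)
    vals = []
    for _ in range(n_sims):
        rho = spearmanr(rng.standard_normal(ranks.size), ranks).statistic
        vals.append(abs(rho))
    v = np.asarray(vals)
    return float(v.mean()), float(v.std(ddof=1))


# ---------------------------------------------------------------------------
# expression matrices

@dataclass
class ExprSimParams:
    """Log-normal TPM generator with planted fold changes.

    ``planted`` maps gene name -> fold change applied to the CTA group; if
    empty and ``n_planted`` > 0, that many genes with baseline abundance above
    ``planted_min_tpm`` are chosen at random.  ``mode='counts'`` emits
    length-scaled Poisson counts (for TPM-computation testing) instead of TPM.
    """

    n_genes: int = 2000
    samples_per_group: int = 4
    group_labels: "tuple[str, str]" = ("CTA", "control")
    log_tpm_loc: float = 3.0       # natural-log location of baseline TPM
    log_tpm_scale: float = 1.5     # across-gene spread
    dispersion: float = 0.25       # within-group log-scale sd per sample
    planted: "dict[str, float]" = field(default_factory=dict)
    n_planted: int = 0
    planted_fold_change: float = 4.0
    planted_min_tpm: float = 60.0
    gene_length_log_mean: float = math.log(2000.0)
    gene_length_log_sd: float = 0.6
    library_size: int = 2_000_000
    mode: str = "tpm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_group < 2:
            raise ValueError("need >= 2 samples per group")
        if any(fc <= 0 for fc in self.planted.values()):
            raise ValueError("fold changes must be > 0")


def simulate_expression(params: ExprSimParams
                        ) -> "tuple[pd.DataFrame, pd.Series, np.ndarray, dict]":
    """Generate (matrix, groups, gene lengths, truth).

    The matrix is genes x samples (TPM, columns renormalized to 1e6, or
    Poisson counts in count mode); ``groups`` maps sample id -> group label.
    """
    rng = np.random.default_rng(params.seed)
    genes = np.array([f"gene{g:05d}" for g in range(params.n_genes)])
    base_log = rng.normal(params.log_tpm_loc, params.log_tpm_scale,
                          params.n_genes)
    lengths = np.exp(rng.normal(params.gene_length_log_mean,
                                params.gene_length_log_sd, params.n_genes))
    planted = dict(params.planted)
    unknown = set(planted) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in matrix: {sorted(unknown)}")
    if not planted and params.n_planted > 0:
        eligible = np.flatnonzero(base_log >= math.log(params.planted_min_tpm))
        if eligible.size < params.n_planted:
            raise ValueError("not enough high-abundance genes to plant")
        chosen = rng.choice(eligible, size=params.n_planted, replace=False)
        planted = {genes[i]: params.planted_fold_change for i in chosen}
    fc_vec = np.ones(params.n_genes)
    for g, fc in planted.items():
        fc_vec[np.flatnonzero(genes == g)[0]] = fc

    g1, g2 = params.group_labels
    cols, data, groups = [], [], {}
    for gi, label in enumerate(params.group_labels):
        for s in range(params.samples_per_group):
            name = f"{label}_{s + 1}"
            log_mu = base_log + (np.log(fc_vec) if label == g1 else 0.0)
            tpm = np.exp(log_mu + rng.normal(0.0, params.dispersion,
                                             params.n_genes))
            cols.append(name)
            data.append(tpm)
            groups[name] = label
    mat = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    mat = mat / mat.sum(axis=0) * 1e6     # TPM columns sum to 1e6
    if params.mode == "counts":
        lam = mat.mul(lengths / 1000.0, axis=0)
        lam = lam / lam.sum(axis=0) * params.library_size
        mat = pd.DataFrame(rng.poisson(lam.to_numpy()).astype(float),
                           index=genes, columns=cols)
    elif params.mode != "tpm":
        raise ValueError(f"unknown mode {params.mode}")
    truth = {"planted": planted, "seed": params.seed, "mode": params.mode}
    return mat, pd.Series(groups, name="group"), lengths, truth


# ---------------------------------------------------------------------------
# consumption tables

@dataclass
class GroupConsumption:
    """Per-group consumption means/spread (ml)."""

    training_mean_ml: float = 1.0
    test_mean_ml: float = 0.25
    sd_ml: float = 0.15
    n_animals: int = 6

    def __post_init__(self) -> None:
        if self.sd_ml < 0:
            raise ValueError("sd must be >= 0")
        if min(self.training_mean_ml, self.test_mean_ml) < 0:
            raise ValueError("volumes must be >= 0")
        if self.n_animals < 2:
            raise ValueError("need >= 2 animals per group")


@dataclass
class ConsumptionSimParams:
    """Two-session CTA consumption generator.

    Defaults emulate a strong-learning control group (test/training ratio
    ~0.23) against a learning-impaired treated group (~0.80), the effect-size
    regime reported for transcription-blocked animals.
    """

    groups: "dict[str, GroupConsumption]" = field(default_factory=lambda: {
        "control": GroupConsumption(1.0, 0.23, 0.15, 6),
        "treated": GroupConsumption(1.0, 0.80, 0.15, 6),
    })
    water8h_mean_ml: float = 0.8
    water8h_sd_ml: float = 0.15
    seed: int = 0


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, n: int
               ) -> np.ndarray:
    if sd == 0:
        return np.full(n, max(mean, 0.0))
    out = rng.normal(mean, sd, n)
    while np.any(out < 0):       # resample the negative tail
        bad = out < 0
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return out


def simulate_consumption(params: ConsumptionSimParams
                         ) -> "tuple[pd.DataFrame, dict]":
    """Animal x session consumption table (long format) plus ground truth."""
    rng = np.random.default_rng(params.seed)
    rows = []
    for gname, g in params.groups.items():
        train = _truncnorm(rng, g.training_mean_ml, g.sd_ml, g.n_animals)
        test = _truncnorm(rng, g.test_mean_ml, g.sd_ml, g.n_animals)
        water = _truncnorm(rng, params.water8h_mean_ml, params.water8h_sd_ml,
                           g.n_animals)
        for a in range(g.n_animals):
            aid = f"{gname}-{a + 1:02d}"
            rows.append((aid, gname, "training", float(train[a])))
            rows.append((aid, gname, "test", float(test[a])))
            rows.append((aid, gname, "water8h", float(water[a])))
    table = pd.DataFrame(rows, columns=["animal", "group", "session",
                                        "volume_ml"])
    truth = {"groups": {k: asdict(v) for k, v in params.groups.items()},
             "true_ratio": {k: (v.test_mean_ml / v.training_mean_ml
                                if v.training_mean_ml > 0 else np.nan)
                            for k, v in params.groups.items()},
             "seed": params.seed}
    return table, truth
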