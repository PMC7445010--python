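"""Intrinsic-excitability feature extraction from current-clamp sweep sets.

A *sweep* is one voltage trace recorded while a square current step (plus a
small seal-test step during the pre-step baseline) is injected.  A *sweep set*
is one cell's family of sweeps across step amplitudes.  From these the module
measures the standard intrinsic-excitability suite: resting potential
(junction-corrected by -10 mV), input resistance from the 25 pA seal test,
sag ratio on the -100 pA step, the F-I curve and its interpolated rheobase,
per-spike metrics (threshold at the 10 V/s slope crossing, amplitude relative
to threshold, full width at half-height), the medium and slow
afterhyperpolarizations from 10-20 Hz trials, and a spike-frequency
accommodation ratio.  Cells failing the series-resistance (>30 MOhm) or
baseline-drift (>10 mV) rules are excluded by the QC filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Sweep",
    "SweepSet",
    "SpikeEvent",
    "CellFeatures",
    "QCRule",
    "ModeError",
    "ProtocolError",
    "BandMissingError",
    "detect_spikes",
    "ap_metrics",
    "firing_rate",
    "ahp_metrics",
    "sag_ratio",
    "passive_properties",
    "fi_and_rheobase",
    "accommodation_ratio",
    "extract_features",
    "qc_filter",
]

#: detection / measurement constants from the recording conventions
SLOPE_THRESHOLD_V_PER_S = 10.0      # AP threshold: slope first exceeds 10 V/s
PEAK_REACH_MV = -20.0               # candidate must reach this within 5 ms
PEAK_SEARCH_MS = 5.0
REFRACTORY_MS = 2.0
POST_SPIKE_MIN_MS = 50.0
SAHP_SEARCH_MS = 500.0
JUNCTION_POTENTIAL_MV = -10.0       # compensated post hoc
SEAL_TEST_PA = 25.0
AHP_BAND_HZ = (10.0, 20.0)
AHP_SPIKE_RANGE = (5, 10)           # metrics averaged from the 5th-10th APs


class ModeError(ValueError):
    """Operation applied to a sweep recorded in the wrong clamp mode."""


class ProtocolError(ValueError):
    """Sweep protocol does not provide the required step or marker."""


class BandMissingError(ValueError):
    """No sweep fired in the 10-20 Hz band required for AHP measurement."""


@dataclass
class Sweep:
    """One current-clamp (or voltage-clamp) trace with its step descriptor.

    Times are in ms from trace start; voltage in mV; currents in pA.
    ``seal_*`` mark the small seal-test step inside the baseline;
    ``baseline_*`` mark the quiet pre-step window used as the reference
    potential.
    """

    dt_ms: float
    voltage_mv: np.ndarray
    step_pa: float
    step_onset_ms: float
    step_offset_ms: float
    mode: str = "current-clamp"
    seal_pa: float = SEAL_TEST_PA
    seal_onset_ms: float = 0.0
    seal_offset_ms: float = 0.0
    baseline_start_ms: float = 0.0
    baseline_end_ms: float = 0.0

    def __post_init__(self) -> None:
        self.voltage_mv = np.asarray(self.voltage_mv, dtype=float)
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if self.step_offset_ms <= self.step_onset_ms:
            raise ValueError("step_offset_ms must exceed step_onset_ms")

    @property
    def n_samples(self) -> int:
        return self.voltage_mv.size

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    @property
    def step_duration_ms(self) -> float:
        return self.step_offset_ms - self.step_onset_ms

    def idx(self, t_ms: float) -> int:
        return int(round(t_ms / self.dt_ms))

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms

    def current_pa(self) -> np.ndarray:
        """Reconstruct the command-current series from the step descriptors."""
        i = np.zeros(self.n_samples)
        t = self.time_ms()
        if self.seal_offset_ms > self.seal_onset_ms:
            i[(t >= self.seal_onset_ms) & (t < self.seal_offset_ms)] = self.seal_pa
        i[(t >= self.step_onset_ms) & (t < self.step_offset_ms)] = self.step_pa
        return i

    def baseline_mean_mv(self) -> float:
        lo, hi = self.idx(self.baseline_start_ms), self.idx(self.baseline_end_ms)
        if hi <= lo:
            raise ProtocolError("baseline window not marked on sweep")
        return float(self.voltage_mv[lo:hi].mean())


@dataclass
class SweepSet:
    """All sweeps of one cell plus cell-level metadata."""

    cell_id: str
    sweeps: "list[Sweep]"
    genotype: str = ""
    series_resistance_mohm: float = np.nan
    mode: str = "current-clamp"

    def __iter__(self):
        return iter(self.sweeps)

    def __len__(self) -> int:
        return len(self.sweeps)

    def by_step(self, step_pa: float, atol: float = 1e-6) -> Sweep:
        for sw in self.sweeps:
            if abs(sw.step_pa - step_pa) <= atol:
                return sw
        raise ProtocolError(f"no sweep with step {step_pa} pA in cell {self.cell_id}")


@dataclass
class SpikeEvent:
    """A single action potential; metrics beyond position are filled by
    :func:`ap_metrics`."""

    index: int                      # sample of the 10 V/s crossing
    time_ms: float
    threshold_mv: float = np.nan
    peak_mv: float = np.nan
    amplitude_mv: float = np.nan
    half_width_ms: float = np.nan
    post_min_mv: float = np.nan
    truncated: bool = False


@dataclass
class QCRule:
    """Exclusion rules: strictly greater-than the printed limits excludes."""

    max_series_resistance_mohm: float = 30.0
    max_drift_mv: float = 10.0

    def __post_init__(self) -> None:
        if self.max_series_resistance_mohm <= 0 or self.max_drift_mv <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class CellFeatures:
    """Per-cell intrinsic-excitability measurement suite."""

    cell_id: str
    genotype: str = ""
    v_rest_mv: float = np.nan            # junction-corrected
    input_resistance_mohm: float = np.nan
    series_resistance_mohm: float = np.nan
    drift_mv: float = np.nan
    sag_ratio: float = np.nan
    fi_current_pa: np.ndarray = field(default_factory=lambda: np.array([]))
    fi_rate_hz: np.ndarray = field(default_factory=lambda: np.array([]))
    rheobase_pa: float = np.nan
    ap_threshold_mv: float = np.nan
    ap_amplitude_mv: float = np.nan
    ap_half_width_ms: float = np.nan
    mahp_mv: float = np.nan
    sahp_mv: float = np.nan
    accommodation_ratio: float = np.nan
    flags: "list[str]" = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("fi_current_pa", "fi_rate_hz", "flags")}
        d["flags"] = ";".join(self.flags)
        return d


# ---------------------------------------------------------------------------
# spike detection and AP metrics

def _dvdt(sweep: Sweep) -> np.ndarray:
    """Forward-difference slope in V/s (== mV/ms)."""
    return np.diff(sweep.voltage_mv) / sweep.dt_ms


def detect_spikes(sweep: Sweep) -> "list[SpikeEvent]":
    """Find action potentials on a current-clamp sweep.

    An event is an upward crossing of the 10 V/s slope criterion whose trace
    reaches at least -20 mV within 5 ms; successive events must be separated
    by a 2 ms refractory interval.
    """
    if sweep.mode != "current-clamp":
        raise ModeError(f"spike detection needs current-clamp, got {sweep.mode}")
    v = sweep.voltage_mv
    dv = _dvdt(sweep)
    above = dv > SLOPE_THRESHOLD_V_PER_S
    crossings = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    reach = int(round(PEAK_SEARCH_MS / sweep.dt_ms))
    refr = REFRACTORY_MS
    events: list[SpikeEvent] = []
    last_t = -np.inf
    for i in crossings:
        t = i * sweep.dt_ms
        if t - last_t < refr:
            continue
        if v[i:i + reach + 1].max() < PEAK_REACH_MV:
            continue
        events.append(SpikeEvent(index=int(i), time_ms=float(t)))
        last_t = t
    return events


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def ap_metrics(sweep: Sweep, events: Sequence[SpikeEvent]) -> "list[SpikeEvent]":
    """Fill threshold, amplitude, half-width and post-spike minimum.

    Threshold is the voltage at the first sample, searching backward at most
    5 ms from the peak, whose forward slope exceeds 10 V/s; amplitude is peak
    minus threshold; half-width is the time spent above threshold + half the
    amplitude (sub-sample linear interpolation); the post-spike minimum is
    taken within 50 ms of the peak or until the next event.
    """
    v = sweep.voltage_mv
    dt = sweep.dt_ms
    dv = _dvdt(sweep)
    out: list[SpikeEvent] = []
    n = v.size
    for k, ev in enumerate(events):
        win = int(round(PEAK_SEARCH_MS / dt))
        hi = min(ev.index + win + 1, n)
        peak_idx = ev.index + int(np.argmax(v[ev.index:hi]))
        if peak_idx >= n - 1 or ev.index == 0:
            out.append(replace(ev, truncated=True))
            continue
        lo = max(peak_idx - win, 0)
        seg = np.flatnonzero(dv[lo:peak_idx] > SLOPE_THRESHOLD_V_PER_S)
        thr_idx = lo + int(seg[0]) if seg.size else ev.index
        thr = float(v[thr_idx])
        peak = float(v[peak_idx])
        amp = peak - thr
        level = thr + amp / 2.0
        # rising crossing of the half-height level
        j = peak_idx
        while j > thr_idx and v[j - 1] >= level:
            j -= 1
        t_up = _interp_crossing((j - 1) * dt, j * dt, v[j - 1], v[j], level) \
            if j > 0 and v[j - 1] < level else j * dt
        # falling crossing
        next_limit = events[k + 1].index if k + 1 < len(events) else n - 1
        j = peak_idx
        while j < next_limit and v[j + 1] >= level:
            j += 1
        if j + 1 >= n or v[j + 1] >= level:
            out.append(replace(ev, threshold_mv=thr, peak_mv=peak,
                               amplitude_mv=amp, truncated=True))
            continue
        t_down = _interp_crossing(j * dt, (j + 1) * dt, v[j], v[j + 1], level)
        # post-spike minimum
        pm_hi = min(peak_idx + int(round(POST_SPIKE_MIN_MS / dt)) + 1, n,
                    next_limit + 1)
        post_min = float(v[peak_idx:pm_hi].min()) if pm_hi > peak_idx else np.nan
        out.append(replace(ev, threshold_mv=thr, peak_mv=peak, amplitude_mv=amp,
                           half_width_ms=float(t_down - t_up),
                           post_min_mv=post_min))
    return out


def firing_rate(sweep: Sweep, events: Optional[Sequence[SpikeEvent]] = None) -> float:
    """Spikes during the step divided by the step duration (Hz)."""
    if events is None:
        events = detect_spikes(sweep)
    n = sum(1 for e in events
            if sweep.step_onset_ms <= e.time_ms < sweep.step_offset_ms)
    return n / (sweep.step_duration_ms / 1000.0)


# ---------------------------------------------------------------------------
# AHPs

@dataclass
class AHPResult:
    mahp_mv: float
    sahp_mv: float
    n_sweeps: int
    partial: bool = False


def ahp_metrics(sweeps: SweepSet) -> AHPResult:
    """Medium and slow AHP, positive magnitudes.

    mAHP: mean over the 5th-10th APs of (threshold - post-spike minimum) in
    sweeps firing at 10-20 Hz.  sAHP: pre-step baseline minus the minimum
    within 500 ms after step offset, averaged over the same sweeps.  A sweep
    in band but with fewer than 10 APs contributes what it has from the 5th
    on and sets the ``partial`` flag.
    """
    mahps: list[float] = []
    sahps: list[float] = []
    partial = False
    n_used = 0
    lo_i, hi_i = AHP_SPIKE_RANGE
    for sw in sweeps:
        if sw.step_pa <= 0:
            continue
        events = ap_metrics(sw, detect_spikes(sw))
        step_events = [e for e in events
                       if sw.step_onset_ms <= e.time_ms < sw.step_offset_ms]
        rate = len(step_events) / (sw.step_duration_ms / 1000.0)
        if not (AHP_BAND_HZ[0] <= rate <= AHP_BAND_HZ[1]):
            continue
        n_used += 1
        if len(step_events) < hi_i:
            partial = True
        sel = step_events[lo_i - 1:hi_i]
        for e in sel:
            if np.isfinite(e.post_min_mv) and np.isfinite(e.threshold_mv):
                mahps.append(e.threshold_mv - e.post_min_mv)
        base = sw.baseline_mean_mv()
        a = sw.idx(sw.step_offset_ms)
        b = min(sw.idx(sw.step_offset_ms + SAHP_SEARCH_MS), sw.n_samples)
        if b > a:
            sahps.append(base - float(sw.voltage_mv[a:b].min()))
    if n_used == 0:
        raise BandMissingError(
            f"cell {sweeps.cell_id}: no sweep fired in the "
            f"{AHP_BAND_HZ[0]:g}-{AHP_BAND_HZ[1]:g} Hz band")
    mahp = float(np.mean(mahps)) if mahps else np.nan
    sahp = float(np.mean(sahps)) if sahps else np.nan
    return AHPResult(mahp, sahp, n_used, partial)


# ---------------------------------------------------------------------------
# passive properties, sag, F-I

def sag_ratio(sweep: Sweep, steady_fraction: float = 0.2) -> float:
    """Sag ratio on a hyperpolarizing step.

    ratio = (V_ss - V_min) / (V_baseline - V_min) with V_ss the mean over the
    last ``steady_fraction`` of the step; 0 = no sag, 1 = full rebound to
    baseline.  The depolarizing-rebound orientation reproduces the reported
    scale (~0.13-0.15 on these neurons).
    """
    if sweep.step_pa >= 0:
        raise ProtocolError("sag ratio needs a hyperpolarizing step")
    v = sweep.voltage_mv
    a, b = sweep.idx(sweep.step_onset_ms), sweep.idx(sweep.step_offset_ms)
    base = sweep.baseline_mean_mv()
    v_min = float(v[a:b].min())
    ss_start = b - int(round(steady_fraction * (b - a)))
    v_ss = float(v[ss_start:b].mean())
    if v_min >= base:
        return 0.0  # degenerate: no hyperpolarization achieved
    return max((v_ss - v_min) / (base - v_min), 0.0)


@dataclass
class PassiveProperties:
    v_rest_mv: float          # junction-corrected
    input_resistance_mohm: float
    series_resistance_mohm: float
    drift_mv: float


def passive_properties(sweeps: SweepSet,
                       seal_steady_fraction: float = 0.2,
                       pre_seal_ms: float = 20.0) -> PassiveProperties:
    """Resting potential, input resistance, series resistance and drift.

    R_in is the steady-state seal-test deflection divided by the seal current;
    the reported resting potential subtracts the 10 mV liquid junction
    potential; drift is the maximum excursion of the per-sweep baseline means
    across the session.
    """
    r_ins: list[float] = []
    baselines: list[float] = []
    for sw in sweeps:
        if sw.seal_offset_ms <= sw.seal_onset_ms:
            raise ProtocolError(f"cell {sweeps.cell_id}: sweep lacks a seal test")
        v = sw.voltage_mv
        a, b = sw.idx(sw.seal_onset_ms), sw.idx(sw.seal_offset_ms)
        pre_a = max(sw.idx(sw.seal_onset_ms - pre_seal_ms), 0)
        ss_start = b - int(round(seal_steady_fraction * (b - a)))
        dv = float(v[ss_start:b].mean() - v[pre_a:a].mean())
        r_ins.append(dv / sw.seal_pa * 1000.0)   # mV / pA -> MOhm
        baselines.append(sw.baseline_mean_mv())
    baselines_arr = np.asarray(baselines)
    return PassiveProperties(
        v_rest_mv=float(baselines_arr.mean()) + JUNCTION_POTENTIAL_MV,
        input_resistance_mohm=float(np.mean(r_ins)),
        series_resistance_mohm=float(sweeps.series_resistance_mohm),
        drift_mv=float(baselines_arr.max() - baselines_arr.min()),
    )


@dataclass
class FIResult:
    current_pa: np.ndarray
    rate_hz: np.ndarray
    rheobase_pa: float
    method: str
    flags: "list[str]" = field(default_factory=list)


def fi_and_rheobase(sweeps: SweepSet, method: str = "two_point") -> FIResult:
    """F-I table over positive steps and the interpolated rheobase.

    ``two_point`` (default): abscissa intercept of the line through the first
    two suprathreshold F-I points, clamped to (last zero-rate current, first
    nonzero-rate current].  ``one_spike``: current at which the line from the
    last zero-rate point to the first suprathreshold point reaches a one-spike
    rate.
    """
    pts = []
    for sw in sweeps:
        if sw.step_pa > 0:
            pts.append((sw.step_pa, firing_rate(sw)))
    if len(pts) < 1:
        raise ProtocolError("no positive current steps")
    pts.sort()
    current = np.array([p[0] for p in pts])
    rate = np.array([p[1] for p in pts])
    flags: list[str] = []
    supra = np.flatnonzero(rate > 0)
    if supra.size == 0:
        return FIResult(current, rate, np.nan, method, ["rheobase-undefined"])
    first = supra[0]
    zeros_below = np.flatnonzero(rate[:first] == 0)
    if zeros_below.size:
        lower = current[zeros_below[-1]]
    else:
        lower = 0.0
        flags.append("no-subthreshold-step")
    upper = current[first]
    if method == "one_spike":
        one_spike_rate = 1000.0 / sweeps.sweeps[0].step_duration_ms
        rheo = lower + (upper - lower) * min(one_spike_rate / rate[first], 1.0)
    elif method == "two_point":
        if supra.size >= 2:
            i1, i2 = supra[0], supra[1]
            slope = (rate[i2] - rate[i1]) / (current[i2] - current[i1])
            if slope > 0:
                rheo = current[i1] - rate[i1] / slope
            else:
                rheo = current[i1]
                flags.append("non-increasing-fi")
        else:
            rheo = upper
            flags.append("single-suprathreshold-point")
        rheo = min(max(rheo, np.nextafter(lower, upper)), upper)
    else:
        raise ValueError(f"unknown rheobase method: {method}")
    return FIResult(current, rate, float(rheo), method, flags)


def accommodation_ratio(sweep: Sweep,
                        events: Optional[Sequence[SpikeEvent]] = None) -> float:
    """Last inter-spike interval over the first; 1 = no accommodation."""
    if events is None:
        events = detect_spikes(sweep)
    times = np.array([e.time_ms for e in events
                      if sweep.step_onset_ms <= e.time_ms < sweep.step_offset_ms])
    if times.size < 5:
        raise ValueError(f"accommodation ratio needs >= 5 spikes, got {times.size}")
    isis = np.diff(times)
    return float(isis[-1] / isis[0])


# ---------------------------------------------------------------------------
# whole-cell extraction and QC

def extract_features(sweeps: SweepSet, sag_step_pa: float = -100.0,
                     rheobase_method: str = "two_point") -> CellFeatures:
    """Run the full measurement suite on one cell."""
    feats = CellFeatures(cell_id=sweeps.cell_id, genotype=sweeps.genotype)
    passive = passive_properties(sweeps)
    feats.v_rest_mv = passive.v_rest_mv
    feats.input_resistance_mohm = passive.input_resistance_mohm
    feats.series_resistance_mohm = passive.series_resistance_mohm
    feats.drift_mv = passive.drift_mv
    try:
        feats.sag_ratio = sag_ratio(sweeps.by_step(sag_step_pa))
    except ProtocolError:
        feats.flags.append("no-sag-step")
    fi = fi_and_rheobase(sweeps, method=rheobase_method)
    feats.fi_current_pa, feats.fi_rate_hz = fi.current_pa, fi.rate_hz
    feats.rheobase_pa = fi.rheobase_pa
    feats.flags.extend(fi.flags)

    # AP metrics from the 5th-10th APs of 10-20 Hz sweeps
    thr, amp, hw = [], [], []
    lo_i, hi_i = AHP_SPIKE_RANGE
    acc: list[float] = []
    for sw in sweeps:
        if sw.step_pa <= 0:
            continue
        events = ap_metrics(sw, detect_spikes(sw))
        step_events = [e for e in events
                       if sw.step_onset_ms <= e.time_ms < sw.step_offset_ms]
        rate = len(step_events) / (sw.step_duration_ms / 1000.0)
        if AHP_BAND_HZ[0] <= rate <= AHP_BAND_HZ[1]:
            for e in step_events[lo_i - 1:hi_i]:
                if not e.truncated:
                    thr.append(e.threshold_mv)
                    amp.append(e.amplitude_mv)
                    hw.append(e.half_width_ms)
        if len(step_events) >= 5:
            try:
                acc.append(accommodation_ratio(sw, step_events))
            except ValueError:
                pass
    if thr:
        feats.ap_threshold_mv = float(np.mean(thr))
        feats.ap_amplitude_mv = float(np.mean(amp))
        feats.ap_half_width_ms = float(np.nanmean(hw)) if hw else np.nan
    else:
        feats.flags.append("no-10-20Hz-band-sweep")
    try:
        ahp = ahp_metrics(sweeps)
        feats.mahp_mv, feats.sahp_mv = ahp.mahp_mv, ahp.sahp_mv
        if ahp.partial:
            feats.flags.append("mahp-partial")
    except BandMissingError:
        feats.flags.append("ahp-band-missing")
    if acc:
        feats.accommodation_ratio = float(np.mean(acc))
    else:
        feats.flags.append("insufficient-spikes-for-accommodation")
    return feats


def qc_filter(cells: Sequence[CellFeatures], rule: Optional[QCRule] = None
              ) -> "tuple[list[CellFeatures], list[tuple[CellFeatures, list[str]]]]":
    """Partition cells into kept and excluded (with reasons).

    Exclusion is strict: series resistance must exceed 30 MOhm, or drift must
    exceed 10 mV, for a cell to be dropped (values exactly at the limit pass).
    """
    rule = rule or QCRule()
    kept: list[CellFeatures] = []
    excluded: list[tuple[CellFeatures, list[str]]] = []
    for c in cells:
        reasons = []
        if np.isfinite(c.series_resistance_mohm) and \
                c.series_resistance_mohm > rule.max_series_resistance_mohm:
            reasons.append("series-resistance")
        if np.isfinite(c.drift_mv) and c.drift_mv > rule.max_drift_mv:
            reasons.append("vm-drift")
        if reasons:
            excluded.append((c, reasons))
        else:
            kept.append(c)
    return kept, excluded
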