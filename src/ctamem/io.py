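"""File formats, run configuration and the pipeline orchestrator.

Voltage traces live in an HDF5 container (``/cell`` attributes plus one group
per sweep); all tabular exchange is TSV/CSV with declared schemas; synthetic
ground truth goes to JSON sidecars that analysis stages never read.  Report
files are deterministic byte streams for a given input (fixed float
formatting, fixed row order) and carry provenance headers (config hash and
seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ephys import Sweep, SweepSet
from .synthetic import SpikeTrial, SpikeTrainSet

__all__ = [
    "SchemaError",
    "write_sweep_file",
    "read_sweep_file",
    "write_spike_trains",
    "read_spike_trains",
    "write_palatability_map",
    "read_palatability_map",
    "write_expression",
    "read_expression",
    "write_table",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("ctamem")

FLOAT_FMT = "%.6g"


class SchemaError(ValueError):
    """File does not conform to the declared layout."""


# ---------------------------------------------------------------------------
# HDF5 sweep container

_SWEEP_ATTRS = ("dt_ms", "step_pa", "step_onset_ms", "step_offset_ms",
                "seal_pa", "seal_onset_ms", "seal_offset_ms",
                "baseline_start_ms", "baseline_end_ms")


def write_sweep_file(path, sweeps: SweepSet) -> None:
    with h5py.File(path, "w") as f:
        cell = f.create_group("cell")
        cell.attrs["id"] = sweeps.cell_id
        cell.attrs["genotype"] = sweeps.genotype
        cell.attrs["mode"] = sweeps.mode
        cell.attrs["series_resistance_MOhm"] = sweeps.series_resistance_mohm
        grp = f.create_group("sweeps")
        for k, sw in enumerate(sweeps):
            g = grp.create_group(f"{k:03d}")
            dv = g.create_dataset("voltage_mV", data=sw.voltage_mv)
            dv.attrs["unit"] = "mV"
            di = g.create_dataset("current_pA", data=sw.current_pa())
            di.attrs["unit"] = "pA"
            for name in _SWEEP_ATTRS:
                g.attrs[name] = getattr(sw, {
                    "dt_ms": "dt_ms", "step_pa": "step_pa",
                    "step_onset_ms": "step_onset_ms",
                    "step_offset_ms": "step_offset_ms", "seal_pa": "seal_pa",
                    "seal_onset_ms": "seal_onset_ms",
                    "seal_offset_ms": "seal_offset_ms",
                    "baseline_start_ms": "baseline_start_ms",
                    "baseline_end_ms": "baseline_end_ms"}[name])


def read_sweep_file(path) -> SweepSet:
    """Lossless load of the HDF5 sweep container; units are verified."""
    with h5py.File(path, "r") as f:
        if "cell" not in f or "sweeps" not in f:
            raise SchemaError(f"{path}: missing /cell or /sweeps group")
        cell = f["cell"]
        sweeps = []
        for key in sorted(f["sweeps"]):
            g = f["sweeps"][key]
            for name in _SWEEP_ATTRS:
                if name not in g.attrs:
                    raise SchemaError(
                        f"{path}: /sweeps/{key} missing attr {name!r}")
            unit = g["voltage_mV"].attrs.get("unit", "mV")
            if unit != "mV":
                raise SchemaError(
                    f"{path}: /sweeps/{key}/voltage_mV unit is {unit!r},"
                    " expected 'mV'")
            sweeps.append(Sweep(
                dt_ms=float(g.attrs["dt_ms"]),
                voltage_mv=g["voltage_mV"][()],
                step_pa=float(g.attrs["step_pa"]),
                step_onset_ms=float(g.attrs["step_onset_ms"]),
                step_offset_ms=float(g.attrs["step_offset_ms"]),
                mode=str(cell.attrs.get("mode", "current-clamp")),
                seal_pa=float(g.attrs["seal_pa"]),
                seal_onset_ms=float(g.attrs["seal_onset_ms"]),
                seal_offset_ms=float(g.attrs["seal_offset_ms"]),
                baseline_start_ms=float(g.attrs["baseline_start_ms"]),
                baseline_end_ms=float(g.attrs["baseline_end_ms"]),
            ))
        return SweepSet(
            cell_id=str(cell.attrs["id"]), sweeps=sweeps,
            genotype=str(cell.attrs.get("genotype", "")),
            series_resistance_mohm=float(
                cell.attrs.get("series_resistance_MOhm", np.nan)),
            mode=str(cell.attrs.get("mode", "current-clamp")))


# ---------------------------------------------------------------------------
# spike trains and palatability map

def write_spike_trains(path, spikes: SpikeTrainSet) -> None:
    """Long-format CSV: unit_id, taste, trial, spike_time_s, trial_duration_s,
    pre_s.  Empty trials keep a NaN spike-time row so the trial count
    round-trips."""
    spikes.to_frame().to_csv(path, index=False, float_format="%.9g")


def read_spike_trains(path) -> SpikeTrainSet:
    df = pd.read_csv(path)
    required = {"unit_id", "taste", "trial", "spike_time_s", "trial_duration_s"}
    if not required <= set(df.columns):
        raise SchemaError(f"{path}: expected columns {sorted(required)}")
    if "pre_s" not in df.columns:
        df["pre_s"] = 0.0
    units: dict[str, list[SpikeTrial]] = {}
    for uid, sub in df.groupby("unit_id", sort=True):
        trials = []
        for trial_key in sorted(sub["trial"].unique()):
            tsub = sub[sub["trial"] == trial_key]
            times = tsub["spike_time_s"].dropna().to_numpy()
            trials.append(SpikeTrial(
                taste=str(tsub["taste"].iloc[0]),
                spikes_s=np.sort(times),
                duration_s=float(tsub["trial_duration_s"].iloc[0]),
                pre_s=float(tsub["pre_s"].iloc[0])))
        units[str(uid)] = trials
    return SpikeTrainSet(units)


def write_palatability_map(path, ranks: dict) -> None:
    pd.DataFrame(sorted(ranks.items()), columns=["taste", "rank"]).to_csv(
        path, index=False)


def read_palatability_map(path) -> dict:
    df = pd.read_csv(path)
    if not {"taste", "rank"} <= set(df.columns):
        raise SchemaError(f"{path}: expected columns taste, rank")
    return {str(r.taste): int(r.rank) for r in df.itertuples()}


# ---------------------------------------------------------------------------
# expression matrices

def write_expression(path, matrix: pd.DataFrame, groups: pd.Series) -> None:
    """Genes x samples TSV plus a sidecar JSON of sample group labels."""
    matrix.to_csv(path, sep="\t", float_format="%.9g", index_label="gene")
    sidecar = Path(str(path) + ".groups.json")
    sidecar.write_text(json.dumps(groups.to_dict(), indent=2, sort_keys=True)
                       + "\n")


def read_expression(path) -> "tuple[pd.DataFrame, pd.Series]":
    matrix = pd.read_csv(path, sep="\t", index_col="gene")
    sidecar = Path(str(path) + ".groups.json")
    if not sidecar.exists():
        raise SchemaError(f"missing group sidecar {sidecar}")
    groups = pd.Series(json.loads(sidecar.read_text()), name="group")
    missing = set(matrix.columns) - set(groups.index)
    if missing:
        raise SchemaError(f"samples without group labels: {sorted(missing)}")
    return matrix, groups


# ---------------------------------------------------------------------------
# provenance-stamped tables

def write_table(path, frame: pd.DataFrame, provenance: Optional[dict] = None
                ) -> None:
    """Deterministic TSV with '#'-prefixed provenance header lines."""
    path = Path(path)
    with open(path, "w") as f:
        f.write(f"# ctamem {__version__}\n")
        for k in sorted(provenance or {}):
            f.write(f"# {k}={provenance[k]}\n")
        frame.to_csv(f, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# run configuration and orchestration

_STAGES = ("simulate", "ephys", "palatability", "de", "behavior")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``stages`` selects what runs (in dependency order); analysis options all
    default to the study-faithful choice.  Unknown keys in a config file are
    rejected outright.
    """

    stages: "list[str]" = field(default_factory=lambda: list(_STAGES))
    out_dir: str = "ctamem-out"
    seed: int = 0
    inputs: "dict[str, str]" = field(default_factory=dict)
    t_test_equal_variance: bool = True
    rheobase_method: str = "two_point"
    de_log: bool = False
    de_tpm_mode: str = "grand_mean"
    palatability_layout: str = "unit_window"
    n_cells_per_genotype: int = 6
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix.lower() == ".json"
                else yaml.safe_load(text)) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        """Hash of the analysis-relevant configuration (where outputs go and
        how chatty the log is do not change any result)."""
        d = {k: v for k, v in asdict(self).items()
             if k not in ("out_dir", "log_level")}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> "dict[str, list[str]]":
    """Execute the selected stages; returns a map stage -> output files.

    Synthetic inputs are generated by the simulate stage when no input paths
    are configured; identical config plus seed reproduces every report byte
    for byte (timestamps are deliberately not written).
    """
    from . import behavior as bh
    from . import de as de_mod
    from . import ephys as ep
    from . import palatability as pal
    from . import synthetic as syn

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": config.hash(), "seed": config.seed}
    produced: dict[str, list[str]] = {}
    rng_seed = int(config.seed)

    def record(stage: str, *paths) -> None:
        produced.setdefault(stage, []).extend(str(p) for p in paths)

    if "simulate" in config.stages:
        log.info("stage simulate: generating synthetic inputs")
        cells, truth = syn.simulate_population(
            syn.NeuronSimParams(noise_sd_mv=0.3, sag_g_ratio=0.2, seed=rng_seed),
            syn.NeuronSimParams(noise_sd_mv=0.3, sag_g_ratio=0.2,
                                r_m_mohm=120.0, seed=rng_seed),
            n_per_genotype=config.n_cells_per_genotype, seed=rng_seed,
            labels=("WT", "KO"))
        cell_paths = []
        for ss in cells:
            p = out / f"sweeps_{ss.cell_id}.h5"
            write_sweep_file(p, ss)
            cell_paths.append(p)
        (out / "sweeps_truth.json").write_text(
            json.dumps(truth, indent=2, default=float) + "\n")
        spikes, st_truth = syn.simulate_taste_units(
            syn.TasteSimParams(seed=rng_seed))
        write_spike_trains(out / "spike_trains.csv", spikes)
        write_palatability_map(out / "palatability_map.csv",
                               syn.DEFAULT_PALATABILITY)
        (out / "spike_trains_truth.json").write_text(
            json.dumps(st_truth, indent=2, default=float) + "\n")
        mat, grp, _, e_truth = syn.simulate_expression(
            syn.ExprSimParams(n_planted=10, seed=rng_seed))
        write_expression(out / "expression.tsv", mat, grp)
        (out / "expression_truth.json").write_text(
            json.dumps(e_truth, indent=2, default=float) + "\n")
        cons, c_truth = syn.simulate_consumption(
            syn.ConsumptionSimParams(seed=rng_seed))
        cons.to_csv(out / "consumption.csv", index=False,
                    float_format="%.9g")
        (out / "consumption_truth.json").write_text(
            json.dumps(c_truth, indent=2, default=float) + "\n")
        record("simulate", *cell_paths, out / "spike_trains.csv",
               out / "expression.tsv", out / "consumption.csv")

    if "ephys" in config.stages:
        log.info("stage ephys: feature extraction + QC")
        paths = (sorted(out.glob("sweeps_*.h5"))
                 if "sweep_files" not in config.inputs
                 else [Path(p) for p in
                       config.inputs["sweep_files"].split(";")])
        if not paths:
            raise FileNotFoundError("ephys stage: no sweep files found")
        feats = [ep.extract_features(read_sweep_file(p),
                                     rheobase_method=config.rheobase_method)
                 for p in paths]
        kept, excluded = ep.qc_filter(feats)
        rows = [f.to_dict() for f in kept]
        write_table(out / "cell_features.tsv", pd.DataFrame(rows), prov)
        qc_rows = [{"cell_id": c.cell_id, "reasons": ";".join(r)}
                   for c, r in excluded]
        write_table(out / "qc_excluded.tsv",
                    pd.DataFrame(qc_rows, columns=["cell_id", "reasons"]), prov)
        record("ephys", out / "cell_features.tsv", out / "qc_excluded.tsv")

    if "palatability" in config.stages:
        log.info("stage palatability: moving-window correlation")
        sp_path = config.inputs.get("spike_trains", out / "spike_trains.csv")
        map_path = config.inputs.get("palatability_map",
                                     out / "palatability_map.csv")
        spikes = read_spike_trains(sp_path)
        ranks = pal.PalatabilityMap(read_palatability_map(map_path))
        tc = pal.population_timecourse(spikes, ranks)
        write_table(out / "palatability_timecourse.tsv", tc.to_frame(), prov)
        record("palatability", out / "palatability_timecourse.tsv")

    if "de" in config.stages:
        log.info("stage de: differential-expression screen")
        expr_path = config.inputs.get("expression", out / "expression.tsv")
        mat, grp = read_expression(expr_path)
        de_table = de_mod.differential_test(mat, grp, log=config.de_log)
        up, down = de_mod.apply_criteria(de_table, tpm_mode=config.de_tpm_mode,
                                         matrix=mat, groups=grp)
        res = pd.concat([up.assign(direction="up"),
                         down.assign(direction="down")])
        res = res.reset_index().rename(columns={"index": "gene"})
        write_table(out / "de_screen.tsv",
                    res[["gene", "fold_change", "p", "mean_tpm", "direction"]],
                    prov)
        record("de", out / "de_screen.tsv")

    if "behavior" in config.stages:
        log.info("stage behavior: CTA memory statistics")
        cons_path = config.inputs.get("consumption", out / "consumption.csv")
        table = pd.read_csv(cons_path)
        report = bh.cta_effect_analysis(table)
        report.to_json(out / "cta_report.json")
        write_table(out / "cta_anova.tsv",
                    report.anova.to_frame().reset_index(), prov)
        write_table(out / "cta_posthoc.tsv", report.posthoc, prov)
        record("behavior", out / "cta_report.json", out / "cta_anova.tsv",
               out / "cta_posthoc.tsv")

    return produced
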