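"""CSV readers/writers, study configuration, and end-to-end orchestration.

The pipeline runs raw traces (or the simulator) through gait-event detection,
EMG integration, strength metrics and the correlation study, writing a cohort
table, a results table, numeric heatmap matrices and a run log that records
every parameter and the BH family sizes.  Every output CSV starts with a
comment line carrying the package version and a hash of the configuration, so
any number in the report can be traced back to its settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, InvalidParameterError
from .types import GRAVITY, MUSCLES, EmgTrace, ForceTrace
from . import emg as emg_mod
from . import gait as gait_mod
from . import strength as strength_mod
from . import stats as stats_mod
from .synthetic import (
    DEFAULT_ENVELOPES,
    cna_column,
    iemg_column,
    gen_emg,
    gen_imtp,
    gen_vgrf,
    run_spec_for_speed,
)
from .strength import RFD_WINDOWS_MS, ImtpTrace


# ---------------------------------------------------------------------------
# Time-series CSV I/O
# ---------------------------------------------------------------------------

def read_timeseries(path: str | Path) -> ForceTrace | dict[str, EmgTrace]:
    """Read a delimited time-series file (`time_s` first, channels after).

    Returns a :class:`ForceTrace` for a single ``fz_N`` channel, or a dict of
    :class:`EmgTrace` keyed by muscle for EMG files.  Sampling must be uniform
    within 1 ppm of the median interval.
    """
    df = pd.read_csv(path, comment="#")
    if df.columns[0] != "time_s":
        raise ConfigError(f"{path}: first column must be 'time_s', got {df.columns[0]!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ConfigError(f"{path}: need at least two samples to infer the rate")
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise ConfigError(f"{path}: time column must be strictly increasing")
    bad = np.flatnonzero(np.abs(dt - med) > max(1e-6 * med, 2e-9))
    if bad.size:
        raise ConfigError(
            f"{path}: non-uniform sampling at row {int(bad[0]) + 1} "
            f"(dt={dt[bad[0]]:.9g}, expected {med:.9g})"
        )
    rate = 1.0 / med
    channels = list(df.columns[1:])
    if not channels:
        raise ConfigError(f"{path}: no data channels after time_s")
    if channels == ["fz_N"]:
        return ForceTrace(df["fz_N"].to_numpy(dtype=float), rate, start_time=float(t[0]))
    unknown = [c for c in channels if c not in MUSCLES]
    if unknown:
        raise ConfigError(
            f"{path}: channels must be 'fz_N' or muscle labels {MUSCLES}, got {unknown}"
        )
    return {
        c: EmgTrace(df[c].to_numpy(dtype=float), rate, c, start_time=float(t[0]))
        for c in channels
    }


def write_timeseries(path: str | Path, traces: ForceTrace | dict[str, EmgTrace],
                     comment: str | None = None) -> None:
    """Write a trace (or a dict of same-rate EMG traces) as `time_s,<channel>…`."""
    if isinstance(traces, ForceTrace):
        data = {"time_s": traces.times(), "fz_N": traces.samples}
    else:
        rates = {tr.rate for tr in traces.values()}
        if len(rates) != 1:
            raise InvalidParameterError("all EMG channels must share one rate")
        first = next(iter(traces.values()))
        data = {"time_s": first.times()}
        data.update({m: tr.samples for m, tr in traces.items()})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        pd.DataFrame(data).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProcessingParams:
    """Signal-processing settings; defaults encode the study protocol."""

    grf_cutoff_hz: float = 50.0
    grf_filter_order: int = 2
    contact_threshold_N: float = 50.0
    min_contact_s: float = 0.05
    min_flight_s: float = 0.02
    emg_low_hz: float = 20.0
    emg_high_hz: float = 400.0
    emg_filter_order: int = 4
    k_cycles: int = 10
    imtp_k_sd: float = 5.0
    imtp_baseline_s: float = 1.0

    def __post_init__(self) -> None:
        if self.contact_threshold_N <= 0:
            raise ConfigError("contact threshold must be positive")
        if self.k_cycles <= 0:
            raise ConfigError("k_cycles must be positive")


@dataclass(frozen=True)
class StatsParams:
    alpha: float = 0.05
    bootstrap_B: int = 1999

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.bootstrap_B < 0:
            raise ConfigError("bootstrap_B must be nonnegative")


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to rerun a study end to end."""

    mode: str = "simulate"  # "simulate" | "files"
    seed: int = 0
    out_dir: str = "runcna_out"
    speeds: tuple[int, ...] = (10, 12, 14)
    # simulate mode
    n_participants: int = 23
    n_strides: int = 40
    planted_rho: float = -0.6
    planted_x: str = "Kflex_ecc"
    planted_muscle: str = "BF"
    # files mode
    participants: tuple[dict, ...] = ()
    isokinetic_csv: str | None = None
    processing: ProcessingParams = field(default_factory=ProcessingParams)
    stats: StatsParams = field(default_factory=StatsParams)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate" and self.n_participants < 3:
            raise ConfigError("need at least 3 simulated participants")
        if not -1.0 <= self.planted_rho <= 1.0:
            raise ConfigError("planted correlation must lie in [-1, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["speeds"] = list(self.speeds)
        d["participants"] = list(self.participants)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        raw = dict(raw)
        proc = ProcessingParams(**raw.pop("processing", {}))
        st = StatsParams(**raw.pop("stats", {}))
        if "speeds" in raw:
            raw["speeds"] = tuple(int(s) for s in raw["speeds"])
        if "participants" in raw:
            raw["participants"] = tuple(raw["participants"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(processing=proc, stats=st, **raw)


# ---------------------------------------------------------------------------
# Stage processing shared by both modes
# ---------------------------------------------------------------------------

def process_running_trial(grf: ForceTrace, emg_traces: dict[str, EmgTrace],
                          speed_kmh: float, proc: ProcessingParams) -> dict[str, float]:
    """One participant × speed: vGRF → cycles → per-muscle CNA columns."""
    filtered = gait_mod.lowpass_vgrf(grf, proc.grf_cutoff_hz, proc.grf_filter_order)
    events = gait_mod.detect_contacts(
        filtered, proc.contact_threshold_N, proc.min_contact_s, proc.min_flight_s
    )
    cycles = gait_mod.select_cycles(events, k=proc.k_cycles)
    sf = gait_mod.trial_stride_frequency(events, cycles)
    row: dict[str, float] = {f"stride_freq_{int(speed_kmh)}": sf}
    for muscle, trace in emg_traces.items():
        band = emg_mod.bandpass_emg(trace, proc.emg_low_hz, proc.emg_high_hz,
                                    proc.emg_filter_order)
        rect = emg_mod.rectify(band)
        res = emg_mod.cna_result(rect, cycles, sf, speed_kmh)
        row[cna_column(muscle, int(speed_kmh))] = res.cna
        row[iemg_column(muscle, int(speed_kmh))] = res.mean_iemg
    return row


def process_imtp_trials(traces: list[ImtpTrace],
                        proc: ProcessingParams) -> dict[str, float]:
    """Best-of-trials IMTP metrics as cohort columns."""
    results = []
    for i, imtp in enumerate(traces):
        onset = strength_mod.imtp_onset(imtp, proc.imtp_k_sd, proc.imtp_baseline_s)
        results.append(strength_mod.imtp_metrics(imtp, onset, trial_index=i))
    best = strength_mod.select_best_trial(results)
    row = {"PF_rel": best.relative_pf}
    for w in RFD_WINDOWS_MS:
        row[f"RFD_0_{w}"] = best.rfd[w]
    return row


# ---------------------------------------------------------------------------
# Simulated study (the slow path: full signals through the full pipeline)
# ---------------------------------------------------------------------------

_ISO_SPECS = {
    # variable -> (joint, muscle_group, action, mean rel PT, sd)
    "Kflex_con": ("knee", "flexor", "concentric", 1.4, 0.25),
    "Kex_con": ("knee", "extensor", "concentric", 2.6, 0.45),
    "Kflex_ecc": ("knee", "flexor", "eccentric", 2.0, 0.35),
    "Kex_ecc": ("knee", "extensor", "eccentric", 3.2, 0.55),
    "Adors_con": ("ankle", "dorsiflexor", "concentric", 0.45, 0.10),
    "Aplan_con": ("ankle", "plantarflexor", "concentric", 1.3, 0.25),
    "Adors_ecc": ("ankle", "dorsiflexor", "eccentric", 0.55, 0.12),
    "Aplan_ecc": ("ankle", "plantarflexor", "eccentric", 1.6, 0.30),
}


def _simulate_participant(pid: str, seed_seq: np.random.SeedSequence,
                          config: StudyConfig) -> dict[str, float]:
    """Generate one participant's signals and push them through the pipeline.

    A latent activation scale for the planted muscle is correlated (at
    ``planted_rho``) with the planted strength variable's z-score, so the
    processed cohort carries the planted association.
    """
    rng = np.random.default_rng(seed_seq)
    proc = config.processing
    row: dict[str, float] = {"participant": pid}

    body_mass = float(np.clip(rng.normal(72.3, 10.3), 50.0, 110.0))
    row["body_mass_kg"] = body_mass
    row["ffm_kg"] = body_mass * float(np.clip(rng.normal(0.85, 0.03), 0.75, 0.95))

    # latent bivariate draw: planted strength z and planted-muscle activation z
    rho = config.planted_rho
    z1, z2 = rng.standard_normal(2)
    strength_z = z1
    act_z = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * z2

    # --- isokinetic: 5 reps per variable, best rep = planted value
    for var, (joint, group, action, mu, sd) in _ISO_SPECS.items():
        z = strength_z if var == config.planted_x else rng.standard_normal()
        rel_pt = max(0.1, mu + sd * z)
        pt = rel_pt * body_mass
        reps = pt * (1.0 - rng.uniform(0.0, 0.06, size=4))
        reps = np.append(reps, pt)
        record = strength_mod.isokinetic_relative_pt(reps, body_mass, joint,
                                                     group, action)
        row[var] = record.relative_pt

    # --- running trials at each speed
    amp_scale = {m: float(np.exp(0.25 * rng.standard_normal())) for m in MUSCLES}
    amp_scale[config.planted_muscle] = float(np.exp(0.25 * act_z))
    for speed in config.speeds:
        env = {m: dict(DEFAULT_ENVELOPES[m]) for m in MUSCLES}
        for m in MUSCLES:
            env[m]["amplitude_uV"] *= amp_scale[m]
        tc_jitter = float(rng.normal(1.0, 0.02))
        base = run_spec_for_speed(float(speed))
        spec = dataclasses.replace(
            base,
            contact_time_s=base.contact_time_s * tc_jitter,
            flight_time_s=base.flight_time_s * float(rng.normal(1.0, 0.02)),
            n_strides=config.n_strides,
            envelope_spec=env,
            noise_sd=5.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        grf, gt = gen_vgrf(spec, body_mass)
        emg_traces, _ = gen_emg(spec, gt)
        row.update(process_running_trial(grf, emg_traces, float(speed), proc))

    # --- IMTP: two trials, rise rate tied to its own latent
    rfd_z = rng.standard_normal()
    imtp_rows = []
    for _ in range(2):
        rise = max(1500.0, 6000.0 + 1500.0 * rfd_z + rng.normal(0.0, 300.0))
        plateau = body_mass * GRAVITY * float(np.clip(rng.normal(2.2, 0.2), 1.5, 3.0))
        trace, _ = gen_imtp(body_mass, baseline_s=2.0, rise_rate=rise,
                            plateau_force=plateau, noise_sd=8.0,
                            seed=int(rng.integers(0, 2**31 - 1)), shape="sigmoid")
        imtp_rows.append(ImtpTrace(trace, body_mass, (0.0, 2.0),
                                   ffm_kg=row["ffm_kg"]))
    row.update(process_imtp_trials(imtp_rows, proc))
    return row


def build_cohort(config: StudyConfig) -> pd.DataFrame:
    """Assemble the participant-level cohort table for either mode."""
    if config.mode == "simulate":
        seeds = np.random.SeedSequence(config.seed).spawn(config.n_participants)
        rows = [
            _simulate_participant(f"P{i + 1:02d}", ss, config)
            for i, ss in enumerate(seeds)
        ]
        return pd.DataFrame(rows)
    return _build_cohort_from_files(config)


def _build_cohort_from_files(config: StudyConfig) -> pd.DataFrame:
    proc = config.processing
    iso = pd.read_csv(config.isokinetic_csv, comment="#") if config.isokinetic_csv else None
    rows = []
    for part in config.participants:
        pid = part["id"]
        try:
            row: dict[str, float] = {"participant": pid,
                                     "body_mass_kg": float(part["body_mass_kg"])}
            if "ffm_kg" in part:
                row["ffm_kg"] = float(part["ffm_kg"])
            for speed in config.speeds:
                key = str(speed)
                if key not in part.get("grf", {}) or key not in part.get("emg", {}):
                    raise ConfigError(f"missing trace file for speed {speed}")
                grf = read_timeseries(part["grf"][key])
                emg_traces = read_timeseries(part["emg"][key])
                if not isinstance(grf, ForceTrace) or isinstance(emg_traces, ForceTrace):
                    raise ConfigError("grf file must hold fz_N; emg file muscle channels")
                row.update(process_running_trial(grf, emg_traces, float(speed), proc))
            imtp_traces = []
            for path in part.get("imtp", []):
                trace = read_timeseries(path)
                if not isinstance(trace, ForceTrace):
                    raise ConfigError("IMTP file must hold a single fz_N channel")
                imtp_traces.append(
                    ImtpTrace(trace, row["body_mass_kg"], (0.0, 2.0),
                              ffm_kg=row.get("ffm_kg"))
                )
            if imtp_traces:
                row.update(process_imtp_trials(imtp_traces, proc))
            if iso is not None:
                for (joint, group, action), grp in iso[iso["participant"] == pid].groupby(
                        ["joint", "muscle_group", "action"]):
                    rec = strength_mod.isokinetic_relative_pt(
                        grp["torque_Nm"].to_numpy(), row["body_mass_kg"],
                        joint, group, action)
                    row[_iso_var_name(joint, group, action)] = rec.relative_pt
            rows.append(row)
        except Exception as exc:  # re-raise with stage context per contract
            raise ConfigError(f"participant {pid}: {exc}") from exc
    return pd.DataFrame(rows)


def _iso_var_name(joint: str, group: str, action: str) -> str:
    prefix = {"knee": "K", "ankle": "A"}[joint]
    grp = {"flexor": "flex", "extensor": "ex",
           "dorsiflexor": "dors", "plantarflexor": "plan"}[group]
    act = {"concentric": "con", "eccentric": "ecc"}[action]
    return f"{prefix}{grp}_{act}"


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path, stamp: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: StudyConfig) -> dict[str, object]:
    """Run the whole study and write cohort, results, heatmaps and a run log.

    Deterministic given the configuration (stage seeds fan out from the
    config seed), so a rerun with the same config is byte-identical.
    """
    out_dir = Path(config.out_dir)
    stamp = f"runcna v{__version__} config_sha256={config.config_hash()}"

    cohort = build_cohort(config)
    design = stats_mod.default_design(config.speeds)
    results = stats_mod.correlation_study(
        cohort, design, alpha=config.stats.alpha,
        bootstrap_B=config.stats.bootstrap_B, seed=config.seed,
    )
    variants = stats_mod.sensitivity_variants(
        cohort, design, alpha=config.stats.alpha, bootstrap_B=0, seed=config.seed,
    )

    _write_csv(cohort, out_dir / "cohort.csv", stamp)
    _write_csv(results, out_dir / "results.csv", stamp)
    for name, table in variants.items():
        if name == "main":
            continue
        _write_csv(table, out_dir / f"sensitivity_{name}.csv", stamp)
    for (family, speed), matrix in stats_mod.heatmap_matrices(results).items():
        _write_csv(matrix.reset_index(),
                   out_dir / f"heatmap_{family}_{int(speed)}.csv", stamp)

    log = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_participants": int(cohort.shape[0]),
        "bh_family_sizes": {fam.family_id: len(fam.pairs) for fam in design},
        "min_detectable_r": round(
            stats_mod.min_detectable_r(cohort.shape[0], config.stats.alpha, 0.80), 2
        ),
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return {"cohort": cohort, "results": results, "variants": variants, "log": log}
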