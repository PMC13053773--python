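"""Seeded synthetic signals and cohorts with known ground truth.

Every generator here exists so that the downstream processing stages have an
oracle: vertical ground-reaction force (vGRF) traces whose 50 N crossings are
known exactly, EMG whose expected rectified amplitude is known in closed form,
isometric mid-thigh pull (IMTP) traces with a known force onset and ramp
slope, and participant cohorts with planted correlation structure.

Signal model
------------
* vGRF stance phases are a sum of two raised-cosine bumps (an early impact
  transient and a mid-stance active peak) riding on the 50 N contact
  threshold, so the noise-free trace crosses 50 N exactly at the stance
  boundaries and is zero in flight.
* EMG is white Gaussian noise band-limited to 20–400 Hz, scaled to unit
  variance and amplitude-modulated by a phase-locked per-cycle envelope.  For
  a Gaussian carrier the expected rectified amplitude under the envelope is
  ``amplitude × sqrt(2/π)``, which gives a closed-form expected iEMG per
  cycle.
* IMTP traces hold body weight for a quiet-standing baseline, then rise
  (linearly or sigmoidally) to a plateau.

All randomness flows from the explicit ``seed`` of each call; there is no
hidden global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InvalidSpecError
from .types import GRAVITY, MUSCLES, EmgTrace, ForceTrace

CONTACT_THRESHOLD_N = 50.0

#: Default burst envelopes (cycle phase 0 = contact onset).  Quadriceps and
#: triceps surae burst during stance, biceps femoris in late swing, tibialis
#: anterior around swing–contact transition.  Amplitudes are plausible
#: un-normalised surface-EMG scales in μV.
DEFAULT_ENVELOPES: dict[str, dict[str, float]] = {
    "VL": {"phase_center": 0.12, "phase_width": 0.35, "amplitude_uV": 120.0},
    "VM": {"phase_center": 0.12, "phase_width": 0.35, "amplitude_uV": 110.0},
    "RF": {"phase_center": 0.15, "phase_width": 0.40, "amplitude_uV": 80.0},
    "BF": {"phase_center": 0.85, "phase_width": 0.30, "amplitude_uV": 90.0},
    "GM": {"phase_center": 0.25, "phase_width": 0.40, "amplitude_uV": 130.0},
    "GL": {"phase_center": 0.25, "phase_width": 0.40, "amplitude_uV": 100.0},
    "SOL": {"phase_center": 0.28, "phase_width": 0.45, "amplitude_uV": 140.0},
    "TA": {"phase_center": 0.95, "phase_width": 0.30, "amplitude_uV": 85.0},
}

#: Contact/flight durations emulating treadmill running at the three study
#: speeds (contact time shortens and flight lengthens with speed; contact
#: stays ≤ 250 ms).
SPEED_PRESETS: dict[float, tuple[float, float]] = {
    10.0: (0.245, 0.095),
    12.0: (0.220, 0.115),
    14.0: (0.200, 0.130),
}


@dataclass(frozen=True)
class SyntheticRunSpec:
    """Parameters of one synthetic treadmill-running trial."""

    speed_kmh: float
    contact_time_s: float
    flight_time_s: float
    n_strides: int
    grf_rate: float = 1000.0
    emg_rate: float = 2000.0
    peak_force_bw: float = 2.5  # multiples of body weight
    envelope_spec: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_ENVELOPES.items()}
    )
    noise_sd: float = 0.0  # N, added to the vGRF
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_kmh <= 0:
            raise InvalidSpecError("speed must be positive")
        if self.contact_time_s <= 0:
            raise InvalidSpecError("contact time must be positive")
        if self.flight_time_s < 0:
            raise InvalidSpecError("flight time must be nonnegative")
        if self.contact_time_s + self.flight_time_s <= 0:
            raise InvalidSpecError("cycle duration must be positive")
        if self.n_strides < 0:
            raise InvalidSpecError("n_strides must be nonnegative")
        if self.grf_rate <= 0 or self.emg_rate <= 0:
            raise InvalidSpecError("sampling rates must be positive")
        if self.peak_force_bw <= 0:
            raise InvalidSpecError("peak force must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise SD must be nonnegative")
        for muscle, env in self.envelope_spec.items():
            if muscle not in MUSCLES:
                raise InvalidSpecError(f"unknown muscle {muscle!r}")
            if not 0.0 <= env["phase_center"] < 1.0:
                raise InvalidSpecError(
                    f"{muscle}: phase_center must lie in [0, 1), got {env['phase_center']}"
                )
            if env["phase_width"] <= 0:
                raise InvalidSpecError(f"{muscle}: phase_width must be positive")
            if env["amplitude_uV"] < 0:
                raise InvalidSpecError(f"{muscle}: amplitude must be nonnegative")

    @property
    def cycle_s(self) -> float:
        return self.contact_time_s + self.flight_time_s

    @property
    def true_stride_frequency(self) -> float:
        """Ground-truth stride frequency 60 / (T_c + T_f), strides·min⁻¹."""
        return 60.0 / self.cycle_s


def run_spec_for_speed(speed_kmh: float, *, n_strides: int = 40, noise_sd: float = 0.0,
                       seed: int = 0, **overrides) -> SyntheticRunSpec:
    """Build a :class:`SyntheticRunSpec` from the per-speed presets."""
    if speed_kmh not in SPEED_PRESETS:
        raise InvalidSpecError(
            f"no preset for {speed_kmh} km/h; presets exist for {sorted(SPEED_PRESETS)}"
        )
    tc, tf = SPEED_PRESETS[speed_kmh]
    return SyntheticRunSpec(
        speed_kmh=speed_kmh, contact_time_s=tc, flight_time_s=tf,
        n_strides=n_strides, noise_sd=noise_sd, seed=seed, **overrides,
    )


@dataclass
class GroundTruth:
    """Known-by-construction quantities attached to a synthetic signal."""

    contact_onsets: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    contact_offsets: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    rate: float = 1000.0
    true_contact_time_s: float = float("nan")
    true_flight_time_s: float = float("nan")
    true_stride_frequency: float = float("nan")
    true_iemg_per_cycle: dict[str, np.ndarray] = field(default_factory=dict)
    true_onset_index: int | None = None
    true_rfd_per_window: dict[int, float] = field(default_factory=dict)
    planted_rho: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        on, off = self.contact_onsets, self.contact_offsets
        if on.size != off.size:
            raise InvalidSpecError("onsets and offsets must pair up")
        if on.size:
            if np.any(off <= on):
                raise InvalidSpecError("each offset must follow its onset")
            if np.any(np.diff(on) <= 0) or np.any(on[1:] <= off[:-1]):
                raise InvalidSpecError("events must strictly alternate onset/offset")

    def onset_times(self) -> np.ndarray:
        return self.contact_onsets / self.rate


def _stance_shape(u: np.ndarray, impact_weight: float = 0.35,
                  impact_center: float = 0.125, impact_width: float = 0.25) -> np.ndarray:
    """Normalised two-bump stance profile on u ∈ [0, 1]; zero at both ends."""
    active = 0.5 * (1.0 + np.cos(2.0 * np.pi * (u - 0.5)))
    d = u - impact_center
    impact = np.where(
        np.abs(d) < impact_width / 2.0,
        0.5 * (1.0 + np.cos(2.0 * np.pi * d / impact_width)),
        0.0,
    )
    shape = active + impact_weight * impact
    # normalise peak to 1 using a dense grid (peak location depends on weights)
    uu = np.linspace(0.0, 1.0, 2001)
    aa = 0.5 * (1.0 + np.cos(2.0 * np.pi * (uu - 0.5)))
    dd = uu - impact_center
    ii = np.where(np.abs(dd) < impact_width / 2.0,
                  0.5 * (1.0 + np.cos(2.0 * np.pi * dd / impact_width)), 0.0)
    return shape / np.max(aa + impact_weight * ii)


def gen_vgrf(spec: SyntheticRunSpec, body_mass: float,
             pad_s: float = 0.05) -> tuple[ForceTrace, GroundTruth]:
    """Generate a synthetic vGRF trace with exactly known contact events.

    Stance segments ride on the 50 N threshold and peak at
    ``peak_force_bw × body weight``; flight is zero force.  Gaussian noise of
    ``spec.noise_sd`` is added on top.  Ground-truth onsets/offsets are the
    50 N crossings of the noise-free trace.
    """
    if body_mass <= 0:
        raise InvalidSpecError("body mass must be positive")
    rate = spec.grf_rate
    if spec.n_strides == 0:
        return ForceTrace(np.array([]), rate), GroundTruth(rate=rate)

    cycle = spec.cycle_s
    duration = 2 * pad_s + spec.n_strides * cycle
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    clean = np.zeros(n)
    peak = spec.peak_force_bw * body_mass * GRAVITY
    if peak <= CONTACT_THRESHOLD_N:
        raise InvalidSpecError("peak force must exceed the 50 N contact threshold")
    for k in range(spec.n_strides):
        start = pad_s + k * cycle
        mask = (t >= start) & (t < start + spec.contact_time_s)
        u = (t[mask] - start) / spec.contact_time_s
        clean[mask] = CONTACT_THRESHOLD_N + (peak - CONTACT_THRESHOLD_N) * _stance_shape(u)

    # rising edge at i means sample i+1 is the first strictly above threshold
    above = clean > CONTACT_THRESHOLD_N
    step = np.diff(above.astype(np.int8))
    rising = np.flatnonzero(step == 1) + 1
    falling = np.flatnonzero(step == -1) + 1

    rng = np.random.default_rng(spec.seed)
    samples = clean + (rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else 0.0)

    gt = GroundTruth(
        contact_onsets=rising.astype(int),
        contact_offsets=falling.astype(int),
        rate=rate,
        true_contact_time_s=spec.contact_time_s,
        true_flight_time_s=spec.flight_time_s,
        true_stride_frequency=spec.true_stride_frequency,
    )
    return ForceTrace(samples, rate), gt


def _envelope(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine burst on cycle phase with wrap-around; constant for width ≥ 1."""
    if width >= 1.0:
        return np.ones_like(phase)
    d = np.remainder(phase - center + 0.5, 1.0) - 0.5
    return np.where(np.abs(d) < width / 2.0,
                    0.5 * (1.0 + np.cos(2.0 * np.pi * d / width)), 0.0)


def _band_limited_carrier(n: int, rate: float, rng: np.random.Generator,
                          low: float = 20.0, high: float = 400.0) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to the EMG analysis band."""
    x = rng.standard_normal(n)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, x)
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_emg(spec: SyntheticRunSpec, events: GroundTruth,
            muscles: tuple[str, ...] | None = None) -> tuple[dict[str, EmgTrace], GroundTruth]:
    """Generate phase-locked EMG for each muscle, given vGRF ground truth.

    Returns the per-muscle traces and the same ``events`` object with
    ``true_iemg_per_cycle`` filled in (expected iEMG per gait cycle,
    ``amplitude × sqrt(2/π) × ∫envelope dt``, in μV·s).
    """
    if events.contact_onsets.size == 0:
        raise InvalidSpecError("events must contain at least one contact")
    muscles = muscles or tuple(spec.envelope_spec)
    onsets_s = events.contact_onsets / events.rate
    cycle = spec.cycle_s
    # cycle k spans [onset_k, onset_{k+1}); the final contact starts the last
    # cycle, closed with the nominal cycle duration
    cycle_starts = onsets_s
    cycle_ends = np.append(onsets_s[1:], onsets_s[-1] + cycle)

    duration = cycle_ends[-1] + 0.05
    n = int(round(duration * spec.emg_rate))
    t = np.arange(n) / spec.emg_rate

    phase = np.zeros(n)
    in_cycle = np.zeros(n, dtype=bool)
    for s, e in zip(cycle_starts, cycle_ends):
        m = (t >= s) & (t < e)
        phase[m] = (t[m] - s) / (e - s)
        in_cycle[m] = True

    child_seeds = np.random.SeedSequence(spec.seed).spawn(len(muscles))
    traces: dict[str, EmgTrace] = {}
    for muscle, ss in zip(muscles, child_seeds):
        env_spec = spec.envelope_spec[muscle]
        rng = np.random.default_rng(ss)
        amp = env_spec["amplitude_uV"]
        if amp == 0.0:
            samples = np.zeros(n)
        else:
            carrier = _band_limited_carrier(n, spec.emg_rate, rng)
            env = amp * _envelope(phase, env_spec["phase_center"], env_spec["phase_width"])
            env[~in_cycle] = 0.0
            samples = carrier * env
        traces[muscle] = EmgTrace(samples, spec.emg_rate, muscle)

        width = min(env_spec["phase_width"], 1.0)
        env_integral_frac = 1.0 if env_spec["phase_width"] >= 1.0 else width / 2.0
        durations = cycle_ends - cycle_starts
        events.true_iemg_per_cycle[muscle] = (
            amp * math.sqrt(2.0 / math.pi) * env_integral_frac * durations
        )
    return traces, events


def gen_imtp(body_mass: float, baseline_s: float = 2.0, rise_rate: float = 6000.0,
             plateau_force: float | None = None, noise_sd: float = 5.0, seed: int = 0,
             rate: float = 1000.0, pull_s: float = 5.0,
             shape: str = "linear") -> tuple[ForceTrace, GroundTruth]:
    """Generate a synthetic IMTP force trace.

    ``baseline_s`` of quiet standing at body weight, then a rise to
    ``plateau_force`` (default 2.2 × body weight) that is either linear at
    ``rise_rate`` N·s⁻¹ or a logistic sigmoid whose maximum slope equals
    ``rise_rate``.  Ground truth: onset = first noise-free sample exceeding
    body weight + 5 × ``noise_sd``; RFD windows computed on the noise-free
    trace anchored at that onset.
    """
    if body_mass <= 0:
        raise InvalidSpecError("body mass must be positive")
    if baseline_s < 0.5:
        raise InvalidSpecError("baseline must be at least 0.5 s to estimate its SD")
    if rise_rate <= 0:
        raise InvalidSpecError("rise rate must be positive")
    bw = body_mass * GRAVITY
    plateau = 2.2 * bw if plateau_force is None else plateau_force
    if plateau <= bw:
        raise InvalidSpecError("plateau force must exceed body weight")
    if shape not in ("linear", "sigmoid"):
        raise InvalidSpecError(f"unknown rise shape {shape!r}")

    n = int(round((baseline_s + pull_s) * rate))
    t = np.arange(n) / rate
    if shape == "linear":
        clean = bw + np.clip(rise_rate * (t - baseline_s), 0.0, plateau - bw)
    else:
        # logistic with max slope = rise_rate at its midpoint
        tau = (plateau - bw) / (4.0 * rise_rate)
        mid = baseline_s + 6.0 * tau
        clean = bw + (plateau - bw) / (1.0 + np.exp(-(t - mid) / tau))
        clean[t < baseline_s] = bw  # quiet standing is exactly body weight

    threshold = bw + 5.0 * noise_sd
    above = clean > threshold
    idx = np.flatnonzero(above)
    true_onset = int(idx[0]) if idx.size else None

    gt = GroundTruth(rate=rate, true_onset_index=true_onset)
    if true_onset is not None:
        # RFD anchored at the last sample at/below threshold (the crossing),
        # matching the analysis convention
        anchor = max(true_onset - 1, 0)
        f0 = clean[anchor]
        for w_ms in (50, 100, 150, 200, 250):
            j = anchor + int(round(w_ms * rate / 1000.0))
            if j < n:
                gt.true_rfd_per_window[w_ms] = (clean[j] - f0) / (w_ms / 1000.0)

    rng = np.random.default_rng(seed)
    samples = clean + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0)
    return ForceTrace(samples, rate), gt


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """A participant table drawn from a multivariate normal with a planted
    correlation structure."""

    n_participants: int
    variable_names: tuple[str, ...]
    correlation_matrix: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.correlation_matrix, dtype=float)
        object.__setattr__(self, "correlation_matrix", r)
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        k = len(self.variable_names)
        if self.n_participants <= 0:
            raise InvalidSpecError("n_participants must be positive")
        if r.shape != (k, k):
            raise InvalidSpecError("correlation matrix shape must match variables")
        if self.means.shape != (k,) or self.sds.shape != (k,):
            raise InvalidSpecError("means/sds must match variables")
        if not np.allclose(r, r.T):
            raise InvalidSpecError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise InvalidSpecError("correlation matrix diagonal must be 1")
        if np.any(np.abs(r) > 1.0 + 1e-12):
            raise InvalidSpecError("correlations must lie in [-1, 1]")
        if np.min(np.linalg.eigvalsh(r)) < -1e-8:
            raise InvalidSpecError("correlation matrix must be positive semidefinite")
        if np.any(self.sds < 0):
            raise InvalidSpecError("SDs must be nonnegative")


def gen_cohort(spec: SyntheticCohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a participant table with the requested correlation structure."""
    d = np.diag(spec.sds)
    cov = d @ spec.correlation_matrix @ d
    rng = np.random.default_rng(spec.seed)
    values = rng.multivariate_normal(spec.means, cov, size=spec.n_participants,
                                     method="svd")
    table = pd.DataFrame(values, columns=list(spec.variable_names))
    table.insert(0, "participant", [f"P{i + 1:02d}" for i in range(spec.n_participants)])
    gt = GroundTruth()
    k = len(spec.variable_names)
    for i in range(k):
        for j in range(i + 1, k):
            rho = spec.correlation_matrix[i, j]
            if rho != 0.0:
                gt.planted_rho[(spec.variable_names[i], spec.variable_names[j])] = float(rho)
    return table, gt


# ---------------------------------------------------------------------------
# Study-shaped cohort: the full strength × CNA column layout with one planted
# correlation, used for parameter-recovery experiments.
# ---------------------------------------------------------------------------

ISOKINETIC_VARS = (
    "Kflex_con", "Kex_con", "Kflex_ecc", "Kex_ecc",
    "Adors_con", "Aplan_con", "Adors_ecc", "Aplan_ecc",
)
IMTP_VARS = ("PF_rel", "RFD_0_50", "RFD_0_100", "RFD_0_150", "RFD_0_200", "RFD_0_250")
SPEEDS = (10, 12, 14)

#: Realistic means/SDs for recreational male runners: relative PT in
#: N·m·kg⁻¹, relative PF in N·kg⁻¹, RFD in N·s⁻¹, CNA in μV·s·min⁻¹.
_STRENGTH_MOMENTS = {
    "Kflex_con": (1.4, 0.25), "Kex_con": (2.6, 0.45),
    "Kflex_ecc": (2.0, 0.35), "Kex_ecc": (3.2, 0.55),
    "Adors_con": (0.45, 0.10), "Aplan_con": (1.3, 0.25),
    "Adors_ecc": (0.55, 0.12), "Aplan_ecc": (1.6, 0.30),
    "PF_rel": (32.0, 5.0),
    "RFD_0_50": (5000.0, 1500.0), "RFD_0_100": (6500.0, 1800.0),
    "RFD_0_150": (6000.0, 1600.0), "RFD_0_200": (5200.0, 1400.0),
    "RFD_0_250": (4500.0, 1200.0),
}
_CNA_MOMENTS = (2800.0, 700.0)  # μV·s·min⁻¹
_SF_MOMENTS = (176.0, 6.0)  # strides·min⁻¹


def cna_column(muscle: str, speed: int) -> str:
    return f"{muscle}_cna_{speed}"


def iemg_column(muscle: str, speed: int) -> str:
    return f"{muscle}_iemg_{speed}"


def planted_cohort(n: int = 23, rho: float = -0.6, x_name: str = "Kflex_ecc",
                   y_name: str | None = None, seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Full study-shaped cohort with one planted strength–CNA correlation.

    All strength variables and all CNA columns are drawn independently except
    the pair (``x_name``, ``y_name``), which carries correlation ``rho``.
    Per-cycle iEMG columns are derived as CNA / stride frequency (stride
    frequency varies independently across participants), so the planted
    association propagates to the per-cycle variant with the same sign.
    """
    y_name = y_name or cna_column("BF", 12)
    variables = list(ISOKINETIC_VARS) + list(IMTP_VARS)
    cna_cols = [cna_column(m, s) for s in SPEEDS for m in MUSCLES]
    variables += cna_cols
    k = len(variables)
    r = np.eye(k)
    ix, iy = variables.index(x_name), variables.index(y_name)
    r[ix, iy] = r[iy, ix] = rho
    means = np.array([
        _STRENGTH_MOMENTS[v][0] if v in _STRENGTH_MOMENTS else _CNA_MOMENTS[0]
        for v in variables
    ])
    sds = np.array([
        _STRENGTH_MOMENTS[v][1] if v in _STRENGTH_MOMENTS else _CNA_MOMENTS[1]
        for v in variables
    ])
    spec = SyntheticCohortSpec(n, tuple(variables), r, means, sds, seed=seed)
    table, gt = gen_cohort(spec)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0F]))
    sf = rng.normal(*_SF_MOMENTS, size=n)
    table["stride_freq_spm"] = sf
    for col in cna_cols:
        muscle, _, speed = col.partition("_cna_")
        table[iemg_column(muscle, int(speed))] = table[col] / sf
    table["body_mass_kg"] = rng.normal(72.3, 10.3, size=n).clip(min=45.0)
    table["ffm_kg"] = table["body_mass_kg"] * rng.normal(0.85, 0.03, size=n).clip(0.7, 0.95)
    return table, gt
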