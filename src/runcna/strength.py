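"""Strength metrics: IMTP force-time characteristics and isokinetic relative
peak torque.

The isometric mid-thigh pull (IMTP) trace holds quiet standing (body weight
only) followed by a maximal pull.  Force onset is the first sustained
crossing of baseline mean + 5 baseline SDs; peak force (PF) and rate of force
development RFD = ΔForce/ΔTime over fixed windows 0–50 … 0–250 ms after
onset are then read off the curve.  The windows correspond to the ground
contact times of submaximal running.  Isokinetic records reduce to the
highest peak torque across repetitions, divided by body mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError, OnsetNotFoundError
from .types import ForceTrace

RFD_WINDOWS_MS = (50, 100, 150, 200, 250)

ISOKINETIC_JOINTS = ("knee", "ankle")
ISOKINETIC_GROUPS = ("flexor", "extensor", "dorsiflexor", "plantarflexor")
ISOKINETIC_ACTIONS = ("concentric", "eccentric")


@dataclass(frozen=True)
class ImtpTrace:
    """An IMTP force trace (summed dual-plate vertical force) plus metadata."""

    trace: ForceTrace
    body_mass: float  # kg
    standing_window: tuple[float, float]  # (start_s, end_s) of quiet standing
    ffm_kg: float | None = None  # optional fat-free mass for normalisation

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise InvalidParameterError("body mass must be positive")
        start, end = self.standing_window
        if end - start < 0.5:
            raise InvalidParameterError("standing window must span at least 0.5 s")
        if start < 0 or end > self.trace.duration:
            raise InvalidParameterError("standing window must lie within the trace")


@dataclass(frozen=True)
class ImtpResult:
    baseline_mean: float  # N
    baseline_sd: float  # N
    onset_index: int
    pf: float  # N
    relative_pf: float  # N·kg⁻¹
    rfd: dict[int, float]  # window (ms) → N·s⁻¹
    rfd_relative: dict[int, float] = field(default_factory=dict)  # N·s⁻¹·kg⁻¹
    relative_pf_ffm: float | None = None  # N·kg⁻¹ fat-free mass
    trial_index: int = 0


@dataclass(frozen=True)
class IsokineticRecord:
    joint: str
    muscle_group: str
    action: str
    pt: float  # N·m
    body_mass: float  # kg
    relative_pt: float  # N·m·kg⁻¹

    def __post_init__(self) -> None:
        if self.joint not in ISOKINETIC_JOINTS:
            raise InvalidParameterError(f"unknown joint {self.joint!r}")
        if self.muscle_group not in ISOKINETIC_GROUPS:
            raise InvalidParameterError(f"unknown muscle group {self.muscle_group!r}")
        if self.action not in ISOKINETIC_ACTIONS:
            raise InvalidParameterError(f"unknown action {self.action!r}")
        if self.pt < 0:
            raise InvalidParameterError("peak torque must be nonnegative")


def imtp_onset(imtp: ImtpTrace, k_sd: float = 5.0, baseline_s: float = 1.0,
               sustain_s: float = 0.010) -> tuple[int, float, float]:
    """Force onset: first sustained crossing of baseline mean + ``k_sd``·SD.

    The baseline is the last ``baseline_s`` of the quiet-standing window
    (avoiding settling transients); its mean is the measured body weight.  A
    crossing counts only if the force stays above threshold for at least
    ``sustain_s`` (guards against single-sample noise spikes).
    """
    rate = imtp.trace.rate
    samples = imtp.trace.samples
    start_s, end_s = imtp.standing_window
    b_start = max(start_s, end_s - baseline_s)
    i0, i1 = int(round(b_start * rate)), int(round(end_s * rate))
    baseline = samples[i0:i1]
    if baseline.size < int(0.5 * rate):
        raise InvalidParameterError("baseline window shorter than 0.5 s")
    mean, sd = float(np.mean(baseline)), float(np.std(baseline, ddof=1))

    threshold = mean + k_sd * sd
    sustain = max(1, int(round(sustain_s * rate)))
    after = samples[i1:]
    above = after > threshold
    if not above.any():
        raise OnsetNotFoundError("force never exceeded the onset threshold")
    # first index where a run of `sustain` consecutive samples is above
    if sustain > 1:
        window_ok = np.convolve(above.astype(int), np.ones(sustain, dtype=int),
                                mode="valid") == sustain
        idx = np.flatnonzero(window_ok)
    else:
        idx = np.flatnonzero(above)
    if idx.size == 0:
        raise OnsetNotFoundError("no sustained crossing of the onset threshold")
    return i1 + int(idx[0]), mean, sd


def imtp_metrics(imtp: ImtpTrace, onset: tuple[int, float, float] | None = None,
                 trial_index: int = 0) -> ImtpResult:
    """Peak force and windowed RFD anchored at the detected onset.

    RFD(0–w) = (F(anchor + w) − F(anchor)) / w with the anchor one sample
    before the onset index — the last sample at or below the threshold — so
    the window origin sits on the threshold crossing itself and the force at
    that point is subtracted (invariant to constant offsets).
    """
    if onset is None:
        onset = imtp_onset(imtp)
    onset_index, mean, sd = onset
    rate = imtp.trace.rate
    samples = imtp.trace.samples
    anchor = max(onset_index - 1, 0)
    max_window = max(RFD_WINDOWS_MS) / 1000.0
    if anchor + int(round(max_window * rate)) >= samples.size:
        raise InsufficientDataError(
            f"trace ends {samples.size / rate:.3f} s in; need "
            f"{max_window:.3f} s of data after onset at {onset_index / rate:.3f} s"
        )
    f0 = samples[anchor]
    pf = float(np.max(samples[onset_index:]))
    rfd = {}
    for w_ms in RFD_WINDOWS_MS:
        j = anchor + int(round(w_ms * rate / 1000.0))
        rfd[w_ms] = float((samples[j] - f0) / (w_ms / 1000.0))
    return ImtpResult(
        baseline_mean=mean, baseline_sd=sd, onset_index=onset_index,
        pf=pf, relative_pf=pf / imtp.body_mass, rfd=rfd,
        rfd_relative={w: v / imtp.body_mass for w, v in rfd.items()},
        relative_pf_ffm=(pf / imtp.ffm_kg) if imtp.ffm_kg else None,
        trial_index=trial_index,
    )


def select_best_trial(trials: list[ImtpResult]) -> ImtpResult:
    """The trial with the highest peak force; ties go to the earlier trial."""
    if not trials:
        raise InsufficientDataError("no IMTP trials supplied")
    best = trials[0]
    for trial in trials[1:]:
        if trial.pf > best.pf:
            best = trial
    return best


def isokinetic_relative_pt(reps: list[float] | np.ndarray, body_mass: float,
                           joint: str = "knee", muscle_group: str = "flexor",
                           action: str = "concentric") -> IsokineticRecord:
    """Highest peak torque across repetitions, normalised to body mass."""
    reps = np.asarray(reps, dtype=float)
    if reps.size == 0:
        raise InsufficientDataError("no repetitions supplied")
    if body_mass <= 0:
        raise InvalidParameterError("body mass must be positive")
    pt = float(np.max(reps))
    return IsokineticRecord(
        joint=joint, muscle_group=muscle_group, action=action,
        pt=pt, body_mass=body_mass, relative_pt=pt / body_mass,
    )
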