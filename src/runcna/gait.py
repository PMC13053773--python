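"""Vertical GRF processing: low-pass filtering, contact detection, stride
frequency, and selection of representative gait cycles.

The temporal half of the activation statistic: stride frequency is
``60 / (T_c + T_f)`` with T_c the contact time and T_f the flight time of one
step, so the analysed "gait cycle" runs from one contact onset to the next
contact onset of the instrumented side.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, InvalidParameterError
from .types import ForceTrace, GaitEvents, StrideSet


def lowpass_vgrf(trace: ForceTrace, cutoff: float = 50.0, order: int = 2) -> ForceTrace:
    """Zero-phase (forward–backward) Butterworth low-pass of the vGRF.

    Two passes of an order-``order`` filter, so the magnitude response is
    squared: gain 0.5 at the cutoff for the default order-2 design.
    """
    nyquist = trace.rate / 2.0
    if cutoff <= 0 or cutoff >= nyquist:
        raise InvalidParameterError(
            f"cutoff must lie in (0, {nyquist}) Hz for rate {trace.rate}, got {cutoff}"
        )
    if trace.n == 0:
        return trace
    sos = sps.butter(order, cutoff, btype="low", fs=trace.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, trace.samples)
    return ForceTrace(filtered, trace.rate, trace.start_time)


def detect_contacts(trace: ForceTrace, threshold: float = 50.0,
                    min_contact_s: float = 0.05, min_flight_s: float = 0.02) -> GaitEvents:
    """Detect ground-contact intervals by thresholding the (filtered) vGRF.

    A contact is a maximal run of samples strictly above ``threshold``.
    Debouncing: gaps shorter than ``min_flight_s`` are merged into the
    surrounding contact, then contacts shorter than ``min_contact_s`` are
    dropped.  A signal that never leaves contact yields a single flagged
    contact spanning the trace; a signal that never crosses yields no events.
    """
    if threshold <= 0:
        raise InvalidParameterError("threshold must be positive")
    if trace.n == 0:
        return GaitEvents((), trace.rate)

    above = trace.samples > threshold
    if above.all():
        return GaitEvents(((0, trace.n),), trace.rate, flagged=True)
    if not above.any():
        return GaitEvents((), trace.rate)

    step = np.diff(above.astype(np.int8))
    onsets = list(np.flatnonzero(step == 1) + 1)
    offsets = list(np.flatnonzero(step == -1) + 1)
    if above[0]:
        onsets.insert(0, 0)
    if above[-1]:
        offsets.append(trace.n)

    pairs = list(zip(onsets, offsets))
    # merge flights shorter than the flight debounce window
    min_gap = int(round(min_flight_s * trace.rate))
    merged: list[list[int]] = []
    for on, off in pairs:
        if merged and on - merged[-1][1] < min_gap:
            merged[-1][1] = off
        else:
            merged.append([on, off])
    # drop contacts shorter than the contact debounce window
    min_len = int(round(min_contact_s * trace.rate))
    kept = [(on, off) for on, off in merged if off - on >= min_len]
    return GaitEvents(tuple((int(a), int(b)) for a, b in kept), trace.rate)


def stride_frequency(contact_time_s: float, flight_time_s: float) -> float:
    """Stride frequency 60 / (T_c + T_f) in strides·min⁻¹."""
    total = contact_time_s + flight_time_s
    if total <= 0:
        raise InvalidParameterError("T_c + T_f must be positive")
    return 60.0 / total


def trial_stride_frequency(events: GaitEvents, cycles: StrideSet | None = None) -> float:
    """Per-trial stride frequency: mean of 60 / cycle-duration over cycles.

    With an explicit :class:`StrideSet` the mean runs over the selected
    cycles only; otherwise over every complete onset-to-onset cycle.
    """
    if cycles is not None:
        durations = cycles.durations()
    else:
        bounds = events.cycle_bounds()
        if bounds.shape[0] == 0:
            raise InsufficientDataError("need at least two contacts for a cycle")
        durations = bounds[:, 1] - bounds[:, 0]
    return float(np.mean(60.0 / durations))


def select_cycles(events: GaitEvents, emg_quality: np.ndarray | None = None,
                  k: int = 10, sd_limit: float = 2.0,
                  min_dev_s: float = 0.005) -> StrideSet:
    """Select the first ``k`` valid gait cycles from a trial.

    A cycle (onset to next onset) is excluded when its contact time or total
    duration deviates more than ``sd_limit`` trial SDs from the trial median,
    or when its EMG-quality flag marks an artefact.  This automated rule
    replaces per-stride visual inspection.  Deviations below ``min_dev_s``
    never exclude: when every cycle is nearly identical the trial SD collapses
    to sampling jitter, and ±1-sample timing noise is not an artefact.
    """
    bounds = events.cycle_bounds()
    n_cycles = bounds.shape[0]
    if n_cycles == 0:
        raise InsufficientDataError("no complete gait cycles in trial")
    tc = events.contact_times()[:n_cycles]
    durations = bounds[:, 1] - bounds[:, 0]

    valid = np.ones(n_cycles, dtype=bool)
    for x in (tc, durations):
        med, sd = np.median(x), np.std(x)
        if sd > 0:
            valid &= np.abs(x - med) <= np.maximum(sd_limit * sd, min_dev_s)
    if emg_quality is not None:
        flags = np.asarray(emg_quality, dtype=bool)
        if flags.size != n_cycles:
            raise InvalidParameterError(
                f"emg_quality has {flags.size} flags for {n_cycles} cycles"
            )
        valid &= ~flags

    idx = np.flatnonzero(valid)
    if idx.size < k:
        raise InsufficientDataError(
            f"only {idx.size} valid cycles available, need {k}"
        )
    chosen = idx[:k]
    return StrideSet(bounds[chosen, 0], bounds[chosen, 1], tuple(int(i) for i in chosen))
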