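"""Core containers for force and EMG time-series and derived gait structures.

All traces are uniformly sampled; indices are 0-based and contact intervals
are half-open ``[onset, offset)``: the onset sample is the first sample
strictly above the contact threshold, the offset sample the first subsequent
sample at or below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

#: The eight instrumented right-lower-limb muscles.
MUSCLES = ("VL", "VM", "RF", "BF", "GM", "GL", "SOL", "TA")

#: Muscles grouped by the joint they primarily act on (used by the
#: joint-matched correlation design).
KNEE_MUSCLES = ("VL", "VM", "RF", "BF")
ANKLE_MUSCLES = ("GM", "GL", "SOL", "TA")

GRAVITY = 9.81  # m·s⁻², used to convert body mass to body weight


@dataclass(frozen=True)
class ForceTrace:
    """Uniformly sampled vertical force signal in newtons."""

    samples: np.ndarray
    rate: float  # samples·s⁻¹
    start_time: float = 0.0  # s

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise InvalidParameterError(f"sampling rate must be positive, got {self.rate}")
        if self.samples.ndim != 1:
            raise InvalidParameterError("force trace must be one-dimensional")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("force trace contains non-finite samples")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.rate


@dataclass(frozen=True)
class EmgTrace:
    """Uniformly sampled surface-EMG signal in microvolts for one muscle."""

    samples: np.ndarray
    rate: float  # samples·s⁻¹
    muscle: str
    start_time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise InvalidParameterError(f"sampling rate must be positive, got {self.rate}")
        if self.muscle not in MUSCLES:
            raise InvalidParameterError(
                f"unknown muscle {self.muscle!r}; expected one of {MUSCLES}"
            )

    @property
    def n(self) -> int:
        return self.samples.size

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.rate


@dataclass(frozen=True)
class GaitEvents:
    """Ground-contact intervals detected on a force trace.

    ``contacts`` holds ``(onset_index, offset_index)`` pairs in sample units.
    Contact time T_c is per contact; flight time T_f is the gap from each
    offset to the next onset, so there is one fewer T_f than contacts.
    """

    contacts: tuple[tuple[int, int], ...]
    rate: float
    flagged: bool = False  # True when the signal never left the contact state

    def __post_init__(self) -> None:
        prev_off = -1
        for onset, offset in self.contacts:
            if not onset < offset:
                raise InvalidParameterError("contact onset must precede offset")
            if onset <= prev_off:
                raise InvalidParameterError("contacts must be non-overlapping and ordered")
            prev_off = offset

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def contact_times(self) -> np.ndarray:
        """T_c per contact, in seconds."""
        return np.array([(off - on) / self.rate for on, off in self.contacts])

    def flight_times(self) -> np.ndarray:
        """T_f per step (offset to next onset), in seconds."""
        return np.array(
            [
                (self.contacts[i + 1][0] - self.contacts[i][1]) / self.rate
                for i in range(len(self.contacts) - 1)
            ]
        )

    def cycle_bounds(self) -> np.ndarray:
        """Onset-to-next-onset cycle boundaries in seconds, shape (n_cycles, 2).

        One cycle = one contact plus the following flight on the instrumented
        side, matching the stride-frequency denominator T_c + T_f.
        """
        onsets = np.array([on for on, _ in self.contacts]) / self.rate
        if onsets.size < 2:
            return np.empty((0, 2))
        return np.column_stack([onsets[:-1], onsets[1:]])


@dataclass(frozen=True)
class StrideSet:
    """Selected gait cycles for iEMG integration.

    Boundaries are in seconds on the shared GRF/EMG clock (both streams start
    at t = 0 from the synchronised A/D converter).
    """

    starts_s: np.ndarray
    ends_s: np.ndarray
    selected_indices: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "starts_s", np.asarray(self.starts_s, dtype=float))
        object.__setattr__(self, "ends_s", np.asarray(self.ends_s, dtype=float))
        if self.starts_s.shape != self.ends_s.shape:
            raise InvalidParameterError("stride boundaries must align")
        if np.any(self.ends_s <= self.starts_s):
            raise InvalidParameterError("cycle end must follow cycle start")
        if np.any(np.diff(self.starts_s) <= 0):
            raise InvalidParameterError("cycle starts must be strictly increasing")

    @property
    def k(self) -> int:
        return self.starts_s.size

    def durations(self) -> np.ndarray:
        return self.ends_s - self.starts_s
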