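"""Core data containers shared across the pipeline.

All signal containers follow the same layout: channels along axis 0,
samples along axis 1, amplitudes in microvolts (arbitrary reference),
time implied by a sampling rate in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Canonical channel order: olfactory bulb, entorhinal cortex, dorsal hippocampus.
CHANNELS = ("OB", "EC", "dHPC")

#: Region pairs analyzed, ordered so that a positive lag means the
#: first-named region leads the second (direction of information influx).
PAIRS = (("OB", "EC"), ("OB", "dHPC"), ("EC", "dHPC"))

#: Default oscillation bands (Hz).
DEFAULT_BANDS = {"theta": (4.0, 12.0), "gamma": (30.0, 80.0)}


@dataclass
class Recording:
    """A multichannel LFP recording for one animal-session.

    Parameters
    ----------
    channels : sequence of str
        Channel names, canonically ``("OB", "EC", "dHPC")``.
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    animal_id, group_label : str
        Identity of the animal and its experimental group.
    artifact_mask : ndarray of bool, shape (n_samples,)
        True marks samples excluded from all downstream estimators.
    """

    channels: tuple
    data: np.ndarray
    fs: float
    animal_id: str = ""
    group_label: str = ""
    artifact_mask: np.ndarray | None = None

    def __post_init__(self):
        self.channels = tuple(self.channels)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channel names for data with "
                f"{self.data.shape[0]} rows"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.data.shape[1], dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != (self.data.shape[1],):
                raise ValueError("artifact mask length must equal sample count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's samples by (case-insensitive) name."""
        lower = [c.lower() for c in self.channels]
        try:
            idx = lower.index(name.lower())
        except ValueError:
            raise KeyError(
                f"channel {name!r} not found; available: {list(self.channels)}"
            ) from None
        return self.data[idx]

    def copy(self) -> "Recording":
        return replace(
            self, data=self.data.copy(), artifact_mask=self.artifact_mask.copy()
        )


@dataclass
class ArenaObject:
    """An object placed in the arena: label, center position (cm), radius (cm)."""

    label: str
    center: tuple
    radius: float = 5.0

    def __post_init__(self):
        self.center = (float(self.center[0]), float(self.center[1]))
        if self.radius < 0:
            raise ValueError("object radius must be non-negative")


@dataclass
class TrackingTrace:
    """Synchronized position samples plus arena and object geometry.

    Positions are in cm with the arena origin at the lower-left corner.
    """

    t: np.ndarray
    body_xy: np.ndarray
    nose_xy: np.ndarray
    arena: tuple = (75.0, 75.0)
    objects: list = field(default_factory=list)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.body_xy = np.asarray(self.body_xy, dtype=float)
        self.nose_xy = np.asarray(self.nose_xy, dtype=float)
        if not (len(self.t) == len(self.body_xy) == len(self.nose_xy)):
            raise ValueError("t, body_xy, nose_xy must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time base must be strictly increasing")

    @property
    def fs(self) -> float:
        """Median tracking rate (Hz)."""
        if len(self.t) < 2:
            return float("nan")
        return 1.0 / float(np.median(np.diff(self.t)))

    def object_by_label(self, label: str) -> ArenaObject:
        for obj in self.objects:
            if obj.label == label:
                return obj
        raise KeyError(f"no object labeled {label!r}")


def validate_band(band: Sequence[float], fs: float) -> tuple:
    """Validate a (f_lo, f_hi) band against the Nyquist limit."""
    f_lo, f_hi = float(band[0]), float(band[1])
    if f_lo >= f_hi:
        raise ValueError(f"degenerate band ({f_lo}, {f_hi})")
    if f_lo <= 0 or f_hi >= fs / 2:
        raise ValueError(f"band ({f_lo}, {f_hi}) outside (0, fs/2) for fs={fs}")
    return f_lo, f_hi
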