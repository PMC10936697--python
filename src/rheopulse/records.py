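"""Core in-memory containers for multichannel bioimpedance recordings.

A :class:`SignalRecord` is the pipeline's universal currency: a channels x
time matrix of uniformly sampled values (volts or raw analog-to-digital
units), a sampling rate, per-channel metadata, and a list of timed
annotations (event markers, free-text notes, blood-pressure readings).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["AnnotationKind", "Annotation", "SignalRecord"]


class AnnotationKind(enum.Enum):
    EVENT_MARKER = "EVENT_MARKER"
    NOTE = "NOTE"
    BP_READING = "BP_READING"


@dataclass(frozen=True)
class Annotation:
    """A timed label attached to a recording.

    Parameters
    ----------
    time_s : float
        Seconds from record start (sample 0 sits at t = 0).
    label : str
        Non-empty text, e.g. ``"BH start"`` or ``"120/80"``.
    kind : AnnotationKind
        Event marker, note, or blood-pressure reading.
    """

    time_s: float
    label: str
    kind: AnnotationKind = AnnotationKind.EVENT_MARKER

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError(f"annotation time must be >= 0, got {self.time_s}")
        if not self.label:
            raise ValueError("annotation label must be non-empty")


@dataclass
class SignalRecord:
    """Uniformly sampled multichannel waveform with annotations.

    ``samples`` has shape ``(n_channels, n_samples)``; all channels share the
    sampling rate ``fs`` and start time. Channel values are in volts or raw
    ADC units as stated per channel in ``channel_units``.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_units: list[str] = field(default_factory=list)
    start_time: str = ""
    annotations: list[Annotation] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float32))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )
        if not self.channel_units:
            self.channel_units = ["V"] * self.n_channels
        if len(self.channel_units) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_units)} units for {self.n_channels} channels"
            )
        for ann in self.annotations:
            if ann.time_s > self.duration_s:
                raise ValueError(
                    f"annotation at {ann.time_s:.3f} s lies beyond record end "
                    f"({self.duration_s:.3f} s)"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds from record start."""
        return np.arange(self.n_samples) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"no channel {label!r}; available: {self.channel_labels}"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples by label."""
        return self.samples[self.channel_index(label)]

    def copy_with(self, **changes) -> "SignalRecord":
        if "samples" not in changes:
            changes["samples"] = self.samples.copy()
        if "annotations" not in changes:
            changes["annotations"] = list(self.annotations)
        return replace(self, **changes)
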