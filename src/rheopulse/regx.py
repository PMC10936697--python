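"""The REGx / PRx moving-correlation autoregulation index.

Two channels (a head bioimpedance derivation and an arm reference, or —
for the invasive PRx — arterial pressure and intracranial pressure) are
reduced to 10-second epoch means; a Pearson correlation over a 5-minute
moving window, re-emitted every 10-60 s, then tracks whether their slow
fluctuations are in phase. A negative index means cerebral-blood-flow
autoregulation is actively countering pressure swings (ACTIVE); a positive
index means the head signal passively follows (PASSIVE, impaired
autoregulation).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .preprocess import ArtifactMask
from .records import SignalRecord

__all__ = [
    "EpochSeries",
    "RegxSeries",
    "ARStatus",
    "epoch_average",
    "epoch_pulse_amplitude",
    "moving_correlation",
    "classify_ar",
    "compare_derivations",
]


class ARStatus(enum.Enum):
    ACTIVE = "ACTIVE"
    PASSIVE = "PASSIVE"


@dataclass
class EpochSeries:
    """One scalar per fixed epoch. ``times`` are epoch centres (s);
    ``valid`` flags epochs with enough unmasked data."""

    epoch_s: float
    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.times.size == self.values.size == self.valid.size):
            raise ValueError("times, values and valid must have equal length")
        if self.times.size > 1 and not np.allclose(np.diff(self.times), self.epoch_s):
            raise ValueError("epoch times must be evenly spaced by epoch_s")


@dataclass
class RegxSeries:
    """Moving-correlation index values with emit times and pair counts.
    Invalid emissions (too few pairs, zero variance) are NaN with
    ``valid`` False."""

    times: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray
    valid: np.ndarray
    window_s: float
    update_s: float


def epoch_average(
    record: SignalRecord,
    channel: str,
    epoch_s: float = 10.0,
    mask: ArtifactMask | None = None,
) -> EpochSeries:
    """Mean of unmasked samples per consecutive epoch.

    Epochs with fewer than 50% unmasked samples are marked invalid (their
    value is NaN). The record must cover at least one full epoch.
    """
    if record.duration_s < epoch_s:
        raise ValueError(
            f"record of {record.duration_s:.1f} s shorter than one {epoch_s}-s epoch"
        )
    x = record.channel(channel).astype(float)
    ok = (
        mask.sample_validity(record.n_samples, record.fs)
        if mask is not None
        else np.ones(record.n_samples, dtype=bool)
    )
    per_epoch = int(round(epoch_s * record.fs))
    n_epochs = record.n_samples // per_epoch
    times = (np.arange(n_epochs) + 0.5) * epoch_s
    values = np.full(n_epochs, np.nan)
    valid = np.zeros(n_epochs, dtype=bool)
    for k in range(n_epochs):
        sel = ok[k * per_epoch : (k + 1) * per_epoch]
        if sel.mean() >= 0.5:
            values[k] = x[k * per_epoch : (k + 1) * per_epoch][sel].mean()
            valid[k] = True
    return EpochSeries(epoch_s=epoch_s, times=times, values=values, valid=valid)


def epoch_pulse_amplitude(
    record: SignalRecord,
    channel: str,
    epoch_s: float = 10.0,
    mask: ArtifactMask | None = None,
) -> EpochSeries:
    """Alternative epoch feature: mean per-beat P1 amplitude per epoch.

    Provided because the original analysis does not state whether raw-signal
    means or pulse amplitudes were correlated; the epoch mean
    (:func:`epoch_average`) is the default elsewhere.
    """
    from .pulses import feature_timeline

    if record.duration_s < epoch_s:
        raise ValueError("record shorter than one epoch")
    timeline = feature_timeline(record, channel, mask=mask)
    n_epochs = int(record.duration_s // epoch_s)
    times = (np.arange(n_epochs) + 0.5) * epoch_s
    values = np.full(n_epochs, np.nan)
    valid = np.zeros(n_epochs, dtype=bool)
    for k in range(n_epochs):
        sel = timeline[
            (timeline.onset_s >= k * epoch_s) & (timeline.onset_s < (k + 1) * epoch_s)
        ]
        amps = sel.p1_amp.dropna()
        if len(amps):
            values[k] = amps.mean()
            valid[k] = True
    return EpochSeries(epoch_s=epoch_s, times=times, values=values, valid=valid)


def moving_correlation(
    x: EpochSeries,
    y: EpochSeries,
    window_s: float = 300.0,
    update_s: float = 10.0,
    min_pairs: int = 20,
) -> RegxSeries:
    """Pearson correlation of two epoch series over a moving window.

    For each emit time ``t`` — starting at exactly ``window_s`` and stepping
    by ``update_s`` — the correlation is computed over the valid epoch pairs
    whose centres lie in ``(t − window_s, t]``. Emissions with fewer than
    ``min_pairs`` pairs, or where either windowed series has zero variance,
    are flagged invalid (NaN) rather than forced to ±1.
    """
    if x.epoch_s != y.epoch_s or x.times.size != y.times.size or not np.allclose(
        x.times, y.times
    ):
        raise ValueError("epoch series must share the same epoch grid")
    epoch_s = x.epoch_s
    if abs(window_s / epoch_s - round(window_s / epoch_s)) > 1e-9:
        raise ValueError("window_s must be a multiple of epoch_s")
    if not (10.0 <= update_s <= 60.0):
        raise ValueError("update_s must lie in [10, 60] seconds")
    duration = x.times[-1] + epoch_s / 2 if x.times.size else 0.0
    emit_times = np.arange(window_s, duration + 1e-9, update_s)
    values = np.full(emit_times.size, np.nan)
    n_pairs = np.zeros(emit_times.size, dtype=int)
    valid = np.zeros(emit_times.size, dtype=bool)
    both = x.valid & y.valid
    for i, t in enumerate(emit_times):
        in_win = (x.times > t - window_s + 1e-9) & (x.times <= t + 1e-9) & both
        n = int(in_win.sum())
        n_pairs[i] = n
        if n < max(min_pairs, 2):
            continue
        xv = x.values[in_win]
        yv = y.values[in_win]
        xc = xv - xv.mean()
        yc = yv - yv.mean()
        sx = np.sqrt(np.sum(xc * xc))
        sy = np.sqrt(np.sum(yc * yc))
        if sx == 0.0 or sy == 0.0:
            continue
        r = float(np.sum(xc * yc) / (sx * sy))
        values[i] = min(max(r, -1.0), 1.0)
        valid[i] = True
    return RegxSeries(
        times=emit_times,
        values=values,
        n_pairs=n_pairs,
        valid=valid,
        window_s=window_s,
        update_s=update_s,
    )


def classify_ar(value: float) -> ARStatus:
    """ACTIVE autoregulation for a negative index, PASSIVE otherwise.

    The tie at exactly zero is resolved to PASSIVE (conservative toward
    impairment). Non-finite values are rejected as unclassifiable.
    """
    if not np.isfinite(value) or not (-1.0 <= value <= 1.0):
        raise ValueError(f"index value must be finite in [-1, 1], got {value}")
    return ARStatus.ACTIVE if value < 0 else ARStatus.PASSIVE


def compare_derivations(a: RegxSeries, b: RegxSeries) -> float:
    """R-squared between two index series over their common valid emissions.

    Used to compare the bifrontal- and bitemporal-derived indices over a
    whole recording. Requires at least 3 common valid samples.
    """
    common_t, ia, ib = np.intersect1d(a.times, b.times, return_indices=True)
    ok = a.valid[ia] & b.valid[ib]
    if ok.sum() < 3:
        raise ValueError(
            f"only {int(ok.sum())} common valid samples; need at least 3"
        )
    r = np.corrcoef(a.values[ia][ok], b.values[ib][ok])[0, 1]
    return float(r * r)
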