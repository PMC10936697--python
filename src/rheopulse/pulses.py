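"""Per-beat pulse-wave morphology.

The pulse wave of head bioimpedance mirrors the intracranial-pressure
waveform: a percussion peak P1, a tidal peak P2 whose relative height
tracks intracranial compliance, and a dicrotic peak P3. This module
segments a smoothed channel into beats at successive pulse minima and
measures, per beat: P1/P2/P3 amplitudes (relative to the beat-onset
minimum) and latencies, the anacrotic (onset-to-P1) time, a catacrotic
"shoulder" (an attenuated P2 that does not form its own maximum), and a
compliance class:

* ``GOOD_ICC`` — P1 > P2, normal compliance reserve;
* ``POOR_ICC`` — P2 > P1 (ties included), compromised compliance;
* ``TRIANGULAR`` — the peaks fused into a single broad hump.

Anacrotic times at or above 180 ms are classed PROLONGED (reduced arterial
elasticity); shorter times are NORMAL.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .preprocess import ArtifactMask
from .records import SignalRecord

__all__ = [
    "Beat",
    "PulseFeatures",
    "MorphClass",
    "AnacroticClass",
    "segment_beats",
    "extract_features",
    "detect_shoulder",
    "classify_morphology",
    "classify_anacrotic",
    "baseline_percent",
    "summarize_epoch",
    "feature_timeline",
]


class MorphClass(enum.Enum):
    GOOD_ICC = "GOOD_ICC"
    POOR_ICC = "POOR_ICC"
    TRIANGULAR = "TRIANGULAR"
    UNDEFINED = "UNDEFINED"


class AnacroticClass(enum.Enum):
    NORMAL = "NORMAL"
    PROLONGED = "PROLONGED"


@dataclass(frozen=True)
class Beat:
    """One beat delimited by successive pulse-wave minima."""

    onset_index: int
    end_index: int
    onset_value: float

    def __post_init__(self) -> None:
        if self.onset_index >= self.end_index:
            raise ValueError("beat onset must precede its end")


@dataclass
class PulseFeatures:
    """Morphology of one beat; amplitudes relative to the onset minimum,
    times in ms from onset. Absent peaks are NaN."""

    p1_amp: float = np.nan
    p2_amp: float = np.nan
    p3_amp: float = np.nan
    p1_time_ms: float = np.nan
    p2_time_ms: float = np.nan
    p3_time_ms: float = np.nan
    anacrotic_ms: float = np.nan
    shoulder: bool = False
    morph_class: MorphClass = MorphClass.UNDEFINED

    @property
    def p2_p1_ratio(self) -> float:
        if np.isnan(self.p1_amp) or np.isnan(self.p2_amp) or self.p1_amp == 0:
            return np.nan
        return self.p2_amp / self.p1_amp


def segment_beats(
    record: SignalRecord,
    channel: str,
    hr_bounds_bpm: tuple[float, float] = (40.0, 180.0),
    mask: ArtifactMask | None = None,
    min_prominence_frac: float = 0.25,
) -> list[Beat]:
    """Delimit beats at successive pulse-wave minima.

    The dominant systolic peak of each beat is located first (refractory
    period ``60 / hr_max`` seconds, prominence floor a fraction of the
    channel's peak-to-peak range, so a flat signal yields no beats); each
    beat onset is then the waveform minimum between successive systolic
    peaks — the cursor-on-the-minimum convention. Candidate beats whose
    duration falls outside the physiologic RR range implied by
    ``hr_bounds_bpm``, or which overlap a supplied artifact mask, are
    dropped.
    """
    x = record.channel(channel).astype(float)
    hr_lo, hr_hi = hr_bounds_bpm
    fs = record.fs
    ptp = float(np.ptp(x))
    if ptp < 1e-12:
        return []
    distance = max(int(round(60.0 / hr_hi * fs)), 1)
    peaks, _ = find_peaks(x, distance=distance, prominence=min_prominence_frac * ptp)
    if peaks.size < 1:
        return []
    def foot(lo: int, hi: int, peak: int) -> int:
        # cursor-on-the-minimum, refined to the foot of the upstroke: the
        # last sample before the peak still within 5% of the valley depth
        seg = x[lo:hi]
        m = lo + int(np.argmin(seg))
        thresh = x[m] + 0.05 * (x[peak] - x[m])
        below = np.flatnonzero(x[m : peak + 1] <= thresh)
        return m + int(below[-1]) if below.size else m

    boundaries = []
    if peaks[0] > 0:
        boundaries.append(foot(0, peaks[0], peaks[0]))
    for p0, p1 in zip(peaks, peaks[1:]):
        boundaries.append(foot(p0 + 1, p1, p1))
    if peaks[-1] < x.size - 1:
        boundaries.append(int(peaks[-1] + np.argmin(x[peaks[-1] :])))
    beats = []
    for i0, i1 in zip(boundaries, boundaries[1:]):
        rr = (i1 - i0) / fs
        if not (60.0 / hr_hi <= rr <= 60.0 / hr_lo):
            continue
        if mask is not None and mask.overlaps(i0 / fs, i1 / fs):
            continue
        beats.append(Beat(onset_index=int(i0), end_index=int(i1), onset_value=float(x[i0])))
    return beats


def _local_maxima(w: np.ndarray) -> np.ndarray:
    """Indices of interior local maxima; plateaus report their first sample."""
    peaks, props = find_peaks(w, plateau_size=1)
    if peaks.size:
        return np.asarray(props["left_edges"], dtype=int)
    return peaks


def detect_shoulder(
    beat_waveform: np.ndarray,
    p1_index: int,
    fs: float,
    smooth_samples: int = 5,
) -> tuple[bool, float]:
    """Detect a catacrotic shoulder after P1.

    A shoulder is a deceleration-then-re-acceleration of the descending
    limb: a local maximum of the first derivative that stays negative (no
    sign change, hence no separate peak). The first difference is lightly
    smoothed before its extrema are located. Returns (found, location in ms
    from beat onset); the location is NaN when absent.
    """
    w = np.asarray(beat_waveform, dtype=float)
    if p1_index >= w.size - 2:
        return False, np.nan
    d = np.diff(w)
    if smooth_samples > 1:
        kernel = np.ones(smooth_samples) / smooth_samples
        d = np.convolve(d, kernel, mode="same")
    seg = d[p1_index:]
    # candidate shoulders: local maxima of the derivative on the descending limb
    cand, _ = find_peaks(seg)
    for i in cand:
        if seg[i] < 0:  # derivative stays negative: no true second peak
            loc_ms = (p1_index + i + 1) / fs * 1000.0
            return True, loc_ms
    return False, np.nan


def extract_features(
    record: SignalRecord,
    beat: Beat,
    channel: str | None = None,
    triangular_min_width_ms: float = 180.0,
) -> PulseFeatures:
    """Measure P1/P2/P3, anacrotic time, shoulder, and compliance class.

    P1 is the first local maximum after onset, P2 the next (or, failing
    that, the derivative-defined shoulder so tidal-wave statistics remain
    computable), P3 the next after P2. A candidate peak measuring below the
    onset value is treated as absent. A beat whose maxima cannot be
    resolved into separate peaks and whose single hump is broad (width at
    half prominence of at least ``triangular_min_width_ms``) is classed
    TRIANGULAR.
    """
    if channel is None:
        if record.n_channels != 1:
            raise ValueError("channel must be named on a multichannel record")
        channel = record.channel_labels[0]
    x = record.channel(channel).astype(float)
    if beat.end_index > x.size:
        raise ValueError("beat extends beyond the record")
    w = x[beat.onset_index : beat.end_index + 1]
    fs = record.fs
    f = PulseFeatures()
    maxima = _local_maxima(w)
    if maxima.size == 0:
        interior = w[1:-1]
        if interior.size and np.ptp(w) > 0 and np.argmax(w) not in (0, w.size - 1):
            maxima = np.array([int(np.argmax(w))])
        else:
            return f  # no local maximum: all peaks absent, class undefined

    onset_v = beat.onset_value
    p1_i = int(maxima[0])
    f.p1_amp = float(w[p1_i] - onset_v)
    f.p1_time_ms = p1_i / fs * 1000.0
    f.anacrotic_ms = f.p1_time_ms

    rest = maxima[1:]
    shoulder, shoulder_ms = detect_shoulder(w, p1_i, fs)
    f.shoulder = bool(shoulder)
    if rest.size:
        p2_i = int(rest[0])
        if w[p2_i] >= onset_v:
            f.p2_amp = float(w[p2_i] - onset_v)
            f.p2_time_ms = p2_i / fs * 1000.0
        if rest.size > 1:
            p3_i = int(rest[1])
            if w[p3_i] >= onset_v:
                f.p3_amp = float(w[p3_i] - onset_v)
                f.p3_time_ms = p3_i / fs * 1000.0
    if np.isnan(f.p2_amp) and shoulder:
        s_i = int(round(shoulder_ms / 1000.0 * fs))
        s_i = min(max(s_i, 0), w.size - 1)
        if w[s_i] >= onset_v:
            f.p2_amp = float(w[s_i] - onset_v)
            f.p2_time_ms = shoulder_ms

    f.morph_class = classify_morphology(f, w, fs, triangular_min_width_ms)
    return f


def classify_morphology(
    features: PulseFeatures,
    beat_waveform: np.ndarray | None = None,
    fs: float | None = None,
    triangular_min_width_ms: float = 180.0,
) -> MorphClass:
    """Compliance class from measured peak amplitudes.

    GOOD_ICC when P1 exceeds P2; POOR_ICC when P2 is at least P1 (ties are
    resolved toward pathology); TRIANGULAR when no separate P2 or shoulder
    was resolvable and the single hump is broad — its width at half
    prominence at least ``triangular_min_width_ms`` (a lone percussion
    peak is several times narrower than the fused three-wave tent).
    """
    if np.isnan(features.p1_amp):
        return MorphClass.UNDEFINED
    if not np.isnan(features.p2_amp):
        if features.p1_amp > features.p2_amp:
            return MorphClass.GOOD_ICC
        return MorphClass.POOR_ICC
    if beat_waveform is not None and fs is not None:
        w = np.asarray(beat_waveform, dtype=float)
        ptp = np.ptp(w)
        if ptp > 0:
            half = w.min() + 0.5 * ptp
            width_ms = np.count_nonzero(w > half) / fs * 1000.0
            if width_ms >= triangular_min_width_ms:
                return MorphClass.TRIANGULAR
    return MorphClass.GOOD_ICC  # lone sharp P1, tidal wave absent


def classify_anacrotic(anacrotic_ms: float, threshold_ms: float = 180.0) -> AnacroticClass:
    """NORMAL below the threshold, PROLONGED at or above it."""
    if anacrotic_ms < 0:
        raise ValueError(f"anacrotic time must be >= 0, got {anacrotic_ms}")
    return (
        AnacroticClass.PROLONGED
        if anacrotic_ms >= threshold_ms
        else AnacroticClass.NORMAL
    )


def baseline_percent(control_mean: float, test_mean: float) -> float:
    """Amplitude change as a percentage of the control/baseline mean."""
    if control_mean == 0:
        raise ValueError("control mean must be non-zero")
    return 100.0 * (test_mean - control_mean) / control_mean


def summarize_epoch(features_in_epoch: list[PulseFeatures]) -> tuple[float, float, dict]:
    """Mean P1 and P2 over an epoch's beats.

    Each peak is averaged over the beats in which it was found; the counts
    per peak are returned alongside. An epoch with no P1-bearing beat is
    rejected.
    """
    p1 = [f.p1_amp for f in features_in_epoch if not np.isnan(f.p1_amp)]
    p2 = [f.p2_amp for f in features_in_epoch if not np.isnan(f.p2_amp)]
    if not p1:
        raise ValueError("epoch has no beat with a measurable P1")
    return (
        float(np.mean(p1)),
        float(np.mean(p2)) if p2 else np.nan,
        {"n_p1": len(p1), "n_p2": len(p2)},
    )


def feature_timeline(
    record: SignalRecord,
    channel: str,
    mask: ArtifactMask | None = None,
    hr_bounds_bpm: tuple[float, float] = (40.0, 180.0),
) -> pd.DataFrame:
    """Segment a channel and tabulate per-beat features.

    Returns one row per beat: ``onset_s``, amplitudes, latencies, anacrotic
    time and classes — the timeline consumed by the challenge analytics.
    """
    beats = segment_beats(record, channel, hr_bounds_bpm, mask)
    rows = []
    for b in beats:
        f = extract_features(record, b, channel)
        rows.append(
            {
                "onset_s": b.onset_index / record.fs,
                "end_s": b.end_index / record.fs,
                "p1_amp": f.p1_amp,
                "p2_amp": f.p2_amp,
                "p3_amp": f.p3_amp,
                "p1_time_ms": f.p1_time_ms,
                "p2_time_ms": f.p2_time_ms,
                "p3_time_ms": f.p3_time_ms,
                "anacrotic_ms": f.anacrotic_ms,
                "shoulder": f.shoulder,
                "morph_class": f.morph_class.value,
                "p2_p1_ratio": f.p2_p1_ratio,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "onset_s",
            "end_s",
            "p1_amp",
            "p2_amp",
            "p3_amp",
            "p1_time_ms",
            "p2_time_ms",
            "p3_time_ms",
            "anacrotic_ms",
            "shoulder",
            "morph_class",
            "p2_p1_ratio",
        ],
    )
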