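"""Synthetic bioimpedance signal generation with known ground truth.

Two families of signals are produced:

* a two-channel sine pair (head / arm) with optional phase-inversion
  intervals — the bench demonstration that drives the moving-correlation
  index from +1 to −1;
* full physiological sessions: three channels (bifrontal, bitemporal, arm)
  of pulse-wave trains built from P1/P2/P3 sub-waves, with posture segments
  (supine vs head-down tilt), breath-hold amplitude responses, mains
  contamination, slow common drift, and seeded blink/talk artifacts.

Every generator is deterministic given its scenario and seed, and returns
enough ground truth (per-beat amplitudes, artifact intervals, drift phase)
to score every downstream analysis stage.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import Annotation, AnnotationKind, SignalRecord

__all__ = [
    "Posture",
    "DriftPhase",
    "ArtifactKind",
    "SubWave",
    "BeatTemplateParams",
    "BreathHold",
    "Drift",
    "Scenario",
    "SessionTruth",
    "generate_sine_pair",
    "render_beat",
    "generate_session",
    "inject_mains",
    "inject_artifacts",
    "default_session_scenario",
]


class Posture(enum.Enum):
    SUPINE = "SUPINE"
    HDT = "HDT"


class DriftPhase(enum.Enum):
    IN_PHASE = "IN_PHASE"
    INVERTED = "INVERTED"


class ArtifactKind(enum.Enum):
    BLINK_SPIKE = "BLINK_SPIKE"
    TALK_BURST = "TALK_BURST"


@dataclass(frozen=True)
class SubWave:
    """One Gaussian sub-wave of a pulse beat: centre latency, peak amplitude
    above baseline, and Gaussian sigma (all widths in milliseconds)."""

    latency_ms: float
    amplitude: float
    width_ms: float


@dataclass(frozen=True)
class BeatTemplateParams:
    """P1/P2/P3 sub-wave parameters for one beat template.

    P1 is the percussion (arterial) wave, P2 the tidal wave whose relative
    height tracks intracranial compliance, P3 the dicrotic wave. Latencies
    must be strictly increasing; overlapping widths are allowed and produce
    the fused triangular morphology.
    """

    p1: SubWave
    p2: SubWave
    p3: SubWave
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not (self.p1.latency_ms < self.p2.latency_ms < self.p3.latency_ms):
            raise ValueError("sub-wave latencies must be strictly increasing")
        for w in (self.p1, self.p2, self.p3):
            if w.width_ms <= 0:
                raise ValueError("sub-wave widths must be positive")
            if w.amplitude < 0:
                raise ValueError("sub-wave amplitudes must be >= 0")

    def with_gains(self, overall: float = 1.0, p2_gain: float = 1.0) -> "BeatTemplateParams":
        """Return a copy with all amplitudes scaled by ``overall`` and P2
        additionally scaled by ``p2_gain``."""

        def scale(w: SubWave, g: float) -> SubWave:
            return SubWave(w.latency_ms, w.amplitude * g, w.width_ms)

        return BeatTemplateParams(
            p1=scale(self.p1, overall),
            p2=scale(self.p2, overall * p2_gain),
            p3=scale(self.p3, overall),
            baseline=self.baseline,
        )

    @property
    def p2_p1_ratio(self) -> float:
        return self.p2.amplitude / self.p1.amplitude


@dataclass(frozen=True)
class BreathHold:
    """A breath-hold challenge event.

    The pulse-amplitude response is a smooth gain ramp: unity until
    ``response_latency_s`` after the hold starts, rising to
    ``amplitude_gain`` at ``peak_after_end_s`` seconds after the hold ends,
    then relaxing back over ``decay_s``. Responses peaking during the hold
    are produced by a negative ``peak_after_end_s``.
    """

    start_s: float
    duration_s: float = 30.0
    amplitude_gain: float = 1.3
    response_latency_s: float = 3.0
    peak_after_end_s: float = 10.0
    decay_s: float = 25.0

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def peak_time_s(self) -> float:
        return self.end_s + self.peak_after_end_s

    def gain_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Multiplicative pulse-amplitude gain at time ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        rise_start = self.start_s + self.response_latency_s
        peak = self.peak_time_s
        w = np.zeros_like(t)
        rising = (t >= rise_start) & (t < peak)
        if peak > rise_start:
            x = (t[rising] - rise_start) / (peak - rise_start)
            w[rising] = 0.5 - 0.5 * np.cos(np.pi * x)
        falling = (t >= peak) & (t < peak + self.decay_s)
        x = (t[falling] - peak) / self.decay_s
        w[falling] = 0.5 + 0.5 * np.cos(np.pi * x)
        return 1.0 + (self.amplitude_gain - 1.0) * w


@dataclass(frozen=True)
class Drift:
    """Slow common baseline co-fluctuation between head and arm channels.

    ``common_phase`` controls the arm channel's sign relative to the head:
    IN_PHASE drift yields a moving-correlation index near +1, INVERTED near
    −1, so the index's ground truth is known by construction.
    """

    freq_hz: float = 0.03
    amplitude: float = 0.05
    common_phase: DriftPhase = DriftPhase.IN_PHASE


@dataclass
class Scenario:
    """Declarative simulation script for a full recording session."""

    duration_s: float
    fs: float = 200.0
    heart_rate_bpm: float = 75.0
    beat_params: dict[Posture, BeatTemplateParams] = field(default_factory=dict)
    posture_segments: list[tuple[float, float, Posture]] = field(default_factory=list)
    bh_events: list[BreathHold] = field(default_factory=list)
    mains: tuple[float, float] = (50.0, 0.05)
    drift: Drift = field(default_factory=Drift)
    artifact_rate_per_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.posture_segments:
            self.posture_segments = [(0.0, self.duration_s, Posture.SUPINE)]
        segs = sorted(self.posture_segments)
        if abs(segs[0][0]) > 1e-9 or abs(segs[-1][1] - self.duration_s) > 1e-9:
            raise ValueError("posture segments must cover [0, duration_s)")
        for (s0, e0, _), (s1, _, _) in zip(segs, segs[1:]):
            if abs(e0 - s1) > 1e-9:
                raise ValueError("posture segments must tile [0, duration_s) without gaps")
        for s, e, _ in segs:
            if e <= s:
                raise ValueError("posture segments must have positive length")
        self.posture_segments = segs
        for bh in self.bh_events:
            if bh.start_s < 0 or bh.end_s > self.duration_s:
                raise ValueError(
                    f"breath-hold [{bh.start_s}, {bh.end_s}] outside recording"
                )
        if self.fs <= 2 * self.mains[0]:
            raise ValueError("fs must exceed twice the mains frequency")
        if not self.beat_params:
            self.beat_params = {
                Posture.SUPINE: default_beat_params(),
                Posture.HDT: default_beat_params().with_gains(p2_gain=1.4),
            }

    def posture_at(self, t: float) -> Posture:
        for s, e, p in self.posture_segments:
            if s <= t < e:
                return p
        return self.posture_segments[-1][2]

    def gain_at(self, t: float) -> float:
        g = 1.0
        for bh in self.bh_events:
            g *= float(bh.gain_at(t))
        return g


@dataclass
class SessionTruth:
    """Ground truth emitted alongside a generated session."""

    beats: pd.DataFrame  # onset_s, posture, p1_amp, p2_amp, p3_amp, gain, ratio, morph_class
    segments: list[tuple[float, float, Posture]]
    drift_phase: DriftPhase
    bh_events: list[BreathHold]
    artifact_intervals: list[tuple[float, float, str]]


def default_beat_params() -> BeatTemplateParams:
    """Supine pulse template: P1-dominant (good intracranial compliance)."""
    return BeatTemplateParams(
        p1=SubWave(100.0, 1.0, 30.0),
        p2=SubWave(250.0, 0.75, 40.0),
        p3=SubWave(400.0, 0.35, 50.0),
        baseline=0.0,
    )


# ---------------------------------------------------------------------------


def generate_sine_pair(
    freq_hz: float = 10.0,
    amplitude: float = 1.0,
    fs: float = 200.0,
    duration_s: float = 60.0,
    inversion_intervals: list[tuple[float, float]] | None = None,
    drift: tuple[float, float] | None = (0.02, 0.1),
) -> SignalRecord:
    """Bench-style head/arm sine pair with optional phase inversion.

    Both channels carry an ``amplitude``-volt sine at ``freq_hz`` plus, by
    default, a small slow additive drift common to both (so 10-s epoch means
    are non-degenerate). Inside each inversion interval the head channel is
    the exact negation of the arm channel, drift included.
    """
    if freq_hz >= fs / 2:
        raise ValueError(f"sine frequency {freq_hz} Hz >= Nyquist ({fs / 2} Hz)")
    inversion_intervals = inversion_intervals or []
    for s, e in inversion_intervals:
        if s < 0 or e > duration_s or e <= s:
            raise ValueError(
                f"inversion interval [{s}, {e}] outside recording [0, {duration_s})"
            )
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    base = amplitude * np.sin(2 * np.pi * freq_hz * t)
    if drift is not None:
        d_freq, d_amp = drift
        base = base + d_amp * np.sin(2 * np.pi * d_freq * t)
    head = base.copy()
    annotations = []
    for s, e in inversion_intervals:
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        head[i0:i1] = -head[i0:i1]
        annotations.append(Annotation(s, "inversion start"))
        if e < duration_s:
            annotations.append(Annotation(e, "inversion end"))
    return SignalRecord(
        samples=np.vstack([head, base]),
        fs=fs,
        channel_labels=["head", "arm"],
        channel_units=["V", "V"],
        annotations=annotations,
    )


def render_beat(
    params: BeatTemplateParams, rr_s: float, fs: float
) -> np.ndarray:
    """Render one beat of duration ``rr_s`` as a sum of Gaussian sub-waves.

    The waveform starts and ends at baseline provided the RR interval leaves
    room for the P3 tail (``rr_s`` must exceed P3 latency + 3 sigma).
    """
    if rr_s <= (params.p3.latency_ms + 3 * params.p3.width_ms) / 1000.0:
        raise ValueError(
            f"RR interval {rr_s} s too short for P3 at {params.p3.latency_ms} ms"
        )
    n = int(round(rr_s * fs))
    t_ms = np.arange(n) / fs * 1000.0
    out = np.full(n, params.baseline, dtype=float)
    for w in (params.p1, params.p2, params.p3):
        out += w.amplitude * np.exp(-0.5 * ((t_ms - w.latency_ms) / w.width_ms) ** 2)
    return out


def inject_mains(
    record: SignalRecord, freq_hz: float = 50.0, amplitude: float = 0.05
) -> SignalRecord:
    """Add a mains sinusoid of ``amplitude`` volts to every channel."""
    if freq_hz >= record.fs / 2:
        raise ValueError(f"mains frequency {freq_hz} Hz >= Nyquist ({record.fs / 2} Hz)")
    t = record.times()
    contaminated = record.samples + amplitude * np.sin(2 * np.pi * freq_hz * t)
    return record.copy_with(samples=contaminated.astype(np.float32))


def inject_artifacts(
    record: SignalRecord,
    rate_per_min: float,
    kinds: tuple[ArtifactKind, ...] = (ArtifactKind.BLINK_SPIKE, ArtifactKind.TALK_BURST),
    seed: int = 0,
    beat_amplitude: float = 1.0,
    spike_gain: float = 5.0,
) -> tuple[SignalRecord, list[tuple[float, float, str]]]:
    """Corrupt a recording with seeded blink spikes and talk bursts.

    Blink spikes are short (~0.2 s) Gaussian transients of ``spike_gain``
    times the beat amplitude; talk bursts are ~1.5 s of broadband noise.
    Returns the corrupted record together with the exact corrupted intervals
    so detector sensitivity is measurable. Reproducible for a fixed seed.
    """
    if rate_per_min < 0:
        raise ValueError(f"artifact rate must be >= 0, got {rate_per_min}")
    if rate_per_min == 0 or not kinds:
        return record.copy_with(), []
    rng = np.random.default_rng(seed)
    duration = record.duration_s
    n_events = rng.poisson(rate_per_min * duration / 60.0)
    samples = record.samples.astype(float).copy()
    t = record.times()
    intervals: list[tuple[float, float, str]] = []
    for _ in range(n_events):
        kind = kinds[rng.integers(len(kinds))]
        if kind is ArtifactKind.BLINK_SPIKE:
            width_s = 0.2
            start = float(rng.uniform(0, max(duration - width_s, 0)))
            centre = start + width_s / 2
            sign = rng.choice([-1.0, 1.0])
            bump = (
                sign
                * spike_gain
                * beat_amplitude
                * np.exp(-0.5 * ((t - centre) / (width_s / 6)) ** 2)
            )
            samples += bump
            intervals.append((start, start + width_s, kind.value))
        else:
            width_s = 1.5
            start = float(rng.uniform(0, max(duration - width_s, 0)))
            i0, i1 = int(start * record.fs), int((start + width_s) * record.fs)
            burst = rng.normal(0.0, 1.5 * beat_amplitude, i1 - i0)
            samples[:, i0:i1] += burst
            intervals.append((start, start + width_s, kind.value))
    intervals.sort()
    return record.copy_with(samples=samples.astype(np.float32)), intervals


def generate_session(scenario: Scenario) -> tuple[SignalRecord, SessionTruth]:
    """Generate a three-channel session (bifrontal, bitemporal, arm).

    Beats are rendered one RR interval at a time from the posture segment's
    template, with all sub-wave amplitudes multiplied by the breath-hold
    gain at the beat onset; the bitemporal channel is a 0.9-scaled copy of
    the bifrontal morphology; the arm channel carries a simpler single-peak
    pulse that does not respond to the cerebral challenges. A slow drift is
    added to all channels (arm sign set by the scenario's drift phase), then
    mains contamination and seeded artifacts. Annotations mark each
    breath-hold start/stop and each posture change; the returned ground
    truth carries per-beat amplitudes and classes.
    """
    fs = scenario.fs
    n = int(round(scenario.duration_s * fs))
    rr = 60.0 / scenario.heart_rate_bpm
    t = np.arange(n) / fs

    bifrontal = np.zeros(n)
    arm = np.zeros(n)
    arm_wave = SubWave(120.0, 0.5, 60.0)
    beat_rows = []
    onset = 0.0
    while onset + rr <= scenario.duration_s + 1e-9:
        posture = scenario.posture_at(onset)
        gain = scenario.gain_at(onset)
        params = scenario.beat_params[posture].with_gains(overall=gain)
        beat = render_beat(params, rr, fs)
        i0 = int(round(onset * fs))
        i1 = min(i0 + beat.size, n)
        bifrontal[i0:i1] += beat[: i1 - i0] - params.baseline
        arm_t_ms = np.arange(i1 - i0) / fs * 1000.0
        arm[i0:i1] += arm_wave.amplitude * np.exp(
            -0.5 * ((arm_t_ms - arm_wave.latency_ms) / arm_wave.width_ms) ** 2
        )
        ratio = params.p2_p1_ratio
        beat_rows.append(
            {
                "onset_s": onset,
                "posture": posture.value,
                "p1_amp": params.p1.amplitude,
                "p2_amp": params.p2.amplitude,
                "p3_amp": params.p3.amplitude,
                "gain": gain,
                "p2_p1_ratio": ratio,
                "morph_class": "POOR_ICC" if ratio >= 1.0 else "GOOD_ICC",
            }
        )
        onset += rr

    bitemporal = 0.9 * bifrontal
    base0 = scenario.beat_params[scenario.posture_segments[0][2]].baseline
    bifrontal = bifrontal + base0
    bitemporal = bitemporal + base0
    d = scenario.drift.amplitude * np.sin(2 * np.pi * scenario.drift.freq_hz * t)
    arm_drift = d if scenario.drift.common_phase is DriftPhase.IN_PHASE else -d
    samples = np.vstack([bifrontal + d, bitemporal + d, arm + arm_drift])

    annotations: list[Annotation] = []
    for s, _, posture in scenario.posture_segments:
        annotations.append(Annotation(max(s, 0.0), f"posture {posture.value}"))
    for k, bh in enumerate(scenario.bh_events, 1):
        annotations.append(Annotation(bh.start_s, f"BH{k} start"))
        annotations.append(Annotation(min(bh.end_s, scenario.duration_s), f"BH{k} end"))
    annotations.sort(key=lambda a: a.time_s)

    record = SignalRecord(
        samples=samples,
        fs=fs,
        channel_labels=["bifrontal", "bitemporal", "arm"],
        channel_units=["V", "V", "V"],
        annotations=annotations,
    )
    if scenario.mains[1] > 0:
        record = inject_mains(record, *scenario.mains)
    artifact_intervals: list[tuple[float, float, str]] = []
    if scenario.artifact_rate_per_min > 0:
        record, artifact_intervals = inject_artifacts(
            record,
            scenario.artifact_rate_per_min,
            seed=scenario.seed,
            beat_amplitude=max(r["p1_amp"] for r in beat_rows),
        )
    truth = SessionTruth(
        beats=pd.DataFrame(beat_rows),
        segments=list(scenario.posture_segments),
        drift_phase=scenario.drift.common_phase,
        bh_events=list(scenario.bh_events),
        artifact_intervals=artifact_intervals,
    )
    return record, truth


def default_session_scenario(
    duration_s: float = 900.0,
    hdt_start_s: float = 600.0,
    bh_starts: tuple[float, ...] = (60.0, 210.0, 360.0),
    bh_gain: float = 1.3,
    hdt_p2_gain: float = 1.4,
    seed: int = 0,
    artifact_rate_per_min: float = 0.0,
    drift_phase: DriftPhase = DriftPhase.IN_PHASE,
) -> Scenario:
    """Study-shaped session: supine control with three 30-s breath-holds,
    then a −15° head-down-tilt segment whose template has the P2 sub-wave
    elevated by ``hdt_p2_gain`` relative to control."""
    supine = default_beat_params()
    return Scenario(
        duration_s=duration_s,
        beat_params={
            Posture.SUPINE: supine,
            Posture.HDT: supine.with_gains(p2_gain=hdt_p2_gain),
        },
        posture_segments=[
            (0.0, hdt_start_s, Posture.SUPINE),
            (hdt_start_s, duration_s, Posture.HDT),
        ],
        bh_events=[BreathHold(start_s=s, amplitude_gain=bh_gain) for s in bh_starts],
        drift=Drift(common_phase=drift_phase),
        artifact_rate_per_min=artifact_rate_per_min,
        seed=seed,
    )
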