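# Methods

## Signal model

A head bioimpedance (REG) channel is modelled as a train of pulse beats on
a slowly drifting baseline, contaminated by mains pickup and occasional
artifacts. Each beat is the sum of three Gaussian sub-waves realising the
P1/P2/P3 taxonomy of the intracranial-pressure pulse: centre latency (ms
from beat onset), peak amplitude (signal units above baseline) and
Gaussian sigma per sub-wave. Gaussians were chosen because they are
simple, differentiable, and fuse controllably into the triangular
morphology as their widths grow; no claim is made that real catacrotic
limbs are Gaussian. Defaults for the supine template are P1 = (100 ms,
1.0, 30 ms), P2 = (250 ms, 0.75, 40 ms), P3 = (400 ms, 0.35, 50 ms) —
latency ordering and a P1-dominant ratio typical of healthy supine
recordings. The head-down-tilt (HDT) template multiplies the P2 amplitude
by 1.4 by default, enough to flip the P2/P1 ratio above 1 so the simulated
tilt reproduces a compromised-compliance morphology; the tilt-induced P2
elevation is a free generator parameter, not a physiological claim.

The bitemporal channel is a 0.9-scaled copy of the bifrontal morphology;
the arm channel carries a single broader pulse (120 ms latency, 0.5
amplitude, 60 ms sigma) that does not respond to the cerebral challenges.
A common slow drift (default 0.03 Hz, 0.05 amplitude — vasomotion-band
co-fluctuation) is added to all channels; the arm copy is either in phase
or sign-inverted, which fixes the ground truth of the autoregulation
index at +1 or −1 by construction. Mains contamination defaults to 50 Hz
(configurable to 60 Hz), amplitude 0.05.

Breath-hold responses are a multiplicative gain on all sub-wave
amplitudes: unity until a response latency (default 3 s) after the hold
starts, a raised-cosine rise to the configured gain (default 1.3) peaking
at a configurable time (default 10 s after the 30-s hold ends, so both
"peaks during the hold" and "peaks after release" are producible), then a
raised-cosine decay (default 25 s). The gain is evaluated at each beat's
onset, so the per-beat ground truth is exact.

## Analysis pipeline

**Smoothing.** Mains suppression uses a centred running average of
`round(0.04 s × fs)` samples. At 200 Hz this is 8 samples — exactly two
50 Hz cycles — so the contaminant is a zero of the filter (verified to
better than nine orders of magnitude) while the sub-10 Hz pulse content
passes nearly untouched. Edges use a shrinking window so output length
equals input length; a centred window has zero group delay, keeping
latencies comparable across channels. The narrow percussion wave is
attenuated a few percent by this window; the attenuation is identical
across conditions and therefore cancels in BL% and ratio statistics (the
test oracles measure recovered amplitudes against an identically smoothed
isolated beat train, not against raw generative amplitudes).

**Artifact masking.** Samples are flagged when their deviation from the
channel median — scaled by the 90th-percentile absolute deviation —
exceeds 5, on either the value or the first difference, on any channel.
The quantile scale (rather than the MAD) stays meaningful on channels
whose energy is concentrated in narrow pulses; it is still insensitive to
the rare spikes being hunted. Flagged runs are padded by 0.25 s and
merged. Thresholds are engineering defaults calibrated only against the
seeded simulator: a clean session yields an empty mask, and blink spikes
of 5× beat amplitude are detected with ≥ 95% sensitivity. Masked samples
are excluded from, never interpolated into, downstream statistics.
Artifact-free stretches are chopped into 5–10-s analysis epochs,
discarding fragments under 5 s.

**Beat segmentation.** The dominant systolic peak of each beat is found
first (refractory period 60/180 s, prominence ≥ 25% of the channel's
peak-to-peak range, so flat signals yield no beats); the beat onset is
then the waveform minimum between successive peaks, refined to the foot
of the upstroke (the last sample within 5% of the valley depth before the
peak). The refinement matters for synthetic beats, whose inter-beat
baseline is flat enough that the raw minimum's position would be decided
by drift; on real, continuously decaying pulse waves the two coincide.
Candidate beats outside 40–180 bpm, or overlapping the artifact mask, are
dropped.

**Morphology.** P1 is the first local maximum after onset (plateau maxima
take their first sample — a deterministic tie-break), P2 the next local
maximum, P3 the one after. When no second maximum exists, the catacrotic
shoulder — a local maximum of the (lightly smoothed) first derivative
that stays negative, i.e. a deceleration–re-acceleration without a sign
change — supplies the P2 location and amplitude, so tidal-wave statistics
remain computable on shoulder-type beats. Candidate peaks measuring below
the onset value are treated as absent. Classification: GOOD_ICC if
P1 > P2, POOR_ICC if P2 ≥ P1 (the tie is resolved toward pathology), and
TRIANGULAR when no separate P2 or shoulder is resolvable and the single
hump's width at half prominence is ≥ 180 ms (a lone percussion peak is
several times narrower than the fused three-wave tent; the width
criterion replaces any beat-fraction rule so it is independent of heart
rate). The anacrotic boundary at exactly 180 ms is classed PROLONGED.

**Autoregulation index.** Epoch feature = 10-s mean of the smoothed raw
channel; epochs with < 50% unmasked samples are invalid. A configurable
alternative (per-epoch mean P1 amplitude) is provided because whether the
original software correlated raw-signal means or pulse amplitudes is not
documented; the raw mean is the default. The moving Pearson correlation
uses a 5-minute window stepped every 10 s (configurable 10–60 s), with
the emission grid anchored so the first value appears at exactly the
window length and a full window holds 30 pairs. Windows with fewer than
20 valid pairs (of 30) or zero variance are emitted as invalid rather
than forced to ±1 — the correlation is undefined there; the bench
sine-pair demonstration therefore includes a small common drift so epoch
means are non-degenerate, and then the index is exactly +1 in aligned and
−1 in inverted segments. Classification: index < 0 → ACTIVE
autoregulation, ≥ 0 → PASSIVE (the zero tie goes to the conservative,
impaired side).

**Challenges.** Breath-hold analysis takes the baseline as the mean P1
over the 30 s before the start marker and searches for the maximal P1
from the start to 90 s after it — wide enough to cover response maxima
both a few seconds after the start and well after the 30-s hold ends; the
peak delay runs from the start marker to the P1 peak of the beat carrying
the maximum. Condition means for the control-vs-HDT comparison exclude
beats inside breath-hold response windows (same 90-s span), since the
hold's transient would otherwise contaminate the baseline. The paired
t-test runs on per-epoch (10-s) means rather than per-beat values, to
avoid the serial-correlation inflation of beat-level pairing; the first k
epochs of each condition are paired, k the smaller epoch count. With
zero-variance non-zero differences the statistic is reported as signed
infinity with p = 0; identical inputs give t = 0, p = 1.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on: P1/P2/P3
beat composition at a configurable heart rate, posture-dependent tidal
elevation, breath-hold gain dynamics, mains pickup, slow common drift
with controllable head–arm phase, and seeded artifacts with exact
corrupted intervals. It does **not** model cerebral hemodynamics, CO₂
kinetics, baroreflex or respiratory coupling, beat-to-beat RR
variability, electrode/skin physics, or amplitude nonstationarity beyond
the scripted gains. Passing tests therefore demonstrate that the
*estimators* recover known generative parameters under realistic noise —
not that the physiological interpretation of those parameters is correct
on real recordings. One visible artifact of the idealisation: at 75 bpm a
10-s epoch holds a non-integer number of beats, so a small beat-aliasing
component enters the epoch means and the session-level index plateaus
near ±0.94 rather than ±1; the analytically clean sine-pair scenario is
used where exact ±1 matters.

## Problem sizes

The default study-shaped session is 15 minutes at 200 Hz (three channels,
180 000 samples each): 10 minutes supine control containing three 30-s
breath-holds with 2.5-minute rests, then 5 minutes of HDT — long enough
for ≥ 50 classified beats per condition and full 5-minute index windows,
while keeping a full test run in seconds. The bench sine-pair scenario is
25 minutes with the middle 10 minutes phase-inverted.

## Known limitations

* Peak amplitudes are referenced to the beat-onset minimum (the cursor
  procedure), not to a fitted baseline; strong drift within a beat biases
  amplitudes by the drift excursion over ~0.4 s.
* The shoulder detector requires the derivative bump to stay strictly
  negative; a shoulder that momentarily plateaus at zero slope registers
  as a true P2.
* EDF export pads the final 1-second record by repeating the last sample;
  readers see up to one extra second on non-integer-length recordings.
* The native dialect is this package's own documented format, not a
  reconstruction of any proprietary acquisition format.
* No mmHg calibration: morphology classes and the index are
  dimensionless; the pipeline deliberately does not estimate absolute
  intracranial pressure.
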