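"""Challenge-level analytics: breath-hold responses, control-vs-HDT
morphology comparison, and session report tables.

A 30-second voluntary breath-hold raises blood CO2 and transiently
increases the pulse amplitude; the analytics here quantify the response as
the maximal P1 within a search window from the hold's start, the delay to
that maximum, and the change as a percentage of the pre-hold baseline
(BL%). Head-down tilt raises intracranial volume load; its signature is a
P2 (tidal-wave) elevation, quantified per channel as condition means with
a paired t-test on per-epoch means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pulses import baseline_percent

__all__ = [
    "BHResult",
    "HDTResult",
    "analyze_breath_hold",
    "compare_hdt",
    "paired_test",
    "build_report",
    "exclude_bh_windows",
]


def exclude_bh_windows(
    features_timeline: pd.DataFrame,
    bh_starts: list[float] | tuple[float, ...],
    window_s: float = 90.0,
) -> pd.DataFrame:
    """Drop beats inside breath-hold response windows.

    Condition means for the control-vs-HDT comparison must come from rest:
    a hold's transient amplitude response (which can outlast the hold by a
    minute) would otherwise inflate the baseline. ``window_s`` matches the
    breath-hold search window.
    """
    tl = features_timeline
    keep = np.ones(len(tl), dtype=bool)
    for s in bh_starts:
        keep &= ~((tl.onset_s >= s) & (tl.onset_s < s + window_s))
    return tl[keep]


@dataclass
class BHResult:
    """Quantified breath-hold response for one event."""

    bh_start_s: float
    bh_end_s: float
    baseline_p1_mean: float
    max_p1: float
    peak_delay_s: float
    bl_percent: float
    n_baseline_beats: int


@dataclass
class HDTResult:
    """Control-vs-head-down-tilt morphology comparison for one channel."""

    control_p1_mean: float
    control_p2_mean: float
    hdt_p1_mean: float
    hdt_p2_mean: float
    bl_percent_p1: float
    bl_percent_p2: float
    t_statistic: float
    p_value: float
    n_control_beats: int
    n_hdt_beats: int
    p2_elevated: bool


def analyze_breath_hold(
    features_timeline: pd.DataFrame,
    bh_start_s: float,
    bh_end_s: float,
    baseline_window_s: float = 30.0,
    search_end_s: float = 90.0,
) -> BHResult:
    """Quantify one breath-hold from a per-beat feature timeline.

    The baseline is the mean P1 over beats in the ``baseline_window_s``
    before the hold starts; the maximum P1 is searched from the start to
    ``search_end_s`` after it (responses peak anywhere from a few seconds
    after the start to well after the end). The peak delay runs from the
    start marker to the P1 peak of the beat carrying the maximum.
    """
    tl = features_timeline
    if bh_start_s >= bh_end_s:
        raise ValueError("breath-hold must have positive duration")
    if tl.empty or bh_end_s > tl.end_s.max() + 1.0:
        raise ValueError("breath-hold event lies outside the feature timeline")
    base = tl[
        (tl.onset_s >= bh_start_s - baseline_window_s)
        & (tl.onset_s < bh_start_s)
        & tl.p1_amp.notna()
    ]
    if base.empty:
        raise ValueError(
            f"no clean baseline beat in the {baseline_window_s:.0f} s before the hold"
        )
    search = tl[
        (tl.onset_s >= bh_start_s)
        & (tl.onset_s < bh_start_s + search_end_s)
        & tl.p1_amp.notna()
    ]
    if search.empty:
        raise ValueError("no clean beat in the breath-hold search window")
    baseline = float(base.p1_amp.mean())
    imax = search.p1_amp.idxmax()
    max_p1 = float(search.loc[imax, "p1_amp"])
    peak_time = float(search.loc[imax, "onset_s"]) + float(
        search.loc[imax, "p1_time_ms"]
    ) / 1000.0
    return BHResult(
        bh_start_s=bh_start_s,
        bh_end_s=bh_end_s,
        baseline_p1_mean=baseline,
        max_p1=max_p1,
        peak_delay_s=peak_time - bh_start_s,
        bl_percent=baseline_percent(baseline, max_p1),
        n_baseline_beats=len(base),
    )


def paired_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Classical paired t-test on the differences ``b − a``.

    Returns (t, two-sided p, n). With zero-variance, non-zero differences
    the statistic is unbounded: reported as signed infinity with p = 0 (a
    documented convention); identical inputs give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    d = b - a
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0, n
        return float(np.sign(mean)) * np.inf, 0.0, n
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p), n


def _epoch_means(tl: pd.DataFrame, column: str, epoch_s: float = 10.0) -> np.ndarray:
    """Per-epoch means of a per-beat quantity, relative to the timeline start."""
    sel = tl[tl[column].notna()]
    if sel.empty:
        return np.array([])
    t0 = sel.onset_s.min()
    bins = ((sel.onset_s - t0) // epoch_s).astype(int)
    return sel.groupby(bins)[column].mean().to_numpy()


def compare_hdt(
    features_control: pd.DataFrame,
    features_hdt: pd.DataFrame,
    epoch_s: float = 10.0,
    min_beats: int = 5,
) -> HDTResult:
    """Compare pulse morphology between supine control and head-down tilt.

    Means of P1 and P2 per condition, their BL% change, and a paired t-test
    on per-epoch P2 means (epoch pairing avoids the serial correlation of
    adjacent beats; the first k epochs of each condition are paired, k the
    smaller epoch count). P2 elevation is flagged when its BL% is positive.
    """
    n_c = int(features_control.p1_amp.notna().sum())
    n_h = int(features_hdt.p1_amp.notna().sum())
    if n_c < min_beats or n_h < min_beats:
        raise ValueError(
            f"need >= {min_beats} classified beats per condition, "
            f"got control={n_c}, hdt={n_h}"
        )
    c_p1 = float(features_control.p1_amp.mean())
    c_p2 = float(features_control.p2_amp.mean())
    h_p1 = float(features_hdt.p1_amp.mean())
    h_p2 = float(features_hdt.p2_amp.mean())
    ec = _epoch_means(features_control, "p2_amp", epoch_s)
    eh = _epoch_means(features_hdt, "p2_amp", epoch_s)
    k = min(ec.size, eh.size)
    if k >= 2:
        t, p, _ = paired_test(ec[:k], eh[:k])
    else:
        t, p = np.nan, np.nan
    bl_p2 = baseline_percent(c_p2, h_p2)
    return HDTResult(
        control_p1_mean=c_p1,
        control_p2_mean=c_p2,
        hdt_p1_mean=h_p1,
        hdt_p2_mean=h_p2,
        bl_percent_p1=baseline_percent(c_p1, h_p1),
        bl_percent_p2=bl_p2,
        t_statistic=t,
        p_value=p,
        n_control_beats=n_c,
        n_hdt_beats=n_h,
        p2_elevated=bl_p2 > 0,
    )


def build_report(
    subject: str,
    hdt_results: dict[str, HDTResult],
    bh_results: dict[str, list[BHResult]] | None = None,
    regx_r2: float | None = None,
) -> pd.DataFrame:
    """Assemble a per-recording report block.

    One row per channel x condition with P1/P2 means, BL% rows, and the
    R-squared between the two head-derivation index traces (marked absent
    when no arm channel was recorded, in which case the index could not be
    computed).
    """
    rows = []
    for channel, res in hdt_results.items():
        rows.append(
            {
                "subject": subject,
                "channel": channel,
                "condition": "control",
                "P1": res.control_p1_mean,
                "P2": res.control_p2_mean,
                "regx_r2": regx_r2 if regx_r2 is not None else np.nan,
            }
        )
        rows.append(
            {
                "subject": subject,
                "channel": channel,
                "condition": "HDT",
                "P1": res.hdt_p1_mean,
                "P2": res.hdt_p2_mean,
                "regx_r2": np.nan,
            }
        )
        rows.append(
            {
                "subject": subject,
                "channel": channel,
                "condition": "BL%",
                "P1": res.bl_percent_p1,
                "P2": res.bl_percent_p2,
                "regx_r2": np.nan,
            }
        )
    report = pd.DataFrame(rows)
    if bh_results:
        bh_rows = []
        for channel, results in bh_results.items():
            for i, r in enumerate(results, 1):
                bh_rows.append(
                    {
                        "subject": subject,
                        "channel": channel,
                        "condition": f"BH{i}",
                        "P1": r.max_p1,
                        "P2": np.nan,
                        "regx_r2": np.nan,
                        "bl_percent": r.bl_percent,
                        "peak_delay_s": r.peak_delay_s,
                    }
                )
        report = pd.concat([report, pd.DataFrame(bh_rows)], ignore_index=True)
    return report
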