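"""Stimulus-response kinetics on per-cell intensity traces.

Quantifies, per cell and per series (451 nm, 560 nm, ORR): pre-stimulus
baseline drift, onset delay after the stimulus, initial rise rate, and time
to peak.

Onset rule: the moving-average-smoothed trace must exceed
``baseline_mean + k_sd * baseline_sd`` for ``m_consecutive`` frames. Because
threshold crossing is late for shallow ramps, the crossing is refined by a
piecewise flat-then-ramp least-squares fit (grid search over candidate onset
frames between the stimulus and the crossing); the refinement is exact on
noiseless ramps and can be disabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .metrics import CellTrace

__all__ = [
    "OnsetResult",
    "PeakResult",
    "baseline_drift",
    "detect_onset",
    "rise_rate",
    "time_to_peak",
    "analyze_traces",
]


@dataclass(frozen=True)
class OnsetResult:
    onset_delay_s: float | None
    onset_time_s: float | None
    no_response: bool
    degenerate_baseline: bool = False


@dataclass(frozen=True)
class PeakResult:
    time_to_peak_s: float
    peak_value: float
    unpeaked: bool


def _smooth(trace: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return np.asarray(trace, dtype=float)
    return uniform_filter1d(np.asarray(trace, dtype=float), size=window, mode="nearest")


def baseline_drift(
    trace: np.ndarray,
    time_s: np.ndarray,
    stimulus_time_s: float,
    n_window: int = 10,
) -> float:
    """Signed percent change across the pre-stimulus segment.

    Compares the first ``n_window`` frames with the last ``n_window`` frames
    strictly before the stimulus; negative values mean a decline.
    """
    trace = np.asarray(trace, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    if not (time_s[0] < stimulus_time_s <= time_s[-1]):
        raise ValueError("stimulus_time_s must be positive and within the record")
    pre = trace[time_s < stimulus_time_s]
    if len(pre) < 2 * n_window:
        raise ValueError(
            f"pre-stimulus segment has {len(pre)} frames; needs at least {2 * n_window}"
        )
    first = float(np.mean(pre[:n_window]))
    last = float(np.mean(pre[-n_window:]))
    if first <= 0:
        raise ValueError("initial window mean must be positive")
    return (last - first) / first * 100.0


def detect_onset(
    trace: np.ndarray,
    time_s: np.ndarray,
    stimulus_time_s: float,
    k_sd: float = 3.0,
    m_consecutive: int = 25,
    smooth_window: int = 25,
    refine: bool = True,
    refine_window_s: float = 2.0,
) -> OnsetResult:
    """Delay between the stimulus and the first sustained rise of the trace."""
    trace = np.asarray(trace, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    if not (time_s[0] <= stimulus_time_s <= time_s[-1]):
        raise ValueError("stimulus_time_s must lie within the record")
    sm = _smooth(trace, smooth_window)
    pre = time_s < stimulus_time_s
    if pre.sum() < 2:
        raise ValueError("pre-stimulus segment too short to estimate a baseline")
    base_mean = float(sm[pre].mean())
    base_sd = float(sm[pre].std(ddof=1))

    degenerate = base_sd == 0.0
    threshold = base_mean if degenerate else base_mean + k_sd * base_sd

    post = np.flatnonzero(time_s >= stimulus_time_s)
    above = sm[post] > threshold
    crossing = None
    run = 0
    for j, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run >= m_consecutive:
            crossing = post[j - m_consecutive + 1]
            break
    if crossing is None:
        return OnsetResult(None, None, no_response=True, degenerate_baseline=degenerate)

    onset_time = float(time_s[crossing])
    if refine:
        onset_time = _refine_onset(
            trace, time_s, stimulus_time_s, crossing, base_mean, refine_window_s
        )
    onset_time = max(onset_time, stimulus_time_s)
    return OnsetResult(
        onset_delay_s=onset_time - stimulus_time_s,
        onset_time_s=onset_time,
        no_response=False,
        degenerate_baseline=degenerate,
    )


def _refine_onset(
    trace: np.ndarray,
    time_s: np.ndarray,
    stimulus_time_s: float,
    crossing: int,
    base_mean: float,
    refine_window_s: float,
) -> float:
    """Piecewise flat/ramp fit: grid-search the breakpoint minimizing SSE.

    The model is flat at the baseline mean up to the breakpoint, then a line
    through (breakpoint, baseline) with a free slope; fitted on the raw trace
    from the stimulus to shortly after the threshold crossing.
    """
    dt = float(np.median(np.diff(time_s)))
    extend = int(round(refine_window_s / dt))
    stim_idx = int(np.searchsorted(time_s, stimulus_time_s))
    stop = min(len(trace), crossing + extend)

    y = trace[stim_idx:stop]
    t = time_s[stim_idx:stop]
    # candidate breakpoints run past the crossing: centered smoothing makes
    # the threshold crossing land up to half a window early on clean ramps
    last_b = min(len(y) - 3, crossing - stim_idx + extend // 2)
    if last_b < 0:
        return float(time_s[crossing])
    best_sse, best_t0 = np.inf, float(time_s[crossing])
    for b in range(0, last_b + 1):
        t0 = t[b]
        sse_flat = float(np.sum((y[:b] - base_mean) ** 2))
        dtb = t[b:] - t0
        yb = y[b:] - base_mean
        # ramp model: line through (t0, baseline) with a free non-negative slope
        denom = float(dtb @ dtb)
        slope = max(float(dtb @ yb) / denom, 0.0) if denom > 0 else 0.0
        resid_ramp = yb - slope * dtb
        sse_ramp = sse_flat + float(resid_ramp @ resid_ramp)
        # step model: jump at t0 to a free level (handles abrupt responses)
        resid_step = yb - yb.mean()
        sse_step = sse_flat + float(resid_step @ resid_step)
        sse = min(sse_ramp, sse_step)
        if sse < best_sse:
            best_sse, best_t0 = sse, float(t0)
    return best_t0


def rise_rate(
    trace: np.ndarray,
    time_s: np.ndarray,
    onset_time_s: float,
    fit_window_s: float = 2.0,
) -> float:
    """Least-squares slope of intensity vs time over [onset, onset+window]."""
    trace = np.asarray(trace, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    end = onset_time_s + fit_window_s
    if onset_time_s < time_s[0] or end > time_s[-1] + 1e-9:
        raise ValueError(
            f"fit window [{onset_time_s:.3f}, {end:.3f}] s extends beyond the record"
        )
    sel = (time_s >= onset_time_s) & (time_s <= end)
    if sel.sum() < 3:
        raise ValueError(f"fit window holds only {int(sel.sum())} samples; needs >= 3")
    slope, _ = np.polyfit(time_s[sel], trace[sel], 1)
    return float(slope)


def time_to_peak(
    trace: np.ndarray,
    time_s: np.ndarray,
    stimulus_time_s: float,
    onset_time_s: float,
    smooth_window: int = 25,
) -> PeakResult:
    """Time of the smoothed post-onset maximum, relative to the stimulus.

    A trace still rising at the end of the record reports the record end and
    is flagged ``unpeaked``.
    """
    trace = np.asarray(trace, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    sm = _smooth(trace, smooth_window)
    post = np.flatnonzero(time_s >= onset_time_s)
    if post.size == 0:
        raise ValueError("onset_time_s beyond the record")
    seg = sm[post]
    peak_j = int(np.argmax(seg))
    unpeaked = peak_j >= seg.size - max(1, smooth_window)
    if unpeaked:
        peak_j = seg.size - 1
    idx = post[peak_j]
    return PeakResult(
        time_to_peak_s=float(time_s[idx] - stimulus_time_s),
        peak_value=float(seg[peak_j]),
        unpeaked=unpeaked,
    )


def analyze_traces(
    traces: list[CellTrace],
    stimulus_time_s: float,
    n_window: int = 10,
    k_sd: float = 3.0,
    m_consecutive: int = 25,
    smooth_window: int = 25,
    fit_window_s: float = 2.0,
    refine_onset: bool = True,
    refine_window_s: float = 2.0,
    smooth_orr: bool = True,
) -> pd.DataFrame:
    """Per-cell, per-series kinetics table.

    The ORR series divides smoothed channel means (smooth-then-ratio) by
    default, since frame-level ratios of low counts amplify noise; set
    ``smooth_orr=False`` for the raw per-frame ratio.
    """
    rows = []
    for tr in traces:
        if smooth_orr:
            s451 = _smooth(tr.mean_451, smooth_window)
            s560 = _smooth(tr.mean_560, smooth_window)
            orr_series = s451 / (s451 + s560)
        else:
            orr_series = tr.orr
        for name, series in (("451", tr.mean_451), ("560", tr.mean_560), ("orr", orr_series)):
            row = {"cell_id": tr.cell_id, "series": name}
            row["baseline_drift_percent"] = baseline_drift(
                series, tr.time_s, stimulus_time_s, n_window
            )
            onset = detect_onset(
                series,
                tr.time_s,
                stimulus_time_s,
                k_sd=k_sd,
                m_consecutive=m_consecutive,
                smooth_window=smooth_window,
                refine=refine_onset,
                refine_window_s=refine_window_s,
            )
            row["no_response"] = onset.no_response
            row["degenerate_baseline"] = onset.degenerate_baseline
            if onset.no_response:
                row.update(
                    onset_delay_s=np.nan,
                    rise_rate_au_per_s=np.nan,
                    time_to_peak_s=np.nan,
                    peak_value=np.nan,
                    unpeaked=False,
                )
            else:
                row["onset_delay_s"] = onset.onset_delay_s
                window = min(fit_window_s, tr.time_s[-1] - onset.onset_time_s)
                row["rise_rate_au_per_s"] = rise_rate(
                    series, tr.time_s, onset.onset_time_s, window
                )
                peak = time_to_peak(
                    series, tr.time_s, stimulus_time_s, onset.onset_time_s, smooth_window
                )
                row["time_to_peak_s"] = peak.time_to_peak_s
                row["peak_value"] = peak.peak_value
                row["unpeaked"] = peak.unpeaked
            rows.append(row)
    return pd.DataFrame(rows)
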