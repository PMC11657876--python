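"""Core intensity metrics: optical redox ratio, photobleaching percent, SNR,
and per-frame ROI trace extraction.

The optical redox ratio (ORR) of a pair of channel means is

    orr = mean_451 / (mean_451 + mean_560)

computed as a ratio of means (means first, then the ratio), never a mean of
pixel ratios. Photobleaching over a time series is quantified from the
averages of the first and last ``n_window`` frames under two sign
conventions:

* ``loss``:   (initial - final) / initial * 100  (positive = bleaching)
* ``signed``: (final - initial) / initial * 100  (a conventional signed change)

Reported percents are conventionally rounded to one decimal; all functions
return full precision and leave rounding to the caller (`round_percent`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_io import ChannelStack
from .segmentation import LabelMask

__all__ = [
    "CellTrace",
    "PhotobleachReport",
    "SNRReport",
    "compute_orr",
    "orr_image",
    "percent_change",
    "round_percent",
    "photobleach_report",
    "compute_snr",
    "extract_traces",
]

_CONVENTIONS = ("loss", "signed")
_SNR_DEFINITIONS = ("contrast", "ratio")


@dataclass
class CellTrace:
    """Per-cell, per-channel mean-intensity time series."""

    cell_id: int
    mean_451: np.ndarray
    mean_560: np.ndarray
    time_s: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        self.mean_451 = np.asarray(self.mean_451, dtype=float)
        self.mean_560 = np.asarray(self.mean_560, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if not (len(self.mean_451) == len(self.mean_560) == len(self.time_s)):
            raise ValueError("trace series must have equal lengths")
        if self.mean_451.min(initial=0) < 0 or self.mean_560.min(initial=0) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def orr(self) -> np.ndarray:
        """Per-frame ORR of the two channel means."""
        total = self.mean_451 + self.mean_560
        if np.any(total <= 0):
            raise ValueError("ORR undefined where both channel means are zero")
        return self.mean_451 / total


@dataclass
class SNRReport:
    signal_mean: float
    background_mean: float
    background_sd: float
    snr: float
    definition: str


@dataclass
class PhotobleachReport:
    """First/last window means and percent changes per cell and per metric."""

    cell_ids: list[int]
    n_window: int
    initial_window_mean: dict  # {"451"|"560"|"orr": np.ndarray per cell}
    final_window_mean: dict
    percent_loss: dict
    percent_signed: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric in ("451", "560", "orr"):
            for i, cid in enumerate(self.cell_ids):
                rows.append(
                    {
                        "cell_id": cid,
                        "metric": metric,
                        "initial_window_mean": self.initial_window_mean[metric][i],
                        "final_window_mean": self.final_window_mean[metric][i],
                        "percent_loss": self.percent_loss[metric][i],
                        "percent_signed": self.percent_signed[metric][i],
                        "n_window": self.n_window,
                    }
                )
        return pd.DataFrame(rows)


def compute_orr(mean_451: float, mean_560: float) -> float:
    """ORR of two channel mean intensities."""
    if mean_451 < 0 or mean_560 < 0:
        raise ValueError("channel means must be non-negative")
    total = mean_451 + mean_560
    if total == 0:
        raise ValueError("ORR undefined: both channel means are zero")
    return float(mean_451) / float(total)


def orr_image(
    img_451: np.ndarray, img_560: np.ndarray, mask: np.ndarray
) -> float:
    """Image-level ORR: masked channel means first, then the ratio."""
    img_451 = np.asarray(img_451, dtype=float)
    img_560 = np.asarray(img_560, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img_451.shape or img_451.shape != img_560.shape:
        raise ValueError("images and mask must share a shape")
    if not mask.any():
        raise ValueError("empty mask: no pixels above threshold")
    return compute_orr(float(img_451[mask].mean()), float(img_560[mask].mean()))


def percent_change(initial: float, final: float, convention: str = "loss") -> float:
    """Percent change between two window means under either sign convention."""
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}")
    if initial <= 0:
        raise ValueError(f"initial window mean must be positive, got {initial}")
    if convention == "loss":
        return (initial - final) / initial * 100.0
    return (final - initial) / initial * 100.0


def round_percent(value, decimals: int = 1):
    """Reporting convention: percents printed at one decimal."""
    return np.round(value, decimals)


def _window_means(series: np.ndarray, n_window: int) -> tuple[float, float]:
    return float(np.mean(series[:n_window])), float(np.mean(series[-n_window:]))


def photobleach_report(
    traces: list[CellTrace] | CellTrace, n_window: int = 10
) -> PhotobleachReport:
    """Windowed percent changes for the 451, 560, and per-frame-ORR series.

    Each trace must span at least ``2 * n_window`` frames so the first and
    last windows do not overlap.
    """
    if isinstance(traces, CellTrace):
        traces = [traces]
    if not traces:
        raise ValueError("no traces given")
    initial = {m: [] for m in ("451", "560", "orr")}
    final = {m: [] for m in ("451", "560", "orr")}
    loss = {m: [] for m in ("451", "560", "orr")}
    signed = {m: [] for m in ("451", "560", "orr")}
    cell_ids = []
    for tr in traces:
        if len(tr.mean_451) < 2 * n_window:
            raise ValueError(
                f"trace for cell {tr.cell_id} has {len(tr.mean_451)} frames; "
                f"needs at least {2 * n_window}"
            )
        cell_ids.append(tr.cell_id)
        for metric, series in (("451", tr.mean_451), ("560", tr.mean_560), ("orr", tr.orr)):
            first, last = _window_means(series, n_window)
            initial[metric].append(first)
            final[metric].append(last)
            loss[metric].append(percent_change(first, last, "loss"))
            signed[metric].append(percent_change(first, last, "signed"))
    return PhotobleachReport(
        cell_ids=cell_ids,
        n_window=n_window,
        initial_window_mean={m: np.array(v) for m, v in initial.items()},
        final_window_mean={m: np.array(v) for m, v in final.items()},
        percent_loss={m: np.array(v) for m, v in loss.items()},
        percent_signed={m: np.array(v) for m, v in signed.items()},
    )


def compute_snr(
    image: np.ndarray,
    signal_mask: np.ndarray,
    background_mask: np.ndarray,
    definition: str = "contrast",
) -> SNRReport:
    """SNR of an image given disjoint signal and background pixel sets.

    ``contrast``: (signal_mean - background_mean) / background_sd (default;
    invariant to a constant offset). ``ratio``: signal_mean / background_sd.
    """
    if definition not in _SNR_DEFINITIONS:
        raise ValueError(f"definition must be one of {_SNR_DEFINITIONS}")
    image = np.asarray(image, dtype=float)
    signal_mask = np.asarray(signal_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not signal_mask.any() or not background_mask.any():
        raise ValueError("signal and background masks must both be non-empty")
    if (signal_mask & background_mask).any():
        raise ValueError("signal and background masks must be disjoint")
    sig = float(image[signal_mask].mean())
    bg = float(image[background_mask].mean())
    bg_sd = float(image[background_mask].std(ddof=1))
    if bg_sd == 0:
        raise ValueError("zero background variance: SNR undefined")
    snr = (sig - bg) / bg_sd if definition == "contrast" else sig / bg_sd
    return SNRReport(
        signal_mean=sig,
        background_mean=bg,
        background_sd=bg_sd,
        snr=snr,
        definition=definition,
    )


def extract_traces(channel_stack: ChannelStack, label_mask: LabelMask) -> list[CellTrace]:
    """Per-frame ROI mean intensities for both channels, one trace per label.

    Both channels are averaged over the same pixel set (the mask drawn on the
    451-nm channel). Zero-pixel labels are excluded with a warning.
    """
    labels = label_mask.labels
    if labels.shape != channel_stack.frame_shape:
        raise ValueError(
            f"label mask shape {labels.shape} does not match frame shape "
            f"{channel_stack.frame_shape}"
        )
    traces = []
    for cid in range(1, label_mask.n_cells + 1):
        rows, cols = np.nonzero(labels == cid)
        if rows.size == 0:
            warnings.warn(f"label {cid} has zero pixels; excluded", stacklevel=2)
            continue
        m451 = channel_stack.data_451[:, rows, cols].mean(axis=1)
        m560 = channel_stack.data_560[:, rows, cols].mean(axis=1)
        traces.append(
            CellTrace(
                cell_id=cid,
                mean_451=m451,
                mean_560=m560,
                time_s=channel_stack.time_s,
                n_pixels=int(rows.size),
            )
        )
    return traces
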