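"""Background thresholding, cell labeling, and static ROI propagation.

The analysis convention: a threshold removes low-intensity background and
(dim) nucleus pixels on the 451-nm channel; cell ROIs are connected
components of the thresholded image, optionally with holes filled so the
nucleus belongs to its cell for trace extraction. ROIs are static — one
pixel set applied to every frame of both channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label

__all__ = [
    "ThresholdResult",
    "LabelMask",
    "threshold_background",
    "segment_cells",
    "propagate_rois",
]

_METHODS = ("fixed", "percentile", "otsu")


@dataclass(frozen=True)
class ThresholdResult:
    mask: np.ndarray
    threshold: float
    method: str
    warning: str | None = None


@dataclass
class LabelMask:
    """Integer cell-label image (0 = background, 1..N = cells)."""

    labels: np.ndarray
    provenance: dict
    source_channel: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def threshold_background(
    image: np.ndarray,
    method: str = "otsu",
    value: float | None = None,
    percentile: float | None = None,
) -> ThresholdResult:
    """Binary foreground mask: pixels strictly above the chosen threshold.

    Methods: ``fixed`` (explicit ``value``), ``percentile`` (``percentile``
    of the intensity distribution), or ``otsu`` (maximal between-class
    variance). A constant image under otsu yields an empty mask plus a
    warning flag rather than an error.
    """
    image = np.asarray(image)
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    warning = None
    if method == "fixed":
        if value is None:
            raise ValueError("fixed method requires a threshold value")
        thr = float(value)
    elif method == "percentile":
        if percentile is None:
            raise ValueError("percentile method requires a percentile")
        thr = float(np.percentile(image, percentile))
    else:
        if image.min() == image.max():
            warning = "constant image: otsu threshold undefined, mask is empty"
            warnings.warn(warning, stacklevel=2)
            thr = float(image.flat[0]) if image.size else 0.0
        else:
            thr = float(threshold_otsu(image))
    return ThresholdResult(mask=image > thr, threshold=thr, method=method, warning=warning)


def segment_cells(
    image: np.ndarray,
    mask: np.ndarray,
    min_area: int = 100,
    fill_holes: bool = True,
    provenance: dict | None = None,
    source_channel: str | None = "451",
) -> LabelMask:
    """Label connected foreground components of at least ``min_area`` pixels.

    With ``fill_holes`` the nucleus hole inside each cell is absorbed into
    its ROI (mirroring whole-cell manual tracing); without it, only
    above-threshold pixels are kept (the image-level metric convention).
    Touching cells are not separated; phantoms are non-touching by design.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
    work = ndi.binary_fill_holes(mask) if fill_holes else mask
    labels = _cc_label(work, connectivity=2)
    if labels.max():
        areas = np.bincount(labels.ravel())
        keep = np.flatnonzero(areas >= min_area)
        keep = keep[keep > 0]
        remap = np.zeros(areas.size, dtype=np.int32)
        remap[keep] = np.arange(1, len(keep) + 1)
        labels = remap[labels]
    prov = {"min_area": min_area, "fill_holes": fill_holes}
    if provenance:
        prov.update(provenance)
    return LabelMask(labels=labels.astype(np.int32), provenance=prov, source_channel=source_channel)


def propagate_rois(label_mask: LabelMask, channel_stack) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Static per-cell pixel memberships, identical on every frame/channel.

    Returns ``{cell_id: (rows, cols)}``. There is deliberately no tracking:
    a single trace drawn on the 451-nm channel is applied to all frames of
    both channels.
    """
    labels = label_mask.labels
    if labels.shape != channel_stack.frame_shape:
        raise ValueError(
            f"label mask shape {labels.shape} does not match frame shape "
            f"{channel_stack.frame_shape}"
        )
    return {
        int(cid): np.nonzero(labels == cid) for cid in label_mask.cell_ids
    }
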