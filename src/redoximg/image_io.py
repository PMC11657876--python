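"""Split-frame TIFF I/O, acquisition metadata, and channel registration.

Each acquired frame holds two spectrally distinct half-FOV sub-images side by
side: one half is the 451-nm emission band, the other the 560-nm band. This
module reads/writes multi-page grayscale TIFF stacks, splits frames into the
two channels, and estimates any residual integer-pixel offset between the two
halves by normalized cross-correlation.

Conventions
-----------
* Arrays are row-major, origin top-left, 0-based indices.
* Timebase: ``t = frame_index / frame_rate_hz``, first frame at t=0.
* ``layout`` names the half carrying the 451-nm channel ("left" or "right");
  the default is "left" (the transmitted path of the splitter), configurable
  because the assignment depends on the optical build.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import tifffile
import yaml

__all__ = [
    "AcquisitionMeta",
    "ChannelStack",
    "RegistrationResult",
    "read_stack",
    "write_stack",
    "read_meta",
    "write_meta",
    "split_frame",
    "compose_frame",
    "register_channels",
    "shift_image",
    "channel_stack_from_frames",
]

_VALID_LAYOUTS = ("left", "right")

#: exposure cannot exceed the frame interval: rate [Hz] x exposure [ms] <= 1000
_EXPOSURE_BUDGET_MS_HZ = 1000.0
_EXPOSURE_TOL = 1e-6


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata attached to every split-frame stack."""

    illumination_mw: float
    exposure_ms: float
    frame_rate_hz: float
    pixel_size_um: float = 0.16
    layout: str = "left"
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.layout not in _VALID_LAYOUTS:
            raise ValueError(
                f"layout must be one of {_VALID_LAYOUTS}, got {self.layout!r}"
            )
        for name in ("illumination_mw", "exposure_ms", "frame_rate_hz", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        budget = self.frame_rate_hz * self.exposure_ms
        if budget > _EXPOSURE_BUDGET_MS_HZ * (1 + _EXPOSURE_TOL):
            raise ValueError(
                "exposure exceeds the frame interval: "
                f"frame_rate_hz*exposure_ms = {budget:.3f} > 1000"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def frame_interval_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    def to_dict(self) -> dict:
        return {
            "illumination_mw": float(self.illumination_mw),
            "exposure_ms": float(self.exposure_ms),
            "frame_rate_hz": float(self.frame_rate_hz),
            "pixel_size_um": float(self.pixel_size_um),
            "layout": self.layout,
            "bit_depth": int(self.bit_depth),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        return cls(**d)


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of integer-pixel channel registration.

    ``shift`` is the displacement (dy, dx) of the 560-nm content relative to
    the 451-nm content; ``aligned`` is the 560-nm image translated by
    ``-shift`` (vacated pixels zero-filled).
    """

    shift: tuple[int, int]
    aligned: np.ndarray
    correlation: float
    low_correlation: bool


@dataclass
class ChannelStack:
    """Registered per-channel T x H x W intensity arrays on a shared timebase."""

    data_451: np.ndarray
    data_560: np.ndarray
    time_s: np.ndarray
    meta: AcquisitionMeta
    registration_shift: tuple[int, int] = (0, 0)
    registration_correlation: float | None = None

    def __post_init__(self) -> None:
        self.data_451 = np.asarray(self.data_451)
        self.data_560 = np.asarray(self.data_560)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.data_451.shape != self.data_560.shape:
            raise ValueError(
                f"channel shapes differ: {self.data_451.shape} vs {self.data_560.shape}"
            )
        if self.data_451.ndim != 3:
            raise ValueError("channel data must be T x H x W")
        if len(self.time_s) != self.data_451.shape[0]:
            raise ValueError("time_s length must equal the number of frames")
        if self.data_451.size and (self.data_451.min() < 0 or self.data_560.min() < 0):
            raise ValueError("intensities must be non-negative")
        dt = np.diff(self.time_s)
        if dt.size:
            if np.any(dt <= 0):
                raise ValueError("time_s must be strictly increasing")
            expected = self.meta.frame_interval_s
            if not np.allclose(dt, expected, rtol=1e-6, atol=1e-9):
                raise ValueError(
                    "time_s spacing must equal 1/frame_rate_hz "
                    f"({expected:.6g} s)"
                )

    @property
    def n_frames(self) -> int:
        return self.data_451.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data_451.shape[1:]


def read_stack(path) -> np.ndarray:
    """Read a multi-page grayscale TIFF into a T x H x W array.

    Raises ``ValueError`` for RGB/multichannel pages or pages of mixed sizes,
    and lets ``tifffile`` raise for unreadable files.
    """
    frames: list[np.ndarray] = []
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            arr = page.asarray()
            if arr.ndim != 2:
                raise ValueError(
                    f"page {i} is not single-channel grayscale (shape {arr.shape})"
                )
            if frames and arr.shape != frames[0].shape:
                raise ValueError(
                    f"inconsistent page sizes: page 0 is {frames[0].shape}, "
                    f"page {i} is {arr.shape}"
                )
            frames.append(arr)
    if not frames:
        raise ValueError(f"no image pages found in {path}")
    return np.stack(frames)


def write_stack(path, stack: np.ndarray, meta: AcquisitionMeta | None = None) -> None:
    """Write a T x H x W array as a multi-page grayscale TIFF.

    Metadata, if given, is embedded as YAML in the image-description tag so a
    stack file is self-describing; a sidecar YAML (``write_meta``) also works.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError("stack must be T x H x W")
    description = yaml.safe_dump(meta.to_dict()) if meta is not None else None
    tifffile.imwrite(path, stack, photometric="minisblack", description=description)


def read_meta(path) -> AcquisitionMeta:
    """Read acquisition metadata from a YAML sidecar or a TIFF description tag."""
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            return AcquisitionMeta.from_dict(yaml.safe_load(fh))
    with tifffile.TiffFile(path) as tif:
        desc = tif.pages[0].description
    if not desc:
        raise ValueError(f"no metadata description found in {path}")
    return AcquisitionMeta.from_dict(yaml.safe_load(desc))


def write_meta(path, meta: AcquisitionMeta) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(meta.to_dict(), fh)


def split_frame(frame: np.ndarray, layout: str = "left") -> tuple[np.ndarray, np.ndarray]:
    """Split one frame into its (img_451, img_560) halves.

    ``layout`` gives the half that carries the 451-nm channel. The frame
    width must be even so the two halves are equal.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if layout not in _VALID_LAYOUTS:
        raise ValueError(f"layout must be one of {_VALID_LAYOUTS}, got {layout!r}")
    h, w = frame.shape
    if w % 2:
        raise ValueError(f"frame width {w} is odd; cannot split into equal halves")
    left, right = frame[:, : w // 2], frame[:, w // 2 :]
    return (left, right) if layout == "left" else (right, left)


def compose_frame(img_451: np.ndarray, img_560: np.ndarray, layout: str = "left") -> np.ndarray:
    """Inverse of :func:`split_frame`."""
    img_451 = np.asarray(img_451)
    img_560 = np.asarray(img_560)
    if img_451.shape != img_560.shape:
        raise ValueError("channel halves must have identical shapes")
    if layout not in _VALID_LAYOUTS:
        raise ValueError(f"layout must be one of {_VALID_LAYOUTS}, got {layout!r}")
    pair = (img_451, img_560) if layout == "left" else (img_560, img_451)
    return np.concatenate(pair, axis=1)


def shift_image(img: np.ndarray, shift: tuple[int, int], fill: float = 0) -> np.ndarray:
    """Translate an image by integer (dy, dx); vacated pixels get ``fill``."""
    dy, dx = int(shift[0]), int(shift[1])
    out = np.full_like(img, fill)
    h, w = img.shape
    ys = slice(max(0, dy), h + min(0, dy))
    xs = slice(max(0, dx), w + min(0, dx))
    ys_src = slice(max(0, -dy), h + min(0, -dy))
    xs_src = slice(max(0, -dx), w + min(0, -dx))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equal-shape arrays; 0 if either is constant."""
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


def register_channels(
    img_451: np.ndarray,
    img_560: np.ndarray,
    max_shift: int = 10,
    low_correlation_threshold: float = 0.2,
) -> RegistrationResult:
    """Find the integer shift of the 560-nm half relative to the 451-nm half.

    Exhaustively scores every integer (dy, dx) within ``+-max_shift`` by the
    normalized cross-correlation of the overlapping regions and returns the
    maximizer. Subpixel registration is deliberately not attempted: the
    downstream analysis never resamples and integer alignment avoids
    interpolation artifacts.
    """
    img_451 = np.asarray(img_451)
    img_560 = np.asarray(img_560)
    if img_451.shape != img_560.shape:
        raise ValueError("images must have identical shapes")
    max_shift = int(max_shift)
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    h, w = img_451.shape
    if max_shift >= min(h, w):
        raise ValueError(
            f"max_shift {max_shift} exceeds the image extent {img_451.shape}"
        )

    best = (-np.inf, (0, 0))
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            a = img_451[max(0, -dy) : h - max(0, dy), max(0, -dx) : w - max(0, dx)]
            b = img_560[max(0, dy) : h + min(0, dy), max(0, dx) : w + min(0, dx)]
            r = _ncc(a, b)
            # deterministic tie-break: prefer the smaller shift
            key = (r, -(abs(dy) + abs(dx)))
            if key > (best[0], -(abs(best[1][0]) + abs(best[1][1]))):
                best = (r, (dy, dx))
    corr, shift = best
    aligned = shift_image(img_560, (-shift[0], -shift[1]))
    return RegistrationResult(
        shift=shift,
        aligned=aligned,
        correlation=corr,
        low_correlation=corr < low_correlation_threshold,
    )


def channel_stack_from_frames(
    stack: np.ndarray,
    meta: AcquisitionMeta,
    register: bool = False,
    max_shift: int = 10,
) -> ChannelStack:
    """Split every frame of a raw stack and optionally register the channels.

    Registration is estimated once on the time-averaged halves (the offset is
    a property of the optics, not of time) and applied to every 560-nm frame.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    halves = [split_frame(frame, meta.layout) for frame in stack]
    data_451 = np.stack([h[0] for h in halves])
    data_560 = np.stack([h[1] for h in halves])

    shift = (0, 0)
    corr: float | None = None
    if register:
        reg = register_channels(
            data_451.mean(axis=0), data_560.mean(axis=0), max_shift=max_shift
        )
        shift, corr = reg.shift, reg.correlation
        if reg.low_correlation:
            warnings.warn(
                "low cross-correlation between channel halves; "
                "registration shift may be unreliable",
                stacklevel=2,
            )
        if shift != (0, 0):
            data_560 = np.stack(
                [shift_image(f, (-shift[0], -shift[1])) for f in data_560]
            )
    time_s = np.arange(stack.shape[0]) / meta.frame_rate_hz
    return ChannelStack(
        data_451=data_451,
        data_560=data_560,
        time_s=time_s,
        meta=meta,
        registration_shift=shift,
        registration_correlation=corr,
    )
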