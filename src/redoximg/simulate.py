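"""Synthetic split-FOV dual-channel time-lapse generator with ground truth.

Emulates the three experiment types the analysis pipeline targets:

* snapshot group comparisons (optionally with a cyanide-like perturbation
  that raises 451-nm cytoplasm intensity),
* continuous-illumination photobleaching runs (monoexponential decay with
  per-cell rate spread),
* glucose-bolus stimulus runs (per-cell delayed piecewise-linear rise with
  heterogeneous rates).

Cell phantoms are elliptical, with a dim nucleus, bright cytoplasm and
punctate mitochondria. Expected cytoplasm intensity scales linearly with
``illumination_mw * exposure_ms`` relative to a fixed reference
(4.14 mW x 10 ms). The camera model is

    counts = Poisson(signal + background_offset) + Normal(0, read_noise_sd)

clipped to [0, 65535] and quantized to uint16 (quantization can be disabled
so noiseless output stays exact for oracle tests). The background offset is
treated as a photon-like background flux so that, with shot noise on,
per-pixel variance tracks the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .image_io import AcquisitionMeta, shift_image

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CellPhantom",
    "SimulationError",
    "make_cell_phantom",
    "apply_glucose_response",
    "simulate_timelapse",
    "add_camera_noise",
    "meta_from_config",
]

#: reference power x exposure at which base intensities are specified
REFERENCE_MW_MS = 4.14 * 10.0

#: frames generated/noised per chunk; fixed so RNG draws are reproducible
_CHUNK_FRAMES = 256

_PLACEMENT_RETRIES = 200


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Full description of one synthetic acquisition."""

    n_cells: int = 12
    fov_shape: tuple[int, int] = (128, 256)  # H x W per channel half
    pixel_size_um: float = 0.16
    n_frames: int = 100
    frame_rate_hz: float = 99.4
    illumination_mw: float = 4.14
    exposure_ms: float = 10.0
    base_intensity_451: float = 300.0
    base_intensity_560: float = 150.0
    nucleus_factor: float = 0.4
    mito_density: float = 25.0  # expected puncta per cell
    mito_factor: float = 1.8
    bleach_rate_451: float = 0.0  # 1/s
    bleach_rate_560: float = 0.0  # 1/s
    bleach_rate_sigma: float = 0.0  # lognormal sigma of the per-cell rate multiplier
    background_offset: float = 100.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    perturbation: str = "none"  # none | cyanide | glucose_bolus
    perturbation_params: dict = field(default_factory=dict)
    channel_shift: tuple[int, int] = (0, 0)  # applied to the 560 half
    layout: str = "left"
    cell_radius_px: tuple[float, float] = (10.0, 16.0)
    nucleus_fraction: float = 0.45  # nucleus semi-axes as a fraction of the cell's
    quantize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0 < self.nucleus_factor <= 1):
            raise ValueError("nucleus_factor must be in (0, 1]")
        for name in (
            "base_intensity_451",
            "base_intensity_560",
            "bleach_rate_451",
            "bleach_rate_560",
            "bleach_rate_sigma",
            "background_offset",
            "read_noise_sd",
            "mito_density",
            "illumination_mw",
            "exposure_ms",
            "frame_rate_hz",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.perturbation not in ("none", "cyanide", "glucose_bolus"):
            raise ValueError(f"unknown perturbation {self.perturbation!r}")
        if not (0 < self.nucleus_fraction < 1):
            raise ValueError("nucleus_fraction must be in (0, 1)")

    @property
    def intensity_scale(self) -> float:
        """Linear power x exposure scaling relative to the reference."""
        return (self.illumination_mw * self.exposure_ms) / REFERENCE_MW_MS

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class GroundTruth:
    """Everything the pipeline is supposed to recover, known exactly."""

    label_mask: np.ndarray  # H x W, 0 background, 1..n_cells
    time_s: np.ndarray
    true_trace_451: np.ndarray  # n_cells x T noiseless per-cell mean (incl. offset)
    true_trace_560: np.ndarray
    true_bleach_percent: dict  # {"451": arr, "560": arr, "orr": arr}; first/last-window convention
    bleach_rate_451: np.ndarray  # per-cell effective rates (1/s)
    bleach_rate_560: np.ndarray
    true_delay_s: np.ndarray | None = None  # glucose mode only
    true_rate_451_au_per_s: np.ndarray | None = None
    true_rate_560_au_per_s: np.ndarray | None = None
    stimulus_time_s: float | None = None


@dataclass
class CellPhantom:
    """Single-cell intensity templates (unit cytoplasm level) on a shared geometry."""

    template_451: np.ndarray
    template_560: np.ndarray
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    n_puncta: int


def _ellipse_mask(shape, center, axes, angle=0.0) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = center
    ay, ax = axes
    c, s = math.cos(angle), math.sin(angle)
    u = (yy - cy) * c + (xx - cx) * s
    v = -(yy - cy) * s + (xx - cx) * c
    return (u / ay) ** 2 + (v / ax) ** 2 <= 1.0


def make_cell_phantom(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    nucleus_axes: tuple[float, float],
    nucleus_factor: float,
    mito_density: float,
    mito_factor: float,
    rng: np.random.Generator,
    angle: float = 0.0,
) -> CellPhantom:
    """Render one elliptical cell into unit-intensity channel templates.

    The cytoplasm is 1.0, the nucleus is dimmed by ``nucleus_factor``, and
    mitochondrial puncta (expected count ``mito_density``, drawn Poisson)
    multiply their pixels by ``mito_factor``. Both channels share the same
    geometry.
    """
    if nucleus_axes[0] >= axes[0] or nucleus_axes[1] >= axes[1]:
        raise ValueError(
            f"nucleus axes {nucleus_axes} must be smaller than cell axes {axes}"
        )
    cell = _ellipse_mask(shape, center, axes, angle)
    nucleus = _ellipse_mask(shape, center, nucleus_axes, angle)
    nucleus &= cell

    template = np.zeros(shape, dtype=np.float64)
    template[cell] = 1.0
    template[nucleus] = nucleus_factor

    cyto = cell & ~nucleus
    n_puncta = 0
    if mito_density > 0 and cyto.any():
        n_puncta = int(rng.poisson(mito_density))
        rows, cols = np.nonzero(cyto)
        if n_puncta > 0:
            picks = rng.integers(0, len(rows), size=n_puncta)
            for p in picks:
                r, c = rows[p], cols[p]
                rr = slice(max(0, r - 1), r + 2)
                cc = slice(max(0, c - 1), c + 2)
                patch = cyto[rr, cc]
                template[rr, cc][patch] = mito_factor
    return CellPhantom(
        template_451=template,
        template_560=template.copy(),
        cell_mask=cell,
        nucleus_mask=nucleus,
        n_puncta=n_puncta,
    )


def apply_glucose_response(
    traces: np.ndarray,
    time_s: np.ndarray,
    stimulus_time_s: float,
    delay_s: np.ndarray,
    rate_au_per_s: np.ndarray,
    plateau_multiplier: float = 3.0,
    drift_au_per_s: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Impose a delayed piecewise-linear stimulus response on baseline traces.

    Each cell's trace is left at its baseline (plus an optional linear
    pre-stimulus drift) until ``stimulus_time_s + delay_s``, then rises
    linearly at ``rate_au_per_s`` until it reaches ``plateau_multiplier``
    times the baseline, after which it stays flat.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    time_s = np.asarray(time_s, dtype=float)
    if not (time_s[0] <= stimulus_time_s <= time_s[-1]):
        raise ValueError(
            f"stimulus_time_s={stimulus_time_s} outside the record "
            f"[{time_s[0]}, {time_s[-1]}]"
        )
    n_cells = traces.shape[0]
    delay_s = np.broadcast_to(np.asarray(delay_s, dtype=float), (n_cells,))
    rate = np.broadcast_to(np.asarray(rate_au_per_s, dtype=float), (n_cells,))
    drift = np.broadcast_to(np.asarray(drift_au_per_s, dtype=float), (n_cells,))
    if np.any(delay_s < 0):
        raise ValueError("delay_s must be non-negative")
    if np.any(rate < 0):
        raise ValueError("rate_au_per_s must be non-negative")

    out = traces.copy()
    stim_idx = int(np.searchsorted(time_s, stimulus_time_s))
    for i in range(n_cells):
        m0 = out[i, min(stim_idx, len(time_s) - 1)]
        # drift runs from t=0 until the stimulus, then holds
        out[i] = out[i] + drift[i] * np.minimum(time_s, stimulus_time_s)
        t0 = stimulus_time_s + delay_s[i]
        v0 = m0 + drift[i] * stimulus_time_s
        ramp = rate[i] * np.clip(time_s - t0, 0.0, None)
        plateau = plateau_multiplier * m0
        out[i] = np.where(time_s >= t0, np.minimum(v0 + ramp, plateau), out[i])
    return out


def meta_from_config(config: SimulationConfig) -> AcquisitionMeta:
    return AcquisitionMeta(
        illumination_mw=config.illumination_mw,
        exposure_ms=config.exposure_ms,
        frame_rate_hz=config.frame_rate_hz,
        pixel_size_um=config.pixel_size_um,
        layout=config.layout,
        bit_depth=16,
    )


def _place_cells(config: SimulationConfig, rng: np.random.Generator):
    """Draw non-overlapping cell geometries; error after bounded retries."""
    h, w = config.fov_shape
    lo, hi = config.cell_radius_px
    margin = 2 + max(abs(config.channel_shift[0]), abs(config.channel_shift[1]))
    occupied = np.zeros((h, w), dtype=bool)
    cells = []
    for _ in range(config.n_cells):
        for _attempt in range(_PLACEMENT_RETRIES):
            ay = rng.uniform(lo, hi)
            ax = rng.uniform(lo, hi)
            angle = rng.uniform(0, math.pi)
            pad = max(ay, ax) + margin
            if 2 * pad >= min(h, w):
                continue
            cy = rng.uniform(pad, h - pad)
            cx = rng.uniform(pad, w - pad)
            foot = _ellipse_mask((h, w), (cy, cx), (ay + margin, ax + margin), angle)
            if not (foot & occupied).any():
                occupied |= foot
                cells.append(((cy, cx), (ay, ax), angle))
                break
        else:
            raise SimulationError(
                f"could not place {config.n_cells} non-overlapping cells in a "
                f"{config.fov_shape} field of view after {_PLACEMENT_RETRIES} retries"
            )
    return cells


def _window_percent(trace: np.ndarray, n_window: int = 10) -> float:
    """First-minus-last window percent (positive = bleaching)."""
    n = min(n_window, len(trace) // 2) or 1
    first = float(np.mean(trace[:n]))
    last = float(np.mean(trace[-n:]))
    return (first - last) / first * 100.0


def add_camera_noise(
    clean: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply the camera model to noiseless expected-count frames.

    Shot noise is Poisson on the expected counts (signal plus background
    flux); read noise is additive Gaussian. Output is quantized to uint16
    unless ``config.quantize`` is off.
    """
    out = np.empty(clean.shape, dtype=np.uint16 if config.quantize else np.float64)
    for start in range(0, clean.shape[0], _CHUNK_FRAMES):
        chunk = clean[start : start + _CHUNK_FRAMES].astype(np.float64)
        if config.shot_noise:
            chunk = rng.poisson(chunk).astype(np.float64)
        if config.read_noise_sd > 0:
            chunk += rng.normal(0.0, config.read_noise_sd, size=chunk.shape)
        if config.quantize:
            chunk = np.clip(np.rint(chunk), 0, 65535)
        else:
            chunk = np.clip(chunk, 0, None)
        out[start : start + _CHUNK_FRAMES] = chunk
    return out


def simulate_timelapse(config: SimulationConfig) -> tuple[np.ndarray, GroundTruth]:
    """Generate a split-frame stack and its ground truth.

    Returns ``(stack, truth)`` where ``stack`` is T x H x 2W (two half-FOV
    channel images composed per ``config.layout``) and ``truth`` carries the
    label mask, noiseless per-cell traces and the generative parameters.
    Deterministic for a fixed config and seed.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.fov_shape
    time_s = config.time_s
    n_frames = config.n_frames
    scale = config.intensity_scale

    cells = _place_cells(config, rng)
    n_cells = len(cells)

    label_mask = np.zeros((h, w), dtype=np.int32)
    templates: list[CellPhantom] = []
    for i, (center, axes, angle) in enumerate(cells, start=1):
        ph = make_cell_phantom(
            (h, w),
            center,
            axes,
            (axes[0] * config.nucleus_fraction, axes[1] * config.nucleus_fraction),
            config.nucleus_factor,
            config.mito_density,
            config.mito_factor,
            rng,
            angle=angle,
        )
        label_mask[ph.cell_mask] = i
        templates.append(ph)

    # per-cell monoexponential bleach rates with lognormal spread
    if config.bleach_rate_sigma > 0 and n_cells:
        mult = np.exp(rng.normal(0.0, config.bleach_rate_sigma, size=n_cells))
    else:
        mult = np.ones(n_cells)
    k451 = config.bleach_rate_451 * mult
    k560 = config.bleach_rate_560 * mult

    # cyanide-like perturbation: static per-channel gain on the cell signal
    gain_451 = gain_560 = 1.0
    if config.perturbation == "cyanide":
        p = config.perturbation_params
        gain_451 = float(p.get("factor_451", 1.35))
        gain_560 = float(p.get("factor_560", 0.95))

    # per-cell baseline mean signal (cytoplasm units x base intensity x scale)
    rows_cols = []
    base_mean_451 = np.zeros(n_cells)
    base_mean_560 = np.zeros(n_cells)
    for i, ph in enumerate(templates):
        rows, cols = np.nonzero(ph.cell_mask)
        rows_cols.append((rows, cols))
        base_mean_451[i] = (
            ph.template_451[rows, cols].mean() * config.base_intensity_451 * scale * gain_451
        )
        base_mean_560[i] = (
            ph.template_560[rows, cols].mean() * config.base_intensity_560 * scale * gain_560
        )

    bleach_451 = np.exp(-np.outer(k451, time_s)) if n_cells else np.zeros((0, n_frames))
    bleach_560 = np.exp(-np.outer(k560, time_s)) if n_cells else np.zeros((0, n_frames))

    # signal-mean trajectories (excluding the background offset)
    sig_451 = base_mean_451[:, None] * bleach_451
    sig_560 = base_mean_560[:, None] * bleach_560

    true_delay = true_rate_451 = true_rate_560 = None
    stimulus_time = None
    if config.perturbation == "glucose_bolus" and n_cells:
        p = config.perturbation_params
        stimulus_time = float(p.get("stimulus_time_s", 8.0))
        d_lo, d_hi = p.get("delay_range_s", (1.0, 4.0))
        r451_lo, r451_hi = p.get("rate_range_451", (0.4, 1.6))
        r560_lo, r560_hi = p.get("rate_range_560", (0.2, 1.1))
        plateau = float(p.get("plateau_multiplier", 3.0))
        drift = float(p.get("drift_au_per_s", 0.0))
        true_delay = rng.uniform(d_lo, d_hi, size=n_cells)
        true_rate_451 = rng.uniform(r451_lo, r451_hi, size=n_cells)
        true_rate_560 = rng.uniform(r560_lo, r560_hi, size=n_cells)
        sig_451 = apply_glucose_response(
            sig_451, time_s, stimulus_time, true_delay, true_rate_451, plateau, drift
        )
        sig_560 = apply_glucose_response(
            sig_560, time_s, stimulus_time, true_delay, true_rate_560, plateau, drift
        )

    # per-cell multiplicative pixel gains so ROI means follow sig exactly
    gains_451 = np.ones((n_cells, n_frames))
    gains_560 = np.ones((n_cells, n_frames))
    for i in range(n_cells):
        if base_mean_451[i] > 0:
            gains_451[i] = sig_451[i] / base_mean_451[i]
        if base_mean_560[i] > 0:
            gains_560[i] = sig_560[i] / base_mean_560[i]

    true_451 = sig_451 + config.background_offset
    true_560 = sig_560 + config.background_offset

    orr_true = np.divide(
        true_451,
        true_451 + true_560,
        out=np.full_like(true_451, np.nan),
        where=(true_451 + true_560) > 0,
    )
    true_bleach = {
        "451": np.array([_window_percent(t) for t in true_451]),
        "560": np.array([_window_percent(t) for t in true_560]),
        "orr": np.array([_window_percent(t) for t in orr_true]),
    }

    # assemble the stack chunk-wise: clean expected counts, then camera noise
    stack = np.empty(
        (n_frames, h, 2 * w), dtype=np.uint16 if config.quantize else np.float64
    )
    noise_rng = rng  # continue the same stream; chunk size is fixed
    for start in range(0, n_frames, _CHUNK_FRAMES):
        stop = min(start + _CHUNK_FRAMES, n_frames)
        nt = stop - start
        clean_451 = np.full((nt, h, w), float(config.background_offset), dtype=np.float64)
        clean_560 = np.full((nt, h, w), float(config.background_offset), dtype=np.float64)
        for i, ph in enumerate(templates):
            rows, cols = rows_cols[i]
            v451 = ph.template_451[rows, cols] * config.base_intensity_451 * scale * gain_451
            v560 = ph.template_560[rows, cols] * config.base_intensity_560 * scale * gain_560
            clean_451[:, rows, cols] += gains_451[i, start:stop, None] * v451[None, :]
            clean_560[:, rows, cols] += gains_560[i, start:stop, None] * v560[None, :]
        if config.channel_shift != (0, 0):
            dy, dx = config.channel_shift
            bg = float(config.background_offset)
            clean_560 = np.stack(
                [shift_image(f, (dy, dx), fill=bg) for f in clean_560]
            )
        sub = np.concatenate([clean_451, clean_560], axis=2)  # noised jointly
        if config.layout == "right":
            sub = np.concatenate([clean_560, clean_451], axis=2)
        noised = _noise_chunk(sub, config, noise_rng)
        stack[start:stop] = noised

    truth = GroundTruth(
        label_mask=label_mask,
        time_s=time_s,
        true_trace_451=true_451,
        true_trace_560=true_560,
        true_bleach_percent=true_bleach,
        bleach_rate_451=k451,
        bleach_rate_560=k560,
        true_delay_s=true_delay,
        true_rate_451_au_per_s=true_rate_451,
        true_rate_560_au_per_s=true_rate_560,
        stimulus_time_s=stimulus_time,
    )
    return stack, truth


def _noise_chunk(
    chunk: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    if config.shot_noise:
        chunk = rng.poisson(chunk).astype(np.float64)
    if config.read_noise_sd > 0:
        chunk = chunk + rng.normal(0.0, config.read_noise_sd, size=chunk.shape)
    if config.quantize:
        return np.clip(np.rint(chunk), 0, 65535).astype(np.uint16)
    return np.clip(chunk, 0.0, None)


def noiseless_clone(config: SimulationConfig) -> SimulationConfig:
    """Copy of a config with every noise source and quantization disabled."""
    return replace(config, shot_noise=False, read_noise_sd=0.0, quantize=False)
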