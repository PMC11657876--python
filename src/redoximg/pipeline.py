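"""End-to-end experiment replications, from config to tidy result tables.

Three experiment kinds are supported, each runnable on simulated stacks
(known ground truth) or on real split-frame TIFF stacks:

* ``group``      — snapshot ORR comparison of control vs perturbed images
                   across condition levels (illumination or exposure sweep);
* ``photobleach``— continuous-illumination stacks, per-cell windowed percent
                   change plus start/end SNR per channel;
* ``dynamics``   — stimulus run, per-cell onset/rate/time-to-peak kinetics.

Outputs are CSV tables plus a YAML run manifest carrying the config, its
hash, and the package version, so every run is reproducible from
config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import analyze_traces
from .image_io import channel_stack_from_frames, read_meta, read_stack
from .metrics import compute_snr, extract_traces, orr_image, photobleach_report
from .segmentation import segment_cells, threshold_background
from .simulate import SimulationConfig, meta_from_config, simulate_timelapse
from .stats import ComparisonResult, compare_groups

__all__ = [
    "ExperimentConfig",
    "run_group_experiment",
    "run_photobleach_experiment",
    "run_dynamics_experiment",
    "run_experiment",
]

logger = logging.getLogger("redoximg")


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment replication."""

    experiment: str  # group | photobleach | dynamics
    simulation: SimulationConfig | None = None
    input_paths: dict | None = None  # real-data mode: paths per condition/group
    conditions: list = field(default_factory=list)  # values of the varied parameter
    vary: str = "illumination_mw"  # which SimulationConfig field the conditions set
    n_images: int = 15  # images per group (group experiment)
    perturbation_params: dict = field(default_factory=dict)
    threshold_method: str = "otsu"
    threshold_value: float | None = None
    min_area: int = 100
    n_window: int = 10
    stimulus_time_s: float | None = None
    alpha: float = 0.05
    gate_alpha: float = 0.05
    k_sd: float = 3.0
    m_consecutive: int = 25
    smooth_window: int = 25
    fit_window_s: float = 2.0
    refine_window_s: float = 2.0
    qc_min_mean: float | None = None  # drop cells whose mean 451 falls below this
    bleach_rate_by_condition: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in ("group", "photobleach", "dynamics"):
            raise ValueError(f"unknown experiment kind {self.experiment!r}")
        if (self.simulation is None) == (self.input_paths is None):
            raise ValueError(
                "exactly one input source required: simulation or input_paths"
            )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulation", None)
        if sim is not None:
            for key in ("fov_shape", "channel_shift", "cell_radius_px"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        canon = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _write_manifest(outdir: Path, config: ExperimentConfig, extra: dict) -> None:
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "config": _plain(config.to_dict()),
    }
    manifest.update(_plain(extra))
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def _load_channel_stack(path, meta=None):
    stack = read_stack(path)
    if meta is None:
        meta = read_meta(path)
    return channel_stack_from_frames(stack, meta, register=True)


def _image_level_orr(cs, config: ExperimentConfig):
    """Image-level ORR on the 451 time-average threshold mask (shared mask)."""
    img_451 = cs.data_451.mean(axis=0)
    img_560 = cs.data_560.mean(axis=0)
    thr = threshold_background(
        img_451, method=config.threshold_method, value=config.threshold_value
    )
    orr = orr_image(img_451, img_560, thr.mask)
    return {
        "orr": orr,
        "mean_451": float(img_451[thr.mask].mean()),
        "mean_560": float(img_560[thr.mask].mean()),
        "threshold": thr.threshold,
        "n_pixels": int(thr.mask.sum()),
    }


def _simulate_channel_stack(sim: SimulationConfig):
    stack, truth = simulate_timelapse(sim)
    cs = channel_stack_from_frames(stack, meta_from_config(sim), register=True)
    return cs, truth


def run_group_experiment(config: ExperimentConfig, outdir=None):
    """Image-level ORR table by condition x group plus a test per condition."""
    if config.experiment != "group":
        raise ValueError("config.experiment must be 'group'")
    rows = []
    if config.simulation is not None:
        base = config.simulation
        conditions = config.conditions or [getattr(base, config.vary)]
        counter = 0
        for cond in conditions:
            for group in ("control", "perturbed"):
                for i in range(config.n_images):
                    sim = replace(
                        base,
                        **{config.vary: cond},
                        perturbation="cyanide" if group == "perturbed" else "none",
                        perturbation_params=config.perturbation_params,
                        seed=config.seed + counter,
                    )
                    counter += 1
                    cs, _ = _simulate_channel_stack(sim)
                    rec = _image_level_orr(cs, config)
                    rec.update(condition=cond, group=group, image=i)
                    rows.append(rec)
            logger.info("condition %s: %d images analyzed", cond, 2 * config.n_images)
    else:
        for cond, groups in config.input_paths.items():
            for group, paths in groups.items():
                for i, p in enumerate(paths):
                    cs = _load_channel_stack(p)
                    rec = _image_level_orr(cs, config)
                    rec.update(condition=cond, group=group, image=i, path=str(p))
                    rows.append(rec)
    table = pd.DataFrame(rows)

    results: dict = {}
    for cond, sub in table.groupby("condition"):
        groups = sub["group"].unique()
        if len(groups) < 2:
            logger.warning("condition %s has a single group; no test run", cond)
            continue
        a = sub.loc[sub["group"] == groups[0], "orr"].to_numpy()
        b = sub.loc[sub["group"] == groups[1], "orr"].to_numpy()
        results[cond] = compare_groups(
            a, b, alpha=config.alpha, gate_alpha=config.gate_alpha
        )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "orr_by_image.csv", index=False)
        _comparison_frame(results).to_csv(outdir / "comparisons.csv", index=False)
        _write_manifest(outdir, config, {"n_rows": len(table)})
    return table, results


def _comparison_frame(results: dict[object, ComparisonResult]) -> pd.DataFrame:
    rows = []
    for cond, r in results.items():
        rows.append(
            {
                "condition": cond,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "shapiro_p_a": r.shapiro_p_a,
                "shapiro_p_b": r.shapiro_p_b,
                "test_used": r.test_used,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "significant": r.significant,
                "stars": r.stars,
            }
        )
    return pd.DataFrame(rows)


def _segment_and_trace(cs, config: ExperimentConfig, truth=None):
    """Shared time-lapse path: threshold the 451 time-average, label, trace."""
    avg_451 = cs.data_451.mean(axis=0)
    thr = threshold_background(
        avg_451, method=config.threshold_method, value=config.threshold_value
    )
    mask = segment_cells(
        avg_451,
        thr.mask,
        min_area=config.min_area,
        fill_holes=True,
        provenance={"method": thr.method, "threshold": thr.threshold},
    )
    traces = extract_traces(cs, mask)
    n_before = len(traces)
    if config.qc_min_mean is not None:
        traces = [t for t in traces if t.mean_451.mean() >= config.qc_min_mean]
    logger.info(
        "frames=%d cells=%d excluded=%d threshold=%.3g",
        cs.n_frames,
        len(traces),
        n_before - len(traces),
        thr.threshold,
    )
    return mask, thr, traces


def run_photobleach_experiment(config: ExperimentConfig, outdir=None):
    """Per-cell windowed percent change and SNR per condition level."""
    if config.experiment != "photobleach":
        raise ValueError("config.experiment must be 'photobleach'")
    tables = []
    snr_rows = []
    if config.simulation is not None:
        base = config.simulation
        conditions = config.conditions or [getattr(base, config.vary)]
        for j, cond in enumerate(conditions):
            overrides = {config.vary: cond, "seed": config.seed + j}
            overrides.update(config.bleach_rate_by_condition.get(cond, {}))
            sim = replace(base, **overrides)
            cs, _ = _simulate_channel_stack(sim)
            tables.append(_photobleach_one(cs, config, cond))
            snr_rows.extend(_snr_start_end(cs, config, cond))
    else:
        for cond, path in config.input_paths.items():
            cs = _load_channel_stack(path)
            tables.append(_photobleach_one(cs, config, cond))
            snr_rows.extend(_snr_start_end(cs, config, cond))
    table = pd.concat(tables, ignore_index=True)
    snr_table = pd.DataFrame(snr_rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "photobleach_by_cell.csv", index=False)
        snr_table.to_csv(outdir / "snr_by_condition.csv", index=False)
        _write_manifest(outdir, config, {"n_rows": len(table)})
    return table, snr_table


def _photobleach_one(cs, config: ExperimentConfig, cond) -> pd.DataFrame:
    _, _, traces = _segment_and_trace(cs, config)
    rep = photobleach_report(traces, n_window=config.n_window)
    frame = rep.to_frame()
    frame.insert(0, "condition", cond)
    return frame


def _snr_start_end(cs, config: ExperimentConfig, cond) -> list[dict]:
    """Contrast SNR of the first-10 and last-10 frame averages per channel."""
    nw = config.n_window
    rows = []
    avg_451 = cs.data_451.mean(axis=0)
    thr = threshold_background(
        avg_451, method=config.threshold_method, value=config.threshold_value
    )
    signal = thr.mask
    background = ~thr.mask
    for chan, data in (("451", cs.data_451), ("560", cs.data_560)):
        start_img = data[:nw].mean(axis=0)
        end_img = data[-nw:].mean(axis=0)
        try:
            start = compute_snr(start_img, signal, background)
            end = compute_snr(end_img, signal, background)
            row = {
                "start_snr": start.snr,
                "end_snr": end.snr,
                "percent_change": (end.snr - start.snr) / start.snr * 100.0,
                "definition": start.definition,
            }
        except ValueError as exc:  # e.g. noiseless background has zero variance
            logger.warning("SNR undefined for channel %s: %s", chan, exc)
            row = {
                "start_snr": np.nan,
                "end_snr": np.nan,
                "percent_change": np.nan,
                "definition": "contrast",
            }
        row.update(condition=cond, channel=chan)
        rows.append(row)
    return rows


def run_dynamics_experiment(config: ExperimentConfig, outdir=None):
    """Per-cell stimulus-response kinetics table plus trace export."""
    if config.experiment != "dynamics":
        raise ValueError("config.experiment must be 'dynamics'")
    if config.simulation is not None:
        cs, truth = _simulate_channel_stack(config.simulation)
        stimulus = config.stimulus_time_s
        if stimulus is None:
            stimulus = truth.stimulus_time_s
    else:
        cs = _load_channel_stack(config.input_paths["stack"])
        truth = None
        stimulus = config.stimulus_time_s
    if stimulus is None:
        raise ValueError("stimulus_time_s must be set for a dynamics experiment")

    _, _, traces = _segment_and_trace(cs, config)
    report = analyze_traces(
        traces,
        stimulus,
        n_window=config.n_window,
        k_sd=config.k_sd,
        m_consecutive=config.m_consecutive,
        smooth_window=config.smooth_window,
        fit_window_s=config.fit_window_s,
        refine_window_s=config.refine_window_s,
    )
    trace_frame = pd.concat(
        [
            pd.DataFrame(
                {
                    "cell_id": t.cell_id,
                    "time_s": t.time_s,
                    "mean_451": t.mean_451,
                    "mean_560": t.mean_560,
                }
            )
            for t in traces
        ],
        ignore_index=True,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_csv(outdir / "dynamics_by_cell.csv", index=False)
        trace_frame.to_csv(outdir / "traces.csv", index=False)
        _write_manifest(outdir, config, {"stimulus_time_s": float(stimulus)})
    return report, trace_frame, truth


def run_experiment(config: ExperimentConfig, outdir=None):
    """Dispatch on ``config.experiment``."""
    runner = {
        "group": run_group_experiment,
        "photobleach": run_photobleach_experiment,
        "dynamics": run_dynamics_experiment,
    }[config.experiment]
    return runner(config, outdir)
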