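"""End-to-end orchestration and group comparison.

Two pipelines are provided: the SEMG path (synthesize → denoise benchmark →
fatigue features → train/evaluate classifiers) and the ultrasound path
(synthesize phantom → track ROI → thickness and texture).  Every run writes
its artifacts plus a manifest (config hash, seed, package versions, stage
timings) under one output directory; a rerun with the same config and seed
reproduces identical CSV contents on the same machine.

Group comparison between two condition arms uses Welch's unequal-variance
two-sample t-test with per-endpoint significance at α = 0.05 (optional Holm
correction across endpoints).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from myofatigue import __version__
from myofatigue import denoise as dn
from myofatigue import features as ft
from myofatigue import model as md
from myofatigue import usbi
from myofatigue.synthetic import (FatigueProfile, FrameSequence, NoiseSpec,
                                  PhantomSpec, add_noise, generate_clean_semg,
                                  generate_labeled_windows,
                                  generate_phantom_sequence)

ALPHA = 0.05


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Seed plus per-stage settings; every subsection validates against its
    module's invariants when the stage objects are built."""

    seed: int = 0
    out_dir: str = "runs/demo"
    # denoising benchmark
    wavelet: str = "db4"
    levels: int = 4
    mode: str = "improved"
    k: float = 2.0
    replicates: int = 20
    # feature extraction
    window_s: float = 1.0
    overlap: float = 0.5
    band: tuple[float, float] = (20.0, 500.0)
    ramp_duration_s: float = 60.0
    # classification
    n_per_class: int = 1000
    window_len: int = 1000
    rms_nonfatigued: float = 0.5
    rms_fatigued: float = 2.0
    noise_sigma: float = 0.1
    train_fraction: float = 0.7
    max_epochs: int = 200
    batch_size: int = 70
    learning_rate: float = 1e-3
    hidden_units: int = 100
    patience: int = 10
    models: tuple[str, ...] = ("lstm", "svm", "bpnn", "cnn")
    # ultrasound
    glcm_levels: int = 32
    phantom: dict = field(default_factory=dict)
    search_margin: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.band, list):
            cfg.band = tuple(cfg.band)
        if isinstance(cfg.models, list):
            cfg.models = tuple(cfg.models)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(out: Path, config: RunConfig, stages: dict[str, float],
                    complete: bool) -> None:
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "complete": complete,
        "stage_seconds": stages,
        "versions": {
            "myofatigue": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


# ---------------------------------------------------------------------------
# SEMG pipeline
# ---------------------------------------------------------------------------


def run_semg_pipeline(config: RunConfig) -> dict:
    """Synthesize → denoise benchmark → features → classifiers.

    Writes ``denoise_benchmark.csv``, ``features.csv``, ``metrics.json`` and
    ``manifest.json`` under ``config.out_dir``; returns the artifact paths
    and the metrics dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}
    rng = np.random.default_rng(config.seed)

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - stage-named rethrow
            stages[name] = time.perf_counter() - t0
            _write_manifest(out, config, stages, complete=False)
            raise StageError(name, exc) from exc
        stages[name] = time.perf_counter() - t0
        return result

    def stage_bench():
        bench = dn.benchmark(seed=int(rng.integers(2**31)),
                             replicates=config.replicates, k=config.k)
        bench.to_csv(out / "denoise_benchmark.csv", index=False)
        return bench

    bench = run_stage("denoise_benchmark", stage_bench)

    def stage_features():
        profile = FatigueProfile(duration_s=config.ramp_duration_s,
                                 rms_start=config.rms_nonfatigued,
                                 rms_end=config.rms_fatigued)
        clean = generate_clean_semg(profile, seed=int(rng.integers(2**31)))
        nspec = NoiseSpec(white_sigma=config.noise_sigma,
                          powerline_amp=0.2, baseline_amp=0.2,
                          seed=int(rng.integers(2**31)))
        noisy, _ = add_noise(clean, nspec)
        den = dn.denoise(noisy, config.wavelet, config.levels,
                         mode=config.mode, k=config.k)
        series = ft.compute_feature_series(den, config.window_s,
                                           config.overlap, config.band)
        series.to_csv(out / "features.csv")
        return series

    run_stage("features", stage_features)

    def stage_classify():
        profiles = (
            FatigueProfile(duration_s=1.0, rms_start=config.rms_nonfatigued,
                           rms_end=config.rms_nonfatigued),
            FatigueProfile(duration_s=1.0, rms_start=config.rms_fatigued,
                           rms_end=config.rms_fatigued),
        )
        data = generate_labeled_windows(
            config.n_per_class, config.window_len, profiles,
            NoiseSpec(white_sigma=config.noise_sigma),
            seed=int(rng.integers(2**31)))
        train, eval_ = md.split_dataset(
            data, md.SplitSpec(config.train_fraction,
                               seed=int(rng.integers(2**31))))
        metrics = {"n_train": len(train), "n_eval": len(eval_)}
        tc = md.TrainingConfig(
            hidden_units=config.hidden_units, batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            early_stopping_patience=config.patience,
            max_epochs=config.max_epochs, seed=int(rng.integers(2**31)))
        for name in config.models:
            if name == "lstm":
                model = md.train_lstm(train, tc)
            else:
                model = md.train_baseline(name, train,
                                          seed=int(rng.integers(2**31)))
            metrics[name] = md.evaluate(model, eval_).as_dict()
        (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
        return metrics

    metrics = run_stage("classify", stage_classify)
    _write_manifest(out, config, stages, complete=True)
    return {"out_dir": str(out), "benchmark": bench, "metrics": metrics}


# ---------------------------------------------------------------------------
# ultrasound pipeline
# ---------------------------------------------------------------------------


def run_usbi_pipeline(config: RunConfig,
                      sequence: FrameSequence | None = None,
                      roi: usbi.ROI | None = None) -> dict:
    """Synthesize (or accept) a phantom sequence, track an ROI, and write
    per-frame tracking plus thickness/texture CSVs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}
    t0 = time.perf_counter()
    try:
        if sequence is None:
            spec = PhantomSpec(seed=config.seed, **config.phantom)
            sequence = generate_phantom_sequence(spec)
        if sequence.boundaries_mm is None:
            raise ValueError(
                "sidecar is missing required field 'boundaries_mm' "
                "(ground-truth layer boundaries)")
        sp = sequence.pixel_spacing_mm
        if roi is None:
            # straddle the surface/deep interface so the template has texture
            deep_row = int(round(sequence.boundaries_mm[0][1] / sp))
            roi = usbi.ROI(max(0, deep_row - 10), 10, 20, 20)
        traj = usbi.track_roi(sequence, roi, config.search_margin)
        rows = []
        for k, (r, rd_k) in enumerate(zip(traj.rois, traj.rd)):
            rows.append({
                "frame": k, "roi_row": r.row, "roi_col": r.col,
                "Rd": rd_k,
                "amplitude": usbi.mean_response_amplitude(sequence.frames[k], r),
            })
        tracking = pd.DataFrame(rows)
        tracking.to_csv(out / "tracking.csv", index=False)

        feats = []
        for k in range(len(sequence)):
            s_mm, d_mm, b_mm = sequence.boundaries_mm[k]
            thick = usbi.thickness_from_boundaries(
                s_mm / sp, d_mm / sp, b_mm / sp, sp)
            r = traj.rois[k] if k < len(traj.rois) else traj.rois[-1]
            tex = usbi.roi_texture(sequence.frames[k], r, config.glcm_levels)
            feats.append({
                "frame": k, "asm": tex.asm, "contrast": tex.contrast,
                "hom": tex.hom, "thickness_surface_mm": thick.surface_mm,
                "thickness_deep_mm": thick.deep_mm,
                "thickness_total_mm": thick.total_mm,
            })
        features = pd.DataFrame(feats)
        features.to_csv(out / "texture_thickness.csv", index=False)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        stages["usbi"] = time.perf_counter() - t0
        _write_manifest(out, config, stages, complete=False)
        raise StageError("usbi", exc) from exc
    stages["usbi"] = time.perf_counter() - t0
    _write_manifest(out, config, stages, complete=True)
    return {"out_dir": str(out), "tracking": tracking, "features": features,
            "truncated": traj.truncated}


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sample comparison of one endpoint between two arms."""

    endpoint: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    statistic: float
    p_value: float
    significant: bool

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def group_compare(values_a, values_b, endpoint: str = "endpoint",
                  alpha: float = ALPHA) -> GroupComparison:
    """Welch's unequal-variance two-sided t-test; significance at α."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        raise ValueError("degenerate comparison: zero variance, equal means")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # distinct constants: difference certain
        stat, p = float("inf"), 0.0
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    if np.array_equal(a, b) or (a.mean() == b.mean() and np.isnan(stat)):
        stat, p = 0.0, 1.0
    stat, p = float(stat), float(p)
    return GroupComparison(
        endpoint=endpoint,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        statistic=stat, p_value=p, significant=bool(p < alpha),
    )


def holm_correct(comparisons: list[GroupComparison],
                 alpha: float = ALPHA) -> list[GroupComparison]:
    """Holm step-down correction across endpoints; returns new comparisons
    with adjusted significance flags (p-values unchanged)."""
    order = np.argsort([c.p_value for c in comparisons])
    m = len(comparisons)
    out = list(comparisons)
    failed = False
    for rank, idx in enumerate(order):
        c = comparisons[idx]
        ok = (not failed) and c.p_value < alpha / (m - rank)
        if not ok:
            failed = True
        out[idx] = dataclasses.replace(c, significant=ok)
    return out
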