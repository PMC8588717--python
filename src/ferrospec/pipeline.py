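"""End-to-end orchestration of the TICS estimation workflow.

One run covers, for each requested soil group and feature variant:

    smooth -> [WPT denoise] -> first derivative -> band screening
           -> [harmonic parameters] -> PCA -> split -> BP training
           -> held-out evaluation

and emits a report table (rows = soil_type x variant; columns R^2, RMSE,
MAE), the selected bands, the PCA summaries, serialized models,
per-sample predictions, and a structured log.  Every number in a run
directory is reproducible from the persisted config and seeds.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bp_model, synthetic_data
from .bp_model import BPConfig
from .feature_selection import VARIANTS, build_feature_sets
from .preprocess import WPTConfig
from .spectra_io import SpectralDataset, read_dataset

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Persisted description of one pipeline run.

    Either ``input`` (a wide/long spectra file) or ``synth_profile``
    (``loessial``/``sandy``/``mixed``) must be set.  ``soil_handling`` is
    ``per-type`` (independent run per soil label, band screening redone per
    type), ``pooled`` (one run over all samples as mixed soil), or ``both``.
    """

    input: str | None = None
    layout: str = "wide"
    targets: str | None = None
    synth_profile: str | None = None
    variants: tuple[str, ...] = VARIANTS
    soil_handling: str = "pooled"
    seed: int = 0
    wpt: dict = field(default_factory=dict)
    screen: dict = field(default_factory=lambda: {"threshold": 0.55, "count": 150})
    pca: dict = field(default_factory=lambda: {"n_components": 5, "min_cumulative": 90.0})
    harmonic_order: int = 150
    bp: dict = field(default_factory=dict)
    outdir: str = "ferrospec_run"

    def __post_init__(self) -> None:
        self.variants = tuple(self.variants)
        if not self.variants:
            raise ValueError("at least one variant required")
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown variants {sorted(unknown)}; choose from {VARIANTS}")
        if self.input is None and self.synth_profile is None:
            raise ValueError("either input or synth_profile must be given")
        if self.soil_handling not in ("per-type", "pooled", "both"):
            raise ValueError("soil_handling must be per-type, pooled or both")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "input": self.input,
            "layout": self.layout,
            "targets": self.targets,
            "synth_profile": self.synth_profile,
            "variants": list(self.variants),
            "soil_handling": self.soil_handling,
            "seed": self.seed,
            "wpt": dict(self.wpt),
            "screen": dict(self.screen),
            "pca": dict(self.pca),
            "harmonic_order": self.harmonic_order,
            "bp": dict(self.bp),
            "outdir": self.outdir,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _load_input(config: RunConfig) -> tuple[SpectralDataset, str]:
    if config.input is not None:
        dataset = read_dataset(config.input, layout=config.layout, targets=config.targets)
        digest = hashlib.sha256(Path(config.input).read_bytes()).hexdigest()[:16]
        return dataset, digest
    profiles = synthetic_data.default_profiles(seed=config.seed)
    if config.synth_profile not in profiles:
        raise ValueError(f"unknown synthetic profile {config.synth_profile!r}")
    dataset = synthetic_data.generate(profiles[config.synth_profile])
    digest = hashlib.sha256(dataset.spectra.tobytes() + dataset.tics.tobytes()).hexdigest()[:16]
    return dataset, digest


def _groups(dataset: SpectralDataset, soil_handling: str):
    groups = []
    if soil_handling in ("per-type", "both"):
        for label in bp_model.pd_unique(np.asarray(dataset.soil_type)):
            mask = np.asarray(dataset.soil_type) == label
            groups.append((str(label), dataset.subset(mask), "per-soil"))
    if soil_handling in ("pooled", "both"):
        groups.append(("mixed", dataset, "pooled"))
    return groups


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute a full run; returns the report and writes the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    log_lines: list[str] = []

    def log(stage: str, message: str, t0: float) -> None:
        log_lines.append(f"{stage}\t{message}\telapsed={time.perf_counter() - t0:.3f}s")

    t0 = time.perf_counter()
    dataset, digest = _load_input(config)
    log("load", f"n_samples={dataset.n_samples} n_bands={dataset.n_bands} input_sha256={digest}", t0)

    wpt_config = WPTConfig(**config.wpt)
    bp_kwargs = dict(config.bp)
    rows = []
    for label, subset, scheme in _groups(dataset, config.soil_handling):
        t1 = time.perf_counter()
        try:
            feature_sets = build_feature_sets(
                subset,
                wpt_config=wpt_config,
                threshold=float(config.screen.get("threshold", 0.55)),
                count=int(config.screen.get("count", 150)),
                n_components=int(config.pca.get("n_components", 5)),
                harmonic_order=config.harmonic_order,
                min_cumulative=float(config.pca.get("min_cumulative", 90.0)),
            )
        except Exception as exc:  # pragma: no cover - error path
            log("features", f"soil={label} FAILED: {exc}", t1)
            (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
            raise
        log("features", f"soil={label} variants={list(feature_sets)}", t1)

        train_idx, test_idx = bp_model.split_dataset(subset, scheme=scheme, seed=config.seed)
        log("split", f"soil={label} train={train_idx.size} test={test_idx.size}", t1)

        for variant in config.variants:
            t2 = time.perf_counter()
            entry = feature_sets[variant]
            scores = entry["scores"]
            bp_config = BPConfig(
                topology=(scores.shape[1], 3, 1),
                seed=config.seed,
                **bp_kwargs,
            )
            model = bp_model.train_bp(scores[train_idx], subset.tics[train_idx], bp_config)
            pred_test = bp_model.predict(model, scores[test_idx])
            report = bp_model.evaluate(subset.tics[test_idx], pred_test, bp_config.r2_mode)
            rows.append({
                "soil_type": label,
                "variant": variant,
                "r_squared": report.r_squared,
                "rmse": report.rmse,
                "mae": report.mae,
                "n_train": int(train_idx.size),
                "n_test": int(test_idx.size),
            })
            slug = f"{label}_{variant}".replace("-", "").replace(" ", "")
            screen = entry["screen"]
            pd.DataFrame({
                "band_index": screen.band_indices,
                "wavelength_nm": subset.wavelengths[screen.band_indices],
                "r": screen.correlations,
            }).to_csv(outdir / f"bands_{slug}.csv", index=False)
            pca = entry["pca"]
            pd.DataFrame({
                "component": np.arange(1, pca.eigenvalues.size + 1),
                "eigenvalue": pca.eigenvalues,
                "variance_contribution_pct": pca.variance_contribution,
                "cumulative_contribution_pct": pca.cumulative_contribution,
            }).to_csv(outdir / f"pca_{slug}.csv", index=False)
            bp_model.save_model(model, outdir / f"model_{slug}.json")
            pd.DataFrame({
                "sample_id": [subset.sample_ids[i] for i in test_idx],
                "measured": subset.tics[test_idx],
                "predicted": pred_test,
            }).to_csv(outdir / f"predictions_{slug}.csv", index=False)
            log("model", f"soil={label} variant={variant} "
                         f"R2={report.r_squared:.4f} RMSE={report.rmse:.4f}", t2)

    report_frame = pd.DataFrame(rows)
    report_frame.to_csv(outdir / "report.csv", index=False)
    config.to_yaml(outdir / "config.yaml")
    log("done", f"rows={len(rows)}", t0)
    log_path.write_text("\n".join(log_lines) + "\n")
    return report_frame
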