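"""Configured end-to-end runs: generate → preprocess → select → evaluate.

A :class:`PipelineConfig` (YAML/JSON-friendly) drives one seeded run whose
stage seeds all derive from a single master seed by stable hashing, so the
same configuration and seed reproduce a byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classifiers import default_classifiers
from .dataset import read_dataset, write_dataset
from .evaluation import (SplitScheme, per_class_metrics, repeated_evaluation)
from .metaheuristics import BBOParams, HSParams, ICAParams
from .preprocessing import preprocess, save_msc_reference
from .selection import select_wavelengths
from .synthetic import Band, GeneratorConfig, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("nitrospec")


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed by stable hashing."""
    digest = hashlib.blake2s(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass
class PipelineConfig:
    """Everything one run needs; mirrors the YAML file structure."""

    output_dir: str = "nitrospec_run"
    input_csv: str | None = None          # if None, generate synthetically
    generator: dict = field(default_factory=dict)
    smoothing_window: int = 5
    selection_k: int = 3
    selection: dict = field(default_factory=dict)       # BBOParams overrides
    ica: dict = field(default_factory=dict)             # ICAParams overrides
    hs: dict = field(default_factory=dict)              # HSParams overrides
    n_rbf_centers: int = 4
    refine_epochs: int = 200
    iterations: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def generator_config(self, seed: int) -> GeneratorConfig:
        kwargs = dict(self.generator)
        bands = kwargs.pop("informative_bands", None)
        if bands is not None:
            kwargs["informative_bands"] = tuple(
                Band(b["center"], b["width"], tuple(b["depths"]))
                for b in bands)
        if "class_names" in kwargs:
            kwargs["class_names"] = tuple(kwargs["class_names"])
        kwargs.setdefault("seed", seed)
        return GeneratorConfig(**kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the staged analysis and write artifacts + report JSON.

    Stage order: data (generate or load) → preprocess → wavelength
    selection → repeated evaluation → report.  Any stage error aborts with
    the stage name; artifacts written by earlier stages are retained.
    """
    if config.input_csv is not None and not Path(config.input_csv).exists():
        raise FileNotFoundError(
            f"stage 'data': input CSV not found: {config.input_csv}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        log.info("stage %s", name)
        return stage_seed(config.seed, name)

    # -- data ---------------------------------------------------------
    seed = _stage("data")
    if config.input_csv is None:
        gen = config.generator_config(seed)
        dataset = generate_dataset(gen)
        write_dataset(dataset, out / "dataset.csv")
    else:
        dataset = read_dataset(config.input_csv)

    # -- preprocess ---------------------------------------------------
    _stage("preprocess")
    try:
        prepared, msc_model = preprocess(dataset,
                                         window=config.smoothing_window)
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc
    write_dataset(prepared, out / "preprocessed.csv")
    save_msc_reference(msc_model, out / "msc_reference.csv",
                       wavelengths=prepared.wavelengths)

    # -- selection ----------------------------------------------------
    seed = _stage("select")
    try:
        params = BBOParams(population=24, generations=70, mutation_prob=0.22,
                           seed=seed, **config.selection) \
            if "seed" not in config.selection else BBOParams(**config.selection)
        selection = select_wavelengths(prepared, k=config.selection_k,
                                       params=params, split_seed=seed)
    except Exception as exc:
        raise RuntimeError(f"stage 'select' failed: {exc}") from exc
    selection.to_json(out / "selection.json")
    effective = prepared.select_bands(selection.indices)

    # -- evaluate -----------------------------------------------------
    seed = _stage("evaluate")
    scheme = SplitScheme(iterations=config.iterations, seed=seed)
    ica = ICAParams(**config.ica) if config.ica else None
    hs = HSParams(**config.hs) if config.hs else None

    def factory(s):
        return default_classifiers(seed=s, ica_params=ica, hs_params=hs,
                                   n_rbf_centers=config.n_rbf_centers,
                                   refine_epochs=config.refine_epochs)

    try:
        report = repeated_evaluation(effective, factory, scheme)
    except Exception as exc:
        raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc

    # -- report -------------------------------------------------------
    _stage("report")
    report.confusion_table().to_csv(out / "confusion.csv", index=False)
    report.metrics_table().to_csv(out / "metrics.csv", index=False)
    payload = {
        "config": asdict(config),
        "selection": {"wavelengths": selection.wavelengths,
                      "indices": selection.indices},
        "classes": list(report.classes),
        "pooled_confusion": {name: cm.counts.tolist()
                             for name, cm in report.pooled.items()},
        "pooled_ccr": {k: round(v, 6) for k, v in report.pooled_ccr().items()},
        "mv_metrics": {
            cls: {k: round(float(v), 6) for k, v in row.items()}
            for cls, row in per_class_metrics(
                report.pooled["MV"]).iterrows()},
        "mean_auc": {name: [None if np.isnan(v) else round(float(v), 6)
                            for v in series.mean(axis=0)]
                     for name, series in report.auc_series.items()},
        "ccr_series": {k: [round(float(v), 6) for v in s]
                       for k, s in report.ccr_series.items()},
    }
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return payload
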