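"""End-to-end orchestration: simulate -> preprocess -> split -> train ->
evaluate -> explain, with config echo, derived seeds, and checksums.

Every stage's random seed is derived deterministically from the single
global seed and the stage name, so adding or removing one stage never
shifts another stage's randomness.  All tabular artifacts are
human-readable CSV/JSON; fitted models are persisted with joblib.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import __version__
from .classifiers import CnnConfig, PcaLdaConfig, RfConfig, SvmConfig, fit_model
from .core import SpectrumDataset, read_dataset, write_dataset
from .errors import SersdxError
from .evaluation import DEFAULT_RATIO, apply_split, evaluate_model, patient_level_votes, split_patients
from .interpret import cnn_saliency
from .preprocess import PreprocessConfig, preprocess_dataset
from .simulate import SimulationConfig, default_config, simulate

logger = logging.getLogger(__name__)

ALL_MODELS = ("pca_lda", "rf", "svm", "cnn")
METRIC_COLUMNS = ["accuracy", "sensitivity", "specificity", "auc"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    simulation: SimulationConfig | None = None  # None -> study-design defaults
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    models: tuple[str, ...] = ALL_MODELS
    model_configs: dict = field(default_factory=dict)  # kind -> config override
    split_ratio: tuple[int, int, int] = DEFAULT_RATIO
    seed: int = 0

    def resolved_model_config(self, kind: str, seed: int):
        if kind in self.model_configs:
            return self.model_configs[kind]
        defaults = {"pca_lda": PcaLdaConfig, "rf": RfConfig, "svm": SvmConfig, "cnn": CnnConfig}
        cfg = defaults[kind]()
        if hasattr(cfg, "seed"):
            cfg.seed = seed
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage and persist all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- simulate -----------------------------------------------------------
    sim_config = config.simulation or default_config()
    sim_config.seed = derive_seed(config.seed, "simulate") if config.simulation is None else sim_config.seed
    logger.info("simulate: %d patients, %d spectra/sample", sim_config.n_patients, sim_config.spectra_per_sample)
    raw = simulate(sim_config)
    write_dataset(raw, out / "spectra_raw.csv", out / "manifest.csv")

    # -- preprocess ---------------------------------------------------------
    logger.info("preprocess: %d spectra", len(raw))
    processed = preprocess_dataset(raw, config.preprocess)
    write_dataset(processed, out / "spectra_preprocessed.csv", out / "manifest.csv")

    # -- split --------------------------------------------------------------
    patients = sorted(set(processed.manifest["patient_id"]))
    split_seed = derive_seed(config.seed, "split")
    split3 = split_patients(patients, config.split_ratio, "three_way", split_seed)
    split2 = split_patients(patients, config.split_ratio, "two_way", split_seed)
    with open(out / "split.json", "w") as fh:
        json.dump({"three_way": split3.to_dict(), "two_way": split2.to_dict()}, fh, indent=2)
    parts3 = apply_split(processed, split3)
    parts2 = apply_split(processed, split2)

    # -- train + evaluate ---------------------------------------------------
    table_rows = []
    for kind in config.models:
        mcfg = config.resolved_model_config(kind, derive_seed(config.seed, f"train:{kind}"))
        logger.info("train: %s", kind)
        if kind == "cnn":
            model = fit_model(kind, parts3["train"], parts3.get("validation"), mcfg)
            test = parts3["test"]
        else:
            model = fit_model(kind, parts2["train"], config=mcfg)
            test = parts2["test"]
        joblib.dump(model, out / f"model_{kind}.joblib")
        report = evaluate_model(model, test)
        with open(out / f"report_{kind}.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        pd.DataFrame({"fpr": report.roc.fpr, "tpr": report.roc.tpr}).to_csv(
            out / f"roc_{kind}.csv", index=False
        )
        pd.DataFrame(patient_level_votes(model, test)).to_csv(
            out / f"sample_votes_{kind}.csv", index=False
        )
        table_rows.append({
            "model": kind, "accuracy": report.accuracy, "sensitivity": report.sensitivity,
            "specificity": report.specificity, "auc": report.roc.auc,
        })
        if kind == "cnn":
            profile = cnn_saliency(model, test)
            pd.DataFrame({"shift": profile.shifts, "contribution": profile.contribution}).to_csv(
                out / "saliency.csv", index=False
            )
            pd.DataFrame(profile.top_peaks, columns=["center", "contribution"]).to_csv(
                out / "saliency_peaks.csv", index=False
            )

    table = pd.DataFrame(table_rows, columns=["model", *METRIC_COLUMNS])
    table.to_csv(out / "comparison_table.csv", index=False)

    # -- provenance ---------------------------------------------------------
    manifest = {
        "sersdx_version": __version__,
        "numpy_version": np.__version__,
        "global_seed": config.seed,
        "stage_seeds": {s: derive_seed(config.seed, s) for s in
                        ["simulate", "split", *[f"train:{k}" for k in config.models]]},
        "simulation_config": sim_config.to_dict(),
        "preprocess_config": vars(config.preprocess),
        "models": list(config.models),
        "split_ratio": list(config.split_ratio),
        "checksums": {p.name: _sha256(p) for p in sorted(out.iterdir())
                      if p.suffix in {".csv", ".json"} and p.name != "run_manifest.json"},
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
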