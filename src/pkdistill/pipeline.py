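"""End-to-end orchestration with cached, resumable stages.

``run_pipeline`` executes generate -> simulate -> metrics -> split -> train
-> evaluate, writing each stage's output under the run directory.  A stage
whose output already exists for the same config hash is reused, so a run
can be resumed after interruption.  Simulations are independent; they are
executed in input order so all outputs are order-deterministic.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .cat import SimulationError, SolverSettings, simulate
from .config import PipelineConfig
from .evaluate import (
    evaluate_model_set,
    feature_importance,
    optimize_reduced_feature_set,
)
from .generate import classify_bcs, sample_virtual_drugs
from .pk import NormalizationScaler, SPKMRecord, assemble_dataset, compute_spkm
from .ranges import FEATURE_COLUMNS, LABEL_COLUMNS
from .surrogate import SurrogateModelSet, split_dataset, train_model_set

__all__ = ["run_pipeline", "simulate_library", "RunManifest"]

logger = logging.getLogger(__name__)

#: float formatting that round-trips exactly through CSV
_FLOAT_FMT = "%.17g"


@dataclass
class RunManifest:
    """Record of one pipeline run: config hash, stage outputs, timings."""

    config_hash: str
    version: str = __version__
    stages: Dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, path: Optional[Path], **info) -> None:
        self.stages[stage] = {
            "output": str(path) if path else None,
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            **info,
        }

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "version": self.version,
                    "config_hash": self.config_hash,
                    "stages": self.stages,
                },
                indent=2,
            )
        )


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT)


def simulate_library(
    library: pd.DataFrame,
    settings: Optional[SolverSettings] = None,
    max_failure_fraction: float = 0.01,
) -> List[SPKMRecord]:
    """Simulate every drug in the library and extract its summary metrics.

    Failed simulations are skipped (flagged degenerate) and counted; the
    batch aborts if more than ``max_failure_fraction`` of them fail.
    """
    settings = settings or SolverSettings()
    records: List[SPKMRecord] = []
    failures = 0
    for _, drug in library.iterrows():
        try:
            result = simulate(drug, settings=settings)
            records.append(compute_spkm(result, dose=float(drug["dose"])))
        except SimulationError as exc:
            failures += 1
            logger.warning("simulation failed: %s", exc)
            records.append(
                SPKMRecord(
                    drug_id=str(drug["id"]),
                    cmax_over_dose=np.nan,
                    tmax=np.nan,
                    auc_over_dose=np.nan,
                    degenerate=True,
                )
            )
    if failures > max_failure_fraction * len(library):
        raise RuntimeError(
            f"{failures}/{len(library)} simulations failed "
            f"(> {max_failure_fraction:.0%} threshold)"
        )
    return records


def run_pipeline(
    config: PipelineConfig,
    out_dir: Union[str, Path],
    resume: bool = True,
) -> RunManifest:
    """Run the full distillation workflow; returns the manifest.

    Outputs under ``out_dir``: ``library.csv``, ``spkm.csv``,
    ``dataset.csv`` + ``scaler.json``, ``split.csv``, ``models/``,
    ``report.json``, ``manifest.json`` and the effective ``config.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest = RunManifest(config_hash=chash)
    config.dump(out / "config.yaml")

    def fresh(path: Path) -> bool:
        """A cached output is reusable if it exists under the same config."""
        marker = path.with_suffix(path.suffix + ".cfg")
        return resume and path.exists() and marker.exists() and (
            marker.read_text() == chash
        )

    def mark(path: Path) -> None:
        path.with_suffix(path.suffix + ".cfg").write_text(chash)

    # --- stage 1: virtual-drug library ---
    lib_path = out / "library.csv"
    if fresh(lib_path):
        library = pd.read_csv(lib_path)
        cached = True
    else:
        library = sample_virtual_drugs(
            config.ranges, n=config.sampling.n, seed=config.sampling.seed
        )
        library["bcs_class"] = classify_bcs(
            library,
            config.sampling.solubility_threshold,
            config.sampling.permeability_threshold,
        )
        _write_csv(library, lib_path)
        mark(lib_path)
        cached = False
    manifest.record("generate", lib_path, n=len(library), cached=cached)

    # --- stage 2: PBPK simulation + summary metrics ---
    spkm_path = out / "spkm.csv"
    if fresh(spkm_path):
        spkm_df = pd.read_csv(spkm_path)
        records = [
            SPKMRecord(
                drug_id=str(r["id"]),
                cmax_over_dose=r["cmax_over_dose"],
                tmax=r["tmax"],
                auc_over_dose=r["auc_over_dose"],
                degenerate=bool(r["degenerate"]),
            )
            for r in spkm_df.to_dict("records")
        ]
        cached = True
    else:
        settings = SolverSettings(
            t_end=config.solver.t_end,
            dt=config.solver.dt,
            rtol=config.solver.rtol,
            atol_dose_scale=config.solver.atol_dose_scale,
            ionization=config.solver.ionization,
        )
        records = simulate_library(
            library, settings, config.solver.max_failure_fraction
        )
        spkm_df = pd.DataFrame(
            [
                {"id": r.drug_id, **r.as_dict(), "degenerate": r.degenerate}
                for r in records
            ]
        )
        _write_csv(spkm_df, spkm_path)
        mark(spkm_path)
        cached = False
    n_failed = sum(r.degenerate for r in records)
    manifest.record("simulate", spkm_path, n=len(records), failed=n_failed,
                    cached=cached)

    # --- stage 3: dataset assembly + normalization ---
    dataset, scaler = assemble_dataset(library, records)
    ds_path = out / "dataset.csv"
    _write_csv(dataset.reset_index(), ds_path)
    scaler.to_json(out / "scaler.json")
    manifest.record("metrics", ds_path, rows=len(dataset))

    # --- stage 4: split + training ---
    split = split_dataset(dataset, config.split.test_fraction, config.split.seed)
    split.to_frame().reset_index().to_csv(out / "split.csv", index=False)
    models_dir = out / "models"
    if fresh(models_dir / "modelset.json"):
        models = SurrogateModelSet.load(models_dir)
        cached = True
    else:
        models = train_model_set(
            dataset,
            split,
            scaler,
            FEATURE_COLUMNS,
            grid=config.training.grid,
            cv_folds=config.training.cv_folds,
            seed=config.training.seed,
            algorithm=config.training.algorithm,
        )
        models.save(models_dir)
        mark(models_dir / "modelset.json")
        cached = False
    manifest.record("train", models_dir, cached=cached)

    # --- stage 5: evaluation + reduced-feature-set search ---
    ffs_report = evaluate_model_set(
        models,
        dataset,
        split,
        bin_width=config.evaluation.bin_width,
        denominator_floor=config.evaluation.denominator_floor,
    )
    importance = feature_importance(models)
    importance.to_csv(out / "importance.csv", float_format=_FLOAT_FMT)
    rfs = optimize_reduced_feature_set(
        dataset,
        split,
        importance,
        models,
        bin_width=config.evaluation.bin_width,
        denominator_floor=config.evaluation.denominator_floor,
    )
    rfs.score_curve.to_csv(out / "rfs_curve.csv", float_format=_FLOAT_FMT)
    rfs.optimal_models.save(out / "models_rfs")
    report = {
        "ffs": ffs_report,
        "rfs": rfs.optimal_report,
        "rfs_features": rfs.optimal_features,
        "n_failed_simulations": n_failed,
    }
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2))
    manifest.record("evaluate", report_path,
                    rfs_size=len(rfs.optimal_features))

    manifest.save(out / "manifest.json")
    return manifest
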