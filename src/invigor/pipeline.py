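"""End-to-end orchestration: discovery and validation runs.

A discovery run reads a cohort with paired mammogram dimensions and
survival, ranks the shape x law grid, optimises the fast/slow cutpoint,
labels the cohort, reports group survival (with multivariate adjustment)
and trains the surrogate classifier. A validation run applies a frozen
surrogate to an independent cohort and reports survival by predicted
group. Every numeric output is reproducible from (config, seed) alone;
reports are JSON (sorted keys, no timestamps) plus delimited tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_io, growth, sm_invigor, surrogate
from .errors import DataError, PipelineStageError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cohort_path: str = ""
    validation_path: str | None = None
    output_dir: str = "invigor_out"
    shape: str | None = None  # None -> take the AIC winner's shape
    law: str | None = None  # None -> take the AIC winner's law label
    sphere_rule: str = "mean"
    horizon_months: float = 120.0
    min_group_frac: float = 0.10
    threshold_p: float = 0.2
    folds: int = 5
    repeats: int = 10
    budget: int = 180
    seed: int = 0
    features: tuple = surrogate.DEFAULT_FEATURES
    adjusters: tuple = sm_invigor.DEFAULT_ADJUSTERS
    zoo: tuple = ("knn",)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        cfg = cls(**raw)
        for key in ("features", "adjusters", "zoo"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def write_json(payload: dict, path: Path):
    path.write_text(json.dumps(_jsonable(payload), sort_keys=True, indent=2) + "\n")


def _stage(name):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            log.info("stage %s: done", name)
            return False

    return _Ctx()


def run_discovery(config: PipelineConfig) -> dict:
    """Execute the full discovery sequence; returns paths of written outputs."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    with _stage("read_cohort"):
        cohort = cohort_io.read_cohort(config.cohort_path)

    with _stage("rank_models"):
        grid = sm_invigor.rank_models(
            cohort,
            horizon_months=config.horizon_months,
            min_group_frac=config.min_group_frac,
            sphere_rule=config.sphere_rule,
        )
        shape = config.shape or grid.best_shape
        spec = (
            sm_invigor._spec_from_label(config.law) if config.law else grid.best_spec
        )
        grid_path = outdir / "model_grid.csv"
        grid.table.to_csv(grid_path, index=False)
        outputs["model_grid"] = str(grid_path)
        write_json(
            {
                "best": grid.best.to_dict(),
                "n_patients": grid.n_patients,
                "volume_fits": grid.volume_fits.to_dict("records")
                if grid.volume_fits is not None
                else None,
            },
            outdir / "model_grid.json",
        )
        outputs["model_grid_json"] = str(outdir / "model_grid.json")

    with _stage("cutpoint"):
        usable = cohort_io.complete_case_subset(
            cohort,
            [
                "screen_dim_major",
                "screen_dim_minor",
                "diag_dim_major",
                "diag_dim_minor",
                "interval_days",
                "bcss_months",
                "event",
            ],
        )
        rates_df = growth.cohort_rates(usable, shape, spec, config.sphere_rule)
        ok = rates_df["valid"].to_numpy()
        import invigor.survival as survival

        t, e = survival.administrative_censor(
            usable.df.loc[ok, "bcss_months"], usable.df.loc[ok, "event"], config.horizon_months
        )
        cut = sm_invigor.optimise_cutpoint(
            rates_df.loc[ok, "rate"], t, e, config.min_group_frac
        )
        write_json(
            {
                "shape": shape,
                "law": spec.label,
                "threshold": cut.threshold,
                "chi_square": cut.chi_square,
                "p_value": cut.p_value,
                "n_slow": cut.n_slow,
                "n_fast": cut.n_fast,
                "n_candidates": cut.n_candidates,
            },
            outdir / "cutpoint.json",
        )
        outputs["cutpoint"] = str(outdir / "cutpoint.json")

    with _stage("label_and_survival"):
        labelled = sm_invigor.compute_sm_invigor(
            usable, shape, spec, cut.threshold, config.sphere_rule
        )
        lab_df = usable.df.copy()
        lab_df["rate"] = labelled["rates"]["rate"].to_numpy()
        lab_df["sm_invigor"] = labelled["rates"]["label"].to_numpy()
        lab_path = outdir / "labelled_cohort.csv"
        lab_df.to_csv(lab_path, index=False)
        outputs["labelled_cohort"] = str(lab_path)
        report = dict(labelled["report"])
        try:
            adj = sm_invigor.multivariate_adjustment(
                usable, labelled["rates"]["label"].to_numpy(), config.adjusters
            )
            report["cox_multivariate"] = {
                "hazard_ratio_fast": float(adj.hazard_ratios["fast"]),
                "p_value_fast": float(adj.p_values["fast"]),
                "coefficients": adj.coefficients.to_dict(),
                "p_values": adj.p_values.to_dict(),
            }
        except DataError as exc:
            report["cox_multivariate"] = {"error": str(exc)}
        write_json(report, outdir / "sm_invigor_report.json")
        outputs["sm_invigor_report"] = str(outdir / "sm_invigor_report.json")

    with _stage("train_surrogate"):
        X, y, _ = surrogate.build_feature_matrix(
            usable, config.features, labelled["rates"]["label"].to_numpy()
        )
        artifact, trace = surrogate.sequential_select(
            X,
            y,
            threshold_p=config.threshold_p,
            zoo=config.zoo,
            budget=config.budget,
            folds=config.folds,
            repeats=config.repeats,
            seed=config.seed,
        )
        model_path = outdir / "surrogate_model.json"
        artifact.save(model_path)
        trace.to_csv(outdir / "selection_trace.csv", index=False)
        outputs["surrogate_model"] = str(model_path)
        outputs["selection_trace"] = str(outdir / "selection_trace.csv")

    with _stage("manifest"):
        from . import __version__

        write_json(
            {
                "package_version": __version__,
                "config": asdict(config),
                "config_hash": config.config_hash(),
                "selected_shape": shape,
                "selected_law": spec.label,
                "threshold": cut.threshold,
                "surrogate_hash": artifact.content_hash(),
            },
            outdir / "manifest.json",
        )
        outputs["manifest"] = str(outdir / "manifest.json")
    return outputs


def run_validation(
    config: PipelineConfig, model: surrogate.SurrogateModelArtifact
) -> dict:
    """Apply a frozen surrogate to the validation cohort and report survival."""
    if not config.validation_path:
        raise DataError("config.validation_path is required for a validation run")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    with _stage("read_validation_cohort"):
        cohort = cohort_io.read_cohort(config.validation_path)
        if len(cohort) == 0:
            raise DataError("validation cohort is empty")
    with _stage("apply_surrogate"):
        result = surrogate.apply_surrogate(model, cohort, config.adjusters)
        out_df = cohort.df.copy()
        out_df["surr_invigor"] = result["labels"].to_numpy()
        out_path = outdir / "validation_labelled.csv"
        out_df.to_csv(out_path, index=False)
        report = {
            "n": len(cohort),
            "n_labelled": result["n_labelled"],
            "n_fast": int((result["labels"] == "fast").sum()),
            "n_slow": int((result["labels"] == "slow").sum()),
            "survival": result["report"],
        }
        write_json(report, outdir / "validation_report.json")
    return {
        "validation_labelled": str(out_path),
        "validation_report": str(outdir / "validation_report.json"),
        "report": report,
    }
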