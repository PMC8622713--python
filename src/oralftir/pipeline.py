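"""End-to-end orchestration: simulate -> preprocess -> QC -> train ->
evaluate -> stratify.

Each stage is a plain function over in-memory objects so the analysis
scripts, the tests and the acceptance script can all drive the same code;
``run_pipeline`` chains them, optionally persisting every stage's output
(CSV/JSON tables, ENVI cubes on request) under an artifact directory.
One global seed is forked per stage by a counter scheme so that stages are
independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as oio
from .dataset import SpectrumSet
from .evaluation import CVReport, FoldAssignment, cross_validate, venetian_blinds
from .pixel_qc import representatives_from_pixels, select_two_per_sample
from .plsda import (
    PLSDAModel,
    extract_feature_bands,
    feature_bands_frame,
    fit_plsda,
    select_n_lv,
)
from .preprocessing import PreprocessConfig, preprocess_general, second_derivative
from .stratify import StratificationResult, stratify
from .synthetic import Cohort, CohortScenario, DistortionConfig, generate_cohort

logger = logging.getLogger(__name__)


def fork_seed(seed: int, stage_index: int) -> int:
    """Counter-based per-stage seed derivation (stable, below 2^31)."""
    return int((seed * 1_000_003 + stage_index) % (2**31 - 1))


@dataclass
class RunConfig:
    """Everything one pipeline run needs, fully serializable to YAML."""

    scenario: CohortScenario = field(default_factory=CohortScenario)
    distortion: DistortionConfig = field(default_factory=DistortionConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    max_lv: int = 10
    threshold: float = 0.5
    cv_k: int = 10
    delta: float = 0.0
    tau_t: float = 3.0
    tau_q: float = 3.0
    seed: int = 42

    def __post_init__(self) -> None:
        # the global seed drives the cohort scenario
        if self.scenario.seed != fork_seed(self.seed, 0):
            self.scenario = replace(self.scenario, seed=fork_seed(self.seed, 0))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)

        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        path.write_text(yaml.safe_dump(_clean(asdict(self)), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "scenario" not in payload:
            raise ValueError("config is missing the cohort scenario")
        scenario = payload.pop("scenario")
        scenario["oed_ground_truth"] = tuple(scenario.get("oed_ground_truth", ()))
        distortion = payload.pop("distortion", {})
        for key in ("scatter_scale_range", "baseline_coeff_sd", "amideII_redshift"):
            if key in distortion:
                distortion[key] = tuple(distortion[key])
        pre = payload.pop("preprocess", {})
        for key in ("region", "steps"):
            if key in pre:
                pre[key] = tuple(pre[key])
        return cls(
            scenario=CohortScenario(**scenario),
            distortion=DistortionConfig(**distortion),
            preprocess=PreprocessConfig(**pre),
            **payload,
        )


@dataclass
class PipelineResult:
    """All artifacts of one end-to-end run."""

    config: RunConfig
    cohort: Cohort
    preprocessed: SpectrumSet
    representatives: SpectrumSet  # 2 per sample, general (non-derivative) form
    model_input: SpectrumSet  # second-derivative, renormalized
    n_lv: int
    cal_errors: np.ndarray
    cv_errors: np.ndarray
    model: PLSDAModel
    folds: FoldAssignment
    cv_report: CVReport
    stratification: StratificationResult
    feature_bands: list


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig) -> Cohort:
    cohort = generate_cohort(config.scenario, config.distortion)
    logger.info(
        "simulate: %d samples, %d areas, %d pixel spectra",
        config.scenario.n_samples,
        len(cohort.areas),
        cohort.pixels.n_spectra,
    )
    return cohort


def stage_preprocess(cohort: Cohort, config: RunConfig) -> SpectrumSet:
    out = preprocess_general(cohort.pixels, config.preprocess)
    logger.info("preprocess: %d rows -> %d wavenumbers", out.n_spectra, len(out.grid))
    return out


def stage_qc(preprocessed: SpectrumSet, config: RunConfig) -> SpectrumSet:
    reps = representatives_from_pixels(
        preprocessed, tau_t=config.tau_t, tau_q=config.tau_q
    )
    pairs = select_two_per_sample(reps)
    logger.info(
        "qc: %d area representatives -> %d retained (2 per sample)",
        reps.n_spectra,
        pairs.n_spectra,
    )
    return pairs


def stage_model_input(representatives: SpectrumSet, config: RunConfig) -> SpectrumSet:
    return second_derivative(representatives, config.preprocess)


def stage_train(
    model_input: SpectrumSet, config: RunConfig
) -> tuple[PLSDAModel, FoldAssignment, int, np.ndarray, np.ndarray]:
    train_mask = np.isin(model_input.classes, ("H", "C"))
    train = model_input.select_rows(train_mask)
    folds = venetian_blinds(train, k=config.cv_k)
    n_lv, cal_err, cv_err = select_n_lv(train, train.classes, folds.folds, config.max_lv)
    model = fit_plsda(train, train.classes, n_lv=n_lv, threshold=config.threshold)
    logger.info("train: %d spectra, chose %d latent variables", train.n_spectra, n_lv)
    return model, folds, n_lv, cal_err, cv_err


def stage_evaluate(
    model_input: SpectrumSet, config: RunConfig, n_lv: int, folds: FoldAssignment
) -> CVReport:
    train = model_input.select_rows(np.isin(model_input.classes, ("H", "C")))

    def factory(subset: SpectrumSet, labels):
        return fit_plsda(subset, labels, n_lv=n_lv, threshold=config.threshold)

    report = cross_validate(factory, train, train.classes, folds)
    logger.info(
        "evaluate: sensitivity %.3f, specificity %.3f, AUC %.3f",
        report.sensitivity,
        report.specificity,
        report.roc.auc,
    )
    return report


def stage_stratify(
    model: PLSDAModel, model_input: SpectrumSet, config: RunConfig
) -> StratificationResult:
    oed = model_input.select_rows(model_input.classes == "D")
    result = stratify(model, oed, delta=config.delta)
    logger.info("stratify: grade counts %s", result.grade_counts)
    return result


# ---------------------------------------------------------------------------
# monolithic run
# ---------------------------------------------------------------------------


def run_pipeline(
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    write_cubes: bool = False,
) -> PipelineResult:
    """Run every stage in order; optionally persist all artifacts.

    With ``out_dir`` set, the resolved config, the representative spectra,
    the fitted model, the CV report, the stratification table and the
    feature-band table are written as CSV/JSON (plus ENVI cubes when
    ``write_cubes``). Identical config and seed give byte-identical files.
    """
    config = config or RunConfig()
    cohort = stage_simulate(config)
    preprocessed = stage_preprocess(cohort, config)
    representatives = stage_qc(preprocessed, config)
    model_input = stage_model_input(representatives, config)
    model, folds, n_lv, cal_err, cv_err = stage_train(model_input, config)
    cv_report = stage_evaluate(model_input, config, n_lv, folds)
    strat = stage_stratify(model, model_input, config)
    bands = extract_feature_bands(model, lv_indices=sorted({1, min(2, model.n_lv)}))

    result = PipelineResult(
        config=config,
        cohort=cohort,
        preprocessed=preprocessed,
        representatives=representatives,
        model_input=model_input,
        n_lv=n_lv,
        cal_errors=cal_err,
        cv_errors=cv_err,
        model=model,
        folds=folds,
        cv_report=cv_report,
        stratification=strat,
        feature_bands=bands,
    )
    if out_dir is not None:
        persist(result, Path(out_dir), write_cubes=write_cubes)
    return result


def persist(result: PipelineResult, out_dir: Path, write_cubes: bool = False) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out_dir / "config.yaml")
    oio.write_csv_spectra(result.representatives, out_dir / "representatives.csv")
    oio.write_csv_spectra(result.model_input, out_dir / "model_input.csv")
    oio.write_json(
        {
            "n_lv": result.n_lv,
            "calibration_errors": result.cal_errors,
            "cv_errors": result.cv_errors,
            "explained_x_variance": result.model.explained_x_variance,
            "coef": result.model.coef,
            "x_mean": result.model.x_mean,
            "y_mean": result.model.y_mean,
            "threshold": result.model.threshold,
            "wavenumbers": result.model.wavenumbers,
            "x_loadings": result.model.x_loadings,
        },
        out_dir / "plsda_model.json",
    )
    oio.write_json(result.cv_report.to_dict(), out_dir / "cv_report.json")
    result.cv_report.predictions.to_csv(out_dir / "cv_predictions.csv", index=False)
    oio.write_json(result.stratification.to_dict(), out_dir / "stratification.json")
    result.stratification.table.to_csv(out_dir / "stratification.csv", index=False)
    feature_bands_frame(result.feature_bands).to_csv(out_dir / "feature_bands.csv", index=False)
    if write_cubes:
        cube_dir = out_dir / "cubes"
        cube_dir.mkdir(exist_ok=True)
        for area_id, area in result.cohort.pixels.groupby("area_id"):
            oio.write_envi_cube(area, cube_dir / f"{area_id}.raw")
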