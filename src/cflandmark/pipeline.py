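"""End-to-end pipeline: simulate -> landmark -> fit -> evaluate -> predict.

Runs the full landmarking workflow from a single declarative run
configuration, writing every artifact (registry tables, stacked dataset,
serialized fits, performance report, calibration tables, predicted-
probability distributions) plus a manifest with derived stage seeds and
SHA-256 checksums, so any stage can be re-run from persisted intermediates
and reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import evaluation as ev
from .landmark import (
    StackedDataset,
    build_stacked_dataset,
    default_landmark_grid,
    write_stacked,
)
from .mixed import DEFAULT_MIXED_OUTCOMES, attach_mixed_features, fit_multivariate_mixed
from .survival import fit_to_json
from .synthetic_registry import GeneratorConfig, Registry, read_registry, simulate_registry, write_registry
from .variants import SeparateLandmarkFits, VariantOptions, fit_variant

__all__ = ["RunConfig", "run_pipeline", "attach_two_stage_features", "predicted_probability_distribution"]

log = logging.getLogger("cflandmark")


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    Exactly one data source: a generator config (simulate) or a directory
    with registry files.  The master seed drives deterministically derived
    per-stage child seeds.
    """

    seed: int
    out_dir: Union[str, pathlib.Path]
    generator: Optional[GeneratorConfig] = None
    registry_dir: Optional[Union[str, pathlib.Path]] = None
    landmark_grid: Sequence[float] = field(default_factory=default_landmark_grid)
    horizon: float = 10.0
    variants: Sequence[int] = (1, 2)
    horizons: Sequence[float] = (2.0, 5.0, 10.0)
    split_fraction: float = 0.8
    cv_reps: int = 0
    predictors: Optional[Sequence[str]] = None

    def validate(self) -> None:
        if (self.generator is None) == (self.registry_dir is None):
            raise ValueError("exactly one of generator / registry_dir must be set")
        if not 0 < self.split_fraction <= 1:
            raise ValueError("split_fraction must be in (0, 1]")


def _child_seeds(master: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def attach_two_stage_features(
    registry: Registry,
    stacked: StackedDataset,
    outcomes: Sequence[str] = DEFAULT_MIXED_OUTCOMES,
) -> StackedDataset:
    """Fit one multivariate mixed model per landmark age and append the
    fitted-value/slope columns to the stacked records (variant 6 input)."""
    frames = []
    for L in stacked.landmark_grid:
        sub = stacked.records[stacked.records["L"] == L]
        if len(sub) == 0:
            continue
        fit = fit_multivariate_mixed(registry.reviews, L, outcomes=outcomes, patient_ids=sub["patient_id"])
        from .landmark import LandmarkDataset

        ld = LandmarkDataset(L=L, records=sub.reset_index(drop=True), exclusion_log={})
        frames.append(attach_mixed_features(ld, fit).records)
    return StackedDataset(pd.concat(frames, ignore_index=True), stacked.landmark_grid)


def predicted_probability_distribution(
    predictions: Dict[float, np.ndarray],
    records: pd.DataFrame,
    bins: Sequence[float] = (0.0, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 1.0),
) -> pd.DataFrame:
    """Counts of individuals by predicted-survival-probability bin, per
    landmark age and horizon (distribution summary of the predictions)."""
    rows = []
    Ls = records["L"].to_numpy()
    for h, p in predictions.items():
        for L in np.unique(Ls):
            idx = np.flatnonzero(Ls == L)
            counts, _ = np.histogram(p[idx], bins=np.asarray(bins))
            for b, cnt in enumerate(counts):
                rows.append(
                    {
                        "L": L,
                        "horizon": h,
                        "bin_lower": bins[b],
                        "bin_upper": bins[b + 1],
                        "count": int(cnt),
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> pathlib.Path:
    """Execute all stages and return the run directory."""
    config.validate()
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 4)
    manifest: Dict[str, object] = {
        "master_seed": config.seed,
        "stage_seeds": {"simulate": seeds[0], "split": seeds[1], "cv": seeds[2]},
        "checksums": {},
        "stages": [],
    }
    checksums: Dict[str, str] = manifest["checksums"]  # type: ignore[assignment]

    def record(stage: str, *paths: pathlib.Path) -> None:
        manifest["stages"].append(stage)  # type: ignore[union-attr]
        for p in paths:
            checksums[str(p.relative_to(out))] = _sha256(p)

    stage = "simulate"
    try:
        if config.generator is not None:
            gen = dataclasses.replace(config.generator, seed=seeds[0])
            log.info("simulating registry: n=%d seed=%d", gen.n_individuals, gen.seed)
            registry = simulate_registry(gen)
            reg_dir = out / "registry"
            write_registry(registry, reg_dir)
            record(stage, reg_dir / "patients.csv", reg_dir / "reviews.csv")
        else:
            registry = read_registry(config.registry_dir)

        stage = "landmark"
        study_window = registry.config_echo.study_window if registry.config_echo else None
        stacked = build_stacked_dataset(
            registry, grid=config.landmark_grid, w=config.horizon, study_window=study_window
        )
        log.info("stacked dataset: %d records, %d landmark ages", len(stacked), len(stacked.landmark_grid))
        stacked_path = out / "stacked.csv"
        write_stacked(stacked, stacked_path)
        record(stage, stacked_path)

        stage = "two_stage"
        if 6 in config.variants:
            stacked = attach_two_stage_features(registry, stacked)
            write_stacked(stacked, out / "stacked_with_mixed.csv")
            record(stage, out / "stacked_with_mixed.csv")

        stage = "split"
        train, holdout = ev.split_stacked(stacked, config.split_fraction, seed=seeds[1])
        write_stacked(train, out / "train.csv")
        write_stacked(holdout, out / "holdout.csv")
        record(stage, out / "train.csv", out / "holdout.csv")

        stage = "fit"
        predictors = list(config.predictors) if config.predictors else None
        fits: Dict[int, object] = {}
        for v in config.variants:
            opts = VariantOptions(variant=v, horizon=config.horizon)
            kwargs = {"predictors": predictors} if predictors else {}
            fit = fit_variant(train, opts, **kwargs)
            fits[v] = fit
            if isinstance(fit, SeparateLandmarkFits):
                fit_dir = out / f"fit_variant{v}"
                fit_dir.mkdir(exist_ok=True)
                paths = []
                for L, f in fit.fits.items():
                    p = fit_dir / f"L{int(L)}.json"
                    p.write_text(fit_to_json(f))
                    paths.append(p)
                record(stage, *paths)
            else:
                p = out / f"fit_variant{v}.json"
                p.write_text(fit_to_json(fit))
                record(stage, p)

        stage = "evaluate"
        report_rows = {}
        eval_records = holdout.records if len(holdout) else train.records
        for v, fit in fits.items():
            if isinstance(fit, SeparateLandmarkFits):
                predictions = {h: fit.predict_at(eval_records, h) for h in config.horizons}
                ref = ev.km_reference_predictions(eval_records, config.horizons)
                report = ev.evaluate_predictions(eval_records, predictions, config.horizons, ref)
            else:
                report = ev.evaluate_fit(fit, eval_records, config.horizons)
                predictions = {h: ev.predict_survival_at(fit, eval_records, h) for h in config.horizons}
            report.per_landmark.to_csv(out / f"performance_variant{v}_per_landmark.csv", index=False)
            dist = predicted_probability_distribution(predictions, eval_records)
            dist.to_csv(out / f"predicted_distribution_variant{v}.csv", index=False)
            report_rows[v] = {
                **report.overall,
                **{f"pct_reduction_{ev._hlab(h)}": r for h, r in report.percent_reduction.items()},
            }
            record(stage, out / f"performance_variant{v}_per_landmark.csv",
                   out / f"predicted_distribution_variant{v}.csv")
            for h in config.horizons:
                cal = ev.calibration_table(predictions[h], eval_records["time"], eval_records["event"], h)
                cal_path = out / f"calibration_variant{v}_{ev._hlab(h)}.csv"
                cal.table.to_csv(cal_path, index=False)
                record(stage, cal_path)
        perf_path = out / "performance_overall.json"
        perf_path.write_text(json.dumps(report_rows, indent=2, default=float))
        record(stage, perf_path)

        stage = "cv"
        if config.cv_reps > 0:
            opts = VariantOptions(variant=2, horizon=config.horizon)
            cv_report = ev.monte_carlo_cv(
                train,
                lambda d: fit_variant(d, opts),
                n_reps=config.cv_reps,
                seed=seeds[2],
                horizons=config.horizons,
            )
            cv_path = out / "cv_summary.csv"
            cv_report.cv_summary.to_csv(cv_path)
            record(stage, cv_path)
    except Exception as err:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {err}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %s", out)
    return out
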