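"""End-to-end pipeline orchestration with config, manifest and provenance.

``run_pipeline`` executes the nine stages — synth, resample, align, fit,
quality, generate, validate, regress, classify — writing per-stage wall
times, output files and content hashes into a JSON manifest.  The single
config seed fans out into named per-stage substreams so any stage can be
re-run in isolation with the same randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from .cohort import cohort_manifest, generate_cohort
from .errors import VcohortError
from .morphometrics import compare_cohorts, measure_anatomy
from .registration import align_calcifications, align_cohort
from .shapeml import classify, clinical_table, mode_scores, svm_regress
from .ssm import fit, generalization, modes_for_variance
from .surface import resample
from .synthetic import GeneratorConfig, make_cohort

STAGES = ("synth", "resample", "align", "fit", "quality", "generate",
          "validate", "regress", "classify")


@dataclass
class RunConfig:
    """All pipeline parameters, with method defaults baked in.

    Stage defaults mirror the method constants: ICP tolerance 0.01 mm with a
    120-iteration cap, calcification tolerance 0.2 mm, 90 % retained
    variance, +/- 2 sigma sampling in 0.5 sigma steps, 6 selected modes,
    ten-fold CV and a 70/30 classification split.
    """

    seed: int = 0
    outdir: str = "vcohort_run"
    # synthetic cohort
    n_patients: int = 68
    wall_points: int = 2000
    calc_points: int = 1500
    # correspondence
    tolerance_mm: float = 0.01
    calc_tolerance_mm: float = 0.2
    max_icp_iter: int = 120
    mean_tol_mm: float = 0.05
    max_mean_iter: int = 10
    nonrigid_iter: int = 10
    # virtual cohort
    variance_fraction: float = 0.90
    boundary: float = 2.0
    step: float = 0.5
    n_virtual: int = 100
    # quality
    quality_modes: list = field(default_factory=lambda: [1, 2, 5, 10, 15, 20])
    # ML
    n_select: int = 6
    folds: int = 10
    tuning_iters: int = 20
    test_fraction: float = 0.30
    target_variable: str = "peak_gradient"
    label_variable: str = "device_size"
    write_surfaces: bool = False

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha1(path: str) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(STAGES, children)}


class _Manifest:
    def __init__(self, config: RunConfig, seeds: dict):
        self.data = {"package_version": __version__,
                     "config": asdict(config), "stage_seeds": seeds,
                     "stages": {}}
        self._t0 = None
        self._current = None

    def start(self, stage: str):
        self._current, self._t0 = stage, time.perf_counter()

    def finish(self, outputs=(), **info):
        entry = {"seconds": round(time.perf_counter() - self._t0, 3),
                 "outputs": {os.path.basename(p): _sha1(p) for p in outputs},
                 **info}
        self.data["stages"][self._current] = entry


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Run all nine stages on a synthetic cohort; returns the manifest dict.

    Artifacts (models, cohort manifest, measurements, results, manifest)
    are written under ``config.outdir``.  Raises with the failing stage
    named; partial artifacts are left in place.
    """
    config = config or RunConfig()
    os.makedirs(config.outdir, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = _Manifest(config, seeds)
    out = lambda name: os.path.join(config.outdir, name)

    stage = "synth"
    try:
        manifest.start(stage)
        gen_cfg = GeneratorConfig(n_patients=config.n_patients,
                                  wall_points=config.wall_points,
                                  calc_points=config.calc_points,
                                  seed=seeds["synth"])
        samples, truth = make_cohort(gen_cfg)
        clin_path = out("clinical.csv")
        clinical_table([s.clinical for s in samples]).to_csv(clin_path, index=False)
        truth_path = out("latents.csv")
        truth.latents.to_csv(truth_path, index=False)
        manifest.finish([clin_path, truth_path], n_patients=len(samples))

        stage = "resample"
        manifest.start(stage)
        wall_target = min(config.wall_points,
                          min(s.wall.n_points for s in samples))
        calc_target = min(config.calc_points,
                          min(s.calcification.n_points for s in samples))
        rng = np.random.default_rng(seeds["resample"])
        walls = [resample(s.wall, wall_target, int(rng.integers(2 ** 31)))
                 for s in samples]
        calcs = [resample(s.calcification, calc_target,
                          int(rng.integers(2 ** 31))) for s in samples]
        manifest.finish([], wall_points=wall_target, calc_points=calc_target)

        stage = "align"
        manifest.start(stage)
        wall_cohort = align_cohort(
            walls, tolerance_mm=config.tolerance_mm,
            max_mean_iter=config.max_mean_iter, mean_tol_mm=config.mean_tol_mm,
            max_iter=config.max_icp_iter, nonrigid_iter=config.nonrigid_iter)
        calc_cohort = align_calcifications(
            calcs, wall_cohort, tolerance_mm=config.calc_tolerance_mm,
            max_iter=config.max_icp_iter, nonrigid_iter=config.nonrigid_iter)
        wall_cohort.save(out("wall_cohort.npz"))
        calc_cohort.save(out("calc_cohort.npz"))
        manifest.finish([out("wall_cohort.npz"), out("calc_cohort.npz")],
                        mean_iterations=wall_cohort.iterations_to_mean_convergence,
                        reference=wall_cohort.reference_id)

        stage = "fit"
        manifest.start(stage)
        wall_model = fit(wall_cohort)
        calc_model = fit(calc_cohort)
        wall_model.save(out("wall_model.npz"))
        calc_model.save(out("calc_model.npz"))
        manifest.finish(
            [out("wall_model.npz"), out("calc_model.npz")],
            wall_modes_90=modes_for_variance(wall_model, config.variance_fraction),
            calc_modes_90=modes_for_variance(calc_model, config.variance_fraction),
            wall_mode1_fraction=float(wall_model.variance_fractions[0]),
            calc_mode1_fraction=float(calc_model.variance_fractions[0]))

        stage = "quality"
        manifest.start(stage)
        M_values = [M for M in config.quality_modes
                    if M <= wall_cohort.n_subjects - 2]
        quality = {"wall": generalization(wall_cohort, M_values).generalization,
                   "calc": generalization(calc_cohort, M_values).generalization}
        qpath = out("quality.json")
        with open(qpath, "w") as fh:
            json.dump({k: {str(M): v for M, v in g.items()}
                       for k, g in quality.items()}, fh, indent=2)
        manifest.finish([qpath])

        stage = "generate"
        manifest.start(stage)
        patients = generate_cohort(
            wall_model, calc_model, n=config.n_virtual,
            variance_fraction=config.variance_fraction,
            boundary=config.boundary, step=config.step,
            seed=seeds["generate"])
        mpath = out("virtual_cohort.csv")
        cohort_manifest(patients).to_csv(mpath, index=False)
        written = [mpath]
        if config.write_surfaces:
            from .surface import write_surface
            surf_dir = out("virtual_surfaces")
            os.makedirs(surf_dir, exist_ok=True)
            for p in patients:
                for tag, shape in (("wall", p.wall), ("calc", p.calcification)):
                    path = os.path.join(surf_dir, f"{p.patient_id}_{tag}.ply")
                    write_surface(shape.surface, path)
        manifest.finish(written, n_virtual=len(patients))

        stage = "validate"
        manifest.start(stage)
        # real subjects are measured on their corresponded rows so both
        # groups share one representation (template discretization); raw
        # surfaces would confound the comparison with registration bias
        real = [measure_anatomy(wall_cohort.row_surface(i),
                                calc_cohort.row_surface(i), "real")
                for i in range(wall_cohort.n_subjects)]
        synth = [measure_anatomy(p.wall.surface, p.calcification.surface,
                                 "synthetic") for p in patients]
        report = compare_cohorts(real, synth)
        import pandas as pd
        meas_path = out("measurements.csv")
        pd.DataFrame([dataclasses.asdict(m) for m in real + synth]
                     ).to_csv(meas_path, index=False)
        vpath = out("validation.json")
        with open(vpath, "w") as fh:
            json.dump({"U_annulus": report.U_annulus,
                       "p_annulus": report.p_annulus,
                       "U_volume": report.U_volume,
                       "p_volume": report.p_volume,
                       "boxplots": report.boxplot_summaries}, fh, indent=2)
        manifest.finish([meas_path, vpath], p_annulus=report.p_annulus,
                        p_volume=report.p_volume)

        stage = "regress"
        manifest.start(stage)
        order = [wall_cohort.patient_ids.index(s.patient_id) for s in samples]
        scores = np.hstack([mode_scores(wall_model, wall_cohort)[order],
                            mode_scores(calc_model, calc_cohort)[order]])
        y = np.array([getattr(s.clinical, config.target_variable)
                      for s in samples], float)
        reg = svm_regress(scores, y, n_select=config.n_select,
                          folds=config.folds,
                          tuning_iters=config.tuning_iters,
                          seed=seeds["regress"])
        rpath = out("regression.json")
        with open(rpath, "w") as fh:
            json.dump({"selected_modes": reg.selected_modes,
                       "hyperparameters": reg.hyperparameters,
                       "cv_rmse": reg.cv_rmse, "r_squared": reg.r_squared,
                       "r_squared_refit": reg.r_squared_refit}, fh, indent=2)
        manifest.finish([rpath], cv_rmse=reg.cv_rmse, r_squared=reg.r_squared)

        stage = "classify"
        manifest.start(stage)
        labels = np.array([getattr(s.clinical, config.label_variable)
                           for s in samples])
        cls = classify(scores, labels, n_select=config.n_select,
                       test_fraction=config.test_fraction,
                       seed=seeds["classify"])
        cpath = out("classification.json")
        with open(cpath, "w") as fh:
            json.dump({name: {"accuracy": m.accuracy, "auroc": m.auroc,
                              "recall": {str(k): v for k, v in m.recall.items()},
                              "precision": {str(k): v
                                            for k, v in m.precision.items()},
                              "confusion": m.confusion.tolist()}
                       for name, m in cls.per_model.items()}, fh, indent=2)
        manifest.finish([cpath],
                        best_auroc=max(m.auroc for m in cls.per_model.values()))
    except Exception as exc:
        partial = out("manifest.json")
        manifest.data["failed_stage"] = stage
        with open(partial, "w") as fh:
            json.dump(manifest.data, fh, indent=2)
        raise VcohortError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    mpath = out("manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest.data, fh, indent=2)
    return manifest.data
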