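"""End-to-end orchestration: simulate -> preprocess -> classify -> report.

Every run is governed by one :class:`RunConfig` (nested simulation,
preprocessing and SVM configs plus a master seed).  A short hash of the
canonical config is stamped into every artifact (manifest, run metadata,
spectrum headers) so that artifacts produced under different configurations
cannot be silently mixed: :func:`run_predict` refuses a training directory
whose hash disagrees with the active config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigMismatchError, InvalidParameterError, MrsidhError
from .evaluate import PerformanceReport, build_report, average_class_spectra
from .features import STAGE_NORMALIZED, FeatureMatrix
from .nested_svm import SVMConfig, CVResult, choose_k_inner_cv, nested_loocv, predict, rank_features_ttest, train_linear_svm
from .preprocess import PreprocessConfig, preprocess_cohort, preprocess_spectrum
from .spectra_io import Spectrum, read_spectrum_txt, write_spectrum_txt
from .synthetic import (
    SimulationConfig,
    default_basis,
    simconfig_from_dict,
    simconfig_to_dict,
    simulate_cohort,
)

logger = logging.getLogger("mrsidh")


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration of a pipeline run."""

    output_dir: str = "results"
    input_dir: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    seed: int | None = None
    make_plots: bool = False
    effect_strength: float = 1.0

    def resolved_simulation(self) -> SimulationConfig:
        """Simulation config with the master seed applied, if given."""
        if self.seed is None:
            return self.simulation
        return self.simulation.replace(seed=int(self.seed))

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "output_dir": self.output_dir,
            "input_dir": self.input_dir,
            "simulation": simconfig_to_dict(self.resolved_simulation()),
            "preprocess": asdict(self.preprocess),
            "svm": asdict(self.svm),
            "seed": self.seed,
            "make_plots": self.make_plots,
            "effect_strength": self.effect_strength,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        prep = d.pop("preprocess", None)
        svm = d.pop("svm", None)
        kwargs: dict = {}
        if sim is not None:
            kwargs["simulation"] = simconfig_from_dict(sim)
        if prep is not None:
            prep = dict(prep)
            for key in ("reference_search_window", "region"):
                if key in prep:
                    prep[key] = tuple(prep[key])
            kwargs["preprocess"] = PreprocessConfig(**prep)
        if svm is not None:
            kwargs["svm"] = SVMConfig(**svm)
        kwargs.update({k: v for k, v in d.items() if v is not None or k == "input_dir"})
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        """Hash of the scientific parameters only (paths excluded), so the
        same analysis in a different directory yields identical artifacts."""
        d = self.to_dict()
        for key in ("output_dir", "input_dir", "make_plots"):
            d.pop(key, None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_run_meta(outdir: Path, config: RunConfig) -> None:
    meta = {"config_hash": config.config_hash(), "config": config.to_dict()}
    with open(outdir / "run_meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, default=str)


def _check_hash(outdir: Path, config: RunConfig) -> None:
    meta_path = outdir / "run_meta.json"
    if not meta_path.exists():
        return
    with open(meta_path, "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    if meta.get("config_hash") != config.config_hash():
        raise ConfigMismatchError(
            f"{outdir} holds artifacts from config {meta.get('config_hash')}, "
            f"current config is {config.config_hash()}; refusing to mix"
        )


def run_simulate(config: RunConfig) -> pd.DataFrame:
    """Simulate a cohort and write spectrum files plus a manifest CSV."""
    outdir = Path(config.output_dir) / "cohort"
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.resolved_simulation()
    logger.info("simulating cohort: n_mut=%d n_wt=%d seed=%d", sim.n_mut, sim.n_wt, sim.seed)
    if sim.n_mut + sim.n_wt == 0:
        logger.warning("empty cohort requested; writing manifest only")
        manifest = pd.DataFrame(columns=["sample_id", "label", "file", "seed", "config_hash"])
        manifest.to_csv(outdir / "manifest.csv", index=False)
        _write_run_meta(outdir.parent, config)
        return manifest
    basis = default_basis(config.effect_strength)
    spectra = simulate_cohort(basis, sim)
    rows = []
    chash = config.config_hash()
    for sp in spectra:
        fname = f"{sp.sample_id}.txt"
        sp.meta["config_hash"] = chash
        sp.meta.pop("concentrations", None)  # not representable in the header
        write_spectrum_txt(sp, outdir / fname)
        rows.append({"sample_id": sp.sample_id, "label": sp.label, "file": fname,
                     "seed": sim.seed, "config_hash": chash})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    _write_run_meta(outdir.parent, config)
    logger.info("wrote %d spectra and manifest to %s", len(rows), outdir)
    return manifest


def load_cohort(cohort_dir) -> list[Spectrum]:
    """Read a simulated or exported cohort back via its manifest."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    spectra = []
    for _, row in manifest.iterrows():
        sp = read_spectrum_txt(cohort_dir / row["file"])
        sp.sample_id = str(row["sample_id"])
        sp.label = str(row["label"])
        spectra.append(sp)
    return spectra


def run_preprocess(config: RunConfig, spectra: list[Spectrum] | None = None) -> FeatureMatrix:
    """Preprocess a cohort and write the feature matrix plus a sidecar log."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _check_hash(outdir, config)
    if spectra is None:
        src = Path(config.input_dir) if config.input_dir else outdir / "cohort"
        spectra = load_cohort(src)
    matrix = preprocess_cohort(spectra, config.preprocess)
    from .features import write_feature_matrix_csv

    write_feature_matrix_csv(matrix, outdir / "feature_matrix.csv")
    pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "phase_correction_deg": matrix.meta["phase_correction_deg"],
            "alignment_shift_points": matrix.meta["alignment_shift_points"],
        }
    ).to_csv(outdir / "preprocess_log.csv", index=False)
    logger.info("feature matrix: %d samples x %d bins", matrix.n_samples, matrix.n_features)
    return matrix


def run_classify(config: RunConfig, matrix: FeatureMatrix) -> CVResult:
    """Nested LOOCV; writes per-sample predictions and selection counts."""
    outdir = Path(config.output_dir)
    cv = nested_loocv(matrix, config.svm)
    cv.to_frame().to_csv(outdir / "cv_predictions.csv", index=False)
    pd.DataFrame(
        {
            "ppm_high": [hi for hi, _ in cv.bin_edges],
            "ppm_low": [lo for _, lo in cv.bin_edges],
            "selection_count": cv.selection_counts,
        }
    ).to_csv(outdir / "selected_features.csv", index=False)
    logger.info("nested LOOCV accuracy: %.3f", cv.accuracy)
    return cv


def _plot_outputs(outdir: Path, matrix_norm: FeatureMatrix, cv: CVResult) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean_mut, mean_wt, diff, edges = average_class_spectra(matrix_norm)
    mid = np.array([(hi + lo) / 2 for hi, lo in edges])
    fig, ax = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    ax[0].plot(mid, mean_wt, label="IDHwt mean", color="tab:blue")
    ax[0].plot(mid, mean_mut, label="IDHmut mean", color="tab:red")
    ax[0].axvspan(3.5, 4.1, color="green", alpha=0.15, label="3.5-4.1 ppm")
    ax[0].legend(); ax[0].set_ylabel("normalized intensity")
    ax[1].plot(mid, diff, color="black")
    ax[1].axvspan(3.5, 4.1, color="green", alpha=0.15)
    ax[1].set_ylabel("mut - wt"); ax[1].set_xlabel("ppm")
    for a in ax:
        a.invert_xaxis()
    fig.tight_layout()
    fig.savefig(outdir / "averaged_spectra.png", dpi=120)
    plt.close(fig)

    from sklearn.metrics import roc_curve

    y = np.array([t == cv.positive_class for t in cv.true_labels], dtype=int)
    fpr, tpr, _ = roc_curve(y, cv.decision_values)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(fpr, tpr, marker="o")
    ax.plot([0, 1], [0, 1], ls="--", color="gray")
    ax.set_xlabel("1 - specificity"); ax.set_ylabel("sensitivity")
    fig.tight_layout()
    fig.savefig(outdir / "roc_curve.png", dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig, spectra: list[Spectrum] | None = None) -> PerformanceReport:
    """The full chain; returns the performance report and writes all artifacts."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if spectra is None and config.input_dir is None:
        run_simulate(config)
        spectra = load_cohort(outdir / "cohort")
    elif spectra is None:
        spectra = load_cohort(config.input_dir)
    unlabeled = [sp.sample_id for sp in spectra if sp.label == "unknown"]
    if unlabeled:
        raise InvalidParameterError(
            f"samples without class labels cannot be cross-validated: {unlabeled}"
        )
    matrix = run_preprocess(config, spectra)
    cv = run_classify(config, matrix)
    report = build_report(cv)
    report.to_json(outdir / "report.json")
    (outdir / "report.txt").write_text(report.summary_text() + "\n", encoding="utf-8")

    matrix_norm = preprocess_cohort(spectra, config.preprocess, final_stage=STAGE_NORMALIZED)
    mean_mut, mean_wt, diff, edges = average_class_spectra(matrix_norm)
    pd.DataFrame(
        {
            "ppm_high": [hi for hi, _ in edges],
            "ppm_low": [lo for _, lo in edges],
            "mean_IDHmut": mean_mut,
            "mean_IDHwt": mean_wt,
            "difference": diff,
        }
    ).to_csv(outdir / "averaged_spectra.csv", index=False)
    if config.make_plots:
        _plot_outputs(outdir, matrix_norm, cv)
    _write_run_meta(outdir, config)
    logger.info("report written to %s", outdir / "report.json")
    return report


def run_predict(
    config: RunConfig,
    training_matrix: FeatureMatrix,
    new_spectra: list[Spectrum],
    training_dir=None,
) -> pd.DataFrame:
    """Train once on the full labeled matrix, then predict new spectra.

    k is chosen by the same inner leave-one-out used inside the nested CV.
    Per-sample preprocessing failures are reported in the output table
    without aborting the batch.
    """
    if training_dir is not None:
        _check_hash(Path(training_dir), config)
    k = choose_k_inner_cv(training_matrix, config.svm)
    order = rank_features_ttest(training_matrix, positive_class=config.svm.positive_class)
    selected = np.sort(order[:k])
    model = train_linear_svm(training_matrix, selected, config.svm)
    rows = []
    for sp in new_spectra:
        try:
            fv = preprocess_spectrum(sp, config.preprocess)
            if fv.bin_edges != training_matrix.bin_edges:
                raise ConfigMismatchError(
                    f"sample {sp.sample_id!r}: bin layout differs from the training matrix"
                )
            label, d = predict(model, fv)
            rows.append({"sample_id": sp.sample_id, "predicted_label": label,
                         "decision_value": d, "error": ""})
        except MrsidhError as exc:
            logger.error("sample %s failed: %s", sp.sample_id, exc)
            rows.append({"sample_id": sp.sample_id, "predicted_label": "",
                         "decision_value": np.nan, "error": str(exc)})
    out = pd.DataFrame(rows, columns=["sample_id", "predicted_label", "decision_value", "error"])
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    out.to_csv(outdir / "predictions.csv", index=False)
    return out
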