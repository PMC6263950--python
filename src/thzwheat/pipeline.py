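"""End-to-end orchestration: simulate -> extract -> features -> train -> fuse
-> evaluate.

One master seed fans out to the stages by fixed offsets (simulation seed,
split seed + 1, SVM seed + 2), so any stage can be rerun in isolation and
reproduce the same downstream artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify, features, fusion
from .config import PipelineConfig, REPORTED_SUBCLASSIFIER_PARAMS
from .evaluate import RecognitionReport, compare_models, confusion, rates
from .optics import OpticalSpectrum, average_scans, extract_optical
from .synthetic import (
    CLASS_ORDER,
    ClassSpecification,
    SyntheticDataset,
    TimeGrid,
    generate_dataset,
)

logger = logging.getLogger("thzwheat")

SIM_SEED_OFFSET = 0
SPLIT_SEED_OFFSET = 1
SVM_SEED_OFFSET = 2


def specs_from_config(config: PipelineConfig) -> list[ClassSpecification]:
    return [
        ClassSpecification(label=label, **config.class_params[label].model_dump())
        for label in CLASS_ORDER
    ]


def simulate_stage(config: PipelineConfig) -> SyntheticDataset:
    return generate_dataset(
        specs=specs_from_config(config),
        n_per_class=config.n_per_class,
        seed=config.seed + SIM_SEED_OFFSET,
        grid=TimeGrid(**config.grid.model_dump()),
        thickness_mm=config.thickness_mm,
        n_scans=config.n_scans,
    )


def extract_stage(
    dataset: SyntheticDataset, config: PipelineConfig
) -> list[OpticalSpectrum]:
    """Average the replicate scans of each pellet, then extract (alpha, n)."""
    spectra = []
    for samp in dataset.samples:
        ref = average_scans([pair[0] for pair in samp.scans])
        sam = average_scans([pair[1] for pair in samp.scans])
        spectra.append(
            extract_optical(
                ref,
                sam,
                dataset.thickness_mm,
                band=(config.band_lo_thz, config.band_hi_thz),
                step=config.grid_step_thz,
                window=config.window,
                label=samp.label,
                sample_id=samp.sample_id,
            )
        )
    return spectra


def _svm_config(
    config: PipelineConfig, kernel: str, probability_scoring: bool = False
) -> classify.SvmConfig:
    # PCA score blocks are pre-normalized per modality (score_scale), so the
    # per-feature z-score is disabled: it would inflate the near-zero-variance
    # trailing components into full-variance noise dimensions
    grid = config.svm_search.grid()
    return classify.SvmConfig(
        kernel=kernel,
        degree=config.poly_degree,
        C_grid=grid,
        gamma_grid=grid,
        cv_folds=config.svm_search.cv_folds,
        seed=config.seed + SVM_SEED_OFFSET,
        scale="none",
        probability_scoring=probability_scoring,
    )


def _fit(
    X: np.ndarray, y: Sequence[str], cfg: classify.SvmConfig, do_search: bool
) -> classify.TrainedClassifier:
    if do_search:
        return classify.fit_with_search(X, y, cfg)
    best, score = cfg, float(
        classify.cross_val_score(
            classify._make_pipeline(cfg, cfg.gamma, cfg.C, probability=False),
            X,
            np.asarray(y),
            cv=classify.StratifiedKFold(
                n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed
            ),
        ).mean()
    )
    return classify.train(X, y, best, cv_accuracy=score)


def feature_fusion_models(
    train_spectra: Sequence[OpticalSpectrum],
    test_spectra: Sequence[OpticalSpectrum],
    config: PipelineConfig,
) -> dict[str, dict[str, RecognitionReport]]:
    """Feature-layer fusion: concatenated PCA scores into one SVM per kernel."""
    counts = config.pca_feature_fusion
    abs_model = features.fit_pca(train_spectra, "absorption", counts.absorption)
    ref_model = features.fit_pca(train_spectra, "refraction", counts.refraction)

    def fused(spectra: Sequence[OpticalSpectrum]) -> np.ndarray:
        return np.hstack(
            [
                features.transform_all(abs_model, spectra) / abs_model.score_scale,
                features.transform_all(ref_model, spectra) / ref_model.score_scale,
            ]
        )

    X_tr, X_te = fused(train_spectra), fused(test_spectra)
    y_tr = [s.label for s in train_spectra]
    y_te = [s.label for s in test_spectra]

    out: dict[str, dict[str, RecognitionReport]] = {}
    for kernel in config.kernels:
        clf = _fit(X_tr, y_tr, _svm_config(config, kernel), config.grid_search)
        logger.info(
            "feature fusion %s: gamma=%g C=%g cv=%.3f",
            kernel, clf.config.gamma, clf.config.C, clf.cv_accuracy or -1,
        )
        out[f"{kernel}_feature_fusion"] = {
            "train": rates(confusion(y_tr, clf.predict(X_tr), split="train")),
            "test": rates(confusion(y_te, clf.predict(X_te), split="test")),
        }
    return out


def decision_fusion_model(
    train_spectra: Sequence[OpticalSpectrum],
    test_spectra: Sequence[OpticalSpectrum],
    config: PipelineConfig,
) -> dict[str, RecognitionReport]:
    """Decision-layer fusion: one RBF sub-classifier per modality, combined
    per sample by Dempster's rule with the epsilon decision thresholds."""
    counts = config.pca_decision_fusion
    models = {
        "absorption": features.fit_pca(train_spectra, "absorption", counts.absorption),
        "refraction": features.fit_pca(train_spectra, "refraction", counts.refraction),
    }
    y_tr = [s.label for s in train_spectra]
    y_te = [s.label for s in test_spectra]

    clfs, X_tr, X_te = {}, {}, {}
    for modality, fmodel in models.items():
        s = fmodel.score_scale
        X_tr[modality] = features.transform_all(fmodel, train_spectra) / s
        X_te[modality] = features.transform_all(fmodel, test_spectra) / s
        cfg = _svm_config(config, "rbf", probability_scoring=True)
        if not config.grid_search:
            rep = REPORTED_SUBCLASSIFIER_PARAMS[modality]
            cfg.gamma, cfg.C = rep["gamma"], rep["C"]
        clfs[modality] = _fit(X_tr[modality], y_tr, cfg, config.grid_search)
        logger.info(
            "DS sub-classifier %s: gamma=%g C=%g cv=%.3f",
            modality, clfs[modality].config.gamma, clfs[modality].config.C,
            clfs[modality].cv_accuracy or -1,
        )

    reports = {}
    for split, Xa, Xr, y in (
        ("train", X_tr["absorption"], X_tr["refraction"], y_tr),
        ("test", X_te["absorption"], X_te["refraction"], y_te),
    ):
        decisions = fusion.ds_pipeline(
            clfs["absorption"],
            clfs["refraction"],
            Xa,
            Xr,
            epsilon1=config.epsilon1,
            epsilon2=config.epsilon2,
        )
        # fold deferred samples back via the argmax fallback so the table
        # stays 4-way; report the deferred count alongside
        pred = [d.fallback_label for d in decisions]
        n_uncertain = sum(1 for d in decisions if d.decision == fusion.UNCERTAIN)
        reports[split] = rates(
            confusion(y, pred, split=split), uncertain_count=n_uncertain
        )
    return reports


def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the whole pipeline and return (optionally persist) the report."""
    logger.info("simulating %d samples/class, seed %d", config.n_per_class, config.seed)
    dataset = simulate_stage(config)
    spectra = extract_stage(dataset, config)

    labels = [s.label for s in spectra]
    train_idx, test_idx = classify.split_dataset(
        labels,
        ratio=config.split_ratio,
        seed=config.seed + SPLIT_SEED_OFFSET,
        stratify=config.stratify,
    )
    train_spectra = [spectra[i] for i in train_idx]
    test_spectra = [spectra[i] for i in test_idx]
    logger.info("split: %d train / %d test", len(train_spectra), len(test_spectra))

    model_reports = feature_fusion_models(train_spectra, test_spectra, config)
    model_reports["ds_decision_fusion"] = decision_fusion_model(
        train_spectra, test_spectra, config
    )

    comparison = compare_models(
        {name: reps["test"] for name, reps in model_reports.items()}
    )
    report = {
        "seed": config.seed,
        "n_train": len(train_spectra),
        "n_test": len(test_spectra),
        "models": {
            name: {split: rep.to_dict() for split, rep in reps.items()}
            for name, reps in model_reports.items()
        },
        "comparison": comparison.to_dict(orient="records"),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        comparison.to_csv(outdir / "comparison.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# spectra on disk (used by the CLI stages)
# ---------------------------------------------------------------------------


def write_spectra(
    spectra: Sequence[OpticalSpectrum], outdir: str | Path
) -> Path:
    outdir = Path(outdir)
    sub = outdir / "spectra"
    sub.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in spectra:
        path = sub / f"{s.sample_id}.txt"
        np.savetxt(
            path,
            np.column_stack([s.freq, s.alpha, s.n]),
            fmt="%.8g",
            header="freq_THz alpha_cm1 n",
        )
        rows.append(
            {
                "sample_id": s.sample_id,
                "label": s.label,
                "path": str(path.relative_to(outdir)),
                "thickness_mm": s.thickness_mm,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    return outdir


def read_spectra(indir: str | Path) -> list[OpticalSpectrum]:
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    out = []
    for _, row in manifest.iterrows():
        data = np.loadtxt(indir / row["path"])
        out.append(
            OpticalSpectrum(
                freq=data[:, 0],
                alpha=data[:, 1],
                n=data[:, 2],
                thickness_mm=float(row["thickness_mm"]),
                label=str(row["label"]),
                sample_id=str(row["sample_id"]),
            )
        )
    return out
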