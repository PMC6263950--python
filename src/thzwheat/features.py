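"""PCA feature extraction per optical modality and feature-layer fusion.

Each modality (absorption spectrum, refractive-index spectrum) gets its own
centered PCA fitted on training spectra only; a spectrum is then represented
by its leading component scores.  Feature-layer fusion concatenates the
absorption scores followed by the refraction scores into one vector that a
single SVM classifies.  Default component counts are 8 for absorption and 10
for refraction (18 fused); the decision-layer route uses 10/8 instead — both
are plain arguments here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .errors import GridMismatchError, InvalidFusionError, RankDeficiencyError
from .optics import OpticalSpectrum

MODALITIES = ("absorption", "refraction")


def spectra_to_matrix(
    spectra: Sequence[OpticalSpectrum], modality: str
) -> np.ndarray:
    """Stack one modality of a spectrum collection into an (n, p) matrix."""
    if modality == "absorption":
        rows = [s.alpha for s in spectra]
    elif modality == "refraction":
        rows = [s.n for s in spectra]
    else:
        raise ValueError(f"unknown modality {modality!r}")
    grid = spectra[0].freq
    for s in spectra[1:]:
        if s.freq.shape != grid.shape or not np.allclose(s.freq, grid):
            raise GridMismatchError("spectra not on a common frequency grid")
    return np.asarray(rows, dtype=float)


@dataclass(frozen=True)
class FeatureModel:
    """Fitted PCA for one modality.

    ``loadings`` has shape (n_components, n_bins), rows orthonormal, each
    row's sign fixed so its largest-magnitude element is positive (PCA is
    otherwise determined only up to sign).
    """

    modality: str
    freq: np.ndarray
    mean_spectrum: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray  # fraction per component, non-increasing
    component_sd: np.ndarray        # absolute per-component score sd (train)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    @property
    def score_scale(self) -> float:
        """Overall score magnitude: root total variance of the training
        scores.  Dividing a modality's score block by this puts the two
        modalities on a common scale while preserving the natural variance
        decay across components."""
        return float(np.sqrt(np.sum(self.component_sd**2)))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "modality": self.modality,
                    "freq": self.freq.tolist(),
                    "mean_spectrum": self.mean_spectrum.tolist(),
                    "loadings": self.loadings.tolist(),
                    "explained_variance": self.explained_variance.tolist(),
                    "component_sd": self.component_sd.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureModel":
        d = json.loads(Path(path).read_text())
        return cls(
            modality=d["modality"],
            freq=np.asarray(d["freq"]),
            mean_spectrum=np.asarray(d["mean_spectrum"]),
            loadings=np.asarray(d["loadings"]),
            explained_variance=np.asarray(d["explained_variance"]),
            component_sd=np.asarray(d["component_sd"]),
        )


@dataclass(frozen=True)
class FeatureVector:
    sample_id: str
    scores: np.ndarray
    modality: str  # absorption | refraction | fused


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-magnitude element is positive."""
    idx = np.argmax(np.abs(loadings), axis=1)
    signs = np.sign(loadings[np.arange(loadings.shape[0]), idx])
    signs[signs == 0] = 1.0
    return loadings * signs[:, None]


def fit_pca(
    spectra: Sequence[OpticalSpectrum], modality: str, n_components: int
) -> FeatureModel:
    """Centered PCA on the training spectra of one modality.

    No variance scaling is applied: the bins of one modality share units, and
    standardization for the classifier happens downstream on the scores.
    """
    X = spectra_to_matrix(spectra, modality)
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_rank:
        raise RankDeficiencyError(
            f"{n_components} components requested but data rank is at most {max_rank}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    return FeatureModel(
        modality=modality,
        freq=spectra[0].freq.copy(),
        mean_spectrum=pca.mean_,
        loadings=_fix_signs(pca.components_),
        explained_variance=pca.explained_variance_ratio_,
        component_sd=np.sqrt(pca.explained_variance_),
    )


def transform(model: FeatureModel, spectrum: OpticalSpectrum) -> FeatureVector:
    """Project one spectrum onto the fitted components."""
    if spectrum.freq.shape != model.freq.shape or not np.allclose(
        spectrum.freq, model.freq
    ):
        raise GridMismatchError("spectrum grid does not match the fitted model")
    x = spectrum.alpha if model.modality == "absorption" else spectrum.n
    scores = model.loadings @ (x - model.mean_spectrum)
    return FeatureVector(
        sample_id=spectrum.sample_id or "", scores=scores, modality=model.modality
    )


def transform_all(
    model: FeatureModel, spectra: Sequence[OpticalSpectrum]
) -> np.ndarray:
    """Score matrix (n_samples, n_components) for a spectrum collection."""
    return np.asarray([transform(model, s).scores for s in spectra])


def reconstruct(model: FeatureModel, fv: FeatureVector) -> np.ndarray:
    """Inverse transform: mean + loadings^T @ scores."""
    return model.mean_spectrum + model.loadings.T @ fv.scores


def concat_features(a: FeatureVector, b: FeatureVector) -> FeatureVector:
    """Feature-layer fusion: absorption scores then refraction scores."""
    if a.sample_id != b.sample_id:
        raise InvalidFusionError("cannot fuse vectors from different samples")
    if a.modality == b.modality:
        raise InvalidFusionError("cannot fuse two vectors of the same modality")
    ordered = sorted([a, b], key=lambda v: MODALITIES.index(v.modality))
    return FeatureVector(
        sample_id=a.sample_id,
        scores=np.concatenate([v.scores for v in ordered]),
        modality="fused",
    )
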