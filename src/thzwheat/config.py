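"""Pipeline configuration: a validated schema with documented defaults.

Every default mirrors the measurement campaign and modelling choices the
pipeline emulates: 60 pellets per class scanned 5 times, 1 mm pellets,
analysis band 0.2–1.6 THz, a 2:1 train/test split, PCA component counts of
8 (absorption) / 10 (refraction) for feature-layer fusion and 10 / 8 for the
decision-layer sub-classifiers, RBF/linear/poly kernels with grid-searched
hyper-parameters, and Dempster-Shafer decision thresholds epsilon_1 = 0.1,
epsilon_2 = 0.3.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .errors import ConfigError
from .synthetic import CLASS_ORDER, DEFAULT_CLASS_PARAMS

#: grid-search optima reported for the two RBF sub-classifiers on the
#: original wheat data; used verbatim when grid search is disabled.
REPORTED_SUBCLASSIFIER_PARAMS = {
    "absorption": {"gamma": 3.5, "C": 1.6},
    "refraction": {"gamma": 3.0, "C": 0.92},
}


class GridConfig(BaseModel):
    span_ps: float = 40.0
    dt_ps: float = 0.02
    t0_ps: float = 8.0


class ClassParams(BaseModel):
    n_mean: float
    alpha_base: float
    alpha_slope: float
    n_slope: float = 0.002
    noise_sd_n: float = 0.004
    noise_sd_alpha: float = 0.3
    noise_sd_alpha_slope: float = 0.2
    noise_sd_curv: float = 0.3
    noise_sd_n_slope: float = 0.002
    rho_n_alpha: float = 0.0
    rho_n_nslope: float = 0.0
    scan_noise_sd: float = 0.002


class PcaCounts(BaseModel):
    absorption: int
    refraction: int


class SvmSearch(BaseModel):
    """Hyper-parameter search space: log2 exponent range for gamma and C."""

    log2_min: int = -6
    log2_max: int = 6
    cv_folds: int = 5

    def grid(self) -> list[float]:
        return [float(2.0**k) for k in range(self.log2_min, self.log2_max + 1)]


class PipelineConfig(BaseModel):
    """Top-level configuration for an end-to-end run."""

    seed: int = 0
    n_per_class: int = 60
    n_scans: int = 5
    thickness_mm: float = 1.0
    band_lo_thz: float = 0.2
    band_hi_thz: float = 1.6
    grid_step_thz: float = 0.01
    window: str = "rect"
    grid: GridConfig = Field(default_factory=GridConfig)
    class_params: dict[str, ClassParams] = Field(
        default_factory=lambda: {
            k: ClassParams(**v) for k, v in DEFAULT_CLASS_PARAMS.items()
        }
    )
    pca_feature_fusion: PcaCounts = Field(
        default_factory=lambda: PcaCounts(absorption=8, refraction=10)
    )
    pca_decision_fusion: PcaCounts = Field(
        default_factory=lambda: PcaCounts(absorption=10, refraction=8)
    )
    kernels: list[str] = Field(default_factory=lambda: ["rbf", "linear", "poly"])
    poly_degree: int = 3
    svm_search: SvmSearch = Field(default_factory=SvmSearch)
    grid_search: bool = True
    split_ratio: tuple[int, int] = (2, 1)
    stratify: bool = True
    epsilon1: float = 0.1
    epsilon2: float = 0.3

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.band_lo_thz >= self.band_hi_thz:
            raise ValueError("band_lo_thz must be below band_hi_thz")
        if self.grid_step_thz <= 0:
            raise ValueError("grid_step_thz must be positive")
        if set(self.class_params) != set(CLASS_ORDER):
            raise ValueError(f"class_params must cover exactly {CLASS_ORDER}")
        if self.window not in ("rect", "hann"):
            raise ValueError("window must be 'rect' or 'hann'")
        for k in self.kernels:
            if k not in ("rbf", "linear", "poly"):
                raise ValueError(f"unknown kernel {k!r}")
        if not (0 <= self.epsilon1 <= 1 and 0 <= self.epsilon2 <= 1):
            raise ValueError("epsilon thresholds must lie in [0, 1]")
        return self


def load_config(path: str | Path | None = None, **overrides: Any) -> PipelineConfig:
    """Load a YAML config (or the defaults) with keyword overrides.

    Raises :class:`ConfigError` with the offending field path on schema
    violations.
    """
    data: dict[str, Any] = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    try:
        return PipelineConfig(**data)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(locs) from exc


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json")))
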