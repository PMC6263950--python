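"""Exception hierarchy for the thzwheat pipeline."""


class ThzWheatError(Exception):
    """Base class for all pipeline errors."""


class InvalidGridError(ThzWheatError):
    """Time or parameter grid violates a precondition (non-uniform, too short, empty)."""


class WindowOverflowError(ThzWheatError):
    """Propagation delay would push the pulse outside the sampled time window."""


class InvalidSpecError(ThzWheatError):
    """Class specification set violates an invariant (ordering, negative sd)."""


class AxisMismatchError(ThzWheatError):
    """Traces or spectra do not share a common axis."""


class DegenerateAmplitudeError(ThzWheatError):
    """Zero or negative amplitude where a log-ratio must be evaluated."""


class EmptyBandError(ThzWheatError):
    """Band restriction selected no frequency bins."""


class GridMismatchError(ThzWheatError):
    """Feature-model grid does not match the spectrum grid."""


class RankDeficiencyError(ThzWheatError):
    """Requested more principal components than the data rank supports."""


class InvalidFusionError(ThzWheatError):
    """Feature vectors cannot be fused (same modality, mismatched sample)."""


class DegenerateSplitError(ThzWheatError):
    """Train/test split left a class empty."""


class DegenerateLabelsError(ThzWheatError):
    """Training data contains fewer than two classes."""


class InvalidProbabilityError(ThzWheatError):
    """Probability vector is not a distribution."""


class TotalConflictError(ThzWheatError):
    """Dempster combination undefined: conflict coefficient K = 1."""


class LabelError(ThzWheatError):
    """Unknown class label."""


class UndefinedRateError(ThzWheatError):
    """Recognition rate undefined for an empty class row."""


class ConfigError(ThzWheatError):
    """Pipeline configuration failed schema validation."""
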