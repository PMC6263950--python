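"""Decision-layer fusion by Dempster-Shafer evidence combination.

The frame of discernment is Theta = {normal, germinated, moldy, worm-eaten, U}
where U is the whole frame — "wheat of uncertain quality".  Each SVM
sub-classifier (absorption, refraction) contributes one mass function per
sample, built from its calibrated class probabilities discounted by a
per-source reliability weight: singleton masses are reliability * p(class),
and the residual 1 - reliability goes to U.  The reliability is taken to be
the sub-classifier's cross-validated training accuracy, so the weaker
modality carries less weight — the classical Shafer discounting construction.

Dempster's rule combines the two sources: mass products on agreeing
singletons (or on U, which intersects everything) reinforce each other, mass
products on distinct singletons are conflict K, and the surviving mass is
renormalized by 1 - K.  A thresholded decision rule then accepts the leading
class only when it beats the runner-up by epsilon_1, the residual uncertainty
mass is below epsilon_2, and the leading class outweighs U; otherwise the
sample is flagged uncertain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import TrainedClassifier
from .errors import InvalidProbabilityError, TotalConflictError
from .synthetic import CLASS_ORDER

#: label used for deferred decisions
UNCERTAIN = "uncertain"

#: default decision thresholds
EPSILON_1 = 0.1
EPSILON_2 = 0.3

_TOL = 1e-9


@dataclass(frozen=True)
class MassFunction:
    """Basic probability assignment over the 4 singletons plus U (= Theta).

    ``singletons`` follows :data:`thzwheat.synthetic.CLASS_ORDER`.
    """

    singletons: np.ndarray
    u: float
    source: str = "combined"  # absorption | refraction | combined

    def __post_init__(self) -> None:
        s = np.asarray(self.singletons, dtype=float)
        object.__setattr__(self, "singletons", s)
        if s.shape != (len(CLASS_ORDER),):
            raise InvalidProbabilityError("need one mass per class")
        if np.any(s < -_TOL) or self.u < -_TOL:
            raise InvalidProbabilityError("masses must be non-negative")
        if abs(s.sum() + self.u - 1.0) > 1e-6:
            raise InvalidProbabilityError("masses must sum to 1")

    def mass(self, label: str) -> float:
        if label == "U":
            return float(self.u)
        return float(self.singletons[CLASS_ORDER.index(label)])


def vacuous() -> MassFunction:
    """The neutral element: all mass on U."""
    return MassFunction(singletons=np.zeros(len(CLASS_ORDER)), u=1.0)


def proba_to_bpa(
    probs: np.ndarray, reliability: float, source: str = "combined"
) -> MassFunction:
    """Discounted BPA: singleton masses reliability*p, remainder on U."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (len(CLASS_ORDER),) or np.any(probs < -_TOL):
        raise InvalidProbabilityError("probabilities must be 4 non-negative values")
    if abs(probs.sum() - 1.0) > 1e-6:
        raise InvalidProbabilityError("probabilities must sum to 1")
    if not 0.0 <= reliability <= 1.0:
        raise ValueError("reliability must be in [0, 1]")
    return MassFunction(
        singletons=reliability * probs, u=1.0 - reliability, source=source
    )


def dempster_combine(
    m1: MassFunction, m2: MassFunction
) -> tuple[MassFunction, float]:
    """Dempster's orthogonal sum of two mass functions on the shared frame.

    Conflict K sums the mass products landing on disjoint singleton pairs;
    U behaves as the identity under intersection.  Raises
    :class:`TotalConflictError` at K = 1, where the rule is undefined.
    """
    s1, s2 = m1.singletons, m2.singletons
    K = float(s1.sum() * s2.sum() - s1 @ s2)
    if K >= 1.0 - _TOL:
        raise TotalConflictError("total conflict between sources (K = 1)")
    numer = s1 * s2 + s1 * m2.u + m1.u * s2
    u = m1.u * m2.u
    norm = 1.0 - K
    return (
        MassFunction(singletons=numer / norm, u=u / norm, source="combined"),
        K,
    )


def decide(
    mc: MassFunction,
    epsilon1: float = EPSILON_1,
    epsilon2: float = EPSILON_2,
) -> str:
    """Thresholded decision on a combined mass function.

    Accept the leading singleton A1 iff
    m(A1) - m(A2) > epsilon1  and  m(U) < epsilon2  and  m(A1) > m(U);
    otherwise return ``"uncertain"``.  Argmax ties go to the first class in
    the fixed order.
    """
    order = np.argsort(-mc.singletons, kind="stable")
    a1, a2 = order[0], order[1]
    if (
        mc.singletons[a1] - mc.singletons[a2] > epsilon1
        and mc.u < epsilon2
        and mc.singletons[a1] > mc.u
    ):
        return CLASS_ORDER[a1]
    return UNCERTAIN


@dataclass(frozen=True)
class FusionDecision:
    """Combined evidence and decision for one sample."""

    sample_id: str
    combined: MassFunction
    conflict_K: float
    decision: str              # class label or "uncertain"
    fallback_label: str        # argmax of combined singleton mass
    epsilon1: float
    epsilon2: float


def ds_pipeline(
    abs_clf: TrainedClassifier,
    ref_clf: TrainedClassifier,
    abs_features: np.ndarray,
    ref_features: np.ndarray,
    sample_ids: list[str] | None = None,
    reliabilities: tuple[float, float] | None = None,
    epsilon1: float = EPSILON_1,
    epsilon2: float = EPSILON_2,
) -> list[FusionDecision]:
    """Per-sample fusion of the two sub-classifiers' probability outputs.

    ``reliabilities`` defaults to each classifier's stored cross-validated
    training accuracy (1.0 when absent).  The ``fallback_label`` lets
    recognition-rate tables stay 4-way even for deferred samples, with the
    uncertain count reported separately.
    """
    if abs_clf.classes != ref_clf.classes:
        raise ValueError("sub-classifiers disagree on class order")
    if reliabilities is None:
        reliabilities = (
            abs_clf.cv_accuracy if abs_clf.cv_accuracy is not None else 1.0,
            ref_clf.cv_accuracy if ref_clf.cv_accuracy is not None else 1.0,
        )
    pa = abs_clf.predict_proba(abs_features)
    pr = ref_clf.predict_proba(ref_features)
    if pa.shape[0] != pr.shape[0]:
        raise ValueError("feature sets have different sample counts")
    n = pa.shape[0]
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(n)]
    decisions = []
    for i in range(n):
        ma = proba_to_bpa(pa[i], reliabilities[0], source="absorption")
        mr = proba_to_bpa(pr[i], reliabilities[1], source="refraction")
        try:
            mc, K = dempster_combine(ma, mr)
            label = decide(mc, epsilon1, epsilon2)
        except TotalConflictError:
            mc, K, label = vacuous(), 1.0, UNCERTAIN
        fallback = CLASS_ORDER[int(np.argmax(mc.singletons))]
        decisions.append(
            FusionDecision(
                sample_id=ids[i],
                combined=mc,
                conflict_K=K,
                decision=label,
                fallback_label=fallback,
                epsilon1=epsilon1,
                epsilon2=epsilon2,
            )
        )
    return decisions
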