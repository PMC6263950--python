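"""Tests of Dempster-Shafer evidence combination and the decision rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thzwheat import fusion
from thzwheat.errors import InvalidProbabilityError, TotalConflictError
from thzwheat.fusion import (
    MassFunction,
    UNCERTAIN,
    decide,
    dempster_combine,
    ds_pipeline,
    proba_to_bpa,
    vacuous,
)
from thzwheat.synthetic import CLASS_ORDER

THETA = frozenset(range(4))


def enumerate_combine(m1: MassFunction, m2: MassFunction):
    """Independent oracle: exhaustive enumeration over focal-element pairs
    (the 4 singletons plus the whole frame), using set intersection."""
    focals1 = [(frozenset([i]), m1.singletons[i]) for i in range(4)]
    focals1.append((THETA, m1.u))
    focals2 = [(frozenset([i]), m2.singletons[i]) for i in range(4)]
    focals2.append((THETA, m2.u))
    K = 0.0
    masses: dict[frozenset, float] = {}
    for A, ma in focals1:
        for B, mb in focals2:
            inter = A & B
            if not inter:
                K += ma * mb
            else:
                masses[inter] = masses.get(inter, 0.0) + ma * mb
    out_s = np.array([masses.get(frozenset([i]), 0.0) for i in range(4)])
    out_u = masses.get(THETA, 0.0)
    return out_s / (1 - K), out_u / (1 - K), K


def mass(*singletons, u=0.0, source="combined"):
    return MassFunction(singletons=np.array(singletons, dtype=float),
                        u=u, source=source)


mass_strategy = (
    st.lists(st.floats(0.001, 1.0), min_size=5, max_size=5)
    .map(lambda w: np.array(w) / np.sum(w))
    .map(lambda w: MassFunction(singletons=w[:4], u=w[4]))
)


class TestProbaToBpa:
    def test_hand_arithmetic(self):
        m = proba_to_bpa(np.array([0.7, 0.1, 0.1, 0.1]), 0.9)
        assert np.allclose(m.singletons, [0.63, 0.09, 0.09, 0.09])
        assert m.u == pytest.approx(0.10)

    def test_full_reliability_keeps_probabilities(self):
        m = proba_to_bpa(np.array([1.0, 0.0, 0.0, 0.0]), 1.0)
        assert m.mass("normal") == pytest.approx(1.0)
        assert m.u == pytest.approx(0.0)

    def test_zero_reliability_is_vacuous(self):
        m = proba_to_bpa(np.array([0.4, 0.3, 0.2, 0.1]), 0.0)
        assert np.allclose(m.singletons, 0.0)
        assert m.u == pytest.approx(1.0)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(InvalidProbabilityError):
            proba_to_bpa(np.array([0.5, 0.2, 0.2, 0.2]), 0.9)
        with pytest.raises(ValueError):
            proba_to_bpa(np.array([0.25, 0.25, 0.25, 0.25]), 1.5)


class TestDempsterCombine:
    def test_two_singleton_hand_example(self):
        # on an effective two-element frame:
        # K = 0.6*0.4 + 0.3*0.5 = 0.39; combined(A) = 0.41/0.61
        m1 = mass(0.6, 0.3, 0, 0, u=0.1)
        m2 = mass(0.5, 0.4, 0, 0, u=0.1)
        mc, K = dempster_combine(m1, m2)
        assert K == pytest.approx(0.39)
        assert mc.singletons[0] == pytest.approx(0.41 / 0.61, abs=1e-9)

    def test_vacuous_is_neutral_element(self):
        m1 = mass(0.5, 0.2, 0.2, 0.05, u=0.05)
        mc, K = dempster_combine(m1, vacuous())
        assert K == 0.0
        assert np.allclose(mc.singletons, m1.singletons)
        assert mc.u == pytest.approx(m1.u)

    def test_total_conflict_rejected(self):
        with pytest.raises(TotalConflictError):
            dempster_combine(mass(1, 0, 0, 0), mass(0, 1, 0, 0))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(m1=mass_strategy, m2=mass_strategy)
    def test_matches_enumeration_oracle(self, m1, m2):
        mc, K = dempster_combine(m1, m2)
        s_ref, u_ref, K_ref = enumerate_combine(m1, m2)
        assert K == pytest.approx(K_ref, abs=1e-12)
        assert np.allclose(mc.singletons, s_ref, atol=1e-12)
        assert mc.u == pytest.approx(u_ref, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(m1=mass_strategy, m2=mass_strategy)
    def test_commutative_normalized_bounded_conflict(self, m1, m2):
        mc12, K12 = dempster_combine(m1, m2)
        mc21, K21 = dempster_combine(m2, m1)
        assert K12 == pytest.approx(K21)
        assert np.allclose(mc12.singletons, mc21.singletons)
        assert 0.0 <= K12 < 1.0
        assert mc12.singletons.sum() + mc12.u == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(m1=mass_strategy, m2=mass_strategy, m3=mass_strategy)
    def test_associative_across_three_sources(self, m1, m2, m3):
        left, _ = dempster_combine(dempster_combine(m1, m2)[0], m3)
        right, _ = dempster_combine(m1, dempster_combine(m2, m3)[0])
        assert np.allclose(left.singletons, right.singletons, atol=1e-9)
        assert left.u == pytest.approx(right.u, abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(m=mass_strategy)
    def test_repeated_evidence_reinforces_leader(self, m):
        # combining a mass function with itself strictly increases the
        # strictly-leading singleton's mass (when some mass sits on U)
        leader = int(np.argmax(m.singletons))
        others = np.delete(m.singletons, leader)
        if m.singletons[leader] <= others.max() + 1e-6:
            return  # no strict leader
        mc, _ = dempster_combine(m, m)
        assert mc.singletons[leader] > m.singletons[leader]


class TestDecide:
    def test_dominant_mass_accepted(self):
        mc = mass(0.9, 0.02, 0.02, 0.02, u=0.04)
        assert decide(mc, 0.1, 0.3) == "normal"

    def test_close_top_two_deferred(self):
        mc = mass(0.40, 0.35, 0.1, 0.05, u=0.10)
        assert decide(mc, 0.1, 0.3) == UNCERTAIN

    def test_large_uncertainty_mass_deferred(self):
        mc = mass(0.4, 0.05, 0.03, 0.02, u=0.5)
        assert decide(mc, 0.1, 0.3) == UNCERTAIN

    def test_leader_must_beat_uncertainty_mass(self):
        mc = mass(0.25, 0.10, 0.05, 0.05, u=0.55)
        assert decide(mc, 0.1, 0.99) == UNCERTAIN


class _StubClassifier:
    """Minimal probability source for pipeline-level fusion tests."""

    classes = CLASS_ORDER

    def __init__(self, probs, n_features=3):
        self._probs = np.asarray(probs, dtype=float)
        self.cv_accuracy = 1.0

    def predict_proba(self, X):
        return np.tile(self._probs, (len(X), 1))


class TestDsPipeline:
    def test_agreeing_confident_sources(self):
        clf = _StubClassifier([0.97, 0.01, 0.01, 0.01])
        decisions = ds_pipeline(clf, clf, np.zeros((3, 2)), np.zeros((3, 2)))
        assert all(d.decision == "normal" for d in decisions)
        assert all(d.conflict_K < 0.1 for d in decisions)

    def test_disagreeing_confident_sources_deferred(self):
        a = _StubClassifier([0.97, 0.01, 0.01, 0.01])
        b = _StubClassifier([0.01, 0.97, 0.01, 0.01])
        decisions = ds_pipeline(a, b, np.zeros((2, 2)), np.zeros((2, 2)))
        assert all(d.decision == UNCERTAIN for d in decisions)
        assert all(d.conflict_K > 0.5 for d in decisions)

    def test_fallback_label_is_argmax_of_combined_mass(self):
        a = _StubClassifier([0.05, 0.55, 0.35, 0.05])
        b = _StubClassifier([0.05, 0.45, 0.45, 0.05])
        decisions = ds_pipeline(a, b, np.zeros((1, 2)), np.zeros((1, 2)))
        assert decisions[0].fallback_label == "germinated"

    def test_reliability_discount_applied(self):
        clf = _StubClassifier([1.0, 0.0, 0.0, 0.0])
        d = ds_pipeline(
            clf, clf, np.zeros((1, 2)), np.zeros((1, 2)),
            reliabilities=(0.0, 0.0),
        )[0]
        assert d.combined.u == pytest.approx(1.0)
        assert d.decision == UNCERTAIN
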