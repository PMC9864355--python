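"""Closed-form disagreement probabilities against frozen oracle values.

Expected values were computed with a 50-digit error-function evaluation of
the truncated-normal intervals, independent of the implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr

from dgdis import (
    DgDisResult,
    InvalidInputError,
    ModelConfig,
    ModelDomainError,
    PatientHaemodynamics,
    Tier,
    WrongDirectionError,
    assign_tier,
    conditional_disagreement,
    dgdis,
    joint_probabilities,
    prob_b,
    prob_dgdis_minus,
    prob_dgdis_plus,
)

# (tpg, co_td) -> conditional probability, defaults; frozen 50-digit values
MINUS_EXPECTED = {
    (6, 3.5): 0.3012064165,
    (7, 4): 0.3092538924,
    (7, 5): 0.07064713429,
    (8, 5): 0.1634226852,
    (8, 6): 0.02499637582,
    (9, 5): 0.3119679801,
    (9, 6): 0.07078033413,
    (10, 6): 0.1635444949,
    (10, 7): 0.02501930901,
    (11, 6): 0.3120715527,
    (11, 7): 0.07084153106,
}
PLUS_EXPECTED = {
    (6, 2.5): 0.354539924,
    (7, 2.5): 0.185801617,
    (7, 3): 0.327752085,
    (8, 3): 0.1717630745,
    (8, 3.5): 0.316993611,
    (9, 3): 0.07433847145,
    (9, 4): 0.3133430356,
    (10, 3): 0.02625434148,
    (10, 4): 0.1642118099,
    (11, 4): 0.0710703096,
    (11, 5): 0.3121117501,
}


class TestProbB:
    @pytest.mark.parametrize(
        "co_td, expected",
        [(6.0, 0.999978672342886), (2.5, 0.880202561971049)],
    )
    def test_frozen_values(self, co_td, expected):
        assert prob_b(co_td) == pytest.approx(expected, abs=1e-12)

    def test_no_truncation_gives_one(self, untruncated_config):
        # co at least 7 sigma from both limits: the condition is vacuous
        assert prob_b(8.0, untruncated_config) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("co_td", [1.0, 11.0])
    def test_unphysiological_co_rejected(self, co_td):
        with pytest.raises(ModelDomainError):
            prob_b(co_td)


class TestDirectionalProbabilities:
    @pytest.mark.parametrize("key, expected", sorted(MINUS_EXPECTED.items()))
    def test_minus_frozen(self, key, expected):
        tpg, co = key
        result = prob_dgdis_minus(PatientHaemodynamics.from_tpg(tpg, co))
        assert result.direction == "minus"
        assert result.p_conditional == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("key, expected", sorted(PLUS_EXPECTED.items()))
    def test_plus_frozen(self, key, expected):
        tpg, co = key
        result = prob_dgdis_plus(PatientHaemodynamics.from_tpg(tpg, co))
        assert result.direction == "plus"
        assert result.p_conditional == pytest.approx(expected, abs=1e-10)

    def test_empty_interval_gives_zero(self):
        # TPG so large that the flip threshold lies below CO_TD - b
        cfg = ModelConfig(mpap_threshold=20, pawp_threshold=15)
        patient = PatientHaemodynamics(mpap=60, pawp=10, co_td=5)  # TPG 50
        result = prob_dgdis_plus(patient, cfg)
        assert result.p_joint == 0.0
        assert result.p_conditional == 0.0

    def test_wrong_direction_raises(self):
        unclassified = PatientHaemodynamics(21, 14, 4)
        precapillary = PatientHaemodynamics(21, 11, 3)
        with pytest.raises(WrongDirectionError):
            prob_dgdis_plus(unclassified)
        with pytest.raises(WrongDirectionError):
            prob_dgdis_minus(precapillary)

    def test_result_components_consistent(self):
        result = prob_dgdis_minus(PatientHaemodynamics(21, 14, 4))
        assert result.p_conditional == pytest.approx(
            result.p_joint / result.p_b, rel=1e-14)
        assert 0.0 <= result.p_joint <= result.p_b <= 1.0


class TestDispatch:
    def test_dispatches_by_td_diagnosis(self):
        minus = dgdis(PatientHaemodynamics(21, 14, 4))
        plus = dgdis(PatientHaemodynamics(21, 11, 3))
        assert minus.direction == "minus"
        assert plus.direction == "plus"
        assert isinstance(minus, DgDisResult)

    def test_refuses_out_of_domain(self):
        with pytest.raises(ModelDomainError, match="entry criteria"):
            dgdis(PatientHaemodynamics(25, 16, 4))


class TestTier:
    @pytest.mark.parametrize(
        "p, tier",
        [
            (0.025, Tier.CONFIDENT),
            (0.0999, Tier.CONFIDENT),
            (0.10, Tier.CONSIDER_DF),
            (0.15, Tier.CONSIDER_DF),
            (0.20, Tier.CONSIDER_DF),
            (0.2001, Tier.USE_DF),
            (0.294, Tier.USE_DF),
            (1.0, Tier.USE_DF),
        ],
    )
    def test_tiers(self, p, tier):
        assert assign_tier(p) is tier

    @pytest.mark.parametrize("p", [-0.1, 1.1])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(InvalidInputError):
            assign_tier(p)


tpg_strategy = st.floats(min_value=5.5, max_value=20.0)
co_strategy = st.floats(min_value=1.3, max_value=10.2)


class TestInvariants:
    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(tpg=tpg_strategy, co=co_strategy)
    def test_partition_identity(self, tpg, co):
        """The two flip events partition B exactly."""
        p_plus, p_minus, p_b = joint_probabilities(tpg, co)
        assert abs(float(p_plus + p_minus - p_b)) <= 1e-12

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(tpg=tpg_strategy, co=co_strategy)
    def test_probability_bounds(self, tpg, co):
        p_plus, p_minus, p_b = joint_probabilities(tpg, co)
        assert 0.0 <= p_plus <= p_b <= 1.0
        assert 0.0 <= p_minus <= p_b
        p, _ = conditional_disagreement(tpg, co)
        assert 0.0 <= float(p) <= 1.0

    def test_closed_form_limit_minus(self, untruncated_config):
        """Without truncation DgDis− reduces to 1 − Φ((c − TPG/2)/σ)."""
        # points >= 7 sigma from both CO limits so truncation is vacuous
        sigma = untruncated_config.sigma
        for tpg, co in [(14, 7.5), (15, 8), (16, 9), (13, 8.5)]:
            patient = PatientHaemodynamics.from_tpg(tpg, co)
            got = prob_dgdis_minus(patient, untruncated_config).p_conditional
            expected = 1.0 - ndtr((co - tpg / 2) / sigma)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_closed_form_limit_plus(self, untruncated_config):
        """Without truncation DgDis+ reduces to Φ((c − TPG/2)/σ)."""
        sigma = untruncated_config.sigma
        for tpg, co in [(16, 7.5), (18, 8), (20, 9)]:
            patient = PatientHaemodynamics.from_tpg(tpg, co)
            got = prob_dgdis_plus(patient, untruncated_config).p_conditional
            expected = ndtr((co - tpg / 2) / sigma)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_boundary_value_half(self, untruncated_config):
        """A patient exactly on the PVR threshold flips with p = 1/2."""
        patient = PatientHaemodynamics.from_tpg(16.0, 8.0)  # PVR exactly 2
        result = dgdis(patient, untruncated_config)
        assert result.p_conditional == pytest.approx(0.5, abs=1e-12)
        # in the central region of the default window the residual
        # truncation shifts the boundary value by < 1e-4
        result_default = dgdis(PatientHaemodynamics.from_tpg(11.0, 5.5))
        assert result_default.p_conditional == pytest.approx(0.5, abs=1e-4)

    def test_monotonic_in_co_central_region(self):
        """At fixed TPG: DgDis− falls and DgDis+ rises with CO_TD."""
        cos = np.linspace(5.4, 6.1, 15)  # min(co-a, b-co) >= 4*sigma
        minus = [prob_dgdis_minus(
            PatientHaemodynamics.from_tpg(8.0, c)).p_conditional for c in cos]
        plus = [prob_dgdis_plus(
            PatientHaemodynamics.from_tpg(13.0, c)).p_conditional for c in cos]
        assert np.all(np.diff(minus) < 0)
        assert np.all(np.diff(plus) > 0)
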