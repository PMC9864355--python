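"""Analytic diagnostic-disagreement probabilities.

The probability that a patient classified from thermodilution CO would be
classified differently from direct-Fick CO is a conditional probability of
the normally distributed CO difference X = CO_TD − CO_DF ~ N(mu, sigma),
conditioned on the direct-Fick value being physiological (event B:
a ≤ CO_DF = CO_TD − X ≤ b):

    P(B)            = P(CO_TD − b ≤ X ≤ CO_TD − a)
    P(DgDis+ ∩ B)   = P(CO_TD − b ≤ X ≤ min(CO_TD − TPG/r, CO_TD − a))
    P(DgDis− ∩ B)   = P(max(CO_TD − TPG/r, CO_TD − b) ≤ X ≤ CO_TD − a)
    P(DgDis± | B)   = P(DgDis± ∩ B) / P(B)

with r the PVR threshold (2 WU by default): the diagnosis flips exactly
when the direct-Fick PVR, TPG / (CO_TD − X), crosses r.  DgDis+ is a
false-positive precapillary diagnosis by TD (flip to unclassified PH under
direct Fick); DgDis− is a false negative (flip to precapillary PH).

The normal CDF is evaluated through :func:`scipy.special.ndtr`, an
error-function-based implementation accurate to double precision.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .config import DEFAULT_CONFIG, ModelConfig
from .exceptions import (
    DegenerateConditionError,
    InvalidInputError,
    ModelDomainError,
    WrongDirectionError,
)
from .haemodynamics import Diagnosis, PatientHaemodynamics, classify


class Tier(str, enum.Enum):
    """Clinical-action tier for a disagreement probability.

    Below 10% the TD-based diagnosis can be trusted; between 10 and 20%
    direct Fick should be considered; above 20% direct Fick should be used.
    """

    CONFIDENT = "confident"
    CONSIDER_DF = "consider_df"
    USE_DF = "use_df"

    def __str__(self) -> str:
        return self.value


def assign_tier(p: float) -> Tier:
    """Map a disagreement probability to its clinical-action tier."""
    if not 0.0 <= p <= 1.0:
        raise InvalidInputError(f"probability must be in [0, 1], got {p!r}")
    if p < 0.10:
        return Tier.CONFIDENT
    if p <= 0.20:
        return Tier.CONSIDER_DF
    return Tier.USE_DF


@dataclass(frozen=True)
class DgDisResult:
    """Diagnostic-disagreement probability for one patient.

    Attributes
    ----------
    direction : str
        ``"plus"`` (false-positive precapillary PH by TD) or ``"minus"``
        (false-negative).
    p_joint : float
        P(flip ∩ B), the unconditional probability of the flip with a
        physiological direct-Fick CO.
    p_b : float
        P(B), the probability that the direct-Fick CO is physiological.
    p_conditional : float
        P(flip | B) = p_joint / p_b, the reported disagreement probability.
    tier : Tier
        Clinical-action tier for ``p_conditional``.
    """

    direction: str
    p_joint: float
    p_b: float
    p_conditional: float
    tier: Tier


def _interval_prob(lo: float, hi: float, mu: float, sigma: float) -> float:
    """P(lo ≤ X ≤ hi) for X ~ N(mu, sigma); 0 for an empty interval."""
    if hi <= lo:
        return 0.0
    return float(ndtr((hi - mu) / sigma) - ndtr((lo - mu) / sigma))


def _check_co_domain(co_td: float, config: ModelConfig) -> None:
    if not config.co_min <= co_td <= config.co_max:
        raise ModelDomainError(
            f"co_td = {co_td!r} L/min outside the physiological interval "
            f"[{config.co_min}, {config.co_max}]; the model conditions on a "
            "physiological observed CO"
        )


def prob_b(co_td: float, config: ModelConfig = DEFAULT_CONFIG) -> float:
    """Probability of event B: the direct-Fick CO lies in [a, b].

    Returns Φ((co_td − a − mu)/sigma) − Φ((co_td − b − mu)/sigma).
    ``co_td`` itself must lie in [a, b].
    """
    _check_co_domain(co_td, config)
    return _interval_prob(co_td - config.co_max, co_td - config.co_min,
                          config.bias, config.sigma)


def _flip_threshold(patient: PatientHaemodynamics, config: ModelConfig) -> float:
    # X at which the direct-Fick PVR crosses the threshold:
    # TPG / (co_td - X) = r  <=>  X = co_td - TPG / r
    return patient.co_td - patient.tpg / config.pvr_threshold


def _result(direction: str, p_joint: float, p_b: float) -> DgDisResult:
    if p_b <= 0.0:
        raise DegenerateConditionError(
            "P(B) is numerically zero; conditional probability undefined"
        )
    p_cond = min(p_joint / p_b, 1.0)
    return DgDisResult(direction=direction, p_joint=p_joint, p_b=p_b,
                       p_conditional=p_cond, tier=assign_tier(p_cond))


def prob_dgdis_plus(patient: PatientHaemodynamics,
                    config: ModelConfig = DEFAULT_CONFIG) -> DgDisResult:
    """Disagreement probability for a patient precapillary by TD.

    DgDis+ is the event that the direct-Fick PVR is at or below the
    threshold, i.e. X ≤ CO_TD − TPG/r.  Jointly with B this is the interval
    [CO_TD − b, min(CO_TD − TPG/r, CO_TD − a)]; an empty interval has
    probability 0.
    """
    diagnosis = classify(patient, config)
    if diagnosis is not Diagnosis.PRECAPILLARY_PH:
        raise WrongDirectionError(
            f"DgDis+ requires a precapillary-PH patient by TD, got {diagnosis}"
        )
    _check_co_domain(patient.co_td, config)
    lo = patient.co_td - config.co_max
    hi = min(_flip_threshold(patient, config), patient.co_td - config.co_min)
    p_joint = _interval_prob(lo, hi, config.bias, config.sigma)
    return _result("plus", p_joint, prob_b(patient.co_td, config))


def prob_dgdis_minus(patient: PatientHaemodynamics,
                     config: ModelConfig = DEFAULT_CONFIG) -> DgDisResult:
    """Disagreement probability for a patient with unclassified PH by TD.

    DgDis− is the event that the direct-Fick PVR exceeds the threshold,
    i.e. X ≥ CO_TD − TPG/r, jointly with B the interval
    [max(CO_TD − TPG/r, CO_TD − b), CO_TD − a].
    """
    diagnosis = classify(patient, config)
    if diagnosis is not Diagnosis.UNCLASSIFIED_PH:
        raise WrongDirectionError(
            f"DgDis- requires an unclassified-PH patient by TD, got {diagnosis}"
        )
    _check_co_domain(patient.co_td, config)
    lo = max(_flip_threshold(patient, config), patient.co_td - config.co_max)
    hi = patient.co_td - config.co_min
    p_joint = _interval_prob(lo, hi, config.bias, config.sigma)
    return _result("minus", p_joint, prob_b(patient.co_td, config))


def dgdis(patient: PatientHaemodynamics,
          config: ModelConfig = DEFAULT_CONFIG) -> DgDisResult:
    """Diagnostic-disagreement probability in the patient's own direction.

    Dispatches to :func:`prob_dgdis_plus` for a precapillary patient and
    :func:`prob_dgdis_minus` for unclassified PH; refuses patients whose
    pressures fall outside the model's entry criteria.
    """
    diagnosis = classify(patient, config)
    if diagnosis is Diagnosis.PRECAPILLARY_PH:
        return prob_dgdis_plus(patient, config)
    if diagnosis is Diagnosis.UNCLASSIFIED_PH:
        return prob_dgdis_minus(patient, config)
    raise ModelDomainError(
        f"patient (mPAP {patient.mpap}, PAWP {patient.pawp}) does not meet "
        f"the entry criteria mPAP > {config.mpap_threshold} mmHg and "
        f"PAWP <= {config.pawp_threshold} mmHg"
    )


def joint_probabilities(tpg, co_td, config: ModelConfig = DEFAULT_CONFIG):
    """Vectorised joint probabilities of both flip events with B.

    Returns ``(p_plus_joint, p_minus_joint, p_b)``.  The two flip events
    partition B up to the measure-zero boundary X = CO_TD − TPG/r, so
    ``p_plus_joint + p_minus_joint == p_b`` identically.
    """
    tpg = np.asarray(tpg, dtype=float)
    co = np.asarray(co_td, dtype=float)
    mu, sigma = config.bias, config.sigma
    t = co - tpg / config.pvr_threshold
    lo_b = co - config.co_max
    hi_b = co - config.co_min
    p_b = ndtr((hi_b - mu) / sigma) - ndtr((lo_b - mu) / sigma)
    hi_plus = np.minimum(t, hi_b)
    p_plus = np.clip(ndtr((hi_plus - mu) / sigma)
                     - ndtr((lo_b - mu) / sigma), 0.0, None)
    lo_minus = np.maximum(t, lo_b)
    p_minus = np.clip(ndtr((hi_b - mu) / sigma)
                      - ndtr((lo_minus - mu) / sigma), 0.0, None)
    return p_plus, p_minus, p_b


def conditional_disagreement(tpg, co_td,
                             config: ModelConfig = DEFAULT_CONFIG):
    """Vectorised P(DgDis | B) over (TPG, CO_TD) arrays.

    For each point the direction is determined by the TD diagnosis
    (PVR above the threshold → plus branch, at or below → minus branch)
    and the corresponding conditional probability is returned.

    Returns
    -------
    p : ndarray
        Conditional disagreement probabilities, shape broadcast from inputs.
    direction : ndarray of int
        +1 on the plus branch (precapillary by TD), −1 on the minus branch.
    """
    tpg = np.asarray(tpg, dtype=float)
    co = np.asarray(co_td, dtype=float)
    if np.any((co < config.co_min) | (co > config.co_max)):
        raise ModelDomainError("co_td values outside [co_min, co_max]")
    mu, sigma = config.bias, config.sigma
    t = co - tpg / config.pvr_threshold          # flip threshold on X
    lo_b = co - config.co_max
    hi_b = co - config.co_min
    p_b = ndtr((hi_b - mu) / sigma) - ndtr((lo_b - mu) / sigma)

    plus_branch = tpg > config.pvr_threshold * co
    hi_plus = np.minimum(t, hi_b)
    joint_plus = np.clip(ndtr((hi_plus - mu) / sigma)
                         - ndtr((lo_b - mu) / sigma), 0.0, None)
    lo_minus = np.maximum(t, lo_b)
    joint_minus = np.clip(ndtr((hi_b - mu) / sigma)
                          - ndtr((lo_minus - mu) / sigma), 0.0, None)
    joint = np.where(plus_branch, joint_plus, joint_minus)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(p_b > 0, joint / p_b, np.nan)
    direction = np.where(plus_branch, 1, -1)
    return p, direction
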