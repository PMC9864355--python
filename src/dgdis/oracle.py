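"""Monte-Carlo estimator of the disagreement probabilities.

An independent brute-force check of the analytic conditional probabilities:
draw CO differences X ~ N(mu, sigma), keep draws whose implied direct-Fick
CO (CO_TD − X) is physiological (event B, enforced by rejection — exact,
no importance weighting), and count the kept draws whose direct-Fick PVR
crosses the diagnostic threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, ModelConfig
from .exceptions import DegenerateConditionError, InvalidParameterError
from .haemodynamics import Diagnosis, PatientHaemodynamics, classify
from .model import _check_co_domain


@dataclass(frozen=True)
class MCEstimate:
    """Monte-Carlo estimate of a conditional disagreement probability.

    ``standard_error`` is the binomial SE sqrt(p·(1−p)/draws_in_b) of the
    conditional estimate given the number of draws that satisfied B.
    """

    estimate: float
    standard_error: float
    draws_total: int
    draws_in_b: int


def estimate_dgdis(patient: PatientHaemodynamics,
                   config: ModelConfig = DEFAULT_CONFIG,
                   draws: int = 1_000_000,
                   seed: int | np.random.Generator | None = None) -> MCEstimate:
    """Estimate P(DgDis | B) for one patient by rejection sampling.

    The flip direction follows the patient's TD diagnosis: a precapillary
    patient flips when the direct-Fick PVR drops to or below the threshold,
    an unclassified patient when it rises above.

    Parameters
    ----------
    draws : int
        Total number of X draws (≥ 1000).
    seed : int, Generator or None
        Seed for reproducibility.
    """
    if draws < 1_000:
        raise InvalidParameterError(f"draws must be >= 1000, got {draws!r}")
    diagnosis = classify(patient, config)
    if diagnosis is Diagnosis.OUT_OF_MODEL_DOMAIN:
        raise DegenerateConditionError(
            "patient outside the model's entry criteria"
        )
    _check_co_domain(patient.co_td, config)

    rng = np.random.default_rng(seed)
    x = rng.normal(config.bias, config.sigma, size=draws)
    co_df = patient.co_td - x
    in_b = (co_df >= config.co_min) & (co_df <= config.co_max)
    n_b = int(in_b.sum())
    if n_b == 0:
        raise DegenerateConditionError(
            "no draws satisfied the physiological-CO condition"
        )
    pvr_df = patient.tpg / co_df[in_b]
    if diagnosis is Diagnosis.PRECAPILLARY_PH:
        flips = pvr_df <= config.pvr_threshold
    else:
        flips = pvr_df > config.pvr_threshold
    p = float(flips.mean())
    se = float(np.sqrt(p * (1.0 - p) / n_b))
    return MCEstimate(estimate=p, standard_error=se,
                      draws_total=draws, draws_in_b=n_b)
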