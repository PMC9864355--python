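"""Model configuration: agreement parameters and diagnostic thresholds.

The model describes the difference between thermodilution and direct-Fick
cardiac output as X = CO_TD − CO_DF ~ N(mu, sigma), with both measurements
constrained to a physiological interval [a, b].  On a Bland–Altman plot
``bias`` is the mean difference mu and ``loa`` is the half-width of the
limits of agreement, 1.96·sigma, so sigma = loa / 1.96.

Defaults reflect the pooled resting agreement between the two methods in
precapillary pulmonary hypertension: bias 0 L/min, 1.96·SD 2 L/min, and
physiological resting CO between 1.3 and 10.2 L/min, with the haemodynamic
definition thresholds mPAP > 20 mmHg, PAWP ≤ 15 mmHg, PVR > 2 WU.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .exceptions import InvalidParameterError

#: 97.5% standard-normal quantile used to convert limits of agreement to SD.
LOA_FACTOR = 1.96


def sd_from_loa(loa: float) -> float:
    """Convert the 1.96·SD limits-of-agreement half-width to the SD.

    A normal variable lies within mu ± 1.96·sigma with probability 95%,
    so the SD of the CO differences is ``loa / 1.96``.

    Parameters
    ----------
    loa : float
        Half-width of the limits of agreement, in L/min. Must be > 0.

    Returns
    -------
    float
        Standard deviation sigma of the CO differences, in L/min.
    """
    if not loa > 0:
        raise InvalidParameterError(f"loa must be > 0, got {loa!r}")
    return loa / LOA_FACTOR


@dataclass(frozen=True)
class ModelConfig:
    """Agreement parameters and diagnostic thresholds.

    Attributes
    ----------
    bias : float
        Mean CO difference mu = E[CO_TD − CO_DF] (L/min).
    loa : float
        1.96·SD of the CO differences (L/min); sigma = loa / 1.96.
    co_min, co_max : float
        Physiological cardiac output interval [a, b] (L/min).
    pvr_threshold : float
        PVR cut-off separating precapillary from unclassified PH (WU).
    mpap_threshold : float
        mPAP entry criterion (mmHg); the model applies to mPAP strictly above.
    pawp_threshold : float
        PAWP entry criterion (mmHg); the model applies to PAWP at or below.
    """

    bias: float = 0.0
    loa: float = 2.0
    co_min: float = 1.3
    co_max: float = 10.2
    pvr_threshold: float = 2.0
    mpap_threshold: float = 20.0
    pawp_threshold: float = 15.0

    def __post_init__(self) -> None:
        if not self.loa > 0:
            raise InvalidParameterError(f"loa must be > 0, got {self.loa!r}")
        if not self.co_min > 0:
            raise InvalidParameterError(
                f"co_min must be > 0, got {self.co_min!r}"
            )
        if not self.co_min < self.co_max:
            raise InvalidParameterError(
                f"co_min must be < co_max, got [{self.co_min!r}, {self.co_max!r}]"
            )
        if not self.pvr_threshold > 0:
            raise InvalidParameterError(
                f"pvr_threshold must be > 0, got {self.pvr_threshold!r}"
            )

    @property
    def sigma(self) -> float:
        """SD of the CO differences (L/min), derived from ``loa``."""
        return sd_from_loa(self.loa)

    def replace(self, **changes: float) -> "ModelConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


#: Default configuration (resting agreement between TD and direct Fick).
DEFAULT_CONFIG = ModelConfig()
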