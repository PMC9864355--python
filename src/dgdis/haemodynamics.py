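"""Patient haemodynamics and the resting haemodynamic classification.

A patient enters the model with mPAP, PAWP (mmHg) and thermodilution
cardiac output CO_TD (L/min).  Derived quantities are the transpulmonary
gradient TPG = mPAP − PAWP and the TD-based pulmonary vascular resistance
PVR_TD = TPG / CO_TD (Wood units).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .config import DEFAULT_CONFIG, ModelConfig
from .exceptions import InvalidInputError


class Diagnosis(str, enum.Enum):
    """Resting haemodynamic classification given mPAP, PAWP and one CO."""

    PRECAPILLARY_PH = "precapillary_ph"
    UNCLASSIFIED_PH = "unclassified_ph"
    OUT_OF_MODEL_DOMAIN = "out_of_model_domain"

    def __str__(self) -> str:  # plain value in reports
        return self.value


@dataclass(frozen=True)
class PatientHaemodynamics:
    """Right-heart-catheterisation measurements for one patient.

    Attributes
    ----------
    mpap : float
        Mean pulmonary artery pressure (mmHg), > 0.
    pawp : float
        Pulmonary artery wedge pressure (mmHg), ≥ 0.
    co_td : float
        Thermodilution cardiac output (L/min), > 0.
    """

    mpap: float
    pawp: float
    co_td: float

    def __post_init__(self) -> None:
        if not self.mpap > 0:
            raise InvalidInputError(f"mpap must be > 0, got {self.mpap!r}")
        if not self.pawp >= 0:
            raise InvalidInputError(f"pawp must be >= 0, got {self.pawp!r}")
        if not self.co_td > 0:
            raise InvalidInputError(f"co_td must be > 0, got {self.co_td!r}")
        if self.tpg < 0:
            raise InvalidInputError(
                f"tpg = mpap - pawp must be >= 0, got {self.tpg!r}"
            )

    @property
    def tpg(self) -> float:
        """Transpulmonary gradient mPAP − PAWP (mmHg)."""
        return self.mpap - self.pawp

    @property
    def pvr_td(self) -> float:
        """Pulmonary vascular resistance TPG / CO_TD (WU)."""
        return self.tpg / self.co_td

    @classmethod
    def from_tpg(cls, tpg: float, co_td: float,
                 pawp: float = 15.0) -> "PatientHaemodynamics":
        """Build a patient from (TPG, CO_TD).

        The classification and the disagreement probabilities depend on the
        pressures only through TPG, so any mPAP/PAWP split consistent with
        the entry criteria is equivalent; mPAP is set to ``pawp + tpg``.
        Note the default entry criteria (mPAP > 20, PAWP ≤ 15) imply
        TPG > 5 mmHg: no split can put a lower TPG inside the domain.
        """
        return cls(mpap=pawp + tpg, pawp=pawp, co_td=co_td)


def classify(patient: PatientHaemodynamics,
             config: ModelConfig = DEFAULT_CONFIG) -> Diagnosis:
    """Classify a patient from TD haemodynamics.

    Precapillary PH requires mPAP > 20 mmHg, PAWP ≤ 15 mmHg and PVR > 2 WU
    (defaults; thresholds configurable).  With the pressure criteria met but
    PVR ≤ 2 WU the patient has unclassified PH.  A PVR exactly at the
    threshold is unclassified (the definition's "> 2 WU" is strict).
    Patients failing the pressure criteria are outside the model's domain.
    """
    if not (patient.mpap > config.mpap_threshold
            and patient.pawp <= config.pawp_threshold):
        return Diagnosis.OUT_OF_MODEL_DOMAIN
    if patient.pvr_td > config.pvr_threshold:
        return Diagnosis.PRECAPILLARY_PH
    return Diagnosis.UNCLASSIFIED_PH
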