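"""Scikit-learn-style front end to the disagreement model.

:class:`DisagreementModel` bundles the agreement parameters (bias, limits
of agreement, physiological CO limits) and the diagnostic thresholds into
one estimator: ``fit`` either validates the declared parameters or
estimates bias and LoA from paired (CO_TD, CO_DF) measurements by
Bland–Altman analysis, and ``predict`` / ``predict_proba`` evaluate the
haemodynamic classification and the disagreement probability for a table
of patients.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .ba import BlandAltman
from .config import ModelConfig
from .haemodynamics import Diagnosis, PatientHaemodynamics, classify
from .model import Tier, assign_tier, conditional_disagreement, prob_b

_PATIENT_COLUMNS = ("mpap", "pawp", "co_td")


class DisagreementModel(BaseEstimator):
    """Diagnostic-disagreement model for thermodilution vs direct Fick.

    Parameters
    ----------
    bias : float, default 0.0
        Mean CO difference CO_TD − CO_DF (L/min); overridden by ``fit``
        when paired data are supplied.
    loa : float, default 2.0
        1.96·SD of the CO differences (L/min); overridden by ``fit`` when
        paired data are supplied.
    co_min, co_max : float, default 1.3, 10.2
        Physiological CO interval [a, b] (L/min).
    pvr_threshold : float, default 2.0
        PVR cut-off (WU) separating precapillary from unclassified PH.
    mpap_threshold, pawp_threshold : float, default 20.0, 15.0
        Pressure entry criteria (mmHg).

    Attributes
    ----------
    bias_, loa_, sigma_ : float
        Agreement parameters in effect after ``fit``.
    config_ : ModelConfig
        Validated configuration used by the prediction methods.
    classes_ : ndarray
        ``["no_flip", "flip"]``, the column order of ``predict_proba``.

    Examples
    --------
    >>> model = DisagreementModel().fit()
    >>> model.predict_proba([[21, 14, 4]])[0, 1]  # mPAP, PAWP, CO_TD
    0.309...
    """

    def __init__(self, bias: float = 0.0, loa: float = 2.0,
                 co_min: float = 1.3, co_max: float = 10.2,
                 pvr_threshold: float = 2.0,
                 mpap_threshold: float = 20.0,
                 pawp_threshold: float = 15.0):
        self.bias = bias
        self.loa = loa
        self.co_min = co_min
        self.co_max = co_max
        self.pvr_threshold = pvr_threshold
        self.mpap_threshold = mpap_threshold
        self.pawp_threshold = pawp_threshold

    def fit(self, X=None, y=None) -> "DisagreementModel":
        """Fix the agreement parameters.

        Parameters
        ----------
        X : (n, 2) array or DataFrame, optional
            Paired measurements (CO_TD, CO_DF).  When given, ``bias_`` and
            ``loa_`` are estimated by Bland–Altman analysis; otherwise the
            declared ``bias`` and ``loa`` parameters are used as-is.
        y : ignored
        """
        if X is None:
            self.bias_ = float(self.bias)
            self.loa_ = float(self.loa)
            self.ba_summary_ = None
        else:
            if isinstance(X, pd.DataFrame):
                X = X.iloc[:, :2].to_numpy()
            ba = BlandAltman().fit(X)
            summary = ba.summary()
            self.bias_ = summary.bias
            self.loa_ = summary.loa
            self.ba_summary_ = summary
        self.config_ = ModelConfig(
            bias=self.bias_, loa=self.loa_,
            co_min=self.co_min, co_max=self.co_max,
            pvr_threshold=self.pvr_threshold,
            mpap_threshold=self.mpap_threshold,
            pawp_threshold=self.pawp_threshold,
        )
        self.sigma_ = self.config_.sigma
        self.classes_ = np.array(["no_flip", "flip"])
        return self

    def _patient_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in _PATIENT_COLUMNS if c not in X.columns]
            if missing:
                raise ValueError(f"missing patient columns: {missing}")
            return X.loc[:, list(_PATIENT_COLUMNS)].astype(float)
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(
                "expected an (n, 3) array with columns (mpap, pawp, co_td) "
                f"or a DataFrame; got shape {arr.shape}"
            )
        return pd.DataFrame(arr, columns=list(_PATIENT_COLUMNS))

    def predict(self, X) -> np.ndarray:
        """Haemodynamic classification by TD for each patient row."""
        check_is_fitted(self, "config_")
        frame = self._patient_frame(X)
        out = [
            classify(PatientHaemodynamics(row.mpap, row.pawp, row.co_td),
                     self.config_).value
            for row in frame.itertuples()
        ]
        return np.asarray(out, dtype=object)

    def predict_proba(self, X) -> np.ndarray:
        """Probability that the diagnosis flips under direct Fick.

        Returns an (n, 2) array with columns [P(no flip), P(flip)],
        conditioned on a physiological direct-Fick CO.  Rows outside the
        model's domain (pressure criteria unmet or CO_TD outside [a, b])
        are NaN.
        """
        check_is_fitted(self, "config_")
        table = self.predict_disagreement(X)
        p = table["p_conditional"].to_numpy()
        return np.column_stack([1.0 - p, p])

    def predict_disagreement(self, X) -> pd.DataFrame:
        """Full per-patient report.

        Columns: the inputs, ``tpg``, ``pvr_td``, ``diagnosis``,
        ``direction`` (+1 flip to unclassified / −1 flip to precapillary,
        0 outside the domain), ``p_b``, ``p_conditional`` and ``tier``.
        Out-of-domain rows carry NaN probabilities and an empty tier.
        """
        check_is_fitted(self, "config_")
        frame = self._patient_frame(X).reset_index(drop=True)
        cfg = self.config_
        n = len(frame)
        tpg = frame["mpap"] - frame["pawp"]
        pvr = tpg / frame["co_td"]
        diagnosis = np.empty(n, dtype=object)
        direction = np.zeros(n, dtype=int)
        p_b = np.full(n, np.nan)
        p_cond = np.full(n, np.nan)
        tier = np.empty(n, dtype=object)
        tier[:] = ""
        for i, row in enumerate(frame.itertuples()):
            patient = PatientHaemodynamics(row.mpap, row.pawp, row.co_td)
            diag = classify(patient, cfg)
            in_co = cfg.co_min <= row.co_td <= cfg.co_max
            if diag is Diagnosis.OUT_OF_MODEL_DOMAIN or not in_co:
                diagnosis[i] = (diag.value if diag is Diagnosis.OUT_OF_MODEL_DOMAIN
                                else f"{diag.value} (co_td outside "
                                     f"[{cfg.co_min}, {cfg.co_max}])")
                continue
            p, d = conditional_disagreement(patient.tpg, patient.co_td, cfg)
            diagnosis[i] = diag.value
            direction[i] = int(d)
            p_b[i] = prob_b(patient.co_td, cfg)
            p_cond[i] = float(p)
            tier[i] = assign_tier(float(p)).value
        return pd.DataFrame({
            "mpap": frame["mpap"], "pawp": frame["pawp"],
            "co_td": frame["co_td"], "tpg": tpg, "pvr_td": pvr,
            "diagnosis": diagnosis, "direction": direction,
            "p_b": p_b, "p_conditional": p_cond, "tier": tier,
        })
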