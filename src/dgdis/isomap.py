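"""Disagreement maps over the TPG × CO_TD plane and iso-lines.

The disagreement probability depends on the pressures only through the
transpulmonary gradient, so the whole model can be pictured on a
TPG-versus-CO_TD plane: the straight line TPG = r·CO (r the PVR threshold)
separates precapillary PH (above) from unclassified PH (below), and curves
of equal disagreement probability (iso-DgDis lines) run on either side of
it.  Away from the CO limits these curves are straight,
TPG/r = CO ∓ z(level)·sigma, and bend ("distortion") near the limits where
the truncation of the CO interval becomes active.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import DEFAULT_CONFIG, ModelConfig
from .exceptions import InvalidParameterError
from .model import conditional_disagreement, joint_probabilities

#: Default plotting window (mmHg, L/min) and grid step.
DEFAULT_TPG_RANGE = (1.0, 25.0)
DEFAULT_STEP = 0.05
#: Bisection tolerance on TPG for iso-line extraction (mmHg).
_TPG_XTOL = 1e-10


@dataclass(frozen=True)
class IsoMapGrid:
    """Disagreement probabilities evaluated on a rectangular grid.

    ``dgdis_values[i, j]`` is the conditional disagreement probability for
    ``tpg_axis[i]`` and ``co_axis[j]``; ``direction[i, j]`` is +1 on the
    precapillary (DgDis+) side and −1 on the unclassified (DgDis−) side.
    """

    tpg_axis: np.ndarray
    co_axis: np.ndarray
    dgdis_values: np.ndarray
    direction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns tpg, co, direction, dgdis."""
        tt, cc = np.meshgrid(self.tpg_axis, self.co_axis, indexing="ij")
        return pd.DataFrame({
            "tpg": tt.ravel(),
            "co": cc.ravel(),
            "direction": self.direction.ravel(),
            "dgdis": self.dgdis_values.ravel(),
        })


@dataclass(frozen=True)
class IsoLine:
    """An iso-probability (or iso-PVR) polyline on the TPG × CO plane.

    ``points`` is an (m, 2) array of (co, tpg) pairs ordered by CO.
    ``gaps`` lists CO values where no point exists at the requested level
    (near the CO limits, where the truncation distorts the field).
    """

    level: float
    kind: str                      # "dgdis" or "pvr"
    points: np.ndarray
    direction: str | None = None   # "plus"/"minus" for dgdis lines
    gaps: tuple[float, ...] = field(default_factory=tuple)


def build_grid(config: ModelConfig = DEFAULT_CONFIG,
               tpg_range: tuple[float, float] = DEFAULT_TPG_RANGE,
               co_range: tuple[float, float] | None = None,
               resolution: int | tuple[int, int] | None = None) -> IsoMapGrid:
    """Evaluate the disagreement probability on a TPG × CO grid.

    Parameters
    ----------
    tpg_range, co_range : (low, high)
        Axis ranges; ``co_range`` defaults to the physiological interval
        and is clipped to it (with a warning) if it extends beyond.
    resolution : int or (n_tpg, n_co), optional
        Points per axis (≥ 2 each); by default a 0.05-step grid.
    """
    if tpg_range[0] <= 0 or tpg_range[1] <= tpg_range[0]:
        raise InvalidParameterError(f"invalid tpg_range {tpg_range!r}")
    if co_range is None:
        co_range = (config.co_min, config.co_max)
    lo, hi = co_range
    if lo < config.co_min or hi > config.co_max:
        lo = max(lo, config.co_min)
        hi = min(hi, config.co_max)
        warnings.warn(
            f"co_range clipped to the physiological interval "
            f"[{config.co_min}, {config.co_max}]", stacklevel=2)
    if not lo < hi:
        raise InvalidParameterError(f"invalid co_range {co_range!r}")

    if resolution is None:
        n_tpg = int(round((tpg_range[1] - tpg_range[0]) / DEFAULT_STEP)) + 1
        n_co = int(round((hi - lo) / DEFAULT_STEP)) + 1
    elif np.isscalar(resolution):
        n_tpg = n_co = int(resolution)
    else:
        n_tpg, n_co = (int(r) for r in resolution)
    if n_tpg < 2 or n_co < 2:
        raise InvalidParameterError("resolution must be >= 2 per axis")

    tpg_axis = np.linspace(tpg_range[0], tpg_range[1], n_tpg)
    co_axis = np.linspace(lo, hi, n_co)
    tt, cc = np.meshgrid(tpg_axis, co_axis, indexing="ij")
    values, direction = conditional_disagreement(tt, cc, config)
    return IsoMapGrid(tpg_axis=tpg_axis, co_axis=co_axis,
                      dgdis_values=values, direction=direction)


def iso_pvr_line(level: float,
                 co_range,
                 n_points: int = 100) -> IsoLine:
    """The straight line of constant PVR: TPG = level × CO.

    ``co_range`` may be a (low, high) tuple (sampled at ``n_points``) or an
    explicit array of CO values.
    """
    if not level > 0:
        raise InvalidParameterError(f"level must be > 0, got {level!r}")
    co = _co_values(co_range, n_points)
    return IsoLine(level=level, kind="pvr",
                   points=np.column_stack([co, level * co]))


def iso_dgdis_line(level: float,
                   config: ModelConfig = DEFAULT_CONFIG,
                   co_range=None,
                   direction: str = "minus",
                   n_points: int = 100,
                   tpg_max: float = DEFAULT_TPG_RANGE[1]) -> IsoLine:
    """Extract the iso-line of constant disagreement probability.

    For each CO the TPG at which the branch's disagreement equals ``level``
    is found by bracketed root-finding (the field is monotone in TPG on
    each side of the PVR-threshold line, which makes bisection robust):
    the minus branch is bracketed between TPG → 0 and the threshold line,
    the plus branch between the threshold line and ``tpg_max``.  CO values
    with no root in the bracket — near the CO limits, where truncation
    caps the attainable probability — are reported as gaps, not
    extrapolated.

    Parameters
    ----------
    level : float
        Target probability, 0 < level < 0.5.
    direction : {"minus", "plus"}
        Which branch to trace.
    """
    if not 0.0 < level < 0.5:
        raise InvalidParameterError(
            f"level must be in (0, 0.5), got {level!r}")
    if direction not in ("minus", "plus"):
        raise InvalidParameterError(f"unknown direction {direction!r}")
    if co_range is None:
        co_range = (config.co_min, config.co_max)
    co_values = _co_values(co_range, n_points)
    r = config.pvr_threshold

    # Branch-specific probability: continuous across the PVR-threshold
    # line (the dispatched probability jumps there), monotone in TPG.
    def p_at(tpg: float, co: float) -> float:
        p_plus, p_minus, p_b = joint_probabilities(tpg, co, config)
        joint = p_plus if direction == "plus" else p_minus
        return float(joint / p_b)

    points = []
    gaps = []
    for co in co_values:
        if direction == "minus":
            lo_t, hi_t = 1e-9, r * co
        else:
            lo_t, hi_t = r * co, max(tpg_max, r * co + 1.0)
        f = lambda tpg: p_at(tpg, co) - level
        f_lo, f_hi = f(lo_t), f(hi_t)
        if f_lo == 0.0:
            points.append((co, lo_t))
            continue
        if f_hi == 0.0:
            points.append((co, hi_t))
            continue
        if np.sign(f_lo) == np.sign(f_hi):
            gaps.append(float(co))
            continue
        tpg = brentq(f, lo_t, hi_t, xtol=_TPG_XTOL)
        points.append((co, tpg))
    pts = np.asarray(points) if points else np.empty((0, 2))
    return IsoLine(level=level, kind="dgdis", points=pts,
                   direction=direction, gaps=tuple(gaps))


def _co_values(co_range, n_points: int) -> np.ndarray:
    if isinstance(co_range, tuple) and len(co_range) == 2:
        return np.linspace(co_range[0], co_range[1], n_points)
    return np.asarray(co_range, dtype=float)
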