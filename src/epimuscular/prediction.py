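"""Forward prediction under proximal-only repositioning, and agreement
statistics against measured data.

The testing protocol repositions only the proximal LG+PL tendon, so the
intermuscular interface is loaded less than when both tendons move
together.  The per-segment scale factor ``r`` (estimated from a
distal-only-resection subset) discounts the intermuscular stiffness
accordingly:

    dF_mod(dP) = dF_mod(P_REF) + sum over segments crossed of
                 (r_j * K_INT,j + K_NV1,j + K_NV2,j) * segment width

Agreement between predicted and measured force differences is summarised
with a Bland–Altman analysis (bias and 1.96-SD limits of agreement) and an
ordinary least-squares regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import StiffnessSet, forward_delta_F
from .exceptions import (
    InsufficientDataError,
    InvalidInputError,
    ParameterError,
    StructuralError,
)


@dataclass(frozen=True)
class PredictionResult:
    """Modelled LG+PL force difference over a proximal displacement grid."""

    dp_mm: np.ndarray
    delta_f_N: np.ndarray
    offset_N: float
    r: tuple[float, ...]
    group: str = ""

    def __post_init__(self) -> None:
        dp = np.asarray(self.dp_mm, dtype=float)
        df = np.asarray(self.delta_f_N, dtype=float)
        if dp.shape != df.shape:
            raise StructuralError("grid and prediction lengths differ")
        object.__setattr__(self, "dp_mm", dp)
        object.__setattr__(self, "delta_f_N", df)


def predict_delta_F(
    stiffness: StiffnessSet,
    r: Sequence[float],
    dp_grid_mm: Sequence[float],
    offset_N: float = 0.0,
) -> PredictionResult:
    """Predict dF_LGPL for proximal-only displacements of LG+PL.

    ``r`` holds one scale factor per stiffness segment, applied to the
    intermuscular pathway only.  With all factors equal to 1 the prediction
    coincides with the calibration forward model.  The default offset of 0
    encodes that no net force is transmitted at the reference position; a
    measured reference value may be supplied instead.
    """
    if not math.isfinite(offset_N):
        raise InvalidInputError("offset must be finite")
    r = tuple(float(v) for v in r)
    if len(r) != stiffness.n_segments:
        raise StructuralError(
            f"r needs {stiffness.n_segments} entries, got {len(r)}"
        )
    grid = np.asarray(dp_grid_mm, dtype=float)
    values = np.array(
        [
            offset_N + forward_delta_F(stiffness, p, int_segment_scale=r).delta_f_lgpl
            for p in grid
        ]
    )
    return PredictionResult(
        dp_mm=grid, delta_f_N=values, offset_N=offset_N, r=r, group=stiffness.group
    )


@dataclass(frozen=True)
class AgreementStats:
    """Bland–Altman and regression summary of predicted-vs-measured forces.

    ``bias_N`` is the mean of (measured − predicted); the limits of
    agreement are bias ± 1.96 × sample SD of the differences.  Regression
    fields describe the OLS fit of measured on predicted and are NaN when
    the fit is degenerate (fewer than 3 points or zero predictor variance).
    """

    bias_N: float
    loa_lower_N: float
    loa_upper_N: float
    sd_diff_N: float
    slope: float
    intercept_N: float
    r_value: float
    n: int

    def to_dict(self) -> dict:
        return {
            "bias_N": self.bias_N,
            "loa_lower_N": self.loa_lower_N,
            "loa_upper_N": self.loa_upper_N,
            "sd_diff_N": self.sd_diff_N,
            "slope": self.slope,
            "intercept_N": self.intercept_N,
            "r_value": self.r_value,
            "n": self.n,
        }


def _series(name: str, x: Sequence[float]) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise StructuralError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


def bland_altman(
    measured: Sequence[float], predicted: Sequence[float]
) -> AgreementStats:
    """Method-agreement statistics between measured and predicted forces."""
    m = _series("measured", measured)
    p = _series("predicted", predicted)
    if m.shape != p.shape:
        raise StructuralError("measured and predicted lengths differ")
    if m.size < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs")
    diff = m - p
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    slope = intercept = r_value = float("nan")
    if m.size >= 3 and float(np.var(p)) > 0.0:
        fit = stats.linregress(p, m)
        slope, intercept, r_value = (
            float(fit.slope),
            float(fit.intercept),
            float(fit.rvalue),
        )
    return AgreementStats(
        bias_N=bias,
        loa_lower_N=bias - 1.96 * sd,
        loa_upper_N=bias + 1.96 * sd,
        sd_diff_N=sd,
        slope=slope,
        intercept_N=intercept,
        r_value=r_value,
        n=int(m.size),
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_value: float
    n: int


def regress_SO_vs_LGPL(
    delta_f_so: Sequence[float], delta_f_lgpl: Sequence[float]
) -> RegressionResult:
    """OLS regression of the SO force change on the LG+PL force difference.

    A positive slope with high correlation indicates that the force missing
    between the LG+PL tendons reappears at the SO distal tendon, the
    signature of myofascial transmission between the synergists.
    """
    y = _series("delta_f_so", delta_f_so)
    x = _series("delta_f_lgpl", delta_f_lgpl)
    if x.shape != y.shape:
        raise StructuralError("series lengths differ")
    if x.size < 3:
        raise InsufficientDataError("regression needs at least 3 points")
    if float(np.var(x)) == 0.0:
        raise ParameterError("predictor has zero variance; fit degenerate")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_value=float(fit.rvalue),
        n=int(x.size),
    )


def percent_of_range(values: Sequence[float]) -> np.ndarray:
    """Express values as a percentage of their total range (per group),
    used to pool animals of different force ranges on one agreement plot."""
    v = _series("values", values)
    span = float(np.max(v) - np.min(v))
    if span == 0.0:
        raise ParameterError("zero range; normalisation undefined")
    return (v - float(np.min(v))) / span * 100.0
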