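"""Four-parameter Hill concentration-response model.

The model used throughout is

    y(x) = s0 + (s_inf - s0) / (1 + 10^(h * (logAC50 - x)))

with x the log10-molar concentration and h the Hill slope.  With h > 0,
y tends to s0 as x -> -inf and to s_inf as x -> +inf, so s0 is the
low-concentration asymptote, matching the S_0 / S_Inf naming of the
input format.  Sign conventions for the slope vary across curve-fitting
software; this package fixes the one above and documents it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ContractError, CurveFitParams, QHTSDataset, efficacy

# exponent clamp: 10**300 is finite in float64, 10**310 is not
_EXP_CLAMP = 300.0


def hill_response(x, p: CurveFitParams):
    """Evaluate the Hill curve at log10-molar concentration(s) ``x``.

    ``x`` may be a scalar or an array; the return matches.  The power
    term's exponent is clamped at +/-300 so extreme arguments return the
    appropriate asymptote instead of overflowing to inf/nan.
    """
    p.require_complete()
    if p.hill_slope == 0:
        raise ContractError("hill_slope must be nonzero to evaluate a curve")
    xa = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(xa)):
        raise ContractError("concentration x must be finite")
    expo = np.clip(p.hill_slope * (p.log_ac50_m - xa), -_EXP_CLAMP, _EXP_CLAMP)
    y = p.s0 + (p.s_inf - p.s0) / (1.0 + np.power(10.0, expo))
    if np.isscalar(x) or xa.ndim == 0:
        return float(y)
    return y


@dataclass
class SampledCurve:
    """A Hill curve sampled on an even grid for line rendering."""

    x: np.ndarray
    y: np.ndarray
    record_index: int = -1

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size != self.y.size or self.x.size < 2:
            raise ContractError("sampled curve needs matching x/y of length >= 2")
        if not np.all(np.diff(self.x) > 0):
            raise ContractError("sampled x grid must be strictly increasing")


def sample_curve(
    p: CurveFitParams,
    grid,
    points_per_curve: int = 64,
    record_index: int = -1,
) -> SampledCurve:
    """Sample the curve over the tested concentration range.

    The line spans [min(grid), max(grid)] inclusive -- no extrapolation
    beyond the titration range -- with ``points_per_curve`` evenly
    spaced points.
    """
    g = np.asarray(grid, dtype=float)
    if g.size < 2 or not np.all(np.isfinite(g)):
        raise ContractError("grid must contain >= 2 finite concentrations")
    lo, hi = float(g.min()), float(g.max())
    if lo == hi:
        raise ContractError("degenerate grid: a single concentration cannot span a curve")
    if points_per_curve < 2:
        raise ContractError("points_per_curve must be >= 2")
    x = np.linspace(lo, hi, int(points_per_curve))
    return SampledCurve(x=x, y=hill_response(x, p), record_index=record_index)


def partition_records(ds: QHTSDataset) -> tuple[list[int], list[int]]:
    """Split record indices into (fitted, point-only), preserving order.

    Fitted records have fit_output == 1 and a complete parameter set;
    everything else renders as points only.  The two lists are disjoint
    and together cover all records.
    """
    fitted: list[int] = []
    points_only: list[int] = []
    for i, rec in enumerate(ds.records):
        if rec.fit_output == 1 and rec.has_complete_params():
            fitted.append(i)
        else:
            points_only.append(i)
    return fitted, points_only


def polarity(p: CurveFitParams) -> str:
    """Classify a curve as ``gain``, ``loss`` or ``flat`` of signal.

    The sign of the efficacy s_inf - s0 distinguishes gain-of-signal
    (response rises with concentration) from loss-of-signal.
    """
    e = efficacy(p)
    if e > 0:
        return "gain"
    if e < 0:
        return "loss"
    return "flat"
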