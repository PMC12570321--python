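"""Ratio-to-pH calibration curves.

A calibration maps a pH-sensitive/pH-independent fluorescence ratio to
pH through a 4-parameter logistic on the ratio scale. Two constructions
are supported:

``full``
    Fit the logistic directly to fixed-cell ratios measured across a pH
    buffer series (e.g. pH 4.0-6.0 in 0.5 steps).

``anchored``
    The simplified single-anchor procedure: measure the fixed-cell ratio
    in one known buffer only (anchor, typically pH 5.0) and rescale a
    solution ratio titration of the same probes so it passes through the
    anchor. Because cells and solution share the probe's pH dependence,
    only the overall scale differs; the anchored curve is the solution
    curve times ``anchor_ratio / R_sol(anchor_pH)``.

Inversion is closed-form:

    pH = pKa + (1/slope) * log10((top - r) / (r - bottom))

Ratios at or beyond the asymptotes cannot be interpolated; a guard band
(default 1% of top - bottom) flags near-asymptote ratios instead of
returning wildly extrapolated pH values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .probes import sigmoid_value
from .spectroscopy import SigmoidFit, TitrationSeries, fit_sigmoid

__all__ = [
    "CalibrationCurve",
    "PHResult",
    "build_calibration_full",
    "build_calibration_anchored",
    "interpolate_ph",
]

#: Anchored-mode ratio points are generated on this grid before refitting.
ANCHOR_PH_GRID = np.round(np.arange(3.5, 7.4 + 1e-9, 0.1), 10)
DEFAULT_ANCHOR_PH = 5.0
DEFAULT_GUARD_FRACTION = 0.01


@dataclass
class CalibrationCurve:
    """Sigmoid ratio-vs-pH curve with provenance and validity ranges."""

    bottom: float
    top: float
    pka: float
    slope: float
    mode: str  # "full" | "anchored"
    valid_ph_range: tuple[float, float]
    anchor: tuple[float, float] | None = None  # (pH, ratio)
    guard_fraction: float = DEFAULT_GUARD_FRACTION
    source: dict = field(default_factory=dict)

    @property
    def valid_ratio_range(self) -> tuple[float, float]:
        """Open interval between the two asymptote values."""
        return (self.bottom, self.top)

    def value(self, ph):
        return sigmoid_value(self, ph)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["valid_ph_range"] = list(self.valid_ph_range)
        d["anchor"] = list(self.anchor) if self.anchor else None
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            d = json.load(fh)
        d["valid_ph_range"] = tuple(d["valid_ph_range"])
        if d.get("anchor"):
            d["anchor"] = tuple(d["anchor"])
        return cls(**d)


def build_calibration_full(ratios: TitrationSeries) -> CalibrationCurve:
    """Fit a calibration sigmoid to measured ratio-vs-pH data."""
    if ratios.n_distinct_ph() < 4:
        raise ValueError("need ratios at >= 4 pH values")
    fit = fit_sigmoid(ratios)
    if not fit.converged:
        raise RuntimeError(f"calibration fit did not converge: {fit.message}")
    return CalibrationCurve(
        bottom=fit.bottom, top=fit.top, pka=fit.pka, slope=fit.slope,
        mode="full",
        valid_ph_range=(float(ratios.ph.min()), float(ratios.ph.max())),
        source={"kind": "full", "n_points": fit.n_points, "rss": fit.rss},
    )


def build_calibration_anchored(
    anchor_ratio: float,
    solution: TitrationSeries | SigmoidFit,
    anchor_ph: float = DEFAULT_ANCHOR_PH,
) -> CalibrationCurve:
    """Single-anchor calibration from one fixed-cell ratio at ``anchor_ph``.

    Generated ratio at pH p is ``anchor_ratio * R_sol(p) / R_sol(anchor_ph)``
    over pH 3.5-7.4; scaling a logistic by a positive constant scales
    bottom and top and leaves pKa and slope unchanged, so the anchored
    parameters are obtained by that exact scaling (a refit of the
    generated grid points converges to the same curve). The result passes
    through the anchor exactly.
    """
    if anchor_ratio <= 0:
        raise ValueError("anchor_ratio must be positive")
    if isinstance(solution, TitrationSeries):
        if not (solution.ph.min() <= anchor_ph <= solution.ph.max()):
            raise ValueError(
                f"anchor pH {anchor_ph} outside solution titration range "
                f"[{solution.ph.min():g}, {solution.ph.max():g}]"
            )
        sol_fit = fit_sigmoid(solution)
        if not sol_fit.converged:
            raise RuntimeError("solution titration fit did not converge")
    else:
        sol_fit = solution
    r_anchor = float(sigmoid_value(sol_fit, anchor_ph))
    if r_anchor <= 0:
        raise ValueError("solution ratio at the anchor pH is not positive")
    k = anchor_ratio / r_anchor
    lo, hi = float(ANCHOR_PH_GRID[0]), float(ANCHOR_PH_GRID[-1])
    return CalibrationCurve(
        bottom=k * sol_fit.bottom, top=k * sol_fit.top,
        pka=sol_fit.pka, slope=sol_fit.slope,
        mode="anchored",
        valid_ph_range=(lo, hi),
        anchor=(float(anchor_ph), float(anchor_ratio)),
        source={"kind": "anchored", "scale": k, "solution_pka": sol_fit.pka},
    )


@dataclass(frozen=True)
class PHResult:
    """Interpolated pH with QC flags (flags are data, not exceptions)."""

    ph: float  # NaN when non-interpolatable
    ratio: float
    non_interpolatable: bool = False
    side: str | None = None  # "above" | "below" the valid ratio range
    extrapolated: bool = False  # pH outside the curve's valid pH range

    @property
    def ok(self) -> bool:
        return not self.non_interpolatable


def interpolate_ph(ratio, curve: CalibrationCurve):
    """Invert the calibration sigmoid for one ratio or an array of ratios.

    Ratios within ``guard_fraction * (top - bottom)`` of either asymptote
    (or beyond) are flagged non-interpolatable with the offending side;
    interpolations landing outside the curve's valid pH range are
    returned but flagged extrapolated.
    """
    arr = np.asarray(ratio, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)

    b, t, k, s = curve.bottom, curve.top, curve.pka, curve.slope
    guard = curve.guard_fraction * (t - b)
    below = arr <= b + guard
    above = arr >= t - guard
    ok = ~(below | above)

    ph = np.full(arr.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ph[ok] = k + np.log10((t - arr[ok]) / (arr[ok] - b)) / s
    lo, hi = curve.valid_ph_range
    extrap = ok & ((ph < lo) | (ph > hi))

    results = [
        PHResult(
            ph=float(ph[i]),
            ratio=float(arr[i]),
            non_interpolatable=bool(below[i] | above[i]),
            side="above" if above[i] else ("below" if below[i] else None),
            extrapolated=bool(extrap[i]),
        )
        for i in range(arr.size)
    ]
    return results[0] if scalar else results


def interpolate_ph_values(ratios: Sequence[float], curve: CalibrationCurve):
    """Vectorized helper: (pH array with NaN for flagged, ok mask)."""
    res = interpolate_ph(np.asarray(ratios, float), curve)
    if isinstance(res, PHResult):
        res = [res]
    ph = np.array([r.ph for r in res])
    ok = np.array([r.ok for r in res])
    return ph, ok
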