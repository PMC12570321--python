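"""Titration fitting and solution spectroscopy.

Implements the plate-reader side of ratiometric pH probe characterization:

* 4-parameter logistic fits of signal-vs-pH titrations (pKa extraction),
* fold-change dynamic range between two pH values,
* relative quantum yield from integrated fluorescence-vs-absorbance slopes,
* extinction coefficient via Beer's law, and
* dye:dextran labeling stoichiometry from absorbance.

All fits are ordinary least squares; replicates enter as individual points
(not pre-averaged) so parameter standard errors reflect replicate scatter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .probes import ProbeModel, sigmoid_value

__all__ = [
    "TitrationSeries",
    "SigmoidFit",
    "QuantumYieldResult",
    "ExtinctionResult",
    "DynamicRange",
    "blank_subtract",
    "fit_sigmoid",
    "dynamic_range",
    "quantum_yield",
    "extinction_coefficient",
    "labeling_ratio",
    "sigmoid_value",
]

_ASSAYS = ("absorbance", "fluorescence", "ratio")

#: Convergence defaults for the logistic fit.
FIT_XTOL = 1e-12
FIT_MAX_NFEV = 10_000


@dataclass
class TitrationSeries:
    """Replicate signal measurements on a pH grid for one probe/channel.

    ``points`` is a tidy frame with columns ``ph``, ``signal``,
    ``replicate`` (CSV schema adds ``probe`` and ``assay`` columns).
    """

    label: str
    points: pd.DataFrame
    assay: str = "fluorescence"
    blank_corrected: bool = False
    negative_after_blank: bool = False

    def __post_init__(self) -> None:
        if self.assay not in _ASSAYS:
            raise ValueError(f"assay must be one of {_ASSAYS}")
        pts = pd.DataFrame(self.points)
        if "replicate" not in pts.columns:
            pts = pts.assign(replicate=0)
        pts = pts[["ph", "signal", "replicate"]].astype(
            {"ph": float, "signal": float}
        )
        if not np.isfinite(pts["ph"]).all() or not np.isfinite(pts["signal"]).all():
            raise ValueError("non-finite pH or signal values")
        if ((pts["ph"] < 0) | (pts["ph"] > 14)).any():
            raise ValueError("pH values outside [0, 14]")
        self.points = pts.reset_index(drop=True)

    @classmethod
    def from_arrays(
        cls,
        ph: Sequence[float],
        signal: Sequence[float],
        replicate: Sequence[int] | None = None,
        label: str = "",
        assay: str = "fluorescence",
        **kw,
    ) -> "TitrationSeries":
        ph = np.asarray(ph, float)
        signal = np.asarray(signal, float)
        rep = np.zeros(ph.size, int) if replicate is None else np.asarray(replicate)
        return cls(
            label, pd.DataFrame({"ph": ph, "signal": signal, "replicate": rep}),
            assay=assay, **kw,
        )

    @property
    def ph(self) -> np.ndarray:
        return self.points["ph"].to_numpy()

    @property
    def signal(self) -> np.ndarray:
        return self.points["signal"].to_numpy()

    def n_distinct_ph(self) -> int:
        return int(np.unique(np.round(self.ph, 6)).size)

    def mean_by_ph(self) -> pd.DataFrame:
        """Replicate-averaged signal per pH, sorted by pH."""
        return (
            self.points.groupby("ph", as_index=False)["signal"]
            .mean()
            .sort_values("ph", ignore_index=True)
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame in the CSV schema: ph, signal, replicate, probe, assay."""
        return self.points.assign(probe=self.label, assay=self.assay)[
            ["ph", "signal", "replicate", "probe", "assay"]
        ]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str | None = None) -> "TitrationSeries":
        df = pd.read_csv(path)
        if label is not None and "probe" in df.columns:
            df = df[df["probe"] == label]
        name = label or (str(df["probe"].iloc[0]) if "probe" in df.columns else "")
        assay = str(df["assay"].iloc[0]) if "assay" in df.columns else "fluorescence"
        return cls.from_arrays(
            df["ph"], df["signal"],
            df["replicate"] if "replicate" in df.columns else None,
            label=name, assay=assay,
        )


@dataclass
class SigmoidFit:
    """4-parameter logistic fit result (``top >= bottom`` canonical form)."""

    bottom: float
    top: float
    pka: float
    slope: float
    se: dict = field(default_factory=dict)
    rss: float = np.nan
    n_points: int = 0
    converged: bool = True
    extrapolated: bool = False  # pKa outside fitted pH range +- 1
    message: str = ""

    def value(self, ph):
        return sigmoid_value(self, ph)


class DegenerateInputError(ValueError):
    """Raised for inputs a fit cannot be attempted on (e.g. constant signal)."""


class UndefinedFoldError(ValueError):
    """Raised when a fold-change would divide by a non-positive signal."""


def blank_subtract(
    series: TitrationSeries, blanks: TitrationSeries, match_tol: float = 0.05
) -> TitrationSeries:
    """Subtract the per-pH mean blank signal from a titration.

    Blanks are matched to sample pH exactly or to the nearest blank pH
    within ``match_tol``. Negative corrected signals are retained, not
    clipped, and the series is flagged.
    """
    blank_mean = blanks.mean_by_ph()
    bph = blank_mean["ph"].to_numpy()
    bsig = blank_mean["signal"].to_numpy()

    out = series.points.copy()
    missing = []
    corrected = np.empty(len(out))
    for i, (p, s) in enumerate(zip(out["ph"], out["signal"])):
        j = int(np.argmin(np.abs(bph - p)))
        if abs(bph[j] - p) > match_tol:
            missing.append(p)
        else:
            corrected[i] = s - bsig[j]
    if missing:
        raise ValueError(
            "no blank within %.2f pH of: %s"
            % (match_tol, sorted(set(np.round(missing, 3))))
        )
    out["signal"] = corrected
    return TitrationSeries(
        series.label, out, assay=series.assay,
        blank_corrected=True,
        negative_after_blank=bool((corrected < 0).any()),
    )


def _model(ph, bottom, top, pka, slope):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (ph - pka)))


def fit_sigmoid(series: TitrationSeries | pd.DataFrame, weights=None) -> SigmoidFit:
    """Least-squares 4-parameter logistic fit of a titration.

    Initialization is deterministic: bottom = min signal, top = max
    signal, pKa = pH of the point nearest mid-range signal, slope = +-1
    from the rank correlation sign of signal vs pH. Both polarities are
    representable; the result is canonicalized so ``top >= bottom``
    (swapping asymptotes and negating slope leaves the curve unchanged).
    """
    if not isinstance(series, TitrationSeries):
        series = TitrationSeries("", series)
    if series.n_distinct_ph() < 4:
        raise DegenerateInputError("need >= 4 distinct pH values to fit")
    ph, sig = series.ph, series.signal
    if np.ptp(sig) == 0:
        raise DegenerateInputError("constant signal: sigmoid fit is degenerate")

    lo, hi = float(sig.min()), float(sig.max())
    mid_idx = int(np.argmin(np.abs(sig - (lo + hi) / 2.0)))
    rho = stats.spearmanr(ph, sig).statistic
    slope0 = -1.0 if rho > 0 else 1.0  # signal rising with pH => base-bright
    p0 = np.array([lo, hi, float(ph[mid_idx]), slope0])

    w = np.ones_like(sig) if weights is None else np.asarray(weights, float)

    def resid(p):
        return w * (_model(ph, *p) - sig)

    res = optimize.least_squares(
        resid, p0, method="lm", xtol=FIT_XTOL, ftol=FIT_XTOL, gtol=FIT_XTOL,
        max_nfev=FIT_MAX_NFEV,
    )
    bottom, top, pka, slope = res.x
    if bottom > top:  # canonical form, same curve
        bottom, top, slope = top, bottom, -slope
    rss = float(2.0 * res.cost)
    n, k = sig.size, 4
    se = {}
    if n > k:
        try:
            jtj_inv = np.linalg.inv(res.jac.T @ res.jac)
            sigma2 = rss / (n - k)
            errs = np.sqrt(np.clip(np.diag(jtj_inv) * sigma2, 0, None))
            se = dict(zip(("bottom", "top", "pka", "slope"), map(float, errs)))
        except np.linalg.LinAlgError:
            pass
    extrap = not (ph.min() - 1.0 <= pka <= ph.max() + 1.0)
    return SigmoidFit(
        bottom=float(bottom), top=float(top), pka=float(pka), slope=float(slope),
        se=se, rss=rss, n_points=int(n),
        converged=bool(res.status > 0), extrapolated=extrap,
        message=res.message,
    )


@dataclass(frozen=True)
class DynamicRange:
    fold: float
    brighter_at: float  # the pH with the larger signal
    dimmer_at: float


def dynamic_range(fit, ph_lo: float, ph_hi: float) -> DynamicRange:
    """Fold-change of the fitted signal between two pH values (>= 1)."""
    if not ph_lo < ph_hi:
        raise ValueError("require ph_lo < ph_hi")
    v_lo = float(sigmoid_value(fit, ph_lo))
    v_hi = float(sigmoid_value(fit, ph_hi))
    vmin, vmax = min(v_lo, v_hi), max(v_lo, v_hi)
    if vmin <= 0:
        raise UndefinedFoldError(
            f"signal {vmin:g} <= 0 at one endpoint; fold-change undefined"
        )
    brighter, dimmer = (ph_lo, ph_hi) if v_lo >= v_hi else (ph_hi, ph_lo)
    return DynamicRange(fold=vmax / vmin, brighter_at=brighter, dimmer_at=dimmer)


def _ols(x, y):
    """Slope, intercept, r^2 of an ordinary least-squares line."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2:
        raise ValueError("need >= 2 points for a line")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


@dataclass(frozen=True)
class QuantumYieldResult:
    phi_unknown: float
    phi_standard: float
    slope_unknown: float
    slope_standard: float
    label: str = ""


def quantum_yield(
    unknown_pairs: Sequence[tuple[float, float]],
    standard_pairs: Sequence[tuple[float, float]],
    phi_standard: float,
    label: str = "",
) -> QuantumYieldResult:
    """Relative quantum yield from fluorescence-vs-absorbance slopes.

    Each pair is (integrated absorbance A, integrated fluorescence F) for
    one dilution. Lines get a free intercept; the yield is

        phi_unknown = phi_standard * m_unknown / m_standard.

    Absorbances above 0.1 are outside the usual linear regime and trigger
    a warning (not an error).
    """
    a_u, f_u = np.asarray(unknown_pairs, float).T
    a_s, f_s = np.asarray(standard_pairs, float).T
    if (a_u > 0.1).any() or (a_s > 0.1).any():
        warnings.warn(
            "absorbance > 0.1: inner-filter effects may bias the slope",
            stacklevel=2,
        )
    m_u, _, _ = _ols(a_u, f_u)
    m_s, _, _ = _ols(a_s, f_s)
    if m_s <= 0:
        raise ValueError("standard slope must be positive")
    return QuantumYieldResult(
        phi_unknown=phi_standard * m_u / m_s,
        phi_standard=phi_standard,
        slope_unknown=m_u,
        slope_standard=m_s,
        label=label,
    )


@dataclass(frozen=True)
class ExtinctionResult:
    epsilon: float  # M^-1 cm^-1
    path_length: float  # cm
    intercept: float
    r_squared: float


def extinction_coefficient(
    points: Sequence[tuple[float, float]], path_length: float = 1.0
) -> ExtinctionResult:
    """Molar extinction coefficient from Beer's law, A = eps * b * c.

    ``points`` are (concentration in M, absorbance) pairs; eps is the
    fitted A-vs-c slope divided by the path length ``b`` (cm). The free
    intercept is reported so blank errors stay visible.
    """
    if path_length <= 0:
        raise ValueError("path_length must be positive")
    c, a = np.asarray(points, float).T
    slope, intercept, r2 = _ols(c, a)
    eps = slope / path_length
    if eps <= 0:
        raise ValueError("fitted extinction coefficient is not positive")
    return ExtinctionResult(eps, path_length, intercept, r2)


def labeling_ratio(
    absorbance: float,
    epsilon: float,
    path_length: float,
    dextran_mass_conc: float,
    dextran_mw: float,
) -> float:
    """Dye:dextran molar ratio from dye absorbance.

    dye molarity = A / (eps * b); dextran molarity = mass concentration
    (mg/mL == g/L) / molecular weight (kDa -> g/mol).
    """
    if min(absorbance, epsilon, path_length, dextran_mass_conc, dextran_mw) <= 0:
        raise ValueError("all inputs must be positive")
    dye_molar = absorbance / (epsilon * path_length)
    dextran_molar = dextran_mass_conc / (dextran_mw * 1000.0)
    return dye_molar / dextran_molar
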