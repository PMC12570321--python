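"""Probe response models.

A pH-sensitive fluorophore's signal (or the pH-sensitive/pH-independent
ratio of a dual-labeled dextran) follows a 4-parameter logistic in pH:

    S(pH) = bottom + (top - bottom) / (1 + 10^(slope * (pH - pKa)))

With ``slope > 0`` the probe is *acid-bright* (signal falls as pH rises,
like ApHID); ``slope < 0`` is *base-bright* (fluorescein, Oregon Green).
The inflection point pKa is the fitted log IC50 of the titration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ProbeModel", "sigmoid_value", "APHID_LIKE", "FLUORESCEIN_LIKE"]


@dataclass(frozen=True)
class ProbeModel:
    """Ground-truth 4-parameter logistic response of a probe.

    Parameters
    ----------
    name : str
        Human-readable probe label.
    bottom, top : float
        Asymptotic signals (a.u.); ``top > bottom >= 0``.
    pka : float
        pH at the inflection (log IC50 of the titration).
    slope : float
        Signed Hill-type slope; positive means acid-bright.
    """

    name: str
    bottom: float
    top: float
    pka: float
    slope: float

    def __post_init__(self) -> None:
        for field in ("bottom", "top", "pka", "slope"):
            if not np.isfinite(getattr(self, field)):
                raise ValueError(f"non-finite probe parameter {field!r}")
        if not self.top > self.bottom >= 0:
            raise ValueError("require top > bottom >= 0")
        if self.slope == 0:
            raise ValueError("slope must be nonzero")

    @property
    def polarity(self) -> str:
        """``acid_bright`` or ``base_bright``, redundant with slope sign."""
        return "acid_bright" if self.slope > 0 else "base_bright"

    def value(self, ph):
        return sigmoid_value(self, ph)


def sigmoid_value(params, ph):
    """Evaluate the 4-parameter logistic at ``ph``.

    ``params`` is anything exposing ``bottom``, ``top``, ``pka`` and
    ``slope`` attributes (a :class:`ProbeModel`, a fitted sigmoid, or a
    calibration curve). Accepts scalars or arrays.
    """
    ph = np.asarray(ph, dtype=float)
    b, t, k, s = params.bottom, params.top, params.pka, params.slope
    out = b + (t - b) / (1.0 + np.power(10.0, s * (ph - k)))
    return out if out.ndim else float(out)


#: ApHID-like acid-bright ratio response. bottom/top/slope were solved so
#: that value(pH 4)/value(pH 6) ~= 12.8 with pKa 5.4, i.e. the ~13-fold
#: dynamic range of the probe between pH 4 and 6.
APHID_LIKE = ProbeModel("ApHID-like", bottom=0.02, top=1.0, pka=5.4, slope=2.0)

#: Fluorescein-like base-bright response (pKa 6.5, ~7x brighter at pH 6
#: than pH 4; brightness increases with alkalinity).
FLUORESCEIN_LIKE = ProbeModel(
    "fluorescein-like", bottom=0.035, top=1.0, pka=6.5, slope=-1.0
)
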