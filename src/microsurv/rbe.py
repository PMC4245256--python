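"""Iso-survival RBE-weighted dose conversion.

A photon reference dose-response curve is tabulated once from the model
assembly; any model SF is then converted to the photon dose giving the same
SF.  Only the monotone high-dose branch of the reference is invertible: the
low-dose bystander dip is excised, and requests outside the attainable SF
range raise with the bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .assembly import BroadbeamField, CellSystemModel, total_survival
from .microdose import SingleEventSpectrum

__all__ = ["ReferenceCurve", "build_reference", "rbe_weighted_dose", "rbe"]


@dataclass
class ReferenceCurve:
    """Tabulated photon dose-response with a monotone invertible branch."""

    doses: np.ndarray
    survival: np.ndarray
    _interp: CubicSpline = field(init=False, repr=False)
    _lo: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if d.ndim != 1 or d.shape != s.shape or d.size < 3:
            raise ValueError("need matching 1-D dose/survival arrays (>= 3 points)")
        if np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(s <= 0) or np.any(s > 1.0 + 1e-12):
            raise ValueError("survival must lie in (0, 1]")
        self.doses, self.survival = d, s
        # longest strictly-decreasing tail = invertible branch
        lo = d.size - 1
        while lo > 0 and s[lo - 1] > s[lo]:
            lo -= 1
        if d.size - lo < 3:
            raise ValueError("no monotone decreasing branch to invert")
        self._lo = lo
        # spline in log-survival: exact for linear-quadratic curves and
        # smooth for the model assembly's high-dose branch
        self._interp = CubicSpline(d[lo:], np.log(s[lo:]), extrapolate=False)

    @property
    def invertible_doses(self) -> tuple[float, float]:
        return float(self.doses[self._lo]), float(self.doses[-1])

    @property
    def invertible_survival(self) -> tuple[float, float]:
        """(min, max) SF attainable on the invertible branch."""
        return float(self.survival[-1]), float(self.survival[self._lo])

    def evaluate(self, dose: float) -> float:
        """SF on the monotone branch at the given photon dose."""
        lo, hi = self.invertible_doses
        if not (lo <= dose <= hi):
            raise ValueError(f"dose {dose} outside invertible branch [{lo}, {hi}]")
        return float(np.exp(self._interp(dose)))

    def invert(self, s: float) -> float:
        """Photon dose on the monotone branch with the given SF."""
        s_lo, s_hi = self.invertible_survival
        if not (s_lo <= s <= s_hi):
            raise ValueError(
                f"survival {s} outside the invertible range [{s_lo}, {s_hi}] "
                f"of the reference curve (doses {self.invertible_doses})"
            )
        d_lo, d_hi = self.invertible_doses
        logs = math.log(s)
        f = lambda d: float(self._interp(d)) - logs
        if f(d_lo) <= 0:
            return d_lo
        if f(d_hi) >= 0:
            return d_hi
        return float(brentq(f, d_lo, d_hi, xtol=1e-13, rtol=8.9e-16))


def build_reference(
    model: CellSystemModel,
    photon_domain_spec: SingleEventSpectrum,
    photon_nucleus_spec: SingleEventSpectrum,
    dose_grid,
) -> ReferenceCurve:
    """Tabulate the photon SF curve of the model assembly on ``dose_grid``."""
    doses = np.asarray(dose_grid, dtype=float)
    if doses.size < 3:
        raise ValueError("dose grid too narrow (need >= 3 points)")
    surv = np.array(
        [total_survival(model, BroadbeamField(photon_domain_spec, photon_nucleus_spec, float(d)))
         for d in doses]
    )
    return ReferenceCurve(doses=doses, survival=np.minimum(surv, 1.0))


def rbe_weighted_dose(s: float, ref: ReferenceCurve) -> float:
    """Photon dose on the reference curve giving the same SF."""
    return ref.invert(s)


def rbe(s: float, absorbed_dose: float, ref: ReferenceCurve) -> float:
    """RBE = iso-survival photon dose / absorbed dose."""
    if absorbed_dose <= 0:
        raise ValueError("absorbed dose must be positive")
    return rbe_weighted_dose(s, ref) / absorbed_dose
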