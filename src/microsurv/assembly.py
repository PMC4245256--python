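"""Composition of the survival channels and experimental decomposition.

Total SF is the product of the targeted and nontargeted channels,

    S = S_T * S_NT,      S_T = x*S_C + (1-x)*S_C*S_B,

and conversely paired measurements on Bcl-2 overexpressing (x = 1) and
control (x = 0) populations decompose as S_B = S_neo/S_bcl2 and
S_C = S_bcl2/S_NT(calculated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Union

import numpy as np

from .microdose import (
    MicrobeamDesign,
    SingleEventSpectrum,
    SpecificEnergyPD,
    microbeam_pd,
    multi_event_pd,
)
from .nontargeted import NTParams, survival_nt
from .targeted import DSMKParams, bcl2_mixture, get_domain_response

__all__ = [
    "CellSystemModel",
    "BroadbeamField",
    "MicrobeamField",
    "SurvivalBreakdown",
    "total_survival",
    "survival_breakdown",
    "derive_SB_exp",
    "derive_SC_exp",
]


@dataclass(frozen=True)
class CellSystemModel:
    """Full parameter set for one cell system: the two targeted channels,
    the nontargeted channel, and the Bcl-2 overexpressing fraction x."""

    targeted_conventional: DSMKParams
    targeted_bcl2: DSMKParams
    nontargeted: NTParams
    x: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.x <= 1.0):
            raise ValueError("x must lie in [0, 1]")
        if self.targeted_conventional.r_n != self.targeted_bcl2.r_n:
            raise ValueError("the two targeted channels must share r_n")


@dataclass(frozen=True)
class BroadbeamField:
    """Uniform-field irradiation described by domain- and nucleus-scale
    single-event spectra and the mean absorbed dose."""

    domain_spec: SingleEventSpectrum
    nucleus_spec: SingleEventSpectrum
    dose: float

    def nucleus_pd(self) -> SpecificEnergyPD:
        return multi_event_pd(self.nucleus_spec, self.dose)


@dataclass(frozen=True)
class MicrobeamField:
    """Microbeam irradiation: a two-point nucleus PD plus the domain-scale
    spectrum used for the (tiny) targeted response of the hit cells."""

    domain_spec: SingleEventSpectrum
    design: MicrobeamDesign

    @property
    def dose(self) -> float:
        return self.design.mean_dose

    def nucleus_pd(self) -> SpecificEnergyPD:
        return microbeam_pd(self.design)


Field = Union[BroadbeamField, MicrobeamField]


class SurvivalBreakdown(NamedTuple):
    s: float
    s_t: float
    s_nt: float
    s_c: float
    s_b: float


def survival_breakdown(model: CellSystemModel, field: Field) -> SurvivalBreakdown:
    """Channel-by-channel SF for one irradiation condition."""
    pd = field.nucleus_pd()
    zmax = 1.0
    if pd.grid.size:
        zmax = max(zmax, float(pd.grid[-1]))
    if pd.atoms_z.size:
        zmax = max(zmax, float(pd.atoms_z.max()))
    s_c = get_domain_response(field.domain_spec, model.targeted_conventional, zmax).survival_over(pd)
    s_b = get_domain_response(field.domain_spec, model.targeted_bcl2, zmax).survival_over(pd)
    s_t = bcl2_mixture(min(s_c, 1.0), min(s_b, 1.0), model.x)
    s_nt = survival_nt(pd, model.nontargeted)
    return SurvivalBreakdown(s=s_t * s_nt, s_t=s_t, s_nt=s_nt, s_c=s_c, s_b=s_b)


def total_survival(model: CellSystemModel, field: Field) -> float:
    """Total SF, S = S_T * S_NT."""
    return survival_breakdown(model, field).s


def _ratio(num, den, what: str):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    if np.any(den <= 0):
        raise ValueError(f"denominator of {what} must be positive")
    r = num / den
    if np.any(r > 1.0):
        warnings.warn(f"{what} ratio exceeded 1 (noise inverted the pair); clipping to 1", stacklevel=3)
        r = np.minimum(r, 1.0)
    return float(r) if r.ndim == 0 else r


def derive_SB_exp(s_neo, s_bcl2):
    """Bcl-2-channel SF from a paired measurement: S_B = S_neo / S_bcl2,
    clipped at 1 with a warning when noise inverts the ratio."""
    return _ratio(s_neo, s_bcl2, "S_B")


def derive_SC_exp(s_bcl2, s_nt_cal):
    """Conventional-channel SF with the calculated nontargeted contribution
    removed: S_C = S_bcl2 / S_NT, clipped at 1 with a warning."""
    return _ratio(s_bcl2, s_nt_cal, "S_C")
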