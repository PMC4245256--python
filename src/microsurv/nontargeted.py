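"""Bystander (nontargeted) survival channel.

Irradiated cells turn into apoptotic-signal emitters with a probability
that rises steeply with their nucleus specific energy; signals propagate
through the whole population, and a fraction of the signal-receiving cells
whose own specific energy is below a threshold are inactivated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .microdose import SpecificEnergyPD, ValidationError

__all__ = [
    "NTParams",
    "trigger_probability",
    "signal_fraction",
    "escape_probability",
    "survival_nt",
]


@dataclass(frozen=True)
class NTParams:
    """Nontargeted-channel parameters.

    a1, a2  : trigger-probability scale and power index (z_n in Gy)
    eta     : fraction of cells receiving the signal from one emitter
    kappa   : fraction of signal-receiving, below-threshold cells inactivated
    z_thre  : threshold nucleus specific energy, Gy (math.inf allowed)
    n_population : number of cells in the whole population, N_W
    """

    a1: float
    a2: float
    eta: float
    kappa: float
    z_thre: float
    n_population: float

    def __post_init__(self) -> None:
        if self.a1 < 0:
            raise ValidationError("a1 must be >= 0")
        if self.a2 <= 0:
            raise ValidationError("a2 must be > 0")
        if not (0.0 <= self.eta <= 1.0):
            raise ValidationError("eta must lie in [0, 1]")
        if not (0.0 <= self.kappa <= 1.0):
            raise ValidationError("kappa must lie in [0, 1]")
        if not (self.z_thre > 0):
            raise ValidationError("z_thre must be > 0 (math.inf allowed)")
        if self.n_population < 1:
            raise ValidationError("n_population must be >= 1")


def trigger_probability(z_n, params: NTParams):
    """Probability that a cell with nucleus specific energy z_n becomes a
    signal emitter: 1 - exp(-a1 * z_n**a2).

    Zero at z_n = 0, non-decreasing, saturating at 1; the free power index
    a2 sets how steeply the trigger switches on.
    """
    scalar = np.isscalar(z_n)
    z = np.asarray(z_n, dtype=float)
    if np.any(z < 0):
        raise ValueError("z_n must be >= 0")
    with np.errstate(over="ignore"):  # huge a1*z**a2 just saturates P_T at 1
        out = -np.expm1(-params.a1 * z**params.a2)
    return float(out) if scalar else out


def signal_fraction(nucleus_pd: SpecificEnergyPD, params: NTParams) -> float:
    """Fraction of signal-emitting cells in the field: E[P_T(z_n)].

    The zero mass contributes nothing since P_T(0) = 0.
    """
    total = nucleus_pd.total_mass()
    if abs(total - 1.0) > 1e-5:
        raise ValidationError(f"nucleus PD not normalised (total mass {total})")
    out = nucleus_pd.expect(lambda z: trigger_probability(z, params), value_at_zero=0.0)
    return min(max(out, 0.0), 1.0)  # quadrature roundoff guard


def escape_probability(p_s: float, params: NTParams) -> float:
    """Probability that a given cell receives no signal from any of the
    other N_W - 1 cells: (1 - eta * P_S)**(N_W - 1).

    This closes the binomial sum over the number of emitters among the
    other cells, each reaching the cell with probability eta.  Evaluated in
    log space; N_W up to several 1e6 underflows naive powering.
    """
    if not (0.0 <= p_s <= 1.0):
        raise ValueError(f"P_S must lie in [0, 1], got {p_s}")
    q = params.eta * p_s
    if q >= 1.0:
        return 0.0
    return float(math.exp((params.n_population - 1.0) * math.log1p(-q)))


def survival_nt(nucleus_pd: SpecificEnergyPD, params: NTParams) -> float:
    """Nontargeted-channel SF:

        S_NT = 1 - kappa * (1 - P_E) * P(z_n < z_thre)

    i.e. one minus the inactivated fraction: cells must receive a signal
    (probability 1 - P_E) and sit below the threshold specific energy; of
    those, a fraction kappa dies.  The below-threshold factor doubles as
    the synergy correction between the channels: heavily hit cells stop
    responding to the signal.  Bounded in [1 - kappa, 1].
    """
    p_s = signal_fraction(nucleus_pd, params)
    p_e = escape_probability(p_s, params)
    below = nucleus_pd.mass_below(params.z_thre)
    below = min(below, 1.0)
    return 1.0 - params.kappa * (1.0 - p_e) * below
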