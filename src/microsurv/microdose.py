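"""Probability densities of specific energy at domain and nucleus scales.

Specific energy z (Gy) is the stochastic analogue of absorbed dose in a
microscopic site.  Broadbeam fields are represented by compound-Poisson
multi-event distributions built from a single-event spectrum; microbeam
fields by two-point distributions (irradiated / non-irradiated cells).

All distributions carry an explicit discrete mass at z = 0 (cells receiving
no energy deposit) plus, optionally, further point masses at z > 0; the
continuous part is a per-Gy density tabulated on an increasing grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "SingleEventSpectrum",
    "SpecificEnergyPD",
    "MicrobeamDesign",
    "lineal_to_specific",
    "specific_to_lineal",
    "multi_event_pd",
    "microbeam_pd",
    "conditional_domain_pd",
]

#: Conversion constant for a unit-density sphere: z[Gy] = LINEAL_FACTOR * y / d^2
#: with y in keV/um and the diameter d in um.  Derived from z = 4*eps/(rho*pi*d^2)
#: and eps = y * (2d/3) with the keV->J and um^3->kg unit factors folded in.
LINEAL_FACTOR = 0.204

_NORM_TOL = 1e-6
_MEAN_TOL = 1e-4


class ValidationError(ValueError):
    """Raised when a distribution fails its structural invariants."""


def lineal_to_specific(y: float, diameter: float) -> float:
    """Specific energy (Gy) of a single event of lineal energy *y* (keV/um)
    in a unit-density sphere of *diameter* um."""
    if diameter <= 0:
        raise ValueError(f"diameter must be positive, got {diameter}")
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("lineal energy must be non-negative")
    out = LINEAL_FACTOR * y / diameter**2
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def specific_to_lineal(z: float, diameter: float) -> float:
    """Inverse of :func:`lineal_to_specific`."""
    if diameter <= 0:
        raise ValueError(f"diameter must be positive, got {diameter}")
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("specific energy must be non-negative")
    out = z * diameter**2 / LINEAL_FACTOR
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


@dataclass(frozen=True)
class SingleEventSpectrum:
    """Single-event specific-energy density for one site size and radiation.

    Parameters
    ----------
    site_radius : float
        Radius of the (spherical) site, um.
    zbar_F : float
        Frequency-mean specific energy per event, Gy (first moment of the
        density).
    grid : ndarray
        Strictly increasing specific-energy values, Gy.
    density : ndarray
        Per-Gy probability density on ``grid``; trapezoidal integral must
        be 1 within 1e-6 and its first moment must match ``zbar_F`` within
        1e-4 relative.
    """

    site_radius: float
    zbar_F: float
    grid: np.ndarray
    density: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        density = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "density", density)
        if self.site_radius <= 0:
            raise ValidationError(f"site_radius must be > 0, got {self.site_radius}")
        if grid.ndim != 1 or grid.shape != density.shape or grid.size < 2:
            raise ValidationError("grid/density must be matching 1-D arrays (>= 2 points)")
        if np.any(np.diff(grid) <= 0):
            raise ValidationError("grid must be strictly increasing")
        if grid[0] < 0:
            raise ValidationError("grid must be non-negative")
        if np.any(density < 0):
            raise ValidationError("density must be non-negative")
        norm = float(np.trapezoid(density, grid))
        if abs(norm - 1.0) > _NORM_TOL:
            raise ValidationError(f"density integrates to {norm!r}, expected 1 within {_NORM_TOL}")
        mean = float(np.trapezoid(grid * density, grid))
        if self.zbar_F <= 0:
            raise ValidationError("zbar_F must be positive")
        if abs(mean - self.zbar_F) > _MEAN_TOL * self.zbar_F:
            raise ValidationError(
                f"first moment {mean!r} does not match zbar_F {self.zbar_F!r} within {_MEAN_TOL} relative"
            )

    def moment(self, k: int) -> float:
        """k-th raw moment of the single-event density."""
        return float(np.trapezoid(self.grid**k * self.density, self.grid))

    @property
    def zbar_D(self) -> float:
        """Dose-mean specific energy per event, Gy (second moment / first)."""
        return self.moment(2) / self.moment(1)

    def rescaled(self, new_radius: float) -> "SingleEventSpectrum":
        """Same event population expressed in a site of a different radius.

        z scales with 1/d^2 at fixed energy imparted, so grid and zbar_F
        scale by (r_old/r_new)^2 and the density by the reciprocal.
        """
        if new_radius <= 0:
            raise ValueError("new_radius must be positive")
        s = (self.site_radius / new_radius) ** 2
        return SingleEventSpectrum(
            site_radius=new_radius,
            zbar_F=self.zbar_F * s,
            grid=self.grid * s,
            density=self.density / s,
            label=self.label,
        )


_EMPTY = np.empty(0)


@dataclass(frozen=True)
class SpecificEnergyPD:
    """Distribution of specific energy for a given mean absorbed dose.

    The distribution is a mixture of a point mass at z = 0 (``zero_mass``),
    optional point masses at z > 0 (``atoms_z``/``atoms_w``, used for
    microbeam fields) and a continuous per-Gy density on ``grid``.
    """

    dose: float
    zero_mass: float
    grid: np.ndarray = field(default_factory=lambda: _EMPTY)
    density: np.ndarray = field(default_factory=lambda: _EMPTY)
    atoms_z: np.ndarray = field(default_factory=lambda: _EMPTY)
    atoms_w: np.ndarray = field(default_factory=lambda: _EMPTY)

    def __post_init__(self) -> None:
        for name in ("grid", "density", "atoms_z", "atoms_w"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.dose < 0:
            raise ValidationError("dose must be >= 0")
        if not (0.0 <= self.zero_mass <= 1.0 + 1e-12):
            raise ValidationError(f"zero_mass must lie in [0, 1], got {self.zero_mass}")
        if self.grid.shape != self.density.shape:
            raise ValidationError("grid/density shape mismatch")
        if self.grid.size and np.any(np.diff(self.grid) <= 0):
            raise ValidationError("grid must be strictly increasing")
        if np.any(self.density < 0) or np.any(self.atoms_w < 0):
            raise ValidationError("density and atom weights must be non-negative")
        if self.atoms_z.shape != self.atoms_w.shape:
            raise ValidationError("atoms_z/atoms_w shape mismatch")
        if np.any(self.atoms_z <= 0):
            raise ValidationError("atoms must sit at z > 0")
        total = self.total_mass()
        if abs(total - 1.0) > _NORM_TOL:
            raise ValidationError(f"total probability {total!r} != 1 within {_NORM_TOL}")

    # -- probabilistic queries -------------------------------------------------

    def continuous_mass(self) -> float:
        if self.grid.size == 0:
            return 0.0
        return float(np.trapezoid(self.density, self.grid))

    def total_mass(self) -> float:
        return self.zero_mass + float(self.atoms_w.sum()) + self.continuous_mass()

    def mean(self) -> float:
        """First moment including all point masses."""
        m = float(np.dot(self.atoms_z, self.atoms_w))
        if self.grid.size:
            m += float(np.trapezoid(self.grid * self.density, self.grid))
        return m

    def expect(self, fn: Callable[[np.ndarray], np.ndarray], *, value_at_zero: float = None) -> float:
        """E[fn(Z)] over the full mixture.

        ``value_at_zero`` overrides fn(0) (useful when fn is tabulated for
        z > 0 only); by default fn is evaluated at 0.
        """
        if value_at_zero is None:
            value_at_zero = float(fn(np.asarray([0.0]))[0])
        out = self.zero_mass * value_at_zero
        if self.atoms_z.size:
            out += float(np.dot(fn(self.atoms_z), self.atoms_w))
        if self.grid.size:
            out += float(np.trapezoid(fn(self.grid) * self.density, self.grid))
        return out

    def mass_below(self, z_threshold: float) -> float:
        """P(Z < z_threshold); the zero mass always counts as below any
        positive threshold."""
        if np.isinf(z_threshold):
            return self.total_mass()
        if z_threshold <= 0:
            return 0.0
        out = self.zero_mass
        out += float(self.atoms_w[self.atoms_z < z_threshold].sum())
        if self.grid.size:
            g, f = self.grid, self.density
            if z_threshold >= g[-1]:
                out += float(np.trapezoid(f, g))
            elif z_threshold > g[0]:
                i = int(np.searchsorted(g, z_threshold))
                gg = np.concatenate([g[:i], [z_threshold]])
                ff = np.concatenate([f[:i], [np.interp(z_threshold, g, f)]])
                out += float(np.trapezoid(ff, gg))
            # below g[0]: continuous mass ~ 0 there
        return out

    def compress(self, n_nodes: int = 256) -> tuple[np.ndarray, np.ndarray]:
        """Mass-preserving quadrature nodes for the continuous part.

        Re-bins the density into at most ``n_nodes`` groups; each group is
        represented by its probability mass and conditional-mean z, which
        integrates piecewise-linear integrands exactly in the group mean.
        Point masses are not included (query ``atoms_z``/``atoms_w``).
        """
        if self.grid.size == 0:
            return _EMPTY, _EMPTY
        g, f = self.grid, self.density
        # cell masses on the tabulation grid (trapezoid pieces)
        dm = 0.5 * (f[1:] + f[:-1]) * np.diff(g)
        zc = 0.5 * (g[1:] + g[:-1])
        if dm.size <= n_nodes:
            keep = dm > 0
            return zc[keep], dm[keep]
        edges = np.array_split(np.arange(dm.size), n_nodes)
        nodes, weights = [], []
        for idx in edges:
            w = dm[idx].sum()
            if w <= 0:
                continue
            nodes.append(float(np.dot(zc[idx], dm[idx]) / w))
            weights.append(float(w))
        return np.asarray(nodes), np.asarray(weights)


@dataclass(frozen=True)
class MicrobeamDesign:
    """Microbeam irradiation layout: N_I cells each given dose_per_cell within
    a population of n_population cells."""

    n_irradiated: int
    n_population: int
    dose_per_cell: float

    def __post_init__(self) -> None:
        if self.n_population < 1:
            raise ValidationError("n_population must be >= 1")
        if not (0 <= self.n_irradiated <= self.n_population):
            raise ValidationError("need 0 <= n_irradiated <= n_population")
        if self.dose_per_cell < 0:
            raise ValidationError("dose_per_cell must be >= 0")

    @property
    def mean_dose(self) -> float:
        """Population-mean absorbed dose, Gy."""
        return self.n_irradiated * self.dose_per_cell / self.n_population


def microbeam_pd(design: MicrobeamDesign) -> SpecificEnergyPD:
    """Two-point nucleus PD for a microbeam field: mass N_I/N_W at the
    per-cell dose, the remainder at z = 0.

    The spread of specific energy among irradiated cells is neglected
    (particle counts per cell are controlled in microbeam experiments).
    """
    frac = design.n_irradiated / design.n_population
    if frac == 0.0 or design.dose_per_cell == 0.0:
        return SpecificEnergyPD(dose=design.mean_dose, zero_mass=1.0)
    return SpecificEnergyPD(
        dose=design.mean_dose,
        zero_mass=1.0 - frac,
        atoms_z=np.array([design.dose_per_cell]),
        atoms_w=np.array([frac]),
    )


# ---------------------------------------------------------------------------
# compound-Poisson multi-event distribution
# ---------------------------------------------------------------------------

def _lattice_pmf(spec: SingleEventSpectrum, h: float, m: int) -> np.ndarray:
    """Bin the single-event density into lattice cells of width h.

    Cell j collects the integral of the (piecewise-linear) density over
    ((j-1/2)h, (j+1/2)h].  Mass falling into cell 0 is pushed to cell 1 so
    that the z = 0 atom of the compound distribution stays purely Poissonian.
    """
    g, f = spec.grid, spec.density
    # CDF of the piecewise-linear density at arbitrary points
    cdf_g = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * np.diff(g))])

    def cdf(x: np.ndarray) -> np.ndarray:
        return np.interp(x, g, cdf_g, left=0.0, right=cdf_g[-1])

    edges = (np.arange(m + 1) - 0.5) * h
    p = np.diff(cdf(edges))
    if p[0] > 0:
        p[1] += p[0]
        p[0] = 0.0
    s = p.sum()
    if s <= 0:
        raise ValidationError("single-event spectrum has no mass on the lattice")
    return p / s


def _choose_lattice(spec: SingleEventSpectrum, dose: float, n_points: int | None,
                    z_max: float | None) -> tuple[float, int]:
    lam = dose / spec.zbar_F
    m2 = spec.moment(2)
    z1_max = float(spec.grid[-1])
    if z_max is None:
        z_max = dose + 12.0 * np.sqrt(max(lam, 1.0) * m2) + 4.0 * z1_max
    if n_points is None:
        # resolve the single-event scale, bounded for tractability
        span = max(spec.grid[1] - spec.grid[0], spec.zbar_F / 64.0)
        h_want = min(spec.zbar_F / 64.0, z1_max / 256.0)
        h_want = max(h_want, span / 1024.0)
        n = int(2 ** np.ceil(np.log2(max(z_max / h_want, 4096))))
        n_points = int(min(max(n, 4096), 2 ** 18))
    h = z_max / n_points
    return h, n_points


def multi_event_pd(
    spec: SingleEventSpectrum,
    dose: float,
    *,
    n_points: int | None = None,
    z_max: float | None = None,
) -> SpecificEnergyPD:
    """Multi-event specific-energy distribution at mean absorbed dose *dose*.

    Events arrive with Poisson statistics (mean event count dose / zbar_F)
    and i.i.d. sizes drawn from the single-event spectrum, i.e. the result
    is the compound-Poisson mixture sum_nu P(nu; lambda) f1^{*nu}.  It is
    evaluated exactly on a uniform lattice through the characteristic
    function, exp(lambda*(phi1 - 1)), which sums the whole Poisson series
    (tighter than any finite truncation).  The zero-event atom exp(-lambda)
    is kept analytic and never discretised.
    """
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    if dose == 0.0:
        return SpecificEnergyPD(dose=0.0, zero_mass=1.0)

    h, m = _choose_lattice(spec, dose, n_points, z_max)
    p = _lattice_pmf(spec, h, m)
    mean_hat = h * float(np.dot(np.arange(m), p))
    lam = dose / mean_hat  # lattice-consistent event rate: preserves the mean

    phi = np.fft.rfft(p)
    q = np.fft.irfft(np.exp(lam * (phi - 1.0)), n=m)
    np.maximum(q, 0.0, out=q)

    zero_mass = float(np.exp(-lam))
    q[0] = max(q[0] - zero_mass, 0.0)

    grid = h * np.arange(1, m)
    density = q[1:] / h
    density[0] += q[0] / h  # residual roundoff at the origin cell
    cont = float(np.trapezoid(density, grid))
    target = 1.0 - zero_mass
    if cont > 0:
        density = density * (target / cont)
    return SpecificEnergyPD(dose=dose, zero_mass=zero_mass, grid=grid, density=density)


def conditional_domain_pd(
    spec_domain: SingleEventSpectrum,
    z_n: float,
    *,
    n_points: int | None = None,
) -> SpecificEnergyPD:
    """Domain specific-energy PD conditional on a nucleus specific energy.

    Approximated as the domain-scale multi-event distribution at mean dose
    z_n (compound Poisson with lambda = z_n / zbar_F of the domain spectrum),
    so its mean is z_n and it is normalised by construction.
    """
    if z_n < 0:
        raise ValueError(f"z_n must be >= 0, got {z_n}")
    return multi_event_pd(spec_domain, z_n, n_points=n_points)
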