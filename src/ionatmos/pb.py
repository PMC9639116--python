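"""Nonlinear Poisson-Boltzmann theory around a uniformly charged cylinder.

The duplex is modeled as an infinite cylinder of radius ``R`` carrying a
constant surface charge density ``sigma`` (e/nm^2, negative for nucleic
acids).  In reduced units (phi in k_BT/e, lengths in nm) the mean-field
equation for the annulus R <= r <= R_max reads

    (1/r) d/dr ( r dphi/dr ) = -4 pi l_B  sum_i q_i n_i  exp(-q_i phi - V_i(r))

with l_B the Bjerrum length, n_i the bulk number density of species i and
V_i an optional ion-nucleic-acid interaction potential (PMF, in k_BT) that
extends the mean-field description with ion-specific structure.  Boundary
conditions: Neumann flux dphi/dr|_R = -4 pi l_B sigma at the surface and
Dirichlet phi = 0 at R_max, which is placed many Debye lengths out so the
profiles reach bulk.

The equation is discretized on a logarithmically spaced radial grid
(uniform in x = ln r, where the operator becomes e^{-2x} d^2 phi/dx^2) and
solved by a damped Newton iteration with analytic tridiagonal Jacobian;
a surface-charge continuation ramp serves as fallback for very stiff cases.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .constants import BJERRUM_NM, DEFAULT_DUPLEX_CHARGE, MOLAR_TO_PER_NM3

__all__ = [
    "CylinderModel",
    "IonSpecies",
    "PBSolution",
    "PBConvergenceError",
    "solve_pb",
    "solve_extended_pb",
    "debye_length",
    "load_pmf_table",
]


class PBConvergenceError(RuntimeError):
    """Newton iteration failed; carries the final residual."""

    def __init__(self, residual: float, message: str | None = None):
        self.residual = residual
        super().__init__(
            message or f"PB solver did not converge (residual {residual:.3e})"
        )


@dataclass(frozen=True)
class CylinderModel:
    """PB problem geometry: radius R, surface charge sigma, length h.

    ``length=None`` resolves to q_NA / (2 pi R |sigma|) with q_NA = 64 (the
    33-bp duplex), which makes the three printed parameters mutually
    consistent.  ``outer_radius=None`` resolves at solve time to
    R + 10 Debye lengths.
    """

    radius: float
    surface_charge: float
    length: float | None = None
    outer_radius: float | None = None

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.outer_radius is not None and self.outer_radius <= self.radius:
            raise ValueError("outer_radius must exceed radius")
        if self.length is None:
            if self.surface_charge == 0:
                raise ValueError("length must be given when surface_charge is 0")
            h = DEFAULT_DUPLEX_CHARGE / (
                2.0 * np.pi * self.radius * abs(self.surface_charge)
            )
            object.__setattr__(self, "length", h)
        if self.length <= 0:
            raise ValueError("length must be positive")

    @property
    def charge_magnitude(self) -> float:
        """|q_NA| implied by the cylinder: 2 pi R h |sigma|, in e."""
        return 2.0 * np.pi * self.radius * self.length * abs(self.surface_charge)


@dataclass(frozen=True)
class IonSpecies:
    """One mobile ion species: valence, bulk concentration, optional PMF.

    ``pmf`` is a two-column table (distance from the axis in nm, potential in
    k_BT); it is held at its first value below the tabulated range and
    clamped to zero beyond it.
    """

    label: str
    valence: int
    conc_molar: float
    pmf: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        if self.conc_molar < 0:
            raise ValueError("bulk concentration must be >= 0")
        if self.valence == 0:
            raise ValueError("valence must be nonzero")
        if self.pmf is not None:
            r, v = (np.asarray(a, float) for a in self.pmf)
            if r.ndim != 1 or r.shape != v.shape or r.size < 2:
                raise ValueError("pmf must be two equal-length 1-D columns")
            if np.any(np.diff(r) <= 0):
                raise ValueError("pmf distances must be strictly increasing")
            object.__setattr__(self, "pmf", (r, v))

    @property
    def number_density(self) -> float:
        """Bulk number density, nm^-3."""
        return self.conc_molar * MOLAR_TO_PER_NM3

    def pmf_on(self, r: np.ndarray) -> np.ndarray:
        """Evaluate the PMF on ``r`` with the clamp extrapolation rule."""
        if self.pmf is None:
            return np.zeros_like(r)
        rt, vt = self.pmf
        v = np.interp(r, rt, vt, left=vt[0], right=0.0)
        return v


def load_pmf_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column whitespace-delimited PMF table (r [nm], V [k_BT]);
    lines starting with '#' are comments."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"PMF table {path} must have two columns")
    return data[:, 0], data[:, 1]


@dataclass
class PBSolution:
    """Converged PB solution on the radial grid [R, R_max]."""

    r: np.ndarray
    phi: np.ndarray
    concentrations: dict[str, np.ndarray]
    cylinder: CylinderModel
    species: tuple[IonSpecies, ...]
    convergence_residual: float
    bjerrum_nm: float

    def concentration(self, label: str) -> np.ndarray:
        return self.concentrations[label]

    def to_frame(self) -> pd.DataFrame:
        cols = {"r_nm": self.r, "phi_kT_e": self.phi}
        for lab, c in self.concentrations.items():
            cols[f"c_{lab}_M"] = c
        return pd.DataFrame(cols)


def _check_bulk_neutrality(species) -> None:
    if not any(s.valence > 0 for s in species) or not any(
        s.valence < 0 for s in species
    ):
        raise ValueError("need at least one cation and one anion species")
    net = sum(s.valence * s.conc_molar for s in species)
    scale = sum(abs(s.valence) * s.conc_molar for s in species)
    if scale == 0:
        raise ValueError("all bulk concentrations are zero")
    if abs(net) > 1e-9 * scale:
        raise ValueError(
            f"bulk electrolyte is not electroneutral: sum q_i c_i = {net:g} M"
        )


def debye_length(
    species,
    temperature: float = 300.0,
    bjerrum_nm: float | None = None,
) -> float:
    """Debye screening length kappa^-1 = (8 pi l_B I)^{-1/2}, nm.

    I is the number-density ionic strength (1/2) sum q_i^2 n_i.  The default
    Bjerrum length (water, 300 K) is scaled as 300/T when a temperature is
    given without an explicit l_B.
    """
    lb = bjerrum_nm if bjerrum_nm is not None else BJERRUM_NM * 300.0 / temperature
    ionic = 0.5 * sum(s.valence**2 * s.number_density for s in species)
    if ionic <= 0:
        raise ValueError("zero ionic strength")
    return 1.0 / np.sqrt(8.0 * np.pi * lb * ionic)


def _solve_radial(
    cylinder: CylinderModel,
    species: tuple[IonSpecies, ...],
    pmf_matrix: np.ndarray,
    grid_size: int,
    tolerance: float,
    bjerrum_nm: float,
    max_iter: int,
) -> PBSolution:
    R = cylinder.radius
    rmax = cylinder.outer_radius
    if rmax is None:
        rmax = R + 10.0 * debye_length(species, bjerrum_nm=bjerrum_nm)
    r = np.geomspace(R, rmax, grid_size)
    x = np.log(r)
    dx = x[1] - x[0]
    lb = bjerrum_nm

    q = np.array([s.valence for s in species], float)[:, None]
    n = np.array([s.number_density for s in species], float)[:, None]
    boltz_v = np.exp(-pmf_matrix)  # (n_species, grid)

    pref = 4.0 * np.pi * lb * np.exp(2.0 * x)[None, :]

    def source(phi):
        # S(phi) = 4 pi l_B e^{2x} sum_i q_i n_i exp(-q_i phi - V_i)
        return np.sum(pref * q * n * boltz_v * np.exp(-q * phi[None, :]), axis=0)

    def dsource(phi):
        return np.sum(
            -pref * q**2 * n * boltz_v * np.exp(-q * phi[None, :]), axis=0
        )

    g = R * (-4.0 * np.pi * lb * cylinder.surface_charge)  # dphi/dx at x0
    scale = max(np.max(np.abs(pref) * np.sum(np.abs(q) * n)), abs(g) / dx**2, 1.0)

    def residual_vec(phi):
        F = np.zeros_like(phi)
        S = source(phi)
        F[0] = (2.0 * phi[1] - 2.0 * phi[0] - 2.0 * dx * g) / dx**2 + S[0]
        F[1:-1] = (phi[:-2] - 2.0 * phi[1:-1] + phi[2:]) / dx**2 + S[1:-1]
        F[-1] = phi[-1]  # Dirichlet
        return F

    def newton(phi, n_iter):
        res = np.inf
        for _ in range(n_iter):
            F = residual_vec(phi)
            res = np.max(np.abs(F[:-1])) / scale
            if res < tolerance:
                return phi, res
            dS = dsource(phi)
            # banded Jacobian: rows = (upper, diag, lower)
            ab = np.zeros((3, phi.size))
            ab[0, 1:] = 1.0 / dx**2  # superdiagonal
            ab[1, :] = -2.0 / dx**2 + dS
            ab[2, :-1] = 1.0 / dx**2  # subdiagonal
            ab[0, 1] = 2.0 / dx**2  # ghost-point Neumann row
            ab[1, -1] = 1.0
            ab[0, -1] = 0.0
            ab[2, -2] = 0.0
            delta = solve_banded((1, 1), ab, -F)
            lam, f0 = 1.0, np.max(np.abs(F[:-1]))
            for _ in range(30):
                trial = phi + lam * delta
                if np.max(np.abs(residual_vec(trial)[:-1])) < f0:
                    phi = trial
                    break
                lam *= 0.5
            else:
                phi = phi + lam * delta
        F = residual_vec(phi)
        return phi, np.max(np.abs(F[:-1])) / scale

    # Debye-Hueckel initial guess
    kappa = 1.0 / debye_length(species, bjerrum_nm=lb)
    from scipy.special import i0, i1, k0, k1

    alpha = k0(kappa * rmax) / i0(kappa * rmax)
    denom = kappa * (k1(kappa * R) + alpha * i1(kappa * R))
    A = 4.0 * np.pi * lb * cylinder.surface_charge / denom
    phi0 = A * (k0(kappa * r) - alpha * i0(kappa * r))
    phi0[-1] = 0.0

    phi, res = newton(phi0.copy(), max_iter)
    if res >= tolerance:
        # continuation in surface charge
        phi = np.zeros_like(r)
        full_sigma = cylinder.surface_charge
        for frac in (0.125, 0.25, 0.5, 0.75, 1.0):
            g_save = g
            g = R * (-4.0 * np.pi * lb * full_sigma * frac)
            phi, res = newton(phi, max_iter)
            g = g_save
        g = R * (-4.0 * np.pi * lb * full_sigma)
        phi, res = newton(phi, max_iter)
        if res >= tolerance:
            raise PBConvergenceError(res)

    conc = {}
    for i, s in enumerate(species):
        conc[s.label] = s.conc_molar * np.exp(
            -s.valence * phi - pmf_matrix[i]
        )
    return PBSolution(
        r=r,
        phi=phi,
        concentrations=conc,
        cylinder=dataclasses.replace(cylinder, outer_radius=rmax),
        species=tuple(species),
        convergence_residual=res,
        bjerrum_nm=lb,
    )


def solve_pb(
    cylinder: CylinderModel,
    species,
    grid_size: int = 2000,
    tolerance: float = 1e-10,
    bjerrum_nm: float = BJERRUM_NM,
    max_iter: int = 60,
) -> PBSolution:
    """Solve the standard nonlinear PB equation (PMFs ignored)."""
    species = tuple(species)
    _check_bulk_neutrality(species)
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    pmf_matrix = np.zeros((len(species), grid_size))
    return _solve_radial(
        cylinder, species, pmf_matrix, grid_size, tolerance, bjerrum_nm, max_iter
    )


def solve_extended_pb(
    cylinder: CylinderModel,
    species,
    grid_size: int = 2000,
    tolerance: float = 1e-10,
    bjerrum_nm: float = BJERRUM_NM,
    max_iter: int = 60,
) -> PBSolution:
    """Solve the extended PB equation with each species' PMF V_i(r) included
    in every Boltzmann factor.  With all V_i = 0 this reproduces
    :func:`solve_pb` exactly."""
    species = tuple(species)
    _check_bulk_neutrality(species)
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    R = cylinder.radius
    rmax = cylinder.outer_radius
    if rmax is None:
        rmax = R + 10.0 * debye_length(species, bjerrum_nm=bjerrum_nm)
    r = np.geomspace(R, rmax, grid_size)
    pmf_matrix = np.zeros((len(species), grid_size))
    for i, s in enumerate(species):
        if s.pmf is not None:
            rt, _ = s.pmf
            if rt[0] > rmax or rt[-1] < R:
                raise ValueError(
                    f"PMF table for {s.label} ([{rt[0]:g}, {rt[-1]:g}] nm) does "
                    f"not overlap the radial grid [{R:g}, {rmax:g}] nm"
                )
            v = s.pmf_on(r)
            if abs(v[-1]) >= 1e-3:
                raise ValueError(
                    f"PMF for {s.label} does not decay to 0 at R_max "
                    f"(|V(R_max)| = {abs(v[-1]):.2e} k_BT)"
                )
            pmf_matrix[i] = v
    return _solve_radial(
        cylinder,
        species,
        pmf_matrix,
        grid_size,
        tolerance,
        bjerrum_nm,
        max_iter,
    )
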