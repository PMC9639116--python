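"""Ion concentration profiles, ion-counting excess and helicoidal densities.

The central bookkeeping quantity is the cumulative ion excess around an
(assumed infinite) cylinder,

    Gamma_i(r) = N_A V_f h  Integral_0^r ( c_i(r') - c_i_inf ) 2 pi r' dr' ,

with N_A V_f converting mol/L to nm^-3, h the axial extent analyzed and
c_i_inf the bulk concentration read off at large r.  Gamma_i = Gamma_i(r_max)
is the total excess (positive for attracted cations, negative for depleted
anions); the mobile charge it carries balances the nucleic-acid charge,
sum_i q_i Gamma_i = |q_NA|.  The per-charge fraction Gamma_i^* = |q_i|
|Gamma_i| / |q_NA| is what ion-counting experiments report.

Profiles can come from particle frames (cylindrical-shell binning around the
helix axis) or directly from a PB solution.  The 2-D untwisted helicoidal
density counter-rotates every ion by the local accumulated twist before
angular binning, so groove features align along the axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .constants import MOLAR_TO_PER_NM3
from .helix import SiteModel, accumulated_twist

__all__ = [
    "IonFrames",
    "ConcentrationProfile",
    "HelicoidalDensity",
    "IonExcess",
    "radial_profile",
    "ion_excess",
    "fraction_excess",
    "electroneutrality_residual",
    "helicoidal_density",
]


@dataclass
class IonFrames:
    """Time series of ion coordinates per species.

    ``positions[label]`` is a list with one ``(n, 3)`` array (nm) per frame.
    Counts may vary across frames (poisson-mode generation); operations that
    require one entry per cation per frame check :meth:`has_fixed_counts`.
    """

    positions: dict[str, list[np.ndarray]]
    box: tuple[float, float, float] | None = None

    def __post_init__(self):
        n = {lab: len(frames) for lab, frames in self.positions.items()}
        if len(set(n.values())) > 1:
            raise ValueError(f"inconsistent frame counts across species: {n}")
        for lab, frames in self.positions.items():
            for i, f in enumerate(frames):
                f = np.asarray(f, float)
                if f.ndim != 2 or f.shape[1] != 3:
                    raise ValueError(f"{lab} frame {i}: expected (n, 3) array")
                if not np.all(np.isfinite(f)):
                    raise ValueError(f"{lab} frame {i}: non-finite coordinates")
                frames[i] = f

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.positions)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.positions.values())))

    def count(self, label: str) -> int:
        """Per-frame ion count N_m (requires fixed counts)."""
        counts = {f.shape[0] for f in self.positions[label]}
        if len(counts) != 1:
            raise ValueError(f"{label}: ion count varies across frames")
        return counts.pop()

    def has_fixed_counts(self) -> bool:
        return all(
            len({f.shape[0] for f in frames}) == 1
            for frames in self.positions.values()
        )

    def subset(self, frame_slice: slice) -> "IonFrames":
        return IonFrames(
            positions={
                lab: list(frames[frame_slice])
                for lab, frames in self.positions.items()
            },
            box=self.box,
        )


@dataclass
class ConcentrationProfile:
    """Binned radial concentrations c_i(r) with their bulk values.

    ``r`` are bin centers (strictly increasing, nonuniform allowed); ``edges``
    is present for particle-derived profiles (half-open bins [r_k, r_{k+1})).
    """

    r: np.ndarray
    concentrations: dict[str, np.ndarray]
    h: float
    c_bulk: dict[str, float]
    n_frames: int = 1
    edges: np.ndarray | None = None
    counts: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self):
        self.r = np.asarray(self.r, float)
        for lab, c in self.concentrations.items():
            c = np.asarray(c, float)
            if np.any(c < 0):
                raise ValueError(f"negative concentration in profile for {lab}")
            self.concentrations[lab] = c

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.concentrations)

    @classmethod
    def from_pb_solution(cls, solution, include_core: bool = False
                         ) -> "ConcentrationProfile":
        """Profile view of a PB solution on its own radial grid.

        With ``include_core`` the region r < R is prepended with c = 0
        (hard-core depletion); by default the profile covers the annulus
        [R, R_max] only, so an uncharged cylinder has zero excess.
        """
        r = solution.r
        conc = {lab: c.copy() for lab, c in solution.concentrations.items()}
        if include_core:
            R = solution.cylinder.radius
            n_core = max(8, int(50 * R))
            core = np.linspace(R / (2 * n_core), R, n_core, endpoint=False)
            r = np.concatenate([core, r])
            conc = {
                lab: np.concatenate([np.zeros(n_core), c])
                for lab, c in conc.items()
            }
        bulk = {s.label: s.conc_molar for s in solution.species}
        return cls(
            r=r,
            concentrations=conc,
            h=solution.cylinder.length,
            c_bulk=bulk,
            n_frames=1,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {"r_nm": self.r}
        for lab, c in self.concentrations.items():
            cols[f"c_{lab}_M"] = c
        return pd.DataFrame(cols)


class IonExcess(NamedTuple):
    """Cumulative excess Gamma(r) and its total for one species."""

    r: np.ndarray
    gamma_of_r: np.ndarray
    total: float
    flagged: bool


def radial_profile(
    frames: IonFrames,
    model: SiteModel | None = None,
    bin_width: float = 0.05,
    r_max: float | None = None,
    axial_window: tuple[float, float] | None = None,
    bulk_fraction: float = 0.2,
    species: tuple[str, ...] | None = None,
) -> ConcentrationProfile:
    """Bin ions into cylindrical shells around the helix axis (the z axis).

    Shell volume is pi (r_{k+1}^2 - r_k^2) h with h the axial window extent;
    counts average over frames and convert to mol/L via N_A V_f.  The bulk
    concentration of each species is the mean over the outermost
    ``bulk_fraction`` of the radial range.  Ions outside the window or beyond
    ``r_max`` are ignored.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if frames.n_frames == 0:
        raise ValueError("no frames to analyze")
    if axial_window is None:
        if model is None:
            raise ValueError("need a model or an explicit axial_window")
        axial_window = (0.0, model.length)
    z0, z1 = axial_window
    h = z1 - z0
    if h <= 0:
        raise ValueError("empty axial window")
    labels = species or frames.species
    if r_max is None:
        r_all = [
            np.hypot(f[:, 0], f[:, 1])
            for lab in labels
            for f in frames.positions[lab]
        ]
        r_max = max((r.max() for r in r_all if r.size), default=0.0)
        if r_max <= 0:
            raise ValueError("no ions found; give r_max explicitly")
    n_bins = max(1, int(np.ceil(r_max / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) * h

    conc: dict[str, np.ndarray] = {}
    bulk: dict[str, float] = {}
    counts_out: dict[str, np.ndarray] = {}
    n_bulk = max(1, int(round(bulk_fraction * n_bins)))
    for lab in labels:
        pts = np.concatenate(frames.positions[lab]) if frames.positions[lab] else \
            np.empty((0, 3))
        in_z = (pts[:, 2] >= z0) & (pts[:, 2] < z1)
        rad = np.hypot(pts[in_z, 0], pts[in_z, 1])
        # half-open bins [r_k, r_{k+1})
        counts, _ = np.histogram(rad, bins=edges)
        extra = np.count_nonzero(rad == edges[-1])  # top edge is excluded
        counts = counts.astype(float)
        if extra:
            counts[-1] -= extra
        counts /= frames.n_frames
        c = counts / (shell_vol * MOLAR_TO_PER_NM3)
        conc[lab] = c
        bulk[lab] = float(np.mean(c[-n_bulk:]))
        counts_out[lab] = counts
    return ConcentrationProfile(
        r=centers,
        concentrations=conc,
        h=h,
        c_bulk=bulk,
        n_frames=frames.n_frames,
        edges=edges,
        counts=counts_out,
    )


def _plateau_ok(r, c, c_inf, bulk_fraction=0.2) -> bool:
    """Bulk-plateau test: the linear trend over the outer bulk window must be
    small (|slope| * range < 1% of the mean) or statistically insignificant
    (within 2 standard errors of zero, so shot noise on a flat profile does
    not flag)."""
    n = max(3, int(round(bulk_fraction * r.size)))
    rb, cb = r[-n:], c[-n:]
    if np.allclose(cb, cb[0]):
        return True
    from scipy.stats import linregress

    fit = linregress(rb, cb)
    mean = np.mean(cb)
    if mean == 0:
        return np.isclose(fit.slope, 0.0)
    small = abs(fit.slope) * (rb[-1] - rb[0]) < 0.01 * abs(mean)
    insignificant = abs(fit.slope) < 2.0 * fit.stderr if fit.stderr > 0 else False
    return small or insignificant


def ion_excess(profile: ConcentrationProfile, species: str) -> IonExcess:
    """Cumulative and total ion excess of one species (trapezoid on bin
    centers).  Anions (depleted species) yield negative Gamma.  If the
    profile lacks a bulk plateau the result is flagged and a warning issued.
    """
    c = profile.concentrations[species]
    r = profile.r
    c_inf = profile.c_bulk[species]
    flagged = not _plateau_ok(r, c, c_inf)
    if flagged:
        warnings.warn(
            f"profile for {species} has no converged bulk plateau; "
            "Gamma may be biased",
            stacklevel=2,
        )
    integrand = (c - c_inf) * 2.0 * np.pi * r
    from scipy.integrate import cumulative_trapezoid

    gamma_r = MOLAR_TO_PER_NM3 * profile.h * cumulative_trapezoid(
        integrand, r, initial=0.0
    )
    return IonExcess(r=r, gamma_of_r=gamma_r, total=float(gamma_r[-1]),
                     flagged=flagged)


def fraction_excess(gamma: float, valence: int, q_na: float) -> float:
    """Per-charge excess fraction Gamma^* = |q_i| Gamma_i / |q_NA|.

    Reported positive for both roles: attracted cations use Gamma_i directly,
    excluded anions use |Gamma_i|.
    """
    if q_na <= 0:
        raise ValueError("q_na must be positive")
    if valence > 0:
        return abs(valence) * gamma / q_na
    return abs(valence) * abs(gamma) / q_na


def electroneutrality_residual(
    gammas: dict[str, float], valences: dict[str, int], q_na: float
) -> float:
    """Relative closure error (sum_i q_i Gamma_i - q_NA) / q_NA."""
    if len(gammas) < 2:
        raise ValueError("need at least two species")
    total = sum(valences[lab] * g for lab, g in gammas.items())
    return (total - q_na) / q_na


@dataclass
class HelicoidalDensity:
    """2-D ion density over (radius, untwisted angle), mol/L.

    ``density[label]`` has shape (n_r_bins, n_angle_bins).  The angular
    origin is the model's base-pair reference angle at z = 0, so a fixed
    groove or backbone feature appears at a fixed untwisted angle.
    """

    r_edges: np.ndarray
    angle_edges_deg: np.ndarray
    density: dict[str, np.ndarray]
    h: float
    n_frames: int

    def angular_integral(self, label: str) -> np.ndarray:
        """Collapse the map over angle; recovers the 1-D radial profile."""
        frac = np.diff(self.angle_edges_deg) / 360.0
        return np.sum(self.density[label] * frac[None, :], axis=1)


def helicoidal_density(
    frames: IonFrames,
    model: SiteModel,
    r_max: float,
    bin_width: float = 0.05,
    angle_bins: int = 36,
    axial_window: tuple[float, float] | None = None,
    species: tuple[str, ...] | None = None,
) -> HelicoidalDensity:
    """Untwisted helicoidal ion density map.

    Each ion's cylindrical angle is rotated by minus the accumulated twist at
    its z before binning, collapsing the helical symmetry; cell volumes are
    pi (r2^2 - r1^2) h (dtheta / 360).
    """
    if axial_window is None:
        axial_window = (0.0, model.length)
    z0, z1 = axial_window
    h = z1 - z0
    if h <= 0:
        raise ValueError("empty axial window")
    if frames.n_frames == 0:
        raise ValueError("no frames to analyze")
    n_r = max(1, int(np.ceil(r_max / bin_width)))
    r_edges = np.arange(n_r + 1) * bin_width
    a_edges = np.linspace(0.0, 360.0, angle_bins + 1)
    cell_vol = (
        np.pi * (r_edges[1:, None] ** 2 - r_edges[:-1, None] ** 2)
        * h * (np.diff(a_edges)[None, :] / 360.0)
    )
    labels = species or frames.species
    density = {}
    for lab in labels:
        pts = np.concatenate(frames.positions[lab])
        in_z = (pts[:, 2] >= z0) & (pts[:, 2] < z1)
        pts = pts[in_z]
        rad = np.hypot(pts[:, 0], pts[:, 1])
        theta = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))
        untw = np.mod(theta - accumulated_twist(model, pts[:, 2]), 360.0)
        hist, _, _ = np.histogram2d(rad, untw, bins=[r_edges, a_edges])
        density[lab] = hist / frames.n_frames / (cell_vol * MOLAR_TO_PER_NM3)
    return HelicoidalDensity(
        r_edges=r_edges,
        angle_edges_deg=a_edges,
        density=density,
        h=h,
        n_frames=frames.n_frames,
    )
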