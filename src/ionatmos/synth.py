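"""Ground-truth ion configuration generator.

Emulates, at desk scale, what an equilibrated ion atmosphere around a duplex
looks like to the analysis stack: diffuse ions drawn from a prescribed radial
concentration law (uniform, tabulated, or a PB solution), uniform in angle
and axial position within a cylindrical sampling domain, plus planted
inner-sphere binding events with specified pattern-class frequencies.  It is
a mean-field sampler by design — no ion-ion correlations or excluded volume —
which is exactly the statistical structure PB theory can predict, so every
analysis stage has a known ground truth.

Determinism: every draw comes from one ``numpy.random.default_rng(seed)``
stream in a fixed order, so a given spec reproduces bitwise.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import MOLAR_TO_PER_NM3
from .helix import SiteAtom, SiteModel, residue_mask
from .patterns import CutoffTable
from .profiles import IonFrames

__all__ = [
    "RadialLaw",
    "SpeciesSpec",
    "PlantedPatternSpec",
    "GeneratorSpec",
    "sample_diffuse_ions",
    "plant_binding_events",
    "write_frames",
    "read_frames",
]

_BASE_ATOM_NAMES = ("N7", "O6", "O2", "O4")


@dataclass(frozen=True)
class RadialLaw:
    """Target radial concentration c(r), mol/L, on [0, r_support]."""

    r: np.ndarray
    c: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.r, float)
        c = np.asarray(self.c, float)
        if r.ndim != 1 or r.shape != c.shape or r.size < 2:
            raise ValueError("radial law needs two equal-length 1-D arrays")
        if np.any(np.diff(r) <= 0):
            raise ValueError("radial law distances must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("radial law concentrations must be >= 0")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "c", c)

    @classmethod
    def uniform(cls, conc_molar: float, r_max: float) -> "RadialLaw":
        return cls(np.array([0.0, r_max]), np.array([conc_molar, conc_molar]))

    @classmethod
    def annulus(cls, conc_molar: float, r_min: float, r_max: float) -> "RadialLaw":
        """Uniform concentration outside an excluded core (zero below r_min)."""
        eps = 1e-9
        return cls(
            np.array([0.0, r_min - eps, r_min, r_max]),
            np.array([0.0, 0.0, conc_molar, conc_molar]),
        )

    @classmethod
    def from_pb_solution(cls, solution, label: str) -> "RadialLaw":
        """c_i(r) of a PB solution, with the hard core r < R at zero."""
        R = solution.cylinder.radius
        eps = 1e-9
        r = np.concatenate([[0.0, R - eps], solution.r])
        c = np.concatenate([[0.0, 0.0], solution.concentrations[label]])
        return cls(r, c)

    def conc_at(self, r) -> np.ndarray:
        return np.interp(r, self.r, self.c, left=self.c[0], right=0.0)


@dataclass(frozen=True)
class SpeciesSpec:
    """One generated species: radial law plus count rule.

    With ``n_ions`` given, exactly that many ions appear in every frame
    (multinomial over shells).  Otherwise the count follows the law's Poisson
    mean: fixed at the rounded mean (``count_mode='fixed'``, default, keeps
    per-species counts constant across frames) or drawn per frame
    (``count_mode='poisson'``, ragged frames).
    """

    label: str
    valence: int
    radial_law: RadialLaw
    n_ions: int | None = None
    count_mode: str = "fixed"

    def __post_init__(self):
        if self.count_mode not in ("fixed", "poisson"):
            raise ValueError("count_mode must be 'fixed' or 'poisson'")


@dataclass(frozen=True)
class PlantedPatternSpec:
    """Plant one pattern class at a target per-(cation, frame) frequency."""

    species: str
    pattern_class: tuple[str, ...]
    frequency: float
    strict: bool = True

    def __post_init__(self):
        object.__setattr__(self, "pattern_class",
                           tuple(sorted(self.pattern_class)))
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must be in [0, 1]")


@dataclass
class GeneratorSpec:
    """Full generator configuration (model, species, domain, plants, seed)."""

    model: SiteModel
    species: list[SpeciesSpec]
    r_max: float
    z_range: tuple[float, float]
    n_frames: int
    seed: int
    planted: list[PlantedPatternSpec] = field(default_factory=list)
    cutoffs: CutoffTable = field(default_factory=CutoffTable.default)
    trim_per_end: int = 3

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.z_range[1] <= self.z_range[0]:
            raise ValueError("empty z_range")
        for sp in self.species:
            if sp.radial_law.r[-1] < self.r_max - 1e-9:
                # laws are clamped to 0 beyond their support, which is fine
                pass
        per_species: dict[str, float] = {}
        for p in self.planted:
            per_species[p.species] = per_species.get(p.species, 0.0) + p.frequency
        for lab, tot in per_species.items():
            if tot > 1.0 + 1e-12:
                raise ValueError(f"planted frequencies for {lab} sum to {tot} > 1")


def _radial_sampler(law: RadialLaw, r_max: float, n_grid: int = 4096):
    """Inverse-CDF sampler for p(r) proportional to c(r) r on [0, r_max];
    returns (sampler(u)->r, mean count per nm of axial length)."""
    # include the law's own breakpoints so discontinuities (e.g. the hard
    # core at the cylinder surface) are represented exactly
    rr = np.union1d(
        np.linspace(0.0, r_max, n_grid),
        law.r[(law.r >= 0.0) & (law.r <= r_max)],
    )
    w = law.conc_at(rr) * rr
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(rr))])
    if cum[-1] <= 0:
        raise ValueError("radial law is not normalizable on the domain "
                         "(zero integral)")
    # ions per nm of height: 2 pi * integral c(r) r dr * N_A V_f
    per_height = 2.0 * np.pi * cum[-1] * MOLAR_TO_PER_NM3
    cdf = cum / cum[-1]

    def sample(u: np.ndarray) -> np.ndarray:
        return np.interp(u, cdf, rr)

    return sample, per_height


def sample_diffuse_ions(spec: GeneratorSpec) -> IonFrames:
    """Draw diffuse ion frames from each species' radial law."""
    rng = np.random.default_rng(spec.seed)
    z0, z1 = spec.z_range
    height = z1 - z0
    positions: dict[str, list[np.ndarray]] = {}
    for sp in spec.species:
        sampler, per_height = _radial_sampler(sp.radial_law, spec.r_max)
        lam = per_height * height
        if sp.n_ions is not None:
            counts = np.full(spec.n_frames, sp.n_ions, dtype=int)
        elif sp.count_mode == "poisson":
            counts = rng.poisson(lam, size=spec.n_frames)
        else:
            counts = np.full(spec.n_frames, int(round(lam)), dtype=int)
        total = int(counts.sum())
        r = sampler(rng.random(total))
        theta = rng.random(total) * 2.0 * np.pi
        z = z0 + rng.random(total) * height
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
        splits = np.cumsum(counts)[:-1]
        positions[sp.label] = [np.ascontiguousarray(a)
                               for a in np.split(pts, splits)]
    return IonFrames(positions=positions)


# ---------------------------------------------------------------------------
# Planted binding events


def _pattern_site_options(
    model: SiteModel, pattern_class: tuple[str, ...], trim_per_end: int
) -> list[tuple[SiteAtom, ...]]:
    """Concrete atom groups that realize a pattern class.

    If a single retained residue carries every required atom name, each such
    residue gives one option; residues carrying fewer extra base atoms are
    preferred (so e.g. an N7 plant lands on adenine rather than guanine,
    keeping the realized contact set exactly the requested class).  Classes
    spanning residues (duplicate names) are built greedily from
    nearest same-name atoms of other residues.
    """
    retained = residue_mask(model, trim_per_end)
    by_res: dict[tuple[int, int], dict[str, list[SiteAtom]]] = {}
    for a in model.atoms:
        key = (a.strand, a.residue_index)
        if key not in retained:
            continue
        by_res.setdefault(key, {}).setdefault(a.name, []).append(a)

    need: dict[str, int] = {}
    for name in pattern_class:
        need[name] = need.get(name, 0) + 1

    single_res: list[tuple[int, tuple[SiteAtom, ...]]] = []
    for key, atoms in by_res.items():
        if all(len(atoms.get(n, ())) >= k for n, k in need.items()):
            group = tuple(atoms[n][i] for n, k in need.items() for i in range(k))
            extra_base = sum(
                1
                for n, lst in atoms.items()
                if n in _BASE_ATOM_NAMES and n not in need
                for _ in lst
            )
            single_res.append((extra_base, group))
    if single_res:
        best = min(e for e, _ in single_res)
        return [g for e, g in single_res if e == best]

    # multi-residue fallback: anchor on atoms with the first name, then take
    # the nearest remaining same-name atoms from other residues
    all_atoms: dict[str, list[SiteAtom]] = {}
    for atoms in by_res.values():
        for n, lst in atoms.items():
            all_atoms.setdefault(n, []).extend(lst)
    first = pattern_class[0]
    options: list[tuple[SiteAtom, ...]] = []
    for anchor in all_atoms.get(first, ()):
        group = [anchor]
        used = {id(anchor)}
        ok = True
        for name in pattern_class[1:]:
            cands = [
                a for a in all_atoms.get(name, ()) if id(a) not in used
            ]
            if not cands:
                ok = False
                break
            nearest = min(
                cands,
                key=lambda a: float(np.linalg.norm(a.xyz - anchor.xyz)),
            )
            group.append(nearest)
            used.add(id(nearest))
        if ok:
            options.append(tuple(group))
    return options


def _place_near(
    group: tuple[SiteAtom, ...], target: float, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Point at distance ``target`` from every atom of the group.

    Single atoms: offset radially outward from the helix axis.  Multi-atom
    groups: least-squares placement; returns (point, feasible_exactly).
    """
    coords = np.array([a.xyz for a in group])
    if len(group) == 1:
        a = coords[0]
        radial = np.array([a[0], a[1], 0.0])
        nrm = np.linalg.norm(radial)
        u = radial / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        return a + target * u, True
    from scipy.optimize import least_squares

    feasible = True
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if np.linalg.norm(coords[i] - coords[j]) > 2.0 * target:
                feasible = False
    centroid = coords.mean(axis=0)
    radial = np.array([centroid[0], centroid[1], 0.0])
    nrm = np.linalg.norm(radial)
    u = radial / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
    x0 = centroid + 0.6 * target * u

    def residuals(p):
        return np.linalg.norm(coords - p[None, :], axis=1) - target

    sol = least_squares(residuals, x0)
    return sol.x, feasible and bool(np.max(np.abs(sol.fun)) < 1e-6)


def plant_binding_events(
    frames: IonFrames, spec: GeneratorSpec
) -> tuple[IonFrames, pd.DataFrame]:
    """Relocate cations onto binding sites at the specified frequencies.

    Per (cation, frame), a pattern class is chosen with its target
    probability (or none); the cation is moved to distance d-dagger - 0.05 nm
    from each required atom.  Geometrically infeasible classes raise in
    strict mode, otherwise fall back to the least-squares point and are
    logged with ``clean=False``.  Returns new frames plus the ground-truth
    event log.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    plants_by_species: dict[str, list[PlantedPatternSpec]] = {}
    for p in spec.planted:
        plants_by_species.setdefault(p.species, []).append(p)

    options_cache: dict[tuple[str, tuple[str, ...]], list] = {}
    new_positions = {
        lab: [f.copy() for f in frs] for lab, frs in frames.positions.items()
    }
    log_rows = []
    for label, plants in plants_by_species.items():
        if label not in new_positions:
            raise ValueError(f"planted species {label!r} not present in frames")
        target = spec.cutoffs.get(label) - 0.05
        freqs = np.array([p.frequency for p in plants])
        cum = np.cumsum(freqs)
        for p in plants:
            key = (label, p.pattern_class)
            if key not in options_cache:
                opts = _pattern_site_options(
                    spec.model, p.pattern_class, spec.trim_per_end
                )
                if not opts:
                    raise ValueError(
                        f"no retained atoms realize pattern {p.pattern_class}"
                    )
                options_cache[key] = opts
        for f, pts in enumerate(new_positions[label]):
            if pts.shape[0] == 0:
                continue
            u = rng.random(pts.shape[0])
            for m in range(pts.shape[0]):
                k = int(np.searchsorted(cum, u[m]))
                if k >= len(plants):
                    continue  # stays diffuse
                plant = plants[k]
                opts = options_cache[(label, plant.pattern_class)]
                group = opts[rng.integers(len(opts))]
                point, clean = _place_near(group, target, rng)
                if not clean and plant.strict:
                    raise ValueError(
                        f"pattern {plant.pattern_class} geometrically "
                        f"infeasible at d = {target:.3f} nm"
                    )
                pts[m] = point
                log_rows.append(
                    {
                        "frame": f,
                        "species": label,
                        "ion": m,
                        "pattern": "+".join(plant.pattern_class),
                        "strand": group[0].strand,
                        "residue": group[0].residue_index,
                        "clean": clean,
                    }
                )
    log = pd.DataFrame(
        log_rows,
        columns=["frame", "species", "ion", "pattern", "strand", "residue",
                 "clean"],
    )
    return IonFrames(positions=new_positions, box=frames.box), log


# ---------------------------------------------------------------------------
# Frame I/O

def _open_text(path, mode):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_frames(frames: IonFrames, model: SiteModel | None, path,
                 format: str = "xyz") -> None:
    """Write ion frames to a multi-frame XYZ or multi-model PDB file.

    Coordinates are written in Angstrom (the conventional unit of both
    formats); species labels become atom names.  XYZ supports ragged frames;
    PDB requires fixed per-species counts.  Model atoms are not embedded —
    the site model travels as its own PDB — but share the coordinate frame.
    """
    if format == "xyz":
        with _open_text(path, "w") as fh:
            for f in range(frames.n_frames):
                blocks = [
                    (lab, frames.positions[lab][f]) for lab in frames.species
                ]
                n = sum(b.shape[0] for _, b in blocks)
                fh.write(f"{n}\nframe={f}\n")
                for lab, b in blocks:
                    for x, y, z in b * 10.0:
                        fh.write(f"{lab} {x:.4f} {y:.4f} {z:.4f}\n")
    elif format == "pdb":
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        if not frames.has_fixed_counts():
            raise ValueError("PDB frames require fixed per-species ion counts")
        counts = {lab: frames.count(lab) for lab in frames.species}
        n = sum(counts.values())
        labels = [lab for lab in frames.species for _ in range(counts[lab])]
        arr = struc.AtomArray(n)
        arr.atom_name = np.array([l[:4] for l in labels], dtype="U6")
        arr.res_name = np.array(["ION"] * n, dtype="U5")
        arr.res_id = np.arange(1, n + 1)
        arr.chain_id = np.array(["I"] * n, dtype="U4")
        elements = ["".join(ch for ch in l if ch.isalpha())[:2] for l in labels]
        arr.element = np.array(elements, dtype="U2")
        arr.hetero = np.ones(n, dtype=bool)
        stack = struc.stack([arr] * frames.n_frames)
        coords = np.stack(
            [
                np.concatenate(
                    [frames.positions[lab][f] for lab in frames.species]
                )
                * 10.0
                for f in range(frames.n_frames)
            ]
        )
        stack.coord = coords
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))
    else:
        raise ValueError(f"unknown frames format {format!r} (xyz or pdb)")


def read_frames(path, format: str = "xyz") -> IonFrames:
    """Read ion frames written by :func:`write_frames` (coordinates back to
    nm; species grouped by atom name)."""
    if format == "xyz":
        per_frame: list[dict[str, list]] = []
        with _open_text(path, "r") as fh:
            lines = fh.read().splitlines()
        i = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            n = int(lines[i].strip())
            frame: dict[str, list] = {}
            for ln in lines[i + 2: i + 2 + n]:
                parts = ln.split()
                frame.setdefault(parts[0], []).append(
                    [float(parts[1]), float(parts[2]), float(parts[3])]
                )
            per_frame.append(frame)
            i += 2 + n
        labels = sorted({lab for fr in per_frame for lab in fr})
        positions = {
            lab: [
                np.asarray(fr.get(lab, np.empty((0, 3))), float).reshape(-1, 3)
                / 10.0
                for fr in per_frame
            ]
            for lab in labels
        }
        return IonFrames(positions=positions)
    if format == "pdb":
        from biotite.structure.io.pdb import PDBFile

        stack = PDBFile.read(str(path)).get_structure()
        names = [str(n) for n in stack.atom_name]
        labels = sorted(set(names))
        idx = {lab: [i for i, n in enumerate(names) if n == lab]
               for lab in labels}
        positions = {
            lab: [stack.coord[f][idx[lab]] / 10.0
                  for f in range(stack.stack_depth())]
            for lab in labels
        }
        return IonFrames(positions=positions)
    raise ValueError(f"unknown frames format {format!r} (xyz or pdb)")
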