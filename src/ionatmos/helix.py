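"""Idealized A-form (RNA) and B-form (DNA) duplex site models.

A :class:`SiteModel` is a geometric stand-in for a relaxed all-atom duplex: it
carries only the atoms that act as inner-sphere cation binding sites — the
phosphate oxygens (O1P, O2P), the sugar oxygens (O3', O4', O5' and, for RNA,
O2') and the nucleobase acceptors (N7 on purines, O6 on guanine, O4 on
thymine/uracil, O2 on cytosine) — wound on per-atom-type cylindrical shells
with a fixed rise and twist per base pair.  That is all the downstream
analyses (helicoidal binning, contact detection) need; the analyses accept any
SiteModel, including one parsed from a real PDB file.

Conventions: strand 1 sequence is given 5'->3'; residue indices are 0-based
internally and 1-based in PDB output; the helix axis is the z axis with base
pair 0 at z = 0.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SITE_ATOM_NAMES",
    "SiteAtom",
    "SiteModel",
    "GrooveGeometry",
    "build_ideal_duplex",
    "accumulated_twist",
    "residue_mask",
    "write_pdb",
    "site_model_from_pdb",
]

SITE_ATOM_NAMES = frozenset(
    {"O1P", "O2P", "N7", "O6", "O2", "O4", "O3'", "O4'", "O5'", "O2'"}
)

PURINES = frozenset({"A", "G"})

_COMPLEMENT = {
    "A": {"A": "U", "B": "T"},
    "U": {"A": "A"},
    "T": {"B": "A"},
    "G": {"A": "C", "B": "C"},
    "C": {"A": "G", "B": "G"},
}

_ALPHABET = {"A": frozenset("ACGU"), "B": frozenset("ACGT")}

# Canonical fiber-diffraction helix parameters.
DEFAULT_RISE_NM = {"A": 0.28, "B": 0.34}
DEFAULT_TWIST_DEG = {"A": 32.7, "B": 36.0}


def _base_atoms(base: str, form: str) -> tuple[str, ...]:
    """Nucleobase binding-site atoms carried by one residue."""
    if base == "A":
        return ("N7",)
    if base == "G":
        return ("N7", "O6")
    if base == "C":
        return ("O2",)
    if base in ("T", "U"):
        return ("O4",)
    raise ValueError(f"unknown base {base!r}")


@dataclass(frozen=True)
class GrooveGeometry:
    """Per-atom-type shell radius, phase angle and axial offset.

    ``radius_nm[name]`` is the distance of atoms called ``name`` from the
    helix axis; ``phase_deg[name]`` their angular offset from the base-pair
    reference angle; ``z_offset_nm[name]`` their axial offset from the
    base-pair plane.  ``strand_phase_deg`` is the angular offset of strand 2
    relative to strand 1 (strand 2 atoms are mirrored: angle = ref +
    strand_phase - phase, z = ref - offset), which sets the groove widths.
    """

    radius_nm: dict[str, float]
    phase_deg: dict[str, float]
    z_offset_nm: dict[str, float]
    strand_phase_deg: float

    @classmethod
    def default(cls, form: str) -> "GrooveGeometry":
        if form == "B":
            return cls(
                radius_nm={"O1P": 1.00, "O2P": 0.95, "O5'": 0.90, "O3'": 0.90,
                           "O4'": 0.75, "N7": 0.35, "O6": 0.30, "O2": 0.25,
                           "O4": 0.30},
                phase_deg={"O1P": 100.0, "O2P": 112.0, "O5'": 85.0, "O3'": 126.0,
                           "O4'": 140.0, "N7": 40.0, "O6": 58.0, "O2": 220.0,
                           "O4": 70.0},
                z_offset_nm={"O1P": 0.00, "O2P": 0.10, "O5'": -0.05, "O3'": 0.15,
                             "O4'": 0.05, "N7": 0.0, "O6": 0.0, "O2": 0.0,
                             "O4": 0.0},
                strand_phase_deg=154.0,
            )
        if form == "A":
            return cls(
                radius_nm={"O1P": 1.30, "O2P": 1.25, "O5'": 1.20, "O3'": 1.20,
                           "O4'": 1.05, "O2'": 1.10, "N7": 0.55, "O6": 0.50,
                           "O2": 0.45, "O4": 0.50},
                phase_deg={"O1P": 95.0, "O2P": 107.0, "O5'": 80.0, "O3'": 121.0,
                           "O4'": 135.0, "O2'": 150.0, "N7": 35.0, "O6": 53.0,
                           "O2": 215.0, "O4": 65.0},
                z_offset_nm={"O1P": 0.00, "O2P": 0.10, "O5'": -0.05, "O3'": 0.15,
                             "O4'": 0.05, "O2'": 0.12, "N7": 0.0, "O6": 0.0,
                             "O2": 0.0, "O4": 0.0},
                strand_phase_deg=190.0,
            )
        raise ValueError(f"form must be 'A' or 'B', got {form!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GrooveGeometry":
        return cls(
            radius_nm=dict(d["radius_nm"]),
            phase_deg=dict(d["phase_deg"]),
            z_offset_nm=dict(d["z_offset_nm"]),
            strand_phase_deg=float(d["strand_phase_deg"]),
        )


@dataclass(frozen=True)
class SiteAtom:
    """One binding-site atom of the duplex."""

    name: str
    residue_index: int
    strand: int
    base: str
    position: tuple[float, float, float]

    @property
    def element(self) -> str:
        return self.name[0]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class SiteModel:
    """Binding-site atoms of an idealized duplex plus its helical frame."""

    sequence: str
    form: str
    atoms: list[SiteAtom]
    rise_per_bp: float
    twist_per_bp: float
    geometry: GrooveGeometry | None = None

    _positions: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> float:
        """End-to-end helix length h, nm."""
        return (self.n_bp - 1) * self.rise_per_bp

    @property
    def total_charge(self) -> float:
        """Backbone charge magnitude |q_NA| = 2*(n_bp - 1), in e."""
        return 2.0 * (self.n_bp - 1)

    def positions(self) -> np.ndarray:
        """All atom coordinates as an (n_atoms, 3) array, nm."""
        if self._positions is None:
            self._positions = np.array([a.position for a in self.atoms], float)
        return self._positions

    def accumulated_twist(self, axial_position: float) -> float:
        return accumulated_twist(self, axial_position)


def build_ideal_duplex(
    sequence: str,
    form: str,
    rise_per_bp: float | None = None,
    twist_per_bp: float | None = None,
    groove_geometry: GrooveGeometry | None = None,
) -> SiteModel:
    """Build an idealized duplex site model.

    The complementary strand is generated by Watson-Crick pairing and runs
    antiparallel: strand-2 residue ``j`` (0-based along its own 5'->3'
    direction) sits at base pair ``n_bp - 1 - j``.  The 5'-terminal residue of
    each strand carries no phosphate, so each strand has ``n_bp - 1``
    phosphate groups and the duplex charge magnitude is ``2*(n_bp - 1)``.
    """
    form = form.upper()
    if form not in ("A", "B"):
        raise ValueError(f"form must be 'A' or 'B', got {form!r}")
    if not sequence:
        raise ValueError("sequence must be non-empty")
    sequence = sequence.upper()
    for i, b in enumerate(sequence):
        if b not in _ALPHABET[form]:
            raise ValueError(
                f"invalid base {b!r} at position {i} for form {form} "
                f"(allowed: {sorted(_ALPHABET[form])})"
            )
    rise = DEFAULT_RISE_NM[form] if rise_per_bp is None else float(rise_per_bp)
    twist = DEFAULT_TWIST_DEG[form] if twist_per_bp is None else float(twist_per_bp)
    if rise <= 0 or twist <= 0:
        raise ValueError("rise_per_bp and twist_per_bp must be positive")
    geom = groove_geometry or GrooveGeometry.default(form)

    n = len(sequence)
    atoms: list[SiteAtom] = []

    def place(name: str, strand: int, pair_index: int) -> tuple[float, float, float]:
        rho = geom.radius_nm[name]
        phi = geom.phase_deg[name]
        dz = geom.z_offset_nm[name]
        theta_ref = pair_index * twist
        if strand == 1:
            theta = theta_ref + phi
            z = pair_index * rise + dz
        else:
            theta = theta_ref + geom.strand_phase_deg - phi
            z = pair_index * rise - dz
        th = math.radians(theta)
        return (rho * math.cos(th), rho * math.sin(th), z)

    for p in range(n):
        b1 = sequence[p]
        b2 = _COMPLEMENT[b1][form]
        # strand 1 residue p at base pair p; strand 2 residue n-1-p at base pair p
        for strand, res, base in ((1, p, b1), (2, n - 1 - p, b2)):
            names: list[str] = []
            if res > 0:  # no 5'-terminal phosphate
                names += ["O1P", "O2P"]
            names += ["O5'", "O3'", "O4'"]
            if form == "A":
                names.append("O2'")
            names += list(_base_atoms(base, form))
            for name in names:
                atoms.append(
                    SiteAtom(
                        name=name,
                        residue_index=res,
                        strand=strand,
                        base=base,
                        position=place(name, strand, p),
                    )
                )

    return SiteModel(
        sequence=sequence,
        form=form,
        atoms=atoms,
        rise_per_bp=rise,
        twist_per_bp=twist,
        geometry=geom,
    )


def accumulated_twist(model: SiteModel, axial_position: float | np.ndarray):
    """Helical twist accumulated at axial position z, degrees.

    Linear in z (``twist_per_bp * z / rise_per_bp``), zero at the origin, and
    extrapolates beyond the helix ends.  Subtracting this angle from a
    particle's cylindrical angle 'untwists' the helix so that groove features
    align along the axis.
    """
    return model.twist_per_bp * np.asarray(axial_position, float) / model.rise_per_bp


def residue_mask(model: SiteModel, trim_per_end: int) -> set[tuple[int, int]]:
    """Residues retained after trimming ``trim_per_end`` bases from each end
    of each strand; returned as a set of ``(strand, residue_index)`` pairs."""
    n = model.n_bp
    if trim_per_end < 0:
        raise ValueError("trim_per_end must be >= 0")
    if 2 * trim_per_end >= n:
        raise ValueError(
            f"trim_per_end={trim_per_end} removes every residue of a {n}-bp duplex"
        )
    keep = range(trim_per_end, n - trim_per_end)
    return {(s, i) for s in (1, 2) for i in keep}


# ---------------------------------------------------------------------------
# PDB I/O

_RES_NAME = {
    ("A", "A"): "A", ("A", "C"): "C", ("A", "G"): "G", ("A", "U"): "U",
    ("B", "A"): "DA", ("B", "C"): "DC", ("B", "G"): "DG", ("B", "T"): "DT",
}
_BASE_FROM_RES = {v: k[1] for k, v in _RES_NAME.items()}


def write_pdb(model: SiteModel, path) -> None:
    """Write the site model as standard PDB ATOM records (chains A/B,
    1-based residue ids, coordinates in Angstrom)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(model.atoms)
    arr = struc.AtomArray(n)
    arr.coord = model.positions() * 10.0  # nm -> A
    arr.chain_id = np.array(
        ["A" if a.strand == 1 else "B" for a in model.atoms], dtype="U4"
    )
    arr.res_id = np.array([a.residue_index + 1 for a in model.atoms])
    arr.res_name = np.array(
        [_RES_NAME[(model.form, a.base)] for a in model.atoms], dtype="U5"
    )
    arr.atom_name = np.array([a.name for a in model.atoms], dtype="U6")
    arr.element = np.array([a.element for a in model.atoms], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("occupancy", np.ones(n))
    arr.set_annotation("b_factor", np.zeros(n))
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def site_model_from_pdb(
    path,
    form: str | None = None,
    rise_per_bp: float | None = None,
    twist_per_bp: float | None = None,
) -> SiteModel:
    """Parse a SiteModel from a PDB file, keeping only controlled-set atoms.

    ``form`` is inferred from the residue names (DA/DC/DG/DT -> B) when not
    given; rise and twist default to the canonical values for that form.
    """
    from biotite.structure.io.pdb import PDBFile

    arr = PDBFile.read(str(path)).get_structure(model=1)
    res_names = set(str(r) for r in arr.res_name)
    if form is None:
        form = "B" if any(r.startswith("D") for r in res_names) else "A"
    atoms: list[SiteAtom] = []
    seq: dict[int, str] = {}
    for i in range(arr.array_length()):
        name = str(arr.atom_name[i])
        if name not in SITE_ATOM_NAMES:
            continue
        res_name = str(arr.res_name[i])
        base = _BASE_FROM_RES.get(res_name, res_name[-1])
        strand = 1 if str(arr.chain_id[i]) == "A" else 2
        res = int(arr.res_id[i]) - 1
        atoms.append(
            SiteAtom(
                name=name,
                residue_index=res,
                strand=strand,
                base=base,
                position=tuple(np.asarray(arr.coord[i], float) / 10.0),
            )
        )
        if strand == 1:
            seq[res] = base
    sequence = "".join(seq[i] for i in sorted(seq))
    return SiteModel(
        sequence=sequence,
        form=form,
        atoms=atoms,
        rise_per_bp=rise_per_bp or DEFAULT_RISE_NM[form],
        twist_per_bp=twist_per_bp or DEFAULT_TWIST_DEG[form],
    )
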