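"""Inner-sphere cation binding patterns.

A cation's binding pattern x = {j, k, ...} is the set of nucleic-acid oxygen
and nitrogen atoms simultaneously within a species-specific cutoff distance
d-dagger (the first minimum of the ion-oxygen radial distribution function,
i.e. direct inner-sphere contact; water-mediated outer-sphere coordination is
deliberately not counted).  Pattern probabilities are per (cation, frame):
p_x = events(x) / (N_m * N_frames), so the complement of sum_x p_x is the
unbound fraction.

Pattern *classes* aggregate by the multiset of atom names ({O1P, O2P},
{O1P, N7}, ...) as binding patterns are usually presented, while raw events
keep full site identities (atom, residue, strand) so that strand-bridging
coordination can be classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .helix import SiteModel, residue_mask

__all__ = [
    "DEFAULT_CUTOFFS_NM",
    "CutoffTable",
    "SiteId",
    "BindingPattern",
    "PatternTable",
    "SiteIndex",
    "detect_contacts",
    "detect_contacts_frames",
    "pattern_probabilities",
    "cumulative_pattern_distribution",
    "classify_bridging",
]

# Inner-sphere contact cutoffs, nm: first minimum of the ion-oxygen radial
# distribution function for each cation.  User-overridable; per
# (cation, site-atom-name) overrides are supported for O vs N granularity.
DEFAULT_CUTOFFS_NM = {
    "LI": 0.28,
    "NA": 0.32,
    "K": 0.36,
    "CS": 0.42,
    "CA": 0.32,
    "SR": 0.35,
    "BA": 0.38,
}


class SiteId(NamedTuple):
    """Identity of one coordinating site atom."""

    name: str
    residue_index: int
    strand: int


@dataclass(frozen=True)
class CutoffTable:
    """Per-cation inner-sphere cutoff distances (nm), optionally refined per
    nucleic-acid atom name."""

    cutoffs: dict[str, float]
    per_atom: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        for k, v in {**self.cutoffs, **self.per_atom}.items():
            if not (0.2 < v < 0.6):
                raise ValueError(f"cutoff for {k} = {v} nm outside (0.2, 0.6) nm")

    @classmethod
    def default(cls) -> "CutoffTable":
        return cls(cutoffs=dict(DEFAULT_CUTOFFS_NM))

    def get(self, species: str, atom_name: str | None = None) -> float:
        key = species.upper()
        if key not in self.cutoffs:
            raise KeyError(f"no cutoff for cation species {species!r}")
        if atom_name is not None and (key, atom_name) in self.per_atom:
            return self.per_atom[(key, atom_name)]
        return self.cutoffs[key]

    def max_cutoff(self, species: str) -> float:
        key = species.upper()
        base = self.get(species)
        refined = [v for (s, _), v in self.per_atom.items() if s == key]
        return max([base] + refined)


@dataclass(frozen=True)
class BindingPattern:
    """One cation's coordinating atoms in one frame."""

    sites: tuple[SiteId, ...]

    def __post_init__(self):
        object.__setattr__(self, "sites", tuple(sorted(self.sites)))

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def pattern_class(self) -> tuple[str, ...]:
        """Multiset of atom names, as used for probability aggregation."""
        return tuple(sorted(s.name for s in self.sites))

    @property
    def flagged(self) -> bool:
        """True for patterns beyond the empirically observed five-atom
        coordination; recorded, not truncated."""
        return len(self.sites) > 5


class SiteIndex:
    """KD-tree over the O/N site atoms retained after end trimming."""

    def __init__(self, model: SiteModel, trim_per_end: int = 0):
        retained = residue_mask(model, trim_per_end)
        self.atoms = [
            a
            for a in model.atoms
            if a.element in ("O", "N") and (a.strand, a.residue_index) in retained
        ]
        self.ids = [SiteId(a.name, a.residue_index, a.strand) for a in self.atoms]
        self.names = np.array([a.name for a in self.atoms])
        coords = np.array([a.position for a in self.atoms], float)
        self._tree = cKDTree(coords) if len(self.atoms) else None

    def query(self, points: np.ndarray, radius: float) -> list[list[int]]:
        if self._tree is None or points.size == 0:
            return [[] for _ in range(len(points))]
        return self._tree.query_ball_point(points, r=radius)


def detect_contacts(
    positions: dict[str, np.ndarray],
    model: SiteModel,
    cutoffs: CutoffTable,
    trim_per_end: int = 0,
    site_index: SiteIndex | None = None,
) -> dict[str, list[Optional[BindingPattern]]]:
    """Per-cation binding pattern for one frame.

    ``positions`` maps cation species label to an (n, 3) array (nm) in the
    model's coordinate frame.  A cation with no site atom within its cutoff
    maps to ``None`` (unbound).  The contact criterion is the closed interval
    d <= d-dagger.
    """
    idx = site_index or SiteIndex(model, trim_per_end)
    out: dict[str, list[Optional[BindingPattern]]] = {}
    for label, pts in positions.items():
        d_max = cutoffs.max_cutoff(label)  # raises KeyError if species unknown
        pts = np.asarray(pts, float).reshape(-1, 3)
        patterns: list[Optional[BindingPattern]] = []
        neighbor_lists = idx.query(pts, d_max)
        for m, neigh in enumerate(neighbor_lists):
            sites = []
            for j in neigh:
                d = np.linalg.norm(pts[m] - np.asarray(idx.atoms[j].position))
                if d <= cutoffs.get(label, idx.names[j]):
                    sites.append(idx.ids[j])
            patterns.append(BindingPattern(tuple(sites)) if sites else None)
        out[label] = patterns
    return out


def detect_contacts_frames(
    frames,
    model: SiteModel,
    cutoffs: CutoffTable,
    trim_per_end: int = 3,
    species: Sequence[str] | None = None,
) -> dict[str, list[list[Optional[BindingPattern]]]]:
    """Contact detection over an :class:`~ionatmos.profiles.IonFrames` series;
    returns, per species, a list over frames of per-cation patterns."""
    idx = SiteIndex(model, trim_per_end)
    labels = list(species) if species is not None else list(frames.species)
    out: dict[str, list[list[Optional[BindingPattern]]]] = {l: [] for l in labels}
    for f in range(frames.n_frames):
        pos = {lab: frames.positions[lab][f] for lab in labels}
        res = detect_contacts(pos, model, cutoffs, site_index=idx)
        for lab in labels:
            out[lab].append(res[lab])
    return out


@dataclass
class PatternTable:
    """Binding-pattern class probabilities p_x with their raw counts."""

    counts: dict[tuple[str, ...], int]
    n_ions: int
    n_frames: int

    def __post_init__(self):
        total = sum(self.counts.values())
        if total > self.n_ions * self.n_frames:
            raise ValueError("more events than (cation, frame) pairs")

    @property
    def probabilities(self) -> dict[tuple[str, ...], float]:
        denom = self.n_ions * self.n_frames
        return {k: v / denom for k, v in self.counts.items()}

    @property
    def bound_probability(self) -> float:
        return sum(self.counts.values()) / (self.n_ions * self.n_frames)

    @property
    def unbound_fraction(self) -> float:
        denom = self.n_ions * self.n_frames
        return (denom - sum(self.counts.values())) / denom

    def sorted_items(self) -> list[tuple[tuple[str, ...], int]]:
        """Descending probability, lexicographic tie-break on the class."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_frame(self) -> pd.DataFrame:
        denom = self.n_ions * self.n_frames
        rows = [
            {"pattern": "+".join(k), "count": v, "p": v / denom}
            for k, v in self.sorted_items()
        ]
        return pd.DataFrame(rows, columns=["pattern", "count", "p"])


def pattern_probabilities(
    per_frame_patterns: list[list[Optional[BindingPattern]]],
    n_ions: int | None = None,
    n_frames: int | None = None,
) -> PatternTable:
    """Tabulate pattern-class probabilities from a complete contact series
    (one entry per cation per frame; ``None`` = unbound)."""
    if n_frames is None:
        n_frames = len(per_frame_patterns)
    if n_ions is None:
        sizes = {len(fr) for fr in per_frame_patterns}
        if len(sizes) != 1:
            raise ValueError("per-frame cation counts vary; give n_ions explicitly")
        n_ions = sizes.pop()
    counts: dict[tuple[str, ...], int] = {}
    for fr in per_frame_patterns:
        for pat in fr:
            if pat is None or len(pat) == 0:
                continue
            key = pat.pattern_class
            counts[key] = counts.get(key, 0) + 1
    return PatternTable(counts=counts, n_ions=n_ions, n_frames=n_frames)


def cumulative_pattern_distribution(
    table: PatternTable, top_k: int | None = None
) -> pd.DataFrame:
    """Cumulative bound probability by pattern rank.

    ``cdf_bound`` normalizes by the total bound probability (reaching 1 at
    the last pattern); ``cum_p`` is the raw per-(cation, frame) cumulative.
    """
    items = table.sorted_items()
    if not items:
        raise ValueError("empty pattern table")
    if top_k is not None:
        top_k = min(top_k, len(items))
    denom = table.n_ions * table.n_frames
    bound = sum(c for _, c in items)
    rows = []
    cum = 0
    for rank, (cls, count) in enumerate(items, start=1):
        cum += count
        rows.append(
            {
                "rank": rank,
                "pattern": "+".join(cls),
                "p": count / denom,
                "cum_p": cum / denom,
                "cdf_bound": cum / bound,
            }
        )
    df = pd.DataFrame(rows)
    return df.iloc[:top_k] if top_k is not None else df


def classify_bridging(pattern: BindingPattern) -> str:
    """Classify a pattern as 'none' (single atom), 'intrastrand' (>= 2 sites
    on one strand) or 'interstrand-bridge' (sites on both strands)."""
    if pattern is None or len(pattern) == 0:
        raise ValueError("empty pattern cannot be classified")
    strands = {s.strand for s in pattern.sites}
    if len(pattern) == 1:
        return "none"
    if len(strands) == 2:
        return "interstrand-bridge"
    return "intrastrand"
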