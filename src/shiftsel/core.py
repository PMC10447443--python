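"""Core domain types for ensemble NMR crystallography of amorphous molecular solids.

The central objects are periodic MD-style :class:`Snapshot` s of a molecular
solid, the :class:`MolecularTopology` shared by every molecule in a snapshot,
and :class:`LocalEnvironment` s (a central molecule plus all molecules in
contact with it).  Chemical shifts enter through
:class:`ShiftDistribution` (the experimentally measured, Gaussian-shaped
distribution of shifts for one atomic site) and :class:`ShiftPrediction`
(a predicted shift with its prediction uncertainty for one site of one
molecule in one snapshot).

Two elementary geometric/NMR operations also live here:
``shielding_to_shift`` (referencing of computed shieldings) and
``dihedral_angle`` (signed torsions used for conformer analysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class ShiftselError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedElementError(ShiftselError):
    """An element symbol is unknown or has no required parameter."""


class GeometryError(ShiftselError):
    """Degenerate or invalid geometry (cells, torsions, alignments)."""


class TopologyError(ShiftselError):
    """Inconsistent molecular topology or snapshot composition."""


class PackingError(ShiftselError):
    """Synthetic packing generation could not satisfy its constraints."""


class MissingPredictionError(ShiftselError):
    """A scored environment lacks a prediction for an included site."""


# ---------------------------------------------------------------------------
# Element data
# ---------------------------------------------------------------------------

_SYMBOLS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn"
).split()

#: element symbol -> atomic number (used e.g. for X-ray-like pair weights)
ATOMIC_NUMBERS: Mapping[str, int] = {s: i + 1 for i, s in enumerate(_SYMBOLS)}

#: single-bond covalent radii in Å (Cordero et al. values, common elements)
COVALENT_RADII: Mapping[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}


def _check_element(element: str) -> str:
    if element not in ATOMIC_NUMBERS:
        raise UnsupportedElementError(f"unknown element symbol: {element!r}")
    return element


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One atom of a snapshot.

    ``site_label`` ties the atom to the compound's labeling scheme (e.g.
    ``"C3"``, ``"H13"``, ``"OH"``) and is identical for the same topological
    position across all molecules of the compound.
    """

    element: str
    position: np.ndarray  # Cartesian Å, shape (3,)
    site_label: str
    molecule_id: int
    atom_id: int

    def __post_init__(self) -> None:
        _check_element(self.element)
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise GeometryError("Atom.position must be a coordinate triple")


@dataclass(frozen=True)
class PeriodicCell:
    """A periodic simulation cell; ``lattice`` rows are the lattice vectors in Å."""

    lattice: np.ndarray  # (3, 3)

    def __post_init__(self) -> None:
        lat = np.asarray(self.lattice, dtype=float)
        if lat.shape != (3, 3):
            raise GeometryError("lattice must be a 3x3 matrix")
        if np.linalg.det(lat) <= 0:
            raise GeometryError("lattice must be right-handed and non-degenerate "
                                f"(det = {np.linalg.det(lat):g})")
        object.__setattr__(self, "lattice", lat)

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.lattice))

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.lattice)

    def to_fractional(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ self.inverse

    def to_cartesian(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.lattice

    @property
    def is_orthorhombic(self) -> bool:
        off = self.lattice - np.diag(np.diag(self.lattice))
        return bool(np.max(np.abs(off)) < 1e-9 * np.max(np.abs(self.lattice)))

    @property
    def plane_spacings(self) -> np.ndarray:
        """Distances between opposite cell faces (one per lattice direction)."""
        # fractional coordinate i changes by 1 across spacing 1/|inv column i|
        return 1.0 / np.linalg.norm(self.inverse, axis=0)

    @classmethod
    def cubic(cls, side: float) -> "PeriodicCell":
        return cls(np.eye(3) * float(side))


@dataclass(frozen=True)
class MolecularTopology:
    """Shared topology of every molecule of the compound.

    Parameters
    ----------
    site_labels:
        Ordered site labels; this order is the canonical atom order within
        each molecule of a :class:`Snapshot`.
    elements:
        Mapping site label -> element symbol.
    bonds:
        Covalent bonds as (label, label) pairs.
    dihedral_defs:
        Named torsions, each a quadruple of bonded site labels
        (e.g. ``{"hydroxyl": ("H1", "O1", "C2", "C3")}``).
    hbond_donor:
        The (oxygen label, hydroxyl proton label) donor pair, or ``None``.
    hbond_acceptors:
        Acceptor sites as (label, element) with element O or N.
    """

    site_labels: Tuple[str, ...]
    elements: Mapping[str, str]
    bonds: frozenset  # of 2-tuples (sorted label pairs)
    dihedral_defs: Mapping[str, Tuple[str, str, str, str]] = field(default_factory=dict)
    hbond_donor: Optional[Tuple[str, str]] = None
    hbond_acceptors: Tuple[Tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        labels = set(self.site_labels)
        if len(labels) != len(self.site_labels):
            raise TopologyError("duplicate site labels")
        for lab in self.site_labels:
            _check_element(self.elements[lab])
        norm_bonds = frozenset(tuple(sorted(b)) for b in self.bonds)
        object.__setattr__(self, "bonds", norm_bonds)
        for a, b in norm_bonds:
            if a not in labels or b not in labels:
                raise TopologyError(f"bond ({a}, {b}) references undeclared site")
        for name, quad in self.dihedral_defs.items():
            if len(quad) != 4 or any(q not in labels for q in quad):
                raise TopologyError(f"dihedral {name!r} references undeclared site")
            for u, v in zip(quad, quad[1:]):
                if tuple(sorted((u, v))) not in norm_bonds:
                    raise TopologyError(
                        f"dihedral {name!r}: consecutive sites {u}-{v} are not bonded")
        if self.hbond_donor is not None:
            o, h = self.hbond_donor
            if o not in labels or h not in labels:
                raise TopologyError("hbond donor references undeclared site")
            if self.elements[o] != "O" or self.elements[h] != "H":
                raise TopologyError("hbond donor must be an O-H pair")
        for lab, el in self.hbond_acceptors:
            if lab not in labels:
                raise TopologyError(f"acceptor {lab!r} undeclared")
            if el not in ("O", "N") or self.elements[lab] != el:
                raise TopologyError(f"acceptor {lab!r} must be O or N")

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    def index(self, label: str) -> int:
        return self.site_labels.index(label)

    def element_array(self) -> np.ndarray:
        return np.array([self.elements[s] for s in self.site_labels], dtype=object)

    def unwrap_order(self) -> Tuple[Tuple[int, int], ...]:
        """(child, parent) site-index pairs in BFS order from the first site.

        Used to make molecules whole under periodic boundary conditions by
        walking bonds outward from an anchor atom.
        """
        adj: dict = {i: [] for i in range(self.n_sites)}
        for a, b in self.bonds:
            ia, ib = self.index(a), self.index(b)
            adj[ia].append(ib)
            adj[ib].append(ia)
        seen = {0}
        order = []
        queue = [0]
        while queue:
            parent = queue.pop(0)
            for child in sorted(adj[parent]):
                if child not in seen:
                    seen.add(child)
                    order.append((child, parent))
                    queue.append(child)
        if len(seen) != self.n_sites:
            raise TopologyError("topology bond graph is disconnected")
        return tuple(order)


@dataclass(frozen=True)
class Snapshot:
    """A periodic cell whose atoms are partitioned into molecules of one topology.

    Atom storage is canonical: ``positions[m, s]`` is the Cartesian position
    (Å) of the site ``topology.site_labels[s]`` of the molecule
    ``molecule_ids[m]``.  Use :meth:`from_atoms` to build from an unordered
    atom list.
    """

    cell: PeriodicCell
    topology: MolecularTopology
    positions: np.ndarray       # (M, n_sites, 3)
    molecule_ids: np.ndarray    # (M,)
    snapshot_id: Tuple[int, int] = (0, 0)  # (trajectory index, frame index)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        mids = np.asarray(self.molecule_ids, dtype=int)
        if pos.ndim != 3 or pos.shape[1] != self.topology.n_sites or pos.shape[2] != 3:
            raise TopologyError("positions must have shape (M, n_sites, 3)")
        if mids.shape != (pos.shape[0],):
            raise TopologyError("molecule_ids length must match positions")
        if len(set(mids.tolist())) != len(mids):
            raise TopologyError("molecule ids must be unique within a snapshot")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "molecule_ids", mids)

    @property
    def n_molecules(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_atoms(self) -> int:
        return self.n_molecules * self.topology.n_sites

    def molecule_index(self, molecule_id: int) -> int:
        hits = np.nonzero(self.molecule_ids == molecule_id)[0]
        if hits.size == 0:
            raise TopologyError(f"unknown molecule id {molecule_id}")
        return int(hits[0])

    @property
    def atoms(self) -> list:
        """Materialize the atom list (canonical order)."""
        out = []
        labels = self.topology.site_labels
        elements = self.topology.elements
        aid = 0
        for m in range(self.n_molecules):
            for s, lab in enumerate(labels):
                out.append(Atom(elements[lab], self.positions[m, s], lab,
                                int(self.molecule_ids[m]), aid))
                aid += 1
        return out

    @classmethod
    def from_atoms(cls, cell: PeriodicCell, topology: MolecularTopology,
                   atoms: Iterable[Atom],
                   snapshot_id: Tuple[int, int] = (0, 0)) -> "Snapshot":
        """Build a snapshot from an unordered atom list.

        Validates that every molecule realizes the topology's site-label set
        exactly once.
        """
        by_mol: dict = {}
        for atom in atoms:
            by_mol.setdefault(atom.molecule_id, {})
            if atom.site_label in by_mol[atom.molecule_id]:
                raise TopologyError(
                    f"molecule {atom.molecule_id} has duplicate site {atom.site_label!r}")
            by_mol[atom.molecule_id][atom.site_label] = atom
        mids = sorted(by_mol)
        want = set(topology.site_labels)
        pos = np.empty((len(mids), topology.n_sites, 3))
        for m, mid in enumerate(mids):
            got = set(by_mol[mid])
            if got != want:
                missing = want - got
                extra = got - want
                raise TopologyError(
                    f"molecule {mid} does not realize the topology "
                    f"(missing {sorted(missing)}, extra {sorted(extra)})")
            for s, lab in enumerate(topology.site_labels):
                atom = by_mol[mid][lab]
                if atom.element != topology.elements[lab]:
                    raise TopologyError(
                        f"site {lab!r} of molecule {mid} has element "
                        f"{atom.element!r}, topology says {topology.elements[lab]!r}")
                pos[m, s] = atom.position
        return cls(cell, topology, pos, np.array(mids), snapshot_id)


@dataclass(frozen=True)
class LocalEnvironment:
    """A central molecule plus all molecules in contact with it.

    Coordinates are unwrapped: every member molecule is contiguous and placed
    at the periodic image closest to the central molecule, so the environment
    can be treated as a finite cluster.  ``coordinates[k, s]`` is the position
    of site ``s`` of member ``member_molecule_ids[k]``; the central molecule
    is always member 0.
    """

    central_molecule_id: int
    member_molecule_ids: Tuple[int, ...]
    coordinates: np.ndarray     # (n_members, n_sites, 3)
    cutoff: float
    source: Tuple[int, int]     # snapshot_id
    topology: MolecularTopology

    def __post_init__(self) -> None:
        if self.member_molecule_ids[0] != self.central_molecule_id:
            raise TopologyError("central molecule must be member 0")
        if len(set(self.member_molecule_ids)) != len(self.member_molecule_ids):
            raise TopologyError("duplicate member molecule")
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_members(self) -> int:
        return len(self.member_molecule_ids)

    @property
    def env_id(self) -> Tuple[int, int, int]:
        """(trajectory, frame, central molecule id) — globally unique key."""
        return (self.source[0], self.source[1], self.central_molecule_id)

    @property
    def central_coordinates(self) -> np.ndarray:
        return self.coordinates[0]

    def site_position(self, member: int, label: str) -> np.ndarray:
        return self.coordinates[member, self.topology.index(label)]

    def element_positions(self, element: str) -> np.ndarray:
        """All positions of a given element across all members, shape (k, 3)."""
        mask = self.topology.element_array() == element
        return self.coordinates[:, mask, :].reshape(-1, 3)


@dataclass(frozen=True)
class ShiftDistribution:
    """Experimental chemical-shift distribution of one site: Gaussian (center, width)."""

    site_label: str
    center_ppm: float
    width_ppm: float

    def __post_init__(self) -> None:
        if not self.width_ppm > 0:
            raise ValueError(f"width_ppm must be > 0 (site {self.site_label!r})")


@dataclass(frozen=True)
class ShiftPrediction:
    """Predicted shift and uncertainty for one site of one molecule in one snapshot."""

    snapshot_id: Tuple[int, int]
    molecule_id: int
    site_label: str
    shift_ppm: float
    uncertainty_ppm: float

    def __post_init__(self) -> None:
        if not self.uncertainty_ppm > 0:
            raise ValueError("uncertainty_ppm must be > 0")


@dataclass(frozen=True)
class ShiftReferencing:
    """Per-element shielding-to-shift offsets (ppm): delta = offset - shielding."""

    offsets: Mapping[str, float] = field(
        default_factory=lambda: {"H": 30.78, "C": 170.04})

    def __post_init__(self) -> None:
        for el, off in self.offsets.items():
            _check_element(el)
            if not math.isfinite(off):
                raise ValueError(f"offset for {el} must be finite")


DEFAULT_REFERENCING = ShiftReferencing()


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def shielding_to_shift(shielding, element: str,
                       ref: ShiftReferencing = DEFAULT_REFERENCING):
    """Convert an isotropic chemical shielding to a chemical shift (both ppm).

    Uses the universal referencing convention ``delta = offset - shielding``:
    the shift is affine in the shielding and order-reversing (more shielded
    nuclei resonate at lower shift).
    """
    if element not in ref.offsets:
        raise UnsupportedElementError(
            f"no referencing offset for element {element!r}")
    return ref.offsets[element] - np.asarray(shielding, dtype=float)


def dihedral_angle(p1, p2, p3, p4, convention: str = "iupac") -> float:
    """Signed torsion angle (degrees, in (-180, 180]) about the p2-p3 axis.

    With ``convention="iupac"`` the sign follows the right-hand rule looking
    from p2 towards p3 (cis = 0, trans = 180).  ``convention="reverse"``
    flips the sign, for comparisons against data using the opposite handedness.
    The value is invariant under rigid motions and under reversing the atom
    order (p4, p3, p2, p1).
    """
    if convention not in ("iupac", "reverse"):
        raise ValueError(f"unknown sign convention {convention!r}")
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    scale = max(np.linalg.norm(b1), nb2, np.linalg.norm(b3))
    if scale == 0.0 or nb2 < 1e-10 * scale:
        raise GeometryError("degenerate torsion: consecutive points coincide")
    if np.linalg.norm(n1) < 1e-10 * scale ** 2 or np.linalg.norm(n2) < 1e-10 * scale ** 2:
        raise GeometryError("degenerate torsion: collinear triple of points")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    angle = math.degrees(math.atan2(y, x))
    if convention == "reverse":
        angle = -angle
    if angle <= -180.0:
        angle += 360.0
    return angle
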