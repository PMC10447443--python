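"""Structural characterization of environment sets.

Covers the analyses run on the selected ("NMR") and reference ensembles:

* hydrogen-bond detection and acceptor censuses (O-H...X motifs, X = O or N,
  with an O-H-X angle above 130 degrees and an H...X distance below 2.5 Å);
* dihedral-angle histograms for conformer populations;
* least-RMSD rigid alignment of environments on chosen central-molecule atoms
  (Kabsch superposition, proper rotations only);
* per-element 3D atomic density maps: the average over aligned environments
  of unnormalized Gaussians (sigma = 0.5 Å) placed at atomic positions,
  evaluated on a 31 x 31 x 31 grid with 12 Å sides (0.4 Å spacing), so a
  value of 1 at a point means an atom of that element sits there in every
  environment;
* total radial distribution functions G(r) and differential correlation
  functions D(r) with Keen-style conventions and X-ray-like Z weighting,
  plus residual/RMSE comparison against a reference curve.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (ATOMIC_NUMBERS, GeometryError, LocalEnvironment,
                   MolecularTopology, Snapshot, TopologyError)
from .environments import make_whole, _pairwise_min_image

__all__ = [
    "HBondCriteria", "HBond", "detect_hbond", "hbond_census",
    "dihedral_histogram", "environment_dihedrals",
    "align_environments", "DensityMapSpec", "density_map",
    "density_difference_map", "radial_distribution", "RDFResult",
    "curve_residual", "CurveResidual",
]

NO_ACCEPTOR = "none"


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria: H...X distance below
    ``max_H_X_distance`` and O-H-X angle above ``min_O_H_X_angle``."""

    max_H_X_distance: float = 2.5     # Å
    min_O_H_X_angle: float = 130.0    # degrees
    acceptor_elements: frozenset = frozenset({"O", "N"})

    def __post_init__(self) -> None:
        if not self.max_H_X_distance > 0:
            raise ValueError("max_H_X_distance must be positive")
        if not 0 < self.min_O_H_X_angle <= 180:
            raise ValueError("min_O_H_X_angle must lie in (0, 180]")


@dataclass(frozen=True)
class HBond:
    """A detected O-H...X hydrogen bond of the central molecule's donor."""

    acceptor_site_label: str
    acceptor_molecule_id: int
    distance: float   # H...X, Å
    angle: float      # O-H-X, degrees


def detect_hbond(env: LocalEnvironment,
                 criteria: HBondCriteria = HBondCriteria()) -> Optional[HBond]:
    """Scan the environment for a hydrogen bond of the central molecule's
    O-H donor.

    Every O or N atom of every member (including the central molecule itself,
    allowing intramolecular bonds) except the donor oxygen is a candidate
    acceptor.  Among candidates satisfying both criteria the one with the
    shortest H...X distance wins; returns ``None`` if no candidate qualifies.
    """
    topo = env.topology
    if topo.hbond_donor is None:
        raise TopologyError("topology declares no O-H donor")
    o_label, h_label = topo.hbond_donor
    o_idx, h_idx = topo.index(o_label), topo.index(h_label)
    o_pos = env.coordinates[0, o_idx]
    h_pos = env.coordinates[0, h_idx]

    elements = topo.element_array()
    acc_sites = np.nonzero(np.isin(elements, list(criteria.acceptor_elements)))[0]
    best: Optional[HBond] = None
    oh = o_pos - h_pos
    oh /= np.linalg.norm(oh)
    for member in range(env.n_members):
        for s in acc_sites:
            if member == 0 and s == o_idx:
                continue  # the donor oxygen itself
            x_pos = env.coordinates[member, s]
            hx = x_pos - h_pos
            d = float(np.linalg.norm(hx))
            if d >= criteria.max_H_X_distance:
                continue
            cosang = float(np.dot(oh, hx / d))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle <= criteria.min_O_H_X_angle:
                continue
            if best is None or d < best.distance:
                best = HBond(topo.site_labels[s],
                             int(env.member_molecule_ids[member]), d, angle)
    return best


def hbond_census(envs: Iterable[LocalEnvironment],
                 criteria: HBondCriteria = HBondCriteria()
                 ) -> Dict[str, float]:
    """Fractions of environments bonded to each acceptor site label, plus
    the ``"none"`` category; fractions sum to 1."""
    counts: Dict[str, int] = {}
    total = 0
    for env in envs:
        hb = detect_hbond(env, criteria)
        key = hb.acceptor_site_label if hb is not None else NO_ACCEPTOR
        counts[key] = counts.get(key, 0) + 1
        total += 1
    if total == 0:
        raise ValueError("empty environment set")
    return {k: v / total for k, v in sorted(counts.items())}


# ---------------------------------------------------------------------------
# Dihedral histograms
# ---------------------------------------------------------------------------

def environment_dihedrals(envs: Iterable[LocalEnvironment], dihedral_name: str,
                          convention: str = "iupac") -> np.ndarray:
    """Dihedral angle of the central molecule for every environment (degrees)."""
    from .core import dihedral_angle
    angles = []
    for env in envs:
        topo = env.topology
        if dihedral_name not in topo.dihedral_defs:
            raise TopologyError(f"undefined dihedral {dihedral_name!r}")
        quad = topo.dihedral_defs[dihedral_name]
        pts = [env.coordinates[0, topo.index(q)] for q in quad]
        angles.append(dihedral_angle(*pts, convention=convention))
    return np.asarray(angles)


def dihedral_histogram(envs: Sequence[LocalEnvironment], dihedral_name: str,
                       bins: int = 36, density: bool = False,
                       convention: str = "iupac"
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of a named central-molecule dihedral over (-180, 180].

    The binning is fixed and periodic: an angle of exactly -180 (the wrap
    point) is counted in the topmost bin.  Returns (counts, bin_edges).
    """
    angles = environment_dihedrals(envs, dihedral_name, convention)
    angles = np.where(angles <= -180.0, angles + 360.0, angles)
    edges = np.linspace(-180.0, 180.0, bins + 1)
    counts, edges = np.histogram(angles, bins=edges, density=density)
    return counts, edges


# ---------------------------------------------------------------------------
# Alignment and density maps
# ---------------------------------------------------------------------------

def _alignment_points(env: LocalEnvironment, labels: Sequence[str]) -> np.ndarray:
    topo = env.topology
    return np.array([env.coordinates[0, topo.index(lab)] for lab in labels])


def align_environments(envs: Sequence[LocalEnvironment],
                       alignment_site_labels: Sequence[str],
                       reference: int = 0
                       ) -> Tuple[List[np.ndarray], np.ndarray]:
    """Rigidly superpose every environment onto a reference using only the
    named central-molecule sites (least-RMSD Kabsch fit, proper rotations).

    Returns ``(aligned, rmsds)``: the transformed full coordinate arrays of
    each environment (same shapes as the inputs) and the per-environment
    RMSD over the alignment atoms, which is the global minimum over all
    proper rigid motions.
    """
    if len(alignment_site_labels) < 3:
        raise GeometryError("alignment needs at least three sites")
    if not envs:
        raise ValueError("empty environment set")
    ref_pts = _alignment_points(envs[reference], alignment_site_labels)
    spread = ref_pts - ref_pts.mean(axis=0)
    if np.linalg.matrix_rank(spread, tol=1e-8) < 2:
        raise GeometryError("alignment sites are collinear or coincident")
    ref_centroid = ref_pts.mean(axis=0)
    aligned, rmsds = [], []
    for env in envs:
        pts = _alignment_points(env, alignment_site_labels)
        centroid = pts.mean(axis=0)
        rot, rssd = Rotation.align_vectors(ref_pts - ref_centroid, pts - centroid)
        moved = rot.apply((env.coordinates - centroid).reshape(-1, 3)).reshape(
            env.coordinates.shape) + ref_centroid
        aligned.append(moved)
        rmsds.append(rssd / np.sqrt(len(alignment_site_labels)))
    return aligned, np.asarray(rmsds)


@dataclass(frozen=True)
class DensityMapSpec:
    """Grid and kernel for 3D atomic density maps.

    Nodes span ``center +/- cube_side/2`` inclusive on each axis
    (``grid_points_per_side`` nodes), hence a spacing of
    ``cube_side / (grid_points_per_side - 1)`` = 0.4 Å by default.
    """

    grid_points_per_side: int = 31
    cube_side: float = 12.0       # Å
    gaussian_width: float = 0.5   # sigma, Å
    center: Optional[np.ndarray] = None  # default: aligned-atom centroid

    def __post_init__(self) -> None:
        if self.grid_points_per_side < 2 or self.cube_side <= 0 \
                or self.gaussian_width <= 0:
            raise ValueError("invalid density map specification")

    @property
    def spacing(self) -> float:
        return self.cube_side / (self.grid_points_per_side - 1)

    def axes(self, center: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        half = self.cube_side / 2.0
        return tuple(np.linspace(c - half, c + half, self.grid_points_per_side)
                     for c in center)


def density_map(aligned_coords: Sequence[np.ndarray],
                elements: np.ndarray, element: str,
                spec: DensityMapSpec = DensityMapSpec(),
                center: Optional[np.ndarray] = None
                ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-element atomic density map over a set of aligned environments.

    ``aligned_coords`` holds the (n_members, n_sites, 3) arrays returned by
    :func:`align_environments`; ``elements`` is the per-site element array of
    the shared topology.  At each grid node the map is the mean over
    environments of the summed unnormalized Gaussians of that element's
    atoms, so it equals 1 where an atom of the element sits in every
    environment.  Returns ``(values, grid_center)`` with values of shape
    (n, n, n) indexed (x, y, z).
    """
    if len(aligned_coords) == 0:
        raise ValueError("empty environment set")
    mask = np.asarray(elements) == element
    if center is None:
        center = spec.center
    if center is None:
        raise ValueError("grid center required (pass the aligned-atom centroid)")
    center = np.asarray(center, dtype=float)
    ax = spec.axes(center)
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    nodes = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    values = np.zeros(len(nodes))
    two_s2 = 2.0 * spec.gaussian_width ** 2
    for coords in aligned_coords:
        pts = coords[:, mask, :].reshape(-1, 3)
        if pts.size == 0:
            continue
        d2 = ((nodes[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
        values += np.exp(-d2 / two_s2).sum(axis=1)
    values /= len(aligned_coords)
    n = spec.grid_points_per_side
    return values.reshape(n, n, n), center


def density_difference_map(map_selected: np.ndarray, map_random: np.ndarray
                           ) -> np.ndarray:
    """Pointwise difference (selected - random) of two maps on identical grids."""
    a = np.asarray(map_selected, dtype=float)
    b = np.asarray(map_random, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"mismatched grids: {a.shape} vs {b.shape}")
    return a - b


# ---------------------------------------------------------------------------
# Radial distribution functions
# ---------------------------------------------------------------------------

@dataclass
class RDFResult:
    """Partial pair distributions and the weighted totals.

    ``g_total(r) -> 1`` at large r; ``d(r) = 4 pi rho r (g_total(r) - 1)``
    (Keen-style differential correlation function) with ``rho`` the total
    atom number density.
    """

    r: np.ndarray
    partials: Dict[Tuple[str, str], np.ndarray]
    weights: Dict[Tuple[str, str], float]
    g_total: np.ndarray
    d: np.ndarray
    rho: float


def radial_distribution(snapshots: Sequence[Snapshot], r_max: float = 10.0,
                        dr: float = 0.05, weighting: str = "xray",
                        central_molecule_ids: Optional[Mapping[Tuple[int, int],
                                                               Sequence[int]]] = None
                        ) -> RDFResult:
    """Element-pair partial g_ab(r) by minimum-image histogramming, combined
    into a total G(r) and D(r).

    ``weighting="xray"`` uses w_ab = c_a c_b Z_a Z_b / (sum_e c_e Z_e)^2
    (X-ray-like, atomic-number proportional); ``"unit"`` uses concentration
    products only.  ``central_molecule_ids`` optionally restricts one side of
    each pair to atoms of chosen central molecules per snapshot (keyed by
    snapshot id), yielding the distribution seen from an ensemble of selected
    molecules.  ``r_max`` must not exceed half the smallest cell face spacing.
    """
    if weighting not in ("xray", "unit"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if not snapshots:
        raise ValueError("no snapshots")
    edges = np.arange(0.0, r_max + dr, dr)
    r = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)

    elements = snapshots[0].topology.element_array()
    species = sorted(set(elements.tolist()))
    pair_hist = {p: np.zeros(len(r)) for p in
                 itertools.combinations_with_replacement(species, 2)}
    norm_acc = {p: 0.0 for p in pair_hist}
    n_by_el_total = {e: 0 for e in species}
    n_atoms_total = 0
    vol_total = 0.0

    for snap in snapshots:
        if float(np.min(snap.cell.plane_spacings)) < 2.0 * r_max:
            raise GeometryError(
                f"r_max = {r_max} Å exceeds half the smallest cell width of "
                f"snapshot {snap.snapshot_id}")
        whole = make_whole(snap)
        pos = whole.reshape(-1, 3)
        el = np.tile(elements, snap.n_molecules)
        dist, _ = _pairwise_min_image(snap.cell, pos)
        vol = snap.cell.volume
        vol_total += vol
        n_atoms_total += len(pos)
        if central_molecule_ids is None:
            row_mask = np.ones(len(pos), dtype=bool)
        else:
            chosen = set(central_molecule_ids.get(snap.snapshot_id, ()))
            per_atom = np.repeat(snap.molecule_ids, snap.topology.n_sites)
            row_mask = np.isin(per_atom, list(chosen))
        np.fill_diagonal(dist, np.inf)
        for a, b in pair_hist:
            rows = row_mask & (el == a)
            cols = el == b
            n_a, n_b = int(rows.sum()), int((el == b).sum())
            if n_a == 0 or n_b == 0:
                continue
            d = dist[np.ix_(rows, cols)].ravel()
            pair_hist[(a, b)] += np.histogram(d[d < r_max + dr], bins=edges)[0]
            # expected ideal-gas counts for ordered (row, col) pairs,
            # excluding self-pairs (the filled diagonal)
            norm_acc[(a, b)] += (n_a * n_b - int((rows & cols).sum())) / vol
        for e in species:
            n_by_el_total[e] += int((el == e).sum())

    partials = {}
    for p, hist in pair_hist.items():
        if norm_acc[p] > 0:
            partials[p] = hist / (norm_acc[p] * shell_vol)
        else:
            partials[p] = np.zeros_like(hist)

    conc = {e: n_by_el_total[e] / n_atoms_total for e in species}
    if weighting == "xray":
        raw = {(a, b): conc[a] * conc[b] * ATOMIC_NUMBERS[a] * ATOMIC_NUMBERS[b]
               for a, b in partials}
    else:
        raw = {(a, b): conc[a] * conc[b] for a, b in partials}
    # off-diagonal pairs appear twice in the double sum over species
    full = {p: (w if p[0] == p[1] else 2 * w) for p, w in raw.items()}
    wsum = sum(full.values())
    weights = {p: w / wsum for p, w in full.items()}
    g_total = sum(weights[p] * partials[p] for p in partials)
    rho = n_atoms_total / vol_total
    d_curve = 4.0 * np.pi * rho * r * (g_total - 1.0)
    return RDFResult(r=r, partials=partials, weights=weights,
                     g_total=g_total, d=d_curve, rho=rho)


# ---------------------------------------------------------------------------
# Curve comparison
# ---------------------------------------------------------------------------

@dataclass
class CurveResidual:
    """Residual (reference - simulated, on the reference grid) and its RMSEs."""

    r: np.ndarray
    residual: np.ndarray
    rmse: float
    rmse_subrange: float
    subrange: Tuple[float, float]


def curve_residual(simulated: Tuple[np.ndarray, np.ndarray],
                   reference: Tuple[np.ndarray, np.ndarray],
                   subrange: Tuple[float, float] = (3.0, 10.0)
                   ) -> CurveResidual:
    """Pointwise residual between a simulated and a reference curve.

    The simulated curve is linearly interpolated onto the reference grid
    restricted to the overlap of the two supports; RMSEs are reported over
    the full overlap and over ``subrange`` (default 3-10 Å).
    """
    r_sim, y_sim = (np.asarray(a, dtype=float) for a in simulated)
    r_ref, y_ref = (np.asarray(a, dtype=float) for a in reference)
    lo = max(r_sim.min(), r_ref.min())
    hi = min(r_sim.max(), r_ref.max())
    if lo >= hi:
        raise ValueError("curves have disjoint r supports")
    mask = (r_ref >= lo) & (r_ref <= hi)
    r = r_ref[mask]
    resid = y_ref[mask] - np.interp(r, r_sim, y_sim)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    sub = (r >= subrange[0]) & (r <= subrange[1])
    rmse_sub = float(np.sqrt(np.mean(resid[sub] ** 2))) if sub.any() else float("nan")
    return CurveResidual(r=r, residual=resid, rmse=rmse,
                         rmse_subrange=rmse_sub, subrange=subrange)
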