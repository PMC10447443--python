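"""Self-contained synthetic fixtures with planted ground truth.

The generator emulates the statistical and geometric structure the selection
method assumes about its inputs, without any force field:

* :func:`generate_packing` builds periodic amorphous packings of a small
  flexible toy molecule (one rotatable backbone bond, an O-H donor, one N
  and one O acceptor) by random insertion with overlap rejection.  Each
  molecule is planted into a conformer class (backbone dihedral +60 or -60
  degrees) and a hydrogen-bond class (donor aimed at a neighboring acceptor
  within the detection criteria, or kept free of acceptors within a buffer
  band), and the ground truth is returned as a manifest.
* :func:`generate_shifts` turns packed snapshots into per-site "predicted"
  shifts (class-dependent mean plus Gaussian noise, heteroscedastic
  log-normal uncertainties, so quartile capping is exercised) and matching
  "experimental" distributions centered on the target-class means with
  linewidths emulating amorphous solids (2-6 ppm for carbons, 0.6-1 ppm for
  protons, 1.8 ppm for the hydroxyl proton).
* :func:`generate_scoring_benchmark` plants a subpopulation directly in
  prediction tables (no geometry), for statistical tests of the selection
  machinery at large environment counts.

All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import (MolecularTopology, PackingError, PeriodicCell, Snapshot,
                   dihedral_angle)
from .environments import _min_image_batch, minimum_image_vector

__all__ = [
    "toy_topology", "toy_template", "trivial_topology", "set_dihedral",
    "generate_packing", "generate_trajectory", "generate_trivial_snapshots",
    "generate_shifts", "generate_scoring_benchmark", "TOY_SHIFT_MODEL",
]


# ---------------------------------------------------------------------------
# Toy molecule
# ---------------------------------------------------------------------------

_TOY_SITES = ("O1", "H1", "C2", "H2a", "H2b", "C3", "H3", "N1", "C4", "O2", "H4")
_TOY_ELEMENTS = {"O1": "O", "H1": "H", "C2": "C", "H2a": "H", "H2b": "H",
                 "C3": "C", "H3": "H", "N1": "N", "C4": "C", "O2": "O",
                 "H4": "H"}
_TOY_BONDS = frozenset({("O1", "H1"), ("O1", "C2"), ("C2", "H2a"),
                        ("C2", "H2b"), ("C2", "C3"), ("C3", "H3"),
                        ("C3", "N1"), ("C3", "C4"), ("C4", "O2"),
                        ("C4", "H4")})
_TOY_DIHEDRALS = {"hydroxyl": ("H1", "O1", "C2", "C3"),
                  "backbone": ("O1", "C2", "C3", "N1")}

_TOY_COORDS = {
    "C3": (0.000, 0.000, 0.000),
    "N1": (1.470, 0.000, 0.000),
    "C4": (-0.730, 1.270, 0.000),
    "H3": (-0.629, -0.629, -0.629),
    "C2": (-0.512, -0.640, 1.281),
    "O1": (-1.829, -0.245, 1.676),
    "H1": (-2.103, 0.668, 1.858),
    "H2a": (0.261, -1.327, 1.624),
    "H2b": (-0.235, 0.007, 2.113),
    "O2": (-0.730, 2.439, 0.350),
    "H4": (-1.742, 1.270, -0.404),
}


def toy_topology() -> MolecularTopology:
    """Topology of the flexible toy molecule used by the synthetic fixtures."""
    return MolecularTopology(
        site_labels=_TOY_SITES,
        elements=_TOY_ELEMENTS,
        bonds=_TOY_BONDS,
        dihedral_defs=_TOY_DIHEDRALS,
        hbond_donor=("O1", "H1"),
        hbond_acceptors=(("N1", "N"), ("O2", "O")),
    )


def toy_template() -> Tuple[MolecularTopology, np.ndarray]:
    """Topology plus base coordinates (Å, centered on the centroid)."""
    topo = toy_topology()
    coords = np.array([_TOY_COORDS[s] for s in topo.site_labels])
    return topo, coords - coords.mean(axis=0)


def trivial_topology() -> MolecularTopology:
    """A rigid 3-atom bent molecule for large-scale bookkeeping runs."""
    return MolecularTopology(
        site_labels=("O1", "H1a", "H1b"),
        elements={"O1": "O", "H1a": "H", "H1b": "H"},
        bonds=frozenset({("O1", "H1a"), ("O1", "H1b")}),
    )


_TRIVIAL_COORDS = np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0],
                            [-0.24, 0.93, 0.0]])


def set_dihedral(coords: np.ndarray, topology: MolecularTopology, name: str,
                 target_deg: float) -> np.ndarray:
    """Return coordinates with the named torsion rotated to ``target_deg``.

    Rotates the bond-graph component on the far side of the torsion's central
    bond; all other atoms stay fixed.
    """
    a, b, c, d = (topology.index(s) for s in topology.dihedral_defs[name])
    coords = np.asarray(coords, dtype=float).copy()
    current = dihedral_angle(coords[a], coords[b], coords[c], coords[d])
    delta = math.radians(target_deg - current)
    # component containing c when the b-c edge is removed
    adj: Dict[int, List[int]] = {i: [] for i in range(topology.n_sites)}
    for u, v in topology.bonds:
        iu, iv = topology.index(u), topology.index(v)
        adj[iu].append(iv)
        adj[iv].append(iu)
    moving = {c}
    stack = [c]
    while stack:
        node = stack.pop()
        for nxt in adj[node]:
            if (node, nxt) in ((b, c), (c, b)):
                continue
            if nxt not in moving:
                moving.add(nxt)
                stack.append(nxt)
    moving.discard(c)
    axis = coords[c] - coords[b]
    axis = axis / np.linalg.norm(axis)
    idx = sorted(moving)
    for sign in (1.0, -1.0):
        rot = Rotation.from_rotvec(axis * sign * delta)
        trial = coords.copy()
        trial[idx] = rot.apply(coords[idx] - coords[c]) + coords[c]
        got = dihedral_angle(trial[a], trial[b], trial[c], trial[d])
        if abs((got - target_deg + 180.0) % 360.0 - 180.0) < 1e-6:
            return trial
    raise RuntimeError("dihedral rotation did not converge")  # pragma: no cover


# ---------------------------------------------------------------------------
# Packing generation
# ---------------------------------------------------------------------------

#: band between the strict detection criteria and the exclusion zone enforced
#: for non-hydrogen-bonded molecules (distance Å, angle degrees)
STRICT_HB = (2.5, 130.0)
BUFFER_HB = (3.0, 120.0)


def _random_rotation(rng: np.random.Generator) -> Rotation:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q))


def _acceptor_atoms(topology: MolecularTopology) -> List[int]:
    """Indices of every O/N site except the donor oxygen (candidate acceptors)."""
    donor_o = topology.hbond_donor[0] if topology.hbond_donor else None
    out = []
    for i, lab in enumerate(topology.site_labels):
        if lab == donor_o:
            continue
        if topology.elements[lab] in ("O", "N"):
            out.append(i)
    return out


def _donor_contact(cell: PeriodicCell, topology: MolecularTopology,
                   coords_m: np.ndarray, others: Mapping[int, np.ndarray],
                   self_id: int, dist_thr: float, angle_thr: float
                   ) -> Optional[Tuple[float, float, int, int]]:
    """Closest qualifying acceptor of the molecule's O-H donor, or None.

    Scans the molecule's own non-donor O/N atoms and every O/N atom of the
    other molecules, under minimum-image displacements.  Returns
    (distance, angle, acceptor site index, acceptor molecule id).
    """
    o_idx = topology.index(topology.hbond_donor[0])
    h_idx = topology.index(topology.hbond_donor[1])
    h = coords_m[h_idx]
    oh = coords_m[o_idx] - h
    oh = oh / np.linalg.norm(oh)
    acc = _acceptor_atoms(topology)
    best = None
    candidates = [(self_id, coords_m)] + [(mid, c) for mid, c in others.items()]
    for mid, coords in candidates:
        for s in acc:
            hx = minimum_image_vector(cell, h, coords[s], search=1)
            d = float(np.linalg.norm(hx))
            if d >= dist_thr or d < 1e-6:
                continue
            ang = math.degrees(math.acos(float(np.clip(np.dot(oh, hx / d),
                                                       -1.0, 1.0))))
            if ang <= angle_thr:
                continue
            if best is None or d < best[0]:
                best = (d, ang, s, mid)
    return best


def _min_intermolecular_distance(cell: PeriodicCell, a: np.ndarray,
                                 b: np.ndarray) -> float:
    diffs = b[None, :, :] - a[:, None, :]
    mi = _min_image_batch(cell, diffs)
    return float(np.sqrt((mi ** 2).sum(axis=-1).min()))


def _orthonormal_basis(u: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    w1 = np.cross(u, ref)
    w1 /= np.linalg.norm(w1)
    return w1, np.cross(u, w1)


def _place_as_donor(rng: np.random.Generator, topology: MolecularTopology,
                    base: np.ndarray, target_pos: np.ndarray
                    ) -> np.ndarray:
    """Pose the molecule so its O-H donor points at ``target_pos``.

    The H...X distance is sampled in (2.05, 2.35) Å and the O-H-X angle in
    (150, 178) degrees — inside the detection criteria with margin; the
    remaining rigid-body freedom (approach direction, azimuth, roll) is
    random.
    """
    o_idx = topology.index(topology.hbond_donor[0])
    h_idx = topology.index(topology.hbond_donor[1])
    d = rng.uniform(2.05, 2.35)
    theta = math.radians(rng.uniform(150.0, 178.0))
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    h_pos = target_pos + d * u
    w1, w2 = _orthonormal_basis(u)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    w = math.cos(phi) * w1 + math.sin(phi) * w2
    # v = desired H->O direction: angle theta away from H->X (= -u)
    v = math.cos(theta) * (-u) + math.sin(theta) * w
    bond = base[o_idx] - base[h_idx]
    r0, _ = Rotation.align_vectors(v[None, :], (bond / np.linalg.norm(bond))[None, :])
    roll = Rotation.from_rotvec(v * rng.uniform(0.0, 2.0 * math.pi))
    rot = roll * r0
    return rot.apply(base - base[h_idx]) + h_pos


def _exact_counts(fractions: Mapping[str, float], n: int) -> Dict[str, int]:
    """Largest-remainder apportionment of n items among classes."""
    raw = {k: fractions[k] * n for k in fractions}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    rest = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:rest]:
        counts[k] += 1
    return counts


def generate_packing(n_molecules: int = 32, cell_side: float = 28.0,
                     molecule_template: Optional[Tuple[MolecularTopology,
                                                       np.ndarray]] = None,
                     conformer_fractions: Optional[Mapping[str, float]] = None,
                     hbond_fraction: float = 0.3,
                     min_intermolecular_distance: float = 2.0,
                     seed=0, max_tries: int = 400, restarts: int = 40,
                     snapshot_id: Tuple[int, int] = (0, 0)
                     ) -> Tuple[Snapshot, pd.DataFrame]:
    """Random-insertion packing with planted conformer and H-bond classes.

    Returns ``(snapshot, manifest)``; the manifest has one row per molecule
    with columns ``molecule_id``, ``conformer_class``, ``hbond_planted``,
    ``acceptor_site`` and ``acceptor_molecule`` (detection outcome at
    generation time).  Planted labels are guaranteed consistent with
    ``detect_hbond`` under the strict criteria, with a buffer band
    (H...X < 3.0 Å, angle > 120 degrees) kept free of acceptors for
    non-bonded molecules.

    Raises :class:`PackingError` when the density or the planted constraints
    cannot be satisfied within the retry budget.
    """
    topo, base0 = molecule_template or toy_template()
    if conformer_fractions is None:
        conformer_fractions = {"A": 0.5, "B": 0.5}
    conf_angle = {"A": 60.0, "B": -60.0}
    cell = PeriodicCell.cubic(cell_side)
    rng = np.random.default_rng(seed)

    conf_counts = _exact_counts(conformer_fractions, n_molecules)
    conf_classes = [k for k, c in sorted(conf_counts.items()) for _ in range(c)]
    rng.shuffle(conf_classes)
    n_hb = int(round(hbond_fraction * n_molecules))
    hb_flags = np.array([True] * n_hb + [False] * (n_molecules - n_hb))
    rng.shuffle(hb_flags)
    all_hbond = n_hb == n_molecules

    order = sorted(range(n_molecules), key=lambda i: hb_flags[i])  # free first

    for attempt in range(restarts):
        result = _try_pack(rng, topo, base0, cell, order, conf_classes,
                           hb_flags, conf_angle, min_intermolecular_distance,
                           max_tries, all_hbond)
        if result is not None:
            placed, records = result
            mids = np.arange(n_molecules)
            pos = np.stack([placed[i] for i in mids])
            snap = Snapshot(cell, topo, pos, mids, snapshot_id)
            manifest = pd.DataFrame(
                [records[i] for i in mids],
                columns=["molecule_id", "conformer_class", "hbond_planted",
                         "acceptor_site", "acceptor_molecule"])
            return snap, manifest
    raise PackingError(
        f"could not pack {n_molecules} molecules in a {cell_side} Å cell "
        f"after {restarts} restarts (density or planted classes infeasible)")


def _try_pack(rng, topo, base0, cell, order, conf_classes, hb_flags,
              conf_angle, min_dist, max_tries, all_hbond):
    placed: Dict[int, np.ndarray] = {}
    records: Dict[int, list] = {}
    pending_closure: Optional[int] = None

    last_mol = order[-1]
    for mol in order:
        base = set_dihedral(base0, topo, "backbone", conf_angle[conf_classes[mol]])
        success = False
        is_first_donor = hb_flags[mol] and not placed
        for _ in range(max_tries):
            trial = set_dihedral(base, topo, "hydroxyl", rng.uniform(-180, 180))
            if hb_flags[mol] and placed:
                # while an all-donor set awaits closure, crowd the pending
                # molecule so its hydroxyl can eventually reach an acceptor
                tgt_mol = pending_closure if pending_closure is not None \
                    else int(rng.choice(sorted(placed)))
                acc = _acceptor_atoms(topo)
                tgt_site = int(rng.choice(acc))
                coords = _place_as_donor(rng, topo, trial,
                                         placed[tgt_mol][tgt_site])
            else:
                rot = _random_rotation(rng)
                coords = rot.apply(trial) + rng.uniform(0, 1, 3) @ cell.lattice
            if any(_min_intermolecular_distance(cell, coords, p) < min_dist
                   for p in placed.values()):
                continue
            # incremental consistency: the new molecule's own donor status,
            # plus existing non-bonded donors against the new acceptors only
            # (adding atoms cannot break an existing hydrogen bond)
            if hb_flags[mol]:
                if not is_first_donor and _donor_contact(
                        cell, topo, coords, placed, mol, *STRICT_HB) is None:
                    continue
            else:
                if _donor_contact(cell, topo, coords, placed, mol,
                                  *BUFFER_HB) is not None:
                    continue
            new_only = {mol: coords}
            clash = False
            for m in placed:
                if hb_flags[m]:
                    continue
                if _donor_contact(cell, topo, placed[m], new_only, m,
                                  *BUFFER_HB) is not None:
                    clash = True
                    break
            if clash:
                continue
            if pending_closure is not None and hb_flags[mol] and placed:
                candidate = dict(placed)
                candidate[mol] = coords
                closed = _close_donor(cell, topo, candidate, pending_closure,
                                      min_dist)
                if closed is not None:
                    placed[mol] = coords
                    placed[pending_closure] = closed
                    pending_closure = None
                    success = True
                    break
                if mol == last_mol:
                    continue  # the last donor must enable closure
            placed[mol] = coords
            if is_first_donor:
                pending_closure = mol
            success = True
            break
        if not success:
            return None

    if pending_closure is not None:
        return None

    # final verification + record detection outcomes
    for mid, coords in placed.items():
        others = {k: v for k, v in placed.items() if k != mid}
        hit = _donor_contact(cell, topo, coords, others, mid, *STRICT_HB)
        if bool(hb_flags[mid]) != (hit is not None):
            return None
        records[mid] = [mid, conf_classes[mid], bool(hb_flags[mid]),
                        topo.site_labels[hit[2]] if hit else None,
                        hit[3] if hit else -1]
    return placed, records


def _close_donor(cell, topo, placed, mol, min_dist, n_steps=720):
    """Swing the pending molecule's hydroxyl proton about its O-C axis and
    look for an orientation whose O-H donor finds a neighboring acceptor
    with margin inside the criteria (2.05 <= H...X < 2.45 Å, angle > 135).

    Only the hydroxyl proton moves, so the sole new steric constraint is
    that proton's minimum-image distance to the other molecules.  Returns
    the adjusted coordinates or None.
    """
    o_idx = topo.index(topo.hbond_donor[0])
    h_idx = topo.index(topo.hbond_donor[1])
    coords = placed[mol]
    # rotation axis: the O-heavy-atom bond (O's neighbor other than H)
    partner = None
    for a, b in topo.bonds:
        pair = {topo.index(a), topo.index(b)}
        if o_idx in pair:
            other = (pair - {o_idx}).pop()
            if other != h_idx:
                partner = other
                break
    if partner is None:
        return None
    axis = coords[o_idx] - coords[partner]
    axis = axis / np.linalg.norm(axis)
    p = coords[h_idx] - coords[o_idx]
    p_par = np.dot(p, axis) * axis
    p_perp = p - p_par
    t = np.linspace(0.0, 2.0 * np.pi, n_steps, endpoint=False)
    h_pos = coords[o_idx] + p_par + np.cos(t)[:, None] * p_perp \
        + np.sin(t)[:, None] * np.cross(axis, p_perp)          # (T, 3)

    others = {k: v for k, v in placed.items() if k != mol}
    if not others:
        return None
    other_atoms = np.concatenate(list(others.values()))        # (K, 3)
    mi = _min_image_batch(cell, other_atoms[None, :, :] - h_pos[:, None, :])
    d_all = np.sqrt((mi ** 2).sum(axis=-1))                    # (T, K)
    steric_ok = d_all.min(axis=1) >= min_dist

    acc_cols = []
    col = 0
    acc_sites = set(_acceptor_atoms(topo))
    for _, c in others.items():
        for s in range(len(c)):
            if s in acc_sites:
                acc_cols.append(col)
            col += 1
    acc_cols = np.asarray(acc_cols, dtype=int)
    d_acc = d_all[:, acc_cols]
    hx = mi[:, acc_cols, :]
    ho = coords[o_idx] - h_pos                                  # (T, 3)
    ho = ho / np.linalg.norm(ho, axis=1, keepdims=True)
    cosang = np.einsum("tj,taj->ta", ho, hx / d_acc[..., None])
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    qualifies = (d_acc >= max(2.05, min_dist)) & (d_acc < 2.45) & (ang > 135.0)
    good = np.nonzero(steric_ok & qualifies.any(axis=1))[0]
    if good.size == 0:
        return None
    trial = coords.copy()
    trial[h_idx] = h_pos[int(good[0])]
    return trial


def generate_trajectory(n_snapshots: int = 50, n_molecules: int = 32,
                        trajectory_index: int = 0, seed=0, **kwargs
                        ) -> Tuple[List[Snapshot], pd.DataFrame]:
    """Generate a trajectory of packings; manifest gains trajectory/frame."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_snapshots)
    snaps, manifests = [], []
    for frame, child in enumerate(children):
        snap, man = generate_packing(n_molecules=n_molecules, seed=child,
                                     snapshot_id=(trajectory_index, frame),
                                     **kwargs)
        man.insert(0, "frame", frame)
        man.insert(0, "trajectory", trajectory_index)
        snaps.append(snap)
        manifests.append(man)
    return snaps, pd.concat(manifests, ignore_index=True)


def generate_trivial_snapshots(n_snapshots: int, n_molecules: int = 128,
                               cell_side: float = 25.0, seed=0,
                               trajectory_index: int = 0
                               ) -> Iterator[Snapshot]:
    """Lazily yield snapshots of randomly placed rigid 3-atom molecules.

    No overlap rejection — intended for large-scale environment bookkeeping
    where only molecule contacts matter, not physical plausibility.
    """
    topo = trivial_topology()
    cell = PeriodicCell.cubic(cell_side)
    rng = np.random.default_rng(seed)
    mids = np.arange(n_molecules)
    for frame in range(n_snapshots):
        centers = rng.uniform(0, cell_side, size=(n_molecules, 3))
        q = rng.normal(size=(n_molecules, 4))
        rots = Rotation.from_quat(q / np.linalg.norm(q, axis=1, keepdims=True))
        mats = rots.as_matrix()                       # (M, 3, 3)
        pos = np.einsum("mij,aj->mai", mats, _TRIVIAL_COORDS) \
            + centers[:, None, :]
        yield Snapshot(cell, topo, pos, mids, (trajectory_index, frame))


# ---------------------------------------------------------------------------
# Shift generation
# ---------------------------------------------------------------------------

#: per-site shift model of the toy molecule: target-class mean (ppm), offset
#: added for conformer class "B", offset added when the donor is NOT H-bonded.
#: The experimental target class is (conformer "A", H-bonded).
TOY_SHIFT_MODEL: Mapping[str, Tuple[float, float, float]] = {
    "H1": (10.5, 0.0, -2.5),   # hydroxyl proton: strong H-bond deshielding
    "H2a": (3.6, 0.4, 0.0),
    "H2b": (3.8, 0.4, 0.0),
    "H3": (2.3, 0.6, 0.0),
    "H4": (6.8, 0.0, 0.0),
    "C2": (64.0, 5.0, -1.5),
    "C3": (41.0, -6.0, 0.0),
    "C4": (192.0, 3.0, 0.0),
}

#: experimental linewidths (ppm) emulating amorphous solids: carbons 2-6,
#: C-H protons 0.6-1, hydroxyl proton 1.8
TOY_LINEWIDTHS: Mapping[str, float] = {
    "H1": 1.8, "H2a": 0.8, "H2b": 0.8, "H3": 0.6, "H4": 1.0,
    "C2": 2.5, "C3": 4.0, "C4": 6.0,
}


def generate_shifts(snapshots: Sequence[Snapshot], manifest: pd.DataFrame,
                    shift_model: Mapping[str, Tuple[float, float, float]] = TOY_SHIFT_MODEL,
                    linewidths: Mapping[str, float] = TOY_LINEWIDTHS,
                    noise: float = 1.0, seed=0
                    ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site predicted shifts plus matching experimental distributions.

    Predicted shift = class mean + Gaussian noise with per-site scale
    ``noise * 0.4 * linewidth``; the prediction uncertainty is log-normal
    with median half the linewidth (heteroscedastic, so the first-quartile
    cap of the scoring step is exercised).  The experimental distributions
    are centered on the target-class means (conformer "A", H-bonded) with
    the given linewidths.  Returns ``(predictions, distributions)`` with the
    documented table schemas.
    """
    topo = snapshots[0].topology
    for site in shift_model:
        if site not in topo.site_labels:
            raise KeyError(f"shift model site {site!r} not in topology")
    rng = np.random.default_rng(seed)
    man = manifest.set_index(["trajectory", "frame", "molecule_id"])
    rows = []
    for snap in snapshots:
        traj, frame = snap.snapshot_id
        for mid in snap.molecule_ids:
            info = man.loc[(traj, frame, int(mid))]
            is_b = info["conformer_class"] == "B"
            no_hb = not bool(info["hbond_planted"])
            for site, (mean, b_off, free_off) in shift_model.items():
                mu = mean + (b_off if is_b else 0.0) + (free_off if no_hb else 0.0)
                width = linewidths[site]
                shift = mu + rng.normal(0.0, noise * 0.4 * width)
                unc = float(np.exp(np.log(0.5 * width) + rng.normal(0.0, 0.35)))
                rows.append((traj, frame, int(mid), site,
                             topo.elements[site], shift, unc))
    predictions = pd.DataFrame(rows, columns=[
        "trajectory", "frame", "molecule_id", "site_label", "element",
        "shift_ppm", "uncertainty_ppm"])
    distributions = pd.DataFrame(
        [(site, topo.elements[site], model[0], linewidths[site])
         for site, model in shift_model.items()],
        columns=["site_label", "element", "center_ppm", "width_ppm"])
    return predictions, distributions


def generate_scoring_benchmark(n_environments: int = 10000, n_sites: int = 8,
                               n_separated: int = 5, separation: float = 3.0,
                               planted_fraction: float = 0.2,
                               sigma_exp: float = 2.0, sigma_pred: float = 1.0,
                               molecules_per_frame: int = 100, seed=0
                               ) -> Tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Plant a subpopulation directly in prediction tables (no geometry).

    A ``planted_fraction`` of environments draw every predicted shift from
    the experimental distribution; the rest draw ``n_separated`` of their
    ``n_sites`` sites from a model displaced by ``separation`` joint
    standard deviations (sqrt(sigma_exp^2 + sigma_pred^2)).  Uncertainties
    are log-normal around ``sigma_pred``.  Returns
    ``(predictions, distributions, planted)`` with ``planted`` a boolean
    Series indexed by environment id.
    """
    rng = np.random.default_rng(seed)
    centers = 20.0 + 15.0 * np.arange(n_sites)
    sites = [f"S{i}" for i in range(n_sites)]
    joint = math.sqrt(sigma_exp ** 2 + sigma_pred ** 2)
    planted = np.zeros(n_environments, dtype=bool)
    planted[:int(round(planted_fraction * n_environments))] = True
    rng.shuffle(planted)

    frames = np.arange(n_environments) // molecules_per_frame
    mols = np.arange(n_environments) % molecules_per_frame
    offsets = np.zeros((n_environments, n_sites))
    offsets[~planted, :n_separated] = separation * joint
    shifts = centers[None, :] + offsets + \
        rng.normal(0.0, sigma_exp, size=(n_environments, n_sites))
    uncert = np.exp(np.log(sigma_pred) + rng.normal(0.0, 0.3,
                                                    size=(n_environments, n_sites)))
    predictions = pd.DataFrame({
        "trajectory": np.repeat(0, n_environments * n_sites),
        "frame": np.repeat(frames, n_sites),
        "molecule_id": np.repeat(mols, n_sites),
        "site_label": np.tile(sites, n_environments),
        "element": "C",
        "shift_ppm": shifts.ravel(),
        "uncertainty_ppm": uncert.ravel(),
    })
    distributions = pd.DataFrame({
        "site_label": sites, "element": "C",
        "center_ppm": centers, "width_ppm": sigma_exp,
    })
    index = pd.MultiIndex.from_arrays(
        [np.zeros(n_environments, dtype=int), frames, mols],
        names=["trajectory", "frame", "molecule_id"])
    return predictions, distributions, pd.Series(planted, index=index,
                                                 name="planted")
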