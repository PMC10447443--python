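"""Extraction of local molecular environments from periodic snapshots.

A local molecular environment is a central molecule together with every
molecule that has at least one atom within a cutoff (default 7 Å) of any
atom of the central molecule, with all distances measured under the minimum
image convention.  Member molecules are unwrapped: each is made contiguous
and shifted to the periodic image realizing its closest contact with the
central molecule, so every environment is a finite cluster.

The neighbor search is an exact, vectorized all-pairs minimum-image distance
computation per snapshot; exactness (not approximation) is the contract.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, List, Sequence, Tuple

import numpy as np

from .core import (GeometryError, LocalEnvironment, PeriodicCell, Snapshot,
                   TopologyError)

__all__ = [
    "minimum_image_vector",
    "extract_environment",
    "extract_all_environments",
    "iter_environments",
    "make_whole",
]

# integer image offsets searched around the rounded fractional displacement
_OFFSETS_27 = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=float)
_step_cache: dict = {}


def minimum_image_vector(cell: PeriodicCell, r1, r2, search: int = 2) -> np.ndarray:
    """Displacement r2 - r1 shifted by the lattice translation of minimum norm.

    The candidate images are enumerated within ``search`` lattice steps of the
    rounded fractional displacement (125 candidates by default), which is
    exact for any cell that is not pathologically skewed; for cells whose
    shortest face spacing exceeds twice the distance of interest the nearest
    image is unique and the search trivially finds it.
    """
    d = np.asarray(r2, dtype=float) - np.asarray(r1, dtype=float)
    f = cell.to_fractional(d)
    base = -np.round(f)
    steps = _step_cache.get(search)
    if steps is None:
        steps = np.array(list(itertools.product(range(-search, search + 1),
                                                repeat=3)), dtype=float)
        _step_cache[search] = steps
    cand = cell.to_cartesian(f + base + steps)
    return cand[np.argmin(np.einsum("ij,ij->i", cand, cand))]


def _min_image_batch(cell: PeriodicCell, d: np.ndarray) -> np.ndarray:
    """Minimum-image displacements for an (..., 3) array of raw displacements."""
    f = cell.to_fractional(d)
    f0 = f - np.round(f)
    if cell.is_orthorhombic:
        return cell.to_cartesian(f0)
    cand = cell.to_cartesian(f0[..., None, :] + _OFFSETS_27)  # (..., 27, 3)
    idx = np.argmin(np.einsum("...ki,...ki->...k", cand, cand), axis=-1)
    return np.take_along_axis(cand, idx[..., None, None], axis=-2)[..., 0, :]


def _pairwise_min_image(cell: PeriodicCell, pos: np.ndarray
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """All-pairs minimum-image distances and integer image shifts.

    Returns ``(dist, shift)`` with ``dist[i, j]`` the minimum-image distance
    between atoms i and j and ``shift[i, j]`` the integer lattice translation
    such that ``pos[j] + shift[i, j] @ lattice`` is the image of j nearest
    to i.
    """
    f = cell.to_fractional(pos)
    df = f[None, :, :] - f[:, None, :]          # (N, N, 3), j relative to i
    base = -np.round(df)
    if cell.is_orthorhombic:
        shift = base
        disp = cell.to_cartesian(df + base)
        dist = np.linalg.norm(disp, axis=-1)
        return dist, shift.astype(np.int64)
    cand_shift = base[:, :, None, :] + _OFFSETS_27          # (N, N, 27, 3)
    cand = cell.to_cartesian(df[:, :, None, :] + cand_shift)
    norms = np.einsum("ijkl,ijkl->ijk", cand, cand)
    idx = np.argmin(norms, axis=-1)
    dist = np.sqrt(np.take_along_axis(norms, idx[:, :, None], axis=-1)[:, :, 0])
    shift = np.take_along_axis(cand_shift, idx[:, :, None, None], axis=2)[:, :, 0, :]
    return dist, shift.astype(np.int64)


def make_whole(snapshot: Snapshot) -> np.ndarray:
    """Unwrap every molecule so its bonds take their minimum-image lengths.

    Walks the topology's bond tree outward from the first site (the anchor
    atom keeps its stored position) and returns contiguous positions of
    shape (M, n_sites, 3).  Vectorized over molecules, which all share one
    topology.
    """
    pos = snapshot.positions.copy()
    cell = snapshot.cell
    for child, parent in snapshot.topology.unwrap_order():
        vec = _min_image_batch(cell, pos[:, child] - pos[:, parent])
        pos[:, child] = pos[:, parent] + vec
    return pos


class _SnapshotContacts:
    """Per-snapshot contact data shared by all environments of the snapshot."""

    def __init__(self, snapshot: Snapshot, cutoff: float):
        if cutoff <= 0:
            raise ValueError("cutoff must be positive")
        self.snapshot = snapshot
        self.cutoff = float(cutoff)
        self.whole = make_whole(snapshot)            # (M, s, 3)
        m, s, _ = self.whole.shape
        dist, shift = _pairwise_min_image(snapshot.cell, self.whole.reshape(-1, 3))
        # reduce atom-pair data to molecule-pair data
        d4 = dist.reshape(m, s, m, s).transpose(0, 2, 1, 3).reshape(m, m, s * s)
        flat = np.argmin(d4, axis=2)
        self.mol_dist = np.take_along_axis(d4, flat[:, :, None], axis=2)[:, :, 0]
        s4 = shift.reshape(m, s, m, s, 3).transpose(0, 2, 1, 3, 4).reshape(m, m, s * s, 3)
        self.mol_shift = np.take_along_axis(
            s4, flat[:, :, None, None], axis=2)[:, :, 0, :]   # (M, M, 3)

    def environment(self, mol_index: int) -> LocalEnvironment:
        snap = self.snapshot
        # closed boundary: contacts at exactly the cutoff are included
        mask = self.mol_dist[mol_index] <= self.cutoff
        mask[mol_index] = False
        others = np.nonzero(mask)[0]
        members = np.concatenate(([mol_index], others))
        coords = self.whole[members].copy()
        if others.size:
            trans = self.mol_shift[mol_index, others] @ snap.cell.lattice
            coords[1:] += trans[:, None, :]
        mids = snap.molecule_ids[members]
        return LocalEnvironment(
            central_molecule_id=int(mids[0]),
            member_molecule_ids=tuple(int(i) for i in mids),
            coordinates=coords,
            cutoff=self.cutoff,
            source=snap.snapshot_id,
            topology=snap.topology,
        )


def extract_environment(snapshot: Snapshot, central_molecule_id: int,
                        cutoff: float = 7.0) -> LocalEnvironment:
    """Extract the local environment of one molecule (see module docstring)."""
    idx = snapshot.molecule_index(central_molecule_id)
    return _SnapshotContacts(snapshot, cutoff).environment(idx)


def iter_environments(snapshots: Iterable[Snapshot], cutoff: float = 7.0
                      ) -> Iterator[LocalEnvironment]:
    """Yield one environment per molecule per snapshot.

    Ordering is deterministic: snapshots in input order, molecules by
    ascending molecule id.  Accepts any iterable, so trajectories can be
    generated lazily without holding all frames in memory.
    """
    labels = None
    for snapshot in snapshots:
        if labels is None:
            labels = snapshot.topology.site_labels
        elif snapshot.topology.site_labels != labels:
            raise TopologyError(
                f"snapshot {snapshot.snapshot_id} has a different topology")
        contacts = _SnapshotContacts(snapshot, cutoff)
        for idx in np.argsort(snapshot.molecule_ids):
            yield contacts.environment(int(idx))


def extract_all_environments(snapshots: Sequence[Snapshot], cutoff: float = 7.0
                             ) -> List[LocalEnvironment]:
    """Extract every environment of every snapshot (one per molecule)."""
    return list(iter_environments(snapshots, cutoff))
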