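"""Formation-energy bookkeeping over local molecular environments.

The formation energy of an environment is the energy difference between the
cluster of all member molecules and the same cluster without the central
molecule, so it contains both the intermolecular interaction of the central
molecule with its surroundings and its conformational (self) energy.

Single-point energies come from a pluggable :class:`EnergyBackend`; the
package ships a bounded additive pair potential (:class:`GaussianPairBackend`)
used for testing and synthetic studies, and a generic external-process
adapter for production backends (semiempirical or DFT codes).  Energies are
kJ/mol at the interface; adapters convert.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Protocol, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import LocalEnvironment, ShiftselError

__all__ = [
    "EnergyBackend", "GaussianPairBackend", "ExternalProcessBackend",
    "formation_energy", "relative_formation_energies", "RelativeEnergies",
    "BackendError",
]


class BackendError(ShiftselError):
    """An energy backend failed for a specific structure."""


class EnergyBackend(Protocol):
    """Contract: a deterministic map from a structure to a total energy.

    The same (elements, coordinates) input must always yield the same energy
    (no hidden state).
    """

    def energy(self, elements: Sequence[str], coordinates: np.ndarray) -> float:
        """Total energy in kJ/mol of a finite (non-periodic) structure."""
        ...


@dataclass(frozen=True)
class GaussianPairBackend:
    """Additive toy potential: a Gaussian pair attraction.

    E = -epsilon * sum_{i<j} exp(-r_ij^2 / (2 r0^2))   [kJ/mol]

    Bounded, smooth and strictly pairwise-additive, which makes formation
    energies exactly decomposable into central-central (self) and
    central-other (interaction) pair sums — the closed form used by the
    bookkeeping tests.
    """

    epsilon: float = 1.0  # kJ/mol, well depth per pair
    r0: float = 3.0       # Å, interaction range

    def energy(self, elements: Sequence[str], coordinates: np.ndarray) -> float:
        pos = np.asarray(coordinates, dtype=float).reshape(-1, 3)
        if len(pos) < 2:
            return 0.0
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=-1)
        iu = np.triu_indices(len(pos), k=1)
        return float(-self.epsilon * np.exp(-d2[iu] / (2.0 * self.r0 ** 2)).sum())


@dataclass
class ExternalProcessBackend:
    """Adapter running an external single-point program.

    Writes the structure as a plain XYZ file, invokes ``command <file>`` and
    parses the last whitespace-separated token of stdout as the energy.
    ``scale`` converts the program's unit to kJ/mol.
    """

    command: Sequence[str]
    scale: float = 1.0

    def energy(self, elements: Sequence[str], coordinates: np.ndarray) -> float:
        import tempfile
        pos = np.asarray(coordinates, dtype=float).reshape(-1, 3)
        with tempfile.NamedTemporaryFile("w", suffix=".xyz", delete=False) as fh:
            fh.write(f"{len(pos)}\nshiftsel single point\n")
            for el, p in zip(elements, pos):
                fh.write(f"{el} {p[0]:.8f} {p[1]:.8f} {p[2]:.8f}\n")
            path = fh.name
        try:
            out = subprocess.run(list(self.command) + [path], check=True,
                                 capture_output=True, text=True)
        except (OSError, subprocess.CalledProcessError) as exc:
            raise BackendError(f"external backend failed: {exc}") from exc
        try:
            return float(out.stdout.split()[-1]) * self.scale
        except (IndexError, ValueError) as exc:
            raise BackendError(
                f"could not parse energy from backend output: {out.stdout!r}") from exc


def _cluster(env: LocalEnvironment, include_central: bool
             ) -> Tuple[list, np.ndarray]:
    elements = env.topology.element_array()
    members = range(env.n_members) if include_central else range(1, env.n_members)
    els, coords = [], []
    for m in members:
        els.extend(elements.tolist())
        coords.append(env.coordinates[m])
    if not coords:
        return [], np.zeros((0, 3))
    return els, np.concatenate(coords, axis=0)


def formation_energy(env: LocalEnvironment, backend: EnergyBackend) -> float:
    """Formation energy of the environment's central molecule (kJ/mol):

    E(all members) - E(members without the central molecule).

    For an environment containing only the central molecule this reduces to
    the central molecule's self energy.  Backend failures are re-raised with
    the environment id attached.
    """
    try:
        els_all, pos_all = _cluster(env, include_central=True)
        e_all = backend.energy(els_all, pos_all)
        els_rest, pos_rest = _cluster(env, include_central=False)
        e_rest = backend.energy(els_rest, pos_rest) if len(els_rest) else 0.0
    except BackendError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise BackendError(f"backend failed for environment {env.env_id}: {exc}"
                           ) from exc
    return e_all - e_rest


@dataclass
class RelativeEnergies:
    """Energies re-zeroed to the mean of a reference set, with group stats."""

    relative: pd.Series
    reference_mean: float
    group_stats: pd.DataFrame  # columns: mean, se, n


def relative_formation_energies(energies: pd.Series,
                                reference_ids: Sequence,
                                groups: Optional[Mapping] = None
                                ) -> RelativeEnergies:
    """Center formation energies on the mean of a reference set and summarize
    groups.

    The zero of the returned values is the mean energy over
    ``reference_ids`` (so the reference set has mean exactly 0).  ``groups``
    optionally maps each id to a group label (e.g. an H-bond acceptor
    category or selected/random); per-group means carry the standard error
    of the mean, s / sqrt(n) with s the sample standard deviation.
    """
    energies = pd.Series(energies, dtype=float)
    ref = energies.loc[list(reference_ids)]
    if ref.empty:
        raise ValueError("empty reference set")
    ref_mean = float(ref.mean())
    relative = energies - ref_mean
    if groups is None:
        stats = pd.DataFrame(columns=["mean", "se", "n"])
    else:
        glab = pd.Series({k: groups[k] for k in energies.index if k in groups})
        if glab.empty:
            raise ValueError("no energies fall in any group")
        sub = relative.loc[glab.index]
        df = pd.DataFrame({"group": glab, "e": sub})
        agg = df.groupby("group")["e"]
        stats = pd.DataFrame({
            "mean": agg.mean(),
            "se": agg.std(ddof=1) / np.sqrt(agg.size()),
            "n": agg.size(),
        })
        if (stats["n"] == 0).any():
            raise ValueError("empty group")
    return RelativeEnergies(relative=relative, reference_mean=ref_mean,
                            group_stats=stats)
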