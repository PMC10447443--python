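"""File I/O, configuration and the end-to-end pipeline.

Formats
-------
* Trajectories: an extended-XYZ dialect (per-frame ``Lattice="..."`` and a
  ``Properties=species:S:1:pos:R:3:site_label:S:1:molecule_id:I:1`` comment
  line, plus ``trajectory=`` / ``frame=`` keys) and PDB with CRYST1 (read
  via gemmi; molecules from residue numbering).
* Tables: delimited text (CSV) with the documented schemas —
  predictions (trajectory, frame, molecule_id, site_label, element,
  shift_ppm, uncertainty_ppm), distributions (site_label, element,
  center_ppm, width_ppm), selections (trajectory, frame, molecule_id,
  probability, selected).
* Volumetric maps: Gaussian-cube-style files.  Following the cube
  convention, a negative voxel count flags Å units (values are written in
  Å here, never Bohr).
* Experimental G(r)/D(r) curves: two-column text (r, value), ``#`` comments.

:func:`run_pipeline` orchestrates extract -> score -> select -> analyze on a
validated :class:`PipelineConfig`; every run writes a provenance record
(config hash, seed, package version) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import shlex
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .core import (COVALENT_RADII, Atom, MolecularTopology, PeriodicCell,
                   ShiftselError, Snapshot)

logger = logging.getLogger(__name__)

__all__ = [
    "read_trajectory", "write_trajectory", "read_pdb",
    "write_table", "read_predictions", "read_distributions",
    "write_cube", "read_curve", "PipelineConfig", "run_pipeline",
]


class ParseError(ShiftselError):
    """A trajectory or table file could not be parsed."""


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

_KEYVAL = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str) -> Dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KEYVAL.finditer(line)}


def write_trajectory(snapshots: Sequence[Snapshot], path) -> None:
    """Write snapshots as extended XYZ (one frame per snapshot)."""
    path = Path(path)
    with path.open("w") as fh:
        for snap in snapshots:
            topo = snap.topology
            lat = " ".join(f"{x:.10g}" for x in snap.cell.lattice.ravel())
            traj, frame = snap.snapshot_id
            fh.write(f"{snap.n_atoms}\n")
            fh.write(f'Lattice="{lat}" '
                     f"Properties=species:S:1:pos:R:3:site_label:S:1:molecule_id:I:1 "
                     f"trajectory={traj} frame={frame}\n")
            for m in range(snap.n_molecules):
                mid = int(snap.molecule_ids[m])
                for s, lab in enumerate(topo.site_labels):
                    x, y, z = snap.positions[m, s]
                    fh.write(f"{topo.elements[lab]} {x:.10f} {y:.10f} {z:.10f} "
                             f"{lab} {mid}\n")


def _perceive_bonds(labels: Sequence[str], elements: Mapping[str, str],
                    coords: np.ndarray) -> frozenset:
    """Fallback bond perception: 1.2 x the sum of covalent radii."""
    bonds = set()
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            ra = COVALENT_RADII.get(elements[a], 0.8)
            rb = COVALENT_RADII.get(elements[b], 0.8)
            if np.linalg.norm(coords[i] - coords[j]) <= 1.2 * (ra + rb):
                bonds.add((a, b))
    return frozenset(bonds)


def read_trajectory(path, fmt: str = "extxyz",
                    topology: Optional[MolecularTopology] = None
                    ) -> List[Snapshot]:
    """Read a trajectory into snapshots.

    ``fmt`` is ``"extxyz"`` or ``"pdb"``.  Without an explicit topology,
    site labels come from the file and bonds are perceived from the first
    molecule of the first frame by the covalent-radius rule (logged).
    """
    if fmt == "pdb":
        return read_pdb(path, topology=topology)
    if fmt != "extxyz":
        raise ValueError(f"unknown trajectory format {fmt!r}")
    path = Path(path)
    lines = path.read_text().splitlines()
    snapshots: List[Snapshot] = []
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}: expected atom count at line {i + 1}") from exc
        if i + 1 >= len(lines):
            raise ParseError(f"{path}: truncated frame at line {i + 1}")
        meta = _parse_comment(lines[i + 1])
        if "Lattice" not in meta:
            raise ParseError(f"{path}: frame {frame_no} is missing its "
                             f"Lattice entry (line {i + 2})")
        lat = np.array([float(x) for x in meta["Lattice"].split()]).reshape(3, 3)
        rows = lines[i + 2: i + 2 + nat]
        if len(rows) < nat:
            raise ParseError(f"{path}: frame {frame_no} declares {nat} atoms "
                             f"but only {len(rows)} rows follow")
        atoms = []
        for k, row in enumerate(rows):
            parts = row.split()
            if len(parts) < 6:
                raise ParseError(f"{path}: malformed atom row at line {i + 3 + k}")
            el, x, y, z, lab, mid = parts[:6]
            atoms.append((el, float(x), float(y), float(z), lab, int(mid)))
        snap_id = (int(meta.get("trajectory", 0)), int(meta.get("frame", frame_no)))
        if topology is None:
            topology = _topology_from_atoms(atoms)
            logger.info("perceived topology with %d sites and %d bonds from %s",
                        topology.n_sites, len(topology.bonds), path)
        snapshots.append(_snapshot_from_rows(lat, topology, atoms, snap_id))
        i += 2 + nat
        frame_no += 1
    if not snapshots:
        raise ParseError(f"{path}: no frames found")
    return snapshots


def _topology_from_atoms(rows) -> MolecularTopology:
    first_mid = rows[0][5]
    mol = [(el, lab, (x, y, z)) for el, x, y, z, lab, mid in rows
           if mid == first_mid]
    labels = tuple(lab for _, lab, _ in mol)
    elements = {lab: el for el, lab, _ in mol}
    coords = np.array([c for _, _, c in mol])
    bonds = _perceive_bonds(labels, elements, coords)
    # perceive the hydroxyl donor (first O-H bond) and acceptor candidates
    donor = None
    for a, b in sorted(bonds):
        pair = {elements[a]: a, elements[b]: b}
        if set(pair) == {"O", "H"}:
            donor = (pair["O"], pair["H"])
            break
    acceptors = tuple((lab, elements[lab]) for lab in labels
                      if elements[lab] in ("O", "N")
                      and (donor is None or lab != donor[0]))
    return MolecularTopology(site_labels=labels, elements=elements,
                             bonds=bonds, hbond_donor=donor,
                             hbond_acceptors=acceptors)


def _snapshot_from_rows(lat, topology, rows, snap_id) -> Snapshot:
    atoms = [Atom(el, np.array([x, y, z]), lab, mid, k)
             for k, (el, x, y, z, lab, mid) in enumerate(rows)]
    return Snapshot.from_atoms(PeriodicCell(lat), topology, atoms, snap_id)


def read_pdb(path, topology: Optional[MolecularTopology] = None
             ) -> List[Snapshot]:
    """Read a PDB file with a CRYST1 record; molecules from residue numbers."""
    import gemmi
    st = gemmi.read_pdb(str(path))
    cell = st.cell
    if cell.a == 1.0 and cell.b == 1.0 and cell.c == 1.0:
        raise ParseError(f"{path}: missing or trivial CRYST1 record")
    lat = np.array(gemmi.UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta,
                                  cell.gamma).orth.mat.tolist()).T
    snapshots = []
    for f, model in enumerate(st):
        rows = []
        for chain in model:
            for res in chain:
                for atom in res:
                    rows.append((atom.element.name,
                                 atom.pos.x, atom.pos.y, atom.pos.z,
                                 atom.name, res.seqid.num))
        if topology is None:
            topology = _topology_from_atoms(rows)
        snapshots.append(_snapshot_from_rows(lat, topology, rows, (0, f)))
    if not snapshots:
        raise ParseError(f"{path}: no models found")
    return snapshots


# ---------------------------------------------------------------------------
# Tables, cubes, curves
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"trajectory", "frame", "molecule_id", "site_label", "shift_ppm",
            "uncertainty_ppm"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: prediction table missing columns "
                         f"{sorted(need - set(df.columns))}")
    return df


def read_distributions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"site_label", "center_ppm", "width_ppm"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: distribution table missing columns "
                         f"{sorted(need - set(df.columns))}")
    return df


def write_cube(path, values: np.ndarray, origin: np.ndarray, spacing: float,
               comment: str = "shiftsel atomic density map") -> None:
    """Write a Gaussian-cube-style volumetric file.

    Negative voxel counts flag Å units (the cube convention); no atoms are
    recorded (atom count 0).  Values are ordered with z fastest.
    """
    values = np.asarray(values)
    nx, ny, nz = values.shape
    with Path(path).open("w") as fh:
        fh.write(f"{comment}\nvalues on a regular grid; lengths in Angstrom\n")
        fh.write(f"{0:5d} {origin[0]:12.6f} {origin[1]:12.6f} {origin[2]:12.6f}\n")
        fh.write(f"{-nx:5d} {spacing:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{-ny:5d} {0.0:12.6f} {spacing:12.6f} {0.0:12.6f}\n")
        fh.write(f"{-nz:5d} {0.0:12.6f} {0.0:12.6f} {spacing:12.6f}\n")
        flat = values.reshape(nx * ny, nz)
        for row in flat:
            for k in range(0, nz, 6):
                fh.write(" ".join(f"{v: .5E}" for v in row[k:k + 6]) + "\n")


def read_curve(path) -> Tuple[np.ndarray, np.ndarray]:
    """Read a two-column (r, value) text curve; '#' starts a comment."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns")
    return data[:, 0], data[:, 1]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Declarative configuration of the full analysis.

    With ``trajectory = None`` the synthetic generator provides the inputs
    (``n_snapshots`` packings of ``n_molecules`` toy molecules); otherwise
    the trajectory and prediction/distribution tables are read from files.
    """

    outdir: str = "shiftsel_out"
    seed: int = 0
    # inputs
    trajectory: Optional[str] = None
    predictions: Optional[str] = None
    distributions: Optional[str] = None
    n_snapshots: int = 20
    n_molecules: int = 16
    hbond_fraction: float = 0.3
    # selection
    cutoff: float = 7.0
    threshold: float = 0.33
    top_fraction: Optional[float] = None
    excluded_sites: Tuple[str, ...] = ()
    # analyses
    hbond_max_distance: float = 2.5
    hbond_min_angle: float = 130.0
    dihedrals: Tuple[str, ...] = ()
    alignment_sites: Tuple[str, ...] = ()
    density_elements: Tuple[str, ...] = ("O", "N")
    n_random_reference: int = 1000
    rdf_r_max: float = 10.0
    reference_curve: Optional[str] = None

    def validate(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")
        if self.top_fraction is not None and not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("excluded_sites", "dihedrals", "alignment_sites",
                    "density_elements"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run extract -> score -> select -> analyze and write all outputs.

    Returns a summary dict (also written as ``summary.json``); every output
    carries provenance through ``provenance.json`` (config hash, seed,
    package version).  Stage failures abort with the stage name attached.
    """
    from . import __version__
    from .energy import GaussianPairBackend, formation_energy, \
        relative_formation_energies
    from .environments import extract_all_environments
    from .scoring import EnsembleSelection, SiteMatchConfig, score_all
    from .structure import (DensityMapSpec, HBondCriteria, align_environments,
                            density_map, density_difference_map,
                            dihedral_histogram, hbond_census,
                            radial_distribution, curve_residual)
    from .synthetic import generate_shifts, generate_trajectory

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: Dict[str, object] = {}
    stage = "setup"
    try:
        stage = "inputs"
        if config.trajectory is None:
            snapshots, manifest = generate_trajectory(
                n_snapshots=config.n_snapshots, n_molecules=config.n_molecules,
                hbond_fraction=config.hbond_fraction, seed=config.seed)
            predictions, distributions = generate_shifts(
                snapshots, manifest, seed=config.seed + 1)
            write_table(manifest, outdir / "manifest.csv")
        else:
            snapshots = read_trajectory(config.trajectory)
            if config.predictions is None or config.distributions is None:
                raise ValueError("file inputs require predictions and "
                                 "distributions tables")
            predictions = read_predictions(config.predictions)
            distributions = read_distributions(config.distributions)
        logger.info("inputs: %d snapshots, %d molecules each",
                    len(snapshots), snapshots[0].n_molecules)

        stage = "extract"
        envs = extract_all_environments(snapshots, cutoff=config.cutoff)
        env_by_id = {e.env_id: e for e in envs}
        summary["n_environments"] = len(envs)
        logger.info("extracted %d environments", len(envs))

        stage = "score"
        match_cfg = SiteMatchConfig.from_data(
            predictions, distributions, exclude=config.excluded_sites,
            threshold=config.threshold, top_fraction=config.top_fraction)
        selection = score_all(predictions, distributions, match_cfg)
        write_table(selection.to_frame(), outdir / "selection.csv")
        summary["n_selected"] = int(len(selection.selected_ids))
        summary["selected_fraction"] = selection.selected_fraction
        logger.info("scored %d environments, selected %d (%.2f%%)",
                    len(selection.probabilities), len(selection.selected_ids),
                    100 * selection.selected_fraction)

        selected_envs = [env_by_id[i] for i in selection.selected_ids
                         if i in env_by_id]
        rng = np.random.default_rng(config.seed + 2)
        n_rand = min(config.n_random_reference, len(envs))
        random_envs = [envs[i] for i in
                       rng.choice(len(envs), size=n_rand, replace=False)]

        stage = "analyze-hbonds"
        criteria = HBondCriteria(config.hbond_max_distance,
                                 config.hbond_min_angle)
        census_all = hbond_census(envs, criteria)
        summary["hbond_census_all"] = census_all
        if selected_envs:
            summary["hbond_census_selected"] = hbond_census(selected_envs,
                                                            criteria)
        else:
            summary["hbond_census_selected"] = None
            logger.warning("empty selection: skipping selected-set analyses")
        pd.DataFrame({
            "category": list(census_all),
            "fraction_all": list(census_all.values()),
            "fraction_selected": [
                (summary["hbond_census_selected"] or {}).get(c, 0.0)
                for c in census_all],
        }).to_csv(outdir / "hbond_census.csv", index=False)

        stage = "analyze-dihedrals"
        dihedrals = config.dihedrals or tuple(
            snapshots[0].topology.dihedral_defs)
        for name in dihedrals:
            counts, edges = dihedral_histogram(envs, name)
            out = {"bin_left": edges[:-1], "bin_right": edges[1:],
                   "count_all": counts}
            if selected_envs:
                sel_counts, _ = dihedral_histogram(selected_envs, name)
                out["count_selected"] = sel_counts
            pd.DataFrame(out).to_csv(outdir / f"dihedral_{name}.csv",
                                     index=False)

        stage = "density-map"
        align_sites = config.alignment_sites or _default_alignment(snapshots)
        if selected_envs and len(selected_envs) >= 2:
            spec = DensityMapSpec()
            for tag, subset in (("selected", selected_envs),
                                ("random", random_envs)):
                aligned, _ = align_environments(subset, align_sites)
                center = np.mean([_align_pts(e, a, align_sites)
                                  for e, a in zip(subset, aligned)], axis=(0, 1))
                for el in config.density_elements:
                    vals, c = density_map(
                        aligned, subset[0].topology.element_array(), el, spec,
                        center=center)
                    origin = c - spec.cube_side / 2.0
                    write_cube(outdir / f"density_{tag}_{el}.cube", vals,
                               origin, spec.spacing)

        stage = "pdf"
        r_max = min(config.rdf_r_max,
                    0.45 * float(min(np.min(s.cell.plane_spacings)
                                     for s in snapshots)))
        rdf = radial_distribution(snapshots, r_max=r_max)
        pd.DataFrame({"r": rdf.r, "g": rdf.g_total, "d": rdf.d}).to_csv(
            outdir / "rdf.csv", index=False)
        if config.reference_curve is not None:
            ref = read_curve(config.reference_curve)
            res = curve_residual((rdf.r, rdf.g_total), ref)
            summary["rdf_rmse"] = res.rmse
            summary["rdf_rmse_3_10"] = res.rmse_subrange

        stage = "energies"
        backend = GaussianPairBackend()
        cache = {}
        for e in random_envs + selected_envs:
            if e.env_id not in cache:
                cache[e.env_id] = formation_energy(e, backend)
        # an environment may sit in both ensembles; key energies by
        # (group, env id) so each group keeps its full membership
        energies = pd.Series(
            {("random", e.env_id): cache[e.env_id] for e in random_envs}
            | {("selected", e.env_id): cache[e.env_id] for e in selected_envs})
        groups = {k: k[0] for k in energies.index}
        rel = relative_formation_energies(
            energies, [("random", e.env_id) for e in random_envs], groups)
        rel.group_stats.to_csv(outdir / "formation_energies.csv")
        summary["formation_energy_groups"] = {
            k: {"mean": float(v["mean"]), "se": float(v["se"]),
                "n": int(v["n"])}
            for k, v in rel.group_stats.iterrows()}

        stage = "provenance"
        prov = {"config_hash": config.config_hash(), "seed": config.seed,
                "version": __version__, "config": asdict(config)}
        (outdir / "provenance.json").write_text(json.dumps(prov, indent=2,
                                                           default=str))
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                        default=str))
    except ShiftselError as exc:
        raise ShiftselError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return summary


def _default_alignment(snapshots) -> Tuple[str, ...]:
    topo = snapshots[0].topology
    donor = topo.hbond_donor
    if donor is not None:
        # donor pair plus its attachment point gives a well-defined frame
        o, h = donor
        for a, b in topo.bonds:
            if a == o and b != h:
                return (h, o, b)
            if b == o and a != h:
                return (h, o, a)
    return tuple(topo.site_labels[:3])


def _align_pts(env, aligned_coords, labels):
    topo = env.topology
    return np.array([aligned_coords[0, topo.index(lab)] for lab in labels])
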