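"""Synthetic inputs for the whole pipeline: no MD engine, no downloads.

Generators here emulate the *shape* of mixed-solvent MD data — a protein
kept rigid (or jittered), probe molecules appearing as a dilute ideal
cosolvent with Poisson-uniform background plus Gaussian accumulation clouds
at planted sites — while staying pure functions of their seed. Defaults
follow the study conditions the pipeline targets: 0.25 M probe
concentration, 300 K, 1 Å voxels, and a pooled analysis window of
20 runs × 200 frames.

These objects write the same text formats the real pipeline reads
(PDB, multi-model PDB trajectories plus a YAML run manifest), so synthetic
fixtures and real MSMD output are interchangeable downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .density import Frame, ProbeSpec, STANDARD_PROBES, TrajectoryBundle
from .exceptions import CryptoHotError
from .structure import (LigandPose, Structure, detect_clashes, superpose,
                        transfer_ligand, write_multimodel_pdb, write_pdb)

__all__ = [
    "PlantedSite", "SyntheticScenario", "SyntheticFeatureSpec",
    "make_toy_protein", "toy_trajectory", "plant_probe_trajectory",
    "make_clash_pair", "make_feature_dataset", "write_bundle", "load_bundle",
]

#: molecules per Å^3 at 1 mol/L
_MOLAR_TO_PER_A3 = 6.02214076e23 / 1e27


@dataclass(frozen=True)
class PlantedSite:
    """A Gaussian probe-accumulation cloud: center (Å), expected probe
    heavy atoms per frame, and isotropic spread (Å)."""

    center: tuple[float, float, float]
    intensity: float = 18.0
    spread: float = 1.5


@dataclass
class SyntheticScenario:
    """Study-condition defaults for a planted-hotspot simulation."""

    seed: int = 0
    n_residues: int = 60
    geometry: str = "helix"              # helix | lattice
    probe: str = "benzene"
    planted_sites: list[PlantedSite] | None = None
    concentration_molar: float = 0.25    # bulk probe concentration
    background_rate: float | None = None  # probe heavy atoms / Å^3 / frame
    n_runs: int = 20
    frames_per_run: int = 200
    padding: float = 8.0
    clash_residues: tuple[str, ...] = ("20", "24")
    jitter_sd: float = 0.0               # per-atom positional noise, Å

    @property
    def probe_spec(self) -> ProbeSpec:
        return STANDARD_PROBES.get(self.probe, ProbeSpec(self.probe, 6))

    @property
    def n_frames(self) -> int:
        return self.n_runs * self.frames_per_run

    def atom_background_rate(self) -> float:
        if self.background_rate is not None:
            return self.background_rate
        return (self.concentration_molar * _MOLAR_TO_PER_A3
                * self.probe_spec.n_heavy_atoms)


@dataclass(frozen=True)
class SyntheticFeatureSpec:
    """Spherical-Gaussian two-class feature table with Mahalanobis
    separation ``delta`` along a fixed random direction."""

    n_pos: int = 60
    n_neg: int = 125
    n_features: int = 10
    delta: float = 0.0
    seed: int = 0
    n_pos_proteins: int = 34
    n_neg_proteins: int = 10

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one row per class")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")


# poly-alanine heavy atoms, local frame around Cα
_ALA_OFFSETS = {
    "N": np.array([-1.20, 0.80, 0.00]),
    "CA": np.array([0.00, 0.00, 0.00]),
    "C": np.array([1.30, 0.60, 0.00]),
    "O": np.array([1.40, 1.83, 0.00]),
    "CB": np.array([0.00, -0.90, 1.20]),
}
_ALA_NAMES = tuple(_ALA_OFFSETS)


def make_toy_protein(n_residues: int = 60, geometry: str = "helix",
                     structure_id: str = "toy") -> Structure:
    """Deterministic poly-Ala toy protein on an ideal α-helix or cubic lattice.

    The helix uses 2.3 Å radius, 1.5 Å rise and 100° twist per residue, so
    consecutive Cα atoms sit ≈ 3.8 Å apart; the lattice places residues on
    a 6 Å cubic grid.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    ca = np.empty((n_residues, 3))
    if geometry == "helix":
        phi = np.deg2rad(100.0) * np.arange(n_residues)
        ca[:, 0] = 2.3 * np.cos(phi)
        ca[:, 1] = 2.3 * np.sin(phi)
        ca[:, 2] = 1.5 * np.arange(n_residues)
        # radial frame: CB points outward, helix axis along z
        radial = np.stack([np.cos(phi), np.sin(phi), np.zeros(n_residues)], axis=1)
        tangent = np.stack([-np.sin(phi), np.cos(phi), np.zeros(n_residues)], axis=1)
        axis = np.array([0.0, 0.0, 1.0])
        frames = [np.stack([tangent[i], radial[i], axis], axis=1)
                  for i in range(n_residues)]
    elif geometry == "lattice":
        side = math.ceil(n_residues ** (1 / 3))
        pts = [(i, j, k) for i in range(side) for j in range(side)
               for k in range(side)][:n_residues]
        ca[:] = np.asarray(pts, float) * 6.0
        frames = [np.eye(3)] * n_residues
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    rows_per_res = len(_ALA_NAMES)
    n = n_residues * rows_per_res
    atom_ids = np.arange(1, n + 1)
    names = np.empty(n, object)
    elements = np.empty(n, object)
    res_ids = np.empty(n, object)
    res_names = np.full(n, "ALA", dtype=object)
    chains = np.full(n, "A", dtype=object)
    coords = np.empty((n, 3))
    k = 0
    for r in range(n_residues):
        for name in _ALA_NAMES:
            names[k] = name
            elements[k] = name[0]       # N, C or O
            res_ids[k] = str(r + 1)
            coords[k] = ca[r] + frames[r] @ _ALA_OFFSETS[name]
            k += 1
    return Structure(structure_id, atom_ids, names, elements, res_ids,
                     res_names, chains, coords, np.zeros(n, bool))


def toy_trajectory(structure: Structure, n_frames: int, jitter_sd: float,
                   seed: int = 0) -> np.ndarray:
    """(F, H, 3) heavy-atom frames: the structure plus isotropic Gaussian
    jitter of standard deviation ``jitter_sd`` per coordinate."""
    rng = np.random.default_rng(seed)
    base = structure.protein().heavy().coords
    return base[None] + rng.normal(0.0, jitter_sd,
                                   size=(n_frames, len(base), 3))


def _default_sites(structure: Structure) -> list[PlantedSite]:
    """Two sites offset from the protein surface, ≥ 15 Å apart."""
    coords = structure.heavy_coords()
    lo, hi = coords.min(0), coords.max(0)
    long_axis = int(np.argmax(hi - lo))
    mid = (lo + hi) / 2
    radial = np.zeros(3)
    radial[(long_axis + 1) % 3] = 1.0
    extent = hi[(long_axis + 1) % 3] - lo[(long_axis + 1) % 3]
    offset = mid + radial * (extent / 2 + 4.0)
    sites = []
    for frac in (0.28, 0.72):
        c = offset.copy()
        c[long_axis] = lo[long_axis] + frac * (hi[long_axis] - lo[long_axis])
        sites.append(PlantedSite(center=tuple(np.round(c, 3))))
    return sites


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """(n, 3, 3) uniform random rotation matrices from unit quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack([
        np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
        np.stack([2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)], -1),
        np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)], -1),
    ], axis=1)


def _probe_template(n_heavy: int) -> np.ndarray:
    """Rigid molecule template: heavy atoms on a ring of 1.2 Å radius."""
    if n_heavy == 1:
        return np.zeros((1, 3))
    ang = 2 * np.pi * np.arange(n_heavy) / n_heavy
    return np.stack([1.2 * np.cos(ang), 1.2 * np.sin(ang),
                     np.zeros(n_heavy)], axis=1)


def plant_probe_trajectory(scenario: SyntheticScenario,
                           structure: Structure | None = None
                           ) -> TrajectoryBundle:
    """Probe heavy-atom trajectory: Poisson-uniform background molecules in
    the padded protein box plus Gaussian clouds at the planted sites.

    Deterministic under the scenario seed. Molecule ids group atoms into
    whole probes, so molecule-count features see coherent molecules.
    """
    rng = np.random.default_rng(scenario.seed)
    protein = structure or make_toy_protein(scenario.n_residues,
                                            scenario.geometry)
    prot_heavy = protein.protein().heavy().coords
    probe = scenario.probe_spec
    sites = scenario.planted_sites
    if sites is None:
        sites = _default_sites(protein)
    lo = prot_heavy.min(0) - scenario.padding
    hi = prot_heavy.max(0) + scenario.padding
    volume = float(np.prod(hi - lo))
    bg_molecules = scenario.atom_background_rate() * volume / probe.n_heavy_atoms
    site_molecules = [s.intensity / probe.n_heavy_atoms for s in sites]
    template = _probe_template(probe.n_heavy_atoms)

    runs: list[list[Frame]] = []
    for _ in range(scenario.n_runs):
        frames: list[Frame] = []
        for _ in range(scenario.frames_per_run):
            centers_parts = []
            n_bg = rng.poisson(bg_molecules)
            centers_parts.append(rng.uniform(lo, hi, size=(n_bg, 3)))
            for s, lam in zip(sites, site_molecules):
                n_s = rng.poisson(lam)
                centers_parts.append(
                    np.asarray(s.center) + rng.normal(0, s.spread, (n_s, 3)))
            centers = np.concatenate(centers_parts, axis=0)
            m = len(centers)
            if m:
                rots = _random_rotations(rng, m)
                atoms = (centers[:, None, :]
                         + np.einsum("mij,kj->mki", rots, template))
                probe_coords = atoms.reshape(-1, 3)
                mol_ids = np.repeat(np.arange(m), probe.n_heavy_atoms)
            else:
                probe_coords = np.zeros((0, 3))
                mol_ids = np.zeros(0, int)
            prot_coords = prot_heavy
            if scenario.jitter_sd > 0:
                prot_coords = prot_heavy + rng.normal(
                    0, scenario.jitter_sd, prot_heavy.shape)
            frames.append(Frame(probe_coords=probe_coords,
                                protein_coords=prot_coords,
                                molecule_ids=mol_ids))
        runs.append(frames)
    return TrajectoryBundle(probe=probe, runs=runs,
                            alignment_reference=protein,
                            fixed_composition=False)


class InfeasiblePlacementError(CryptoHotError):
    """No ligand pose realises exactly the requested clash set."""


def make_clash_pair(scenario: SyntheticScenario,
                    max_orientations: int = 400
                    ) -> tuple[Structure, Structure, str]:
    """Construct an apo/holo pair whose clash set is exactly the planted one.

    The apo structure is the toy protein. A rigid 5-atom carbon cross is
    positioned (seeded search over outward offsets and orientations) so
    that precisely ``scenario.clash_residues`` have a heavy atom strictly
    within 2.5 Å of a ligand atom. The holo structure is the apo plus
    ligand under a random rigid transform, so the standard superpose →
    transfer → clash route must recover the planted residues.
    """
    rng = np.random.default_rng(scenario.seed + 101)
    apo = make_toy_protein(scenario.n_residues, scenario.geometry)
    prot = apo.protein()
    groups = prot.residue_atom_indices(heavy_only=True)
    wanted = {("A", r) for r in scenario.clash_residues}
    missing = [r for _, r in wanted if ("A", r) not in groups]
    if missing:
        raise InfeasiblePlacementError(f"clash residues not in protein: {missing}")
    target_atoms = np.concatenate([prot.coords[groups[k]] for k in sorted(wanted)])
    anchor = target_atoms.mean(axis=0)
    center_all = prot.heavy_coords().mean(axis=0)
    outward = anchor - center_all
    norm = np.linalg.norm(outward)
    outward = outward / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])

    arm = 1.5
    cross = np.array([[0, 0, 0], [arm, 0, 0], [-arm, 0, 0],
                      [0, arm, 0], [0, -arm, 0]], float)
    wanted_full = {k for k in apo.residue_keys() if (k[0], k[1]) in wanted}
    for radius in np.arange(1.0, 7.0, 0.25):
        base = anchor + outward * radius
        rots = _random_rotations(rng, max_orientations)
        for rot in rots:
            lig_coords = base + cross @ rot.T
            pose = LigandPose(atom_names=np.array(["C1", "C2", "C3", "C4", "C5"],
                                                  object),
                              elements=np.array(["C"] * 5, object),
                              coords=lig_coords, source_structure="synthetic")
            site = detect_clashes(apo, pose, cutoff=2.5)
            if site.clash_residues == wanted_full:
                return apo, _build_holo(apo, lig_coords, rng), "LIG"
    raise InfeasiblePlacementError(
        f"could not realise clash set {sorted(wanted)} with a rigid cross")


def _build_holo(apo: Structure, ligand_coords: np.ndarray,
                rng: np.random.Generator) -> Structure:
    rot = _random_rotations(rng, 1)[0]
    trans = rng.uniform(-10, 10, 3)
    n = len(apo)
    m = len(ligand_coords)
    atom_ids = np.concatenate([apo.atom_ids, np.arange(n + 1, n + m + 1)])
    names = np.concatenate([apo.atom_names,
                            np.array([f"C{i+1}" for i in range(m)], object)])
    elements = np.concatenate([apo.elements, np.array(["C"] * m, object)])
    res_ids = np.concatenate([apo.res_ids, np.array(["900"] * m, object)])
    res_names = np.concatenate([apo.res_names, np.array(["LIG"] * m, object)])
    chains = np.concatenate([apo.chain_ids, np.array(["A"] * m, object)])
    coords = np.vstack([apo.coords, ligand_coords]) @ rot.T + trans
    het = np.concatenate([apo.is_het, np.ones(m, bool)])
    return Structure("holo", atom_ids, names, elements, res_ids, res_names,
                     chains, coords, het)


def make_feature_dataset(spec: SyntheticFeatureSpec):
    """Two spherical Gaussian classes separated by ``delta`` along a fixed
    seeded unit direction; 60 positives over 34 proteins and 125 negatives
    over 10 proteins by default. Returns an mlrank Dataset."""
    from .mlrank import Dataset

    rng = np.random.default_rng(spec.seed)
    u = rng.normal(size=spec.n_features)
    u /= np.linalg.norm(u)
    pos = rng.normal(size=(spec.n_pos, spec.n_features)) + spec.delta * u
    neg = rng.normal(size=(spec.n_neg, spec.n_features))
    import pandas as pd
    X = pd.DataFrame(np.vstack([pos, neg]),
                     columns=[f"f{i}" for i in range(spec.n_features)])
    y = np.concatenate([np.ones(spec.n_pos, int), np.zeros(spec.n_neg, int)])
    prot = np.concatenate([
        np.array([f"pos{i % spec.n_pos_proteins:02d}" for i in range(spec.n_pos)]),
        np.array([f"neg{i % spec.n_neg_proteins:02d}" for i in range(spec.n_neg)]),
    ])
    hid = np.array([f"H{i:03d}" for i in range(spec.n_pos + spec.n_neg)])
    return Dataset(X=X, y=y, protein_ids=prot, hotspot_ids=hid)


def write_bundle(bundle: TrajectoryBundle, outdir: str,
                 structure: Structure | None = None) -> str:
    """Write runs as multi-model PDBs plus a YAML manifest; returns its path.

    Probe heavy atoms become HETATM records (residue PRB, one residue per
    molecule); protein heavy atoms are written separately once.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ref = structure or bundle.alignment_reference
    run_files = []
    for r, run in enumerate(bundle.runs):
        path = out / f"run{r:02d}.pdb"
        with open(path, "w") as fh:
            for m, frame in enumerate(run, start=1):
                fh.write(f"MODEL     {m:4d}\n")
                serial = 1
                for p, (x, y, z) in enumerate(frame.probe_coords):
                    mol = int(bundle.molecule_ids(frame)[p])
                    fh.write(
                        f"HETATM{serial % 100000:5d}  C   PRB P{(mol + 1) % 10000:4d}"
                        f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
                    serial += 1
                fh.write("ENDMDL\n")
            fh.write("END\n")
        run_files.append(path.name)
    if ref is not None:
        write_pdb(ref, str(out / "reference.pdb"))
    manifest = {
        "probe": {"name": bundle.probe.name,
                  "n_heavy_atoms": bundle.probe.n_heavy_atoms},
        "runs": run_files,
        "reference": "reference.pdb" if ref is not None else None,
        "fixed_composition": bool(bundle.fixed_composition),
    }
    mpath = out / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh)
    return str(mpath)


def load_bundle(manifest_path: str) -> TrajectoryBundle:
    """Read a run manifest written by :func:`write_bundle`."""
    import gemmi

    mpath = Path(manifest_path)
    with open(mpath) as fh:
        manifest = yaml.safe_load(fh)
    probe = ProbeSpec(manifest["probe"]["name"],
                      int(manifest["probe"]["n_heavy_atoms"]))
    reference = None
    if manifest.get("reference"):
        from .structure import read_structure
        reference = read_structure(str(mpath.parent / manifest["reference"]))
    ref_coords = (reference.protein().heavy().coords
                  if reference is not None else np.zeros((0, 3)))
    runs = []
    for fname in manifest["runs"]:
        st = gemmi.read_structure(str(mpath.parent / fname),
                                  format=gemmi.CoorFormat.Pdb)
        frames = []
        for model in st:
            coords, mols = [], []
            for chain in model:
                for residue in chain:
                    if residue.name != "PRB":
                        continue
                    for atom in residue:
                        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                        mols.append(residue.seqid.num - 1)
            frames.append(Frame(
                probe_coords=np.asarray(coords, float).reshape(-1, 3),
                protein_coords=ref_coords,
                molecule_ids=np.asarray(mols, int)))
        runs.append(frames)
    return TrajectoryBundle(probe=probe, runs=runs,
                            alignment_reference=reference,
                            fixed_composition=manifest.get(
                                "fixed_composition", True))
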