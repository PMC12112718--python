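"""Probe-occupancy voxel grids and grid free energies from mixed-solvent MD.

Trajectories of probe heavy atoms (benzene, dimethyl-ether, phenol,
methyl-imidazole, acetonitrile, ethylene glycol, or user-defined cosolvents)
are binned on a cubic lattice (1 Å spacing by default) fixed to the protein
frame. Raw per-voxel counts are normalised by the number of analysed frames
and by the probe's heavy-atom count, so occupancies are comparable across
probes of different sizes. A grid free energy (GFE) converts occupancy into
a per-voxel binding-favourability score relative to bulk solvent,

    GFE(v) = -k_B T ln( occupancy(v) / bulk_occupancy ),

capped for empty voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import GridFormatError, TrajectoryError
from .structure import Structure, _kabsch

__all__ = [
    "ProbeSpec", "Frame", "TrajectoryBundle", "VoxelGrid", "GFEGrid",
    "STANDARD_PROBES", "build_grid", "accumulate_occupancy",
    "normalize_occupancy", "compute_gfe", "write_dx", "read_dx",
    "KB_KCAL_PER_MOL_K",
]

#: Boltzmann constant in kcal/(mol·K)
KB_KCAL_PER_MOL_K = 0.0019872041


@dataclass(frozen=True)
class ProbeSpec:
    """A cosolvent probe: its name and heavy-atom count.

    Trajectory atoms are grouped into molecules either by an explicit
    per-atom molecule id carried on each frame or, by default, as
    contiguous blocks of ``n_heavy_atoms`` atoms.
    """

    name: str
    n_heavy_atoms: int

    def __post_init__(self) -> None:
        if self.n_heavy_atoms < 1:
            raise ValueError("n_heavy_atoms must be >= 1")


#: The six probes of the standard panel with their heavy-atom counts.
STANDARD_PROBES: dict[str, ProbeSpec] = {
    "benzene": ProbeSpec("benzene", 6),
    "dimethyl-ether": ProbeSpec("dimethyl-ether", 3),
    "phenol": ProbeSpec("phenol", 7),
    "methyl-imidazole": ProbeSpec("methyl-imidazole", 6),
    "acetonitrile": ProbeSpec("acetonitrile", 3),
    "ethylene-glycol": ProbeSpec("ethylene-glycol", 4),
}


@dataclass
class Frame:
    """One trajectory frame: probe heavy atoms plus protein heavy atoms."""

    probe_coords: np.ndarray            # (M, 3) Å
    protein_coords: np.ndarray          # (P, 3) Å
    molecule_ids: np.ndarray | None = None   # (M,) int, optional

    def __post_init__(self) -> None:
        self.probe_coords = np.asarray(self.probe_coords, float).reshape(-1, 3)
        self.protein_coords = np.asarray(self.protein_coords, float).reshape(-1, 3)
        if self.molecule_ids is not None:
            self.molecule_ids = np.asarray(self.molecule_ids, int)
            if len(self.molecule_ids) != len(self.probe_coords):
                raise TrajectoryError("molecule_ids length mismatch")


@dataclass
class TrajectoryBundle:
    """Pooled MSMD runs for a single probe, pre-aligned or alignable.

    ``runs`` is a list of frame sequences (one per independent simulation).
    All frames are pooled with equal weight; selecting an analysis window
    (e.g. the last half of each run) is the caller's responsibility and is
    supported by ``window()``.
    """

    probe: ProbeSpec
    runs: list[list[Frame]]
    alignment_reference: Structure | None = None
    #: real MD systems have a fixed atom count per frame; synthetic
    #: Poisson-background trajectories do not and disable the check
    fixed_composition: bool = True

    @property
    def n_frames_total(self) -> int:
        return sum(len(r) for r in self.runs)

    def frames(self) -> list[Frame]:
        return [f for run in self.runs for f in run]

    def window(self, fraction: float = 0.5) -> "TrajectoryBundle":
        """Keep the final ``fraction`` of each run (e.g. the analysed window)."""
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        runs = [r[int(round(len(r) * (1 - fraction))):] for r in self.runs]
        return TrajectoryBundle(self.probe, runs, self.alignment_reference)

    def molecule_ids(self, frame: Frame) -> np.ndarray:
        """Per-atom molecule ids; contiguous blocks of n_heavy_atoms by default."""
        if frame.molecule_ids is not None:
            return frame.molecule_ids
        m = len(frame.probe_coords)
        return np.arange(m) // self.probe.n_heavy_atoms


@dataclass
class VoxelGrid:
    """Cubic occupancy lattice for one probe.

    Voxels are half-open cells ``[origin + i·s, origin + (i+1)·s)`` per axis;
    a voxel's *center* is ``origin + (i + 1/2)·s``. ``occupancy`` is
    ``raw_counts / (n_frames × n_heavy_atoms)`` once normalised.
    """

    origin: np.ndarray                 # (3,) Å, minimum corner
    spacing: float
    shape: tuple[int, int, int]
    raw_counts: np.ndarray             # shape-sized float array
    probe: ProbeSpec | None = None
    n_frames: int = 0
    occupancy: np.ndarray | None = None
    spill: int = 0                     # atoms that fell outside the box

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float).reshape(3)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        self.shape = tuple(int(n) for n in self.shape)
        self.raw_counts = np.asarray(self.raw_counts, float).reshape(self.shape)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def lattice(self) -> tuple:
        return (tuple(np.round(self.origin, 6)), round(self.spacing, 6), self.shape)

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Centers (Å) of voxels given as an (n, 3) array of lattice indices."""
        idx = np.asarray(indices, int).reshape(-1, 3)
        return self.origin + (idx + 0.5) * self.spacing

    def copy(self) -> "VoxelGrid":
        return replace(
            self,
            origin=self.origin.copy(),
            raw_counts=self.raw_counts.copy(),
            occupancy=None if self.occupancy is None else self.occupancy.copy(),
        )


@dataclass
class GFEGrid:
    """Grid free energy on the same lattice as its parent VoxelGrid."""

    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    gfe: np.ndarray                    # kcal/mol
    temperature: float = 300.0
    bulk_occupancy: float = 1.0
    gfe_cap: float = 3.0
    probe: ProbeSpec | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.gfe = np.asarray(self.gfe, float).reshape(self.shape)
        if not np.isfinite(self.gfe).all():
            raise ValueError("GFE values must be finite")

    def lattice(self) -> tuple:
        return (tuple(np.round(self.origin, 6)), round(self.spacing, 6), self.shape)


def build_grid(reference: Structure, padding: float = 8.0,
               spacing: float = 1.0, probe: ProbeSpec | None = None) -> VoxelGrid:
    """Empty grid whose box covers the protein heavy atoms plus ``padding``.

    The origin is the padded minimum corner snapped down onto the spacing
    lattice, so grids built from slightly shifted references remain
    commensurate.
    """
    if padding < 0:
        raise ValueError("padding must be non-negative")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    coords = reference.heavy_coords()
    if len(coords) == 0:
        raise ValueError("reference structure has no heavy atoms")
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    origin = np.floor(lo / spacing) * spacing
    shape = tuple(int(np.floor((hi[k] - origin[k]) / spacing)) + 1 for k in range(3))
    return VoxelGrid(origin=origin, spacing=spacing, shape=shape,
                     raw_counts=np.zeros(shape), probe=probe)


def _frame_alignment(frame: Frame, reference_coords: np.ndarray):
    if len(frame.protein_coords) != len(reference_coords):
        raise TrajectoryError(
            "frame protein atom count differs from alignment reference")
    return _kabsch(frame.protein_coords, reference_coords)


def accumulate_occupancy(bundle: TrajectoryBundle, grid: VoxelGrid,
                         align: bool = False) -> VoxelGrid:
    """Bin probe heavy atoms of every pooled frame into the grid.

    With ``align=True`` each frame's protein coordinates are first
    superposed (Kabsch, all supplied protein atoms) onto the bundle's
    alignment reference and the same rigid transform is applied to the
    probe atoms, so occupancy is accumulated in a protein-fixed frame.
    Atoms outside the box are ignored but tallied in ``spill``.
    """
    out = grid.copy()
    out.probe = bundle.probe
    frames = bundle.frames()
    if frames:
        n_atoms = len(frames[0].probe_coords)
        ref_coords = None
        if align:
            if bundle.alignment_reference is None:
                raise TrajectoryError("align=True requires an alignment_reference")
            ref_coords = bundle.alignment_reference.heavy_coords()
        pooled = []
        for f in frames:
            if bundle.fixed_composition and len(f.probe_coords) != n_atoms:
                raise TrajectoryError("probe atom count varies across frames")
            coords = f.probe_coords
            if align and len(coords):
                rot, trans, _ = _frame_alignment(f, ref_coords)
                coords = coords @ rot.T + trans
            pooled.append(coords)
        if pooled and sum(map(len, pooled)):
            coords = np.concatenate(pooled, axis=0)
            idx = np.floor((coords - out.origin) / out.spacing).astype(int)
            inb = np.all((idx >= 0) & (idx < np.array(out.shape)), axis=1)
            out.spill += int((~inb).sum())
            flat = np.ravel_multi_index(idx[inb].T, out.shape)
            np.add.at(out.raw_counts.reshape(-1), flat, 1.0)
    out.n_frames += len(frames)
    out.occupancy = None
    return out


def normalize_occupancy(grid: VoxelGrid) -> VoxelGrid:
    """occupancy = raw_counts / (n_frames × probe heavy atoms per molecule)."""
    if grid.n_frames <= 0:
        raise ZeroDivisionError("grid has no accumulated frames")
    if grid.probe is None:
        raise ValueError("grid has no probe specification")
    out = grid.copy()
    out.occupancy = out.raw_counts / (grid.n_frames * grid.probe.n_heavy_atoms)
    return out


def solvent_mask(grid: VoxelGrid, reference: Structure,
                 distance: float = 5.0) -> np.ndarray:
    """Boolean mask of voxels whose centers lie > ``distance`` from the protein."""
    tree = cKDTree(reference.heavy_coords())
    all_idx = np.indices(grid.shape).reshape(3, -1).T
    centers = grid.voxel_centers(all_idx)
    d, _ = tree.query(centers, k=1)
    return (d > distance).reshape(grid.shape)


def compute_gfe(grid: VoxelGrid, temperature: float = 300.0,
                bulk_occupancy: float | None = None, cap: float = 3.0,
                reference: Structure | None = None,
                solvent_distance: float = 5.0) -> GFEGrid:
    """Grid free energy −k_B·T·ln(occupancy/bulk), capped at ``cap`` kcal/mol.

    ``bulk_occupancy`` defaults to the mean occupancy over solvent-exposed
    voxels (centers farther than ``solvent_distance`` from any protein heavy
    atom of ``reference``), the conventional bulk reference for cosolvent
    maps. Voxels with zero occupancy take the cap value.
    """
    if grid.occupancy is None:
        grid = normalize_occupancy(grid)
    occ = grid.occupancy
    if bulk_occupancy is None:
        if reference is None:
            raise ValueError("need bulk_occupancy or a reference structure")
        mask = solvent_mask(grid, reference, solvent_distance)
        if not mask.any():
            raise ValueError("no solvent-exposed voxels to define bulk")
        bulk_occupancy = float(occ[mask].mean())
    if bulk_occupancy <= 0:
        raise ValueError("bulk_occupancy must be positive")
    gfe = np.full(grid.shape, float(cap))
    pos = occ > 0
    gfe[pos] = -KB_KCAL_PER_MOL_K * temperature * np.log(occ[pos] / bulk_occupancy)
    np.minimum(gfe, cap, out=gfe)
    return GFEGrid(origin=grid.origin.copy(), spacing=grid.spacing,
                   shape=grid.shape, gfe=gfe, temperature=temperature,
                   bulk_occupancy=float(bulk_occupancy), gfe_cap=float(cap),
                   probe=grid.probe)


# ---------------------------------------------------------------------------
# OpenDX scalar-field I/O (written by hand; the format is three header
# objects plus whitespace-separated values with the z index varying fastest)

def write_dx(path: str, origin: np.ndarray, spacing: float,
             values: np.ndarray, comment: str = "cryptohot grid") -> None:
    values = np.asarray(values, float)
    nx, ny, nz = values.shape
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*np.asarray(origin, float)))
        fh.write(f"delta {spacing:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {spacing:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {spacing:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {values.size} "
                 "data follows\n")
        flat = values.reshape(-1)
        for start in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.10g}" for v in flat[start:start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')


def read_dx(path: str) -> tuple[np.ndarray, float, np.ndarray]:
    """Read an OpenDX scalar field; returns (origin, spacing, values)."""
    shape = None
    origin = None
    deltas: list[np.ndarray] = []
    values: list[float] = []
    n_items = None
    in_data = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if in_data:
                if line.startswith(("attribute", "object", "component")):
                    in_data = False
                    continue
                values.extend(float(tok) for tok in line.split())
                continue
            if line.startswith("object") and "gridpositions" in line:
                try:
                    shape = tuple(int(t) for t in line.split()[-3:])
                except ValueError as exc:
                    raise GridFormatError(f"{path}: bad counts line") from exc
            elif line.startswith("origin"):
                origin = np.array([float(t) for t in line.split()[1:4]])
            elif line.startswith("delta"):
                deltas.append(np.array([float(t) for t in line.split()[1:4]]))
            elif line.startswith("object") and "data follows" in line:
                n_items = int(line.split("items")[1].split()[0])
                in_data = True
    if shape is None or origin is None or len(deltas) != 3:
        raise GridFormatError(f"{path}: malformed OpenDX header")
    delta = np.array(deltas)
    spacing = float(delta[0, 0])
    if not (np.allclose(np.diag(delta), spacing) and
            np.allclose(delta - np.diag(np.diag(delta)), 0)):
        raise GridFormatError(f"{path}: non-cubic or rotated deltas unsupported")
    if n_items is None or len(values) != n_items or n_items != int(np.prod(shape)):
        raise GridFormatError(f"{path}: value count mismatch")
    return origin, spacing, np.array(values).reshape(shape)


def grid_to_dx(grid: VoxelGrid, path: str, field: str = "occupancy") -> None:
    """Serialize a VoxelGrid's occupancy (or raw counts) as OpenDX."""
    if field == "occupancy":
        if grid.occupancy is None:
            raise ValueError("grid is not normalised; no occupancy to write")
        values = grid.occupancy
    elif field == "raw_counts":
        values = grid.raw_counts
    else:
        raise ValueError(f"unknown field {field!r}")
    name = grid.probe.name if grid.probe else "grid"
    write_dx(path, grid.origin, grid.spacing, values,
             comment=f"cryptohot {field} for {name}, n_frames={grid.n_frames}")


def gfe_to_dx(grid: GFEGrid, path: str) -> None:
    write_dx(path, grid.origin, grid.spacing, grid.gfe,
             comment=f"cryptohot GFE (kcal/mol), T={grid.temperature} K")
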