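"""Hotspot- and surface-derived features for cryptic-site classification.

For each hotspot, a *surface patch* is the set of residues with a heavy atom
within a cutoff (4.5 Å default) of any hotspot voxel center. From the patch
and the trajectories we compute:

* per-probe grid free energy (mean over hotspot voxels) and frame-averaged
  probe-molecule count inside the hotspot;
* size — solvent-accessible surface area (Shrake–Rupley, probe radius
  1.4 Å) summed over patch residues, trajectory-averaged;
* protrusion — fraction of patch residues with fewer than 120 protein heavy
  atoms in an 8–12 Å shell around the residue centroid;
* convexity — mean ratio of closest solvent-exposed-atom distance to
  centroid distance over adjacent residue pairs (centroids < 8 Å apart);
* compactness — mean over residue pairs of the closest heavy-atom distance;
* hydrophobicity — mean Kyte–Doolittle index of patch residues;
* charge density — net formal charge (Arg/Lys positive, Asp/Glu negative,
  His neutral) divided by the trajectory-averaged patch area;
* flexibility — mean per-residue Cα RMSF over the patch, one value per
  probe simulation, after two-pass rigid alignment.

A hotspot absent from a probe's map is not missing data: it is imputed with
the GFE cap and zero probe count, since absence of accumulation is itself
informative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import biotite.structure as bst
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .density import GFEGrid, TrajectoryBundle, VoxelGrid, normalize_occupancy
from .hotspots import Hotspot
from .structure import Structure, _kabsch

__all__ = [
    "PatchParams", "SurfacePatch", "define_patch", "compute_size",
    "compute_compactness", "compute_protrusion", "compute_convexity",
    "compute_hydrophobicity", "compute_charge_density", "compute_rmsf",
    "hotspot_probe_features", "hotspot_feature_row", "assemble_features",
    "KYTE_DOOLITTLE",
]

#: Kyte–Doolittle hydropathy index per residue.
KYTE_DOOLITTLE: dict[str, float] = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

_POSITIVE = {"ARG", "LYS"}
_NEGATIVE = {"ASP", "GLU"}

#: element van der Waals radii (Å) used for SASA
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}


@dataclass(frozen=True)
class PatchParams:
    """Patch and protrusion-shell geometry (Å)."""

    patch_cutoff: float = 4.5
    protrusion_inner: float = 8.0
    protrusion_outer: float = 12.0
    protrusion_neighbor_max: int = 120
    frame_stride: int = 1
    adjacency_cutoff: float = 8.0     # residue pairs counted as neighbours

    def __post_init__(self) -> None:
        if not 0 < self.protrusion_inner < self.protrusion_outer:
            raise ValueError("need 0 < inner < outer shell radius")
        if self.patch_cutoff <= 0 or self.frame_stride < 1:
            raise ValueError("invalid patch parameters")


@dataclass
class SurfacePatch:
    """Residues forming the protein surface near one hotspot."""

    residues: frozenset[tuple[str, str]]    # (chain_id, res_id)
    hotspot_id: str

    def __len__(self) -> int:
        return len(self.residues)


def define_patch(hotspot: Hotspot, structure: Structure,
                 params: PatchParams = PatchParams()) -> SurfacePatch:
    """Residues with any heavy atom within ``patch_cutoff`` of a voxel center."""
    centers = hotspot.voxel_centers()
    prot = structure.protein()
    tree = cKDTree(centers)
    residues: set[tuple[str, str]] = set()
    for key, idx in prot.residue_atom_indices(heavy_only=True).items():
        d, _ = tree.query(prot.coords[idx], k=1)
        if np.any(d <= params.patch_cutoff):
            residues.add(key)
    if not residues:
        warnings.warn(f"hotspot {hotspot.id}: empty surface patch", stacklevel=2)
    return SurfacePatch(residues=frozenset(residues), hotspot_id=hotspot.id)


def _to_atom_array(structure: Structure, coords: np.ndarray | None = None
                   ) -> bst.AtomArray:
    prot = structure.protein().heavy()
    n = len(prot)
    arr = bst.AtomArray(n)
    arr.coord = (coords if coords is not None else prot.coords).astype(np.float32)
    arr.chain_id = prot.chain_ids.astype("U4")
    # biotite wants integer residue ids; preserve order, remap insertion codes
    keys = [(c, r) for c, r in zip(prot.chain_ids, prot.res_ids)]
    remap: dict[tuple[str, str], int] = {}
    for k in keys:
        remap.setdefault(k, len(remap) + 1)
    arr.res_id = np.array([remap[k] for k in keys], int)
    arr.res_name = prot.res_names.astype("U5")
    arr.atom_name = prot.atom_names.astype("U6")
    arr.element = prot.elements.astype("U2")
    arr.hetero = np.zeros(n, bool)
    return arr


def _per_atom_sasa(structure: Structure, coords: np.ndarray | None = None,
                   point_number: int = 200) -> np.ndarray:
    """Shrake–Rupley SASA per heavy atom of the protein part (Å²)."""
    arr = _to_atom_array(structure, coords)
    radii = np.array([VDW_RADII.get(e.upper(), 1.7) for e in arr.element])
    sasa = bst.sasa(arr, probe_radius=1.4, point_number=point_number,
                    vdw_radii=radii)
    return np.nan_to_num(np.asarray(sasa, float))


def _patch_atom_mask(structure: Structure, patch: SurfacePatch) -> np.ndarray:
    prot = structure.protein().heavy()
    keys = set(patch.residues)
    return np.array([(c, r) in keys
                     for c, r in zip(prot.chain_ids, prot.res_ids)], bool)


def compute_size(patch: SurfacePatch, structure: Structure,
                 frames: np.ndarray | None = None,
                 params: PatchParams = PatchParams(),
                 point_number: int = 200) -> float:
    """Trajectory-averaged accessible surface area of the patch (Å²).

    ``frames`` is an optional (F, H, 3) array of protein heavy-atom
    coordinates in the order of ``structure.protein().heavy()``; without it
    the static structure is used.
    """
    if not patch.residues:
        return 0.0
    mask = _patch_atom_mask(structure, patch)
    if frames is None:
        return float(_per_atom_sasa(structure, point_number=point_number)[mask].sum())
    frames = np.asarray(frames, float)
    vals = [
        _per_atom_sasa(structure, frames[i], point_number=point_number)[mask].sum()
        for i in range(0, len(frames), params.frame_stride)
    ]
    return float(np.mean(vals))


def _residue_groups(structure: Structure, patch: SurfacePatch
                    ) -> dict[tuple[str, str], np.ndarray]:
    prot = structure.protein()
    groups = prot.residue_atom_indices(heavy_only=True)
    return {k: groups[k] for k in sorted(patch.residues) if k in groups}


def compute_compactness(patch: SurfacePatch, structure: Structure) -> float:
    """Mean over residue pairs of the minimum heavy-atom distance (Å)."""
    groups = _residue_groups(structure, patch)
    keys = list(groups)
    if len(keys) < 2:
        return 0.0
    prot = structure.protein()
    dists = []
    for i in range(len(keys)):
        ci = prot.coords[groups[keys[i]]]
        for j in range(i + 1, len(keys)):
            cj = prot.coords[groups[keys[j]]]
            diff = ci[:, None, :] - cj[None, :, :]
            dists.append(np.sqrt((diff ** 2).sum(-1)).min())
    return float(np.mean(dists))


def compute_protrusion(patch: SurfacePatch, structure: Structure,
                       params: PatchParams = PatchParams()) -> float:
    """Fraction of patch residues with < ``protrusion_neighbor_max`` protein
    heavy atoms at shell distance (inner, outer] from the residue centroid."""
    groups = _residue_groups(structure, patch)
    if not groups:
        return 0.0
    prot = structure.protein()
    all_heavy = prot.heavy_coords()
    tree = cKDTree(all_heavy)
    protruding = 0
    for idx in groups.values():
        centroid = prot.coords[idx].mean(axis=0)
        n_outer = len(tree.query_ball_point(centroid, params.protrusion_outer))
        n_inner = len(tree.query_ball_point(centroid, params.protrusion_inner))
        if n_outer - n_inner < params.protrusion_neighbor_max:
            protruding += 1
    return protruding / len(groups)


def compute_convexity(patch: SurfacePatch, structure: Structure,
                      params: PatchParams = PatchParams(),
                      point_number: int = 200) -> float:
    """Mean ratio of closest exposed-atom distance to centroid distance over
    adjacent residue pairs; > 1 on convex bulges, < 1 inside concave pockets."""
    groups = _residue_groups(structure, patch)
    keys = list(groups)
    if len(keys) < 2:
        warnings.warn("convexity undefined for < 2 residues; imputing 0",
                      stacklevel=2)
        return 0.0
    prot = structure.protein()
    sasa = _per_atom_sasa(structure, point_number=point_number)
    heavy_idx = np.flatnonzero(prot.is_heavy)
    pos_in_heavy = {int(g): k for k, g in enumerate(heavy_idx)}
    centroids = {k: prot.coords[groups[k]].mean(axis=0) for k in keys}
    ratios = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            cd = float(np.linalg.norm(centroids[keys[i]] - centroids[keys[j]]))
            if cd >= params.adjacency_cutoff or cd == 0:
                continue
            exp_i = [a for a in groups[keys[i]] if sasa[pos_in_heavy[int(a)]] > 0]
            exp_j = [a for a in groups[keys[j]] if sasa[pos_in_heavy[int(a)]] > 0]
            if not exp_i or not exp_j:
                continue
            diff = prot.coords[exp_i][:, None, :] - prot.coords[exp_j][None, :, :]
            dmin = float(np.sqrt((diff ** 2).sum(-1)).min())
            ratios.append(dmin / cd)
    if not ratios:
        warnings.warn("no adjacent residue pairs; imputing convexity 0",
                      stacklevel=2)
        return 0.0
    return float(np.mean(ratios))


def compute_hydrophobicity(patch: SurfacePatch, structure: Structure) -> float:
    """Mean Kyte–Doolittle index over patch residues."""
    prot = structure.protein()
    names = {}
    for c, r, n in zip(prot.chain_ids, prot.res_ids, prot.res_names):
        names[(c, r)] = n
    values = []
    for key in sorted(patch.residues):
        resname = names.get(key)
        if resname in KYTE_DOOLITTLE:
            values.append(KYTE_DOOLITTLE[resname])
        else:
            warnings.warn(f"unknown residue {resname!r} skipped in hydrophobicity",
                          stacklevel=2)
    return float(np.mean(values)) if values else 0.0


def compute_charge_density(patch: SurfacePatch, structure: Structure,
                           size: float) -> float:
    """(nArg + nLys − nAsp − nGlu) / size, His counted neutral (e/Å²)."""
    if size <= 0:
        warnings.warn("zero patch area; imputing charge density 0", stacklevel=2)
        return 0.0
    prot = structure.protein()
    names = {}
    for c, r, n in zip(prot.chain_ids, prot.res_ids, prot.res_names):
        names[(c, r)] = n
    net = 0
    for key in patch.residues:
        resname = names.get(key)
        if resname in _POSITIVE:
            net += 1
        elif resname in _NEGATIVE:
            net -= 1
    return net / size


def _ca_positions(structure: Structure, frames: np.ndarray
                  ) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Cα coordinates per frame; frames indexed over protein heavy atoms."""
    prot = structure.protein().heavy()
    mask = prot.atom_names == "CA"
    keys = [(c, r) for c, r in zip(prot.chain_ids[mask], prot.res_ids[mask])]
    return np.asarray(frames, float)[:, mask, :], keys


def compute_rmsf(structure: Structure, frames: np.ndarray,
                 patch: SurfacePatch | None = None,
                 align: bool = True) -> float | np.ndarray:
    """Mean per-residue Cα RMSF (Å), two-pass aligned.

    Frames are first superposed onto the initial frame, the mean structure
    is formed, frames are re-superposed onto that mean, and
    RMSF_i = sqrt(<|r_i − r̄_i|²>). With a patch, the patch-residue mean is
    returned; otherwise the full per-residue vector. ``align=False`` skips
    the superposition for trajectories already in the protein frame.
    """
    ca, keys = _ca_positions(structure, frames)
    if len(ca) < 2:
        raise ValueError("RMSF needs at least two frames")

    def align_all(target: np.ndarray) -> np.ndarray:
        if not align:
            return ca
        out = np.empty_like(ca)
        for f in range(len(ca)):
            rot, trans, _ = _kabsch(ca[f], target)
            out[f] = ca[f] @ rot.T + trans
        return out

    mean1 = align_all(ca[0]).mean(axis=0)
    aligned = align_all(mean1)
    mean2 = aligned.mean(axis=0)
    rmsf = np.sqrt(((aligned - mean2) ** 2).sum(-1).mean(axis=0))
    if patch is None:
        return rmsf
    sel = [k in patch.residues for k in keys]
    if not any(sel):
        return 0.0
    return float(rmsf[np.asarray(sel)].mean())


def protein_heavy_frames(bundle: TrajectoryBundle) -> np.ndarray:
    """Stack protein heavy-atom coordinates of all pooled frames, (F, H, 3)."""
    return np.stack([f.protein_coords for f in bundle.frames()])


def hotspot_probe_features(hotspot: Hotspot, grid: VoxelGrid, gfe: GFEGrid,
                           bundle: TrajectoryBundle | None = None,
                           aggregate: str = "mean") -> tuple[float, float]:
    """(GFE over hotspot voxels, frame-averaged probe-molecule count inside).

    ``aggregate`` picks mean (default) or min GFE over the hotspot's voxels.
    The molecule count takes, per frame, the number of distinct probe
    molecules with at least one heavy atom inside the hotspot voxel set.
    """
    if hotspot.lattice != gfe.lattice():
        raise ValueError("hotspot and GFE grid on different lattices")
    idx = np.array(sorted(hotspot.voxels), int)
    vals = gfe.gfe[tuple(idx.T)]
    gfe_value = float(vals.min() if aggregate == "min" else vals.mean())
    if bundle is None:
        return gfe_value, 0.0
    voxset = {int(np.ravel_multi_index(v, grid.shape)) for v in hotspot.voxels}
    shape_arr = np.array(grid.shape)
    counts = []
    for frame in bundle.frames():
        if len(frame.probe_coords) == 0:
            counts.append(0)
            continue
        vidx = np.floor((frame.probe_coords - grid.origin) / grid.spacing).astype(int)
        inb = np.all((vidx >= 0) & (vidx < shape_arr), axis=1)
        flat = np.ravel_multi_index(vidx[inb].T, grid.shape)
        inside = np.fromiter((f in voxset for f in flat), bool, count=len(flat))
        mols = bundle.molecule_ids(frame)[inb][inside]
        counts.append(len(np.unique(mols)))
    return gfe_value, float(np.mean(counts)) if counts else 0.0


def hotspot_feature_row(hotspot: Hotspot, structure: Structure,
                        per_probe: dict[str, tuple[VoxelGrid, GFEGrid,
                                                   TrajectoryBundle | None]],
                        params: PatchParams = PatchParams(),
                        gfe_cap: float = 3.0,
                        prefix: str = "",
                        protein_id: str = "") -> dict:
    """Assemble one hotspot's named feature dict.

    ``per_probe`` maps probe name to (occupancy grid, GFE grid, bundle);
    probes without a map for this hotspot are imputed with ``gfe_cap`` and
    zero count. With ``prefix`` (e.g. ``water_``) the same features are
    stored under prefixed names, used for the water-environment feature set.
    """
    patch = define_patch(hotspot, structure, params)
    row: dict = {"hotspot_id": hotspot.id,
                 "protein_id": protein_id or structure.id}
    rmsf_frames: dict[str, np.ndarray | None] = {}
    for probe_name, (grid, gfe, bundle) in sorted(per_probe.items()):
        if grid is None or gfe is None:
            g_val, n_val = float(gfe_cap), 0.0
        else:
            g_val, n_val = hotspot_probe_features(hotspot, grid, gfe, bundle)
        row[f"{prefix}gfe_{probe_name}"] = g_val
        row[f"{prefix}count_{probe_name}"] = n_val
        rmsf_frames[probe_name] = (protein_heavy_frames(bundle)
                                   if bundle is not None and bundle.n_frames_total >= 2
                                   else None)
    size_frames = next((f for f in rmsf_frames.values() if f is not None), None)
    size = compute_size(patch, structure, frames=size_frames, params=params)
    row[f"{prefix}size"] = size
    row[f"{prefix}protrusion"] = compute_protrusion(patch, structure, params)
    row[f"{prefix}convexity"] = compute_convexity(patch, structure, params)
    row[f"{prefix}compactness"] = compute_compactness(patch, structure)
    row[f"{prefix}hydrophobicity"] = compute_hydrophobicity(patch, structure)
    row[f"{prefix}charge_density"] = compute_charge_density(patch, structure, size)
    for probe_name, frames in sorted(rmsf_frames.items()):
        row[f"{prefix}rmsf_{probe_name}"] = (
            compute_rmsf(structure, frames, patch) if frames is not None else 0.0)
    if not prefix:
        row["label"] = hotspot.label
    return row


def assemble_features(rows: list[dict]) -> pd.DataFrame:
    """Fixed-column-order feature table; errors on duplicate hotspot ids."""
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    key_cols = [c for c in ("hotspot_id", "protein_id") if c in df.columns]
    if key_cols and df.duplicated(subset=key_cols).any():
        raise ValueError("duplicate hotspot ids in feature rows")
    feature_cols = sorted(c for c in df.columns
                          if c not in ("hotspot_id", "protein_id", "label"))
    ordered = key_cols + feature_cols + (["label"] if "label" in df.columns else [])
    df = df[ordered]
    df[feature_cols] = df[feature_cols].fillna(0.0)
    return df
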