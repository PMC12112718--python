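"""Hotspot detection from probe occupancy grids and cryptic/non-cryptic labeling.

Voxels whose normalised occupancy strictly exceeds a threshold are clustered
per probe with DBSCAN (Euclidean metric over voxel centers). Clusters from
all probes sharing one lattice are then merged whenever their voxel sets
overlap by more than a set fraction (relative to the smaller cluster by
default), taking the transitive closure so the result is independent of
input order. A merged hotspot is labeled *cryptic* against a clash-based
cryptic-site definition when

1. at least ``clash_fraction`` of its voxel centers lie within
   ``clash_distance`` of a heavy atom of a clashing residue, and
2. at least one voxel center lies within ``ligand_distance`` of a ligand
   heavy atom.

A third, human judgement ("manual inspection") is carried as an annotation
and never set automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .exceptions import LatticeMismatchError
from .density import ProbeSpec, VoxelGrid
from .structure import CrypticSiteDefinition, Structure

__all__ = [
    "DetectionParams", "LabelParams", "ProbeCluster", "Hotspot",
    "select_voxels", "cluster_voxels", "merge_clusters", "label_cryptic",
    "detect_hotspots", "hotspots_to_frame", "hotspots_to_pdb",
]


@dataclass(frozen=True)
class DetectionParams:
    """Detection defaults: occupancy > 0.0004, DBSCAN ε=3.0 Å / min_samples=7,
    merge clusters overlapping by more than 20% of the smaller one."""

    occupancy_threshold: float = 0.0004
    eps: float = 3.0
    min_samples: int = 7
    overlap_fraction: float = 0.20
    overlap_mode: str = "min"        # "min" or "jaccard"

    def __post_init__(self) -> None:
        if min(self.occupancy_threshold, self.eps, self.min_samples) <= 0:
            raise ValueError("detection parameters must be positive")
        if not 0 < self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in (0, 1)")
        if self.overlap_mode not in ("min", "jaccard"):
            raise ValueError("overlap_mode must be 'min' or 'jaccard'")


@dataclass(frozen=True)
class LabelParams:
    """Cryptic-labeling distances: 80% of voxels within 3.5 Å of clashing
    residues, at least one voxel within 4.5 Å of the ligand."""

    clash_fraction: float = 0.80
    clash_distance: float = 3.5
    ligand_distance: float = 4.5

    def __post_init__(self) -> None:
        if not 0 < self.clash_fraction <= 1:
            raise ValueError("clash_fraction must be in (0, 1]")
        if self.clash_distance <= 0 or self.ligand_distance <= 0:
            raise ValueError("distances must be positive")


@dataclass
class ProbeCluster:
    """A DBSCAN cluster of high-occupancy voxels for a single probe."""

    probe: ProbeSpec
    voxels: frozenset[tuple[int, int, int]]
    occupancy_sum: float
    centroid: np.ndarray
    lattice: tuple

    def __len__(self) -> int:
        return len(self.voxels)


@dataclass
class Hotspot:
    """Union of merged probe clusters on one lattice."""

    id: str
    voxels: frozenset[tuple[int, int, int]]
    contributing_probes: frozenset[str]
    per_probe_occupancy: dict[str, float]
    lattice: tuple
    label: str = "unlabeled"          # cryptic | non_cryptic | unlabeled
    manual_flag: str | None = None

    def __post_init__(self) -> None:
        if not self.voxels:
            raise ValueError("hotspot must have voxels")
        if not self.contributing_probes:
            raise ValueError("hotspot must have contributing probes")

    @property
    def total_occupancy(self) -> float:
        return float(sum(self.per_probe_occupancy.values()))

    def voxel_centers(self) -> np.ndarray:
        origin, spacing, _ = self.lattice
        idx = np.array(sorted(self.voxels), dtype=int)
        return np.asarray(origin, float) + (idx + 0.5) * spacing

    @property
    def centroid(self) -> np.ndarray:
        return self.voxel_centers().mean(axis=0)


def select_voxels(grid: VoxelGrid, params: DetectionParams = DetectionParams()
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Indices and centers of voxels with occupancy strictly above threshold."""
    if grid.occupancy is None:
        raise ValueError("grid is not normalised")
    idx = np.argwhere(grid.occupancy > params.occupancy_threshold)
    return idx, grid.voxel_centers(idx)


def cluster_voxels(grid: VoxelGrid, params: DetectionParams = DetectionParams()
                   ) -> list[ProbeCluster]:
    """DBSCAN over selected voxel centers; noise voxels are discarded.

    Clusters are returned sorted by occupancy sum, descending; input order
    to DBSCAN follows lattice order so border-point assignment is
    deterministic.
    """
    idx, centers = select_voxels(grid, params)
    if len(idx) == 0:
        return []
    labels = DBSCAN(eps=params.eps, min_samples=params.min_samples,
                    metric="euclidean").fit(centers).labels_
    clusters: list[ProbeCluster] = []
    occ = grid.occupancy
    for lab in sorted(set(labels) - {-1}):
        sel = labels == lab
        vox = frozenset(map(tuple, idx[sel]))
        osum = float(occ[tuple(idx[sel].T)].sum())
        clusters.append(ProbeCluster(
            probe=grid.probe, voxels=vox, occupancy_sum=osum,
            centroid=centers[sel].mean(axis=0), lattice=grid.lattice()))
    clusters.sort(key=lambda c: (-c.occupancy_sum, tuple(np.round(c.centroid, 6))))
    return clusters


def _overlap(a: ProbeCluster, b: ProbeCluster, mode: str) -> float:
    inter = len(a.voxels & b.voxels)
    if inter == 0:
        return 0.0
    if mode == "jaccard":
        return inter / len(a.voxels | b.voxels)
    return inter / min(len(a.voxels), len(b.voxels))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_clusters(clusters: list[ProbeCluster],
                   params: DetectionParams = DetectionParams()) -> list[Hotspot]:
    """Merge clusters (from all probes) with pairwise overlap > threshold.

    Merging is transitive (connected components of the overlap graph), so
    the partition is invariant under permutation of the input. Hotspot ids
    are assigned by descending total occupancy, ties broken by lexicographic
    centroid.
    """
    if not clusters:
        return []
    lattices = {c.lattice for c in clusters}
    if len(lattices) > 1:
        raise LatticeMismatchError("clusters live on different lattices")
    n = len(clusters)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if _overlap(clusters[i], clusters[j], params.overlap_mode) \
                    > params.overlap_fraction:
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    hotspots = []
    for members in groups.values():
        vox = frozenset().union(*(clusters[i].voxels for i in members))
        per_probe: dict[str, float] = {}
        for i in members:
            name = clusters[i].probe.name
            per_probe[name] = per_probe.get(name, 0.0) + clusters[i].occupancy_sum
        hotspots.append(Hotspot(
            id="", voxels=vox, contributing_probes=frozenset(per_probe),
            per_probe_occupancy=per_probe, lattice=clusters[members[0]].lattice))
    hotspots.sort(key=lambda h: (-h.total_occupancy, tuple(np.round(h.centroid, 6))))
    for k, h in enumerate(hotspots, start=1):
        h.id = f"HS{k:02d}"
    return hotspots


def label_cryptic(hotspot: Hotspot, site: CrypticSiteDefinition, apo: Structure,
                  params: LabelParams = LabelParams()) -> Hotspot:
    """Return a copy of the hotspot labeled cryptic/non_cryptic against the site.

    Distances are measured from voxel centers to heavy atoms of the clashing
    residues (criterion 1, fraction ≥ ``clash_fraction``) and to ligand
    heavy atoms (criterion 2, at least one voxel). An empty clash set labels
    everything non_cryptic with a warning.
    """
    out = Hotspot(id=hotspot.id, voxels=hotspot.voxels,
                  contributing_probes=hotspot.contributing_probes,
                  per_probe_occupancy=dict(hotspot.per_probe_occupancy),
                  lattice=hotspot.lattice, manual_flag=hotspot.manual_flag)
    if not site.clash_residues:
        warnings.warn("empty clash set: labeling hotspot non_cryptic",
                      stacklevel=2)
        out.label = "non_cryptic"
        return out
    centers = hotspot.voxel_centers()
    res_atoms = apo.protein().residue_atom_indices(heavy_only=True)
    prot = apo.protein()
    clash_idx = [i for key in site.residue_ids for i in res_atoms.get(key, [])]
    if not clash_idx:
        warnings.warn("clash residues absent from structure; labeling non_cryptic",
                      stacklevel=2)
        out.label = "non_cryptic"
        return out
    clash_coords = prot.coords[np.asarray(clash_idx, int)]
    d_clash, _ = cKDTree(clash_coords).query(centers, k=1)
    frac = float(np.mean(d_clash <= params.clash_distance))
    d_lig, _ = cKDTree(site.ligand.coords).query(centers, k=1)
    near_ligand = bool(np.any(d_lig <= params.ligand_distance))
    cryptic = (frac >= params.clash_fraction) and near_ligand
    out.label = "cryptic" if cryptic else "non_cryptic"
    return out


def detect_hotspots(grids: list[VoxelGrid],
                    params: DetectionParams = DetectionParams()) -> list[Hotspot]:
    """Full detection: per-probe clustering then cross-probe merging."""
    clusters: list[ProbeCluster] = []
    for grid in grids:
        clusters.extend(cluster_voxels(grid, params))
    return merge_clusters(clusters, params)


def hotspots_to_frame(hotspots: list[Hotspot]) -> pd.DataFrame:
    """Tabular report: id, probes, voxel count, centroid, occupancies, label."""
    rows = []
    for h in hotspots:
        c = h.centroid
        row = {
            "hotspot_id": h.id,
            "probes": "+".join(sorted(h.contributing_probes)),
            "n_voxels": len(h.voxels),
            "centroid_x": round(float(c[0]), 3),
            "centroid_y": round(float(c[1]), 3),
            "centroid_z": round(float(c[2]), 3),
            "total_occupancy": h.total_occupancy,
            "label": h.label,
        }
        for probe, occ in sorted(h.per_probe_occupancy.items()):
            row[f"occ_{probe}"] = occ
        rows.append(row)
    return pd.DataFrame(rows)


def hotspots_to_pdb(hotspots: list[Hotspot], path: str) -> None:
    """One HETATM pseudo-atom per voxel center, hotspots as residues."""
    with open(path, "w") as fh:
        serial = 1
        for k, h in enumerate(hotspots, start=1):
            for x, y, z in h.voxel_centers():
                fh.write(
                    f"HETATM{serial % 100000:5d}  C   HOT {'H'}{k % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C\n")
                serial += 1
        fh.write("END\n")
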