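"""Mapping residue-level predictor scores onto hotspots for head-to-head comparison.

Residue-level cryptic-site predictors (e.g. CryptoSite, PocketMiner) score
individual residues. To compare them with hotspot-level ranking, each
surface-contacting hotspot receives the mean score of all residues having a
heavy atom within a contact cutoff of any hotspot voxel center. A hotspot
counts as surface-contacting when strictly more than a set fraction of its
voxel centers lie within the cutoff of any protein heavy atom. Recommended
classification thresholds: 10.0 for CryptoSite, 0.7 for PocketMiner,
compared with ``score >= threshold``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .hotspots import Hotspot
from .structure import Structure

__all__ = [
    "ResidueScoreTable", "MappingParams", "METHOD_THRESHOLDS",
    "surface_contact", "map_scores", "classify_external", "map_all_hotspots",
]

#: Recommended decision thresholds of the supported external methods.
METHOD_THRESHOLDS: dict[str, float] = {
    "cryptosite": 10.0,
    "pocketminer": 0.7,
}


@dataclass
class ResidueScoreTable:
    """Per-residue scores of one external predictor."""

    scores: dict[tuple[str, str], float]      # (chain_id, res_id) -> score
    method: str
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.threshold is None:
            key = self.method.lower()
            if key not in METHOD_THRESHOLDS:
                raise ValueError(
                    f"no default threshold for method {self.method!r}; pass one")
            self.threshold = METHOD_THRESHOLDS[key]

    @classmethod
    def from_csv(cls, path: str, method: str,
                 threshold: float | None = None) -> "ResidueScoreTable":
        """CSV with columns chain_id, res_id (or resnum), score."""
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        chain = cols.get("chain_id") or cols.get("chain")
        res = cols.get("res_id") or cols.get("resnum") or cols.get("residue_number")
        score = cols.get("score")
        if not (chain and res and score):
            raise ValueError(f"{path}: need chain, residue and score columns")
        scores: dict[tuple[str, str], float] = {}
        for _, row in df.iterrows():
            key = (str(row[chain]), str(row[res]))
            if key in scores and scores[key] != float(row[score]):
                raise ValueError(f"{path}: conflicting scores for residue {key}")
            scores[key] = float(row[score])
        return cls(scores=scores, method=method, threshold=threshold)


@dataclass(frozen=True)
class MappingParams:
    """Contact rule: > 80% of voxel centers within 5 Å of a protein atom."""

    contact_cutoff: float = 5.0
    contact_fraction: float = 0.80

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if not 0 < self.contact_fraction <= 1:
            raise ValueError("contact_fraction must be in (0, 1]")


def surface_contact(hotspot: Hotspot, structure: Structure,
                    params: MappingParams = MappingParams()) -> bool:
    """True iff strictly more than ``contact_fraction`` of voxel centers lie
    within ``contact_cutoff`` of any protein heavy atom."""
    centers = hotspot.voxel_centers()
    tree = cKDTree(structure.protein().heavy_coords())
    d, _ = tree.query(centers, k=1)
    return float(np.mean(d <= params.contact_cutoff)) > params.contact_fraction


def map_scores(hotspot: Hotspot, structure: Structure, table: ResidueScoreTable,
               params: MappingParams = MappingParams()) -> float | None:
    """Mean external score over residues within the contact cutoff.

    Hotspots failing the surface-contact rule get ``None`` (missing score);
    likewise when no scored residue lies in range.
    """
    if not surface_contact(hotspot, structure, params):
        return None
    centers = hotspot.voxel_centers()
    prot = structure.protein()
    tree = cKDTree(centers)
    values = []
    for key, idx in prot.residue_atom_indices(heavy_only=True).items():
        if key not in table.scores:
            continue
        d, _ = tree.query(prot.coords[idx], k=1)
        if np.any(d <= params.contact_cutoff):
            values.append(table.scores[key])
    if not values:
        warnings.warn(f"hotspot {hotspot.id}: no scored residues within "
                      f"{params.contact_cutoff} Å", stacklevel=2)
        return None
    return float(np.mean(values))


def classify_external(score: float | None, threshold: float) -> bool | None:
    """Positive iff score ≥ threshold; missing scores stay missing."""
    if score is None:
        return None
    return score >= threshold


def map_all_hotspots(hotspots: list[Hotspot], structure: Structure,
                     table: ResidueScoreTable,
                     params: MappingParams = MappingParams()) -> pd.DataFrame:
    """Score every hotspot with one external method.

    Returns a table with the mapped score, the thresholded prediction and a
    ranking score where missing (non-contacting) hotspots sink to −inf so
    they rank last while staying out of classification metrics.
    """
    rows = []
    for h in hotspots:
        score = map_scores(h, structure, table, params)
        rows.append({
            "hotspot_id": h.id,
            "method": table.method,
            "score": np.nan if score is None else score,
            "predicted_positive": classify_external(score, table.threshold),
            "ranking_score": -np.inf if score is None else score,
            "label": h.label,
        })
    return pd.DataFrame(rows)
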