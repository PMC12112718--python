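"""Protein structures, apo/holo superposition and steric-clash cryptic-site definition.

A cryptic site is operationalised here the way it is defined for apo/holo
pairs: superpose the holo structure onto the apo structure, carry the holo
ligand into the apo frame, and flag every apo residue with a heavy atom
strictly closer than a cutoff (default 2.5 Å) to any ligand heavy atom.
Those clashing residues *are* the cryptic site; downstream modules label
probe hotspots against them.

All distance criteria operate on heavy atoms only; waters and monoatomic
ions are dropped when a file is read.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .exceptions import (
    CorrespondenceError,
    EmptyStructureError,
    InvalidLigandError,
    LigandNotFoundError,
    StructureFormatError,
)

__all__ = [
    "Structure",
    "LigandPose",
    "SuperpositionResult",
    "CrypticSiteDefinition",
    "read_structure",
    "superpose",
    "transfer_ligand",
    "detect_clashes",
    "detect_cryptic_site",
    "write_pdb",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "SOL", "TIP3", "TIP4", "SPC"}
_ION_NAMES = {
    "NA", "CL", "K", "MG", "ZN", "MN", "FE", "CA", "CD", "NI", "CU",
    "CO", "BR", "IOD", "CS", "LI", "SR", "BA", "F", "RB", "HG",
}


@dataclass
class Structure:
    """Atom table for one model of a structure.

    Residues are keyed by ``(chain_id, res_id)`` where ``res_id`` is the
    residue sequence number with any insertion code concatenated
    (e.g. ``"52"`` or ``"52A"``), which makes residue identity unambiguous.
    """

    id: str
    atom_ids: np.ndarray          # (N,) int
    atom_names: np.ndarray        # (N,) str
    elements: np.ndarray          # (N,) str, upper-case symbol
    res_ids: np.ndarray           # (N,) str
    res_names: np.ndarray         # (N,) str
    chain_ids: np.ndarray         # (N,) str
    coords: np.ndarray            # (N, 3) float, Å
    is_het: np.ndarray            # (N,) bool, HETATM record

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not np.isfinite(self.coords).all():
            raise StructureFormatError(f"{self.id}: non-finite coordinates")
        if len(np.unique(self.atom_ids)) != len(self.atom_ids):
            raise StructureFormatError(f"{self.id}: duplicate atom ids")

    def __len__(self) -> int:
        return len(self.atom_ids)

    @property
    def is_heavy(self) -> np.ndarray:
        return ~np.isin(self.elements, ("H", "D"))

    def subset(self, mask: np.ndarray, sid: str | None = None) -> "Structure":
        return Structure(
            id=sid or self.id,
            atom_ids=self.atom_ids[mask],
            atom_names=self.atom_names[mask],
            elements=self.elements[mask],
            res_ids=self.res_ids[mask],
            res_names=self.res_names[mask],
            chain_ids=self.chain_ids[mask],
            coords=self.coords[mask],
            is_het=self.is_het[mask],
        )

    def heavy(self) -> "Structure":
        return self.subset(self.is_heavy)

    def protein(self) -> "Structure":
        """Non-HETATM part of the structure."""
        return self.subset(~self.is_het)

    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.is_heavy]

    def ca_index(self) -> dict[tuple[str, str], int]:
        """Map (chain_id, res_id) -> index of the Cα atom."""
        out: dict[tuple[str, str], int] = {}
        for i in np.flatnonzero((self.atom_names == "CA") & ~self.is_het):
            out.setdefault((self.chain_ids[i], self.res_ids[i]), int(i))
        return out

    def residue_keys(self) -> list[tuple[str, str, str]]:
        """Unique (chain_id, res_id, res_name) triples in atom order."""
        seen: dict[tuple[str, str, str], None] = {}
        for c, r, n in zip(self.chain_ids, self.res_ids, self.res_names):
            seen.setdefault((str(c), str(r), str(n)), None)
        return list(seen)

    def residue_atom_indices(self, heavy_only: bool = True) -> dict[tuple[str, str], np.ndarray]:
        """Map (chain_id, res_id) -> atom indices, heavy atoms only by default."""
        mask = self.is_heavy if heavy_only else np.ones(len(self), bool)
        groups: dict[tuple[str, str], list[int]] = {}
        for i in np.flatnonzero(mask):
            groups.setdefault((self.chain_ids[i], self.res_ids[i]), []).append(int(i))
        return {k: np.asarray(v, dtype=int) for k, v in groups.items()}

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        out = self.subset(np.ones(len(self), bool))
        out.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return out


@dataclass
class LigandPose:
    """Heavy atoms of a ligand, usually expressed in the apo frame."""

    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    source_structure: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.coords) == 0:
            raise InvalidLigandError("ligand pose has no heavy atoms")
        if not np.isfinite(self.coords).all():
            raise InvalidLigandError("ligand pose has non-finite coordinates")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LigandPose":
        return LigandPose(
            atom_names=self.atom_names.copy(),
            elements=self.elements.copy(),
            coords=self.coords @ np.asarray(rotation).T + np.asarray(translation),
            source_structure=self.source_structure,
        )


@dataclass
class SuperpositionResult:
    """Least-squares rigid transform mapping mobile onto reference coordinates."""

    rotation: np.ndarray      # (3, 3) proper rotation
    translation: np.ndarray   # (3,)
    rmsd: float               # post-fit RMSD over the matched atoms, Å
    n_atoms_used: int

    def __post_init__(self) -> None:
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-6:
            raise ValueError(f"rotation determinant {det} is not +1")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "SuperpositionResult":
        return cls(np.eye(3), np.zeros(3), 0.0, 0)


@dataclass
class CrypticSiteDefinition:
    """Clash-based definition of a cryptic site in the apo frame."""

    clash_residues: set[tuple[str, str, str]]   # (chain_id, res_id, res_name)
    ligand: LigandPose
    clash_cutoff: float = 2.5

    def __post_init__(self) -> None:
        if self.clash_cutoff <= 0:
            raise ValueError("clash_cutoff must be positive")

    @property
    def residue_ids(self) -> set[tuple[str, str]]:
        return {(c, r) for c, r, _ in self.clash_residues}


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per atom name: highest occupancy, ties broken toward altloc 'A'."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in residue:
        by_name.setdefault(atom.name, []).append(atom)
    kept = []
    for atoms in by_name.values():
        if len(atoms) == 1:
            kept.append(atoms[0])
        else:
            # altloc '' and 'A' rank ahead of later letters at equal occupancy
            order = {"": 0, "A": 0}
            atoms.sort(key=lambda a: (-a.occ, order.get(a.altloc, 1), a.altloc))
            kept.append(atoms[0])
    kept.sort(key=lambda a: a.serial)
    return kept


def read_structure(path: str, model_index: int | None = None,
                   drop_solvent: bool = True) -> Structure:
    """Read one model of a PDB (or mmCIF-free PDB-like) file into a Structure.

    Parameters
    ----------
    path : str
        Path to the coordinate file.
    model_index : int, optional
        1-based MODEL number to read; by default the first model.
    drop_solvent : bool
        Drop waters and monoatomic ions (the default for all pipeline uses).
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    if model_index is None:
        model = st[0]
    else:
        model = None
        for m in st:
            if m.num == model_index:
                model = m
                break
        if model is None:
            if 1 <= model_index <= len(st):
                model = st[model_index - 1]
            else:
                raise EmptyStructureError(f"{path}: no MODEL {model_index}")

    rows: list[tuple] = []
    for chain in model:
        for residue in chain:
            rname = residue.name.strip().upper()
            is_het = residue.het_flag == "H"
            if drop_solvent and (rname in _WATER_NAMES or rname in _ION_NAMES):
                continue
            icode = residue.seqid.icode.strip()
            res_id = f"{residue.seqid.num}{icode}"
            for atom in _resolve_altlocs(residue):
                rows.append((
                    atom.serial, atom.name, atom.element.name.upper(),
                    res_id, rname, chain.name, atom.pos.x, atom.pos.y,
                    atom.pos.z, is_het,
                ))
    if not rows:
        raise EmptyStructureError(f"{path}: model contains no atoms after filtering")

    n = len(rows)
    ids = np.empty(n, dtype=int)
    names = np.empty(n, dtype=object)
    elements = np.empty(n, dtype=object)
    res_ids = np.empty(n, dtype=object)
    res_names = np.empty(n, dtype=object)
    chains = np.empty(n, dtype=object)
    coords = np.empty((n, 3), dtype=float)
    het = np.empty(n, dtype=bool)
    for i, row in enumerate(rows):
        ids[i], names[i], elements[i], res_ids[i], res_names[i], chains[i] = row[:6]
        coords[i] = row[6:9]
        het[i] = row[9]
    # files written without serials can repeat 0; renumber then
    if len(np.unique(ids)) != n:
        ids = np.arange(1, n + 1)
    sid = str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return Structure(sid, ids, names, elements, res_ids, res_names, chains, coords, het)


def _kabsch(mobile_pts: np.ndarray, ref_pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares proper rotation + translation mapping mobile onto ref."""
    pm = mobile_pts.mean(axis=0)
    pr = ref_pts.mean(axis=0)
    h = (mobile_pts - pm).T @ (ref_pts - pr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = pr - rot @ pm
    moved = mobile_pts @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_pts) ** 2, axis=1))))
    return rot, trans, rmsd


def superpose(mobile: Structure, reference: Structure,
              selection: str = "ca") -> SuperpositionResult:
    """Rigid-body (Kabsch) superposition of ``mobile`` onto ``reference``.

    ``selection='ca'`` matches Cα atoms of residues shared by
    (chain_id, res_id); ``selection='heavy'`` matches heavy atoms shared by
    (chain_id, res_id, atom_name). At least 3 pairs are required.
    """
    if selection == "ca":
        im = mobile.ca_index()
        ir = reference.ca_index()
        keys = [k for k in im if k in ir]
        mob_idx = [im[k] for k in keys]
        ref_idx = [ir[k] for k in keys]
    elif selection == "heavy":
        def heavy_index(s: Structure) -> dict[tuple, int]:
            out: dict[tuple, int] = {}
            for i in np.flatnonzero(s.is_heavy & ~s.is_het):
                out.setdefault((s.chain_ids[i], s.res_ids[i], s.atom_names[i]), int(i))
            return out
        im = heavy_index(mobile)
        ir = heavy_index(reference)
        keys = [k for k in im if k in ir]
        mob_idx = [im[k] for k in keys]
        ref_idx = [ir[k] for k in keys]
    else:
        raise ValueError(f"unknown selection {selection!r}")

    if len(keys) < 3:
        raise CorrespondenceError(
            f"only {len(keys)} matched atom pairs; at least 3 required")
    rot, trans, rmsd = _kabsch(mobile.coords[mob_idx], reference.coords[ref_idx])
    return SuperpositionResult(rot, trans, rmsd, len(keys))


def transfer_ligand(holo: Structure, ligand_resname: str,
                    transform: SuperpositionResult) -> LigandPose:
    """Express the holo ligand's heavy atoms in the apo frame via ``transform``."""
    mask = holo.is_het & (holo.res_names == ligand_resname.upper()) & holo.is_heavy
    if not mask.any():
        raise LigandNotFoundError(
            f"residue name {ligand_resname!r} not found among HETATM records of {holo.id}")
    return LigandPose(
        atom_names=holo.atom_names[mask].copy(),
        elements=holo.elements[mask].copy(),
        coords=transform.apply(holo.coords[mask]),
        source_structure=holo.id,
    )


def guess_ligand_resname(holo: Structure) -> str:
    """Largest HETATM residue by heavy-atom count; a pragmatic default."""
    counts: dict[str, int] = {}
    for i in np.flatnonzero(holo.is_het & holo.is_heavy):
        counts[holo.res_names[i]] = counts.get(holo.res_names[i], 0) + 1
    if not counts:
        raise LigandNotFoundError(f"{holo.id}: no HETATM residues")
    return max(counts, key=lambda k: (counts[k], k))


def detect_clashes(apo: Structure, ligand: LigandPose,
                   cutoff: float = 2.5) -> CrypticSiteDefinition:
    """Apo residues with a heavy atom strictly closer than ``cutoff`` to the ligand.

    Distances are Euclidean, heavy atoms only on both sides; the ligand must
    already be in the apo coordinate frame.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tree = cKDTree(ligand.coords)
    prot = apo.protein()
    mask = prot.is_heavy
    idx = np.flatnonzero(mask)
    dmin, _ = tree.query(prot.coords[idx], k=1)
    clashing: set[tuple[str, str, str]] = set()
    for i, d in zip(idx, dmin):
        if d < cutoff:
            clashing.add((str(prot.chain_ids[i]), str(prot.res_ids[i]),
                          str(prot.res_names[i])))
    return CrypticSiteDefinition(clash_residues=clashing, ligand=ligand,
                                 clash_cutoff=cutoff)


def detect_cryptic_site(apo_path: str, holo_path: str,
                        ligand_resname: str | None = None,
                        cutoff: float = 2.5,
                        selection: str = "ca") -> CrypticSiteDefinition:
    """End-to-end apo/holo clash workflow on two coordinate files.

    Reads both structures, superposes the holo onto the apo (Cα by default),
    transfers the ligand (auto-detected as the largest HETATM residue when
    not named) and reports the clashing residues at ``cutoff``.
    """
    apo = read_structure(apo_path)
    holo = read_structure(holo_path)
    if ligand_resname is None:
        ligand_resname = guess_ligand_resname(holo)
    fit = superpose(holo, apo, selection=selection)
    ligand = transfer_ligand(holo, ligand_resname, fit)
    return detect_clashes(apo, ligand, cutoff=cutoff)


def write_pdb(structure: Structure, path: str) -> None:
    """Write a Structure as a minimal single-model PDB file."""
    with open(path, "w") as fh:
        fh.write(_pdb_lines(structure))
        fh.write("END\n")


def _split_res_id(res_id: str) -> tuple[int, str]:
    num = res_id
    icode = " "
    if res_id and res_id[-1] in string.ascii_uppercase:
        num, icode = res_id[:-1], res_id[-1]
    return int(num), icode


def _pdb_lines(s: Structure) -> str:
    lines = []
    for i in range(len(s)):
        rec = "HETATM" if s.is_het[i] else "ATOM  "
        name = s.atom_names[i]
        name_f = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
        num, icode = _split_res_id(s.res_ids[i])
        x, y, z = s.coords[i]
        lines.append(
            f"{rec}{int(s.atom_ids[i]) % 100000:5d} {name_f}{'':1s}{s.res_names[i]:>3s} "
            f"{s.chain_ids[i][:1]:1s}{num:4d}{icode:1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{s.elements[i]:>2s}\n")
    return "".join(lines)


def write_multimodel_pdb(structure: Structure, frames: np.ndarray, path: str) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame)."""
    frames = np.asarray(frames, float)
    base = structure
    with open(path, "w") as fh:
        for m, coords in enumerate(frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            shifted = base.subset(np.ones(len(base), bool))
            shifted.coords = coords
            fh.write(_pdb_lines(shifted))
            fh.write("ENDMDL\n")
        fh.write("END\n")
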