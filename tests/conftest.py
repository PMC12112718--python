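"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from cryptohot.structure import Structure, LigandPose


def build_structure(residues, sid="fixture", het_resnames=()):
    """Construct a Structure from [(chain, res_id, res_name, [(atom, elem, xyz)])]."""
    rows = []
    aid = 1
    for chain, rid, rname, atoms in residues:
        for name, elem, xyz in atoms:
            rows.append((aid, name, elem, str(rid), rname, chain, xyz,
                         rname in het_resnames))
            aid += 1
    n = len(rows)
    return Structure(
        id=sid,
        atom_ids=np.array([r[0] for r in rows]),
        atom_names=np.array([r[1] for r in rows], object),
        elements=np.array([r[2] for r in rows], object),
        res_ids=np.array([r[3] for r in rows], object),
        res_names=np.array([r[4] for r in rows], object),
        chain_ids=np.array([r[5] for r in rows], object),
        coords=np.array([r[6] for r in rows], float),
        is_het=np.array([r[7] for r in rows], bool),
    )


def single_atom_residues(points, resname="GLY", element="C", chain="A"):
    """One-atom residues at the given coordinates."""
    return build_structure(
        [(chain, i + 1, resname, [("CA", element, tuple(p))])
         for i, p in enumerate(points)])


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def ligand_from_points(points):
    pts = np.asarray(points, float).reshape(-1, 3)
    return LigandPose(
        atom_names=np.array([f"C{i+1}" for i in range(len(pts))], object),
        elements=np.array(["C"] * len(pts), object),
        coords=pts, source_structure="fixture")


def brute_force_clashes(structure, ligand_coords, cutoff):
    """O(n·m) all-pairs reference for clash detection."""
    prot = structure.protein()
    out = set()
    for i in np.flatnonzero(prot.is_heavy):
        for lc in ligand_coords:
            if np.linalg.norm(prot.coords[i] - lc) < cutoff:
                out.add((str(prot.chain_ids[i]), str(prot.res_ids[i]),
                         str(prot.res_names[i])))
                break
    return out


def brute_force_dbscan(points, eps, min_samples):
    """Density-reachability DBSCAN reference; returns label per point (-1 noise)."""
    pts = np.asarray(points, float)
    n = len(pts)
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    neighbors = [set(np.flatnonzero(d[i] <= eps)) for i in range(n)]
    core = [len(nb) >= min_samples for nb in neighbors]
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cid
                    stack.append(k)
        cid += 1
    return labels


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240612)


# Expensive shared computations for the acceptance checks --------------------

@pytest.fixture(scope="session")
def adaboost_delta3_loocv():
    """AdaBoost LOOCV on the 60/125 synthetic table at separation 3."""
    from cryptohot.mlrank import ModelSpec, loocv
    from cryptohot.synth import SyntheticFeatureSpec, make_feature_dataset
    ds = make_feature_dataset(SyntheticFeatureSpec(delta=3.0, seed=11))
    metrics, probs = loocv(ds, ModelSpec("adaboost", seed=0))
    return ds, metrics, probs
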