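"""Surface-patch features: SASA, shape descriptors, RMSF, probe features."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_structure, single_atom_residues
from cryptohot.density import (Frame, GFEGrid, ProbeSpec, TrajectoryBundle,
                               VoxelGrid)
from cryptohot.features import (PatchParams, SurfacePatch, assemble_features,
                                compute_charge_density, compute_compactness,
                                compute_convexity, compute_hydrophobicity,
                                compute_protrusion, compute_rmsf, compute_size,
                                define_patch, hotspot_probe_features,
                                _per_atom_sasa)
from cryptohot.hotspots import Hotspot
from cryptohot.synth import make_toy_protein, toy_trajectory

PROBE = ProbeSpec("benzene", 6)


def make_hotspot(voxels, lattice=((0.0, 0.0, 0.0), 1.0, (40, 40, 40))):
    return Hotspot(id="HS01", voxels=frozenset(map(tuple, voxels)),
                   contributing_probes=frozenset({"benzene"}),
                   per_probe_occupancy={"benzene": 1.0}, lattice=lattice)


def patch_of(structure, res_ids):
    return SurfacePatch(residues=frozenset(("A", str(r)) for r in res_ids),
                        hotspot_id="HS01")


class TestDefinePatch:
    def test_voxel_on_calpha_included(self):
        s = single_atom_residues([(0.5, 0.5, 0.5), (30.0, 0, 0)])
        h = make_hotspot([(0, 0, 0)])
        patch = define_patch(h, s)
        assert patch.residues == {("A", "1")}

    def test_boundary_exclusion(self):
        s = single_atom_residues([(0.5 + 4.6, 0.5, 0.5)])
        h = make_hotspot([(0, 0, 0)])
        with pytest.warns(UserWarning):
            patch = define_patch(h, s)
        assert len(patch) == 0

    def test_matches_brute_force_membership(self, rng):
        pts = rng.uniform(0, 20, size=(40, 3))
        s = single_atom_residues(pts)
        vox = {tuple(v) for v in rng.integers(0, 20, size=(25, 3))}
        h = make_hotspot(vox, lattice=((0.0, 0.0, 0.0), 1.0, (20, 20, 20)))
        got = define_patch(h, s).residues
        centers = np.array(sorted(vox), float) + 0.5
        expected = {("A", str(i + 1)) for i, p in enumerate(pts)
                    if min(np.linalg.norm(centers - p, axis=1)) <= 4.5}
        assert got == expected


class TestSize:
    def test_single_residue_matches_mdtraj_within_2_percent(self):
        import mdtraj as md
        import mdtraj.core.element as elem

        s = make_toy_protein(6, "helix")
        patch = patch_of(s, range(1, 7))
        size = compute_size(patch, s, point_number=960)

        top = md.Topology()
        chain = top.add_chain()
        prot = s.protein().heavy()
        last = None
        for i in range(len(prot)):
            key = (prot.chain_ids[i], prot.res_ids[i])
            if key != last:
                res = top.add_residue(prot.res_names[i], chain)
                last = key
            top.add_atom(prot.atom_names[i],
                         elem.get_by_symbol(prot.elements[i].capitalize()), res)
        traj = md.Trajectory(prot.coords[None] / 10.0, top)
        ref = md.shrake_rupley(traj, probe_radius=0.14,
                               n_sphere_points=960)[0].sum() * 100
        assert size == pytest.approx(ref, rel=0.02)

    def test_static_trajectory_average_equals_single_frame(self):
        s = make_toy_protein(5)
        patch = patch_of(s, range(1, 6))
        frames = np.repeat(s.protein().heavy().coords[None], 4, axis=0)
        assert compute_size(patch, s, frames=frames) == \
            pytest.approx(compute_size(patch, s))

    def test_buried_residue_contributes_nearly_nothing(self, rng):
        # central atom enclosed by a tight full shell of blockers
        shell = []
        golden = np.pi * (3 - np.sqrt(5))
        for i in range(200):
            z = 1 - 2 * (i + 0.5) / 200
            r = np.sqrt(1 - z * z)
            th = golden * i
            shell.append((3.0 * r * np.cos(th), 3.0 * r * np.sin(th), 3.0 * z))
        pts = [(0.0, 0.0, 0.0)] + shell
        s = single_atom_residues(pts)
        buried = compute_size(patch_of(s, [1]), s)
        exposed = compute_size(
            patch_of(single_atom_residues([(0.0, 0.0, 0.0)]), [1]),
            single_atom_residues([(0.0, 0.0, 0.0)]))
        assert buried < 0.02 * exposed

    def test_empty_patch_is_zero(self):
        s = make_toy_protein(5)
        assert compute_size(SurfacePatch(frozenset(), "HS01"), s) == 0.0


class TestCompactness:
    def test_two_single_atom_residues(self):
        s = single_atom_residues([(0, 0, 0), (5, 0, 0)])
        assert compute_compactness(patch_of(s, [1, 2]), s) == pytest.approx(5.0)

    def test_three_residues_mean_of_min_distances(self):
        s = single_atom_residues([(0, 0, 0), (3, 0, 0), (3, 4, 0)])
        # pairwise min distances: 3, 5, 4 -> mean 4
        assert compute_compactness(patch_of(s, [1, 2, 3]), s) == pytest.approx(4.0)

    def test_matches_brute_force(self, rng):
        s = make_toy_protein(8)
        patch = patch_of(s, range(1, 9))
        got = compute_compactness(patch, s)
        groups = s.protein().residue_atom_indices()
        keys = sorted(patch.residues)
        ds = []
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                ci = s.coords[groups[keys[i]]]
                cj = s.coords[groups[keys[j]]]
                ds.append(min(np.linalg.norm(a - b)
                              for a in ci for b in cj))
        assert got == pytest.approx(np.mean(ds))


class TestProtrusion:
    def test_isolated_residue_protrudes(self):
        s = single_atom_residues([(0, 0, 0)])
        assert compute_protrusion(patch_of(s, [1]), s) == 1.0

    def test_dense_shell_suppresses_protrusion(self):
        pts = [(0.0, 0.0, 0.0)]
        grid = np.arange(-12, 13, 1.5)
        for x in grid:
            for y in grid:
                for z in grid:
                    r = np.sqrt(x * x + y * y + z * z)
                    if 8 < r <= 12:
                        pts.append((x, y, z))
        s = single_atom_residues(pts)
        assert compute_protrusion(patch_of(s, [1]), s) == 0.0

    def test_matches_brute_force_shell_count(self, rng):
        pts = rng.uniform(0, 25, size=(150, 3))
        s = single_atom_residues(pts)
        patch = patch_of(s, range(1, 11))
        params = PatchParams()
        got = compute_protrusion(patch, s, params)
        frac = 0
        for i in range(10):
            c = pts[i]
            d = np.linalg.norm(pts - c, axis=1)
            n = int(np.sum((d > 8.0) & (d <= 12.0)))
            frac += n < 120
        assert got == pytest.approx(frac / 10)


class TestConvexity:
    def test_hand_built_ratio(self):
        s = build_structure([
            ("A", 1, "GLY", [("CA", "C", (0.0, 0.0, 0.0)),
                             ("CB", "C", (-2.0, 0.0, 0.0))]),
            ("A", 2, "GLY", [("CA", "C", (4.0, 0.0, 0.0)),
                             ("CB", "C", (6.0, 0.0, 0.0))]),
        ])
        # centroids -1 and 5 (distance 6), closest exposed atoms 0 and 4
        assert compute_convexity(patch_of(s, [1, 2]), s) == \
            pytest.approx(4.0 / 6.0, abs=1e-6)

    def test_single_atom_residues_give_unit_ratio(self):
        s = single_atom_residues([(0, 0, 0), (5, 0, 0)])
        assert compute_convexity(patch_of(s, [1, 2]), s) == pytest.approx(1.0)

    def test_concave_pocket_exceeds_convex_surface(self):
        """Inside a pocket the mutually visible (exposed) atoms sit on the
        rim, farther apart than the residue centroids; on a convex bulge the
        closest exposed atoms track the centroids."""
        # convex: two fully exposed residues
        conv = build_structure([
            ("A", 1, "GLY", [("CA", "C", (0.0, 0.0, 0.0)),
                             ("CB", "C", (0.0, 0.0, 2.0))]),
            ("A", 2, "GLY", [("CA", "C", (6.0, 0.0, 0.0)),
                             ("CB", "C", (6.0, 0.0, 2.0))]),
        ])
        convexity_conv = compute_convexity(patch_of(conv, [1, 2]), conv)
        # concave: the closest atoms (z=0) are buried by a blocker slab,
        # leaving only the rim atoms (z=2) exposed
        blockers = [("BLK", "C", (x, y, -0.4))
                    for x in np.arange(-2, 8.5, 0.8)
                    for y in np.arange(-2.4, 2.5, 0.8)]
        blockers += [("BLK", "C", (x, y, 0.6))
                     for x in np.arange(1.2, 5.2, 0.8)
                     for y in np.arange(-2.4, 2.5, 0.8)]
        conc = build_structure([
            ("A", 1, "GLY", [("CA", "C", (0.0, 0.0, 0.0)),
                             ("CB", "C", (-1.0, 0.0, 2.0))]),
            ("A", 2, "GLY", [("CA", "C", (6.0, 0.0, 0.0)),
                             ("CB", "C", (7.0, 0.0, 2.0))]),
            ("B", 99, "GLY", [(f"X{i}", "C", xyz)
                              for i, (_, _, xyz) in enumerate(blockers)]),
        ])
        convexity_conc = compute_convexity(patch_of(conc, [1, 2]), conc)
        assert convexity_conv < convexity_conc

    def test_lone_residue_imputed(self):
        s = single_atom_residues([(0, 0, 0)])
        with pytest.warns(UserWarning):
            assert compute_convexity(patch_of(s, [1]), s) == 0.0


class TestPhysicochemical:
    def test_all_ile(self):
        s = single_atom_residues([(0, 0, 0), (5, 0, 0)], resname="ILE")
        assert compute_hydrophobicity(patch_of(s, [1, 2]), s) == 4.5

    def test_ile_plus_arg_cancels(self):
        s = build_structure([
            ("A", 1, "ILE", [("CA", "C", (0, 0, 0))]),
            ("A", 2, "ARG", [("CA", "C", (5, 0, 0))]),
        ])
        assert compute_hydrophobicity(patch_of(s, [1, 2]), s) == 0.0

    def test_unknown_residue_warns_and_skips(self):
        s = build_structure([
            ("A", 1, "ILE", [("CA", "C", (0, 0, 0))]),
            ("A", 2, "XXX", [("CA", "C", (5, 0, 0))]),
        ])
        with pytest.warns(UserWarning):
            assert compute_hydrophobicity(patch_of(s, [1, 2]), s) == 4.5

    def test_random_composition_matches_hand_mean(self, rng):
        from cryptohot.features import KYTE_DOOLITTLE
        names = rng.choice(list(KYTE_DOOLITTLE), size=12)
        s = build_structure([("A", i + 1, n, [("CA", "C", (6.0 * i, 0, 0))])
                             for i, n in enumerate(names)])
        got = compute_hydrophobicity(patch_of(s, range(1, 13)), s)
        assert got == pytest.approx(np.mean([KYTE_DOOLITTLE[n] for n in names]))

    def test_charge_density_neutral(self):
        s = single_atom_residues([(0, 0, 0)], resname="SER")
        assert compute_charge_density(patch_of(s, [1]), s, size=50.0) == 0.0

    def test_charge_density_single_lysine(self):
        s = single_atom_residues([(0, 0, 0)], resname="LYS")
        assert compute_charge_density(patch_of(s, [1]), s, size=100.0) == \
            pytest.approx(0.01)

    def test_charge_density_mixed_histidine_neutral(self):
        s = build_structure([
            ("A", 1, "ARG", [("CA", "C", (0, 0, 0))]),
            ("A", 2, "LYS", [("CA", "C", (5, 0, 0))]),
            ("A", 3, "ASP", [("CA", "C", (10, 0, 0))]),
            ("A", 4, "HIS", [("CA", "C", (15, 0, 0))]),
        ])
        got = compute_charge_density(patch_of(s, [1, 2, 3, 4]), s, size=10.0)
        assert got == pytest.approx(0.1)   # (+2 - 1 + 0) / 10

    def test_zero_size_imputed(self):
        s = single_atom_residues([(0, 0, 0)], resname="LYS")
        with pytest.warns(UserWarning):
            assert compute_charge_density(patch_of(s, [1]), s, size=0.0) == 0.0


class TestRMSF:
    def test_static_trajectory_is_zero(self):
        s = make_toy_protein(20)
        frames = np.repeat(s.protein().heavy().coords[None], 5, axis=0)
        rmsf = compute_rmsf(s, frames)
        np.testing.assert_allclose(rmsf, 0.0, atol=1e-10)

    def test_alternating_calpha_closed_form(self):
        s = make_toy_protein(100)
        base = s.protein().heavy().coords
        ca_rows = np.flatnonzero(s.protein().heavy().atom_names == "CA")
        target = ca_rows[10]
        d = 0.8
        frames = np.repeat(base[None], 6, axis=0)
        frames[::2, target, 0] += d
        frames[1::2, target, 0] -= d
        rmsf = compute_rmsf(s, frames, align=False)
        assert rmsf[10] == pytest.approx(d, rel=1e-9)
        assert np.median(rmsf) < 1e-12
        # with alignment the fit soaks up a few percent but no more
        assert compute_rmsf(s, frames)[10] == pytest.approx(d, rel=0.05)

    def test_rigid_translation_aligned_away(self):
        s = make_toy_protein(20)
        base = s.protein().heavy().coords
        frames = np.stack([base + np.array([t, 2 * t, -t])
                           for t in range(6)])
        rmsf = compute_rmsf(s, frames)
        np.testing.assert_allclose(rmsf, 0.0, atol=1e-8)

    def test_patch_mean(self):
        s = make_toy_protein(30)
        frames = toy_trajectory(s, n_frames=40, jitter_sd=0.3, seed=5)
        full = compute_rmsf(s, frames)
        patch = patch_of(s, [1, 2, 3])
        got = compute_rmsf(s, frames, patch)
        assert got == pytest.approx(np.mean(full[:3]))

    def test_fewer_than_two_frames_rejected(self):
        s = make_toy_protein(5)
        with pytest.raises(ValueError):
            compute_rmsf(s, s.protein().heavy().coords[None])


class TestProbeFeatures:
    def _setup(self, occupancy=0.01):
        grid = VoxelGrid(origin=np.zeros(3), spacing=1.0, shape=(10, 10, 10),
                         raw_counts=np.zeros((10, 10, 10)), probe=PROBE,
                         n_frames=4)
        grid.occupancy = np.full((10, 10, 10), occupancy)
        gfe = GFEGrid(origin=np.zeros(3), spacing=1.0, shape=(10, 10, 10),
                      gfe=np.zeros((10, 10, 10)), probe=PROBE)
        h = make_hotspot([(2, 2, 2), (2, 2, 3), (3, 2, 2)],
                         lattice=((0.0, 0.0, 0.0), 1.0, (10, 10, 10)))
        return grid, gfe, h

    def test_bulk_occupancy_means_zero_gfe(self):
        grid, gfe, h = self._setup()
        g, _ = hotspot_probe_features(h, grid, gfe)
        assert g == 0.0

    def test_one_molecule_inside_every_frame(self):
        grid, gfe, h = self._setup()
        frames = [Frame(probe_coords=np.array([[2.5, 2.5, 2.5]] * 6),
                        protein_coords=np.zeros((1, 3)),
                        molecule_ids=np.zeros(6, int)) for _ in range(4)]
        bundle = TrajectoryBundle(PROBE, [frames])
        _, count = hotspot_probe_features(h, grid, gfe, bundle)
        assert count == 1.0

    def test_molecule_count_matches_brute_force(self, rng):
        grid, gfe, h = self._setup()
        frames = []
        for _ in range(10):
            pts = rng.uniform(0, 10, size=(12, 3))
            frames.append(Frame(probe_coords=pts,
                                protein_coords=np.zeros((1, 3)),
                                molecule_ids=np.repeat(np.arange(2), 6)))
        bundle = TrajectoryBundle(PROBE, [frames], fixed_composition=True)
        _, count = hotspot_probe_features(h, grid, gfe, bundle)
        vox = h.voxels
        expected = []
        for f in frames:
            mols = set()
            for mid, p in zip(f.molecule_ids, f.probe_coords):
                if tuple(np.floor(p).astype(int)) in vox:
                    mols.add(int(mid))
            expected.append(len(mols))
        assert count == pytest.approx(np.mean(expected))

    def test_min_aggregation_option(self):
        grid, gfe, h = self._setup()
        idx = np.array(sorted(h.voxels))
        gfe.gfe[tuple(idx.T)] = [-1.0, 0.5, 2.0]
        g_mean, _ = hotspot_probe_features(h, grid, gfe)
        g_min, _ = hotspot_probe_features(h, grid, gfe, aggregate="min")
        assert g_mean == pytest.approx(0.5)
        assert g_min == -1.0


class TestAssemble:
    def test_three_rows_stable_order(self):
        rows = [{"hotspot_id": f"HS{i}", "protein_id": "P", "size": float(i),
                 "gfe_benzene": 0.1, "label": "unlabeled"} for i in range(3)]
        df = assemble_features(rows)
        assert list(df.columns) == ["hotspot_id", "protein_id", "gfe_benzene",
                                    "size", "label"]
        assert len(df) == 3

    def test_duplicate_ids_rejected(self):
        rows = [{"hotspot_id": "HS1", "protein_id": "P", "size": 1.0},
                {"hotspot_id": "HS1", "protein_id": "P", "size": 2.0}]
        with pytest.raises(ValueError):
            assemble_features(rows)

    def test_missing_values_imputed_and_csv_round_trip(self, tmp_path):
        rows = [{"hotspot_id": "HS1", "protein_id": "P", "size": 1.0,
                 "gfe_benzene": -0.5},
                {"hotspot_id": "HS2", "protein_id": "P", "size": 2.0}]
        df = assemble_features(rows)
        assert df["gfe_benzene"].notna().all()
        path = tmp_path / "feat.csv"
        df.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, df)
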