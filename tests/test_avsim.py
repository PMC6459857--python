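"""Accessible-volume geometry and Shrake–Rupley SASA."""

import numpy as np
import pytest

from mfdlab import avsim


def lone_attachment():
    return avsim.StructureModel.from_arrays(
        np.zeros((1, 3)), radii=[1.7], chains=["A"], res_ids=[1],
        atom_names=["CA"])


DYE = avsim.DyeParams(linker_length=8.0, linker_width=2.0, dye_radii=(3.0,),
                      attachment="A:1:CA")


class TestAccessibleVolume:
    def test_free_space_cloud_is_a_ball(self):
        """No obstructions: the cloud fills the linker-length ball
        (volume within 5% of 4/3·π·L³)."""
        av = avsim.compute_av(lone_attachment(), DYE, grid_spacing=0.6)
        analytic = 4.0 / 3.0 * np.pi * 8.0 ** 3
        assert av.volume == pytest.approx(analytic, rel=0.05)

    def test_half_space_centroid_matches_spherical_cap(self):
        """An atom plane below the attachment leaves a spherical-cap
        cloud whose centroid offset matches the analytic value."""
        xs = np.arange(-12, 12.5, 1.5)
        plane = np.array([[x, y, -3.0] for x in xs for y in xs])
        coords = np.vstack([np.zeros((1, 3)), plane])
        n = len(coords)
        s = avsim.StructureModel.from_arrays(
            coords, radii=np.full(n, 1.5), chains=["A"] * n,
            res_ids=np.arange(1, n + 1), atom_names=["CA"] * n)
        av = avsim.compute_av(s, DYE, grid_spacing=0.5)
        # allowed z >= plane + r_atom + r_dye
        z_min = -3.0 + 1.5 + 3.0
        assert av.points[:, 2].min() >= z_min - 0.26
        L = DYE.linker_length
        z = np.linspace(z_min, L, 2001)
        w = L ** 2 - z ** 2
        z_cap = np.trapezoid(z * w, z) / np.trapezoid(w, z)
        got = np.average(av.points[:, 2], weights=av.weights)
        assert got == pytest.approx(z_cap, rel=0.08)

    def test_grid_refinement_converges(self):
        """Halving the spacing moves the mean dye position < 0.5 Å."""
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, -3.5]])
        s = avsim.StructureModel.from_arrays(
            coords, radii=[1.7, 1.7], chains=["A", "A"], res_ids=[1, 2],
            atom_names=["CA", "CA"])
        a = avsim.compute_av(s, DYE, grid_spacing=1.0).mean_position()
        b = avsim.compute_av(s, DYE, grid_spacing=0.5).mean_position()
        assert np.linalg.norm(a - b) < 0.5

    def test_volume_monotone_under_added_obstructions(self):
        rng = np.random.default_rng(0)
        extra = rng.uniform(-6, 6, (15, 3))
        vols = []
        for k in (0, 5, 15):
            coords = np.vstack([np.zeros((1, 3)), extra[:k]])
            n = len(coords)
            s = avsim.StructureModel.from_arrays(
                coords, radii=np.full(n, 1.7), chains=["A"] * n,
                res_ids=np.arange(1, n + 1), atom_names=["CA"] * n)
            vols.append(avsim.compute_av(s, DYE, grid_spacing=0.8).volume)
        assert vols[0] >= vols[1] >= vols[2]

    def test_buried_attachment_gives_flagged_empty_cloud(self):
        """Attachment enclosed in a tight atom cage: empty cloud."""
        shell = []
        for th in np.linspace(0, np.pi, 10):
            for ph in np.linspace(0, 2 * np.pi, 20, endpoint=False):
                shell.append([3.0 * np.sin(th) * np.cos(ph),
                              3.0 * np.sin(th) * np.sin(ph),
                              3.0 * np.cos(th)])
        coords = np.vstack([np.zeros((1, 3)), shell])
        n = len(coords)
        s = avsim.StructureModel.from_arrays(
            coords, radii=np.full(n, 1.7), chains=["A"] * n,
            res_ids=np.arange(1, n + 1), atom_names=["CA"] * n)
        with pytest.warns(UserWarning, match="buried|allowed"):
            av = avsim.compute_av(s, DYE, grid_spacing=0.8)
        assert av.empty


class TestMeanFretDistance:
    def _cloud(self, center, radius, n, seed):
        rng = np.random.default_rng(seed)
        p = rng.standard_normal((4 * n, 3))
        p = p[np.linalg.norm(p, axis=1) <= 1.0][:n] * radius
        return avsim.AVCloud(np.asarray(center) + p, np.ones(len(p)),
                             np.asarray(center, float), 0.5)

    def test_point_clouds_give_exact_distance(self):
        a = avsim.AVCloud(np.zeros((1, 3)), np.ones(1), np.zeros(3), 0.5)
        b = avsim.AVCloud(np.array([[47.0, 0, 0]]), np.ones(1),
                          np.zeros(3), 0.5)
        res = avsim.mean_fret_distance(a, b, 53.0)
        assert res.rda_e == pytest.approx(47.0, abs=1e-9)
        assert res.r_mp == pytest.approx(47.0, abs=1e-9)

    def test_overlapping_clouds_sane(self):
        a = self._cloud([0, 0, 0], 3.5, 400, 1)
        res = avsim.mean_fret_distance(a, a, 53.0)
        assert 0 < res.rda_e < res.r_mp + 2 * 3.5 + 1

    def test_subsampled_average_matches_brute_force(self):
        """Monte-Carlo pair subsampling agrees with the full
        weighted pair average within 1 Å."""
        a = self._cloud([0, 0, 0], 3.5, 500, 2)
        b = self._cloud([45.0, 0, 0], 3.5, 500, 3)
        # independent brute force over all pairs
        d = np.sqrt(((a.points[:, None, :] - b.points[None, :, :]) ** 2)
                    .sum(-1)).ravel()
        e_full = np.mean(1.0 / (1.0 + (d / 53.0) ** 6))
        brute = 53.0 * (1.0 / e_full - 1.0) ** (1.0 / 6.0)
        sub = avsim.mean_fret_distance(a, b, 53.0, max_pairs=50_000, seed=0)
        assert sub.subsampled
        assert sub.rda_e == pytest.approx(brute, abs=1.0)

    def test_rigid_motion_invariance(self):
        a = self._cloud([0, 0, 0], 3.0, 300, 4)
        b = self._cloud([40.0, 5.0, -3.0], 3.0, 300, 5)
        base = avsim.mean_fret_distance(a, b, 53.0).rda_e
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        shift = np.array([5.0, -2.0, 9.0])
        a2 = avsim.AVCloud(a.points @ R.T + shift, a.weights,
                           a.attachment_point @ R.T + shift, 0.5)
        b2 = avsim.AVCloud(b.points @ R.T + shift, b.weights,
                           b.attachment_point @ R.T + shift, 0.5)
        moved = avsim.mean_fret_distance(a2, b2, 53.0).rda_e
        assert moved == pytest.approx(base, abs=1e-9)


def ring_residue(center=np.zeros(3)):
    """Synthetic 12-heavy-atom tyrosine-like residue (geometry is a
    stand-in built for numerical tests, not a real rotamer)."""
    ring = [[1.4 * np.cos(a), 1.4 * np.sin(a), 0.0]
            for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
    extra = [[2.8, 0.0, 0.0],      # OH
             [-2.0, 0.0, 1.2],     # CB
             [-2.8, 0.8, 2.2],     # CA
             [-4.0, 0.0, 2.6],     # C
             [-4.6, 0.6, 3.5],     # O
             [-2.2, 2.2, 2.6]]     # N
    coords = np.asarray(ring + extra) + center
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2",
             "OH", "CB", "CA", "C", "O", "N"]
    elements = [n[0] for n in names]
    return coords, names, elements


class TestSASA:
    def test_isolated_atom_matches_analytic_sphere(self):
        s = avsim.StructureModel.from_arrays(np.zeros((1, 3)), radii=[1.7])
        got = avsim.shrake_rupley_sasa(s)[0]
        assert got == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=1e-6)

    def test_enclosed_atom_has_zero_area(self):
        shell = []
        for th in np.linspace(0.1, np.pi - 0.1, 12):
            for ph in np.linspace(0, 2 * np.pi, 24, endpoint=False):
                shell.append([2.5 * np.sin(th) * np.cos(ph),
                              2.5 * np.sin(th) * np.sin(ph),
                              2.5 * np.cos(th)])
        shell += [[0, 0, 2.5], [0, 0, -2.5]]
        coords = np.vstack([np.zeros((1, 3)), shell])
        s = avsim.StructureModel.from_arrays(
            coords, radii=np.full(len(coords), 1.7))
        assert avsim.shrake_rupley_sasa(s)[0] == pytest.approx(0.0, abs=1e-9)

    def test_additivity_for_distant_chains(self):
        """Chains far apart give per-chain SASA equal to isolated
        computation."""
        c1, n1, e1 = ring_residue()
        iso = avsim.StructureModel.from_arrays(
            c1, radii=np.full(12, 1.7), atom_names=n1, elements=e1)
        sasa_iso = avsim.shrake_rupley_sasa(iso)
        both = avsim.StructureModel.from_arrays(
            np.vstack([c1, c1 + [500.0, 0, 0]]), radii=np.full(24, 1.7),
            atom_names=n1 * 2, elements=e1 * 2)
        sasa_both = avsim.shrake_rupley_sasa(both)
        assert np.allclose(sasa_both[:12], sasa_iso, atol=1e-6)
        assert np.allclose(sasa_both[12:], sasa_iso, atol=1e-6)

    def test_isolated_residue_at_least_reference_exposure(self):
        """A free residue is at least as exposed as the in-chain
        reference context that normalises relative SASA."""
        coords, names, elements = ring_residue()
        s = avsim.StructureModel.from_arrays(
            coords, radii=np.full(12, 1.7), chains=["A"] * 12,
            res_ids=np.full(12, 1), res_names=["TYR"] * 12,
            atom_names=names, elements=elements)
        pct, flags = avsim.relative_sasa(s, "A", 1)
        assert pct >= 95.0
        assert not flags

    def test_clamped_residue_convergence_and_cross_check(self):
        """Buried-interface residue: doubling the sphere-point density
        changes the value by < 1 percentage point, and an independent
        implementation (biotite) agrees."""
        coords, names, elements = ring_residue()
        xs = np.arange(-8, 8.5, 1.6)
        top = np.array([[x, y, 4.5] for x in xs for y in xs])
        bot = np.array([[x, y, -4.5] for x in xs for y in xs])
        allc = np.vstack([coords, top, bot])
        n = len(allc)
        s = avsim.StructureModel.from_arrays(
            allc, radii=np.full(n, 1.7), chains=["A"] * n,
            res_ids=np.r_[np.full(12, 1), np.arange(2, n - 10)],
            res_names=["TYR"] * 12 + ["GLY"] * (n - 12),
            atom_names=names + ["CA"] * (n - 12),
            elements=elements + ["C"] * (n - 12))
        p1, _ = avsim.relative_sasa(s, "A", 1, n_points=960)
        p2, _ = avsim.relative_sasa(s, "A", 1, n_points=1920)
        assert abs(p1 - p2) < 1.0
        assert p1 < 60.0      # clamp buries the residue substantially

        import biotite.structure as struc
        arr = struc.AtomArray(n)
        arr.coord = allc.astype(np.float32)
        arr.element = np.array(["C"] * n)
        arr.atom_name = s.atom_names
        arr.res_id = s.res_ids
        arr.res_name = s.res_names
        arr.chain_id = s.chains
        ref = struc.sasa(arr, probe_radius=1.4,
                         vdw_radii=np.full(n, 1.7), point_number=1920)
        ref_pct = 100.0 * ref[:12].sum() / avsim.REF_SASA["TYR"]
        assert p2 == pytest.approx(ref_pct, abs=1.0)

    def test_missing_atoms_flagged(self):
        coords, names, elements = ring_residue()
        s = avsim.StructureModel.from_arrays(
            coords[:8], radii=np.full(8, 1.7), chains=["A"] * 8,
            res_ids=np.full(8, 1), res_names=["TYR"] * 8,
            atom_names=names[:8], elements=elements[:8])
        pct, flags = avsim.relative_sasa(s, "A", 1)
        assert flags and "8/12" in flags[0]


PDB_TEXT = """\
ATOM      1  N   ALA A   1      -0.525   1.363   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.526   0.000   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.153   1.062   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1      -0.507  -0.785  -1.205  1.00  0.00           C
ATOM      6  CA AGLY A   2       3.800   0.000   0.000  0.40  0.00           C
ATOM      7  CA BGLY A   2       4.200   0.000   0.000  0.60  0.00           C
HETATM    8  S   SO4 B   9       9.000   9.000   9.000  1.00  0.00           S
END
"""


class TestPDBReading:
    def test_atoms_radii_and_altloc_resolution(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(PDB_TEXT)
        s = avsim.StructureModel.from_pdb(path)
        assert len(s) == 7     # altlocs collapse to one CA
        i = s.select_atom("A:2:CA")
        # highest-occupancy alternate location wins
        assert s.coords[i][0] == pytest.approx(4.2)
        assert s.radii[list(s.elements).index("S")] == pytest.approx(1.8)
        with pytest.raises(KeyError):
            s.select_atom("A:99:CA")
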