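"""Multi-shell stimulation-field solver vs closed forms and FD oracle."""

import numpy as np
import pytest

from tacsim.fields import (FieldFormatError, FieldMap, PointSourceSet,
                           StimulationConfig, efield_at, load_field_map,
                           normal_field, pad_sources, potential_multishell,
                           region_mean_field, save_field_map)
from tacsim.geometry import ShellModel, parcellate

from oracles import FDSphere

R = 0.092


@pytest.fixture(scope="module")
def polar_sources():
    return PointSourceSet(positions=np.array([[0, 0, R], [0, 0, -R]]),
                          currents=np.array([1e-3, -1e-3]))


class TestPadSources:
    def test_degenerate_single_point(self, layout1010):
        cfg = StimulationConfig(sources_per_pad=1)
        src = pad_sources(cfg, layout1010, R)
        assert len(src.currents) == 2
        np.testing.assert_allclose(src.currents, [cfg.current, -cfg.current])
        np.testing.assert_allclose(src.positions[0], layout1010.position("PO9"))

    def test_charge_conservation_and_split(self, layout1010):
        cfg = StimulationConfig(current=1.12e-3, sources_per_pad=15)
        src = pad_sources(cfg, layout1010, R)
        assert abs(src.currents.sum()) < 1e-18
        anode = src.currents[src.currents > 0]
        assert len(anode) == 15
        np.testing.assert_allclose(anode, 1.12e-3 / 15)

    def test_sources_on_scalp(self, layout1010):
        src = pad_sources(StimulationConfig(), layout1010, R)
        np.testing.assert_allclose(np.linalg.norm(src.positions, axis=1), R,
                                   atol=1e-12)

    def test_unknown_electrode(self, layout1020):
        # PO9 is not part of the classic 19-channel montage
        with pytest.raises(KeyError):
            pad_sources(StimulationConfig(), layout1020, R)

    def test_imbalanced_currents_rejected(self):
        with pytest.raises(ValueError):
            PointSourceSet(positions=np.array([[0, 0, R], [0, 0, -R]]),
                           currents=np.array([1e-3, -2e-3]))


class TestPotential:
    def test_zero_currents_zero_potential(self, homogeneous_shells):
        src = PointSourceSet(positions=np.array([[0, 0, R], [0, 0, -R]]),
                             currents=np.array([0.0, 0.0]))
        pts = np.array([[0.01, 0.0, 0.02], [0.0, 0.03, -0.01]])
        phi = potential_multishell(homogeneous_shells, src, pts)
        np.testing.assert_allclose(phi, 0.0, atol=1e-18)

    def test_linearity_in_current(self, homogeneous_shells, polar_sources):
        pts = np.array([[0.01, 0.02, 0.03], [0.0, 0.0, 0.05], [0.04, 0.0, 0.0]])
        phi1 = potential_multishell(homogeneous_shells, polar_sources, pts)
        doubled = PointSourceSet(polar_sources.positions, 2 * polar_sources.currents)
        phi2 = potential_multishell(homogeneous_shells, doubled, pts)
        np.testing.assert_allclose(phi2, 2 * phi1, rtol=1e-12)

    def test_superposition(self, homogeneous_shells):
        pts = np.array([[0.01, 0.02, 0.03], [0.02, -0.01, 0.04]])
        s1 = PointSourceSet(np.array([[0, 0, R], [0, 0, -R]]),
                            np.array([1e-3, -1e-3]))
        s2 = PointSourceSet(np.array([[R, 0, 0], [-R, 0, 0]]),
                            np.array([5e-4, -5e-4]))
        both = PointSourceSet(np.vstack([s1.positions, s2.positions]),
                              np.concatenate([s1.currents, s2.currents]))
        phi = potential_multishell(homogeneous_shells, both, pts, zero_mean=False)
        phi_sum = (potential_multishell(homogeneous_shells, s1, pts, zero_mean=False)
                   + potential_multishell(homogeneous_shells, s2, pts,
                                          zero_mean=False))
        np.testing.assert_allclose(phi, phi_sum, rtol=1e-12)

    def test_homogeneous_closed_form(self, homogeneous_shells, polar_sources):
        """Equal conductivities: the classic single-sphere series
        phi = I/(4 pi sigma R) sum (2n+1)/n (r/R)^n P_n(cos gamma)."""
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 3))
        pts = pts / np.linalg.norm(pts, axis=1)[:, None] * rng.uniform(0.01, 0.06, 12)[:, None]
        phi = potential_multishell(homogeneous_shells, polar_sources, pts)

        def closed(p, s_dir, current):
            r = np.linalg.norm(p)
            u = p @ s_dir / r
            tot, Pm, Pc = 0.0, 1.0, u
            for n in range(1, 400):
                tot += (2 * n + 1) / n * (r / R) ** n * Pc
                Pm, Pc = Pc, ((2 * n + 1) * u * Pc - n * Pm) / (n + 1)
            return current / (4 * np.pi * 0.33 * R) * tot

        ref = np.array([closed(p, np.array([0, 0, 1.0]), 1e-3)
                        + closed(p, np.array([0, 0, -1.0]), -1e-3) for p in pts])
        ref -= ref.mean()
        np.testing.assert_allclose(phi, ref, atol=1e-12 + 1e-9 * np.abs(ref).max())

    def test_point_outside_head_rejected(self, homogeneous_shells, polar_sources):
        with pytest.raises(Exception):
            potential_multishell(homogeneous_shells, polar_sources,
                                 np.array([[0.0, 0.0, 0.1]]))

    @pytest.mark.parametrize("conds", [(0.33, 0.33), (0.33, 0.008)])
    def test_fd_oracle(self, polar_sources, conds):
        """Series solution matches the finite-volume Laplace solver to
        < 1% max relative error at interior points."""
        shells = ShellModel(radii=(0.082, R), conductivities=conds)
        fd = FDSphere([0.082, R], list(conds), Nr=92, Nth=128)
        phi_fd = fd.solve(fd.rhs_surface_poles(1e-3))
        mask = fd.interior_mask()
        pts = fd.cell_points(mask)
        phi_s = potential_multishell(shells, polar_sources, pts)
        a = phi_fd[mask] - phi_fd[mask].mean()
        b = phi_s - phi_s.mean()
        assert np.abs(a - b).max() / np.abs(b).max() < 0.01


class TestEField:
    def test_zero_current_zero_field(self, homogeneous_shells):
        src = PointSourceSet(np.array([[0, 0, R], [0, 0, -R]]),
                             np.array([0.0, 0.0]))
        E = efield_at(homogeneous_shells, src, np.array([[0.01, 0.02, 0.0]])).E
        np.testing.assert_allclose(E, 0.0, atol=1e-18)

    def test_center_field_parallel_to_axis(self, homogeneous_shells, polar_sources):
        E = efield_at(homogeneous_shells, polar_sources,
                      np.array([[0.0, 0.0, 1e-6]])).E[0]
        cross = np.cross(E, [0.0, 0.0, 1.0])
        assert np.linalg.norm(cross) < 1e-6 * np.linalg.norm(E)

    def test_matches_numerical_gradient(self, field_shells, layout1010):
        """Analytic E agrees with central differences of the potential
        to < 0.1% at random interior points."""
        src = pad_sources(StimulationConfig(), layout1010, R)
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        pts = pts / np.linalg.norm(pts, axis=1)[:, None] * 0.077
        E = efield_at(field_shells, src, pts).E
        h = 1e-6
        En = np.zeros_like(E)
        for k in range(3):
            dp = np.zeros(3)
            dp[k] = h
            En[:, k] = (potential_multishell(field_shells, src, pts - dp,
                                             zero_mean=False)
                        - potential_multishell(field_shells, src, pts + dp,
                                               zero_mean=False)) / (2 * h)
        rel = np.linalg.norm(E - En, axis=1) / np.linalg.norm(E, axis=1)
        assert rel.max() < 1e-3

    def test_skull_attenuates_cortical_field(self, field_shells, layout1010):
        src = pad_sources(StimulationConfig(), layout1010, R)
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(64, 3))
        pts = pts / np.linalg.norm(pts, axis=1)[:, None] * 0.077
        E = efield_at(field_shells, src, pts).E
        eq = ShellModel(radii=field_shells.radii,
                        conductivities=(0.33, 0.33, 0.33, 0.33))
        E_eq = efield_at(eq, src, pts).E
        assert (np.linalg.norm(E, axis=1).mean()
                < np.linalg.norm(E_eq, axis=1).mean())


class TestNormalField:
    def test_projection_examples(self, small_mesh):
        E = np.tile([0.0, 0.0, 1.0], (small_mesh.n_triangles, 1))
        En = normal_field(FieldMap(E=E), small_mesh)
        np.testing.assert_allclose(En, small_mesh.normals[:, 2])
        # field orthogonal to a normal gives zero
        n0 = small_mesh.normals[0]
        t = np.cross(n0, [0.0, 0.0, 1.0])
        t /= np.linalg.norm(t)
        E0 = np.tile(t, (small_mesh.n_triangles, 1))
        assert abs(normal_field(FieldMap(E=E0), small_mesh)[0]) < 1e-12

    def test_flip_antisymmetry(self, small_mesh):
        rng = np.random.default_rng(0)
        E = rng.normal(size=(small_mesh.n_triangles, 3))
        En = normal_field(FieldMap(E=E), small_mesh)
        flipped = type(small_mesh)(vertices=small_mesh.vertices,
                                   triangles=small_mesh.triangles[:, ::-1])
        En_f = normal_field(FieldMap(E=E), flipped)
        np.testing.assert_allclose(En_f, -En, atol=1e-15)

    def test_length_mismatch(self, small_mesh):
        with pytest.raises(ValueError):
            normal_field(FieldMap(E=np.zeros((3, 3))), small_mesh)


class TestRegionMeanField:
    def test_mean_and_lambda(self, small_mesh, small_parcellation):
        En = np.zeros(small_mesh.n_triangles)
        members = small_parcellation.members(0)
        En[members[0]] = 1.0
        En[members[1]] = 3.0
        coeffs = region_mean_field(En, small_parcellation, lambda_=2.0)
        expected = (1.0 + 3.0) / len(members)
        assert coeffs.mean_normal_field[0] == pytest.approx(expected)
        np.testing.assert_allclose(coeffs.offsets,
                                   2.0 * coeffs.mean_normal_field)

    def test_lambda_zero_means_no_stimulation(self, small_mesh, small_parcellation):
        En = np.random.default_rng(0).normal(size=small_mesh.n_triangles)
        coeffs = region_mean_field(En, small_parcellation, lambda_=0.0)
        np.testing.assert_allclose(coeffs.offsets, 0.0)

    def test_electrode_swap_negates(self, field_shells, layout1010, small_mesh,
                                    small_parcellation):
        cfg = StimulationConfig()
        swapped = StimulationConfig(anode=cfg.cathode, cathode=cfg.anode)
        E1 = efield_at(field_shells, pad_sources(cfg, layout1010, R),
                       small_mesh.barycenters)
        E2 = efield_at(field_shells, pad_sources(swapped, layout1010, R),
                       small_mesh.barycenters)
        c1 = region_mean_field(normal_field(E1, small_mesh), small_parcellation, 1.0)
        c2 = region_mean_field(normal_field(E2, small_mesh), small_parcellation, 1.0)
        np.testing.assert_allclose(c2.mean_normal_field, -c1.mean_normal_field,
                                   rtol=1e-9, atol=1e-12)


class TestFieldMapIO:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        fm = FieldMap(E=rng.normal(size=(17, 3)))
        path = tmp_path / "field.tsv"
        save_field_map(fm, path)
        back = load_field_map(path)
        np.testing.assert_allclose(back.E, fm.E, rtol=1e-10)

    def test_gap_in_indices(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("0\t1\t2\t3\n2\t4\t5\t6\n")
        with pytest.raises(FieldFormatError):
            load_field_map(path)

    def test_duplicate_indices(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("0\t1\t2\t3\n0\t4\t5\t6\n")
        with pytest.raises(FieldFormatError):
            load_field_map(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(FieldFormatError):
            load_field_map(path)
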