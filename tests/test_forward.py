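"""Spherical head model, analytic lead field, scalp projection."""

import numpy as np
import pytest

from tvconn import forward as fw
from tvconn.ground_truth import TrialTensor


class TestHeadGeometry:
    def test_unfolded_normals_are_radial(self, small_head):
        _, src, _ = small_head
        radial = src.positions / np.linalg.norm(src.positions, axis=1, keepdims=True)
        dots = np.sum(src.normals * radial, axis=1)
        np.testing.assert_allclose(dots, 1.0, atol=1e-9)

    def test_mesh_is_closed_surface(self, small_head):
        _, src, _ = small_head
        assert src.euler_characteristic() == 2

    def test_electrodes_on_scalp_shell(self, small_head):
        head, _, sens = small_head
        radii = np.linalg.norm(sens.positions, axis=1)
        np.testing.assert_allclose(radii, head.shell_radii[2])

    def test_strong_folding_reverses_neighbour_normals(self):
        # oracle: direct scan of the fixture mesh for an adjacent pair with
        # opposed normals
        r_src = 0.85 * 80.0
        _, src, _ = fw.build_head_model(
            n_vertices=2000, n_electrodes=32, fold_amplitude=0.15 * r_src
        )
        e = src.edges()
        dots = np.sum(src.normals[e[:, 0]] * src.normals[e[:, 1]], axis=1)
        assert dots.min() < 0.0

    def test_fold_outside_brain_shell_rejected(self):
        with pytest.raises(ValueError, match="brain shell"):
            fw.build_head_model(n_vertices=200, n_electrodes=16,
                                fold_amplitude=30.0)

    def test_size_preconditions(self):
        with pytest.raises(ValueError):
            fw.build_head_model(n_vertices=10, n_electrodes=32)
        with pytest.raises(ValueError):
            fw.build_head_model(n_vertices=100, n_electrodes=4)


class TestLeadField:
    def test_free_medium_expansion_matches_direct_formula(self, small_head):
        # with the layered transfer replaced by the free-medium radial decay
        # the series must reproduce the exact infinite-medium dipole formula
        head, src, sens = small_head
        r3 = head.shell_radii[2]
        transfer = np.array([r3 ** -(n + 1) for n in range(81)])
        lf = fw.compute_leadfield(head, src, sens, average_reference=False,
                                  transfer=transfer)
        direct = np.empty_like(lf.G)
        for v in range(src.n_vertices):
            direct[:, v] = fw.free_medium_potential(
                src.positions[v], src.normals[v], sens.positions,
                sigma=head.conductivities[0],
            )
        err = np.abs(lf.G - direct).max() / np.abs(direct).max()
        assert err < 1e-8

    def test_series_converged_at_default_truncation(self, small_head, small_leadfield):
        head, src, sens = small_head
        double = fw.HeadModel(shell_radii=head.shell_radii,
                              conductivities=head.conductivities,
                              series_truncation=2 * head.series_truncation)
        g2 = fw.compute_leadfield(double, src, sens).G
        rel = np.abs(g2 - small_leadfield.G).max() / np.abs(g2).max()
        assert rel < 1e-6

    def test_average_reference_column_sums(self, small_leadfield):
        col = small_leadfield.G.sum(axis=0)
        norm = np.linalg.norm(small_leadfield.G, axis=0)
        assert np.all(np.abs(col) < 1e-10 * np.maximum(norm, 1e-30))

    def test_mirror_symmetry(self):
        # mirror-symmetric dipoles with mirrored electrodes give mirrored
        # gain patterns (spherical symmetry of the head)
        head = fw.HeadModel()
        pos = np.array([[30.0, 20.0, 10.0], [-30.0, 20.0, 10.0]])
        nrm = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
        src = fw.SourceSpace(positions=pos, normals=nrm,
                             triangles=np.zeros((1, 3), int))
        e = np.array([[50.0, 40.0, 60.0], [-50.0, 40.0, 60.0]])
        e = e / np.linalg.norm(e, axis=1, keepdims=True) * head.shell_radii[2]
        sens = fw.SensorArray(positions=e)
        g = fw.compute_leadfield(head, src, sens, average_reference=False).G
        np.testing.assert_allclose(g[0, 0], g[1, 1], rtol=1e-10)
        np.testing.assert_allclose(g[1, 0], g[0, 1], rtol=1e-10)

    def test_gain_decays_with_depth(self):
        # radial dipole line under a fixed electrode: deeper = weaker
        head = fw.HeadModel()
        depths = np.linspace(20.0, 65.0, 12)
        pos = np.column_stack([np.zeros(12), np.zeros(12), depths])
        nrm = np.tile([0.0, 0.0, 1.0], (12, 1))
        src = fw.SourceSpace(positions=pos, normals=nrm,
                             triangles=np.zeros((1, 3), int))
        sens = fw.SensorArray(
            positions=np.array([[0.0, 0.0, head.shell_radii[2]]])
        )
        g = fw.compute_leadfield(head, src, sens, average_reference=False).G[0]
        assert np.all(np.diff(np.abs(g)) > 0)

    def test_matches_mne_sphere_model(self, small_head):
        # independent cross-check against the layered-sphere EEG model in MNE
        import mne

        mne.set_log_level("ERROR")
        head, src, sens = small_head
        lf = fw.compute_leadfield(head, src, sens)
        r3 = head.shell_radii[2] / 1000.0
        sphere = mne.make_sphere_model(
            r0=(0.0, 0.0, 0.0), head_radius=r3,
            relative_radii=tuple(r / head.shell_radii[2] for r in head.shell_radii),
            sigmas=head.conductivities,
        )
        ch_pos = {
            f"E{i:03d}": sens.positions[i] / 1000.0
            for i in range(sens.n_sensors)
        }
        info = mne.create_info(list(ch_pos), 256.0, "eeg")
        info.set_montage(
            mne.channels.make_dig_montage(ch_pos=ch_pos, coord_frame="head")
        )
        idx = [0, 75, 150, 225, 299]
        vsrc = mne.setup_volume_source_space(
            pos=dict(rr=src.positions[idx] / 1000.0, nn=src.normals[idx])
        )
        fwd = mne.make_forward_solution(
            info, trans=mne.transforms.Transform("head", "mri"), src=vsrc,
            bem=sphere, eeg=True, meg=False,
        )
        g3 = fwd["sol"]["data"]
        g_mne = np.stack(
            [g3[:, 3 * i: 3 * i + 3] @ src.normals[v] for i, v in enumerate(idx)],
            axis=1,
        )
        g_mne -= g_mne.mean(axis=0, keepdims=True)
        scales = []
        for i in range(len(idx)):
            a, b = lf.G[:, idx[i]], g_mne[:, i]
            assert np.corrcoef(a, b)[0, 1] > 0.999
            scales.append(np.dot(a, b) / np.dot(b, b))
        scales = np.asarray(scales)
        # one consistent unit conversion across dipoles
        assert scales.std() / scales.mean() < 0.01


class TestDipoleMapping:
    def test_regions_map_to_distinct_vertices(self, small_head, model):
        _, src, _ = small_head
        idx = fw.map_ground_truth_dipoles(src, model)
        assert len(idx) == 10
        assert len(set(idx.tolist())) == 10

    def test_exact_vertex_is_selected(self, small_head, model):
        from tvconn.ground_truth import GroundTruthModel

        _, src, _ = small_head
        # two well-separated regions so planting one target cannot steal the
        # other's nearest vertex
        two = GroundTruthModel(
            regions=[model.regions[model.index("V1")],
                     model.regions[model.index("MFG_R")]],
            connections=[],
        )
        center, scale = fw.mni_to_sphere_affine(two, src)
        coords = np.array([r.mni_xyz for r in two.regions])
        mapped = (coords - center) * scale
        positions = src.positions.copy()
        positions[17] = mapped[0]  # plant region 0's target exactly
        planted = fw.SourceSpace(positions=positions, normals=src.normals,
                                 triangles=src.triangles)
        idx = fw.map_ground_truth_dipoles(planted, two)
        # (planting shifts the mean source radius, hence the affine, by a
        # fraction of a millimetre -- far below the mesh spacing)
        assert idx[0] == 17
        assert np.linalg.norm(planted.positions[idx[0]] - mapped[0]) < 0.5


@pytest.fixture(scope="module")
def projected(small_head, small_leadfield, few_trials, model):
    _, src, _ = small_head
    trials, _ = few_trials
    idx = fw.map_ground_truth_dipoles(src, model)
    scalp, (clean, noise) = fw.project_and_add_noise(
        small_leadfield, trials, scalp_snr=5.0, vertex_indices=idx,
        seed=4, return_components=True,
    )
    return scalp, clean, noise


class TestScalpProjection:
    def test_noiseless_projection_is_linear(self, small_head, small_leadfield,
                                            few_trials, model):
        _, src, _ = small_head
        trials, _ = few_trials
        idx = fw.map_ground_truth_dipoles(src, model)
        scalp = fw.project_and_add_noise(
            small_leadfield, trials, scalp_snr=np.inf, vertex_indices=idx,
            scale=2.0, seed=0,
        )
        expected = 2.0 * np.einsum(
            "em,rmn->ren", small_leadfield.G[:, idx], trials.data
        )
        np.testing.assert_allclose(scalp.data, expected, atol=1e-12)

    def test_realized_snr(self, projected):
        scalp, clean, noise = projected
        ratio = np.mean(clean ** 2) / np.mean(noise ** 2)
        assert abs(ratio / 5.0 - 1.0) < 0.05

    def test_average_reference_preserved(self, projected):
        scalp, _, _ = projected
        sensor_mean = scalp.data.mean(axis=1)
        assert np.abs(sensor_mean).max() < 1e-9 * np.abs(scalp.data).max()

    def test_peak_amplitude_default_scaling(self, small_head, small_leadfield,
                                            few_trials, model):
        _, src, _ = small_head
        trials, _ = few_trials
        idx = fw.map_ground_truth_dipoles(src, model)
        _, (clean, _) = fw.project_and_add_noise(
            small_leadfield, trials, scalp_snr=3.0, vertex_indices=idx,
            target_peak=50.0, seed=0, return_components=True,
        )
        np.testing.assert_allclose(np.abs(clean).max(), 50.0)

    def test_zero_source_rejected(self, small_leadfield):
        zeros = TrialTensor(data=np.zeros((2, 10, 30)), fs=256.0, t0_ms=-200.0)
        with pytest.raises(ValueError, match="zero-power"):
            fw.project_and_add_noise(
                small_leadfield, zeros, scalp_snr=5.0,
                vertex_indices=np.arange(10),
            )
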