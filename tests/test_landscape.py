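import numpy as np
import pandas as pd
import pytest

from hopland import StageAnnotation
from hopland.hopfield import build_weight_matrix, energy
from hopland.landscape import project_samples, render_surface, trajectory
from hopland.preprocess import discretize


def frame(values, gene_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=gene_ids or [f"g{i}" for i in range(values.shape[0])],
        columns=sample_ids or [f"s{j}" for j in range(values.shape[1])])


def rank2_dataset(n_genes=6, n_samples=10, seed=5):
    """Samples lying exactly in a 2-D affine subspace of gene space."""
    rng = np.random.default_rng(seed)
    basis = rng.normal(size=(2, n_genes))
    scores = rng.normal(scale=(3.0, 1.0), size=(n_samples, 2))
    return frame((scores @ basis).T)


class TestProjectSamples:
    def test_identical_samples_project_to_origin(self):
        data = frame(np.tile([[1.0], [2.0], [3.0]], (1, 5)))
        scores, _ = project_samples(data)
        np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-9)

    def test_inverse_projection_recovers_in_plane_samples(self):
        data = rank2_dataset()
        scores, projection = project_samples(data)
        reconstructed = projection.inverse_transform(scores.to_numpy())
        np.testing.assert_allclose(reconstructed,
                                   data.to_numpy().T, atol=1e-9)

    def test_variance_concentrated_on_one_gene_separates_along_pc1(self):
        # two clusters separated only along gene 0
        cluster = np.array([[-5.0] * 4 + [5.0] * 4,
                            [0.1, -0.1, 0.05, -0.05] * 2])
        scores, _ = project_samples(frame(cluster))
        pc1 = scores["pc1"].to_numpy()
        assert (pc1[:4] < 0).all() and (pc1[4:] > 0).all()
        assert np.abs(scores["pc1"]).max() > 10 * np.abs(scores["pc2"]).max()

    def test_deterministic_sign_convention(self):
        data = rank2_dataset(seed=9)
        scores_a, proj_a = project_samples(data)
        scores_b, proj_b = project_samples(data)
        np.testing.assert_array_equal(scores_a.to_numpy(), scores_b.to_numpy())
        for c in range(2):
            pivot = np.argmax(np.abs(proj_a.components[c]))
            assert proj_a.components[c, pivot] > 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 3 samples"):
            project_samples(frame([[1.0, 2.0], [0.0, 1.0]]))


class TestRenderSurface:
    def test_grid_spans_samples_and_is_finite(self, fitted_default):
        surface = fitted_default.render_surface(grid_size=12)
        points = surface.sample_points
        assert surface.grid_x.min() <= points["pc1"].min()
        assert surface.grid_x.max() >= points["pc1"].max()
        assert surface.grid_y.min() <= points["pc2"].min()
        assert surface.grid_y.max() >= points["pc2"].max()
        assert np.isfinite(surface.grid_energy).all()
        assert surface.grid_energy.shape == (12, 12)

    def test_in_plane_sample_energy_matches_grid_pipeline(self):
        # for samples lying exactly in the PC1-PC2 plane, inverse-mapping
        # their coordinates reproduces them, so the grid scoring pipeline
        # must return each sample's own energy at its coordinates
        data = rank2_dataset()
        weights = build_weight_matrix(data)
        scores, projection = project_samples(data)
        own = render_surface(data, weights, threshold=0.5,
                             grid_size=3).sample_points
        for sample, row in scores.iterrows():
            inverse = projection.inverse_transform(
                row.to_numpy()[None, :])[0]
            state = discretize(
                pd.DataFrame({"x": inverse}, index=data.index), 0.5)["x"]
            recomputed = energy(state, weights)
            expected = own.loc[own["sample_id"] == sample, "energy"].iloc[0]
            assert recomputed == pytest.approx(expected, abs=1e-9)

    def test_all_zero_grid_point_scores_zero(self):
        data = rank2_dataset()
        weights = build_weight_matrix(data)
        surface = render_surface(data, weights, threshold=1e6, grid_size=3)
        # absurdly large threshold discretises every grid point to the
        # all-zero state, whose energy is exactly 0
        np.testing.assert_array_equal(surface.grid_energy, 0.0)

    def test_degenerate_axis_expanded_with_warning(self):
        # samples vary along a single direction: PC2 scores are all ~0
        rng = np.random.default_rng(3)
        direction = rng.normal(size=4)
        scores = np.linspace(-2, 2, 6)
        data = frame(np.outer(direction, scores))
        weights = build_weight_matrix(data)
        with pytest.warns(UserWarning, match="degenerate"):
            surface = render_surface(data, weights, threshold=0.5,
                                     grid_size=5)
        assert surface.grid_y.max() - surface.grid_y.min() >= 2.0

    def test_deterministic_and_refinement_consistent(self):
        data = rank2_dataset(seed=21)
        weights = build_weight_matrix(data)
        kwargs = dict(threshold=0.5, margin=0.0)
        a = render_surface(data, weights, grid_size=3, **kwargs)
        b = render_surface(data, weights, grid_size=3, **kwargs)
        np.testing.assert_array_equal(a.grid_energy, b.grid_energy)
        # grid_size 5 contains the size-3 nodes (endpoints + midpoint)
        fine = render_surface(data, weights, grid_size=5, **kwargs)
        for i3, i5 in [(0, 0), (1, 2), (2, 4)]:
            for j3, j5 in [(0, 0), (1, 2), (2, 4)]:
                assert fine.grid_energy[i5, j5] == pytest.approx(
                    a.grid_energy[i3, j3], abs=1e-9)

    def test_invalid_grid_size(self, fitted_default):
        with pytest.raises(ValueError, match="grid_size"):
            fitted_default.render_surface(grid_size=1)

    def test_transient_neighbourhood_energy_exceeds_endpoint(
            self, fitted_default):
        surface = fitted_default.render_surface(grid_size=30)
        points = surface.sample_points

        def neighbourhood(row):
            ix = np.argsort(np.abs(surface.grid_x - row.pc1))[:2]
            iy = np.argsort(np.abs(surface.grid_y - row.pc2))[:2]
            return np.mean([surface.grid_energy[i, j]
                            for i in ix for j in iy])

        by_stage = {}
        for stage, group in points.groupby("stage"):
            by_stage[stage] = np.mean(
                [neighbourhood(r) for r in group.itertuples()])
        order = fitted_default.annotation.stage_order
        endpoints = [by_stage[order[0]], by_stage[order[-1]]]
        transients = [by_stage[s]
                      for s in fitted_default.annotation.transient_stages]
        assert min(transients) > max(endpoints)


class TestTrajectory:
    def test_two_stages_single_segment(self, toy_matrix, toy_annotation):
        points = pd.DataFrame({
            "sample_id": toy_annotation.samples,
            "pc1": [0.0, 1.0, 2.0, 3.0],
            "pc2": [0.0, 0.0, 1.0, 1.0],
            "energy": [-1.0, -3.0, -5.0, -7.0]})
        traj = trajectory(points, toy_annotation)
        assert len(traj) == 2
        assert traj.loc[0, "pc1"] == pytest.approx(0.5)
        assert traj.loc[1, "energy"] == pytest.approx(-6.0)

    def test_singleton_stage_centroid_is_the_sample(self):
        ann = StageAnnotation({"a": "X", "b": "Y", "c": "Y"}, ["X", "Y"])
        points = pd.DataFrame({
            "sample_id": ["a", "b", "c"],
            "pc1": [1.5, 0.0, 1.0], "pc2": [-2.0, 0.0, 1.0],
            "energy": [-9.0, 0.0, -2.0]})
        traj = trajectory(points, ann)
        row = traj[traj["stage"] == "X"].iloc[0]
        assert (row.pc1, row.pc2, row.energy) == (1.5, -2.0, -9.0)

    def test_arc_energy_rises_then_falls(self, fitted_default):
        traj = fitted_default.trajectory()
        energies = traj["energy"].to_numpy()
        peak = energies.argmax()
        assert 0 < peak < len(energies) - 1
        assert (np.diff(energies[:peak + 1]) > 0).all()
        assert (np.diff(energies[peak:]) < 0).all()
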