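import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hopland import StageAnnotation
from hopland.hopfield import (build_weight_matrix, energy, recall,
                              sample_energies, stage_energies)
from hopland.preprocess import discretize, zscore_normalize

from conftest import brute_force_energy, random_instance


def frame(rows):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(rows.shape[0])],
                        columns=[f"s{j}" for j in range(rows.shape[1])])


class TestWeightMatrix:
    def test_duplicate_and_negated_rows(self):
        base = np.array([1.0, -2.0, 0.5, 3.0])
        weights = build_weight_matrix(frame([base, base, -base]))
        assert weights.iloc[0, 1] == pytest.approx(1.0)
        assert weights.iloc[0, 2] == pytest.approx(-1.0)

    def test_symmetric_zero_diagonal_bounded(self):
        rng = np.random.default_rng(3)
        weights = build_weight_matrix(frame(rng.normal(size=(8, 10))))
        w = weights.to_numpy()
        np.testing.assert_array_equal(w, w.T)
        np.testing.assert_array_equal(np.diag(w), 0.0)
        assert np.abs(w).max() <= 1.0

    def test_zero_variance_gene_named(self):
        data = frame([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]])
        with pytest.raises(ValueError, match="g1"):
            build_weight_matrix(data)

    def test_dimension_preconditions(self):
        with pytest.raises(ValueError, match=">= 2 genes"):
            build_weight_matrix(frame([[1.0, 2.0, 3.0]]))
        with pytest.raises(ValueError, match=">= 3 samples"):
            build_weight_matrix(frame([[1.0, 2.0], [2.0, 1.0]]))


class TestEnergy:
    def test_zero_state_is_zero(self):
        _, w = random_instance(np.random.default_rng(0), 5)
        assert energy(np.zeros(5), w) == 0.0

    def test_two_node_aligned_pair(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert energy(np.array([1, 1]), w) == pytest.approx(-1.0)
        assert energy(np.array([1, -1]), w) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_instance(self):
        rng = np.random.default_rng(42)
        h, w = random_instance(rng, 6)
        assert energy(h, w) == pytest.approx(brute_force_energy(h, w),
                                             abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        _, w = random_instance(np.random.default_rng(0), 4)
        with pytest.raises(ValueError, match="mismatch"):
            energy(np.ones(5), w)

    @given(st.integers(0, 10_000), st.integers(2, 25))
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_quadratic_form_properties(self, seed, n):
        rng = np.random.default_rng(seed)
        h, w = random_instance(rng, n)
        e = energy(h, w)
        # matches the independent double-loop oracle
        assert e == pytest.approx(brute_force_energy(h, w), abs=1e-9)
        # sign symmetry of the quadratic form
        assert energy(-h, w) == pytest.approx(e, abs=1e-12)
        # invariance under simultaneous permutation of genes
        perm = rng.permutation(n)
        assert energy(h[perm], w[np.ix_(perm, perm)]) == pytest.approx(
            e, abs=1e-9)


class TestStageEnergies:
    def make(self, n_per_stage):
        rng = np.random.default_rng(7)
        samples, mapping = [], {}
        for stage, count in n_per_stage.items():
            for i in range(count):
                sid = f"{stage}_{i}"
                samples.append(sid)
                mapping[sid] = stage
        ann = StageAnnotation(mapping, list(n_per_stage))
        data = pd.DataFrame(rng.normal(size=(6, len(samples))),
                            index=[f"g{i}" for i in range(6)],
                            columns=samples)
        z = zscore_normalize(data)
        return discretize(z), build_weight_matrix(z), ann

    def test_singleton_stages_copy_sample_energies(self):
        states, weights, ann = self.make({"A": 1, "B": 1, "C": 1})
        profile = stage_energies(states, weights, ann)
        for stage in ann.stage_order:
            sample = ann.samples_of(stage)[0]
            assert profile.per_stage[stage] == profile.per_sample[sample]

    def test_stage_mean_is_replicate_mean(self):
        states, weights, ann = self.make({"A": 3, "B": 2})
        profile = stage_energies(states, weights, ann)
        for stage in ann.stage_order:
            expected = profile.per_sample[ann.samples_of(stage)].mean()
            assert profile.per_stage[stage] == pytest.approx(expected)

    def test_duplicating_every_replicate_leaves_stage_mean_unchanged(self):
        states, weights, ann = self.make({"A": 3, "B": 2})
        baseline = stage_energies(states, weights, ann).per_stage
        dup = states.copy()
        mapping = dict(ann.sample_to_stage)
        for sample in ann.samples_of("A"):
            dup[f"{sample}_dup"] = states[sample]
            mapping[f"{sample}_dup"] = "A"
        profile = stage_energies(dup, weights,
                                 StageAnnotation(mapping, ann.stage_order))
        assert profile.per_stage["A"] == pytest.approx(baseline["A"])
        assert profile.per_stage["B"] == pytest.approx(baseline["B"])

    def test_centroid_aggregate_scores_consensus(self):
        states, weights, ann = self.make({"A": 3, "B": 2})
        profile = stage_energies(states, weights, ann, aggregate="centroid")
        consensus = np.sign(
            states[ann.samples_of("A")].mean(axis=1).to_numpy())
        assert profile.per_stage["A"] == pytest.approx(
            energy(consensus, weights))

    def test_arc_middle_stages_have_higher_energy(self, fitted_default):
        per_stage = fitted_default.energies.per_stage
        endpoints = [per_stage.iloc[0], per_stage.iloc[-1]]
        middles = per_stage.iloc[1:-1]
        assert middles.min() > max(endpoints)


class TestRecall:
    def test_fixed_point_returned_unchanged(self):
        rng = np.random.default_rng(11)
        h, w = random_instance(rng, 8)
        attractor, _ = recall(h, w, max_sweeps=100)
        final, trajectory = recall(attractor, w, max_sweeps=100)
        np.testing.assert_array_equal(final, attractor)
        assert len(trajectory) == 1

    def test_two_node_converges_to_aligned_minimum(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        final, trajectory = recall(np.array([1, -1]), w)
        # enumerating the 9 ternary states: (+1,+1) and (-1,-1) are the
        # global minima at E=-1; fixed-order updates land on (-1,-1)
        assert trajectory[-1] == pytest.approx(-1.0)
        assert tuple(final) in {(1, 1), (-1, -1)}

    def test_energy_never_increases_between_sweeps(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            h, w = random_instance(rng, int(rng.integers(2, 15)))
            _, trajectory = recall(h, w, max_sweeps=30)
            diffs = np.diff(trajectory)
            assert (diffs <= 1e-9).all()

    def test_invalid_arguments(self):
        h, w = random_instance(np.random.default_rng(0), 4)
        with pytest.raises(ValueError, match="max_sweeps"):
            recall(h, w, max_sweeps=0)
        with pytest.raises(ValueError, match="mode"):
            recall(h, w, mode="synchronous")


def test_sample_energies_match_single_energy(fitted_default):
    states, weights = fitted_default.states, fitted_default.weights
    per_sample = sample_energies(states, weights)
    for sample in states.columns[:5]:
        assert per_sample[sample] == pytest.approx(
            energy(states[sample], weights), abs=1e-9)
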