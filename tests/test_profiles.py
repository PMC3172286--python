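"""Model-profile enumeration, selection, gene assignment and significance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from marrownet.profiles import (
    UNASSIGNED,
    ModelProfile,
    ModelProfileSet,
    assign_genes,
    enumerate_candidate_profiles,
    profile_significance,
    select_model_profiles,
    to_logratio_trajectory,
    trajectories,
)
from marrownet.simulate import SimConfig, model_profile_set, simulate_timecourse
from tests.conftest import matrix_from_log2


class TestEnumeration:
    @pytest.mark.parametrize("T", [3, 4, 5])
    @pytest.mark.parametrize("c", [1, 2, 3])
    def test_count_matches_closed_form(self, T, c):
        assert len(enumerate_candidate_profiles(T, c)) == (2 * c + 1) ** (T - 1) - 1

    def test_smallest_case_lists_both_directions(self):
        cands = enumerate_candidate_profiles(2, 1)
        assert {p.steps for p in cands} == {(0, -1), (0, 1)}

    def test_profiles_start_at_zero_with_bounded_steps(self):
        for p in enumerate_candidate_profiles(5, 2):
            assert p.steps[0] == 0
            assert max(abs(a - b) for a, b in itertools.pairwise(p.steps)) <= 2


class TestSelection:
    def test_all_candidates_returned_when_m_equals_count(self):
        cands = enumerate_candidate_profiles(3, 1)
        chosen = select_model_profiles(cands, len(cands))
        assert {p.steps for p in chosen.profiles} == {p.steps for p in cands}

    def test_two_from_two_are_anticorrelated(self):
        cands = enumerate_candidate_profiles(2, 1)
        chosen = select_model_profiles(cands, 2)
        assert {p.steps for p in chosen.profiles} == {(0, -1), (0, 1)}

    def test_too_many_requested_rejected(self):
        with pytest.raises(ValueError, match="candidates"):
            select_model_profiles(enumerate_candidate_profiles(2, 1), 3)

    def test_maxmin_selection_beats_random_subsets(self):
        """The greedy set's minimum pairwise distance dominates random picks."""
        cands = enumerate_candidate_profiles(5, 2)
        chosen = select_model_profiles(cands, 10)
        z = chosen.steps_matrix()
        z = (z - z.mean(1, keepdims=True)) / np.linalg.norm(
            z - z.mean(1, keepdims=True), axis=1, keepdims=True
        )
        d = 1 - z @ z.T
        greedy_min = (d + np.eye(len(d)) * 9).min()

        steps = np.array([p.steps for p in cands], float)
        zs = (steps - steps.mean(1, keepdims=True)) / np.linalg.norm(
            steps - steps.mean(1, keepdims=True), axis=1, keepdims=True
        )
        dall = 1 - zs @ zs.T
        rng = np.random.default_rng(0)
        for _ in range(1000):
            idx = rng.choice(len(cands), 10, replace=False)
            sub = dall[np.ix_(idx, idx)] + np.eye(10) * 9
            assert greedy_min >= sub.min() - 1e-9

    def test_selection_is_deterministic(self):
        cands = enumerate_candidate_profiles(5, 2)
        a = select_model_profiles(cands, 50, seed=0)
        b = select_model_profiles(cands, 50, seed=99)
        assert [p.steps for p in a.profiles] == [p.steps for p in b.profiles]


class TestTrajectories:
    def test_flat_gene_gives_zero_vector(self):
        matrix = matrix_from_log2(np.full((1, 20), 8.0), ["FLAT"], 4)
        assert np.allclose(to_logratio_trajectory(matrix, "FLAT"), 0.0)

    def test_first_element_always_zero(self, small_sim):
        _, matrix, _ = small_sim
        traj = trajectories(matrix)
        assert np.all(traj[0].to_numpy() == 0.0)

    def test_noiseless_planted_gene_proportional_to_steps(self):
        cfg = SimConfig(n_genes=20, n_de=5, n_modules=0, noise_sd=0.0, seed=6)
        matrix, truth = simulate_timecourse(cfg)
        gene = sorted(truth.de_genes)[0]
        steps = np.array(truth.profile_of_gene[gene], float)
        traj = to_logratio_trajectory(matrix, gene)
        assert np.allclose(traj, cfg.effect_log2 * steps, atol=1e-9)


def _pset(step_lists):
    return ModelProfileSet(
        [ModelProfile(i, tuple(s)) for i, s in enumerate(step_lists)], max_unit_change=2
    )


class TestAssignment:
    def test_exact_profile_match(self):
        pset = _pset([(0, -1, -2, -2, -1), (0, 1, 2, 2, 1)])
        traj = pd.DataFrame([[0, 1, 2, 2, 1]], index=["G"], columns=range(5), dtype=float)
        assert assign_genes(traj, pset)["G"] == 1

    def test_inverted_trajectory_picks_inverted_profile(self):
        pset = _pset([(0, -1, -2, -2, -1), (0, 1, 2, 2, 1)])
        traj = pd.DataFrame([[0, -1, -2, -2, -1]], index=["G"], columns=range(5), dtype=float)
        assert assign_genes(traj, pset)["G"] == 0

    def test_constant_trajectory_unassigned(self):
        pset = _pset([(0, 1, 2, 2, 1)])
        traj = pd.DataFrame([[0, 0, 0, 0, 0]], index=["G"], columns=range(5), dtype=float)
        assert assign_genes(traj, pset)["G"] == UNASSIGNED

    def test_tie_goes_to_lowest_profile_id(self):
        # duplicate profiles correlate identically with anything
        pset = _pset([(0, 1, 2, 2, 1), (0, 1, 2, 2, 1)])
        traj = pd.DataFrame([[0, 1, 1.5, 2, 1]], index=["G"], columns=range(5), dtype=float)
        assert assign_genes(traj, pset)["G"] == 0

    def test_gene_relabeling_equivariance(self, small_sim):
        cfg, matrix, truth = small_sim
        pset = model_profile_set(cfg)
        traj = trajectories(matrix, sorted(truth.de_genes))
        base = assign_genes(traj, pset)
        shuffled = traj.sample(frac=1.0, random_state=1)
        permuted = assign_genes(shuffled, pset)
        assert permuted.sort_index().equals(base.sort_index())

    def test_planted_profiles_recovered(self, small_sim):
        cfg, matrix, truth = small_sim
        pset = model_profile_set(cfg)
        steps_of = {p.profile_id: p.steps for p in pset.profiles}
        traj = trajectories(matrix, sorted(truth.de_genes))
        assignment = assign_genes(traj, pset)
        hits = sum(
            1 for g in truth.de_genes
            if assignment[g] != UNASSIGNED and steps_of[assignment[g]] == truth.profile_of_gene[g]
        )
        assert hits / len(truth.de_genes) >= 0.90


class TestSignificance:
    def test_unhit_profile_gets_p_one(self):
        pset = _pset([(0, 1, 2, 2, 1), (0, -1, -2, -2, -1)])
        traj = pd.DataFrame(
            [[0, 1, 2, 2, 1.01], [0, 1, 2, 2, 0.99]],
            index=["A", "B"], columns=range(5),
        )
        assignment = assign_genes(traj, pset)
        result = profile_significance(assignment, traj, pset, alpha=0.05)
        table = result.table.set_index("profile_id")
        assert table.loc[1, "n_observed"] == 0
        assert table.loc[1, "p_value"] == 1.0

    def test_exact_enumeration_of_24_permutations_at_T5(self, small_sim):
        cfg, matrix, truth = small_sim
        pset = model_profile_set(cfg)
        traj = trajectories(matrix, sorted(truth.de_genes)[:20])
        assignment = assign_genes(traj, pset)
        result = profile_significance(assignment, traj, pset)
        assert result.n_permutations == 24

    def test_planted_cluster_reaches_bonferroni_significance(self):
        # all differential genes share one module profile: that profile's
        # observed count dwarfs any permutation expectation
        cfg = SimConfig(n_genes=300, n_de=100, n_modules=1, module_size=100,
                        noise_sd=0.2, seed=12)
        matrix, truth = simulate_timecourse(cfg)
        pset = model_profile_set(cfg)
        traj = trajectories(matrix, sorted(truth.de_genes))
        assignment = assign_genes(traj, pset)
        result = profile_significance(assignment, traj, pset, alpha=0.001)
        (planted_steps,) = {truth.profile_of_gene[g] for g in truth.de_genes}
        planted_id = next(
            p.profile_id for p in pset.profiles if p.steps == planted_steps
        )
        table = result.table.set_index("profile_id")
        assert table.loc[planted_id, "significant"]
        assert planted_id in result.significant_profiles()
        assert set(result.clustered_genes()) >= set(result.assigned_genes(planted_id))
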