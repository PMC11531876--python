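"""Sign-pattern Jacobians, quasi-sign-stability and extinction cascades."""

import numpy as np
import pytest
import scipy.linalg

import trophicweb as tw
from trophicweb.stability_extinction import (
    build_sign_jacobian,
    trajectory_table,
    _child_seed,
)
from trophicweb.topology_metrics import SpeciesMetrics


def _pair_web():
    web = tw.FoodWeb(
        [tw.Species("prey", body_mass=1.0), tw.Species("pred", body_mass=10.0)],
        [tw.TrophicLink("prey", "pred")],
    )
    return web, {tw.TrophicLink("prey", "pred"): 0.4}


def _metrics(values):
    return {
        s: SpeciesMetrics(
            species_id=s, trophic_level=v, degree=int(v), omnivory=v,
            trophic_similarity=v, intermodule_connectivity=v, total_is=v,
            module=0,
        )
        for s, v in values.items()
    }


class TestSignJacobian:
    def test_pair_sign_pattern_and_bounds(self, rng):
        web, medians = _pair_web()
        ids = web.species_ids  # ('pred', 'prey')
        i_pred, i_prey = ids.index("pred"), ids.index("prey")
        for _ in range(1000):
            a = build_sign_jacobian(web, medians, rng)
            assert a[i_prey, i_pred] < 0  # consumer's effect on resource
            assert a[i_pred, i_prey] > 0  # resource's effect on consumer
            assert abs(a[i_prey, i_pred]) <= 0.4
            assert abs(a[i_pred, i_prey]) <= 0.4
            assert a[i_pred, i_pred] == a[i_prey, i_prey] == 0

    def test_no_links_zero_matrix(self, rng):
        web = tw.FoodWeb([tw.Species("A"), tw.Species("B")], [])
        assert np.all(build_sign_jacobian(web, {}, rng) == 0)

    def test_self_links_leave_diagonal_zero(self, rng):
        web = tw.FoodWeb(
            [tw.Species("A", body_mass=1.0), tw.Species("B", body_mass=1.0)],
            [tw.TrophicLink("A", "B"), tw.TrophicLink("B", "B")],
        )
        medians = {l: 1.0 for l in web.links}
        a = build_sign_jacobian(web, medians, rng)
        assert np.all(np.diag(a) == 0)

    def test_missing_is_rejected(self, rng):
        web, _ = _pair_web()
        with pytest.raises(tw.ValidationError, match="no interaction strength"):
            build_sign_jacobian(web, {}, rng)

    def test_sign_pattern_on_synthetic_web(self, small_synth_web, rng):
        medians = {l: 1.0 for l in small_synth_web.links}
        a = build_sign_jacobian(small_synth_web, medians, rng)
        ids = small_synth_web.species_ids
        index = {s: i for i, s in enumerate(ids)}
        for l in small_synth_web.links:
            if l.is_self_link:
                continue
            i, j = index[l.resource_id], index[l.consumer_id]
            # Mutual predation pairs would overwrite; assert one
            # negative/positive transpose pair per directed link.
            reverse = tw.TrophicLink(l.consumer_id, l.resource_id)
            if reverse not in small_synth_web.links:
                assert a[i, j] < 0 and a[j, i] > 0
        assert np.all(np.diag(a) == 0)


class TestQSS:
    def test_predator_prey_pair_is_neutrally_stable(self):
        # Eigenvalues of [[0, -a], [b, 0]] are ±i·sqrt(ab): the maximum
        # real part is exactly zero in every replicate.
        web, medians = _pair_web()
        result = tw.qss(web, medians, n_reps=200, seed=0)
        assert np.all(np.abs(result.eigen_samples) < 1e-10)
        assert result.median_eigen == pytest.approx(0.0, abs=1e-10)

    def test_linkless_web_max_eigen_exactly_zero(self):
        web = tw.FoodWeb([tw.Species("A"), tw.Species("B")], [])
        result = tw.qss(web, {}, n_reps=5, seed=0)
        assert np.all(result.eigen_samples == 0.0)

    def test_replicates_match_independent_eigensolver(self, small_synth_web):
        # Same randomized matrices, independent LAPACK route.
        medians = {l: 1.0 for l in small_synth_web.links}
        rng = np.random.default_rng(77)
        for _ in range(10):
            a = build_sign_jacobian(small_synth_web, medians, rng)
            ours = tw.max_real_eigenvalue(a)
            oracle = float(np.max(scipy.linalg.eigvals(a).real))
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_summaries_match_samples(self, small_synth_web, default_coeffs):
        est = tw.monte_carlo_interaction_strengths(
            small_synth_web, default_coeffs, 50, seed=0
        )
        medians = tw.median_interaction_strengths(est)
        result = tw.qss(small_synth_web, medians, n_reps=64, seed=5)
        assert result.median_eigen == pytest.approx(np.median(result.eigen_samples))
        assert result.iqr[0] <= result.median_eigen <= result.iqr[1]

    def test_deterministic_under_seed(self, small_synth_web):
        medians = {l: 0.5 for l in small_synth_web.links}
        a = tw.qss(small_synth_web, medians, n_reps=20, seed=3)
        b = tw.qss(small_synth_web, medians, n_reps=20, seed=3)
        assert np.array_equal(a.eigen_samples, b.eigen_samples)

    def test_empty_web_rejected(self):
        with pytest.raises(tw.ValidationError):
            tw.qss(tw.FoodWeb([], []), {}, n_reps=1, seed=0)


class TestRankSpecies:
    def test_descending_with_lexicographic_ties(self):
        metrics = _metrics({"A": 5.0, "B": 3.0, "C": 5.0})
        assert tw.rank_species(metrics, "degree") == ["A", "C", "B"]

    def test_single_species(self):
        assert tw.rank_species(_metrics({"A": 1.0}), "total_is") == ["A"]

    def test_first_element_attains_maximum(self, rng):
        for _ in range(20):
            values = {f"s{i}": float(v) for i, v in enumerate(rng.random(15))}
            order = tw.rank_species(_metrics(values), "omnivory")
            assert values[order[0]] == max(values.values())

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError, match="unknown criterion"):
            tw.rank_species(_metrics({"A": 1.0}), "charisma")


class TestComponents:
    def test_chain_is_one_component(self):
        web = tw.FoodWeb(
            [tw.Species(s) for s in "ABCDE"],
            [tw.TrophicLink(a, b) for a, b in zip("ABCD", "BCDE")],
        )
        assert tw.count_components(web) == 1

    def test_two_disjoint_pairs(self):
        web = tw.FoodWeb(
            [tw.Species(s) for s in "ABCD"],
            [tw.TrophicLink("A", "B"), tw.TrophicLink("C", "D")],
        )
        assert tw.count_components(web) == 2

    def test_empty_web_zero(self):
        assert tw.count_components(tw.FoodWeb([], [])) == 0

    def test_matches_union_find_oracle(self, rng):
        for _ in range(20):
            n = 12
            ids = [f"s{i}" for i in range(n)]
            links = [
                (ids[a], ids[b])
                for a in range(n)
                for b in range(n)
                if a != b and rng.random() < 0.08
            ]
            web = tw.FoodWeb(
                [tw.Species(s) for s in ids],
                [tw.TrophicLink(a, b) for a, b in links],
            )
            parent = {s: s for s in ids}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for a, b in links:
                parent[find(a)] = find(b)
            n_roots = len({find(s) for s in ids})
            assert tw.count_components(web) == n_roots


class TestSequentialExtinction:
    def test_removing_middle_of_chain_splits(self):
        web = tw.FoodWeb(
            [tw.Species(s, body_mass=1.0) for s in "ABC"],
            [tw.TrophicLink("A", "B"), tw.TrophicLink("B", "C")],
        )
        medians = {l: 1.0 for l in web.links}
        metrics = _metrics({"A": 0.0, "B": 2.0, "C": 1.0})
        traj = tw.sequential_extinction(
            web, ["B"], metrics, medians, "degree", k=1, n_reps=10, seed=0
        )
        assert traj.steps[0].n_components == 2
        assert traj.steps[0].n_species_remaining == 2

    def test_species_remaining_strictly_decreasing(self, small_synth_web, default_coeffs):
        est = tw.monte_carlo_interaction_strengths(
            small_synth_web, default_coeffs, 20, seed=0
        )
        medians = tw.median_interaction_strengths(est)
        totals = {
            s: tw.total_interaction_strength(s, est, small_synth_web)
            for s in small_synth_web.species_ids
        }
        metrics = tw.compute_species_metrics(small_synth_web, totals, seed=0)
        order = tw.rank_species(metrics, "degree")
        traj = tw.sequential_extinction(
            small_synth_web, order, metrics, medians, "degree",
            k=8, n_reps=10, seed=0,
        )
        remaining = [s.n_species_remaining for s in traj.steps]
        assert remaining == list(
            range(small_synth_web.n_species - 1,
                  small_synth_web.n_species - 1 - len(remaining), -1)
        )
        # Ranking metadata is recorded in removal order.
        values = [s.rank_metric_value for s in traj.steps]
        assert values == sorted(values, reverse=True)

    def test_k_larger_than_web_rejected(self, fixture_web):
        with pytest.raises(ValueError, match="exceeds species count"):
            tw.sequential_extinction(
                fixture_web, list(fixture_web.species_ids), {}, {}, "degree",
                k=10, n_reps=1, seed=0,
            )

    def test_removing_absent_species_rejected(self):
        web = tw.FoodWeb(
            [tw.Species(s, body_mass=1.0) for s in "ABC"],
            [tw.TrophicLink("A", "B")],
        )
        metrics = _metrics({"A": 1.0, "B": 2.0, "C": 3.0})
        with pytest.raises(KeyError, match="already absent"):
            tw.sequential_extinction(
                web, ["A", "A"], metrics, {l: 1.0 for l in web.links},
                "degree", k=2, n_reps=1, seed=0,
            )

    def test_trajectories_bit_identical_under_seed(self, small_synth_web, default_coeffs):
        est = tw.monte_carlo_interaction_strengths(
            small_synth_web, default_coeffs, 20, seed=0
        )
        medians = tw.median_interaction_strengths(est)
        metrics = tw.compute_species_metrics(small_synth_web, seed=0)
        order = tw.rank_species(metrics, "trophic_level")
        runs = [
            tw.sequential_extinction(
                small_synth_web, order, metrics, medians, "trophic_level",
                k=5, n_reps=25, seed=99,
            )
            for _ in range(2)
        ]
        for s1, s2 in zip(runs[0].steps, runs[1].steps):
            assert s1.removed_species_id == s2.removed_species_id
            assert np.array_equal(s1.qss.eigen_samples, s2.qss.eigen_samples)

    def test_child_seeds_distinct_across_steps_and_criteria(self):
        seen = {
            tuple(_child_seed(7, c, t).generate_state(2))
            for c in tw.CRITERIA
            for t in range(1, 11)
        }
        assert len(seen) == len(tw.CRITERIA) * 10


class TestDetectFragmentation:
    def _traj(self, comps):
        web = tw.FoodWeb([tw.Species("x")], [])
        qss_stub = tw.QSSResult(np.zeros(1), 0.0, 0.0, (0.0, 0.0))
        steps = tuple(
            tw.ExtinctionStep(
                removed_species_id=f"r{i}", rank_metric_value=0.0,
                qss=qss_stub, n_components=c, n_species_remaining=10 - i,
            )
            for i, c in enumerate(comps)
        )
        return tw.ExtinctionTrajectory(criterion="degree", steps=steps)

    def test_increase_points_flagged(self):
        traj = self._traj([1, 1, 2, 2, 9])
        assert tw.detect_fragmentation(traj) == ["r2", "r4"]

    def test_no_fragmentation_empty(self):
        assert tw.detect_fragmentation(self._traj([1, 1, 1])) == []

    def test_first_step_compared_to_one(self):
        assert tw.detect_fragmentation(self._traj([3, 3])) == ["r0"]

    def test_trajectory_table_columns(self):
        table = trajectory_table(self._traj([1, 2]))
        assert list(table.columns) == [
            "step", "removed_species", "metric_value",
            "median_eigen", "q25", "q75", "n_components",
        ]
        assert list(table.n_components) == [1, 2]
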