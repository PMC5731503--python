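"""Merged graph construction and the restricted-matching solvers."""

import math

import pytest

from scafmerge import (
    AssemblyPoint,
    InstanceTooLargeError,
    Orientation,
    WeightPolicy,
    assign_weights,
    build_msag,
    consistency_score,
    merge_exact,
    merge_greedy,
    merge_matching,
    scaffold_orders,
    validate_solution,
)
from scafmerge.points import Assembly, Extremity
from scafmerge.synth import SimulationConfig, corrupt, generate_reference

F, R, U = Orientation.FORWARD, Orientation.REVERSE, Orientation.UNKNOWN


def ap(s1, o1, s2, o2, **kw):
    return AssemblyPoint(s1, o1, s2, o2, **kw)


def random_instance(seed, n_scaffolds=6, n_assemblies=2):
    """A small random merging instance built from corrupted references."""
    config = SimulationConfig(
        n_scaffolds=n_scaffolds,
        n_chromosomes=1,
        n_assemblies=n_assemblies,
        p_adjacency_error=0.2,
        p_orientation_loss=0.3,
        p_missing=0.15,
        seed=seed,
    )
    reference = generate_reference(config)
    assemblies = [corrupt(reference, config, i) for i in range(n_assemblies)]
    return assemblies, build_msag(assemblies)


class TestWeights:
    def test_defaults(self):
        policy = WeightPolicy()
        assert policy.default_actual == 1.0
        assert policy.default_candidate_factor == 0.75
        assert policy.threshold == 0.0

    def test_actual_edge_unset_cw(self):
        asm = Assembly.from_points("A1", [ap("s1", F, "s2", F)])
        (e,) = assign_weights([asm])
        assert e.weight == 1.0

    def test_unoriented_point_yields_four_candidates(self):
        asm = Assembly.from_points("A1", [ap("s1", U, "s2", U)])
        edges = assign_weights([asm])
        assert [e.weight for e in edges] == [0.75] * 4
        assert {e.kind for e in edges} == {"candidate"}

    def test_candidate_weight_scales_with_cw(self):
        asm = Assembly.from_points("A1", [ap("s1", F, "s2", U, cw=0.8)])
        edges = assign_weights([asm])
        assert [e.weight for e in edges] == pytest.approx([0.6, 0.6])


class TestMsag:
    def test_worked_example_weights(self, fig_assemblies):
        msag = build_msag(fig_assemblies)
        weights = {
            tuple(str(v) for v in e.key): e.weight for e in msag.edges
        }
        assert weights == {
            ("s1.h", "s2.t"): 2.0,
            ("s1.h", "s3.t"): 1.0,
            ("s2.h", "s3.h"): 0.75,
            ("s2.h", "s3.t"): 1.75,
            ("s3.h", "s4.h"): 1.75,
            ("s3.h", "s4.t"): 0.75,
        }

    def test_threshold_filters_before_solving(self, fig_assemblies):
        msag = build_msag(fig_assemblies, WeightPolicy(threshold=1.5))
        assert sorted(e.weight for e in msag.edges) == [1.75, 1.75, 2.0]

    def test_single_point_msag_mirrors_sag(self):
        asm = Assembly.from_points("A1", [ap("s1", F, "s2", F, cw=0.9)])
        msag = build_msag([asm])
        (e,) = msag.edges
        assert e.weight == 0.9
        assert [c[0] for c in e.contributors] == ["A1"]


MERGERS = [merge_greedy, merge_matching, merge_exact]


class TestSolvers:
    @pytest.mark.parametrize("solver", MERGERS)
    def test_worked_example_solution(self, fig_assemblies, solver):
        msag = build_msag(fig_assemblies)
        M = solver(msag)
        assert M.objective == pytest.approx(5.5)
        assert {p.key for p in M.points} == {
            ("s1", "+", "s2", "+"),
            ("s2", "+", "s3", "+"),
            ("s3", "+", "s4", "-"),
        }
        assert validate_solution(M, fig_assemblies) == []
        chains = scaffold_orders(M, msag.scaffolds)
        assert chains == [([("s1", "+"), ("s2", "+"), ("s3", "+"), ("s4", "-")], False)]

    def test_empty_msag(self, fig_assemblies):
        msag = build_msag(fig_assemblies, WeightPolicy(threshold=10))
        assert msag.edges == []
        for solver in MERGERS:
            assert solver(msag).points == ()

    def _triangle(self, w3=3.0, w2=2.0, w1=1.0):
        asms = [
            Assembly.from_points("A1", [ap("s1", F, "s2", F, cw=1.0)]),
            Assembly.from_points("A2", [ap("s2", F, "s3", F, cw=1.0)]),
            Assembly.from_points("A3", [ap("s3", F, "s1", F, cw=1.0)]),
        ]
        # distinct weights via duplicated colors
        extra = [
            Assembly.from_points("B1", [ap("s1", F, "s2", F)]),
            Assembly.from_points("B2", [ap("s1", F, "s2", F, cw=1.0)]),
            Assembly.from_points("B3", [ap("s2", F, "s3", F)]),
        ]
        return asms + extra

    def test_greedy_never_closes_forbidden_cycle(self):
        asms = self._triangle()
        msag = build_msag(asms)
        M = merge_greedy(msag, allow_circular=False)
        assert len(M.points) == 2  # one triangle edge rejected
        assert validate_solution(M, asms, allow_circular=False) == []
        chains = scaffold_orders(M, msag.scaffolds)
        assert not any(circ for _, circ in chains)

    def test_circular_exception_admits_full_cycle(self):
        asms = self._triangle()
        msag = build_msag(asms)
        M = merge_greedy(msag, allow_circular=True)
        assert len(M.points) == 3
        assert validate_solution(M, asms, allow_circular=True) == []
        chains = scaffold_orders(M, msag.scaffolds)
        assert [circ for _, circ in chains] == [True]

    def test_matching_cycle_repair_drops_lightest_edge(self):
        asms = self._triangle()
        msag = build_msag(asms)
        M = merge_matching(msag, allow_circular=False)
        # blossom picks all three disjoint edges; the weight-1 one must go
        weights = sorted(e.weight for e in M.edges)
        assert weights == [2.0, 3.0]
        assert validate_solution(M, asms) == []

    @pytest.mark.parametrize("allow_circular", [False, True])
    def test_one_realization_per_unoriented_point(self, allow_circular):
        asm = Assembly.from_points("A1", [ap("s1", U, "s2", U)])
        msag = build_msag([asm])
        for solver in MERGERS:
            M = solver(msag, allow_circular=allow_circular)
            assert len(M.points) == 1
            assert validate_solution([p for p in M.points], [asm], allow_circular) == []

    def test_exact_prefers_heavier_of_conflicting_edges(self):
        asms = [
            Assembly.from_points("A1", [ap("s1", F, "s2", F, cw=1.0)]),
            Assembly.from_points("A2", [ap("s1", F, "s3", F, cw=0.5)]),
        ]
        M = merge_exact(build_msag(asms))
        assert {p.key for p in M.points} == {("s1", "+", "s2", "+")}

    def test_exact_instance_bound(self, fig_assemblies):
        msag = build_msag(fig_assemblies)
        with pytest.raises(InstanceTooLargeError):
            merge_exact(msag, max_edges=3)

    @pytest.mark.parametrize("solver", MERGERS)
    def test_determinism(self, solver):
        assemblies, msag = random_instance(seed=11)
        first = solver(msag)
        again = solver(build_msag(assemblies))
        assert [p.key for p in first.points] == [p.key for p in again.points]
        assert first.objective == again.objective


class TestValidator:
    def test_two_realizations_of_one_point_reported(self):
        asm = Assembly.from_points("A1", [ap("s1", U, "s2", U)])
        M = [ap("s1", F, "s2", F), ap("s1", R, "s2", R)]
        violations = validate_solution(M, [asm])
        assert any("realizations" in v for v in violations)

    def test_matching_violation_reported(self):
        asm = Assembly.from_points("A1", [ap("s1", F, "s2", F)])
        M = [ap("s1", F, "s2", F), ap("s1", F, "s3", F)]
        violations = validate_solution(M, [asm])
        assert any("matching violation" in v for v in violations)

    def test_cycle_reported_without_circular_flag(self):
        M = [ap("s1", F, "s2", F), ap("s2", F, "s1", F)]
        asm = Assembly.from_points("A1", M)
        assert validate_solution(M, [asm], allow_circular=False)
        assert validate_solution(M, [asm], allow_circular=True) == []


class TestConsistencyScore:
    def test_worked_example(self, fig_assemblies):
        M = [ap("s1", F, "s2", F), ap("s2", F, "s3", F), ap("s3", F, "s4", R)]
        a2 = fig_assemblies[1]
        assert consistency_score(M, a2) == pytest.approx(2.75)

    def test_disjoint_assembly_scores_zero(self, fig_assemblies):
        M = [ap("s1", R, "s4", F)]
        assert consistency_score(M, fig_assemblies[1]) == 0.0

    def test_self_score_counts_every_point(self):
        asm = Assembly.from_points(
            "A1", [ap("s1", F, "s2", F), ap("s2", F, "s3", F)]
        )
        assert consistency_score(asm.points, asm) == pytest.approx(2.0)


class TestSolverProperties:
    """Randomized cross-checks of the heuristics against the exact oracle."""

    SEEDS = range(40)

    def _solvable(self, seed):
        assemblies, msag = random_instance(seed)
        if len(msag.edges) > 26:
            return None
        return assemblies, msag

    def test_heuristics_bounded_by_exact_and_feasible(self):
        checked = 0
        for seed in self.SEEDS:
            inst = self._solvable(seed)
            if inst is None:
                continue
            assemblies, msag = inst
            exact = merge_exact(msag, max_edges=30)
            for solver in (merge_greedy, merge_matching):
                M = solver(msag)
                assert M.objective <= exact.objective + 1e-9
                assert validate_solution(M, assemblies) == []
            assert validate_solution(exact, assemblies) == []
            checked += 1
        assert checked >= 30

    def test_objective_matches_summed_consistency_scores(self):
        """The matching objective equals Σ_i CS_M(A_i): the reformulation of
        the merging problem as weighted matching is exact under these
        weight semantics."""
        for seed in self.SEEDS:
            assemblies, msag = random_instance(seed)
            M = merge_greedy(msag)
            total_cs = sum(consistency_score(M, a) for a in assemblies)
            assert total_cs == pytest.approx(M.objective)

    def test_threshold_monotonicity(self):
        for seed in range(10):
            assemblies, _ = random_instance(seed, n_scaffolds=5)
            prev = math.inf
            for threshold in (0.0, 0.8, 1.2, 2.0):
                msag = build_msag(assemblies, WeightPolicy(threshold=threshold))
                if len(msag.edges) > 26:
                    prev = math.inf
                    continue
                obj = merge_exact(msag, max_edges=30).objective
                assert obj <= prev + 1e-9
                prev = obj
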