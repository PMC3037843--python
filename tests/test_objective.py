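"""Component criteria, steering scalar and the recovery objective."""

import numpy as np
import pytest

from groupfix import (
    Anchors,
    Candidate,
    CandidateSet,
    MatingList,
    Pedigree,
    PermissionMatrix,
    SteeringConfig,
    calibrate_anchors,
    components,
    recovery_objective,
    scalar_fitness,
)
from groupfix.objective import ObjectiveComponents, components_cached
from groupfix.problem import MateSelectionProblem


def make_list(pairs, groups=None):
    groups = groups or {}
    return MatingList(
        pairs=list(pairs),
        male_group_of={s: groups.get(s, "M") for s, _ in pairs},
        female_group_of={d: groups.get(d, "F") for _, d in pairs},
    )


class TestComponents:
    def test_single_pair_of_founders(self):
        cs = CandidateSet(
            [
                Candidate(id="s", sex="M", group="M", index=10.0, maxuse=1),
                Candidate(id="d", sex="F", group="F", index=20.0, maxuse=1),
            ]
        )
        ped = Pedigree([("s", None, None), ("d", None, None)])
        oc = components(make_list([("s", "d")]), ped, cs)
        assert oc.mean_progeny_index == 15.0
        # p = (1/2, 1/2) over two non-inbred unrelated parents: p'Kp = 0.25
        assert oc.parental_coancestry == pytest.approx(0.25)
        assert oc.mean_progeny_inbreeding == 0.0

    def test_full_sib_pair_progeny_inbreeding(self):
        cs = CandidateSet(
            [
                Candidate(id="X", sex="M", group="M", index=0.0, maxuse=1),
                Candidate(id="Y", sex="F", group="F", index=0.0, maxuse=1),
            ]
        )
        ped = Pedigree(
            [("A", None, None), ("B", None, None), ("X", "A", "B"), ("Y", "A", "B")]
        )
        oc = components(make_list([("X", "Y")]), ped, cs)
        assert oc.mean_progeny_inbreeding == pytest.approx(0.25)

    def test_empty_list_rejected(self):
        cs = CandidateSet([Candidate(id="s", sex="M", group="M", index=0, maxuse=1)])
        with pytest.raises(ValueError, match="empty"):
            components(make_list([]), Pedigree([("s", None, None)]), cs)

    def test_matches_brute_force_on_random_lists(self, fixture_problem):
        """Cached fast path and direct recomputation agree pairwise."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            ml = fixture_problem.decode(fixture_problem.init_population(1, rng)[0], rng)
            fast = components_cached(ml, fixture_problem)
            slow = components(ml, fixture_problem.pedigree, fixture_problem.candidates)
            assert fast.mean_progeny_index == pytest.approx(slow.mean_progeny_index)
            assert fast.parental_coancestry == pytest.approx(slow.parental_coancestry)
            assert fast.mean_progeny_inbreeding == pytest.approx(
                slow.mean_progeny_inbreeding
            )
            # independent brute force straight from the definitions
            counts = ml.use_counts()
            nt = len(ml)
            ped = fixture_problem.pedigree
            coan = 0.0
            for a, ca in counts.items():
                for b, cb in counts.items():
                    coan += (ca / (2 * nt)) * (cb / (2 * nt)) * ped.kinship(a, b)
            assert fast.parental_coancestry == pytest.approx(coan, abs=1e-12)


class TestScalarFitness:
    ANCHORS = Anchors(
        index_0deg=10.0, coancestry_0deg=0.10, index_90deg=2.0, coancestry_90deg=0.02
    )

    def comp(self, g, c, f=0.0, illegal=0):
        return ObjectiveComponents(g, c, f, illegal)

    def test_zero_degrees_ranks_by_index(self):
        sc = SteeringConfig(target_degrees=0, inbreeding_weight=0, anchors=self.ANCHORS)
        sols = [self.comp(g, c) for g, c in [(3, 0.09), (7, 0.02), (5, 0.5)]]
        fits = [scalar_fitness(s, sc) for s in sols]
        assert np.argsort(fits).tolist() == np.argsort([3, 7, 5]).tolist()

    def test_ninety_degrees_ranks_by_low_coancestry(self):
        sc = SteeringConfig(target_degrees=90, inbreeding_weight=0, anchors=self.ANCHORS)
        sols = [self.comp(g, c) for g, c in [(3, 0.09), (7, 0.02), (5, 0.5)]]
        fits = [scalar_fitness(s, sc) for s in sols]
        assert np.argsort(fits).tolist() == np.argsort([-0.09, -0.02, -0.5]).tolist()

    def test_penalty_charges_weight_per_illegal_pair(self):
        sc = SteeringConfig(
            target_degrees=25, inbreeding_weight=0, penalty_weight=100, anchors=self.ANCHORS
        )
        legal = scalar_fitness(self.comp(5, 0.05), sc)
        broken = scalar_fitness(self.comp(5, 0.05, illegal=1), sc)
        assert legal - broken == pytest.approx(100.0)
        assert scalar_fitness(self.comp(5, 0.05, illegal=0), sc) == legal  # no charge

    def test_missing_anchors_is_an_error(self):
        with pytest.raises(ValueError, match="anchors"):
            scalar_fitness(self.comp(1, 0.1), SteeringConfig())


class TestAnchors:
    def test_anchors_match_exhaustive_extremes_on_tiny_problem(self):
        """Two males, two females, no grouping freedom: enumerate all
        decodable lists and compare with the calibrated anchors."""
        cands = [
            Candidate(id="m1", sex="M", group="M", index=4.0, maxuse=2),
            Candidate(id="m2", sex="M", group="M", index=1.0, maxuse=2),
            Candidate(id="f1", sex="F", group="F", index=3.0, maxuse=1),
            Candidate(id="f2", sex="F", group="F", index=2.0, maxuse=1),
        ]
        cs = CandidateSet(cands)
        ped = Pedigree(
            [("P", None, None), ("m1", "P", None), ("m2", "P", None),
             ("f1", None, None), ("f2", None, None)]
        )
        pm = PermissionMatrix(("M",), ("F",), np.ones((1, 1), dtype=int))
        prob = MateSelectionProblem(cs, ped, pm, {"F": 1.0})
        # exhaustive over male use vectors (2,0), (1,1), (0,2):
        # mean midparent index is 3.25 (m1 both), 2.5 (split), 1.75 (m2 both)
        best_index = max(
            ((4 + 3) / 2 + (4 + 2) / 2) / 2,
            ((4 + 3) / 2 + (1 + 2) / 2) / 2,
            ((4 + 2) / 2 + (1 + 3) / 2) / 2,
            ((1 + 3) / 2 + (1 + 2) / 2) / 2,
        )
        anchors = calibrate_anchors(prob, seed=11, budget=1500, pop_size=20)
        assert anchors.index_0deg == pytest.approx(best_index)
        # minimum coancestry: using both half-sib males spreads contributions
        assert anchors.coancestry_90deg <= anchors.coancestry_0deg + 1e-12

    def test_anchors_deterministic_for_fixed_seed(self, fixture_problem):
        a1 = calibrate_anchors(fixture_problem, seed=5, budget=600, pop_size=12)
        a2 = calibrate_anchors(fixture_problem, seed=5, budget=600, pop_size=12)
        assert a1 == a2

    def test_index_anchor_bounds_random_solutions(self, fixture_problem):
        anchors = calibrate_anchors(fixture_problem, seed=2, budget=2000, pop_size=20)
        rng = np.random.default_rng(8)
        for _ in range(300):
            ml = fixture_problem.decode(fixture_problem.init_population(1, rng)[0], rng)
            oc = components_cached(ml, fixture_problem)
            assert oc.mean_progeny_index <= anchors.index_0deg + 1e-9


class TestRecoveryObjective:
    def test_shared_pair_counting(self):
        target = make_list([("a", "x"), ("b", "y"), ("c", "z")])
        fit = recovery_objective(target)
        oc = ObjectiveComponents(0, 0, 0, 0)
        assert fit(make_list(target.pairs), oc) == 3.0
        assert fit(make_list([("q", "r"), ("s", "t")]), oc) == 0.0
        assert fit(make_list([("a", "x"), ("s", "t")]), oc) == 1.0

    def test_duplicate_pairs_counted_as_multiset(self):
        target = make_list([("a", "x"), ("a", "x")])
        fit = recovery_objective(target)
        oc = ObjectiveComponents(0, 0, 0, 0)
        assert fit(make_list([("a", "x")]), oc) == 1.0
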