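"""Permission matrix, action types, weight transform and group targets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from groupfix import (
    Candidate,
    CandidateSet,
    InfeasibleGroupingError,
    PermissionMatrix,
    allocate_grouped,
    derive_action_types,
    female_group_targets,
    integerize_targets,
    rank_allocate,
    reallocate_male_capacity,
    relative_weights,
)
from groupfix.grouping import ActionType

from .conftest import table2_raw_vector


def single_column(perm_col, raw):
    """Helper: build a one-column permission matrix and compute W."""
    pm = PermissionMatrix(
        male_groups=tuple(f"M{i}" for i in range(len(perm_col))),
        female_groups=("F",),
        entries=np.asarray(perm_col, dtype=np.int64).reshape(-1, 1),
    )
    at = derive_action_types(pm)
    return relative_weights(at, raw)[:, 0]


class TestActionTypes:
    def test_worked_example_classification(self, table2_permission):
        at = derive_action_types(table2_permission).to_frame()
        # single permitted male group → fixed weight of one
        assert at.loc["MG1", "FG1"] == ActionType.FIXED_ONE
        assert list(at["FG3"]) == [ActionType.OPT] * 3 + [ActionType.CALC]
        assert at.loc["MG4", "FG2"] == ActionType.NONE
        # 9 raw weights to optimise in the worked example
        assert derive_action_types(table2_permission).n_opt == 9

    def test_all_ones_attains_opt_count_bound(self):
        pm = PermissionMatrix(("A", "B"), ("x", "y"), np.ones((2, 2), dtype=int))
        at = derive_action_types(pm)
        assert at.n_opt == 2  # N_FG * (N_MG - 1)
        assert list(at.to_frame()["x"]) == [ActionType.OPT, ActionType.CALC]

    def test_empty_column_is_infeasible(self):
        with pytest.raises(InfeasibleGroupingError, match="lonely"):
            PermissionMatrix(("A",), ("lonely",), np.zeros((1, 1), dtype=int))


class TestRelativeWeights:
    def test_reproduces_worked_example(self, table2_permission):
        at = derive_action_types(table2_permission)
        W = relative_weights(at, table2_raw_vector(at))
        expect = np.array(
            [
                [1.0, 0.0, 0.15, 0.0, 0.0],
                [0.0, 0.667, 0.30, 0.16, 0.0],
                [0.0, 0.333, 0.30, 0.24, 0.8],
                [0.0, 0.0, 0.25, 0.60, 0.2],
            ]
        )
        assert np.allclose(np.round(W, 3), expect)

    def test_all_raw_zero_gives_last_group_everything(self):
        W = single_column([1, 1, 1], [0.0, 0.0])
        assert W[2] == 1.0 and W[0] == W[1] == 0.0

    def test_raw_one_rest_zero_gives_last_group_nothing(self):
        W = single_column([1, 1, 1], [1.0, 0.0])
        assert W[2] == pytest.approx(0.0)

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_mean_half_puts_last_group_at_column_average(self, k):
        """k−1 positive raw weights averaging 0.5 → W_last = 1/k."""
        rng = np.random.default_rng(k)
        vals = rng.uniform(0.2, 0.8, k - 1)
        vals = vals * (0.5 / vals.mean())
        W = single_column([1] * k, list(vals))
        assert W[-1] == pytest.approx(1.0 / k, abs=1e-12)
        assert W[-1] == pytest.approx(W[W > -1].mean(), abs=1e-12)

    def test_last_group_not_permitted_is_plain_normalisation(self):
        W = single_column([1, 1, 0], [0.2, 0.1])
        assert np.allclose(W, [2 / 3, 1 / 3, 0.0])

    def test_degenerate_column_falls_back_to_uniform(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="groupfix.grouping"):
            W = single_column([1, 1, 0], [0.0, 0.0])
        assert np.allclose(W, [0.5, 0.5, 0.0])
        assert any("uniform" in r.message for r in caplog.records)

    def test_raw_values_truncated_to_unit_interval(self):
        assert np.allclose(single_column([1, 1, 1], [7.0, -3.0]), [1.0, 0.0, 0.0])

    @given(
        raw=st.lists(st.floats(0, 1), min_size=2, max_size=5),
        last_permitted=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_columns_always_sum_to_one(self, raw, last_permitted):
        col = [1] * len(raw) + [1 if last_permitted else 0]
        W = single_column(col, raw)
        assert W.sum() == pytest.approx(1.0, abs=1e-9)
        assert (W >= -1e-12).all()

    @given(
        others=st.lists(st.floats(0, 1), min_size=1, max_size=4),
        r=st.floats(0, 1),
        bump=st.floats(0.01, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_raising_a_raw_weight_never_lowers_its_relative_weight(
        self, others, r, bump
    ):
        col = [1] * (len(others) + 2)
        w_before = single_column(col, [r] + others)[0]
        w_after = single_column(col, [min(r + bump, 1.0)] + others)[0]
        assert w_after >= w_before - 1e-12


class TestFemaleGroupTargets:
    def test_round_product(self):
        assert female_group_targets({"a": 100}, {"a": 0.5}) == {"a": 50}
        assert female_group_targets({"a": 7}, {"a": 1.0}) == {"a": 7}

    def test_empty_group_with_positive_proportion_errors(self):
        with pytest.raises(InfeasibleGroupingError, match="'ghost'"):
            female_group_targets({"ghost": 0}, {"ghost": 0.5})

    def test_missing_or_invalid_proportion_errors(self):
        with pytest.raises(KeyError):
            female_group_targets({"a": 5}, {})
        with pytest.raises(ValueError):
            female_group_targets({"a": 5}, {"a": 1.5})


class TestIntegerize:
    def test_exact_products_untouched(self):
        W = np.array([[0.5], [0.5]])
        nmg = integerize_targets(W, [4], np.random.default_rng(0))
        assert nmg[:, 0].tolist() == [2, 2]

    def test_worked_example_weights_give_exact_integer_targets(self):
        W = np.array([[0.15], [0.3], [0.3], [0.25]])
        nmg = integerize_targets(W, [20], np.random.default_rng(0))
        assert nmg[:, 0].tolist() == [3, 6, 6, 5]

    def test_remainder_distribution_is_weight_proportional(self):
        W = np.full((3, 1), 1 / 3)
        rng = np.random.default_rng(42)
        totals = np.zeros(3)
        n = 10_000
        for _ in range(n):
            nmg = integerize_targets(W, [10], rng)
            assert nmg[:, 0].sum() == 10
            totals += nmg[:, 0]
        assert np.allclose(totals / n, 10 / 3, atol=0.05)

    def test_zero_weight_cells_stay_zero(self):
        W = np.array([[0.7], [0.0], [0.3]])
        rng = np.random.default_rng(1)
        for _ in range(200):
            assert integerize_targets(W, [7], rng)[1, 0] == 0


class TestReallocate:
    def _pm(self, entries):
        e = np.asarray(entries, dtype=np.int64)
        return PermissionMatrix(
            tuple(f"M{i}" for i in range(e.shape[0])),
            tuple(f"F{j}" for j in range(e.shape[1])),
            e,
        )

    def test_within_capacity_unchanged(self):
        pm = self._pm([[1, 1], [1, 1]])
        nmg = np.array([[2, 1], [1, 2]])
        out = reallocate_male_capacity(nmg, pm, [5, 5], [0, 0], np.random.default_rng(0))
        assert np.array_equal(out, nmg)

    def test_single_overflow_moves_one_unit(self):
        """2×2 with row 0 one over cap: the only legal repairs move one
        unit down a column, preserving column sums."""
        pm = self._pm([[1, 1], [1, 1]])
        nmg = np.array([[3, 2], [1, 1]])
        out = reallocate_male_capacity(nmg, pm, [4, 9], [0, 0], np.random.default_rng(3))
        assert out.sum(axis=0).tolist() == [4, 3]  # column sums kept
        assert out[0].sum() == 4 and out[1].sum() == 3
        assert int(np.abs(out - nmg).sum()) == 2  # exactly one unit moved

    def test_global_infeasibility_detected(self):
        pm = self._pm([[1], [1]])
        with pytest.raises(InfeasibleGroupingError, match="capacity"):
            reallocate_male_capacity(
                np.array([[3], [3]]), pm, [2, 2], [0, 0], np.random.default_rng(0)
            )

    @pytest.mark.parametrize("seed", range(8))
    def test_random_instances_feasible_and_column_preserving(self, seed):
        """Instances built by perturbing a known-feasible witness are
        always repaired to feasibility with column sums intact."""
        rng = np.random.default_rng(seed)
        pm_entries = (rng.random((4, 5)) < 0.7).astype(int)
        pm_entries[0, pm_entries.sum(axis=0) == 0] = 1  # no empty columns
        pm = self._pm(pm_entries)
        for _ in range(60):
            witness = rng.integers(0, 4, (4, 5)) * pm.entries
            caps = witness.sum(axis=1) + rng.integers(0, 3, 4)
            # shuffle units within columns (permitted cells only)
            nmg = witness.copy()
            for _ in range(15):
                j = int(rng.integers(5))
                permitted = np.flatnonzero(pm.entries[:, j])
                if len(permitted) < 2:
                    continue
                src = permitted[nmg[permitted, j] > 0]
                if len(src) == 0:
                    continue
                a = int(rng.choice(src))
                b = int(rng.choice(permitted[permitted != a]))
                nmg[a, j] -= 1
                nmg[b, j] += 1
            out = reallocate_male_capacity(nmg, pm, caps, [0, 0, 0, 0], rng)
            assert np.array_equal(out.sum(axis=0), nmg.sum(axis=0))
            assert (out.sum(axis=1) <= caps).all()
            assert (out[pm.entries == 0] == 0).all()


class TestAllocateGrouped:
    def test_trivial_grouping_reduces_to_rank_allocation(self):
        rng = np.random.default_rng(5)
        pm = PermissionMatrix(("M",), ("F",), np.ones((1, 1), dtype=int))
        m_nm = [2, 1]
        f_nm = [1, 1, 1]
        rankings = rng.random((2, 2))
        flat = rank_allocate(["a", "b"], m_nm, rankings, ["x", "y", "z"], f_nm)
        from groupfix.driver import ranked_male_matings

        order = ranked_male_matings(["a", "b"], m_nm, rankings)
        male_matings = [(["a", "b"][i], "M") for i, _ in order]
        female_matings = [(f, "F", False) for f, n in zip("xyz", f_nm) for _ in range(n)]
        ml = allocate_grouped(male_matings, female_matings, np.array([[3]]), pm)
        assert ml.pairs == flat

    def test_block_diagonal_keeps_matings_within_farm(self):
        pm = PermissionMatrix(
            ("Farm 1", "Farm 2", "Farm 3"),
            ("Farm 1", "Farm 2", "Farm 3"),
            np.eye(3, dtype=int),
        )
        male_matings = [(f"s{i}", f"Farm {i}") for i in (2, 1, 3, 2, 1)]
        female_matings = [
            (f"d{k}", f"Farm {g}", False) for k, g in enumerate((1, 1, 2, 2, 3))
        ]
        nmg = np.diag([2, 2, 1])
        ml = allocate_grouped(male_matings, female_matings, nmg, pm)
        for s, d in ml.pairs:
            assert ml.male_group_of[s] == ml.female_group_of[d]
        assert np.array_equal(ml.combination_counts(pm), nmg)

    @pytest.mark.parametrize("seed", range(20))
    def test_counts_always_match_quota(self, seed):
        """Random consistent instances: per-cell pair counts equal Nmg."""
        rng = np.random.default_rng(seed)
        n_mg, n_fg = 3, 3
        entries = (rng.random((n_mg, n_fg)) < 0.6).astype(int)
        entries[rng.integers(n_mg), entries.sum(axis=0) == 0] = 1
        pm = PermissionMatrix(
            tuple(f"M{i}" for i in range(n_mg)),
            tuple(f"F{j}" for j in range(n_fg)),
            entries,
        )
        nmg = rng.integers(0, 4, (n_mg, n_fg)) * entries
        male_matings = [
            (f"s{i}_{c}", f"M{i}")
            for i in range(n_mg)
            for c in range(int(nmg[i].sum()))
        ]
        rng.shuffle(male_matings)
        female_matings = [
            (f"d{j}_{c}", f"F{j}", False)
            for j in range(n_fg)
            for c in range(int(nmg[:, j].sum()))
        ]
        ml = allocate_grouped(male_matings, female_matings, nmg, pm)
        assert np.array_equal(ml.combination_counts(pm), nmg)
        assert ml.illegal_pair_count(pm) == 0


class TestMOET:
    def _problem(self):
        from groupfix.problem import MateSelectionProblem
        from groupfix import Pedigree

        cands = [
            Candidate(id=f"s{i}", sex="M", group="M", index=float(i), maxuse=6)
            for i in range(3)
        ]
        cands.append(
            Candidate(
                id="moet", sex="F", group="F", index=0.0,
                maxuse=3, minuse=3, absminuse=3, moet=True,
            )
        )
        cands += [
            Candidate(id=f"d{j}", sex="F", group="F", index=0.0, maxuse=1)
            for j in range(6)
        ]
        cs = CandidateSet(cands)
        ped = Pedigree([(c.id, None, None) for c in cands])
        pm = PermissionMatrix(("M",), ("F",), np.ones((1, 1), dtype=int))
        return MateSelectionProblem(cs, ped, pm, {"F": 1.0})

    def test_moet_female_keeps_one_sire(self):
        """All matings of a superovulated female must share her first sire."""
        prob = self._problem()
        rng = np.random.default_rng(0)
        for _ in range(50):
            ml = prob.decode(prob.init_population(1, rng)[0], rng)
            sires = {s for s, d in ml.pairs if d == "moet"}
            assert len(sires) == 1
            assert sum(1 for _, d in ml.pairs if d == "moet") == 3
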