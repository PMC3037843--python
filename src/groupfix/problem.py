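"""Genotype layout and full decode: optimiser vector → mating list.

The optimiser only ever sees a flat real vector.  Its segments are:

* ``raw_nm`` — one value per candidate (both sexes), rounded to integers
  at decode time and repaired into legal use counts;
* ``ranking`` — one value per male mating slot, where each male owns
  ``min(maxuse, Nt)`` slots and slot ``r`` is active only while his
  ``Nm > r``; the values drive the order of mate allocation;
* ``raw_r`` — one value in [0, 1] per "Opt" cell of the action-type
  matrix (grouped mode only), driving the group-combination targets.

``mode="groupfix"`` composes the full repair pipeline, so every decoded
mating list is legal with respect to the group permission matrix by
construction.  ``mode="penalty"`` reproduces the baseline strategy it is
compared against: per-candidate constraints are still repaired, but group
quotas are ignored and allocation is permission-blind, so illegal pairs
can occur and must be discouraged through a fitness penalty instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .candidates import CandidateSet
from .driver import fix_use_vector, rank_allocate, ranked_male_matings
from .grouping import (
    ActionTypeMatrix,
    InfeasibleGroupingError,
    MatingList,
    PermissionMatrix,
    allocate_grouped,
    derive_action_types,
    female_group_targets,
    integerize_targets,
    reallocate_male_capacity,
    relative_weights,
)

__all__ = ["GenotypeLayout", "MateSelectionProblem"]

ZERO_ADD_DAMPING = 0.1  # males at Nm = 0 are re-activated with reduced probability


@dataclass(frozen=True)
class GenotypeLayout:
    """Index bookkeeping for the flat genotype vector."""

    n_candidates: int
    n_males: int
    slots_per_male: np.ndarray  # number of ranking slots for each male
    n_ranking: int
    n_raw_r: int

    @property
    def dim(self) -> int:
        return self.n_candidates + self.n_ranking + self.n_raw_r

    def split(self, vector: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a = self.n_candidates
        b = a + self.n_ranking
        return vector[:a], vector[a:b], vector[b:]


class MateSelectionProblem:
    """A mate-selection instance: candidates, pedigree, permissions, targets.

    Parameters
    ----------
    candidates
        The candidate set (both sexes, with groups and use limits).
    pedigree
        Pedigree covering all candidates (used by the objective; kinship
        over the candidate set is computed once and cached).
    permissions
        The group mating permission matrix.  Every candidate group must
        appear among its row (males) or column (females) labels.
    proportions
        Selection proportion per female group; the per-group mating
        target is ``round(candidates × proportion)``.
    mode
        ``"groupfix"`` (repair, always legal) or ``"penalty"`` (baseline,
        permission-blind allocation).
    """

    def __init__(
        self,
        candidates: CandidateSet,
        pedigree,
        permissions: PermissionMatrix,
        proportions: Mapping[str, float],
        mode: str = "groupfix",
        moet_retries: int = 30,
    ):
        if mode not in ("groupfix", "penalty"):
            raise ValueError(f"unknown mode {mode!r}")
        self.candidates = candidates
        self.pedigree = pedigree
        self.pm = permissions
        self.proportions = dict(proportions)
        self.mode = mode
        self.moet_retries = moet_retries

        cs = candidates
        self.male_idx = np.flatnonzero(cs.sex == "M")
        self.female_idx = np.flatnonzero(cs.sex == "F")
        for g in cs.male_groups:
            if g not in permissions.male_groups:
                raise ValueError(f"male group {g!r} missing from permission matrix rows")
        for g in cs.female_groups:
            if g not in permissions.female_groups:
                raise ValueError(
                    f"female group {g!r} missing from permission matrix columns"
                )

        self.action_types: ActionTypeMatrix = derive_action_types(permissions)

        fg_counts = {
            g: int((cs.group[self.female_idx] == g).sum())
            for g in permissions.female_groups
            if (cs.group[self.female_idx] == g).any()
        }
        self.nt_by_fg = female_group_targets(fg_counts, {
            g: self.proportions[g] for g in fg_counts
        })
        # column targets aligned with the permission matrix (0 for empty groups)
        self.nt_female = np.asarray(
            [self.nt_by_fg.get(g, 0) for g in permissions.female_groups],
            dtype=np.int64,
        )
        self.nt = int(self.nt_female.sum())

        # per-male-group member indices and capacity bounds
        self.males_by_group = {
            g: self.male_idx[cs.group[self.male_idx] == g]
            for g in permissions.male_groups
        }
        self.females_by_group = {
            g: self.female_idx[cs.group[self.female_idx] == g]
            for g in permissions.female_groups
        }
        self.max_row = np.asarray(
            [int(cs.maxuse[self.males_by_group[g]].sum()) for g in permissions.male_groups],
            dtype=np.int64,
        )
        lo_used = np.maximum(cs.minuse, 1)
        abs_floor = np.where(cs.absminuse > 0, lo_used, 0)
        self.min_row = np.asarray(
            [int(abs_floor[self.males_by_group[g]].sum()) for g in permissions.male_groups],
            dtype=np.int64,
        )
        # a group's total is 0 or at least its smallest member minimum
        self.gap_floor_row = np.asarray(
            [
                int(lo_used[self.males_by_group[g]].min())
                if len(self.males_by_group[g])
                else 0
                for g in permissions.male_groups
            ],
            dtype=np.int64,
        )

        slots = np.minimum(cs.maxuse[self.male_idx], self.nt).astype(np.int64)
        n_raw_r = self.action_types.n_opt if mode == "groupfix" else 0
        self.layout = GenotypeLayout(
            n_candidates=len(cs),
            n_males=len(self.male_idx),
            slots_per_male=slots,
            n_ranking=int(slots.sum()),
            n_raw_r=n_raw_r,
        )
        self._slot_offsets = np.concatenate([[0], np.cumsum(slots)])

        K = pedigree.kinship_matrix(list(cs.ids))
        self.kinship = K.to_numpy()

    # -- genotype bounds and initialisation ------------------------------

    @property
    def dim(self) -> int:
        return self.layout.dim

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.zeros(self.dim)
        hi = np.ones(self.dim)
        hi[: self.layout.n_candidates] = self.candidates.maxuse.astype(float)
        return lo, hi

    def init_population(self, size: int, rng: np.random.Generator) -> np.ndarray:
        pop = rng.random((size, self.dim))
        nmax = self.candidates.maxuse
        pop[:, : self.layout.n_candidates] = rng.integers(
            0, nmax + 1, size=(size, self.layout.n_candidates)
        ).astype(float)
        return pop

    # -- decoding ---------------------------------------------------------

    def _rankings_matrix(self, ranking_flat: np.ndarray) -> np.ndarray:
        n_m = self.layout.n_males
        width = int(self.layout.slots_per_male.max()) if n_m else 0
        out = np.zeros((n_m, width))
        for k in range(n_m):
            a, b = self._slot_offsets[k], self._slot_offsets[k + 1]
            out[k, : b - a] = ranking_flat[a:b]
        return out

    def _fix_sex_groups(
        self,
        raw_nm: np.ndarray,
        groups: Mapping[str, np.ndarray],
        targets: Mapping[str, int],
        rng: np.random.Generator,
        damping: float,
    ) -> np.ndarray:
        cs = self.candidates
        nm = np.zeros(len(cs), dtype=np.int64)
        for g, members in groups.items():
            nt = int(targets.get(g, 0))
            if len(members) == 0:
                if nt:
                    raise InfeasibleGroupingError(
                        f"group {g!r} has a target of {nt} matings but no candidates"
                    )
                continue
            nm[members] = fix_use_vector(
                raw_nm[members],
                cs.maxuse[members],
                cs.minuse[members],
                cs.absminuse[members],
                nt,
                rng,
                zero_add_damping=damping,
            )
        return nm

    def decode(self, vector: np.ndarray, rng: np.random.Generator) -> MatingList:
        if self.mode == "groupfix":
            last_err: Exception | None = None
            for _ in range(max(1, self.moet_retries)):
                try:
                    return self._decode_groupfix(vector, rng)
                except InfeasibleGroupingError as err:
                    # MOET repair deadlock: retry with fresh decode randomness
                    last_err = err
            raise last_err  # pragma: no cover - needs a pathological MOET setup
        return self._decode_penalty(vector, rng)

    def _decode_groupfix(self, vector: np.ndarray, rng: np.random.Generator) -> MatingList:
        cs = self.candidates
        pm = self.pm
        raw_nm, ranking_flat, raw_r = self.layout.split(np.asarray(vector, dtype=float))

        # 1. female use counts per group
        nm = self._fix_sex_groups(raw_nm, self.females_by_group, self.nt_by_fg, rng, 1.0)

        # 2-3. group-combination targets
        W = relative_weights(self.action_types, raw_r)
        nmg = integerize_targets(W, self.nt_female, rng)

        # 4. male-group capacity repair
        nmg = reallocate_male_capacity(
            nmg, pm, self.max_row, self.min_row, rng, gap_floor=self.gap_floor_row
        )

        # 5. male use counts per group, to the repaired row sums
        row_targets = {g: int(nmg[i].sum()) for i, g in enumerate(pm.male_groups)}
        nm_m = self._fix_sex_groups(
            raw_nm, self.males_by_group, row_targets, rng, ZERO_ADD_DAMPING
        )
        nm = nm + nm_m

        # 6. rank-ordered male matings
        rankings = self._rankings_matrix(ranking_flat)
        order = ranked_male_matings(
            cs.ids[self.male_idx], nm[self.male_idx], rankings
        )
        male_matings = [
            (str(cs.ids[self.male_idx[i]]), str(cs.group[self.male_idx[i]]))
            for i, _ in order
        ]

        # 7. female matings in fixed candidate order
        female_matings = [
            (str(cs.ids[k]), str(cs.group[k]), bool(cs.moet[k]))
            for k in self.female_idx
            for _ in range(int(nm[k]))
        ]

        return allocate_grouped(male_matings, female_matings, nmg, pm)

    def _decode_penalty(self, vector: np.ndarray, rng: np.random.Generator) -> MatingList:
        cs = self.candidates
        raw_nm, ranking_flat, _ = self.layout.split(np.asarray(vector, dtype=float))

        nm_f = self._fix_sex_groups(raw_nm, self.females_by_group, self.nt_by_fg, rng, 1.0)
        nm_m = np.zeros(len(cs), dtype=np.int64)
        nm_m[self.male_idx] = fix_use_vector(
            raw_nm[self.male_idx],
            cs.maxuse[self.male_idx],
            cs.minuse[self.male_idx],
            cs.absminuse[self.male_idx],
            self.nt,
            rng,
            zero_add_damping=ZERO_ADD_DAMPING,
        )
        rankings = self._rankings_matrix(ranking_flat)
        female_ids = [str(cs.ids[k]) for k in self.female_idx]
        pairs = rank_allocate(
            cs.ids[self.male_idx],
            nm_m[self.male_idx],
            rankings,
            female_ids,
            nm_f[self.female_idx],
        )
        return MatingList(
            pairs=pairs,
            male_group_of={str(cs.ids[k]): str(cs.group[k]) for k in self.male_idx},
            female_group_of={str(cs.ids[k]): str(cs.group[k]) for k in self.female_idx},
            group_targets=None,
            permission=self.pm,
        )
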