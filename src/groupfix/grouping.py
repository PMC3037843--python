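"""Group-permission machinery: the repair-by-construction core.

A binary permission matrix (male groups × female groups) declares which
group combinations may be mated.  Rather than penalising solutions that
break it, the decoder *builds* legality in:

1. :func:`derive_action_types` classifies every permitted cell.  A column
   with a single permitted male group is fixed (weight 1).  Otherwise all
   permitted rows except the last carry an optimised raw weight ``R`` in
   [0, 1], and the last male group — if permitted — has its weight
   *calculated* as the complement, so one fewer variable per column needs
   optimising.
2. :func:`relative_weights` maps raw weights ``R`` to relative weights
   ``W`` that always sum to one down each column.  With the last male
   group permitted, ``k`` = (number of positive ``R``) + 1 and the
   denominator ``D = 1 + (k − 2) ΣR / (k − 1)`` gives ``W_i = R_i / D``
   and ``W_last = 1 − ΣR / D``.  This puts the calculated last-row weight
   at the column average when the positive raw weights average 0.5, at 1
   when all ``R`` are zero, and at 0 when some ``R`` is 1 and the rest 0.
3. :func:`integerize_targets` turns ``W × Nt`` into integer per-cell
   mating targets (floor plus ``W``-proportional stochastic distribution
   of the remainder) and :func:`reallocate_male_capacity` repairs any
   male-group totals that exceed the group's summed ``maxuse`` (or fall
   below its summed unconditional minimum).
4. :func:`allocate_grouped` walks male matings in rank order and gives
   each the first unallocated female mating that is permission-legal and
   still has quota in its group-combination cell; MOET females are then
   repaired so that all their matings share the sire of their first.

Every mating list produced this way is legal by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PermissionMatrix",
    "ActionType",
    "InfeasibleGroupingError",
    "derive_action_types",
    "relative_weights",
    "female_group_targets",
    "integerize_targets",
    "reallocate_male_capacity",
    "allocate_grouped",
    "MatingList",
    "read_permission_csv",
    "write_permission_csv",
]

log = logging.getLogger(__name__)


class InfeasibleGroupingError(ValueError):
    """The permission matrix or capacities make the targets unreachable."""


# Action types per permitted cell
class ActionType:
    NONE = "."       # permission = 0
    FIXED_ONE = "1"  # only permitted male group in its column; W = 1
    OPT = "Opt"      # raw weight R to be optimised
    CALC = "Calc"    # last male group, weight calculated as complement


@dataclass(frozen=True)
class PermissionMatrix:
    """Binary male-group × female-group mating legality."""

    male_groups: tuple[str, ...]
    female_groups: tuple[str, ...]
    entries: np.ndarray  # int {0,1}, shape (n_mg, n_fg)

    def __post_init__(self):
        e = np.asarray(self.entries, dtype=np.int64)
        if e.shape != (len(self.male_groups), len(self.female_groups)):
            raise ValueError("permission matrix shape does not match group labels")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("permission matrix entries must be 0 or 1")
        object.__setattr__(self, "entries", e)
        for j, fg in enumerate(self.female_groups):
            if e[:, j].sum() == 0:
                raise InfeasibleGroupingError(
                    f"female group {fg!r} has no permitted male group"
                )

    @property
    def n_mg(self) -> int:
        return len(self.male_groups)

    @property
    def n_fg(self) -> int:
        return len(self.female_groups)

    def permitted(self, mg: str, fg: str) -> bool:
        i = self.male_groups.index(mg)
        j = self.female_groups.index(fg)
        return bool(self.entries[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, index=list(self.male_groups), columns=list(self.female_groups)
        )


@dataclass(frozen=True)
class ActionTypeMatrix:
    pm: PermissionMatrix
    entries: np.ndarray  # dtype=object over ActionType values
    opt_cells: tuple[tuple[int, int], ...]  # genotype layout: ordered (i, j)

    @property
    def n_opt(self) -> int:
        return len(self.opt_cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries,
            index=list(self.pm.male_groups),
            columns=list(self.pm.female_groups),
        )


def derive_action_types(pm: PermissionMatrix) -> ActionTypeMatrix:
    """Classify each cell and fix the ordered layout of raw weights.

    The number of raw weights to optimise is between 0 (every column has
    a single permitted male group) and ``n_fg * (n_mg - 1)`` (everything
    permitted).  Cells are laid out column by column, top to bottom.
    """
    e = pm.entries
    at = np.full(e.shape, ActionType.NONE, dtype=object)
    opt_cells: list[tuple[int, int]] = []
    last = pm.n_mg - 1
    for j in range(pm.n_fg):
        rows = np.flatnonzero(e[:, j])
        if len(rows) == 1:
            at[rows[0], j] = ActionType.FIXED_ONE
            continue
        for i in rows:
            if i == last:
                at[i, j] = ActionType.CALC
            else:
                at[i, j] = ActionType.OPT
                opt_cells.append((int(i), j))
    return ActionTypeMatrix(pm=pm, entries=at, opt_cells=tuple(opt_cells))


def relative_weights(
    at: ActionTypeMatrix, raw_r: Sequence[float]
) -> np.ndarray:
    """Raw weights ``R`` (one per Opt cell, truncated to [0, 1]) → ``W``.

    Returns the full relative-weight matrix; each column sums to 1 over
    its permitted cells and is exactly 0 elsewhere.  When the last male
    group is *not* permitted the column is a plain normalisation
    ``W = R / ΣR`` (uniform over permitted cells if all ``R`` are 0 — a
    degenerate column, logged as a warning).
    """
    pm = at.pm
    raw = np.clip(np.asarray(raw_r, dtype=float), 0.0, 1.0)
    if len(raw) != at.n_opt:
        raise ValueError(f"expected {at.n_opt} raw weights, got {len(raw)}")
    R = np.zeros(pm.entries.shape)
    for v, (i, j) in zip(raw, at.opt_cells):
        R[i, j] = v
    W = np.zeros(pm.entries.shape)
    last = pm.n_mg - 1
    for j in range(pm.n_fg):
        rows = np.flatnonzero(pm.entries[:, j])
        if len(rows) == 1:
            W[rows[0], j] = 1.0
            continue
        opt_rows = rows[rows != last]
        s = float(R[opt_rows, j].sum())
        if pm.entries[last, j]:
            k = int((R[opt_rows, j] > 0).sum()) + 1
            d = 1.0 if s == 0.0 else 1.0 + (k - 2) * s / (k - 1)
            W[opt_rows, j] = R[opt_rows, j] / d
            W[last, j] = 1.0 - s / d
        else:
            if s == 0.0:
                log.warning(
                    "all raw weights zero for female group %r with last male "
                    "group not permitted; falling back to uniform weights",
                    pm.female_groups[j],
                )
                W[opt_rows, j] = 1.0 / len(opt_rows)
            else:
                W[opt_rows, j] = R[opt_rows, j] / s
    return W


def female_group_targets(
    counts: Mapping[str, int], proportions: Mapping[str, float]
) -> dict[str, int]:
    """Target matings per female group: round(candidates × proportion)."""
    targets: dict[str, int] = {}
    for g, n in counts.items():
        try:
            p = proportions[g]
        except KeyError:
            raise KeyError(f"no selection proportion declared for female group {g!r}")
        if not (0.0 < p <= 1.0):
            raise ValueError(f"selection proportion for {g!r} must be in (0, 1]")
        if n == 0:
            raise InfeasibleGroupingError(
                f"female group {g!r} has no candidates but a positive proportion"
            )
        targets[g] = int(np.floor(n * p + 0.5))
    return targets


def integerize_targets(
    W: np.ndarray,
    nt_female: Sequence[int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Integer per-cell targets ``Nmg`` with exact column sums.

    ``Nmg = floor(W · Nt_j)`` leaves a remainder of fewer than the number
    of positive-weight rows; the leftover matings are assigned one at a
    time to rows drawn with probability proportional to ``W``, so cells
    with ``W = 0`` never receive a mating.
    """
    W = np.asarray(W, dtype=float)
    nmg = np.zeros(W.shape, dtype=np.int64)
    for j, nt in enumerate(nt_female):
        col = W[:, j]
        base = np.floor(col * nt).astype(np.int64)
        nmg[:, j] = base
        rem = int(nt - base.sum())
        if rem > 0:
            pos = np.flatnonzero(col > 0)
            p = col[pos] / col[pos].sum()
            extra = rng.choice(pos, size=rem, replace=True, p=p)
            np.add.at(nmg[:, j], extra, 1)
    return nmg


def reallocate_male_capacity(
    nmg: np.ndarray,
    pm: PermissionMatrix,
    max_row: Sequence[int],
    min_row: Sequence[int],
    rng: np.random.Generator,
    attempts_factor: int = 200,
    gap_floor: Sequence[int] | None = None,
) -> np.ndarray:
    """Repair male-group row sums to within their capacity bounds.

    Moves one mating at a time from a randomly chosen row to a random
    partner row, within a female group permitted at both ends, whenever a
    row exceeds its summed ``maxuse`` or falls below its summed
    unconditional minimum.  A move is kept when it reduces the total
    constraint violation, and kept with probability ½ when it leaves the
    violation unchanged — such sideways moves let stock drift towards
    rows with slack when the direct recipient is itself full.  Column
    sums never change and forbidden cells stay zero.  Gives up after
    ``attempts_factor × n_mg × n_fg`` proposals, which signals capacities
    that are structurally incompatible with the permission matrix.

    ``gap_floor`` (optional, one value per male group) marks a forbidden
    zone ``(0, gap_floor)`` for each row sum: a group whose members all
    carry a conditional minimum use cannot collectively perform fewer
    matings than the smallest such minimum, so row totals inside the gap
    are treated as violations and pushed to either side.
    """
    nmg = np.array(nmg, dtype=np.int64, copy=True)
    max_row = np.asarray(max_row, dtype=np.int64)
    min_row = np.asarray(min_row, dtype=np.int64)
    nt_total = int(nmg.sum())
    if nt_total > int(max_row.sum()):
        raise InfeasibleGroupingError(
            f"total matings {nt_total} exceed summed male capacity {int(max_row.sum())}"
        )
    if nt_total < int(min_row.sum()):
        raise InfeasibleGroupingError(
            f"total matings {nt_total} below summed male unconditional minimum "
            f"{int(min_row.sum())}"
        )
    n_mg, n_fg = nmg.shape
    rows = nmg.sum(axis=1)
    gap = (
        np.zeros(n_mg, dtype=np.int64)
        if gap_floor is None
        else np.asarray(gap_floor, dtype=np.int64)
    )

    def violation(r):
        v = int(np.maximum(r - max_row, 0).sum() + np.maximum(min_row - r, 0).sum())
        in_gap = (r > 0) & (r < gap)
        v += int(np.minimum(r, gap - r)[in_gap].sum())
        return v

    pot = violation(rows)
    budget = attempts_factor * n_mg * n_fg
    for _ in range(budget):
        if pot == 0:
            return nmg
        j = int(rng.integers(n_fg))
        permitted = np.flatnonzero(pm.entries[:, j] == 1)
        sources = permitted[nmg[permitted, j] > 0]
        if len(sources) == 0 or len(permitted) < 2:
            continue
        src = int(rng.choice(sources))
        dst = int(rng.choice(permitted[permitted != src]))
        rows[src] -= 1
        rows[dst] += 1
        new_pot = violation(rows)
        if new_pot < pot or (new_pot == pot and rng.random() < 0.5):
            nmg[src, j] -= 1
            nmg[dst, j] += 1
            pot = new_pot
        else:
            rows[src] += 1
            rows[dst] -= 1
    raise InfeasibleGroupingError(
        "male-group capacity reallocation did not converge within "
        f"{budget} proposals; check group capacities against the permission matrix"
    )


@dataclass
class MatingList:
    """Ordered sire × dam pairs with group bookkeeping."""

    pairs: list[tuple[str, str]]
    male_group_of: dict[str, str] = field(default_factory=dict)
    female_group_of: dict[str, str] = field(default_factory=dict)
    group_targets: np.ndarray | None = None  # Nmg actually used, if grouped
    permission: PermissionMatrix | None = None

    def __len__(self) -> int:
        return len(self.pairs)

    def use_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s, d in self.pairs:
            counts[s] = counts.get(s, 0) + 1
            counts[d] = counts.get(d, 0) + 1
        return counts

    def combination_counts(self, pm: PermissionMatrix) -> np.ndarray:
        out = np.zeros((pm.n_mg, pm.n_fg), dtype=np.int64)
        mg_index = {g: i for i, g in enumerate(pm.male_groups)}
        fg_index = {g: j for j, g in enumerate(pm.female_groups)}
        for s, d in self.pairs:
            out[mg_index[self.male_group_of[s]], fg_index[self.female_group_of[d]]] += 1
        return out

    def illegal_pair_count(self, pm: PermissionMatrix) -> int:
        counts = self.combination_counts(pm)
        return int(counts[pm.entries == 0].sum())

    def to_frame(self, pedigree=None) -> pd.DataFrame:
        df = pd.DataFrame(self.pairs, columns=["sire", "dam"])
        df["male_group"] = [self.male_group_of[s] for s, _ in self.pairs]
        df["female_group"] = [self.female_group_of[d] for _, d in self.pairs]
        if pedigree is not None:
            parents = sorted({a for p in self.pairs for a in p})
            K = pedigree.kinship_matrix(parents)
            df["progeny_inbreeding"] = [K.loc[s, d] for s, d in self.pairs]
        return df


def allocate_grouped(
    male_matings: Sequence[tuple[str, str]],
    female_matings: Sequence[tuple[str, str, bool]],
    nmg: np.ndarray,
    pm: PermissionMatrix,
) -> MatingList:
    """Allocate rank-ordered male matings under group quotas.

    ``male_matings`` are ``(male id, male group)`` in rank order;
    ``female_matings`` are ``(female id, female group, moet flag)`` in the
    fixed female order, one entry per mating.  Each male mating takes the
    first unallocated female mating whose group combination is permitted
    and still below its ``nmg`` quota — consistent counts guarantee the
    walk completes with every cell exactly on target.

    MOET females are repaired afterwards: every mating of a MOET female is
    reassigned to the sire of her first-allocated mating, rebalancing sire
    use by swapping with a non-MOET pair in the same female group.  If no
    such swap exists the deadlock is reported via ``InfeasibleGroupingError``
    (callers retry the decode with fresh randomness).
    """
    mg_index = {g: i for i, g in enumerate(pm.male_groups)}
    fg_index = {g: j for j, g in enumerate(pm.female_groups)}
    remaining = np.array(nmg, dtype=np.int64, copy=True)
    n_f = len(female_matings)
    taken = np.zeros(n_f, dtype=bool)
    fg_idx = np.asarray([fg_index[fg] for _, fg, _ in female_matings], dtype=np.int64)
    assigned: list[tuple[int, int]] = []  # (male mating position, female mating position)
    scan_start = 0
    for pos_m, (mid, mgrp) in enumerate(male_matings):
        i = mg_index[mgrp]
        found = -1
        for k in range(scan_start, n_f):
            if taken[k]:
                continue
            j = fg_idx[k]
            if pm.entries[i, j] and remaining[i, j] > 0:
                found = k
                break
        if found < 0:
            raise AssertionError(
                "grouped allocation deadlock: inconsistent counts upstream "
                f"(male mating {pos_m} of group {mgrp!r})"
            )
        taken[found] = True
        remaining[i, fg_idx[found]] -= 1
        assigned.append((pos_m, found))
        while scan_start < n_f and taken[scan_start]:
            scan_start += 1

    sire_of = {k: male_matings[pm_][0] for pm_, k in assigned}
    mgrp_of_slot = {k: male_matings[pm_][1] for pm_, k in assigned}

    # MOET repair: all matings of a MOET female share her first-assigned sire
    by_female: dict[str, list[int]] = {}
    for k, (fid, _, _) in enumerate(female_matings):
        by_female.setdefault(fid, []).append(k)
    for fid, slots in by_female.items():
        if not female_matings[slots[0]][2] or len(slots) < 2:
            continue
        first = min(slots, key=lambda k: [p for p, kk in assigned if kk == k][0])
        target_sire = sire_of[first]
        target_mgrp = mgrp_of_slot[first]
        fg = fg_index[female_matings[first][1]]
        for k in slots:
            if k == first or sire_of[k] == target_sire:
                continue
            # swap with a pair of the target sire in the same female group
            donor = None
            for k2, s2 in sire_of.items():
                if (
                    s2 == target_sire
                    and k2 not in slots
                    and fg_idx[k2] == fg
                    and not female_matings[k2][2]
                ):
                    donor = k2
                    break
            if donor is None:
                raise InfeasibleGroupingError(
                    f"cannot honour MOET same-sire rule for female {fid!r}: "
                    "no compatible swap partner in her female group"
                )
            sire_of[k], sire_of[donor] = sire_of[donor], sire_of[k]
            mgrp_of_slot[k], mgrp_of_slot[donor] = mgrp_of_slot[donor], mgrp_of_slot[k]

    pairs: list[tuple[str, str]] = []
    male_group_of: dict[str, str] = {}
    female_group_of: dict[str, str] = {}
    for pos_m, k in sorted(assigned):
        fid, fgrp, _ = female_matings[k]
        sid = sire_of[k]
        pairs.append((sid, fid))
        male_group_of[sid] = mgrp_of_slot[k]
        female_group_of[fid] = fgrp
    for mid, mgrp in male_matings:
        male_group_of.setdefault(mid, mgrp)
    return MatingList(
        pairs=pairs,
        male_group_of=male_group_of,
        female_group_of=female_group_of,
        group_targets=np.array(nmg, dtype=np.int64, copy=True),
        permission=pm,
    )


def read_permission_csv(path) -> PermissionMatrix:
    """Permission CSV: first row female group labels, first column male labels."""
    df = pd.read_csv(path, index_col=0)
    return PermissionMatrix(
        male_groups=tuple(str(g) for g in df.index),
        female_groups=tuple(str(g) for g in df.columns),
        entries=df.to_numpy(dtype=np.int64),
    )


def write_permission_csv(pm: PermissionMatrix, path) -> None:
    pm.to_frame().to_csv(path)
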