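"""The ungrouped mate-selection driver.

Two repair steps translate an optimiser's raw variables into a legal
solution without ever rejecting it:

* :func:`fix_use_vector` coerces raw per-candidate mating counts into
  counts that respect ``maxuse`` / ``minuse`` / ``absminuse`` and sum to
  the targeted total number of matings ``Nt``;
* :func:`rank_allocate` turns fixed male and female counts plus one
  ranking value per male mating into an explicit mating list: male
  matings are visited in rank order (largest ranking value first) and
  each takes the leftmost still-unallocated female mating.

Row and column mating counts of the result always match the fixed use
vectors, so per-candidate constraints cannot be broken by construction.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "FeasibilityError",
    "snap_to_use_limits",
    "fix_use_vector",
    "ranked_male_matings",
    "rank_allocate",
]


class FeasibilityError(ValueError):
    """Targeted matings cannot be met under the declared use limits."""


def snap_to_use_limits(
    raw: Sequence[int],
    maxuse: Sequence[int],
    minuse: Sequence[int],
    absminuse: Sequence[int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Coerce raw counts into the per-candidate limits (no total yet).

    A value strictly between 0 and ``minuse`` moves to whichever end is
    closer with linearly graded probability — a raw value of 2 under
    ``minuse = 5`` goes up to 5 with probability 2/5 and down to 0 with
    probability 3/5.  Values above ``maxuse`` are clamped down; candidates
    with a positive ``absminuse`` are forced into use at ``minuse`` or
    above.
    """
    raw = np.asarray(raw)
    maxu = np.asarray(maxuse, dtype=np.int64)
    minu = np.asarray(minuse, dtype=np.int64)
    absmin = np.asarray(absminuse, dtype=np.int64)
    lo_used = np.maximum(minu, 1)
    nm = np.maximum(np.rint(raw).astype(np.int64), 0)
    between = (nm > 0) & (nm < lo_used) & (absmin == 0)
    if between.any():
        p_up = nm[between] / lo_used[between]
        up = rng.random(int(between.sum())) < p_up
        nm[between] = np.where(up, lo_used[between], 0)
    nm = np.minimum(nm, maxu)
    must_use = absmin > 0
    nm[must_use] = np.maximum(nm[must_use], lo_used[must_use])
    return nm


def fix_use_vector(
    raw: Sequence[int],
    maxuse: Sequence[int],
    minuse: Sequence[int],
    absminuse: Sequence[int],
    nt: int,
    rng: np.random.Generator,
    zero_add_damping: float = 1.0,
    max_sweeps: int = 2000,
) -> np.ndarray:
    """Repair raw mating counts into a legal use vector summing to ``nt``.

    Raw values are first made non-negative; a value strictly between 0 and
    ``minuse`` is snapped to 0 or to ``minuse`` with probability linear in
    closeness (value 2 under ``minuse`` 5 goes up with probability 2/5);
    values above ``maxuse`` or below an unconditional floor are clamped.
    An iterative loop then picks a random candidate and adds or subtracts
    one mating (jumping across the forbidden ``(0, minuse)`` gap where
    needed) until the total equals ``nt``; any step that violates a
    constraint or moves the total away from ``nt`` is reversed.

    ``zero_add_damping`` scales down the probability of adding a mating to
    a candidate currently at ``Nm = 0`` — an optimal solution typically
    leaves many males unused, so discouraging re-activation speeds
    convergence.
    """
    raw = np.asarray(raw)
    maxu = np.asarray(maxuse, dtype=np.int64)
    minu = np.asarray(minuse, dtype=np.int64)
    absmin = np.asarray(absminuse, dtype=np.int64)
    n = len(raw)
    if not (len(maxu) == len(minu) == len(absmin) == n):
        raise ValueError("use-limit arrays must match the number of candidates")
    # floor of the "used" state; absminuse > 0 forbids the zero state
    lo_used = np.maximum(minu, 1)
    lower_bound = np.where(absmin > 0, lo_used, 0).sum()
    if not (lower_bound <= nt <= maxu.sum()):
        raise FeasibilityError(
            f"target matings nt={nt} outside feasible range "
            f"[{lower_bound}, {int(maxu.sum())}] for this candidate list"
        )

    nm = snap_to_use_limits(raw, maxu, minu, absmin, rng)

    total = int(nm.sum())
    max_iter = max_sweeps * n + 50 * abs(nt - total) + 1000
    stall_after = max_iter // 2
    for it in range(max_iter):
        if total == nt:
            return nm
        i = int(rng.integers(n))
        cur = nm[i]
        if total < nt:
            if cur >= maxu[i]:
                continue
            if cur == 0:
                if zero_add_damping < 1.0 and rng.random() >= zero_add_damping:
                    continue
                new = int(lo_used[i])
            else:
                new = cur + 1
            if new > maxu[i]:
                continue
        else:
            if cur == 0:
                continue
            if cur - 1 >= lo_used[i]:
                new = cur - 1
            elif absmin[i] == 0:
                new = 0
            else:
                continue
        new_total = total - cur + new
        gain = abs(nt - total) - abs(nt - new_total)
        # minuse gaps force jumps that may not shrink the gap by themselves;
        # tolerate sideways moves (and, if stalled, backward ones) so the
        # walk can cross them
        if gain > 0 or (gain == 0 and rng.random() < 0.5) or (
            gain < 0 and it > stall_after and rng.random() < 0.25
        ):
            nm[i] = new
            total = new_total
    raise FeasibilityError(
        f"use-vector adjustment did not reach nt={nt} (stuck at {total}); "
        "the minuse gaps of this candidate list may make the target unreachable"
    )


def ranked_male_matings(
    male_ids: Sequence[str],
    male_nm: Sequence[int],
    rankings: np.ndarray,
) -> list[tuple[int, int]]:
    """Order male matings by their ranking criterion.

    ``rankings`` is a 2-D array, one row per male, one column per mating
    slot; slot ``r`` of male ``i`` is in use when ``nm_i > r``.  Returns
    ``(male position, slot)`` pairs sorted by descending ranking value
    (rank 1 = largest), ties broken by male input order then slot index.
    """
    nm = np.asarray(male_nm, dtype=np.int64)
    entries: list[tuple[float, int, int]] = []
    for i in range(len(nm)):
        for r in range(int(nm[i])):
            entries.append((-float(rankings[i, r]), i, r))
    entries.sort()
    return [(i, r) for _, i, r in entries]


def rank_allocate(
    male_ids: Sequence[str],
    male_nm: Sequence[int],
    rankings: np.ndarray,
    female_ids: Sequence[str],
    female_nm: Sequence[int],
) -> list[tuple[str, str]]:
    """Allocate ranked male matings to female matings, left to right.

    Female matings are laid out in candidate order (a female with
    ``Nm = k`` occupies ``k`` consecutive positions).  The first-ranked
    male mating takes the first female mating, the second-ranked the
    next, and so on.  Total male and female matings must agree.
    """
    m_nm = np.asarray(male_nm, dtype=np.int64)
    f_nm = np.asarray(female_nm, dtype=np.int64)
    if int(m_nm.sum()) != int(f_nm.sum()):
        raise ValueError(
            f"male matings ({int(m_nm.sum())}) != female matings ({int(f_nm.sum())})"
        )
    order = ranked_male_matings(male_ids, m_nm, rankings)
    female_slots = [f for j, f in enumerate(female_ids) for _ in range(int(f_nm[j]))]
    return [(str(male_ids[i]), str(female_slots[k])) for k, (i, _) in enumerate(order)]
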