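"""Pedigree storage, inbreeding coefficients and pairwise kinship (coancestry).

The mate-selection objective needs two quantities from the pedigree:

* Wright's inbreeding coefficient ``F`` for every animal — the probability
  that the two alleles an animal carries at a locus are identical by
  descent; and
* the kinship (coancestry) ``f(a, b)`` between two animals — the
  probability that one allele sampled from each is identical by descent,
  which equals the inbreeding coefficient of a prospective offspring of
  ``a × b``.

Two independent algorithms are implemented and cross-checked in the test
suite: the tabular method builds the additive relationship matrix ``A``
row by row in topological order (kinship is ``A / 2``), while
:meth:`Pedigree.inbreeding` uses a Meuwissen–Luo style ancestor-tracing
recursion that never materialises ``A``.  Candidate sets in practical
mate-selection runs are a few thousand animals, so the O(n²) tabular
method is exact and cheap at that scale.

Unknown parents are treated as unique, unrelated, non-inbred founders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "PedigreeError", "read_pedigree_csv", "write_pedigree_csv"]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate or unknown id)."""


_MISSING = ("", "0", ".", "NA", "na", "nan", "None")


def _norm_parent(value) -> str | None:
    if value is None:
        return None
    s = str(value).strip()
    if s in _MISSING:
        return None
    return s


@dataclass
class Pedigree:
    """Parent map over opaque string ids.

    Parameters
    ----------
    records
        Iterable of ``(animal, sire, dam)`` triples.  ``sire``/``dam`` may
        be ``None`` (or one of ``"", "0", "."``) for an unknown founder
        parent.  A parent named but never listed as an animal is treated
        as an unknown founder as well, i.e. unrelated and non-inbred.
    """

    records: Sequence[tuple[str, str | None, str | None]]
    _ids: list[str] = field(init=False, repr=False)
    _sire: np.ndarray = field(init=False, repr=False)
    _dam: np.ndarray = field(init=False, repr=False)
    _index: dict[str, int] = field(init=False, repr=False)
    _topo: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids: list[str] = []
        index: dict[str, int] = {}
        for rec in self.records:
            a = str(rec[0]).strip()
            if a in index:
                raise PedigreeError(f"duplicate animal id {a!r}")
            if _norm_parent(a) is None:
                raise PedigreeError(f"invalid animal id {rec[0]!r}")
            index[a] = len(ids)
            ids.append(a)
        # parents named but never listed become founder records, so two
        # animals naming the same parent share that ancestor
        for rec in self.records:
            for p in (rec[1], rec[2]):
                p = _norm_parent(p)
                if p is not None and p not in index:
                    index[p] = len(ids)
                    ids.append(p)
        n = len(ids)
        sire = np.full(n, -1, dtype=np.int64)
        dam = np.full(n, -1, dtype=np.int64)
        for rec in self.records:
            i = index[str(rec[0]).strip()]
            for arr, p in ((sire, rec[1]), (dam, rec[2])):
                p = _norm_parent(p)
                if p is not None and p in index:
                    arr[i] = index[p]
        self._ids = ids
        self._index = index
        self._sire = sire
        self._dam = dam
        self._topo = self._toposort()

    # -- structure -------------------------------------------------------

    def _toposort(self) -> np.ndarray:
        """Ancestors-before-descendants order; raises on a cycle."""
        n = len(self._ids)
        state = np.zeros(n, dtype=np.int8)  # 0 unvisited, 1 in stack, 2 done
        order: list[int] = []
        for start in range(n):
            if state[start]:
                continue
            stack: list[tuple[int, int]] = [(start, 0)]
            while stack:
                node, phase = stack.pop()
                if phase == 0:
                    if state[node] == 2:
                        continue
                    if state[node] == 1:
                        continue
                    state[node] = 1
                    stack.append((node, 1))
                    for p in (self._sire[node], self._dam[node]):
                        if p >= 0:
                            if state[p] == 1:
                                raise PedigreeError(
                                    "pedigree cycle involving "
                                    f"{self._ids[p]!r} and {self._ids[node]!r}"
                                )
                            if state[p] == 0:
                                stack.append((p, 0))
                else:
                    state[node] = 2
                    order.append(node)
        return np.asarray(order, dtype=np.int64)

    def __len__(self) -> int:
        return len(self._ids)

    def __contains__(self, animal: str) -> bool:
        return str(animal) in self._index

    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    def parents(self, animal: str) -> tuple[str | None, str | None]:
        i = self._require(animal)
        s, d = self._sire[i], self._dam[i]
        return (self._ids[s] if s >= 0 else None, self._ids[d] if d >= 0 else None)

    def _require(self, animal: str) -> int:
        try:
            return self._index[str(animal)]
        except KeyError:
            raise KeyError(f"animal {animal!r} not in pedigree") from None

    def _ancestor_closure(self, idx: np.ndarray) -> np.ndarray:
        """Indices of idx plus all their ancestors, in internal order."""
        seen = np.zeros(len(self._ids), dtype=bool)
        stack = list(idx)
        while stack:
            i = stack.pop()
            if seen[i]:
                continue
            seen[i] = True
            for p in (self._sire[i], self._dam[i]):
                if p >= 0 and not seen[p]:
                    stack.append(p)
        return np.flatnonzero(seen)

    # -- inbreeding (Meuwissen–Luo style ancestor tracing) ---------------

    def inbreeding(self) -> dict[str, float]:
        """Wright's inbreeding coefficient for every animal.

        Meuwissen–Luo style ancestor tracing: for a non-founder ``i`` with
        parents ``s, d``, a virtual offspring ``x`` of ``s × d`` satisfies
        ``a_xx = 1 + F_i = D_x + Σ_j L_j² D_j`` where the sum runs over the
        ancestors ``j`` of the parent pair, ``L`` are path coefficients
        accumulated youngest-first (seeded with ``L_s = L_d = 1/2``) and
        ``D_j = 0.5 − 0.25 (F_sire(j) + F_dam(j))`` is the Mendelian-sampling
        term (1 for founders, ``0.75 − 0.25 F_p`` with one known parent).
        Hence ``F_i = Σ_j L_j² D_j − 0.5 − 0.25 (F_s + F_d)``.
        Founders and animals with any unknown parent get 0.
        """
        import heapq

        n = len(self._ids)
        F = np.zeros(n)
        D = np.zeros(n)
        sire, dam = self._sire, self._dam
        rank = self._topo_rank
        for i in self._topo:
            s, d = sire[i], dam[i]
            fs = F[s] if s >= 0 else 0.0
            fd = F[d] if d >= 0 else 0.0
            D[i] = 1.0 - 0.25 * ((1.0 + fs) * (s >= 0) + (1.0 + fd) * (d >= 0))
            if s < 0 or d < 0:
                continue
            coeff: dict[int, float] = {}
            for p in (s, d):
                coeff[p] = coeff.get(p, 0.0) + 0.5
            heap = [(-rank[j], int(j)) for j in coeff]
            heapq.heapify(heap)
            seen: set[int] = set()
            acc = 0.0
            while heap:
                _, j = heapq.heappop(heap)
                if j in seen:
                    continue
                seen.add(j)
                lj = coeff[j]
                acc += lj * lj * D[j]
                for p in (sire[j], dam[j]):
                    if p >= 0:
                        if p not in coeff:
                            coeff[int(p)] = 0.0
                            heapq.heappush(heap, (-rank[p], int(p)))
                        coeff[int(p)] += 0.5 * lj
            F[i] = acc - 0.5 - 0.25 * (fs + fd)
        return {self._ids[i]: float(F[i]) for i in range(n)}

    @property
    def _topo_rank(self) -> np.ndarray:
        r = getattr(self, "_topo_rank_cache", None)
        if r is None:
            r = np.empty(len(self._ids), dtype=np.int64)
            r[self._topo] = np.arange(len(self._topo))
            self._topo_rank_cache = r
        return r

    # -- kinship (tabular method) ----------------------------------------

    def kinship_matrix(self, subset: Sequence[str] | None = None) -> pd.DataFrame:
        """Pairwise kinship for ``subset`` (default: all animals).

        Builds the additive relationship matrix over the ancestor closure
        of the subset with the tabular method and returns ``A/2`` sliced
        to the requested animals, as a labelled DataFrame.
        """
        if subset is None:
            subset_idx = np.arange(len(self._ids))
        else:
            subset_idx = np.asarray([self._require(a) for a in subset])
        closure = self._ancestor_closure(subset_idx)
        # order closure topologically
        order = closure[np.argsort(self._topo_rank[closure])]
        pos = {int(g): k for k, g in enumerate(order)}
        m = len(order)
        A = np.zeros((m, m))
        for k, g in enumerate(order):
            s, d = self._sire[g], self._dam[g]
            ks = pos.get(int(s), -1)
            kd = pos.get(int(d), -1)
            row = np.zeros(k)
            if ks >= 0:
                row += 0.5 * A[ks, :k]
            if kd >= 0:
                row += 0.5 * A[kd, :k]
            A[k, :k] = row
            A[:k, k] = row
            A[k, k] = 1.0 + (0.5 * A[ks, kd] if ks >= 0 and kd >= 0 else 0.0)
        sel = np.asarray([pos[int(i)] for i in subset_idx])
        labels = [self._ids[i] for i in subset_idx]
        return pd.DataFrame(0.5 * A[np.ix_(sel, sel)], index=labels, columns=labels)

    def kinship(self, a: str, b: str) -> float:
        """Coancestry f(a, b); ``f(a, a) = (1 + F_a)/2``."""
        ia, ib = self._require(a), self._require(b)
        if ia == ib:
            K = self.kinship_matrix([a])
            return float(K.iloc[0, 0])
        K = self.kinship_matrix([a, b])
        return float(K.iloc[0, 1])

    # -- convenience -----------------------------------------------------

    def inbreeding_array(self, ids: Sequence[str]) -> np.ndarray:
        F = self.inbreeding()
        return np.asarray([F[str(a)] for a in ids])


def read_pedigree_csv(path) -> Pedigree:
    """Read a pedigree CSV with header ``id,sire,dam``; 0/empty = unknown."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    for c in ("id", "sire", "dam"):
        if c not in cols:
            raise PedigreeError(f"pedigree CSV missing column {c!r}")
    return Pedigree(list(zip(df["id"], df["sire"], df["dam"])))


def write_pedigree_csv(ped: Pedigree, path) -> None:
    rows = []
    for a in ped.ids:
        s, d = ped.parents(a)
        rows.append((a, s or "0", d or "0"))
    pd.DataFrame(rows, columns=["id", "sire", "dam"]).to_csv(path, index=False)
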