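"""Selection candidates: ids, sex, group, merit index and use limits.

Each candidate carries three use limits on ``Nm``, its number of matings
in a solution:

* ``maxuse`` — hard upper limit (1 for natural-mating females, a few tens
  for natural-mating sires, very large for AI sires);
* ``minuse`` — minimum *given the animal is used at all* (e.g. a breeder
  may refuse natural-mating groups smaller than 15 cows), so ``Nm = 0``
  remains allowed;
* ``absminuse`` — unconditional minimum (e.g. remaining semen doses that
  must all be used), usually 0.

``moet`` flags females whose matings arise from superovulation with
in-vivo fertilisation: all of a MOET female's matings must share one sire.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["Candidate", "CandidateSet", "read_candidates_csv", "write_candidates_csv"]

_SEX = {"m": "M", "male": "M", "f": "F", "female": "F"}


@dataclass(frozen=True)
class Candidate:
    id: str
    sex: str  # "M" or "F"
    group: str
    index: float
    maxuse: int
    minuse: int = 1
    absminuse: int = 0
    moet: bool = False

    def __post_init__(self):
        sex = _SEX.get(str(self.sex).strip().lower())
        if sex is None:
            raise ValueError(f"candidate {self.id!r}: sex must be male/female, got {self.sex!r}")
        object.__setattr__(self, "sex", sex)
        if self.maxuse < 0 or self.minuse < 0 or self.absminuse < 0:
            raise ValueError(f"candidate {self.id!r}: negative use limit")
        if self.absminuse > self.maxuse or self.minuse > self.maxuse:
            raise ValueError(
                f"candidate {self.id!r}: use limits must satisfy "
                f"absminuse <= maxuse and minuse <= maxuse"
            )
        if self.absminuse > 0 and self.absminuse > self.minuse:
            raise ValueError(
                f"candidate {self.id!r}: a positive absminuse may not exceed minuse"
            )


class CandidateSet:
    """Array-backed view over a list of candidates (order is preserved).

    The decode hot path works on the numpy arrays exposed here; the
    original :class:`Candidate` objects stay available via ``.candidates``.
    """

    def __init__(self, candidates: Iterable[Candidate]):
        self.candidates: list[Candidate] = list(candidates)
        ids = [c.id for c in self.candidates]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate candidate ids")
        self.ids = np.asarray(ids, dtype=object)
        self.sex = np.asarray([c.sex for c in self.candidates], dtype=object)
        self.group = np.asarray([c.group for c in self.candidates], dtype=object)
        self.index = np.asarray([c.index for c in self.candidates], dtype=float)
        self.maxuse = np.asarray([c.maxuse for c in self.candidates], dtype=np.int64)
        self.minuse = np.asarray([c.minuse for c in self.candidates], dtype=np.int64)
        self.absminuse = np.asarray([c.absminuse for c in self.candidates], dtype=np.int64)
        self.moet = np.asarray([c.moet for c in self.candidates], dtype=bool)
        self._pos = {i: k for k, i in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.candidates)

    def position(self, animal_id: str) -> int:
        return self._pos[animal_id]

    def mask(self, sex: str | None = None, group: str | None = None) -> np.ndarray:
        m = np.ones(len(self), dtype=bool)
        if sex is not None:
            m &= self.sex == _SEX.get(sex.lower(), sex)
        if group is not None:
            m &= self.group == group
        return m

    @property
    def male_groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.candidates:
            if c.sex == "M":
                seen.setdefault(c.group)
        return list(seen)

    @property
    def female_groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.candidates:
            if c.sex == "F":
                seen.setdefault(c.group)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sex": self.sex,
                "group": self.group,
                "index": self.index,
                "maxuse": self.maxuse,
                "minuse": self.minuse,
                "absminuse": self.absminuse,
                "moet": self.moet.astype(int),
            }
        )


def read_candidates_csv(path) -> CandidateSet:
    """Read a candidate CSV: ``id,sex,group,index,maxuse,minuse,absminuse,moet``."""
    df = pd.read_csv(path, dtype={"id": str, "sex": str, "group": str})
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["id", "sex", "group", "index", "maxuse"]
    for c in required:
        if c not in df.columns:
            raise ValueError(f"candidate CSV missing column {c!r}")
    cands = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        cands.append(
            Candidate(
                id=str(d["id"]),
                sex=str(d["sex"]),
                group=str(d["group"]),
                index=float(d["index"]),
                maxuse=int(d["maxuse"]),
                minuse=int(d.get("minuse", 1) if not pd.isna(d.get("minuse", 1)) else 1),
                absminuse=int(d.get("absminuse", 0) if not pd.isna(d.get("absminuse", 0)) else 0),
                moet=bool(int(d.get("moet", 0) if not pd.isna(d.get("moet", 0)) else 0)),
            )
        )
    return CandidateSet(cands)


def write_candidates_csv(cs: CandidateSet, path) -> None:
    cs.to_frame().to_csv(path, index=False)
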