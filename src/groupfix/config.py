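"""Run configuration and input validation.

A run is described by one YAML file pointing at the three input CSVs
(candidates, pedigree, permission matrix) plus steering, DE and
selection-proportion settings.  :func:`validate_inputs` aggregates every
problem it finds instead of failing on the first, so a practitioner can
fix a whole input set in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .candidates import CandidateSet, read_candidates_csv
from .de import DEConfig
from .grouping import PermissionMatrix, read_permission_csv
from .pedigree import Pedigree, read_pedigree_csv

__all__ = ["RunConfig", "ValidationItem", "ValidationReport", "load_config", "validate_inputs"]


@dataclass(frozen=True)
class RunConfig:
    candidates: Path
    pedigree: Path
    permissions: Path
    proportions: dict[str, float]
    target_degrees: float = 25.0
    inbreeding_weight: float = -1.0
    penalty_weight: float = 0.0
    mode: str = "groupfix"
    de: DEConfig = field(default_factory=DEConfig)
    anchor_budget: int = 20_000
    output_dir: Path = Path("groupfix_out")
    seed: int = 0


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw: dict[str, Any] = yaml.safe_load(fh)
    base = Path(path).parent
    de_raw = raw.get("de", {})
    de = DEConfig(
        pop_size=int(de_raw.get("pop_size", 50)),
        f=float(de_raw.get("f", 0.8)),
        cr=float(de_raw.get("cr", 0.9)),
        generations=int(de_raw.get("generations", 1000)),
        seed=int(raw.get("seed", 0)),
    )
    steering = raw.get("steering", {})
    return RunConfig(
        candidates=base / raw["candidates"],
        pedigree=base / raw["pedigree"],
        permissions=base / raw["permissions"],
        proportions={str(k): float(v) for k, v in raw["proportions"].items()},
        target_degrees=float(steering.get("target_degrees", 25.0)),
        inbreeding_weight=float(steering.get("inbreeding_weight", -1.0)),
        penalty_weight=float(steering.get("penalty_weight", 0.0)),
        mode=str(steering.get("mode", "groupfix")),
        de=de,
        anchor_budget=int(raw.get("anchor_budget", 20_000)),
        output_dir=base / raw.get("output_dir", "groupfix_out"),
        seed=int(raw.get("seed", 0)),
    )


@dataclass(frozen=True)
class ValidationItem:
    severity: str  # "fatal" | "warning"
    message: str


@dataclass
class ValidationReport:
    items: list[ValidationItem] = field(default_factory=list)

    def fatal(self, msg: str):
        self.items.append(ValidationItem("fatal", msg))

    def warn(self, msg: str):
        self.items.append(ValidationItem("warning", msg))

    @property
    def ok(self) -> bool:
        return not any(i.severity == "fatal" for i in self.items)

    def __str__(self) -> str:
        if not self.items:
            return "inputs valid"
        return "\n".join(f"[{i.severity}] {i.message}" for i in self.items)


def validate_inputs(rc: RunConfig) -> tuple[ValidationReport, tuple | None]:
    """Check files, group coverage and feasibility bounds; aggregate errors.

    Returns the report plus, when everything parses, the loaded
    ``(candidates, pedigree, permissions)`` so callers need not re-read.
    """
    report = ValidationReport()
    loaded: dict[str, Any] = {}
    for name, path, reader in (
        ("candidates", rc.candidates, read_candidates_csv),
        ("pedigree", rc.pedigree, read_pedigree_csv),
        ("permissions", rc.permissions, read_permission_csv),
    ):
        if not Path(path).exists():
            report.fatal(f"{name} file not found: {path}")
            continue
        try:
            loaded[name] = reader(path)
        except Exception as err:
            report.fatal(f"could not parse {name} ({path}): {err}")
    if len(loaded) < 3:
        return report, None

    cs: CandidateSet = loaded["candidates"]
    ped: Pedigree = loaded["pedigree"]
    pm: PermissionMatrix = loaded["permissions"]

    for g in cs.male_groups:
        if g not in pm.male_groups:
            report.fatal(f"male group {g!r} not a row of the permission matrix")
    for g in cs.female_groups:
        if g not in pm.female_groups:
            report.fatal(f"female group {g!r} not a column of the permission matrix")

    missing_ped = [str(i) for i in cs.ids if str(i) not in ped]
    if missing_ped:
        report.warn(
            f"{len(missing_ped)} candidates absent from the pedigree (treated as "
            f"founders): {missing_ped[:5]}{'…' if len(missing_ped) > 5 else ''}"
        )

    nt = 0
    for g in cs.female_groups:
        members = cs.mask(sex="F", group=g)
        p = rc.proportions.get(g)
        if p is None:
            report.fatal(f"no selection proportion declared for female group {g!r}")
            continue
        if not (0 < p <= 1):
            report.fatal(f"selection proportion for {g!r} must be in (0, 1], got {p}")
            continue
        nt += int(np.floor(int(members.sum()) * p + 0.5))
    males = cs.mask(sex="M")
    max_m = int(cs.maxuse[males].sum())
    lo_used = np.maximum(cs.minuse, 1)
    abs_floor = int(np.where(cs.absminuse > 0, lo_used, 0)[males].sum())
    if nt > max_m:
        report.fatal(
            f"target of {nt} matings exceeds total male capacity {max_m} (sum of maxuse)"
        )
    if nt < abs_floor:
        report.fatal(
            f"target of {nt} matings is below the unconditional male minimum {abs_floor}"
        )
    return report, (cs, ped, pm)
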