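import numpy as np
import pytest

from groupfix import Candidate, CandidateSet, PermissionMatrix, Pedigree
from groupfix.problem import MateSelectionProblem
from groupfix.simulate import cross_farm_permission_matrix, small_fixture


@pytest.fixture
def table2_permission() -> PermissionMatrix:
    """The 4×5 worked example permission matrix."""
    return PermissionMatrix(
        male_groups=("MG1", "MG2", "MG3", "MG4"),
        female_groups=("FG1", "FG2", "FG3", "FG4", "FG5"),
        entries=np.array(
            [
                [1, 1, 1, 0, 0],
                [0, 1, 1, 1, 0],
                [0, 1, 1, 1, 1],
                [0, 0, 1, 1, 1],
            ]
        ),
    )


TABLE2_RAW = {
    ("MG1", "FG2"): 0.0,
    ("MG2", "FG2"): 0.2,
    ("MG3", "FG2"): 0.1,
    ("MG1", "FG3"): 0.3,
    ("MG2", "FG3"): 0.6,
    ("MG3", "FG3"): 0.6,
    ("MG2", "FG4"): 0.2,
    ("MG3", "FG4"): 0.3,
    ("MG3", "FG5"): 0.8,
}


def table2_raw_vector(at):
    """Raw weights for the worked example, ordered per the layout."""
    return [
        TABLE2_RAW[(at.pm.male_groups[i], at.pm.female_groups[j])]
        for i, j in at.opt_cells
    ]


@pytest.fixture
def fixture_problem():
    cs, ped, pm, props = small_fixture(0)
    return MateSelectionProblem(cs, ped, pm, props)


@pytest.fixture
def fixture_penalty_problem():
    cs, ped, pm, props = small_fixture(0)
    return MateSelectionProblem(cs, ped, pm, props, mode="penalty")


def build_cross_farm_problem(mode: str = "groupfix") -> MateSelectionProblem:
    """A compact instance on the cross-farm permission structure.

    Three farms plus juvenile, embryo and AI groups — the same shape as
    the full test-dataset scenario, small enough for thousands of decodes
    in seconds.  All candidates are founders (kinship plays no role in
    decode-legality checks).
    """
    pm = cross_farm_permission_matrix(3)
    rng = np.random.default_rng(42)
    cands = []
    k = 0

    def add(sex, group, n, maxuse, minuse=1):
        nonlocal k
        for _ in range(n):
            k += 1
            cands.append(
                Candidate(
                    id=f"X{k}", sex=sex, group=group,
                    index=round(float(rng.normal()), 3),
                    maxuse=maxuse, minuse=minuse,
                )
            )

    for farm in ("Farm 1", "Farm 2", "Farm 3"):
        add("M", farm, 5, maxuse=6)
        add("F", farm, 8, maxuse=1)
    add("M", "Juvenile", 6, maxuse=2)
    add("F", "Juvenile", 8, maxuse=1)
    add("M", "Embryo", 4, maxuse=1)
    add("F", "Embryo", 6, maxuse=1)
    add("M", "AI", 2, maxuse=1000)
    cs = CandidateSet(cands)
    ped = Pedigree([(c.id, None, None) for c in cands])
    props = {"Farm 1": 0.75, "Farm 2": 0.75, "Farm 3": 0.75, "Juvenile": 0.5, "Embryo": 0.5}
    return MateSelectionProblem(cs, ped, pm, props, mode=mode)


@pytest.fixture(scope="session")
def cross_farm_problem():
    return build_cross_farm_problem()
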