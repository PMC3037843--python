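# groupfix

Constrained **mate selection** for animal breeding programs: given a
table of selection candidates, their pedigree and a *group mating
permission matrix*, `groupfix` produces a mating list that maximises a
balance of progeny merit, parental coancestry and progeny inbreeding —
and that **cannot** violate the declared grouping constraints, because
legality is built into the decoding of every candidate solution rather
than enforced through penalties.

It is written for quantitative geneticists and breeding-program
operators who need tactical mating decisions across farms, age classes
and reproductive technologies (natural mating, AI, MOET), and for
researchers studying repair-based constraint handling in evolutionary
optimisation.

## The method in brief

A mate-selection solution is encoded as a flat real vector
("genotype") holding, per candidate, a raw use count; per male mating
slot, a ranking value; and, per optimisable group combination, a raw
weight *R* ∈ [0, 1]. Decoding repairs this vector into a legal mating
list:

1. **Use counts.** Raw counts *Nm* are snapped into the per-candidate
   limits *Maxuse*, *Minuse* (minimum if used at all) and *AbsMinuse*
   (unconditional minimum), then nudged ±1 at random until each female
   group meets its target number of matings *Nt*ⱼ =
   round(candidates × selection proportion).
2. **Group targets.** For each female group *j*, relative weights over
   male groups are derived from the raw weights. With the last male
   group permitted and *k*ⱼ = (number of positive *R*) + 1,

   *W*ᵢⱼ = *R*ᵢⱼ / *D*ⱼ, *W*(last)ⱼ = 1 − Σ*R*·ⱼ / *D*ⱼ, where
   *D*ⱼ = 1 + (*k*ⱼ − 2) Σ*R*·ⱼ / (*k*ⱼ − 1);

   without the last group, *W*ᵢⱼ = *R*ᵢⱼ / Σ*R*·ⱼ. Columns of *W*
   always sum to one, and *W*ᵢⱼ ≡ 0 wherever mating is not permitted.
   Targets *Nmg*ᵢⱼ = *W*ᵢⱼ·*Nt*ⱼ are integerised stochastically and
   repaired against male-group capacities.
3. **Mate allocation.** Male matings, sorted by their ranking values,
   each take the first unallocated female mating that is
   permission-legal and still under its group-combination quota. MOET
   females keep a single sire across all their matings.

Fitness of a decoded list combines the mean progeny index *G*, the
use-weighted parental coancestry *C* = **p**′**K****p** (with
*p*ᵢ = *Nm*ᵢ/2*Nt*) and the mean progeny inbreeding F̄, steered by a
*target degrees* angle on the *G*/*C* frontier (0° = maximum gain,
90° = minimum coancestry). A penalising baseline — permission-blind
decoding plus fitness penalty of weight × illegal matings — is included
for comparison. The search engine is classic differential evolution
(rand/1/bin).

Kinship and inbreeding come from the pedigree via the tabular method
and a Meuwissen–Luo-style recursion (cross-checked against each other
and against path counting in the tests).

## A worked example

```python
import numpy as np
from groupfix import PermissionMatrix, derive_action_types, relative_weights

pm = PermissionMatrix(
    male_groups=("MG1", "MG2", "MG3", "MG4"),
    female_groups=("FG1", "FG2", "FG3", "FG4", "FG5"),
    entries=np.array([[1, 1, 1, 0, 0],
                      [0, 1, 1, 1, 0],
                      [0, 1, 1, 1, 1],
                      [0, 0, 1, 1, 1]]),
)
at = derive_action_types(pm)
raw = [0.0, 0.2, 0.1, 0.3, 0.6, 0.6, 0.2, 0.3, 0.8]  # one R per "Opt" cell
print(np.round(relative_weights(at, raw), 3))
```

prints

```
[[1.    0.    0.15  0.    0.   ]
 [0.    0.667 0.3   0.16  0.   ]
 [0.    0.333 0.3   0.24  0.8  ]
 [0.    0.    0.25  0.6   0.2  ]]
```

Column FG2 splits its matings 2:1 between MG2 and MG3 (0.667/0.333);
in FG4 the calculated last group receives *W* = 0.6 because the two
optimised raw weights there (0.2, 0.3) average below one half; FG1 has
a single permitted group, so its weight is fixed at 1. Each column sums
to one, so multiplying by the female-group targets yields a complete,
legal apportionment of matings over group combinations.

The scripts in `examples/` walk through each capability — the weight
transform, the ungrouped driver, legality-by-construction decoding,
frontier-steered optimisation, the repair-vs-penalty comparison and the
synthetic multi-farm population generator. The `groupfix` command
exposes the same workflow from a shell (`simulate`, `validate`, `run`,
`compare`, `frontier`) driven by one YAML configuration file.

## Layout

```
src/groupfix/
  pedigree.py    inbreeding & kinship (tabular + Meuwissen–Luo)
  candidates.py  candidate table, use limits, CSV I/O
  driver.py      use-count repair and ranked mate allocation
  grouping.py    permission matrix, weight transform, group quotas
  problem.py     genotype layout and full decode (repair & penalty modes)
  objective.py   component criteria, frontier steering, recovery objective
  de.py          differential evolution and strategy comparison
  simulate.py    synthetic breeding populations and the small fixture
  config.py      run configuration and input validation
  cli.py         the `groupfix` command
```

See `docs/methods.md` for the modelling assumptions, parameter
defaults and numerical choices.
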