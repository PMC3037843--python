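"""From raw weights to relative mating-group weights.

For each female group, one weight per permitted male group decides how
that group's matings are split across male groups.  Only the non-last
permitted male groups carry an optimised raw weight R in [0, 1]; the
last male group's weight is calculated as a complement so each column of
relative weights W sums to one with as few variables as possible.
"""

import numpy as np

from groupfix import PermissionMatrix, derive_action_types, relative_weights

pm = PermissionMatrix(
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
at = derive_action_types(pm)
print("Action types ('1' fixed, 'Opt' optimised, 'Calc' complement):")
print(at.to_frame(), "\n")
print(f"{at.n_opt} raw weights to optimise "
      f"(bound: N_FG x (N_MG - 1) = {pm.n_fg * (pm.n_mg - 1)})\n")

raw = {("MG1", "FG2"): 0.0, ("MG2", "FG2"): 0.2, ("MG3", "FG2"): 0.1,
       ("MG1", "FG3"): 0.3, ("MG2", "FG3"): 0.6, ("MG3", "FG3"): 0.6,
       ("MG2", "FG4"): 0.2, ("MG3", "FG4"): 0.3, ("MG3", "FG5"): 0.8}
W = relative_weights(
    at, [raw[(pm.male_groups[i], pm.female_groups[j])] for i, j in at.opt_cells]
)
print("Relative weights W (columns sum to one over permitted cells):")
print(np.round(W, 3))
print("\nFG2 splits 2:1 between MG2 and MG3 (0.667 / 0.333); in FG4 the "
      "calculated last group MG4 receives 0.6 because the optimised raw "
      "weights there average below one half.")
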