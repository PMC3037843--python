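"""The ungrouped mate-selection driver on a three-male example.

Raw optimiser variables (use counts and ranking values) become a mating
list: male matings sorted by ranking value, each taking the leftmost
unallocated female mating.  Row and column totals always match the use
counts, so per-candidate limits cannot be violated.
"""

import numpy as np

from groupfix import fix_use_vector, rank_allocate

rng = np.random.default_rng(0)

# three males, four females, three matings targeted
nm_males = fix_use_vector(
    raw=[2, 0, 1], maxuse=[3, 3, 3], minuse=[1, 1, 1], absminuse=[0, 0, 0],
    nt=3, rng=rng,
)
nm_females = fix_use_vector(
    raw=[1, 0, 1, 1], maxuse=[1, 1, 1, 1], minuse=[1, 1, 1, 1],
    absminuse=[0, 0, 0, 0], nt=3, rng=rng,
)
print("male use counts:  ", nm_males)
print("female use counts:", nm_females)

rankings = np.array([[5.32, 2.16, 0.0], [0.0, 0.0, 0.0], [7.64, 0.0, 0.0]])
pairs = rank_allocate(
    ["male1", "male2", "male3"], nm_males, rankings,
    ["female1", "female2", "female3", "female4"], nm_females,
)
print("mating list:", pairs)
print("\nThe highest ranking value (7.64, male3's single mating) claims the "
      "first female mating; male1's two matings follow in rank order.")
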