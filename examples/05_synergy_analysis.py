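"""Test which miRNA pairs share significantly more targets than chance
(miRNA-miRNA synergy).

Builds target sets with two co-regulation modules: miRNAs within a module
work on a common gene program, miRNAs in different modules do not.  For
every pair the upper hypergeometric tail gives the probability of sharing
at least the observed number of targets in a universe of N mRNAs;
Benjamini-Hochberg controls the FDR over all pairs at 0.05.  Expect
within-module pairs to be called synergistic and cross-module pairs not.
"""

import numpy as np

import invarmir as iv

rng = np.random.default_rng(3)
universe = [f"mRNA-{i:04d}" for i in range(150)]
program_a = rng.choice(universe, size=30, replace=False)
program_b = rng.choice(universe, size=30, replace=False)

target_sets = {}
for i in range(3):  # module A: share most of program A plus private targets
    own = set(rng.choice(program_a, size=24, replace=False))
    own |= set(rng.choice(universe, size=10, replace=False))
    target_sets[f"miR-A{i + 1}"] = own
for i in range(3):  # module B
    own = set(rng.choice(program_b, size=24, replace=False))
    own |= set(rng.choice(universe, size=10, replace=False))
    target_sets[f"miR-B{i + 1}"] = own

result = iv.synergy_matrix(target_sets, universe_size=len(universe), cutoff=0.05)
table = result.to_long().sort_values("adj_p")
print("miRNA pairs ordered by adjusted overlap p-value:")
print(table.to_string(index=False))

n_syn = int(result.synergistic.sum() // 2)
print(f"\nsynergistic pairs at FDR 0.05: {n_syn} of {len(table)}")
print(f"minimum synergistic partners per miRNA: {iv.min_synergy_partners(result)}")
# Within-module pairs share ~20 of ~34 targets in a 150-gene universe --
# far beyond the hypergeometric expectation (~7) -- while cross-module
# sharing stays at chance level.
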