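"""Exact identity coefficients on classic relationships, checked two ways.

The recursive calculator gives exact condensed identity coefficients
(Delta1..Delta9) and all derived pair identities; gene dropping estimates the
same quantities by Monte Carlo.
"""

import numpy as np

from infdom import (Individual, Pedigree, condensed_identity,
                    gene_drop_oracle, inbreeding, kinship, pair_identities)

sibs = Pedigree([Individual("m", 0), Individual("f", 0),
                 Individual("s1", 1, "m", "f"),
                 Individual("s2", 1, "m", "f")])
print("full sibs: kinship =", kinship(sibs, "s1", "s2"))
d = condensed_identity(sibs, "s1", "s2").delta
print("  Delta7, Delta8, Delta9 =", d[6], d[7], d[8])

chain = Pedigree([Individual("x0", 0)]
                 + [Individual(f"x{t}", t, f"x{t-1}", f"x{t-1}")
                    for t in range(1, 6)], selfing_allowed=True)
print("\nselfing chain inbreeding (theory 1 - 2^-t):")
for t in range(6):
    print(f"  t={t}: F = {inbreeding(chain, f'x{t}'):.6f}")

# an inbred pair from a small random-mating population
from infdom import make_random_pedigree

ped = make_random_pedigree(4, 5, selfing_allowed=True, seed=7)
a, b = ped.generation_members(5)[0].id, ped.generation_members(5)[1].id
exact = pair_identities(ped, a, b)
oracle = gene_drop_oracle(ped, [(a, b)], n_reps=200_000, seed=1).iloc[0]
print(f"\ninbred pair ({a}, {b}) after 5 generations, N=4:")
for f in ("Fab", "Faa", "Fbb", "Faabb", "Ft_abab"):
    print(f"  {f}: exact = {getattr(exact, f):.4f}, "
          f"gene-drop = {oracle[f]:.4f} +- {oracle[f + '_se']:.4f}")
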