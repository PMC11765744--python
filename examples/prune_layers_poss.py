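"""Layer subset selection with Pareto optimization (POSS).

Each of 8 optional layers contributes an additive amount to the loss (mixed
signs: some layers help, some hurt).  POSS evolves a non-dominated archive
over (loss, number of included layers); the frontier shows the best mask at
every size, and the final selection respects a minimum-depth constraint.
Mask convention: bit 1 excludes the layer, 0 includes it.
"""

import numpy as np

import zoocnn as z

coeffs = np.random.default_rng(7).uniform(-1, 1, 8)


def loss(mask):
    return float(sum(c for c, bit in zip(coeffs, mask) if bit == 0))


archive = z.poss_optimize(loss, n=8, budget=4000, seed=0)
print("layer contributions:", np.round(coeffs, 3))
print("Pareto frontier (loss vs included layers):")
for rec in sorted(archive, key=lambda r: r.included):
    print(f"  mask {''.join(map(str, rec.mask))}  included={rec.included}  "
          f"loss={rec.loss:+.3f}")

chosen = z.select_final(archive, min_layers=3)
print(f"selected mask with >=3 layers kept: {''.join(map(str, chosen))}")
print("(the unconstrained optimum keeps exactly the negative-contribution layers)")
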