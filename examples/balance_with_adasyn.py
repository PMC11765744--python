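"""Rebalance minority classes with ADASYN.

Computes the adaptive synthesis plan for each minority class of an
imbalanced corpus and applies it: with balance level beta = 1 every class
ends within one sample of the majority count.  The per-class total G equals
round(beta * (majority - minority)); harder minority points (more
non-minority nearest neighbours) receive more synthetic samples.
"""

import zoocnn as z

dataset = z.generate_images({0: 278, 1: 158, 2: 149}, side=32, seed=1)
print("before:", dataset.class_counts())

for label in (1, 2):
    plan = z.compute_plan(dataset, label, k=5, beta=1.0)
    print(
        f"class {label}: G = {plan.G} synthetic samples, "
        f"max per-point difficulty = {plan.ratios.max():.3f}"
    )

balanced = z.balance_dataset(dataset, k=5, beta=1.0, seed=0)
print("after: ", balanced.class_counts())
n_synth = sum(p == "synthetic" for p in balanced.provenance)
print(f"{n_synth} synthetic images flagged in provenance; originals untouched.")
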