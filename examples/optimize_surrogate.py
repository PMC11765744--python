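"""Derivative-free hyperparameter search with the surrogate evaluator.

Runs the classification-based optimizer (population 50, 300 evaluations,
exploration annealed 0.6 -> 0.3, step 0.1, patience 30) against the
deterministic surrogate objective, whose optimum sits at the published
tuned point: learning rate 1.253981e-4, dropout 0.44.  The search should
land close to both.
"""

import zoocnn as z

trace = z.sracos_optimize(
    z.SurrogateEvaluator(),
    z.default_space(),
    z.OptimizerConfig(budget=300, population=50, seed=0),
)
best = trace.best_candidate
print(f"evaluations used: {trace.evaluations_used}")
print(f"best objective (negated fitness): {trace.best_value:.6f}")
print(f"best depth:         {best.depth}")
print(f"best filters:       {best.filters}")
print(f"best learning rate: {best.learning_rate:.3e}  (tuned: 1.254e-04)")
print(f"best dropout:       {best.dropout:.3f}        (tuned: 0.44)")
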