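"""Find the sweet-spot compensation rate on the nonlinear maintenance task.

A 12-20-10 sigmoid network tries to keep reproducing its own initial
input-output mapping while white-noise fluctuations of fixed magnitude
(||de|| = 2) corrupt the weights every step.  Backpropagation-based
compensation of increasing magnitude is applied in stages; each stage settles
and we read off its steady-state error.  The stage with the lowest error is
the "sweet spot" — the theory predicts it lies BELOW the fluctuation
magnitude for an accurate gradient rule.
"""

import synmaint as sm

eps = 2.0
task = sm.make_task(layer_sizes=(12, 20, 10), n_inputs=200, seed=0)
comp = sm.CompensationConfig(rule="exact_gradient")
stages = tuple(r * eps for r in (0.25, 0.35, 0.5, 0.7, 1.0, 1.4, 2.0))

result = sm.staircase(task, comp, eps, stages, stage_length=1200,
                      settle_discard=800, seed=1)

print(f"fluctuation magnitude ||de|| = {eps}")
print("stage magnitude -> steady-state error")
for m, e in zip(result.stage_magnitudes, result.stage_steady_errors):
    marker = "  <- sweet spot" if m == result.sweet_spot_magnitude else ""
    print(f"  {m:5.2f} -> {e:.4f}{marker}")
ratio = result.sweet_spot_magnitude / eps
print(f"\nsweet-spot ratio ||dc||:||de|| = {ratio:.2f}")
print("A ratio below 1 means optimal maintenance under-compensates: most of")
print("the ongoing synaptic change is the task-independent fluctuation itself.")
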