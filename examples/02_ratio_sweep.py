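"""Steady-state error as a function of the compensation:fluctuation ratio.

Independent maintenance simulations are run for each ratio on a grid, with a
fresh teacher network and input suite per repeat.  Two regimes are compared:
an accurate gradient rule with moderate fluctuations (low steady-state error;
optimum ratio < 1) and a heavily noise-corrupted rule with large fluctuations
(high steady-state error; optimum ratio near 1).
"""

import synmaint as sm

grid = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0)


def factory(seed_seq):
    return sm.make_task(layer_sizes=(12, 20, 10), n_inputs=200, seed=seed_seq)


for label, comp, eps in [
    ("accurate gradient, ||de|| = 2", sm.CompensationConfig(rule="exact_gradient"), 2.0),
    ("noise-corrupted (gamma2:gamma1 = 2), ||de|| = 4",
     sm.CompensationConfig.from_ratio("corrupted_gradient", 1.0, noise_ratio=2.0), 4.0),
]:
    res = sm.ratio_sweep(None, comp, eps, grid, n_steps=2000, repeats=2,
                         seed=11, window=500, system_factory=factory)
    print(f"\n{label}")
    for r, m, s in zip(res.ratios, res.steady_errors, res.steady_sds):
        print(f"  ratio {r:4.2f}: steady error {m:.3f} +/- {s:.3f}")
    print(f"  optimum ratio = {res.argmin_ratio}")
print("\nThe optimum shifts toward 1 as the rule degrades: imprecise")
print("compensation points in averagely curved directions, like the noise.")
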