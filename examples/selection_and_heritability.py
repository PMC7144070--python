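"""Simulate divergent selection on olfactory preference and estimate
realized heritability.

Three replicate lines are selected upward (parents = odor-arm flies), three
downward, and three unselected controls, for 30 generations under a
liability-threshold model with true h2 = 0.25.  Realized heritability is then
re-estimated from each line's trajectory as the slope of cumulative response
on cumulative selection differential — on the latent liability scale (exact
under breeder's-equation transmission) and on the observable PI scale (the
assay-only convention: the selected group's PI is +/-1 by construction).
"""

import numpy as np

from olfsel.quantgen import pi_scale_inputs, realized_h2
from olfsel.selection import SelectionParams
from olfsel.synth import gen_selection_experiment

template = SelectionParams(h2=0.25, n_flies=200, n_generations=30)
experiment = gen_selection_experiment(template, seed=1)

final = experiment[experiment.generation == 29].groupby("direction").pi.mean()
print("mean PI at generation 29 (3 lines each):")
for direction in ("positive", "control", "negative"):
    print(f"  {direction:>8}: {final[direction]:+.3f}")

print("\nrealized h2 per line (true liability h2 = 0.25):")
for (direction, rep), df in experiment.groupby(["direction", "replicate"]):
    if direction == "control":
        continue
    pop = np.append(df.mu.to_numpy(), df.mu.iloc[-1] + df.r_liab.iloc[-1])
    est_liab = realized_h2(pop, (df.mu + df.s_liab).to_numpy())
    pop_pi = np.append(df.pi.to_numpy(), df.pi.iloc[-1] + df.r_pi.iloc[-1])
    target = 1.0 if direction == "positive" else -1.0
    est_pi = realized_h2(pop_pi, np.full(len(df), target), scale="pi")
    print(f"  {direction:>8} line {rep}: liability h2 = {est_liab.h2_hat:.4f}"
          f" +/- {est_liab.se:.4f} | PI-scale h2 = {est_pi.h2_hat:.4f}"
          f" +/- {est_pi.se:.4f} (p = {est_pi.p_value:.2e})")

print("\nThe liability-scale slope returns the generating h2 exactly; the")
print("PI-scale slope is smaller because the selected-group PI is pinned at")
print("+/-1, which inflates the denominator of the regression.")
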