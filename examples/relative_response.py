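"""Relative response (AUC ratios) and scenario classification.

Computes each note variant's area under the fitted response curve as a
proportion of the own-call AUC, then classifies the population into the
null / matched / intermediate recognition scenarios.
"""

import warnings

import numpy as np

from callspace import (classify_scenario, fit_population, predict_curves,
                       relative_response_table)
from callspace.simulate import PopulationConfig, simulate_trials

pop = PopulationConfig(name="Careiro", own_note=4, center_freq=3.12,
                       note_offsets={2: -2.4, 3: -1.2, 4: 0.0}, n_trials=600)
trials, _ = simulate_trials(pop, seed=3)

with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    fit = fit_population(trials)
grid = np.linspace(*fit.freq_range, 256)
table = relative_response_table(predict_curves(fit, grid), own_note=4,
                                population=pop.name)
for note in sorted(table.relative):
    print(f"  {note} notes: AUC = {table.auc[note]:.4f} kHz  "
          f"relative = {table.relative[note]:.3f}")
call = classify_scenario(table, fit.note_effect_pvalue, alpha=0.05, floor=0.05)
print(f"scenario: {call.scenario}  (note-effect p = {call.note_effect_pvalue:.2e})")
print("Relative response 1.0 is the own call; graded, non-negligible foreign "
      "responses with a significant note effect give the intermediate scenario.")
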