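"""Fit one population's recognition surface from simulated phonotaxis trials.

The generating surface is unimodal in stimulus frequency with graded note
offsets (own two-note call favored); the penalized-spline logistic fit
recovers the offsets and tests the note effect.
"""

import warnings

import numpy as np

from callspace import fit_population, predict_curves
from callspace.simulate import PopulationConfig, simulate_trials

pop = PopulationConfig(name="Catuaba", own_note=2, center_freq=3.34,
                       note_offsets={2: 0.0, 3: -1.2, 4: -2.4}, n_trials=600)
trials, truth = simulate_trials(pop, seed=11)

with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    fit = fit_population(trials)

print(f"n = {fit.n_trials} trials,  smoothing lambda = {fit.smoothing_lambda:.3g}")
print(f"note offsets (logit, ref = {fit.reference_note}): "
      f"{ {k: round(v, 2) for k, v in fit.note_offsets.items()} }")
print(f"note-effect LRT p = {fit.note_effect_pvalue:.2e}")
print(f"deviance explained = {100 * fit.deviance_explained:.1f}%")

grid = np.linspace(*fit.freq_range, 5)
curves = predict_curves(fit, grid)
for note, curve in sorted(curves.curves.items()):
    print(f"  {note}-note curve at {np.round(grid, 2)} kHz: {np.round(curve, 2)}")
print("Offsets near the generating (0, -1.2, -2.4) and a tiny p-value mean "
      "recognition depends on note number; curves peak at the call frequency.")
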