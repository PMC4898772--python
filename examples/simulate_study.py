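"""Generate a synthetic playback study and write it to disk.

The eight populations mirror the real study design (own note counts,
call frequencies, trial counts); the 'decoupled' preset makes every
population's recognition surface favor four-note calls regardless of its
own call.
"""

from callspace import make_preset, write_study

study = make_preset("decoupled", seed=7)
print(f"preset={study.preset}  populations={len(study.populations)}  "
      f"trials={len(study.trials)}")
for pop in study.populations:
    own = pop.own_note
    print(f"  {pop.name:<10} own note {own}  center {pop.center_freq} kHz  "
          f"n={pop.n_trials}")
paths = write_study(study, "scratch/example_study")
print("files:", *[str(p) for p in paths.values()])
print("Trial totals match the 593 playback experiments of the study design; "
      "tree, traits and trials are the three inputs the pipeline consumes.")
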