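# callspace

Do acoustic signals and their behavioral recognition evolve together, or at
different tempos?  `callspace` implements a complete analysis of this
question for frog advertisement calls, modeled on the *Allobates femoralis*
(brilliant-thighed poison frog) system, where the evolving signal character
is the number of notes per call (one to four) and recognition is measured
by binary phonotaxis: a territorial male either approaches a playback
speaker or does not.

The package combines three pieces:

1. **Recognition surfaces.** Per population, the probability of positive
   phonotaxis is modeled on the logit scale as

   `logit P(response) = β_k + f(freq)`

   where `β_k` is an unpenalized offset for the stimulus note count *k*
   and `f` is a penalized cubic B-spline in the stimulus mid-frequency
   (kHz), fitted by penalized IRLS with GCV-selected smoothing.  The note
   effect is tested by a likelihood-ratio statistic against the nested
   no-notes model refitted at the same smoothing parameter, referred to
   χ² with (levels − 1) df, with Bonferroni correction `α/k` across the
   *k* populations.

2. **Ancestral note states.** The note count evolves on a rooted phylogeny
   under the equal-rates Mk model (all transitions at one rate *q*;
   `P_ii(t) = 1/S + (S−1)/S·e^{−Sqt}`, `P_ij(t) = 1/S − 1/S·e^{−Sqt}`).
   The rate is fitted by maximum likelihood (Felsenstein pruning), marginal
   ancestral states are computed by the rerooting method, reconstructions
   can be averaged across a posterior sample of trees by matching rooted
   clades, and state changes are counted from max-marginal assignments.

3. **The synthesis.** Each note variant's area under the fitted response
   curve (AUC) is expressed relative to the own-call AUC; populations are
   classified into *null* (responds to everything alike), *matched*
   (responds only to its own call), or *intermediate* (graded) scenarios;
   and a Spearman score per population asks whether the ancestor's state
   probabilities predict today's relative responses.  The global verdict is
   *coupled* only if every population is matched — anything else is
   evidence of *decoupled* evolution between sender and receiver.

A synthetic-data module generates Yule trees, Gillespie-simulated Mk
characters and Bernoulli phonotaxis trials with the same design as the
real study (eight populations, 593 trials), so the entire pipeline is
testable end-to-end with no field data.

## Worked example

```python
from callspace import RunConfig, run_full_pipeline
report = run_full_pipeline(RunConfig(preset="decoupled", seed=1))
print(report.verdict, round(report.mean_score, 3), report.permutation_pvalue)
```

prints

```
decoupled 0.621 0.006099390060993901
```

meaning: on a synthetic study in which every population's recognition
surface favors the ancestral four-note call while the populations' own
calls vary, the pipeline classifies most populations as *intermediate*
(graded responses with a significant note effect), returns the
*decoupled* verdict, and finds that the ancestral state ranking predicts
the relative responses (mean Spearman score 0.62, permutation p ≈ 0.006
over 10,000 within-population permutations).  The `examples/` scripts walk
through each stage separately — simulation, recognition fits, relative
responses, ancestral reconstruction and the full pipeline — each printing
the numbers it computes and what they mean.

The same analysis runs from the shell on Newick + CSV inputs:

```sh
callspace simulate --preset decoupled --seed 7 --out data/
callspace run-all --trees data/tree.nwk --traits data/traits.csv \
    --trials data/trials.csv --out out/ --seed 7
```

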