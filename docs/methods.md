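# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Recognition model

Binary phonotaxis trials for one population are modeled as independent
Bernoulli outcomes with

    logit p_i = β_{k(i)} + f(x_i)

where `k(i)` is the stimulus note count, `x_i` the stimulus mid-frequency
in kHz, `β` unpenalized categorical offsets (reference level fixed at 0)
and `f` a cubic B-spline with `n_basis = 8` functions: boundary knots at
the observed frequency extremes, interior knots at evenly spaced
quantiles, and a second-difference penalty `λ‖D₂γ‖²` on the spline
coefficients.  Because the basis is a partition of unity, the constant
function lies in the penalty's null space, so the intercept is implicit
and unpenalized and the fitted probabilities reproduce the sample
positive fraction exactly (intercept score equation).

Fitting is penalized IRLS: working-response weighted least squares with
the penalty added to the normal equations, convergence at a 1e-8 relative
change in the penalized deviance, at most 200 iterations, and the linear
predictor clipped to ±30 (probabilities then stay strictly inside (0,1);
beyond ±30 the Bernoulli likelihood is flat to double precision).  The
smoothing parameter is chosen by GCV, `n·D(λ)/(n−edf)²` with
`edf = tr[(XᵀWX + λP)⁻¹XᵀWX]`, over the 17-point log grid λ ∈ 10^[−4,4];
a fixed-λ mode and a target-df mode (`df4`: the most flexible grid λ whose
edf stays within 4 + parametric terms) are provided.  An optional
per-note-smooth variant (one spline per note level) exists for
sensitivity analysis; the shared smooth is the default because observed
response curves for different note counts are near-parallel on the logit
scale.

**Reference level.** The dummy reference is the note level with the most
positive responses.  This is deliberate: when a rarely-recognized variant
is completely separated (zero positives), the separation then lands in
that variant's own dummy coefficient rather than contaminating the shared
smooth.

**Separation.** Complete or quasi-complete separation drives coefficients
toward infinity.  Any fit whose IRLS fails to converge or whose
coefficients exceed 50 in absolute value (already unphysical on the logit
scale) is refitted with a small ridge on all coefficients, starting at
1e-6 and escalating tenfold (to at most 1e-2) until the fit is tame, with
a warning each time.  The data cannot distinguish an offset of −15 from
−50, so this changes no scientifically meaningful quantity; it prevents
boundary spikes in the spline from leaking probability into curves for
variants that were never recognized.

**Note-effect test.** The reduced model (no note offsets) is refitted at
the full model's λ, so both fits minimize the same penalized objective
over nested parameter spaces; the statistic is the difference in
*penalized* deviance, which is nonnegative by construction, referred to
χ² with (note levels − 1) df — only the unpenalized offsets differ
between the fits, so the smooth's effective df cancels.  This is a
deliberate departure from mgcv-style approximate p-values (which involve
smoothing-parameter uncertainty); simulated null data at the study's
sample size (n = 80) give an empirical size of about 0.05 at nominal
0.05, which the test suite checks against the [0.03, 0.08] band.
Deviance explained is reported against the intercept-only null,
`1 − D_model/D_null`.

## Equal-rates Mk model

The note count is a discrete nominal character with S = 4 states.  The
equal-rates (ER) generator has off-diagonal rate q and diagonal −(S−1)q;
the transition matrix is computed in closed form (spectral decomposition
of the complete-graph Laplacian) rather than by `expm`, and tests verify
the two agree to 1e-10 and satisfy Chapman–Kolmogorov.  Branch lengths
are in arbitrary positive units (the inference trees' substitution or
time units); q is in reciprocal units, so only the product q·t matters.

The likelihood is Felsenstein pruning with per-node rescaling of the
conditional likelihoods (log-scalers accumulated), uniform 1/S root prior
— the ER stationary distribution, which also makes the likelihood
invariant to root placement.  Zero-length branches get an identity
transition matrix.  Rate estimation is bounded Brent search on log₁₀(q) ∈
[−6, 3] with 1e-8 tolerance; if all tips share one state the likelihood is
monotone decreasing in q and the lower bound is returned flagged
non-converged.

Marginal ancestral states follow the rerooting construction: for a
reversible chain with its stationary root prior, the marginal at a node
equals the root posterior of the tree rerooted there.  They are computed
in one up-pass and one down-pass (outside-subtree messages), which tests
verify against exhaustive enumeration over all joint internal assignments
on trees of up to six tips, to 1e-10.

**Tree samples.** Across a posterior sample, internal nodes are matched
by rooted bipartition (the frozenset of subtended tip labels).  Each
clade's summary is the mean marginal over the trees containing it plus
its coverage (fraction of trees) — the same bookkeeping used to annotate
a maximum-clade-credibility tree.  The rate is refitted per tree by
default; a fixed-rate mode exists for large samples.

**Change counting.** Each node takes its maximum-marginal state, ties
broken toward the parent's assigned state (root ties to the lowest state
index); every edge whose endpoints differ contributes one change keyed
(parent state → child state).  This is a reproducible stand-in for
eyeballing reconstructions; it is exact only in the sparse-change regime.
Simulations at about 0.5 expected changes per tree recover the true
node-implied changes in well over 80% of replicates, but histories with
multiple events per edge (reversals) are unidentifiable for any edge-wise
method, so counts on deep trees or at high rates should be read as
parsimony-flavored summaries, not event counts.  Joint reconstruction and
stochastic mapping are out of scope, but the assignment step is isolated
so either could be swapped in.

## Relative response and scenarios

Fitted response curves are evaluated on a 256-point uniform grid over the
population's own tested frequency range (no extrapolation; per-population
ranges, since a common range would require extrapolating some fits).  The
AUC is the trapezoidal integral (kHz·probability); each variant's AUC is
divided by the own-call AUC.  Values above 1 are meaningful (a foreign
variant recognized better than the own call) and are never capped.

Scenario rules, with α = 0.05 (optionally the Bonferroni-corrected
0.00625) and floor = 0.05:

* **null** — note-effect p ≥ α;
* **matched** — p < α and every non-own relative response ≤ floor;
* **intermediate** — otherwise.

The floor reads "less than 5% of the own-call response" as "not
recognized"; it is a reporting convention, not an estimate.

## Decoupling synthesis

Each population's "ancestor" is the parent node of its tip.  Ancestral
probabilities are restricted to the tested variants {2,3,4} and
renormalized (untested one-note calls carry no playback information),
then compared with the relative responses by Spearman rank correlation.
Probabilities are rounded to 9 decimals before ranking so analytically
tied values — the ER model gives exactly equal support to all unobserved
states at low rates — rank as ties instead of being ordered by
floating-point noise.  Constant vectors yield a flagged score of 0.

The verdict is **coupled** iff every population is matched, else
**decoupled**.  Because n populations is small, the mean score gets a
permutation p-value: each population's relative responses are permuted
across its variants (10,000 draws, seeded; implemented exactly by
enumerating the v! per-population score values and sampling indices),
with the add-one estimator.  This rank-correlation + permutation
construction is this package's formalization of an argument usually made
qualitatively; reports label it as such.

## Synthetic data

The generator emulates the study design, not the field.  Defaults: eight
populations with the study's own note counts, call frequencies
(2.87–3.44 kHz) and per-population trial counts (72, 67, 89, 73, 72, 72,
80, 68; 593 total); stimulus variants {2,3,4}; stimulus frequencies
uniform on center ± 0.3 kHz; response probability
`logit p = a + β_k − ((f − c)/0.15)²` — a smooth unimodal surface of the
same shape class as observed response curves, with peak amplitude a = 2.0
(peak recognition ≈ 0.88) and graded offsets of −1.2 logits per note of
distance in the intermediate/decoupled presets (peak foreign recognition
≈ 0.3–0.7 of own, matching the graded patterns seen in real playback
data).  The matched construction uses −12 (foreign recognition < 5e-5 per
trial, i.e. effectively never — the defining feature of that scenario).
Trees are Yule: root at the first split, waiting time Exp(k·birth rate)
with k lineages, tips extended by a final Exp(n·birth rate) interval;
expected height (1/λ)·Σ_{k=2..n} 1/k.  Characters evolve by Gillespie
simulation (waiting Exp((S−1)q), uniform jump), with every event
recorded as ground truth.

Presets: **null** (all offsets equal), **intermediate** (graded toward
the own call), **coupled** (tip states from the Mk simulation, own call =
tip state, matched surfaces), **decoupled** (study tip states, all
surfaces graded toward four notes — so the three- and two-note senders'
receivers track the putative ancestor, the pattern of interest).

One integer seed drives everything through `numpy.random.SeedSequence`
spawn keys (tree = 0, character = 1, population i = 10 + i), so identical
configurations produce byte-identical files.

What passing tests show: the estimators recover the generating surfaces,
rates and scenarios under the model's own assumptions at the study's
sample sizes.  What they do not show: robustness to real-data features
the generator omits — heterogeneous trial difficulty, within-male
correlation from repeated testing, non-quadratic or asymmetric frequency
response, observation error in the trait states, and non-Yule tree shape.

## Problem sizes

The test suite uses the sizes its claims need: enumeration oracles on ≤6
tips (50 instances), rate recovery on 200-tip trees (20 replicates per
rate), offset recovery at n = 2000, test size at n = 80 over 1000 null
replicates, and scenario recovery over 40 seeded studies per preset.  The
acceptance script runs the full pipeline once at the study's own design
size (8 populations, 593 trials) plus a 20-replicate rate-recovery check.

## Known limitations

* Under heavy separation with GCV-minimal smoothing, spline boundary
  behavior can inflate a foreign variant's relative response by a few
  percent of the own-call AUC even with zero observed foreign positives
  (about 1 preset study in 40); the ridge escalation bounds but does not
  eliminate this.
* The LRT's χ² reference treats λ as fixed; smoothing-parameter
  uncertainty is ignored (empirical size is checked by simulation).
* Clade matching uses rooted bipartitions, so reconstructions averaged
  over trees that disagree about the root can split support among clades
  that would coincide unrooted.
* `decoupling_verdict`'s permutation null permutes responses within
  populations only; it does not model phylogenetic correlation among
  populations' scores.
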