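# Methods

## Censored lognormal mixture for motor latencies

Motor tests are scored by completion time with a hard 60-s ceiling; a
mouse that does not finish scores 60. The observed latency mixes two
qualitatively different outcomes — outright failure and lognormal
completion time right-censored at the ceiling:

    y' ~ omega * LogNormal(mu, sigma) + (1 - omega) * delta_60,
    y = y' if y' < 60, else 60.

The likelihood has two branches: an uncensored trial contributes
`omega * f_LN(y; mu, sigma)`; a trial at the ceiling contributes
`omega * (1 - F_LN(60)) + (1 - omega)`. A score of 60 is therefore
deliberately ambiguous between "failed" and "slow", and the model never
tries to separate the two. The censored branch is accumulated with
log-sum-exp; the implied observed-data distribution (density on (0, 60)
plus an atom at 60) integrates to 1, which the test suite checks by
quadrature.

**Fitting.** The NLL is minimized over the unconstrained parameters
(logit omega, mu, log sigma) by L-BFGS-B with an analytic gradient.
Mixture likelihoods can be multimodal, so the default fit uses five
deterministic starts: omega0 in {0.25, 0.5, 0.9} with mu0 = log of the
uncensored median and sigma0 = the sd of the uncensored log-latencies,
plus {0.5, 0.9} with 2x that sd; the best optimum wins. Special cases
are handled in closed form: with no censored trials the MLE is the
plain lognormal MLE (denominator n) with omega pinned at 1; with no
uncensored trials (mu, sigma) are unidentifiable and the fit is
reported degenerate (omega = 0, mu/sigma NaN) rather than invented. An
optimum with |logit omega| > 12 is reported at the corresponding
boundary (omega exactly 1 or 0) so boundary solutions are visible
instead of masquerading as interior estimates.

**Bootstrap.** Confidence intervals are percentile intervals over
parametric-bootstrap replicates: each replicate simulates a dataset of
the original size from the fitted parameters (Bernoulli(omega)
completion; completers draw LogNormal(mu, sigma) censored at 60) and is
refit. Replicate refits warm-start from the generating parameters with
a single optimizer start — the replicate truly comes from that
neighborhood, the analytic gradient makes each refit ~1 ms, and in
validation runs the warm start reproduces the multi-start optimum;
primary fits always use the full multi-start. Per-replicate RNG streams
are keyed by (seed, replicate index), so results are reproducible and
independent of execution order. Failed refits are dropped and counted.
The default replicate count is 10,000; the `run-all` pipeline default
is 500 for desk-scale runtime, and coverage of the 95% interval at 500
replicates is verified at 90–98% in the acceptance suite.

**Model assessment.** Predictive-ECDF envelopes simulate `n_draws`
datasets from the fit, compute each ECDF on a fixed latency grid, and
report pointwise band quantiles together with the fraction of observed
ECDF points inside the band. Q-Q points pair the sorted uncensored
latencies (plotting positions (i - 1/2)/m) against quantiles of the
fitted completion distribution truncated at 60; censored observations
are excluded from the Q-Q set because their completion times are
unobserved.

**Summary statistic.** Because a 60 stands for an arbitrarily long
unobserved time, trial means are uninformative; group comparisons use
the per-animal median across 1–3 trials (even counts: midpoint of the
two central values).

**Pooling.** Mixture fits default to pooled trials within a group —
the mixture is a trial-level model — with a `--medians` flag to fit
per-animal medians instead.

## Rank-based inference

Kruskal-Wallis, Conover-Iman and Dunn statistics are implemented from
their defining formulas with mid-ranks for ties, because the
tie-corrected post-hoc statistics are themselves deliverables here;
scipy's `kruskal` and statsmodels' BH serve as independent
cross-checks in the tests, never as the implementation.

- KW: `H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2`, divided by
  `1 - sum(t^3 - t)/(N^3 - N)`; p from chi-square on k-1 df.
- Conover: `t = (Rbar_a - Rbar_b) / sqrt(S^2 ((N-1-H)/(N-k)) (1/n_a + 1/n_b))`
  with `S^2 = (sum R_i^2 - N(N+1)^2/4)/(N-1)`; the tie-corrected H
  enters the scale factor; two-sided Student t on N-k df. Under heavy
  ties H can exceed N-1; the scale is floored at 0 and the statistic
  then degenerates to ±inf/0 by the sign of the rank difference.
- Dunn: `z = (Rbar_a - Rbar_b) / sqrt((N(N+1)/12 - sum(t^3-t)/(12(N-1))) (1/n_a + 1/n_b))`,
  two-sided normal p.
- BH: step-up `q_(i) = min_{j>=i} (m/j) p_(j)` capped at 1, returned in
  input order. The adjustment family is all pairwise comparisons within
  one endpoint/test.

All post-hoc p-values are two-sided. Under a shared lognormal null the
KW test's empirical size at nominal 5% is verified <= 6% over 2,000
simulations.

## Bioenergetic indices

Specific activity = mean of duplicate total-activity wells minus the
non-specific control; negative values are retained and flagged, not
clamped, since clamping would bias the cohort mean used for centering.
Plate effects are removed per assay by multiplying each sample by
(grand mean of reference specific activities across plates)/(plate
reference mean) — a ratio-of-reference-means factor, the simplest
construction consistent with five reference aliquots per plate. It
equalizes cross-plate reference means exactly and is idempotent.

Features are mean-centered by dividing by the cohort mean over all
animals in the analysis run (not per group), so each centered feature
averages 1. On centered features:

- MHI = (CI + CII + CIV)/(CS + mtDNA density + 1) x 100. The +1 is a
  constant balancing term (three numerator terms over three denominator
  factors) and is never centered; the all-average animal scores exactly
  100.
- MRC = mean(sqrt CI + sqrt CII + sqrt CIV) / mean(cbrt mtDNA density
  + cbrt CS) x 100: square roots apply surface-area scaling to the
  cristae-bound chain complexes and cube roots volume scaling to the
  content markers. With every centered feature at 1 the cohort MRC is
  150 by construction (3/2 x 100). Both a cohort value and a
  per-animal variant (same roots applied animal-wise) are reported,
  since either granularity is plausible in practice.

**qPCR.** dCt = mean nuclear Ct - mean mitochondrial Ct from
triplicates; mtDNAcn = 2^dCt x 2 (diploid nuclear genome). A single
replicate deviating more than 1 Ct from the triplicate median is
dropped (standard qPCR QC); fewer than two usable wells is an error,
and residual spread above 1 Ct raises a warning flag. mtDNA density
follows the index's reference protocol, 2^Ct x 10^-12 ("as-printed").
Note that this quantity *increases* with Ct while template abundance
decreases; because the discrepancy cannot be resolved from the formula
alone, the package evaluates the printed form by default and exposes
`inverse` (2^-Ct x 10^-12) behind an explicit switch rather than
silently guessing intent. The choice does not affect MHI's anchor at
100, which is fixed by mean-centering.

## Respirometry

Each well's trace is summarized per injection phase by the mean over
all cycles in the phase (robust on plateau-shaped traces; no
last-cycle selection). The rotenone + antimycin A plateau estimates
non-mitochondrial oxygen consumption and is subtracted from every
state by default (standard for isolated mitochondria; a switch
disables it). States are divided by the well's protein mass; negative
corrected states are clamped to 0 with a QC flag since negative
respiration is physically meaningless. RCR = State 3 / State 4o is
computed per well and then averaged across a mouse's (typically five)
wells, respecting within-well pairing; a `of-means` switch computes
the ratio of averaged states instead. RCR is undefined (NaN, flagged)
when State 4o <= 0.

## Factorial endpoints

`value ~ genotype + condition + genotype:condition` by OLS
(statsmodels) with treatment coding; the saturated 2x2 model reproduces
cell means exactly. Pairwise contrasts are cell-mean differences with
pooled residual variance (no Welch variant — a single homoscedastic
model is the stated analysis), two-sided t on the residual df, BH
across exactly the requested family; the family must be given
explicitly because figure-level families vary by endpoint.

## Synthetic data

Generators emulate the stated structure of each input: trials are drawn
from the mixture forward model (default four genotype x condition
groups, 16 animals each, 3 trials, 60-s ceiling, with ASO-SPF given
lower omega and slower completion); enzymology has duplicate wells
(CV 5%), a non-specific control, multiplicative plate effects over two
plates, and five reference aliquots per plate per assay; qPCR encodes a
target copy number through dCt = log2(M/2) with iid Ct noise (0.15 Ct)
on triplicates; OCR traces are phase plateaus plus iid cycle noise,
five wells per mouse, protein drawn around 8 ug. Group effect sizes
are chosen to mirror the qualitative direction of the biology the
pipeline targets, not any published magnitude. One master seed expands
into fixed per-generator streams, so outputs are byte-reproducible and
stream-independent.

What the generators do *not* emulate: per-animal random effects and
trial-order learning in behavior, correlated (non-iid) plate noise,
qPCR efficiency differences between amplicons, and drift or injection
artifacts in OCR traces. Green recovery tests therefore establish
correctness of the estimators under the assumed generative structure,
not robustness to those real-data features.

## Numerical choices

- Optimizer: L-BFGS-B, analytic gradient, max 500 iterations per start;
  softplus/log-sum-exp identities keep omega near 0/1 stable.
- Boundary threshold |logit omega| = 12 (omega within ~6e-6 of the
  boundary).
- Bootstrap/percentile intervals use `numpy.percentile` on finite
  replicate estimates.
- CSV output uses `%.12g` floats, LF line endings, UTF-8 — byte-stable
  across platforms.
- Degenerate inputs: all-censored data -> degenerate fit; fewer than
  two distinct uncensored latencies alongside censored ones -> error;
  zero cohort mean -> error; empty factorial cell -> error.

## Limitations

- No per-animal random effects: pooled-trial fits treat trials as
  independent, which understates uncertainty if animals differ strongly
  within a group.
- Percentile bootstrap CIs can undercover near parameter boundaries
  (omega near 1).
- The Conover scale factor floor under extreme ties is a pragmatic
  guard, not a published correction.
- MRC on negative centered features (possible after negative specific
  activities) is undefined and reported as NaN.
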