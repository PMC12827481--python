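# Methods

## Model and assumptions

The score treats DILI risk as the degree of transcriptional perturbation
of a fixed gene signature — the union of the regulons of eight
liver-expressed, apoptosis-promoting transcription factors — in a
treatment-vs-control comparison.  The statistical model is the standard
linear-model / empirical-Bayes framework for gene expression:

* Per gene, log2 expression follows a linear model with an intercept,
  optional donor/batch fixed effects, and a treatment indicator.  The
  design is QR-transformed so the treatment contrast occupies one
  coordinate of the data and the residuals occupy the remaining
  d = n − rank(X) orthonormal coordinates; the gene's evidence is the
  (d+1)-vector v_g of those coordinates.
* Residual variances are modelled as s_g² ~ s₀²·F(d, d₀); the
  hyperparameters are estimated by the method of moments on log s²
  (digamma/trigamma identities, Newton inversion of the trigamma, d₀
  capped at 10⁶ and reported as ∞ above it).  With the mean-variance
  trend enabled, the prior variance is a robustified lowess curve
  (span 0.5, one bisquare iteration) in average log-expression, with d₀
  estimated from the residual dispersion around the curve.
* Moderated t = contrast coordinate / √(posterior variance), mapped to a
  normal-equivalent z through the t CDF.  The mapping runs in log-space
  tails, so |t| of several hundred converts without saturating.

The self-contained rotation test replaces sample permutation: under the
null, v_g/|v_g| is uniform on the d-sphere, so a random unit vector r
yields a resampled contrast coordinate r·v_g and residual variance
(|v_g|² − (r·v_g)²)/d, which is re-moderated with the hyperparameters
estimated once from the observed data (re-estimating per rotation is
possible in principle but adds cost without changing the level; the
one-time estimate is the conventional shortcut).  One rotation is shared
by all genes of a draw, which preserves the inter-gene correlation
structure; this is what keeps the type-I error controlled when signature
genes are co-expressed, and is verified in the acceptance suite against a
gene-permutation test that demonstrably inflates under a shared latent
factor.  Rotation p-values use the (b+1)/(nrot+1) convention with a ≥
comparison, making 1/(nrot+1) the exact floor.

Assumptions worth stating: Gaussian errors on the log scale (rotation
uniformity needs spherical symmetry), a correctly specified mean model
(donor effects additive), and a signature whose perturbation is in fact
informative for hepatotoxic stress — the score measures transcriptional
perturbation, not toxicity itself.

## Score definition and parameters

raw = (PropUp + PropDown)·(−log₁₀ FDR.mixed), normalised by (raw − 0)/4
and clipped to [0, 1].

| parameter | default | meaning / why |
|---|---|---|
| nrot | 9999 | rotations per test; sets the p floor 1/10000 and hence the max raw score 4, the min–max constant |
| set_statistic | floormean | directional means of z floored at 0; mixed = mean |z| (flooring is a no-op on absolute values) |
| active_z_threshold | √2 | "active" gene cutoff for PropUp/PropDown; a convention inherited from the reference rotation-test implementation, not a printed constant, hence config-exposed |
| norm_min, norm_max | 0, 4 | min–max normalisation constants |
| n_noise_iter | 50 | noise-injection re-scorings per treatment |
| ridge_points | 10000 | size of the normal sample drawn from (mean, SD) for ridge plots |
| prior_count (log-CPM) | 0.5 | count offset for log2-CPM |
| tpm_threshold | 1 | liver-expression filter on TFs when building signatures |
| max_evidence | C | regulon curation filter (A<B<C<D<E, A strongest) |

Noise injection adds ε ~ N(0, σ_g²) on the log scale, σ_g being the
gene's SD across **all** samples of the experiment (not the contrast
subset), fresh per iteration from per-iteration substreams of one master
seed.  The rotation stream is shared across iterations, so with σ ≡ 0
every iteration reproduces the point estimate exactly.  The score of
record for a treatment is the mean over iterations; the ridge sample is
not clipped to [0, 1] (visualisation only), the point estimate is.

Platform defaults: counts input (RNA-seq, shallow 3'-end) is converted to
log2-CPM and analysed with the mean-variance trend on; microarray log
intensities are used as-is with the trend on; generic log input defaults
to trend off.  Probes collapse to genes by keeping the probe with the
highest mean intensity across all samples (ties: first in input order —
deterministic, and ties are measure-zero on real data).  Ortholog mapping
keeps only one-to-one pairs; ambiguous genes are dropped and counted
rather than aggregated, to avoid inventing expression values.

## Evaluation components

* Threshold sweep: candidate cutoffs are all observed scores plus 0 and 1;
  prediction is positive iff score ≥ cutoff (closed on the positive side,
  so each observed score is its own usable cutoff).  Undefined metrics
  (0/0) propagate as missing, never as 0; MCC is 0 when a marginal is 0.
  Best threshold = argmax MCC, lowest on ties.
* Fisher's exact test: two-sided p by the probability-mass definition;
  the odds ratio is the conditional MLE of the noncentral hypergeometric
  model with an exact 95% CI from inverting one-sided tests at α/2
  (scipy's implementation of the same estimator the R convention uses;
  CI upper limits can differ from R's by <1% due to inversion details).
* Pair ranking: ΔDILI per structurally-similar pair per dose, one-sample
  two-sided t-test across pairs; an all-zero Δ vector gives p = 1 by
  convention, a constant non-zero Δ is flagged degenerate with p → 0.
* Dose-response: log-logistic f(x) = c + (d−c)/(1+exp(b(ln x − ln e))),
  fitted by least squares with e parameterised on the log scale
  (positivity and exact dose-rescaling equivariance), heuristic
  initialisation (asymptotes from the data range, midpoint from the
  half-range crossing, slope from a logit-linear regression) plus five
  jittered restarts, best SSE wins.  The 4-parameter fit bounds c, d to
  [0, 1] (normalised scores); the 2-parameter fit fixes c=0, d=1.
  Negative b means the response rises with dose.  SEs are asymptotic
  (Jacobian-based, delta method for e), and a flat response is flagged
  non-identifiable with slope p = 1 rather than fitted silently.

## Synthetic data

The generator emulates the structure the score assumes:
Y[g,s] = μ_g + ρF_s + δ_g(dose)·1[treated] + ε with ε ~ N(0, noise_sd²),
F_s a shared standard-normal factor, and δ_g(dose) = ±δ/(1+exp(b(ln dose −
ln e))) for the perturbed fraction of signature genes.  Defaults are the
package's study conditions: a 241-gene signature over 8 TF sets, 3
replicates per group, doses 0.1/1/10 × C_max, log2 baseline N(8, 2²),
residual SD 0.5, effect size 1 log2 unit on 60% of signature genes split
evenly up/down, Hill (−1, 1) so the perturbation is half-maximal at
C_max.  Values not fixed by the study design (baseline scale, noise SD,
effect size and split) were chosen once as typical of moderate-depth
liver transcriptomics and are not tuned.  A count mode
(Poisson around 2^Y, then log-CPM) exercises the counts path.  Panels
spawn one substream per compound from the master seed, so they are
reproducible and order-independent.

What the generator does *not* emulate: plate/library-size artefacts of
shallow 3'-end protocols, mean-variance relationships of real counts
beyond Poisson, donor-specific biology, or any real regulon membership
(the bundled 241-gene GMT is a synthetic stand-in with the right
structure).  Passing tests therefore demonstrate the statistical
machinery — calibration, power ordering, parameter recovery,
determinism — not clinical predictivity on real data.

## Problem sizes in the validation suite

The statistical acceptance checks use desk-scale problem sizes chosen to
make their Monte-Carlo error small relative to the tested tolerance: 500
replicate simulations for type-I error (binomial 99% CI half-width ≈
0.025 around α = 0.05), a 500,000-draw brute-force rotation oracle
(3-SE agreement band ≈ 0.015 at the compared p), 20 seeds × 2000 genes
for hyperparameter recovery (±1 on d₀ = 4, ±10% on s₀² = 2), and 50
seeds for noisy EC50 recovery (median within 25%).

## Known limitations

* The exact floormean/active-threshold conventions are reference-
  compatible by intent but not printed anywhere authoritative; both are
  config-exposed.
* The conditional-MLE CI can differ from R's `fisher.test` upper limit by
  up to ~1% (both are exact inversions; the root-finding conventions
  differ).
* With a single tested set, FDR.mixed = p.mixed; multi-set runs share one
  rotation stream, so per-TF breakdowns are comparable within a call but
  add no fresh randomness.
* Scores at the p floor are indistinguishable beyond PropUp + PropDown;
  increasing nrot is the only way to extend the scale (and changes the
  normalisation constant).
* The noise-injection SD is computed per experiment (all samples), which
  conflates treatment effect with technical noise for strong responders;
  this biases iteration means conservatively downward at high doses.
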