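# aegis-dili

Dose-dependent drug-induced liver injury (DILI) risk scoring from
treatment-vs-control transcriptomics.

Most clinically relevant (intrinsic) DILI is dose-dependent, and the
mechanisms of many hepatotoxic drugs converge on apoptosis.  This package
quantifies how strongly a treatment perturbs the regulons of
apoptosis-regulating transcription factors (ATF3, E2F3, FOXA1, FOXO3, JUN,
PPARG, REST, TFAP4 — liver-expressed positive regulators of apoptosis) and
turns that perturbation into a normalised risk score in [0, 1] that can be
compared across compounds, doses (expressed as multiples of the clinical
C_max), species, and transcriptomics platforms (RNA-seq counts, microarray
intensities, shallow 3'-end profiling).  It is aimed at safety scientists
and computational biologists ranking compounds during preclinical drug
discovery.

## The score

For one treatment-vs-control contrast, each gene g is fitted by a linear
model (intercept, optional donor fixed effects, treatment indicator) and
its residual variance s_g² is shrunk by empirical Bayes toward a prior
(d₀, s₀²), giving moderated t statistics and normal-equivalent z scores.
The combined signature set is then tested with a **rotation gene-set
test**: the data of each gene reduce to the (d+1)-vector of its contrast
coordinate and d residual coordinates; resampling draws random unit
vectors on the d-sphere, **one rotation shared by all genes per draw**, so
inter-gene correlation is preserved.  Set summaries are *floormean*
statistics

    S_up = mean(max(z, 0)),  S_down = mean(max(−z, 0)),  S_mixed = mean(|z|)

with p-values (b+1)/(nrot+1) over nrot = 9999 rotations and
Benjamini–Hochberg adjustment across sets.  The score is

    raw        = (PropUp + PropDown) · (−log₁₀ FDR.mixed)
    normalised = clip(raw / 4, 0, 1)

where PropUp/PropDown are the fractions of signature genes with |z| > √2
in each direction.  The p-value floor of 1/10000 makes 4 the exact maximum
of the raw score, hence the min–max constants (min 0, max 4).  Confidence
comes from 50 noise-injection re-scorings (gene-level SD noise), and the
mean/SD parameterise 10,000-point normal samples for ridge plots.

Around the score the package provides threshold calibration (stepwise
cutoff sweep with specificity/sensitivity/precision/MCC and the best-MCC
high-risk threshold), Fisher's exact test with the conditional-MLE odds
ratio and exact CI, paired compound ranking (ΔDILI with a one-sample
t-test), log-logistic (Hill) dose-response fits of score vs dose, and a
fully specified synthetic-data generator so every stage is testable
without any external download.

## Worked example

```python
from aegis import (DiliScoreModel, RotationConfig, ScoringConfig,
                   SimulationConfig, fit_loglogistic, simulate_experiment)

exp = simulate_experiment(SimulationConfig(seed=1))  # 241-gene signature,
#   doses 0.1/1/10 x C_max, 3 replicates/group, Hill-scaled perturbation
model = DiliScoreModel(exp.matrix, exp.design, exp.signature,
                       rotation=RotationConfig(nrot=9999),
                       scoring=ScoringConfig(n_noise_iter=50), seed=1)
res = model.fit()
print(res.summary())
```

```
DILI score results
  signature sets: 9 (241 combined genes)
  rotations: 9999   trend: False
  contrasts scored: 3

 compound  dose_multiple  donor  prop_up  prop_down  fdr_mixed     raw  normalized  score_mean  score_sd
compound1            0.1 donor1  0.05809    0.08714     0.4577 0.04929     0.01232     0.01929   0.01667
compound1              1 donor1   0.1452     0.1494     0.0016  0.8237      0.2059      0.1142   0.05434
compound1             10 donor1   0.2863     0.2656     0.0001   2.207      0.5519      0.3378   0.04732
```

One row per treatment contrast: at 0.1×C_max the signature is essentially
unperturbed (score ≈ 0.01), at 10×C_max more than half of the signature
responds (55% of genes active in either direction, FDR at the 1e-4 floor,
normalised point score 0.55; mean over 50 noise iterations 0.34 ± 0.05).
Fitting the dose response:

```python
scores = res.scores[res.scores.dose_multiple > 0]
print(fit_loglogistic(scores["dose_multiple"], scores["score_mean"], n_params=2).summary())
```

```
log-logistic dose-response fit (2 parameters, 3 observations)
  converged: True   identifiable: True
  SSE: 0.000110513
  b (Hill slope)      -0.6221   se 0.0446   p 0.0455
  e (EC50)              29.28   se 3.72   p 0.0805
  c (lower)                 0   (fixed)
  d (upper)                 1   (fixed)
```

The negative Hill slope means the score rises with dose; the EC50 is the
dose multiple at half-maximal perturbation.

The same workflow is available from the shell:

```sh
aegis simulate --seed 8 --out fx/
aegis score --matrix fx/expression.tsv --samples fx/samples.csv \
            --signature fx/signature.gmt --platform rnaseq --seed 1 --out out/
aegis calibrate --scores out/scores.tsv --labels labels.csv --out cal/
aegis fit-dose --scores out/scores.tsv --out fit.json
aegis metrics --tp 9 --fn 3 --fp 1 --tn 6
```

The bundled signature file (`aegis.default_signature()`) is a synthetic
stand-in with the correct structure (8 TF regulons, 241 distinct genes);
supply your own GMT built from a curated regulon resource for real
analyses (`aegis.build_signature` applies the TPM > 1 liver-expression and
evidence A–C filters).

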