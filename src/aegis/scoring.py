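"""DILI score computation, noise-injection confidence and ridge samples.

The raw score of a treatment is

    raw = (PropUp + PropDown) * -log10(FDR.mixed)

where PropUp/PropDown are the fractions of signature genes actively shifted
up/down and FDR.mixed is the BH-adjusted mixed-direction rotation p-value.
With 9999 rotations the p-value floor is 1/10000, so raw <= 4; the score of
record is min-max normalised to [0, 1] with min 0 and max 4.

Confidence is estimated by re-scoring each treatment 50 times with Gaussian
noise added to the expression values, scaled per gene by that gene's
standard deviation across all samples of the experiment.  The mean/SD over
iterations parameterise a 10,000-point normal "ridge" sample used for
visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, SampleDesign
from .linear_model import fit_contrast, moderate
from .rotation import RotationConfig, RotationTestResult, rotation_test, rotation_test_multi
from .signature import COMBINED_SET, GeneSignature


@dataclass
class ScoringConfig:
    norm_min: float = 0.0
    norm_max: float = 4.0
    n_noise_iter: int = 50
    ridge_points: int = 10000
    seed: int | None = None
    clip: bool = True

    def __post_init__(self) -> None:
        if self.norm_max <= self.norm_min:
            raise ValueError("norm_max must exceed norm_min")
        if self.n_noise_iter < 1:
            raise ValueError("n_noise_iter must be >= 1")


@dataclass
class DiliScore:
    """Raw and min-max normalised DILI score for one treatment contrast."""

    raw: float
    normalized: float
    prop_up: float
    prop_down: float
    fdr_mixed: float
    metadata: dict = field(default_factory=dict)


@dataclass
class ScoreDistribution:
    """Noise-injection score distribution: per-iteration scores, their
    mean/SD, and a normal ridge sample (not clipped; visualisation only)."""

    mean: float
    sd: float
    iteration_scores: np.ndarray
    ridge_sample: np.ndarray
    point: DiliScore | None = None


def dili_score(row: pd.Series, cfg: ScoringConfig | None = None, metadata: dict | None = None) -> DiliScore:
    """Score one rotation-test result row: (prop_up + prop_down) *
    -log10(fdr_mixed), min-max normalised (and clipped) to [0, 1]."""
    cfg = cfg or ScoringConfig()
    fdr = float(row["fdr_mixed"])
    if not (0.0 < fdr <= 1.0):
        raise ValueError(f"fdr_mixed must be in (0, 1], got {fdr}")
    raw = (float(row["prop_up"]) + float(row["prop_down"])) * -np.log10(fdr)
    normalized = (raw - cfg.norm_min) / (cfg.norm_max - cfg.norm_min)
    if cfg.clip:
        normalized = float(np.clip(normalized, 0.0, 1.0))
    return DiliScore(
        raw=raw,
        normalized=normalized,
        prop_up=float(row["prop_up"]),
        prop_down=float(row["prop_down"]),
        fdr_mixed=fdr,
        metadata=metadata or {},
    )


def score_contrast(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    sig: GeneSignature,
    rot_cfg: RotationConfig | None = None,
    score_cfg: ScoringConfig | None = None,
    set_name: str | None = None,
) -> DiliScore:
    """Full pipeline for one contrast: fit -> moderate -> rotate -> score."""
    rot_cfg = rot_cfg or RotationConfig()
    fit = fit_contrast(matrix, design)
    mod = moderate(fit, trend=rot_cfg.trend)
    res = rotation_test(fit, mod, sig, rot_cfg, set_name=set_name)
    return dili_score(res.table.iloc[0], score_cfg)


def score_with_confidence(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    sig: GeneSignature,
    rot_cfg: RotationConfig | None = None,
    score_cfg: ScoringConfig | None = None,
    noise_sd: np.ndarray | None = None,
    set_name: str | None = None,
) -> ScoreDistribution:
    """Noise-injection confidence for one treatment contrast.

    Each iteration adds fresh Gaussian noise eps[g, s] ~ N(0, sigma_g^2)
    on the log scale, with sigma_g the sample SD of gene g across all
    samples (``noise_sd`` overrides, e.g. to use the SD of a wider
    experiment than the contrast subset), then recomputes the score.  One
    master seed spawns independent per-iteration streams, so results are
    reproducible and independent of iteration order.
    """
    rot_cfg = rot_cfg or RotationConfig()
    score_cfg = score_cfg or ScoringConfig()
    if matrix.scale != "log":
        raise ValueError("score_with_confidence expects a log-scale matrix")
    sigma = matrix.values.std(axis=1, ddof=1) if noise_sd is None else np.asarray(noise_sd, float)
    n_iter = score_cfg.n_noise_iter
    ss = np.random.SeedSequence(score_cfg.seed)
    children = ss.spawn(n_iter + 2)
    scores = np.empty(n_iter)
    point = score_contrast(matrix, design, sig, rot_cfg, score_cfg, set_name=set_name)
    # one rotation stream shared by all iterations: with zero noise every
    # iteration then reproduces the point estimate exactly
    rot_seed = rot_cfg.seed
    if rot_seed is None:
        rot_seed = int(np.random.default_rng(children[-2]).integers(2**31 - 1))
    it_rot = RotationConfig(
        nrot=rot_cfg.nrot,
        set_statistic=rot_cfg.set_statistic,
        seed=rot_seed,
        trend=rot_cfg.trend,
        active_z_threshold=rot_cfg.active_z_threshold,
    )
    for i in range(n_iter):
        rng = np.random.default_rng(children[i])
        noisy = matrix.values + sigma[:, None] * rng.standard_normal(matrix.values.shape)
        noisy_m = ExpressionMatrix(noisy, matrix.gene_ids, matrix.sample_ids, "log")
        scores[i] = score_contrast(noisy_m, design, sig, it_rot, score_cfg, set_name=set_name).normalized
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1)) if n_iter > 1 else 0.0
    ridge_rng = np.random.default_rng(children[-1])
    ridge = mean + sd * ridge_rng.standard_normal(score_cfg.ridge_points)
    return ScoreDistribution(mean=mean, sd=sd, iteration_scores=scores,
                             ridge_sample=ridge, point=point)


def regulon_breakdown(
    fit,
    mod,
    sig: GeneSignature,
    rot_cfg: RotationConfig | None = None,
    score_cfg: ScoringConfig | None = None,
) -> pd.DataFrame:
    """Per-TF perturbation scores from one shared-rotation multi-set test.

    Returns a DataFrame indexed by TF (combined set excluded when per-TF
    sets exist) with prop_up, prop_down, fdr_mixed, raw and normalized.
    """
    score_cfg = score_cfg or ScoringConfig()
    tf_sets = {n: g for n, g in sig.sets.items() if n != COMBINED_SET}
    sub = GeneSignature(sets=tf_sets or dict(sig.sets), provenance=sig.provenance)
    res = rotation_test_multi(fit, mod, sub, rot_cfg)
    rows = []
    for name in res.table.index:
        sc = dili_score(res.table.loc[name], score_cfg)
        rows.append(
            {
                "set": name,
                "n_genes": int(res.table.loc[name, "n_genes"]),
                "prop_up": sc.prop_up,
                "prop_down": sc.prop_down,
                "fdr_mixed": sc.fdr_mixed,
                "raw": sc.raw,
                "normalized": sc.normalized,
            }
        )
    return pd.DataFrame(rows).set_index("set")
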