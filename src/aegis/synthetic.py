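"""Synthetic treatment-vs-control experiments with known ground truth.

The generator emulates the data the score assumes: a log2-scale expression
matrix in which a configurable fraction of signature genes is shifted up
or down in treated samples, with the shift scaled across dose by a Hill
(log-logistic) factor, per-gene Gaussian noise, and an optional shared
latent factor inducing inter-gene correlation.  Defaults mirror the study
conditions the score was built for: a 241-gene signature over 8 TF
regulons, 3 replicates per group, and doses of 0.1, 1 and 10 x C_max.

Y[g, s] = mu_g + rho * F_s + delta_g(dose_s) * 1[s treated] + eps[g, s]

with eps ~ N(0, noise_sd^2), F_s ~ N(0, 1) shared across genes, and
delta_g(dose) = sign_g * effect_size / (1 + exp(b * (ln dose - ln e)))
for perturbed signature genes (0 otherwise).  With negative Hill slope b
the perturbation grows with dose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, SampleDesign
from .signature import COMBINED_SET, GeneSignature

TF_NAMES = ("ATF3", "E2F3", "FOXA1", "FOXO3", "JUN", "PPARG", "REST", "TFAP4")


@dataclass
class SimulationConfig:
    """Generative settings; defaults are the package's study conditions.

    ``effect_size`` is the asymptotic log2 shift of a perturbed gene;
    ``hill`` = (slope, EC50 in dose multiples) scales it across dose;
    ``gene_correlation`` is the loading of a shared standard-normal factor.
    """

    n_genes: int = 2000
    n_signature: int = 241
    n_tf_sets: int = 8
    n_per_group: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    effect_size: float = 1.0
    frac_perturbed: float = 0.6
    direction_mix: float = 0.5
    dose_levels: tuple = (0.1, 1.0, 10.0)
    hill: tuple = (-1.0, 1.0)
    gene_correlation: float = 0.0
    noise_sd: float = 0.5
    compound: str = "compound1"
    count_mode: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_perturbed <= 1.0 and 0.0 <= self.direction_mix <= 1.0):
            raise ValueError("fractions must be in [0, 1]")
        if any(d <= 0 for d in self.dose_levels):
            raise ValueError("dose levels must be > 0")
        if self.n_signature > self.n_genes:
            raise ValueError("n_signature cannot exceed n_genes")
        if self.n_tf_sets < 1 or self.n_tf_sets > self.n_signature:
            raise ValueError("invalid n_tf_sets")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class SimulatedExperiment:
    """Matrix + design + signature + ground truth for one compound."""

    matrix: ExpressionMatrix
    design: SampleDesign
    signature: GeneSignature
    truth: dict

    def write(self, outdir: str | Path) -> None:
        """Write matrix TSV, sample sheet CSV, signature GMT and truth JSON."""
        from .signature import write_signature

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.matrix.to_tsv(outdir / "expression.tsv")
        self.design.to_csv(outdir / "samples.csv")
        write_signature(self.signature, outdir / "signature.gmt")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2, default=str))


def hill_factor(dose: float, slope: float, ec50: float) -> float:
    """Log-logistic dose scaling in [0, 1]; rises with dose when slope < 0."""
    return 1.0 / (1.0 + np.exp(slope * (np.log(dose) - np.log(ec50))))


def _make_signature(cfg: SimulationConfig, gene_ids: list[str], rng: np.random.Generator) -> tuple[GeneSignature, list[str]]:
    sig_genes = list(rng.choice(gene_ids, size=cfg.n_signature, replace=False))
    names = list(TF_NAMES[: cfg.n_tf_sets]) if cfg.n_tf_sets <= len(TF_NAMES) else [
        f"TF{i+1}" for i in range(cfg.n_tf_sets)
    ]
    splits = np.array_split(np.arange(cfg.n_signature), cfg.n_tf_sets)
    sets = {name: [sig_genes[i] for i in idx] for name, idx in zip(names, splits)}
    sets[COMBINED_SET] = list(sig_genes)
    return GeneSignature(sets=sets, provenance="simulated"), sig_genes


def simulate_experiment(cfg: SimulationConfig | None = None, **overrides) -> SimulatedExperiment:
    """Generate one treatment-vs-control experiment for one compound.

    Samples: ``n_per_group`` vehicle controls plus ``n_per_group`` treated
    samples at every dose level.  The truth record lists the perturbed
    genes, their directions, and the realised per-dose effect sizes.
    """
    if cfg is None:
        cfg = SimulationConfig(**overrides)
    elif overrides:
        cfg = SimulationConfig(**{**asdict(cfg), **overrides})
    rng = np.random.default_rng(cfg.seed)

    width = len(str(cfg.n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    signature, sig_genes = _make_signature(cfg, gene_ids, rng)

    n_pert = int(round(cfg.frac_perturbed * cfg.n_signature))
    perturbed = list(rng.choice(sig_genes, size=n_pert, replace=False)) if n_pert else []
    n_up = int(round(cfg.direction_mix * n_pert))
    signs = np.array([1.0] * n_up + [-1.0] * (n_pert - n_up))

    sample_ids, compounds, doses, groups, donors = [], [], [], [], []
    for r in range(cfg.n_per_group):
        sample_ids.append(f"ctrl_r{r + 1}")
        compounds.append("vehicle")
        doses.append(0.0)
        groups.append("control")
        donors.append("donor1")
    for dose in cfg.dose_levels:
        for r in range(cfg.n_per_group):
            sample_ids.append(f"treat_d{dose:g}_r{r + 1}")
            compounds.append(cfg.compound)
            doses.append(dose)
            groups.append("treatment")
            donors.append("donor1")
    n_samples = len(sample_ids)

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    Y = mu[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_samples))
    if cfg.gene_correlation:
        F = rng.standard_normal(n_samples)
        Y += cfg.gene_correlation * F[None, :]

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    slope, ec50 = cfg.hill
    realized: dict[str, float] = {}
    for s_idx in range(n_samples):
        if groups[s_idx] != "treatment":
            continue
        factor = hill_factor(doses[s_idx], slope, ec50)
        realized[f"{doses[s_idx]:g}"] = float(cfg.effect_size * factor)
        for g, sign in zip(perturbed, signs):
            Y[gene_pos[g], s_idx] += sign * cfg.effect_size * factor

    if cfg.count_mode:
        lam = np.exp2(np.clip(Y, 0, 30))
        counts = rng.poisson(lam).astype(float)
        matrix = ExpressionMatrix(counts, gene_ids, sample_ids, "counts")
    else:
        matrix = ExpressionMatrix(Y, gene_ids, sample_ids, "log")

    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "compound": compounds,
                "dose_multiple": doses,
                "group": groups,
                "donor": donors,
            }
        )
    )
    truth = {
        "perturbed_genes": perturbed,
        "directions": {g: int(s) for g, s in zip(perturbed, signs)},
        "effect_size": cfg.effect_size,
        "realized_delta_by_dose": realized,
        "frac_perturbed": cfg.frac_perturbed,
        "compound": cfg.compound,
        "label": "positive" if cfg.effect_size > 0 and n_pert else "negative",
    }
    return SimulatedExperiment(matrix=matrix, design=design, signature=signature, truth=truth)


def simulate_compound_panel(
    cfg: SimulationConfig | None = None,
    n_positive: int = 12,
    n_negative: int = 7,
    **overrides,
) -> list[SimulatedExperiment]:
    """A panel of independently simulated compounds with DILI labels.

    Positives use the configured effect size; negatives use effect 0.  The
    master seed spawns an independent substream per compound, so the panel
    is reproducible and order-independent.
    """
    if cfg is None:
        cfg = SimulationConfig(**overrides)
    elif overrides:
        cfg = SimulationConfig(**{**asdict(cfg), **overrides})
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(n_positive + n_negative)
    panel = []
    for i in range(n_positive + n_negative):
        positive = i < n_positive
        sub_seed = int(np.random.default_rng(children[i]).integers(2**31 - 1))
        sub = SimulationConfig(
            **{
                **asdict(cfg),
                "effect_size": cfg.effect_size if positive else 0.0,
                "compound": f"{'pos' if positive else 'neg'}_{i + 1 if positive else i - n_positive + 1}",
                "seed": sub_seed,
            }
        )
        panel.append(simulate_experiment(sub))
    return panel
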