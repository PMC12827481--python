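"""Model/Results interface tying the pipeline together.

:class:`DiliScoreModel` is constructed from an expression matrix, a sample
design and a gene signature; :meth:`DiliScoreModel.fit` scores every
(compound, dose, donor) treatment contrast against its matched controls
and returns a :class:`DiliScoreResults` carrying the scores, their
noise-injection uncertainties, the per-TF regulon breakdown and a
``summary()`` table.

Typical use::

    model = DiliScoreModel(matrix, design, signature, seed=1)
    res = model.fit()
    print(res.summary())
    res.to_tsv("out/")
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, SampleDesign, load_expression, log_cpm
from .linear_model import fit_contrast, moderate
from .rotation import RotationConfig
from .scoring import (
    ScoringConfig,
    ScoreDistribution,
    regulon_breakdown,
    score_with_confidence,
)
from .signature import GeneSignature, read_signature

PLATFORM_DEFAULTS = {
    # platform -> (expects counts, trend)
    "rnaseq": (True, True),
    "microarray": (False, True),
    "shallow3prime": (True, True),
}


class DiliScoreModel:
    """Dose-dependent DILI risk score model for one experiment.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Genes x samples; counts are converted to log2-CPM on construction
        (enabling the mean-variance trend by default).
    design : SampleDesign
        Sample sheet; every sample id must exist in the matrix.
    signature : GeneSignature
        TF regulon signature; the combined set drives the score.
    rotation, scoring : optional configs; ``seed`` (if given) overrides
        both configs' seeds and makes the whole fit reproducible.
    trend : force the mean-variance trend on/off (default: on for counts
        input, off for log input).
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        design: SampleDesign,
        signature: GeneSignature,
        rotation: RotationConfig | None = None,
        scoring: ScoringConfig | None = None,
        trend: bool | None = None,
        seed: int | None = None,
    ) -> None:
        design.check_matrix(matrix)
        if matrix.scale == "counts":
            matrix = log_cpm(matrix)
            trend = True if trend is None else trend
        else:
            trend = False if trend is None else trend
        self.matrix = matrix
        self.design = design
        self.signature = signature
        self.seed = seed
        self.rotation = rotation or RotationConfig()
        self.rotation.trend = trend
        self.scoring = scoring or ScoringConfig()
        self.trend = trend

    @classmethod
    def from_files(
        cls,
        matrix_path: str | Path,
        samples_path: str | Path,
        signature_path: str | Path,
        platform: str = "rnaseq",
        **kwargs,
    ) -> "DiliScoreModel":
        if platform not in PLATFORM_DEFAULTS:
            raise ValueError(f"platform must be one of {sorted(PLATFORM_DEFAULTS)}")
        counts, trend = PLATFORM_DEFAULTS[platform]
        matrix = load_expression(matrix_path, scale="counts" if counts else "log")
        design = SampleDesign.from_csv(samples_path)
        signature = read_signature(signature_path)
        kwargs.setdefault("trend", trend)
        return cls(matrix, design, signature, **kwargs)

    def _contrasts(self) -> list[dict]:
        """One contrast per (compound, dose, donor) treatment group vs its
        donor-matched controls (all controls when the donor has none)."""
        tab = self.design.table
        controls = tab[tab["group"] == "control"]
        if controls.empty:
            raise ValueError("no control samples in design")
        treatments = tab[tab["group"] == "treatment"]
        if treatments.empty:
            raise ValueError("no treatment samples in design")
        out = []
        keys = sorted(
            treatments.groupby(["compound", "dose_multiple", "donor"]).groups
        )
        for compound, dose, donor in keys:
            treat = treatments[
                (treatments["compound"] == compound)
                & (treatments["dose_multiple"] == dose)
                & (treatments["donor"] == donor)
            ]
            ctrl = controls[controls["donor"] == donor]
            if ctrl.empty:
                ctrl = controls
            if len(ctrl) < 2 or len(treat) < 2:
                raise ValueError(
                    f"contrast ({compound}, {dose}, {donor}) needs >=2 treatment and "
                    f">=2 control samples (got {len(treat)} and {len(ctrl)})"
                )
            out.append(
                {
                    "compound": compound,
                    "dose_multiple": dose,
                    "donor": donor,
                    "design": SampleDesign(pd.concat([ctrl, treat], ignore_index=True)),
                }
            )
        return out

    def fit(self, noise: bool = True) -> "DiliScoreResults":
        """Score every treatment contrast.

        With ``noise=True`` (default) each contrast is re-scored
        ``scoring.n_noise_iter`` times under gene-level noise injection and
        the score of record is the iteration mean; with ``noise=False`` a
        single no-noise score is reported (score_sd = 0).
        """
        contrasts = self._contrasts()
        sigma = self.matrix.values.std(axis=1, ddof=1)
        master = np.random.SeedSequence(self.seed)
        children = master.spawn(len(contrasts))
        rows = []
        regulon_rows = []
        ridge: dict[tuple, np.ndarray] = {}
        for child, con in zip(children, contrasts):
            sub_design = con["design"]
            sub_matrix = self.matrix.subset_samples(list(sub_design.table["sample_id"]))
            crng = np.random.default_rng(child)
            rot_cfg = RotationConfig(
                nrot=self.rotation.nrot,
                set_statistic=self.rotation.set_statistic,
                seed=int(crng.integers(2**31 - 1)),
                trend=self.trend,
                active_z_threshold=self.rotation.active_z_threshold,
            )
            score_cfg = ScoringConfig(
                norm_min=self.scoring.norm_min,
                norm_max=self.scoring.norm_max,
                n_noise_iter=self.scoring.n_noise_iter if noise else 1,
                ridge_points=self.scoring.ridge_points,
                seed=int(crng.integers(2**31 - 1)),
                clip=self.scoring.clip,
            )
            if noise:
                dist = score_with_confidence(
                    sub_matrix, sub_design, self.signature, rot_cfg, score_cfg,
                    noise_sd=sigma,
                )
                point = dist.point
                score_mean, score_sd = dist.mean, dist.sd
                ridge[(con["compound"], con["dose_multiple"], con["donor"])] = dist.ridge_sample
            else:
                from .scoring import score_contrast

                point = score_contrast(sub_matrix, sub_design, self.signature, rot_cfg, score_cfg)
                score_mean, score_sd = point.normalized, 0.0
            rows.append(
                {
                    "compound": con["compound"],
                    "dose_multiple": con["dose_multiple"],
                    "donor": con["donor"],
                    "prop_up": point.prop_up,
                    "prop_down": point.prop_down,
                    "fdr_mixed": point.fdr_mixed,
                    "raw": point.raw,
                    "normalized": point.normalized,
                    "score_mean": score_mean,
                    "score_sd": score_sd,
                }
            )
            if len(self.signature.tf_names) > 1:
                fitc = fit_contrast(sub_matrix, sub_design)
                modc = moderate(fitc, trend=self.trend)
                bd = regulon_breakdown(fitc, modc, self.signature, rot_cfg, score_cfg)
                bd = bd.reset_index()
                bd.insert(0, "compound", con["compound"])
                bd.insert(1, "dose_multiple", con["dose_multiple"])
                bd.insert(2, "donor", con["donor"])
                regulon_rows.append(bd)
        scores = pd.DataFrame(rows)
        regulons = (
            pd.concat(regulon_rows, ignore_index=True) if regulon_rows else pd.DataFrame()
        )
        return DiliScoreResults(model=self, scores=scores, regulon_scores=regulons, ridge_samples=ridge)


@dataclass
class DiliScoreResults:
    """Fitted DILI scores with uncertainties and regulon breakdown."""

    model: DiliScoreModel
    scores: pd.DataFrame
    regulon_scores: pd.DataFrame
    ridge_samples: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "DILI score results",
            f"  signature sets: {len(self.model.signature.set_names)} "
            f"({len(self.model.signature.combined)} combined genes)",
            f"  rotations: {self.model.rotation.nrot}   trend: {self.model.trend}",
            f"  contrasts scored: {len(self.scores)}",
            "",
            self.scores.to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
                columns=[
                    "compound", "dose_multiple", "donor", "prop_up", "prop_down",
                    "fdr_mixed", "raw", "normalized", "score_mean", "score_sd",
                ],
            ),
        ]
        return "\n".join(lines)

    def signature_hash(self) -> str:
        payload = json.dumps(self.model.signature.sets, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def provenance(self) -> dict:
        import scipy
        import statsmodels

        from . import __version__

        return {
            "seed": self.model.seed,
            "rotation": {
                "nrot": self.model.rotation.nrot,
                "set_statistic": self.model.rotation.set_statistic,
                "active_z_threshold": self.model.rotation.active_z_threshold,
                "trend": self.model.trend,
            },
            "scoring": {
                "norm_min": self.model.scoring.norm_min,
                "norm_max": self.model.scoring.norm_max,
                "n_noise_iter": self.model.scoring.n_noise_iter,
                "ridge_points": self.model.scoring.ridge_points,
            },
            "signature_sha256": self.signature_hash(),
            "versions": {
                "aegis": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "statsmodels": statsmodels.__version__,
            },
        }

    def to_tsv(self, outdir: str | Path) -> None:
        """Write scores.tsv, regulon_scores.tsv and provenance.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
        if not self.regulon_scores.empty:
            self.regulon_scores.to_csv(outdir / "regulon_scores.tsv", sep="\t", index=False)
        (outdir / "provenance.json").write_text(json.dumps(self.provenance(), indent=2))

    def plot_ridge(self, ax=None):
        """Stacked density ("ridge") plot of the noise-injection score
        distributions, one row per treatment contrast."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.8 * max(len(self.ridge_samples), 1) + 1))
        from scipy.stats import gaussian_kde

        grid = np.linspace(-0.1, 1.1, 300)
        for i, (key, sample) in enumerate(sorted(self.ridge_samples.items())):
            if np.std(sample) < 1e-12:
                dens = np.zeros_like(grid)
                dens[np.argmin(np.abs(grid - sample.mean()))] = 1.0
            else:
                dens = gaussian_kde(sample)(grid)
                dens /= dens.max()
            ax.fill_between(grid, i, i + 0.9 * dens, alpha=0.7)
            ax.text(-0.12, i, " ".join(str(k) for k in key), ha="right", va="bottom", fontsize=8)
        ax.set_xlabel("normalised DILI score")
        ax.set_yticks([])
        return ax
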