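"""DILI score formula, noise-injection confidence and regulon breakdown."""

import numpy as np
import pandas as pd
import pytest

from aegis import (
    COMBINED_SET,
    GeneSignature,
    RotationConfig,
    ScoringConfig,
    dili_score,
    fit_contrast,
    moderate,
    regulon_breakdown,
    score_contrast,
    score_with_confidence,
)
from aegis.expression import ExpressionMatrix


def row(prop_up, prop_down, fdr):
    return pd.Series({"prop_up": prop_up, "prop_down": prop_down, "fdr_mixed": fdr})


class TestFormula:
    @pytest.mark.parametrize(
        "prop_up,prop_down,fdr,raw,norm",
        [
            (0.5, 0.25, 1e-4, 3.0, 0.75),
            (0.0, 0.0, 1.0, 0.0, 0.0),
            (0.6, 0.4, 1e-4, 4.0, 1.0),  # maximal case at the 9999-rotation floor
            (1.0, 0.0, 0.1, 1.0, 0.25),
        ],
    )
    def test_score_arithmetic(self, prop_up, prop_down, fdr, raw, norm):
        sc = dili_score(row(prop_up, prop_down, fdr))
        assert sc.raw == pytest.approx(raw)
        assert sc.normalized == pytest.approx(norm)

    def test_clipping_above_norm_max(self):
        sc = dili_score(row(1.0, 0.0, 1e-6))  # raw 6 > 4, only possible with nrot > 10^4
        assert sc.raw == pytest.approx(6.0)
        assert sc.normalized == 1.0
        unclipped = dili_score(row(1.0, 0.0, 1e-6), ScoringConfig(clip=False))
        assert unclipped.normalized == pytest.approx(1.5)

    def test_invalid_fdr_rejected(self):
        with pytest.raises(ValueError):
            dili_score(row(0.5, 0.5, 0.0))


class TestNoiseInjection:
    def test_zero_noise_gives_zero_sd(self, small_experiment):
        exp = small_experiment
        sub = exp.design.table[
            (exp.design.table.group == "control") | (exp.design.table.dose_multiple == 10.0)
        ]
        from aegis import SampleDesign

        design = SampleDesign(sub.reset_index(drop=True))
        m = exp.matrix.subset_samples(list(design.table["sample_id"]))
        dist = score_with_confidence(
            m, design, exp.signature,
            RotationConfig(nrot=199, seed=1),
            ScoringConfig(n_noise_iter=5, ridge_points=100, seed=2),
            noise_sd=np.zeros(m.n_genes),
        )
        assert dist.sd == 0.0
        assert np.unique(dist.iteration_scores).size == 1
        assert dist.iteration_scores[0] == dist.point.normalized
        np.testing.assert_allclose(dist.ridge_sample, dist.mean)

    def test_same_seed_identical_distribution(self, small_experiment):
        exp = small_experiment
        from aegis import SampleDesign

        sub = exp.design.table[
            (exp.design.table.group == "control") | (exp.design.table.dose_multiple == 10.0)
        ]
        design = SampleDesign(sub.reset_index(drop=True))
        m = exp.matrix.subset_samples(list(design.table["sample_id"]))
        kw = dict(
            rot_cfg=RotationConfig(nrot=199, seed=4),
            score_cfg=ScoringConfig(n_noise_iter=6, ridge_points=50, seed=9),
        )
        a = score_with_confidence(m, design, exp.signature, **kw)
        b = score_with_confidence(m, design, exp.signature, **kw)
        np.testing.assert_array_equal(a.iteration_scores, b.iteration_scores)
        np.testing.assert_array_equal(a.ridge_sample, b.ridge_sample)

    def test_mean_tracks_noise_free_score(self, small_experiment):
        from aegis import SampleDesign

        exp = small_experiment
        sub = exp.design.table[
            (exp.design.table.group == "control") | (exp.design.table.dose_multiple == 10.0)
        ]
        design = SampleDesign(sub.reset_index(drop=True))
        m = exp.matrix.subset_samples(list(design.table["sample_id"]))
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            dist = score_with_confidence(
                m, design, exp.signature,
                RotationConfig(nrot=199, seed=seed),
                ScoringConfig(n_noise_iter=20, ridge_points=10, seed=seed),
                noise_sd=np.full(m.n_genes, 0.05),
            )
            if abs(dist.mean - dist.point.normalized) < max(4 * dist.sd / np.sqrt(20), 0.02):
                hits += 1
        assert hits >= int(0.75 * n_seeds)


class TestInvariances:
    def test_gene_and_sample_order_invariance(self, small_experiment):
        from aegis import SampleDesign

        exp = small_experiment
        sub = exp.design.table[
            (exp.design.table.group == "control") | (exp.design.table.dose_multiple == 10.0)
        ].reset_index(drop=True)
        design = SampleDesign(sub)
        m = exp.matrix.subset_samples(list(sub["sample_id"]))
        base = score_contrast(m, design, exp.signature, RotationConfig(nrot=199, seed=7))
        rng = np.random.default_rng(0)
        gene_perm = rng.permutation(m.n_genes)
        m_shuf = ExpressionMatrix(
            m.values[gene_perm], [m.gene_ids[i] for i in gene_perm], m.sample_ids, "log"
        )
        shuf = score_contrast(m_shuf, design, exp.signature, RotationConfig(nrot=199, seed=7))
        assert shuf.raw == pytest.approx(base.raw, rel=1e-9)
        # swap samples within the control group
        order = sub["sample_id"].tolist()
        order[0], order[1] = order[1], order[0]
        design2 = SampleDesign(sub.set_index("sample_id").loc[order].reset_index())
        swapped = score_contrast(m, design2, exp.signature, RotationConfig(nrot=199, seed=7))
        assert swapped.raw == pytest.approx(base.raw, rel=1e-9)


class TestRegulonBreakdown:
    def _fit(self, matrix, design):
        fit = fit_contrast(matrix, design)
        return fit, moderate(fit)

    def test_perturbed_regulon_scores_highest(self, matrix_from_values, two_group_design):
        rng = np.random.default_rng(2)
        design = two_group_design()
        Y = rng.normal(0, 0.5, size=(120, 6))
        genes = [f"g{i}" for i in range(120)]
        sets = {
            "JUN": genes[:20],
            "ATF3": genes[20:40],
            "REST": genes[40:60],
        }
        sets[COMBINED_SET] = genes[:60]
        Y[:20, 3:] += 3.0  # perturb only the JUN regulon
        m = matrix_from_values(Y, samples=list(design.table["sample_id"]))
        fit, mod = self._fit(m, design)
        bd = regulon_breakdown(
            fit, mod, GeneSignature(sets=sets), RotationConfig(nrot=999, seed=0)
        )
        assert bd["normalized"].idxmax() == "JUN"
        assert bd.loc["JUN", "normalized"] > bd.drop("JUN")["normalized"].max()

    def test_all_null_scores_low(self, null_experiment):
        fit, mod = self._fit(null_experiment.matrix, null_experiment.design)
        bd = regulon_breakdown(
            fit, mod, null_experiment.signature, RotationConfig(nrot=999, seed=1)
        )
        assert (bd["normalized"] < 0.25).all()

    def test_single_set_breakdown_equals_combined(self, matrix_from_values, two_group_design):
        rng = np.random.default_rng(4)
        design = two_group_design()
        Y = rng.normal(size=(50, 6))
        Y[:10, 3:] += 2
        m = matrix_from_values(Y, samples=list(design.table["sample_id"]))
        fit, mod = self._fit(m, design)
        genes = [f"g{i}" for i in range(10)]
        sig = GeneSignature(sets={"onlytf": genes, COMBINED_SET: genes})
        bd = regulon_breakdown(fit, mod, sig, RotationConfig(nrot=499, seed=6))
        combined = score_contrast(m, design, sig, RotationConfig(nrot=499, seed=6))
        assert bd.loc["onlytf", "raw"] == pytest.approx(combined.raw)
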