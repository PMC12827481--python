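"""Self-contained rotation gene-set testing (ROAST-style).

Instead of permuting samples, the test resamples by rotating each gene's
data in the residual space of the linear model.  Per gene the data reduce
to the (d+1)-vector v_g = (effect coordinate, d residual coordinates).
Under the null hypothesis v_g / |v_g| is uniform on the d-sphere, so a
random unit vector r gives a new effect coordinate u*_g = r . v_g and a
new residual variance (|v_g|^2 - u*_g^2) / d.  Crucially ONE rotation r is
shared by all genes of a draw, which preserves inter-gene correlation --
the property that keeps the test's type-I error controlled when set genes
are co-expressed (a gene-permutation test is not robust to this).

Set statistics are "floormean" summaries of the moderated z-scores:
S_up = mean(max(z, 0)), S_down = mean(max(-z, 0)), S_mixed = mean(|z|).
p-values use the (b + 1) / (nrot + 1) convention, so the smallest
achievable p with 9999 rotations is 1/10000.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .linear_model import ContrastFit, ModerationResult, t_to_z
from .signature import GeneSignature

logger = logging.getLogger(__name__)

_ROTATION_CHUNK = 4096  # rotations per block, bounds peak memory


@dataclass
class RotationConfig:
    """Settings for the rotation test.

    ``active_z_threshold`` defines an "active" gene: |z| above it counts
    toward PropUp/PropDown.  The default sqrt(2) mirrors the reference
    implementation's convention; it is exposed because it is a convention,
    not a printed constant.
    """

    nrot: int = 9999
    set_statistic: str = "floormean"
    seed: int | None = None
    trend: bool = False
    active_z_threshold: float = math.sqrt(2.0)

    def __post_init__(self) -> None:
        if self.nrot < 1:
            raise ValueError("nrot must be >= 1")
        if self.active_z_threshold <= 0:
            raise ValueError("active_z_threshold must be > 0")
        if self.set_statistic not in ("floormean", "mean", "msq"):
            raise ValueError("set_statistic must be floormean, mean or msq")


@dataclass
class RotationTestResult:
    """Per-set rotation test output.

    ``table`` holds one row per tested set with columns n_genes, prop_up,
    prop_down, s_up, s_down, s_mixed, p_up, p_down, p_two_sided, p_mixed,
    fdr_mixed.  ``gene_z`` maps set name -> observed per-gene z Series.
    """

    table: pd.DataFrame
    gene_z: dict[str, pd.Series] = field(default_factory=dict)

    def row(self, set_name: str) -> pd.Series:
        return self.table.loc[set_name]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "set"
        out.to_csv(path, sep="\t")


def _set_stats(z: np.ndarray, statistic: str, axis: int = -1):
    """(S_up, S_down, S_mixed) for observed (1-D) or rotated (2-D) z."""
    if statistic == "floormean":
        s_up = np.maximum(z, 0.0).mean(axis=axis)
        s_down = np.maximum(-z, 0.0).mean(axis=axis)
        s_mixed = np.abs(z).mean(axis=axis)
    elif statistic == "mean":
        m = z.mean(axis=axis)
        s_up, s_down = m, -m
        s_mixed = np.abs(z).mean(axis=axis)
    else:  # msq
        s_up = (np.square(z) * (z > 0)).mean(axis=axis)
        s_down = (np.square(z) * (z < 0)).mean(axis=axis)
        s_mixed = np.square(z).mean(axis=axis)
    return s_up, s_down, s_mixed


def rotation_test_multi(
    fit: ContrastFit,
    mod: ModerationResult,
    sig: GeneSignature,
    cfg: RotationConfig | None = None,
) -> RotationTestResult:
    """Rotation test for every set of ``sig`` with shared rotations.

    All sets within one call see the same random rotations (one random
    stream), so their statistics are comparable and the mixed p-values are
    BH-adjusted across sets.  Sets are intersected with measured genes;
    intersections of 0 genes raise, of 1 gene are skipped with a warning.
    """
    cfg = cfg or RotationConfig()
    d = fit.df_resid
    if d < 1:
        raise ValueError("rotation impossible with 0 residual degrees of freedom")
    gene_index = {g: i for i, g in enumerate(fit.gene_ids)}

    set_rows: dict[str, np.ndarray] = {}
    for name, genes in sig.sets.items():
        rows = np.array([gene_index[g] for g in genes if g in gene_index], dtype=int)
        if rows.size == 0:
            raise ValueError(f"gene set '{name}' has no overlap with measured genes")
        if rows.size < 2:
            logger.warning("gene set '%s' overlaps only %d gene(s); skipped", name, rows.size)
            continue
        if rows.size < len(genes):
            logger.info("gene set '%s': %d of %d genes measured", name, rows.size, len(genes))
        set_rows[name] = rows
    if not set_rows:
        raise ValueError("no gene set with >= 2 measured genes")

    union = np.unique(np.concatenate(list(set_rows.values())))
    pos_in_union = {r: j for j, r in enumerate(union)}

    # observed statistics
    z_obs = mod.z
    d0 = mod.d0
    s02_u = mod.s02_per_gene(len(fit.gene_ids))[union]
    v = np.column_stack([fit.effect_coord[union], fit.resid_coords[union]])  # Gu x (d+1)
    v_norm2 = (v**2).sum(axis=1)

    names = list(set_rows)
    obs = {
        name: _set_stats(z_obs[set_rows[name]], cfg.set_statistic) for name in names
    }

    # rotated statistics, chunked over rotations
    rng = np.random.default_rng(cfg.seed)
    exceed = {name: np.zeros(3, dtype=np.int64) for name in names}
    done = 0
    while done < cfg.nrot:
        k = min(_ROTATION_CHUNK, cfg.nrot - done)
        r = rng.standard_normal((k, d + 1))
        r /= np.linalg.norm(r, axis=1, keepdims=True)
        u = r @ v.T  # k x Gu rotated effect coordinates
        s2_rot = np.maximum(v_norm2[None, :] - u**2, 0.0) / d
        if np.isinf(d0):
            s2_post = np.broadcast_to(s02_u[None, :], u.shape)
        elif d0 == 0:
            s2_post = s2_rot
        else:
            s2_post = (d0 * s02_u[None, :] + d * s2_rot) / (d0 + d)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_rot = u / np.sqrt(s2_post)
        t_rot = np.where(np.isnan(t_rot), 0.0, t_rot)
        z_rot = t_to_z(t_rot, mod.df_total)
        for name in names:
            cols = np.fromiter((pos_in_union[r_] for r_ in set_rows[name]), dtype=int)
            s_up, s_down, s_mixed = _set_stats(z_rot[:, cols], cfg.set_statistic, axis=1)
            o_up, o_down, o_mixed = obs[name]
            exceed[name] += np.array(
                [(s_up >= o_up).sum(), (s_down >= o_down).sum(), (s_mixed >= o_mixed).sum()]
            )
        done += k

    thr = cfg.active_z_threshold
    records = []
    gene_z: dict[str, pd.Series] = {}
    for name in names:
        rows = set_rows[name]
        zset = z_obs[rows]
        n_set = rows.size
        b_up, b_down, b_mixed = exceed[name]
        p_up = (b_up + 1.0) / (cfg.nrot + 1.0)
        p_down = (b_down + 1.0) / (cfg.nrot + 1.0)
        p_mixed = (b_mixed + 1.0) / (cfg.nrot + 1.0)
        records.append(
            {
                "n_genes": n_set,
                "prop_up": float((zset > thr).sum()) / n_set,
                "prop_down": float((zset < -thr).sum()) / n_set,
                "s_up": obs[name][0],
                "s_down": obs[name][1],
                "s_mixed": obs[name][2],
                "p_up": p_up,
                "p_down": p_down,
                "p_two_sided": min(1.0, 2.0 * min(p_up, p_down)),
                "p_mixed": p_mixed,
            }
        )
        gene_z[name] = pd.Series(zset, index=[fit.gene_ids[i] for i in rows])
    table = pd.DataFrame(records, index=pd.Index(names, name="set"))
    table["fdr_mixed"] = multipletests(table["p_mixed"].to_numpy(), method="fdr_bh")[1]
    return RotationTestResult(table=table, gene_z=gene_z)


def rotation_test(
    fit: ContrastFit,
    mod: ModerationResult,
    sig_or_genes,
    cfg: RotationConfig | None = None,
    set_name: str | None = None,
) -> RotationTestResult:
    """Rotation test for a single gene set.

    ``sig_or_genes`` may be a :class:`GeneSignature` (``set_name`` selects
    the set, default the combined set) or a plain list of gene ids.
    """
    from .signature import COMBINED_SET

    if isinstance(sig_or_genes, GeneSignature):
        name = set_name or (
            COMBINED_SET if COMBINED_SET in sig_or_genes.sets else sig_or_genes.set_names[0]
        )
        genes = sig_or_genes.sets[name]
    else:
        name = set_name or "set"
        genes = list(sig_or_genes)
    single = GeneSignature(sets={name: genes})
    return rotation_test_multi(fit, mod, single, cfg)
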