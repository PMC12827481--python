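"""Expression matrices, sample sheets, probe collapse and ortholog mapping.

The analysis operates on a genes x samples matrix on the log2 scale.  Raw
RNA-seq counts are converted with :func:`log_cpm`; microarray log
intensities are used as-is after probe-to-gene collapse (keeping, per gene,
the probe with the highest mean intensity across all samples) and optional
one-to-one ortholog relabelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_SAMPLE_COLUMNS = ("sample_id", "compound", "dose_multiple", "group")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a scale tag.

    ``scale`` is ``"counts"`` (non-negative raw counts) or ``"log"``
    (log2 intensities or log2-CPM).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    scale: str = "log"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"dimension mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.scale not in ("counts", "log"):
            raise ValueError("scale must be 'counts' or 'log'")
        if self.scale == "counts":
            if np.isnan(self.values).any():
                raise ValueError("NaN values in count matrix")
            if (self.values < 0).any():
                raise ValueError("negative values in count matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(self.values[:, idx], self.gene_ids, list(sample_ids), self.scale)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


@dataclass
class SampleDesign:
    """Per-sample metadata: compound, dose (x C_max), group, donor/batch.

    ``group`` is ``"treatment"`` or ``"control"``.  Doses are expressed as
    multiples of the compound's clinical C_max so that thresholds and
    dose-response fits are comparable across compounds.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = set(REQUIRED_SAMPLE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        df["sample_id"] = df["sample_id"].astype(str)
        df["group"] = df["group"].astype(str).str.lower()
        bad = set(df["group"]) - {"treatment", "control"}
        if bad:
            raise ValueError(f"group must be treatment/control, got {sorted(bad)}")
        df["dose_multiple"] = pd.to_numeric(df["dose_multiple"])
        if (df["dose_multiple"] < 0).any():
            raise ValueError("dose_multiple must be >= 0")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in sample sheet")
        if "donor" not in df.columns:
            df["donor"] = "donor1"
        self.table = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleDesign":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        return cls(pd.read_csv(path, sep=sep))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def check_matrix(self, m: ExpressionMatrix) -> None:
        missing = set(self.table["sample_id"]) - set(m.sample_ids)
        if missing:
            raise ValueError(f"sample sheet ids absent from matrix: {sorted(missing)}")


@dataclass
class MappingTable:
    """Identifier mapping (probe -> gene, or source species -> ortholog)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        if not {"source_id", "target_id"} <= set(df.columns):
            raise ValueError("mapping table needs columns 'source_id', 'target_id'")
        df["source_id"] = df["source_id"].astype(str).str.strip()
        df["target_id"] = df["target_id"].astype(str).str.strip()
        df = df.drop_duplicates(subset=["source_id", "target_id"])
        self.table = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MappingTable":
        return cls(pd.read_csv(path, sep="\t"))


def load_expression(path: str | Path, fmt: str | None = None, scale: str = "log") -> ExpressionMatrix:
    """Load a TSV (header = sample ids, first column = gene ids) or a
    MatrixMarket file with ``.rows``/``.cols`` id sidecars."""
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.duplicated().any():
            raise ValueError(f"{path}: duplicate gene ids")
        return ExpressionMatrix(df.to_numpy(float), list(df.index.astype(str)),
                                list(df.columns.astype(str)), scale)
    if fmt == "mtx":
        from scipy.io import mmread

        raw = mmread(path)
        values = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw, dtype=float)
        genes = Path(str(path) + ".rows").read_text().split()
        samples = Path(str(path) + ".cols").read_text().split()
        return ExpressionMatrix(values, genes, samples, scale)
    raise ValueError(f"unknown expression format: {fmt}")


def write_mtx(m: ExpressionMatrix, path: str | Path) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    mmwrite(str(path), csr_matrix(m.values))
    Path(str(path) + ".rows").write_text("\n".join(m.gene_ids) + "\n")
    Path(str(path) + ".cols").write_text("\n".join(m.sample_ids) + "\n")


def collapse_probes(m: ExpressionMatrix, probe_to_gene: MappingTable) -> ExpressionMatrix:
    """Collapse probe rows to gene rows, keeping per gene the probe with the
    highest mean intensity across all samples (ties: first in input order)."""
    if m.scale != "log":
        raise ValueError("probe collapse expects a log-scale matrix")
    mapping = probe_to_gene.table
    if mapping["source_id"].duplicated().any():
        raise ValueError("a probe maps to multiple genes; mapping must be unique per probe")
    probe_gene = dict(zip(mapping["source_id"], mapping["target_id"]))
    means = m.values.mean(axis=1)
    best: dict[str, int] = {}
    n_unmapped = 0
    for i, probe in enumerate(m.gene_ids):
        gene = probe_gene.get(probe)
        if gene is None:
            n_unmapped += 1
            continue
        if gene not in best or means[i] > means[best[gene]]:
            best[gene] = i
    if not best:
        raise ValueError("no probes overlap the probe-to-gene mapping")
    if n_unmapped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_unmapped)
    genes = list(best)
    rows = [best[g] for g in genes]
    return ExpressionMatrix(m.values[rows], genes, m.sample_ids, "log")


def map_orthologs(m: ExpressionMatrix, orthologs: MappingTable) -> ExpressionMatrix:
    """Relabel gene ids through a one-to-one ortholog map.

    Genes with zero or multiple targets, and targets hit by multiple
    sources, are dropped (counts logged) rather than aggregated.
    """
    tab = orthologs.table
    tab = tab[tab["source_id"].isin(m.gene_ids)]
    src_counts = tab["source_id"].value_counts()
    tgt_counts = tab["target_id"].value_counts()
    one2one = tab[
        tab["source_id"].map(src_counts).eq(1) & tab["target_id"].map(tgt_counts).eq(1)
    ]
    if one2one.empty:
        raise ValueError("ortholog mapping empty after one-to-one filtering")
    n_dropped = m.n_genes - len(one2one)
    if n_dropped:
        logger.info("map_orthologs: dropped %d genes without a unique ortholog", n_dropped)
    src_to_tgt = dict(zip(one2one["source_id"], one2one["target_id"]))
    rows = [i for i, g in enumerate(m.gene_ids) if g in src_to_tgt]
    genes = [src_to_tgt[m.gene_ids[i]] for i in rows]
    return ExpressionMatrix(m.values[rows], genes, m.sample_ids, m.scale)


def log_cpm(m: ExpressionMatrix, prior_count: float = 0.5) -> ExpressionMatrix:
    """Counts to log2 counts-per-million.

    value[g, s] = log2((count[g, s] + prior) / (lib_s + 2 * prior) * 1e6)
    where lib_s is the column (library) total.
    """
    if m.scale != "counts":
        raise ValueError("log_cpm expects a counts matrix")
    lib = m.values.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size in counts matrix")
    vals = np.log2((m.values + prior_count) / (lib + 2.0 * prior_count) * 1e6)
    return ExpressionMatrix(vals, m.gene_ids, m.sample_ids, "log")
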