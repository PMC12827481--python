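"""Transcription-factor regulon gene signatures.

The DILI score tests a fixed gene signature: the union of the target genes
(regulons) of apoptosis-regulating transcription factors that are expressed
in the liver.  This module builds such a signature from a regulon table
(TF, target, evidence level) and a tissue expression reference (gene, TPM),
and reads/writes signatures in GMT or two-column TSV form.

Evidence levels follow the DoRothEA convention A < B < C < D < E, A being
the strongest curation level; "evidence up to C" keeps levels A, B and C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Name of the combined (union) gene set in every signature.
COMBINED_SET = "AEGIS_combined"

EVIDENCE_LEVELS = ("A", "B", "C", "D", "E")


class SignatureError(ValueError):
    """Raised when a signature is empty or violates its invariants."""


@dataclass
class RegulonTable:
    """TF -> target regulon assignments with curation evidence levels.

    ``table`` has columns ``tf``, ``target``, ``evidence`` and optionally
    ``mode`` (sign of regulation, +1/-1).  Duplicate (tf, target) pairs are
    dropped on construction; the regulation sign is carried but not used by
    the score, which is sign-agnostic at the set level.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        required = {"tf", "target", "evidence"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"regulon table missing columns: {sorted(missing)}")
        for col in ("tf", "target", "evidence"):
            df[col] = df[col].astype(str).str.strip()
        bad = set(df["evidence"]) - set(EVIDENCE_LEVELS)
        if bad:
            raise ValueError(f"unknown evidence levels: {sorted(bad)}")
        n0 = len(df)
        df = df.drop_duplicates(subset=["tf", "target"], keep="first")
        if len(df) < n0:
            logger.warning("dropped %d duplicate (tf, target) pairs", n0 - len(df))
        self.table = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegulonTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class ExpressionReference:
    """Reference tissue abundances (TPM) used to filter TFs by expression."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        if not {"gene", "abundance"} <= set(df.columns):
            raise ValueError("expression reference needs columns 'gene', 'abundance'")
        df["gene"] = df["gene"].astype(str).str.strip()
        if (df["abundance"] < 0).any():
            raise ValueError("abundances must be >= 0")
        self.table = df.reset_index(drop=True)

    def abundance(self, gene: str) -> float | None:
        hit = self.table.loc[self.table["gene"] == gene, "abundance"]
        return None if hit.empty else float(hit.iloc[0])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionReference":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class GeneSignature:
    """Named gene sets: one per TF plus the combined union set.

    ``sets`` maps set name to an ordered list of unique gene symbols.  The
    combined set, when present, must equal the deduplicated union of the
    per-TF sets (first-appearance order).
    """

    sets: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.sets:
            raise SignatureError("empty signature: no gene sets")
        clean: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            genes = [str(g).strip() for g in genes]
            uniq = list(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                logger.warning("set %s: removed %d duplicate genes", name, len(genes) - len(uniq))
            if not uniq:
                raise SignatureError(f"empty signature set: {name}")
            clean[name] = uniq
        self.sets = clean
        if COMBINED_SET in self.sets:
            expected = _union([g for n, g in self.sets.items() if n != COMBINED_SET])
            if expected and set(self.sets[COMBINED_SET]) != set(expected):
                raise SignatureError(
                    f"{COMBINED_SET} does not equal the union of the per-TF sets"
                )

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)

    @property
    def tf_names(self) -> list[str]:
        return [n for n in self.sets if n != COMBINED_SET]

    @property
    def combined(self) -> list[str]:
        if COMBINED_SET in self.sets:
            return self.sets[COMBINED_SET]
        return _union(list(self.sets.values()))

    def membership_table(self) -> pd.DataFrame:
        """Long-form (set, gene) table, one row per membership."""
        rows = [(name, g) for name, genes in self.sets.items() for g in genes]
        return pd.DataFrame(rows, columns=["set", "gene"])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSignature) and self.sets == other.sets


def _union(gene_lists: list[list[str]]) -> list[str]:
    out: dict[str, None] = {}
    for genes in gene_lists:
        for g in genes:
            out.setdefault(g)
    return list(out)


def build_signature(
    regulons: RegulonTable,
    tf_list: list[str],
    max_evidence: str = "C",
    reference: ExpressionReference | None = None,
    tpm_threshold: float = 1.0,
) -> GeneSignature:
    """Build a signature from regulons, keeping liver-expressed TFs and
    well-curated targets.

    A TF is retained when its reference abundance exceeds ``tpm_threshold``
    (TFs absent from the reference are excluded with a warning; with no
    reference all TFs pass).  Per-TF sets keep targets with evidence level
    at or below ``max_evidence``; a combined union set is appended.
    """
    if not tf_list:
        raise ValueError("tf_list must be non-empty")
    if max_evidence not in EVIDENCE_LEVELS:
        raise ValueError(f"max_evidence must be one of {EVIDENCE_LEVELS}")
    keep_levels = set(EVIDENCE_LEVELS[: EVIDENCE_LEVELS.index(max_evidence) + 1])

    sets: dict[str, list[str]] = {}
    for tf in tf_list:
        tf = str(tf).strip()
        if reference is not None:
            tpm = reference.abundance(tf)
            if tpm is None:
                logger.warning("TF %s absent from expression reference; excluded", tf)
                continue
            if tpm <= tpm_threshold:
                continue
        sub = regulons.table
        targets = sub.loc[
            (sub["tf"] == tf) & (sub["evidence"].isin(keep_levels)), "target"
        ].tolist()
        if targets:
            sets[tf] = list(dict.fromkeys(targets))
    if not sets:
        raise SignatureError(
            "empty signature: no TF passed the expression and evidence filters"
        )
    sets[COMBINED_SET] = _union(list(sets.values()))
    prov = f"built from regulon table (evidence<={max_evidence}, TPM>{tpm_threshold})"
    return GeneSignature(sets=sets, provenance=prov)


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "gmt" if str(path).lower().endswith(".gmt") else "tsv"


def read_signature(path: str | Path, fmt: str | None = None) -> GeneSignature:
    """Read a signature from a GMT file or a two-column (set, gene) TSV."""
    fmt = _infer_format(path, fmt)
    path = Path(path)
    if fmt == "gmt":
        sets: dict[str, list[str]] = {}
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            sets[parts[0]] = parts[2:]
        if not sets:
            raise SignatureError(f"{path}: no gene sets found")
        return GeneSignature(sets=sets, provenance=f"read from {path.name}")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        if not {"set", "gene"} <= set(df.columns):
            raise ValueError(f"{path}: TSV signature needs columns 'set', 'gene'")
        sets = {str(name): sub["gene"].astype(str).tolist()
                for name, sub in df.groupby("set", sort=False)}
        return GeneSignature(sets=sets, provenance=f"read from {path.name}")
    raise ValueError(f"unknown signature format: {fmt}")


def write_signature(sig: GeneSignature, path: str | Path, fmt: str | None = None) -> None:
    """Write a signature; round-trips byte-stably with :func:`read_signature`."""
    fmt = _infer_format(path, fmt)
    path = Path(path)
    if fmt == "gmt":
        # description column = set name, keeping write->read->write byte-stable
        lines = [
            "\t".join([name, name, *genes]) for name, genes in sig.sets.items()
        ]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "tsv":
        sig.membership_table().to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown signature format: {fmt}")


def default_signature() -> GeneSignature:
    """The bundled synthetic stand-in for the 241-gene apoptosis signature.

    The set names are the eight liver-expressed apoptosis-regulating TFs
    (ATF3, E2F3, FOXA1, FOXO3, JUN, PPARG, REST, TFAP4); the member gene
    identifiers are synthetic placeholders (the published membership is
    distributed as journal supplementary data, not re-shipped here).  Use
    :func:`read_signature` with your own GMT for real analyses.
    """
    from importlib.resources import files

    path = files("aegis").joinpath("data/aegis_signature_synthetic.gmt")
    with path.open("r") as fh:  # type: ignore[call-arg]
        text = fh.read()
    sets: dict[str, list[str]] = {}
    for line in text.splitlines():
        if line.strip():
            parts = line.split("\t")
            sets[parts[0]] = parts[2:]
    return GeneSignature(sets=sets, provenance="bundled synthetic stand-in signature")
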