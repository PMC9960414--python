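"""Readers and writers for the tabular formats the pipeline consumes.

All downstream modules work on the in-memory domain types defined here;
nothing else in the package touches the filesystem. Coordinates are 1-based
inclusive internally; BED input (0-based half-open) is converted on read and
converted back on write.

Formats: GMT gene sets, expression TSV (genes x samples), clinical TSV, MAF
(minimal column subset), SEG, BED4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from metabosub.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

SCALE_TAGS = ("counts", "tpm", "log_tpm", "centered")

#: days per month used when converting follow-up given in days
DAYS_PER_MONTH = 30.44


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """Named, ordered, duplicate-free list of gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"duplicate symbols in gene set {self.name!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: object) -> bool:
        return symbol in self.genes


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a declared expression scale."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.scale_tag not in SCALE_TAGS:
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if self.scale_tag != "counts" and not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite values in expression matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale_tag: str) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), scale_tag)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids),
                                self.values[rows, :], self.scale_tag)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise ValidationError(f"samples absent from matrix: {missing}")
        cols = [index[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples),
                                self.values[:, cols], self.scale_tag)


CLINICAL_COLUMNS = [
    "sample_id", "os_months", "os_event", "purity",
    "stage", "t_stage", "n_stage", "m_stage", "grade", "age", "sex", "smoking",
]


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations (overall survival, purity, staging)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for col in ("sample_id", "os_months", "os_event"):
            if col not in df.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids in clinical table: {dupes}")
        events = df["os_event"].dropna()
        if not events.isin([0, 1]).all():
            raise ValidationError("os_event must be 0 or 1")
        if (df["os_months"].dropna() < 0).any():
            raise ValidationError("os_months must be non-negative")
        if "purity" in df.columns:
            purity = df["purity"].dropna()
            if ((purity < 0) | (purity > 1)).any():
                raise ValidationError("purity must lie in [0, 1]")
        else:
            self.df = df.assign(purity=np.nan)
        self.df = self.df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def subset(self, samples: Iterable[str]) -> "ClinicalTable":
        keep = set(samples)
        return ClinicalTable(self.df[self.df["sample_id"].isin(keep)].copy())


VARIANT_CLASS_MAP = {"SNP": "SNV", "DNP": "SNV", "TNP": "SNV", "INS": "INDEL", "DEL": "INDEL"}


@dataclass
class MutationTable:
    """Somatic small-variant records restricted to SNV / INDEL classes."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "gene", "variant_class", "chrom", "pos"]
        for col in required:
            if col not in self.df.columns:
                raise ValidationError(f"mutation table missing column {col!r}")
        bad = set(self.df["variant_class"]) - {"SNV", "INDEL"}
        if bad:
            raise ValidationError(f"variant_class outside SNV/INDEL: {sorted(bad)}")
        self.df = self.df.reset_index(drop=True)


@dataclass
class SegmentTable:
    """Copy-number segments, 1-based inclusive coordinates."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "chrom", "start", "end", "num_probes", "seg_mean"]
        for col in required:
            if col not in self.df.columns:
                raise ValidationError(f"segment table missing column {col!r}")
        if (self.df["start"] > self.df["end"]).any():
            bad = self.df[self.df["start"] > self.df["end"]]
            raise ValidationError(f"segments with start > end: {bad.index.tolist()}")
        if (self.df["num_probes"] < 0).any():
            raise ValidationError("num_probes must be >= 0")
        self.df = self.df.reset_index(drop=True)


@dataclass
class GeneCoordinates:
    """Gene intervals, 1-based inclusive coordinates (converted from BED)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene", "chrom", "start", "end"]
        for col in required:
            if col not in self.df.columns:
                raise ValidationError(f"gene coordinates missing column {col!r}")
        if (self.df["start"] > self.df["end"]).any():
            raise ValidationError("gene intervals with start > end")
        self.df = self.df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one tab-separated line per set (name, description, genes...).

    The description field is discarded. Duplicate symbols within a line are
    collapsed, keeping first occurrence, with a warning.
    """
    sets: list[GeneSet] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 tab-separated "
                                  f"fields, got {len(fields)}")
            name, genes = fields[0], fields[2:]
            genes = [g for g in genes if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                logger.warning("%s: line %d (%s): %d duplicate symbols collapsed",
                               path, lineno, name, len(genes) - len(unique))
            sets.append(GeneSet(name, tuple(unique)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as handle:
        for gs in sets:
            handle.write("\t".join([gs.name, "na", *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path, scale_tag: str) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene ids, header sample ids).

    Duplicate gene rows are resolved by keeping the row with the highest mean
    (logged); duplicate sample columns are an error.
    """
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")[1:]
    dupes = [s for s, n in pd.Series(header).value_counts().items() if n > 1]
    if dupes:
        raise FormatError(f"{path}: duplicate sample ids {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().to_numpy().any():
        gi, sj = np.argwhere(df.isna().to_numpy())[0]
        raise FormatError(f"{path}: non-numeric value at gene {df.index[gi]!r}, "
                          f"sample {df.columns[sj]!r}")
    if df.index.duplicated().any():
        means = df.mean(axis=1)
        keep_pos = []
        seen: dict[str, int] = {}
        for pos, gene in enumerate(df.index):
            if gene not in seen:
                seen[gene] = pos
                keep_pos.append(pos)
            else:
                prev = seen[gene]
                if means.iloc[pos] > means.iloc[prev]:
                    keep_pos[keep_pos.index(prev)] = pos
                    seen[gene] = pos
                logger.info("%s: duplicate gene row %r resolved by highest mean",
                            path, gene)
        df = df.iloc[sorted(keep_pos)]
    return ExpressionMatrix.from_frame(df, scale_tag)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# clinical TSV
# ---------------------------------------------------------------------------

def read_clinical_tsv(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV. Required columns: sample_id, os_months, os_event.

    Optional columns (purity, stage, t_stage, n_stage, m_stage, grade, age,
    sex, smoking) are carried through; unknown columns are preserved as-is.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return ClinicalTable(df)


def write_clinical_tsv(clinical: ClinicalTable, path: str | Path) -> None:
    cols = [c for c in CLINICAL_COLUMNS if c in clinical.df.columns]
    cols += [c for c in clinical.df.columns if c not in cols]
    clinical.df[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

MAF_REQUIRED = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Type"]


def read_maf_minimal(path: str | Path) -> MutationTable:
    """Read the minimal MAF column subset.

    Variant_Type SNP/DNP/TNP map to SNV, INS/DEL to INDEL; other types are
    dropped with the count logged. Chromosome/Start_Position are optional.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in MAF_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required MAF column {col!r}")
    mapped = df["Variant_Type"].map(VARIANT_CLASS_MAP)
    n_dropped = int(mapped.isna().sum())
    if n_dropped:
        logger.info("%s: dropped %d records with unsupported Variant_Type",
                    path, n_dropped)
    df = df[mapped.notna()].copy()
    out = pd.DataFrame({
        "sample_id": df["Tumor_Sample_Barcode"],
        "gene": df["Hugo_Symbol"],
        "variant_class": df["Variant_Type"].map(VARIANT_CLASS_MAP),
        "chrom": df.get("Chromosome", pd.Series(["NA"] * len(df), index=df.index)),
        "pos": pd.to_numeric(
            df.get("Start_Position", pd.Series([0] * len(df), index=df.index)),
            errors="coerce").fillna(0).astype(int),
    })
    return MutationTable(out)


def write_maf_minimal(mutations: MutationTable, path: str | Path) -> None:
    reverse = {"SNV": "SNP", "INDEL": "INS"}
    df = pd.DataFrame({
        "Hugo_Symbol": mutations.df["gene"],
        "Tumor_Sample_Barcode": mutations.df["sample_id"],
        "Variant_Type": mutations.df["variant_class"].map(reverse),
        "Chromosome": mutations.df["chrom"],
        "Start_Position": mutations.df["pos"],
    })
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SEG
# ---------------------------------------------------------------------------

SEG_COLUMNS = {"ID": "sample_id", "chrom": "chrom", "loc.start": "start",
               "loc.end": "end", "num.mark": "num_probes", "seg.mean": "seg_mean"}


def read_seg(path: str | Path) -> SegmentTable:
    """Read a SEG file (ID, chrom, loc.start, loc.end, num.mark, seg.mean).

    A missing num.mark column yields num_probes=0 with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("ID", "chrom", "loc.start", "loc.end", "seg.mean"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing SEG column {col!r}")
    if "num.mark" not in df.columns:
        logger.warning("%s: num.mark column absent; num_probes set to 0", path)
        df["num.mark"] = 0
    out = df.rename(columns=SEG_COLUMNS)[list(SEG_COLUMNS.values())].copy()
    out["chrom"] = out["chrom"].astype(str)
    out["sample_id"] = out["sample_id"].astype(str)
    out[["start", "end"]] = out[["start", "end"]].astype(int)
    out["num_probes"] = out["num_probes"].fillna(0).astype(int)
    if (out["start"] > out["end"]).any():
        bad = out.index[out["start"] > out["end"]].tolist()
        raise FormatError(f"{path}: segments with start > end at rows {bad}")
    return SegmentTable(out)


def write_seg(segments: SegmentTable, path: str | Path) -> None:
    reverse = {v: k for k, v in SEG_COLUMNS.items()}
    segments.df.rename(columns=reverse).to_csv(path, sep="\t", index=False,
                                               float_format="%.17g")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> GeneCoordinates:
    """Read BED4 gene intervals, converting 0-based half-open to 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene"],
                     dtype={"chrom": str, "gene": str})
    if df[["start", "end"]].isna().any().any():
        raise FormatError(f"{path}: missing coordinates in BED file")
    out = pd.DataFrame({
        "gene": df["gene"],
        "chrom": df["chrom"],
        "start": df["start"].astype(int) + 1,  # BED is 0-based half-open
        "end": df["end"].astype(int),
    })
    return GeneCoordinates(out)


def write_bed(coords: GeneCoordinates, path: str | Path) -> None:
    df = pd.DataFrame({
        "chrom": coords.df["chrom"],
        "start": coords.df["start"] - 1,
        "end": coords.df["end"],
        "gene": coords.df["gene"],
    })
    df.to_csv(path, sep="\t", index=False, header=False)
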