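"""Readers and writers for the text formats the pipeline touches.

Every reader converts to the internal 0-based half-open convention at the
file boundary; writers convert back.  Gzip is handled transparently
(pandas ``compression='infer'``).  Tab-separated only; lines beginning with
``#`` are ignored.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeLayout, GenomicInterval, to_one_based, to_zero_based
from .svtools import SVRecord

logger = logging.getLogger("svcascade")

VALID_CONTEXTS = ("CG", "CHG", "CHH")

__all__ = [
    "read_cytosine_report",
    "write_cytosine_report",
    "read_intervals",
    "write_intervals",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_sv_table",
    "write_sv_table",
    "read_sv_vcf",
    "read_expression",
    "write_expression",
    "read_sample_sheet",
    "read_rnamod_table",
    "write_rnamod_table",
]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Bismark-style cytosine report
# ---------------------------------------------------------------------------

_CYT_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context", "trinuc"]


def read_cytosine_report(path, min_coverage: int = 5) -> pd.DataFrame:
    """Read a cytosine report (chrom, 1-based pos, strand, meth, unmeth,
    context, trinucleotide); keep sites with coverage strictly greater than
    ``min_coverage``; positions returned 0-based.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=_CYT_COLUMNS,
            dtype={"chrom": str, "strand": str, "context": str, "trinuc": str},
            compression="infer",
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed cytosine report {path}: {exc}") from exc
    if df.empty:
        logger.warning("empty cytosine report: %s", path)
        return df.assign(pos=pd.Series(dtype=int))
    for col in ("pos", "meth", "unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"{path}: non-numeric {col!r} field at data line {line}")
        df[col] = vals.astype(int)
    unknown = ~df["context"].isin(VALID_CONTEXTS)
    if unknown.any():
        line = int(np.flatnonzero(unknown.to_numpy())[0]) + 1
        raise ValueError(
            f"{path}: unknown methylation context "
            f"{df['context'].iloc[line - 1]!r} at data line {line}"
        )
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        raise ValueError(f"{path}: negative counts")
    df["pos"] = df["pos"].map(to_zero_based)
    coverage = df["meth"] + df["unmeth"]
    df = df[coverage > min_coverage].reset_index(drop=True)
    return df


def write_cytosine_report(df: pd.DataFrame, path) -> None:
    """Write calls back to the 1-based report format."""
    out = df.copy()
    out["pos"] = out["pos"].map(to_one_based)
    if "trinuc" not in out.columns:
        out["trinuc"] = out["context"]
    out[_CYT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED family
# ---------------------------------------------------------------------------

def read_intervals(path, dialect: str = "BED", layout: GenomeLayout | None = None):
    """Read a BED-family file.

    dialect 'BED'/'domainBED' -> list[GenomicInterval];
    dialect 'bedGraph' -> list[(GenomicInterval, float)] (value = e.g. PC1).
    """
    if dialect not in ("BED", "domainBED", "bedGraph"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, compression="infer")
    except pd.errors.EmptyDataError:
        logger.warning("empty %s file: %s", dialect, path)
        return []
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected >=3 tab-separated columns")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        if start >= end:
            raise ValueError(f"{path}: start >= end at data line {i}")
        interval = GenomicInterval(chrom, start, end)
        if layout is not None:
            layout.validate(interval)
        if dialect == "bedGraph":
            if df.shape[1] < 4:
                raise ValueError(f"{path}: bedGraph requires a value column")
            out.append((interval, float(row[3])))
        else:
            out.append(interval)
    return out


def write_intervals(intervals, path, values=None, names=None) -> None:
    """Write intervals as BED3 (or bedGraph when ``values`` given, BED4 with names)."""
    with _open_text(path, "wt") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if values is not None:
                cols.append(repr(float(values[i])))
            elif names is not None:
                cols.append(str(names[i]))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def _gff_attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if part and "=" in part:
            key, value = part.split("=", 1)
            out[key] = value
    return out


def read_gff3_genes(path, layout: GenomeLayout | None = None) -> list[GeneModel]:
    """Read gene and exon features from a GFF3 file (1-based inclusive ->
    0-based half-open).  Duplicate gene IDs are an error."""
    genes: dict[str, dict] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: expected 9 GFF3 columns at line {lineno}")
            chrom, _source, ftype, start1, end1, _score, strand, _phase, attrs = fields
            start = to_zero_based(int(start1))
            end = int(end1)  # 1-based inclusive end == 0-based exclusive end
            interval = GenomicInterval(chrom, start, end)
            if layout is not None:
                layout.validate(interval)
            attributes = _gff_attributes(attrs)
            if ftype == "gene":
                gene_id = attributes.get("ID")
                if not gene_id:
                    raise ValueError(f"{path}: gene without ID at line {lineno}")
                if gene_id in genes:
                    raise ValueError(f"{path}: duplicate gene id {gene_id!r}")
                genes[gene_id] = {"interval": interval, "strand": strand}
            elif ftype == "exon":
                parent = attributes.get("Parent")
                if parent:
                    exons.setdefault(parent, []).append(interval)
    return [
        GeneModel(gene_id, info["interval"], info["strand"], exons.get(gene_id, []))
        for gene_id, info in genes.items()
    ]


def write_gff3_genes(genes: list[GeneModel], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            iv = gene.interval
            fh.write(
                f"{iv.chrom}\tsvcascade\tgene\t{to_one_based(iv.start)}\t{iv.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            for k, exon in enumerate(gene.exons, start=1):
                fh.write(
                    f"{exon.chrom}\tsvcascade\texon\t{to_one_based(exon.start)}\t{exon.end}\t.\t"
                    f"{gene.strand}\t.\tID={gene.gene_id}.exon{k};Parent={gene.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# SV tables
# ---------------------------------------------------------------------------

def read_sv_table(path, layout: GenomeLayout | None = None) -> list[SVRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", compression="infer")
    required = {"id", "chrom", "start", "end", "type", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing SV columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        interval = GenomicInterval(str(row.chrom), int(row.start), int(row.end))
        if layout is not None:
            layout.validate(interval)
        records.append(
            SVRecord(
                id=str(row.id),
                sv_type=str(row.type),
                interval=interval,
                length=int(row.length),
                source=str(getattr(row, "source", "")) if "source" in df.columns else "",
            )
        )
    return records


def write_sv_table(svs: list[SVRecord], path) -> None:
    rows = [
        {
            "id": sv.id, "chrom": sv.interval.chrom, "start": sv.interval.start,
            "end": sv.interval.end, "type": sv.sv_type, "length": sv.length,
            "source": sv.source,
        }
        for sv in svs
    ]
    pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "type", "length", "source"]).to_csv(
        path, sep="\t", index=False
    )


def read_sv_vcf(path) -> list[SVRecord]:
    """Optional VCF 4.2 SV reader (SVTYPE/SVLEN/END info keys)."""
    from cyvcf2 import VCF

    records = []
    for i, variant in enumerate(VCF(str(path))):
        svtype = variant.INFO.get("SVTYPE")
        if svtype not in ("INS", "DEL", "INV"):
            continue
        start = variant.start  # cyvcf2 is already 0-based
        end = variant.INFO.get("END", start + 1)
        svlen = abs(int(variant.INFO.get("SVLEN", end - start)))
        if svtype == "INS":
            interval = GenomicInterval(variant.CHROM, start, start + 1)
        else:
            interval = GenomicInterval(variant.CHROM, start, int(end))
        records.append(
            SVRecord(
                id=variant.ID or f"vcf_sv{i}", sv_type=svtype, interval=interval,
                length=svlen if svtype == "INS" else interval.length, source="vcf",
            )
        )
    return records


# ---------------------------------------------------------------------------
# Expression tables + sample sheet
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Gene x sample TPM matrix; first column 'gene_id' becomes the index."""
    df = pd.read_csv(path, sep="\t", comment="#", compression="infer")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: expression table needs a 'gene_id' column")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    return df.set_index("gene_id")


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", compression="infer")
    required = {"sample", "accession", "tissue", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing sample-sheet columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# RNA modification site tables
# ---------------------------------------------------------------------------

_RNAMOD_COLUMNS = ["transcript", "position", "type", "modified", "coverage", "fraction"]


def read_rnamod_table(path) -> pd.DataFrame:
    """Per-site RNA modification table; recompute fraction = modified/coverage
    and check the stated fraction within 1e-6."""
    df = pd.read_csv(path, sep="\t", comment="#", compression="infer")
    missing = set(_RNAMOD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing RNA-mod columns {sorted(missing)}")
    bad_type = ~df["type"].isin(("m6A", "m5C"))
    if bad_type.any():
        raise ValueError(f"{path}: unknown modification type {df['type'][bad_type].iloc[0]!r}")
    if ((df["fraction"] < 0) | (df["fraction"] > 1)).any():
        raise ValueError(f"{path}: fraction outside [0, 1]")
    if (df["modified"] > df["coverage"]).any():
        raise ValueError(f"{path}: modified reads exceed coverage")
    with np.errstate(invalid="ignore"):
        recomputed = df["modified"] / df["coverage"]
    mismatch = (recomputed - df["fraction"]).abs() > 1e-6
    if mismatch.any():
        line = int(np.flatnonzero(mismatch.to_numpy())[0]) + 1
        raise ValueError(f"{path}: stated fraction inconsistent with counts at data line {line}")
    df = df.copy()
    df["fraction"] = recomputed
    return df


def write_rnamod_table(df: pd.DataFrame, path) -> None:
    df[_RNAMOD_COLUMNS].to_csv(path, sep="\t", index=False)
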