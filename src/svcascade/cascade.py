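"""Gene-level integration of SVs, DMRs and AMRs into cascade categories and
the expression-impact comparison across them.

Categories (priority high to low): InDel-AMG (gene overlapping an InDel-AMR
window), InDel-DMG (gene concurrently harboring an InDel and a DMR), DMG
(DMR only), SV-gene (SV only), genome-wide (no overlap).  "Harboring" is
interpreted, by default, against the gene footprint: body plus 2 kb upstream
(strand-aware) — the same window that defines DMR-associated proximal genes
(DPGs); a body-only mode is available.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust, welch_t
from .genome import GeneModel, GenomicInterval, IntervalIndex
from .svtools import SVRecord

CATEGORY_PRIORITY = ("InDel-AMG", "InDel-DMG", "DMG", "SV-gene", "genome-wide")

__all__ = ["CATEGORY_PRIORITY", "find_dpgs", "classify_genes", "expression_impact_by_category"]


def _df_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]


def find_dpgs(dmrs: pd.DataFrame, genes: Sequence[GeneModel], window: int = 2000) -> set[str]:
    """Genes with a DMR within ``window`` bp upstream of the TSS (strand-aware)."""
    index = IntervalIndex((iv, i) for i, iv in enumerate(_df_intervals(dmrs)))
    out = set()
    for gene in genes:
        up = gene.upstream(window)
        if up is not None and index.any_overlap(up):
            out.add(gene.gene_id)
    return out


def classify_genes(
    genes: Sequence[GeneModel],
    svs: Iterable[SVRecord],
    dmrs: pd.DataFrame,
    amrs: pd.DataFrame,
    footprint_flank: int = 2000,
    mode: str = "footprint",
    sv_types: tuple[str, ...] = ("INS", "DEL", "INV"),
) -> pd.DataFrame:
    """Per-gene cascade flags and resolved category.

    Flags: ``sv_gene`` (footprint overlaps an SV of ``sv_types``), ``dmg``
    (overlaps a DMR), ``indel_dmg`` (both, with the SV restricted to
    InDels), ``indel_amg`` (overlaps an InDel-AMR window), ``dpg`` (DMR in
    the 2-kb upstream promoter window).  ``mode`` 'footprint' uses body +
    ``footprint_flank`` upstream; 'body' uses the gene body only.
    """
    if mode not in ("footprint", "body"):
        raise ValueError(f"unknown mode {mode!r}")
    svs = [sv for sv in svs if sv.sv_type in sv_types]
    sv_index = IntervalIndex((sv.interval, sv) for sv in svs)
    dmr_index = IntervalIndex((iv, i) for i, iv in enumerate(_df_intervals(dmrs)))
    amr_index = IntervalIndex((iv, i) for i, iv in enumerate(_df_intervals(amrs)))
    dpgs = find_dpgs(dmrs, genes, window=footprint_flank)

    rows = []
    for gene in genes:
        region = gene.footprint(footprint_flank) if mode == "footprint" else gene.interval
        sv_hits = sv_index.query(region)
        has_sv = bool(sv_hits)
        has_indel = any(sv.is_indel for sv in sv_hits)
        has_dmr = dmr_index.any_overlap(region)
        has_amr = amr_index.any_overlap(region)
        indel_dmg = has_indel and has_dmr
        if has_amr:
            category = "InDel-AMG"
        elif indel_dmg:
            category = "InDel-DMG"
        elif has_dmr:
            category = "DMG"
        elif has_sv:
            category = "SV-gene"
        else:
            category = "genome-wide"
        rows.append({
            "gene_id": gene.gene_id, "sv_gene": has_sv, "dpg": gene.gene_id in dpgs,
            "dmg": has_dmr, "indel_dmg": indel_dmg, "indel_amg": has_amr,
            "category": category,
        })
    return pd.DataFrame(rows).set_index("gene_id")


def expression_impact_by_category(
    labels: pd.DataFrame,
    degs: pd.DataFrame,
    min_group: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """|log2FC| distributions per cascade category plus pairwise Welch tests.

    Genes with status 'not_expressed' are excluded.  Categories with fewer
    than ``min_group`` genes are excluded from the tests but summarized
    descriptively.  Pairwise p-values are BH-adjusted.
    """
    joined = labels.join(degs[["log2fc", "status"]], how="inner")
    joined = joined[joined["status"] != "not_expressed"]
    joined["abs_log2fc"] = joined["log2fc"].abs()

    summaries = []
    vectors: dict[str, np.ndarray] = {}
    for category in CATEGORY_PRIORITY:
        values = joined.loc[joined["category"] == category, "abs_log2fc"].to_numpy()
        vectors[category] = values
        summaries.append({
            "category": category, "n": len(values),
            "mean_abs_log2fc": float(np.mean(values)) if len(values) else np.nan,
            "median_abs_log2fc": float(np.median(values)) if len(values) else np.nan,
        })
    summary = pd.DataFrame(summaries)

    tests = []
    testable = [c for c in CATEGORY_PRIORITY if len(vectors[c]) >= min_group]
    for i in range(len(testable)):
        for j in range(i + 1, len(testable)):
            ca, cb = testable[i], testable[j]
            t, p = welch_t(vectors[ca], vectors[cb])
            tests.append({"category_a": ca, "category_b": cb, "t": t, "p": p})
    tests_df = pd.DataFrame(tests, columns=["category_a", "category_b", "t", "p"])
    if len(tests_df):
        tests_df["q"] = bh_adjust(tests_df["p"].to_numpy())
    else:
        tests_df["q"] = []
    return summary, tests_df
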