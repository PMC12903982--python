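"""Differential expression (Welch stand-in with DESeq2-style thresholds),
region DEG proportions, and RNA-modification site/transcript summaries.

The DE test here is deliberately simple and swappable: log2FC is computed on
mean TPM with a pseudocount of 1, significance from a Welch two-tailed
t-test on log2(TPM+1) across replicates, BH-adjusted; a gene is up/down when
|log2FC| >= 1 and q < 0.05.  Externally computed DEG tables with the same
columns can be passed anywhere a DEG frame is expected — the downstream
cascade logic is agnostic to the DE engine.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust, welch_t
from .genome import GeneModel, GenomicInterval, IntervalIndex

DEG_LOG2FC_MIN = 1.0
DEG_Q_MAX = 0.05

__all__ = [
    "compute_degs",
    "deg_proportion_in_regions",
    "summarize_mod_sites",
    "classify_transcript_mod_level",
    "co_modification_sets",
]


def compute_degs(
    expr: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    min_tpm: float = 1.0,
    log2fc_min: float = DEG_LOG2FC_MIN,
    q_max: float = DEG_Q_MAX,
) -> pd.DataFrame:
    """Differential expression of condition B over A.

    ``expr`` is a gene x sample TPM frame.  Genes below ``min_tpm`` in every
    sample are 'not_expressed' and excluded from testing and multiplicity.
    Requires >= 2 replicates per condition.
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("compute_degs requires >= 2 replicates per condition")
    a = expr[list(samples_a)].to_numpy(dtype=float)
    b = expr[list(samples_b)].to_numpy(dtype=float)
    expressed = (np.concatenate([a, b], axis=1) >= min_tpm).any(axis=1)

    log2fc = np.log2((b.mean(axis=1) + 1.0) / (a.mean(axis=1) + 1.0))
    pvals = np.full(len(expr), np.nan)
    for i in np.flatnonzero(expressed):
        _, p = welch_t(np.log2(b[i] + 1.0), np.log2(a[i] + 1.0))
        pvals[i] = p
    qvals = np.full(len(expr), np.nan)
    tested = expressed & ~np.isnan(pvals)
    qvals[tested] = bh_adjust(pvals[tested])

    status = np.full(len(expr), "ns", dtype=object)
    status[~expressed] = "not_expressed"
    significant = tested & (np.abs(log2fc) >= log2fc_min) & (qvals < q_max)
    status[significant & (log2fc > 0)] = "up"
    status[significant & (log2fc < 0)] = "down"
    return pd.DataFrame({
        "gene_id": expr.index, "log2fc": log2fc, "p": pvals, "q": qvals, "status": status,
    }).set_index("gene_id")


def _truncate2(x: float) -> float:
    """Truncate (not round) a percentage to two decimals."""
    return math.floor(x * 100.0) / 100.0


def deg_proportion_in_regions(
    genes: Sequence[GeneModel],
    regions: Sequence[GenomicInterval],
    degs: pd.DataFrame,
) -> dict:
    """Expressed-gene and DEG counts inside a region set vs genome-wide.

    A gene belongs to the region set on >= 1 bp overlap of its interval.
    Percentages are 100 x DEG / expressed, reported truncated to two
    decimals alongside full precision.
    """
    index = IntervalIndex((r, i) for i, r in enumerate(regions))
    in_region = {g.gene_id for g in genes if index.any_overlap(g.interval)}

    def tally(ids):
        sub = degs.loc[degs.index.intersection(ids)] if ids is not None else degs
        expressed = int((sub["status"] != "not_expressed").sum())
        n_deg = int(sub["status"].isin(("up", "down")).sum())
        if expressed == 0:
            return {"expressed": 0, "deg": n_deg, "percent": float("nan"),
                    "percent_truncated": float("nan"), "undefined": True}
        pct = 100.0 * n_deg / expressed
        return {"expressed": expressed, "deg": n_deg, "percent": pct,
                "percent_truncated": _truncate2(pct), "undefined": False}

    return {"regions": tally(in_region), "genome": tally(None)}


def summarize_mod_sites(
    sites: pd.DataFrame,
    fraction_bins: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    count_bins: Sequence[float] = (1, 3, 6),
) -> dict[str, dict[str, pd.Series]]:
    """Per-type histograms: site counts per fraction bin and transcript
    counts per number-of-sites bin.

    Fraction bins are lower-inclusive ([a, b), last bin closed); count bins
    are the left edges of right-open classes, the last one unbounded
    (default: <3, 3-5, >=6).
    """
    out: dict[str, dict[str, pd.Series]] = {}
    edges = np.asarray(fraction_bins, dtype=float)
    for mod_type, sub in sites.groupby("type"):
        frac_idx = np.clip(np.searchsorted(edges, sub["fraction"].to_numpy(), side="right") - 1,
                           0, len(edges) - 2)
        frac_labels = [f"[{edges[i]:g},{edges[i+1]:g})" for i in range(len(edges) - 1)]
        frac_hist = pd.Series(0, index=frac_labels, dtype=int)
        for i in frac_idx:
            frac_hist.iloc[i] += 1

        per_transcript = sub.groupby("transcript").size()
        count_edges = list(count_bins) + [np.inf]
        count_labels = []
        for i in range(len(count_bins)):
            lo, hi = count_edges[i], count_edges[i + 1]
            count_labels.append(f">={lo:g}" if np.isinf(hi) else f"[{lo:g},{hi:g})")
        count_hist = pd.Series(0, index=count_labels, dtype=int)
        for n in per_transcript:
            i = int(np.clip(np.searchsorted(count_bins, n, side="right") - 1, 0, len(count_bins) - 1))
            count_hist.iloc[i] += 1
        out[mod_type] = {"site_fractions": frac_hist, "transcript_site_counts": count_hist}
    return out


def classify_transcript_mod_level(
    sites: pd.DataFrame,
    expression: pd.Series,
    mod_type: str = "m6A",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group transcripts by maximum modification fraction and compare
    expression across groups.

    High: max fraction in [0.5, 1.0]; Low: (0, 0.5); Non: no site of the
    type.  Pairwise Welch two-tailed t-tests on log2(TPM+1); group means
    reported on both the TPM and log2(TPM+1) scales.
    """
    sub = sites[sites["type"] == mod_type]
    max_frac = sub.groupby("transcript")["fraction"].max()
    groups = pd.Series("Non", index=expression.index, dtype=object, name="group")
    common = max_frac.index.intersection(expression.index)
    groups.loc[common[max_frac.loc[common] >= 0.5]] = "High"
    groups.loc[common[(max_frac.loc[common] > 0) & (max_frac.loc[common] < 0.5)]] = "Low"

    table = pd.DataFrame({"group": groups, "tpm": expression})
    table["log2_tpm"] = np.log2(table["tpm"] + 1.0)
    tests = []
    names = ["High", "Low", "Non"]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            x = table.loc[table["group"] == names[i], "log2_tpm"].to_numpy()
            y = table.loc[table["group"] == names[j], "log2_tpm"].to_numpy()
            t, p = welch_t(x, y)
            tests.append({"group_a": names[i], "group_b": names[j],
                          "mean_a": float(np.mean(x)) if len(x) else np.nan,
                          "mean_b": float(np.mean(y)) if len(y) else np.nan,
                          "t": t, "p": p})
    return table, pd.DataFrame(tests)


def co_modification_sets(
    m6a_transcripts: set[str],
    m5c_transcripts: set[str],
    expression: pd.Series,
) -> tuple[pd.DataFrame, dict]:
    """Partition transcripts into {Both, m6A-only, m5C-only, none}, report
    mutual-overlap percentages and pairwise expression comparisons."""
    universe = expression.index
    both = m6a_transcripts & m5c_transcripts

    def group_of(t):
        if t in both:
            return "Both"
        if t in m6a_transcripts:
            return "m6A-only"
        if t in m5c_transcripts:
            return "m5C-only"
        return "none"

    table = pd.DataFrame({
        "group": [group_of(t) for t in universe],
        "tpm": expression.to_numpy(dtype=float),
    }, index=universe)
    table["log2_tpm"] = np.log2(table["tpm"] + 1.0)

    pct_m6a_in_m5c = 100.0 * len(both) / len(m6a_transcripts) if m6a_transcripts else float("nan")
    pct_m5c_in_m6a = 100.0 * len(both) / len(m5c_transcripts) if m5c_transcripts else float("nan")
    tests = []
    names = ["Both", "m6A-only", "m5C-only", "none"]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            x = table.loc[table["group"] == names[i], "log2_tpm"].to_numpy()
            y = table.loc[table["group"] == names[j], "log2_tpm"].to_numpy()
            t, p = welch_t(x, y)
            tests.append({"group_a": names[i], "group_b": names[j], "t": t, "p": p})
    stats = {
        "pct_m6a_also_m5c": pct_m6a_in_m5c,
        "pct_m5c_also_m6a": pct_m5c_in_m6a,
        "n_both": len(both),
        "pairwise_tests": pd.DataFrame(tests),
    }
    return table, stats
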