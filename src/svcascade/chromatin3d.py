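"""A/B compartment assignment and switch segmentation; TAD conserved vs
differential classification; SV-TAD co-occurrence statistics.

Compartment labels come from the sign of the Hi-C first principal component
(PC1) after per-chromosome orientation: PC1 is defined only up to sign, so
each chromosome's track is flipped, if needed, to correlate positively with
gene density (A = active, gene dense; B = inactive, methylation rich).

TAD comparison operates on domain calls alone: a domain is *conserved* when
the other condition has a domain with both boundaries within a tolerance
(one calling bin, 20 kb, by default), otherwise *differential*.  The merged
union of differential domains of both conditions forms the differential
region set used for SV accumulation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import welch_t
from .genome import GenomeLayout, GenomicInterval, IntervalIndex, merge_intervals
from .svtools import SVRecord

__all__ = [
    "TadDomain",
    "assign_compartments",
    "detect_switch_segments",
    "match_tads",
    "differential_regions",
    "sv_counts_per_tad",
    "sv_density_profile",
    "fraction_svs_in_regions",
    "boundary_sv_window_stats",
]


@dataclass(frozen=True)
class TadDomain:
    """One topologically associating domain call."""

    interval: GenomicInterval
    condition: str = ""
    stage: str = ""

    @property
    def boundaries(self) -> tuple[int, int]:
        return (self.interval.start, self.interval.end)


# ---------------------------------------------------------------------------
# A/B compartments
# ---------------------------------------------------------------------------

def assign_compartments(
    pc1: pd.DataFrame,
    gene_density: np.ndarray,
) -> pd.DataFrame:
    """Label PC1 bins as A/B/NA.

    ``pc1`` has columns chrom, start, end, pc1 (identical binning as
    ``gene_density``, one value per bin, same order).  Per chromosome the
    PC1 sign is oriented so its Pearson correlation with gene density is
    positive; oriented pc1 > 0 -> A, < 0 -> B, == 0 (or all-zero chromosome)
    -> NA.
    """
    if len(pc1) != len(gene_density):
        raise ValueError("pc1 and gene_density tracks are binned differently")
    out = pc1.copy().reset_index(drop=True)
    density = np.asarray(gene_density, dtype=float)
    out["oriented_pc1"] = np.nan
    for chrom, idx in out.groupby("chrom", sort=False).groups.items():
        values = out.loc[idx, "pc1"].to_numpy(dtype=float)
        dens = density[np.asarray(idx)]
        if np.all(values == 0):
            import logging
            logging.getLogger("svcascade").warning(
                "all-zero PC1 on %s: labelling NA", chrom)
            out.loc[idx, "oriented_pc1"] = 0.0
            continue
        sign = 1.0
        if np.std(values) > 0 and np.std(dens) > 0:
            if np.corrcoef(values, dens)[0, 1] < 0:
                sign = -1.0
        out.loc[idx, "oriented_pc1"] = sign * values
    out["label"] = np.select(
        [out["oriented_pc1"] > 0, out["oriented_pc1"] < 0], ["A", "B"], default="NA"
    )
    return out


def detect_switch_segments(bins_a: pd.DataFrame, bins_b: pd.DataFrame) -> pd.DataFrame:
    """Segment the binned genome into compartment-switch classes.

    Maximal runs of >= 2 consecutive bins labelled A in condition A and B in
    condition B form A2B segments (symmetrically B2A).  Runs of length 1 and
    unchanged bins are stable (classed by the condition-A label); NA bins in
    either condition break runs and belong to no segment.
    """
    key_cols = ["chrom", "start", "end"]
    if len(bins_a) != len(bins_b) or not bins_a[key_cols].reset_index(drop=True).equals(
        bins_b[key_cols].reset_index(drop=True)
    ):
        raise ValueError("compartment bin sets are not identical")
    a = bins_a.reset_index(drop=True)
    b = bins_b.reset_index(drop=True)

    states = []
    for la, lb in zip(a["label"], b["label"]):
        if la == "NA" or lb == "NA":
            states.append(None)
        elif la == "A" and lb == "B":
            states.append("A2B")
        elif la == "B" and lb == "A":
            states.append("B2A")
        else:
            states.append("stableA" if la == "A" else "stableB")

    segments = []
    i = 0
    n = len(states)
    while i < n:
        state = states[i]
        if state is None:
            i += 1
            continue
        j = i
        chrom = a.loc[i, "chrom"]
        while (j + 1 < n and states[j + 1] == state and a.loc[j + 1, "chrom"] == chrom
               and a.loc[j + 1, "start"] == a.loc[j, "end"]):
            j += 1
        n_bins = j - i + 1
        cls = state
        if state in ("A2B", "B2A") and n_bins < 2:
            # single-bin flip: not a valid switch; stable under the initial label
            cls = "stableA" if a.loc[i, "label"] == "A" else "stableB"
        segments.append({
            "chrom": chrom, "start": int(a.loc[i, "start"]), "end": int(a.loc[j, "end"]),
            "from_label": a.loc[i, "label"], "to_label": b.loc[i, "label"],
            "n_bins": n_bins, "class": cls,
        })
        i = j + 1
    return pd.DataFrame(
        segments,
        columns=["chrom", "start", "end", "from_label", "to_label", "n_bins", "class"],
    )


# ---------------------------------------------------------------------------
# TAD comparison
# ---------------------------------------------------------------------------

def match_tads(
    tads_a: list[TadDomain],
    tads_b: list[TadDomain],
    tolerance: int = 20_000,
) -> pd.DataFrame:
    """Classify each domain of both conditions as conserved or differential.

    A domain is conserved iff the other condition has a partner with
    |start - start'| <= tolerance and |end - end'| <= tolerance; the relation
    is symmetric by construction.  Returns one row per input domain.
    """
    def classify(domains, partners):
        by_chrom: dict[str, list[TadDomain]] = {}
        for d in partners:
            by_chrom.setdefault(d.interval.chrom, []).append(d)
        rows = []
        for k, dom in enumerate(domains):
            partner = None
            for cand in by_chrom.get(dom.interval.chrom, []):
                if (abs(cand.interval.start - dom.interval.start) <= tolerance
                        and abs(cand.interval.end - dom.interval.end) <= tolerance):
                    partner = cand
                    break
            rows.append({
                "condition": dom.condition, "stage": dom.stage,
                "chrom": dom.interval.chrom,
                "start": dom.interval.start, "end": dom.interval.end,
                "label": "conserved" if partner is not None else "differential",
                "partner": (f"{partner.interval.chrom}:{partner.interval.start}-"
                            f"{partner.interval.end}") if partner else "",
            })
        return rows

    rows = classify(tads_a, tads_b) + classify(tads_b, tads_a)
    return pd.DataFrame(
        rows, columns=["condition", "stage", "chrom", "start", "end", "label", "partner"]
    )


def differential_regions(comparisons: pd.DataFrame) -> list[GenomicInterval]:
    """Merged union of the differential domains of both conditions."""
    diff = comparisons[comparisons["label"] == "differential"]
    return merge_intervals(
        GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in diff.itertuples()
    )


# ---------------------------------------------------------------------------
# SV / TAD statistics
# ---------------------------------------------------------------------------

def sv_counts_per_tad(svs: list[SVRecord], comparisons: pd.DataFrame):
    """Per-domain SV counts (>= 1 bp overlap of the SV reference interval)
    plus a Welch two-tailed t-test of conserved vs differential counts.

    Returns (per-domain DataFrame, stats dict).  With an empty group the test
    is undefined and the dict carries NaN statistics.
    """
    index = IntervalIndex()
    for i, row in enumerate(comparisons.itertuples()):
        index.add(GenomicInterval(row.chrom, int(row.start), int(row.end)), i)
    counts = np.zeros(len(comparisons), dtype=int)
    for sv in svs:
        for i in set(index.query(sv.interval)):
            counts[i] += 1
    out = comparisons.copy().reset_index(drop=True)
    out["sv_count"] = counts
    conserved = out.loc[out["label"] == "conserved", "sv_count"].to_numpy()
    differential = out.loc[out["label"] == "differential", "sv_count"].to_numpy()
    if len(conserved) == 0 or len(differential) == 0:
        stats = {"mean_conserved": float(conserved.mean()) if len(conserved) else np.nan,
                 "mean_differential": float(differential.mean()) if len(differential) else np.nan,
                 "t": np.nan, "p": np.nan}
    else:
        t, p = welch_t(differential, conserved)
        stats = {"mean_conserved": float(conserved.mean()),
                 "mean_differential": float(differential.mean()), "t": t, "p": p}
    return out, stats


def sv_density_profile(
    svs: list[SVRecord],
    comparisons: pd.DataFrame,
    body_bins: int = 50,
    flank_frac: float = 0.5,
) -> pd.DataFrame:
    """SV-midpoint density around conserved and differential domains.

    Each domain is rescaled to ``body_bins`` bins plus flanks of
    ``flank_frac`` x length on each side (same number of bins per flank,
    scaled the same way); SV midpoints accumulate per bin and densities are
    reported as mean SVs per Mb per domain, separately per label.
    """
    n_flank = int(round(body_bins * flank_frac))
    n_bins = body_bins + 2 * n_flank
    mids_by_chrom: dict[str, np.ndarray] = {}
    for sv in svs:
        mids_by_chrom.setdefault(sv.interval.chrom, [])
    for sv in svs:
        mids_by_chrom[sv.interval.chrom].append(sv.interval.midpoint)
    mids_by_chrom = {c: np.sort(np.asarray(v)) for c, v in mids_by_chrom.items()}

    profiles = {}
    for label in ("conserved", "differential"):
        doms = comparisons[comparisons["label"] == label]
        density = np.zeros(n_bins)
        n_dom = 0
        for row in doms.itertuples():
            start, end = int(row.start), int(row.end)
            length = end - start
            if length <= 0:
                continue
            n_dom += 1
            bin_bp = length / body_bins
            window_start = start - int(flank_frac * length)
            mids = mids_by_chrom.get(row.chrom, np.array([]))
            lo = np.searchsorted(mids, window_start)
            hi = np.searchsorted(mids, end + int(flank_frac * length))
            for mid in mids[lo:hi]:
                b = int((mid - window_start) // bin_bp)
                if 0 <= b < n_bins:
                    density[b] += 1.0 / (bin_bp / 1e6)
        profiles[label] = density / n_dom if n_dom else density
    rel = (np.arange(n_bins) - n_flank + 0.5) / body_bins  # 0..1 = body
    return pd.DataFrame({
        "bin": np.arange(n_bins), "rel_position": rel,
        "conserved": profiles["conserved"], "differential": profiles["differential"],
    })


def fraction_svs_in_regions(svs: list[SVRecord], regions: list[GenomicInterval]) -> float:
    """Fraction of SVs whose reference interval overlaps the (merged) region
    set by >= 1 bp."""
    if not svs:
        raise ValueError("empty SV set")
    index = IntervalIndex((region, i) for i, region in enumerate(regions))
    hits = sum(1 for sv in svs if index.any_overlap(sv.interval))
    return hits / len(svs)


def boundary_sv_window_stats(
    comparisons: pd.DataFrame,
    svs: list[SVRecord],
    layout: GenomeLayout,
    window: int = 10_000_000,
    boundary_width: int = 20_000,
):
    """Per-window proportion of TAD boundaries overlapping >= 1 SV.

    Boundaries are ``boundary_width`` intervals centred on every distinct
    domain edge (both conditions pooled).  The genome is tiled into
    non-overlapping windows; windows containing no boundary are excluded
    from the unweighted mean.  Returns (per-window DataFrame, mean).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    half = boundary_width // 2
    edges = set()
    for row in comparisons.itertuples():
        edges.add((row.chrom, int(row.start)))
        edges.add((row.chrom, int(row.end)))
    boundaries = [
        GenomicInterval(chrom, max(0, e - half), e + half) for chrom, e in sorted(edges)
    ]
    sv_index = IntervalIndex((sv.interval, sv.id) for sv in svs)

    rows = []
    for chrom in layout.names:
        length = layout.length(chrom)
        for w_start in range(0, length, window):
            w = GenomicInterval(chrom, w_start, min(w_start + window, length))
            in_window = [b for b in boundaries
                         if b.chrom == chrom and w.start <= b.midpoint < w.end]
            n_total = len(in_window)
            n_hit = sum(1 for b in in_window if sv_index.any_overlap(b))
            rows.append({
                "chrom": chrom, "start": w.start, "end": w.end,
                "n_boundaries": n_total, "n_sv_boundaries": n_hit,
                "proportion": (n_hit / n_total) if n_total else np.nan,
            })
    df = pd.DataFrame(rows)
    valid = df["proportion"].dropna()
    mean = float(valid.mean()) if len(valid) else 0.0
    return df, mean
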