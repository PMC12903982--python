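"""Window methylation pooling, DMR/DML calling, InDel-AMR detection,
and metagene profiles.

DMRs are called on non-overlapping windows (1 kb by convention) by pooling
cytosine counts across replicates and strands per window, testing each
window's 2x2 count table between the two conditions with a two-sided Fisher
exact test, and adjusting across all tested windows of the same sequence
context.  Context-specific effect-size and significance thresholds:

=======  ==========  =========
context  |delta| >=  q-value <
=======  ==========  =========
CG       0.20        0.05
CHG      0.15        0.01
CHH      0.10        0.01
=======  ==========  =========

An InDel-AMR ("acquired methylation region") is a 100-bp window of the
carrier methylome with freqC strictly above 0.2 that lies at least 90%
within an InDel's variant-sequence span — methylation carried by the variant
sequence itself rather than epiallelic change of shared sequence.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust, fisher_exact_two_sided
from .genome import GenomeLayout, GenomicInterval, GeneModel
from .svtools import SVRecord

logger = logging.getLogger("svcascade")

#: per-context (min |delta|, max q) DMR thresholds
DMR_THRESHOLDS: dict[str, tuple[float, float]] = {
    "CG": (0.20, 0.05),
    "CHG": (0.15, 0.01),
    "CHH": (0.10, 0.01),
}

#: DML thresholds on RNA-modification fractions
DML_DELTA_MIN = 0.20
DML_Q_MAX = 0.05

__all__ = [
    "DMR_THRESHOLDS",
    "tile_windows",
    "pool_window_methylation",
    "fisher_window_test",
    "call_dmrs",
    "call_amrs",
    "call_dmls",
    "metagene_profile",
]


def tile_windows(layout: GenomeLayout, size: int, step: int | None = None) -> list[GenomicInterval]:
    """Tile every chromosome left to right with windows of ``size`` bp every
    ``step`` bp (default: non-overlapping).  The terminal partial window is
    retained."""
    if size <= 0:
        raise ValueError(f"window size must be positive, got {size}")
    step = size if step is None else step
    if step <= 0:
        raise ValueError(f"window step must be positive, got {step}")
    windows = []
    for chrom in layout.names:
        length = layout.length(chrom)
        for start in range(0, length, step):
            windows.append(GenomicInterval(chrom, start, min(start + size, length)))
    return windows


def _positional_sums(calls: pd.DataFrame, chrom: str):
    """Sorted positions with cumulative methylated/total counts for one chromosome."""
    sub = calls[calls["chrom"] == chrom]
    pos = sub["pos"].to_numpy()
    order = np.argsort(pos, kind="stable")
    pos = pos[order]
    meth = sub["meth"].to_numpy()[order].astype(np.int64)
    total = meth + sub["unmeth"].to_numpy()[order].astype(np.int64)
    return pos, np.concatenate([[0], np.cumsum(meth)]), np.concatenate([[0], np.cumsum(total)])


def pool_window_methylation(
    calls: pd.DataFrame,
    windows: Sequence[GenomicInterval],
    context: str | None = None,
) -> pd.DataFrame:
    """Pool per-cytosine counts into windows (across strands; concatenate
    replicate call frames before calling to pool across replicates).

    Returns one row per window with ``meth``, ``total`` and ``freqc``
    (NaN where the window has no covered site — flagged no-data and excluded
    from testing downstream).
    """
    if context is not None:
        if context not in DMR_THRESHOLDS:
            raise ValueError(f"unknown context {context!r}")
        calls = calls[calls["context"] == context]
    rows = []
    by_chrom: dict[str, tuple] = {}
    for win in windows:
        if win.chrom not in by_chrom:
            by_chrom[win.chrom] = _positional_sums(calls, win.chrom)
        pos, cum_meth, cum_total = by_chrom[win.chrom]
        i0 = np.searchsorted(pos, win.start, side="left")
        i1 = np.searchsorted(pos, win.end, side="left")
        meth = int(cum_meth[i1] - cum_meth[i0])
        total = int(cum_total[i1] - cum_total[i0])
        rows.append((win.chrom, win.start, win.end, meth, total))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "meth", "total"])
    with np.errstate(invalid="ignore"):
        df["freqc"] = np.where(df["total"] > 0, df["meth"] / df["total"].replace(0, 1), np.nan)
    df["context"] = context if context is not None else "all"
    return df


def fisher_window_test(meth_a: int, total_a: int, meth_b: int, total_b: int) -> float:
    """Two-sided exact p-value for one window's pooled 2x2 count table."""
    return fisher_exact_two_sided(meth_a, total_a, meth_b, total_b)


def call_dmrs(
    windows_a: pd.DataFrame,
    windows_b: pd.DataFrame,
    context: str,
    thresholds: dict[str, tuple[float, float]] | None = None,
    adjust: Callable[[np.ndarray], np.ndarray] = bh_adjust,
    return_all: bool = False,
) -> pd.DataFrame:
    """Call DMRs between two conditions summarized on the same window set.

    Windows with zero pooled coverage in either condition are excluded from
    testing and multiplicity.  ``adjust`` is the multiple-testing correction
    (Benjamini-Hochberg by default; any p->q callable may be plugged in).
    """
    if thresholds is None:
        thresholds = DMR_THRESHOLDS
    if context not in thresholds:
        raise ValueError(f"unknown context {context!r}")
    key_cols = ["chrom", "start", "end"]
    if len(windows_a) != len(windows_b) or not (
        windows_a[key_cols].reset_index(drop=True).equals(windows_b[key_cols].reset_index(drop=True))
    ):
        raise ValueError("window sets of the two conditions are not identical")

    a = windows_a.reset_index(drop=True)
    b = windows_b.reset_index(drop=True)
    tested_mask = (a["total"] > 0) & (b["total"] > 0)
    tested = pd.DataFrame({
        "chrom": a["chrom"], "start": a["start"], "end": a["end"],
        "meth_a": a["meth"], "total_a": a["total"],
        "meth_b": b["meth"], "total_b": b["total"],
    })[tested_mask.to_numpy()].reset_index(drop=True)

    freq_a = tested["meth_a"] / tested["total_a"]
    freq_b = tested["meth_b"] / tested["total_b"]
    tested["freqc_a"] = freq_a
    tested["freqc_b"] = freq_b
    tested["delta"] = freq_b - freq_a
    tested["p"] = [
        fisher_exact_two_sided(ma, ta, mb, tb)
        for ma, ta, mb, tb in zip(
            tested["meth_a"], tested["total_a"], tested["meth_b"], tested["total_b"]
        )
    ]
    tested["q"] = adjust(tested["p"].to_numpy())
    tested["context"] = context
    tested["direction"] = np.where(tested["delta"] >= 0, "hyper-in-B", "hypo-in-B")

    delta_min, q_max = thresholds[context]
    tested["is_dmr"] = (tested["delta"].abs() >= delta_min) & (tested["q"] < q_max)
    if return_all:
        return tested
    return tested[tested["is_dmr"]].reset_index(drop=True)


def call_amrs(
    windows100: pd.DataFrame,
    svs: Iterable[SVRecord],
    freqc_min: float = 0.2,
    overlap_min: float = 0.9,
) -> pd.DataFrame:
    """Detect InDel-AMRs among 100-bp methylome windows of the carrier.

    A window is reported iff freqC > ``freqc_min`` (strict) and the best
    InDel covers >= ``overlap_min`` of the window (overlap measured against
    the InDel's variant-sequence span); it is linked to the InDel achieving
    the maximum.  Inversions are rejected: the AMR concept is defined for
    InDels only.
    """
    svs = list(svs)
    bad = [sv.id for sv in svs if not sv.is_indel]
    if bad:
        raise ValueError(f"call_amrs accepts InDels only; got inversion(s): {bad[:3]}")

    from .genome import IntervalIndex

    index = IntervalIndex((sv.meth_span, sv) for sv in svs)
    rows = []
    candidates = windows100[windows100["freqc"] > freqc_min]
    for row in candidates.itertuples(index=False):
        window = GenomicInterval(row.chrom, int(row.start), int(row.end))
        best_frac, best_sv = 0.0, None
        for sv in sorted(index.query(window), key=lambda s: s.id):
            frac = window.overlap_len(sv.meth_span) / window.length
            if frac > best_frac:
                best_frac, best_sv = frac, sv
        if best_sv is not None and best_frac >= overlap_min:
            rows.append((row.chrom, int(row.start), int(row.end),
                         float(row.freqc), best_sv.id, best_frac))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "freqc", "sv_id", "overlap"])


def call_dmls(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    delta_min: float = DML_DELTA_MIN,
    q_max: float = DML_Q_MAX,
    adjust: Callable[[np.ndarray], np.ndarray] = bh_adjust,
    return_all: bool = False,
) -> pd.DataFrame:
    """Call differential RNA-methylation loci between matched site tables.

    Sites are matched on (transcript, position, type); unmatched sites are
    skipped with their count logged.  Per modification type the (modified,
    unmodified) counts are compared with the exact test and BH-adjusted;
    a DML needs |delta fraction| >= 0.20 and q < 0.05.
    """
    keys = ["transcript", "position", "type"]
    merged = sites_a.merge(sites_b, on=keys, suffixes=("_a", "_b"), how="inner")
    skipped = (len(sites_a) - len(merged)) + (len(sites_b) - len(merged))
    if skipped:
        logger.info("call_dmls: %d unmatched site rows skipped", skipped)
    merged = merged[(merged["coverage_a"] > 0) & (merged["coverage_b"] > 0)].reset_index(drop=True)
    merged["delta"] = merged["fraction_b"] - merged["fraction_a"]
    merged["p"] = [
        fisher_exact_two_sided(int(ma), int(ca), int(mb), int(cb))
        for ma, ca, mb, cb in zip(
            merged["modified_a"], merged["coverage_a"],
            merged["modified_b"], merged["coverage_b"],
        )
    ]
    merged["q"] = np.nan
    for mod_type, idx in merged.groupby("type").groups.items():
        merged.loc[idx, "q"] = adjust(merged.loc[idx, "p"].to_numpy())
    merged["is_dml"] = (merged["delta"].abs() >= delta_min) & (merged["q"] < q_max)
    cols = keys + ["fraction_a", "fraction_b", "delta", "p", "q", "is_dml"]
    out = merged[cols]
    if return_all:
        return out
    return out[out["is_dml"]].reset_index(drop=True)


def metagene_profile(
    calls: pd.DataFrame,
    features: Sequence[GeneModel],
    flank: int = 3000,
    flank_bin: int = 100,
    body_bins: int = 30,
) -> pd.DataFrame:
    """Strand-oriented methylation profile over upstream flank, scaled body,
    and downstream flank of a feature set.

    Flanks are cut into fixed ``flank_bin``-bp bins (``flank // flank_bin``
    per side); the body into ``body_bins`` equal fractions.  Each feature
    contributes its per-bin pooled methylation level; the profile is the mean
    across contributing features.  Features shorter than ``body_bins`` bp are
    skipped with a warning.
    """
    n_flank = flank // flank_bin
    n_bins = 2 * n_flank + body_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    by_chrom: dict[str, tuple] = {}

    def bin_level(chrom, start, end):
        if chrom not in by_chrom:
            by_chrom[chrom] = _positional_sums(calls, chrom)
        pos, cum_meth, cum_total = by_chrom[chrom]
        i0 = np.searchsorted(pos, max(0, start), side="left")
        i1 = np.searchsorted(pos, max(0, end), side="left")
        meth = cum_meth[i1] - cum_meth[i0]
        total = cum_total[i1] - cum_total[i0]
        return (meth / total) if total > 0 else np.nan

    n_skipped = 0
    for feature in features:
        iv = feature.interval
        if iv.length < body_bins:
            n_skipped += 1
            continue
        edges = []
        for k in range(n_flank):
            edges.append((iv.start - flank + k * flank_bin, iv.start - flank + (k + 1) * flank_bin))
        body_edges = np.linspace(iv.start, iv.end, body_bins + 1)
        for k in range(body_bins):
            edges.append((int(body_edges[k]), int(body_edges[k + 1])))
        for k in range(n_flank):
            edges.append((iv.end + k * flank_bin, iv.end + (k + 1) * flank_bin))
        levels = [bin_level(iv.chrom, s, e) for s, e in edges]
        if feature.strand == "-":
            levels = levels[::-1]
        for i, level in enumerate(levels):
            if not np.isnan(level):
                sums[i] += level
                counts[i] += 1
    if n_skipped:
        logger.warning("metagene_profile: skipped %d features shorter than %d bp",
                       n_skipped, body_bins)

    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    segment = (["upstream"] * n_flank) + (["body"] * body_bins) + (["downstream"] * n_flank)
    return pd.DataFrame({"bin": np.arange(n_bins), "segment": segment,
                         "level": mean, "n_features": counts})
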