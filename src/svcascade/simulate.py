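"""Two-condition synthetic multi-omics generator with planted ground truth.

The generator emulates a wild-vs-cultivar comparison on a shared reference
frame: gene models, SV callsets, condition-specific TAD calls whose
differential domains co-locate with SVs at a configurable rate, PC1
compartment tracks consistent with gene density, replicate bisulfite
cytosine reports with planted DMRs and SV-carried methylation (AMRs),
replicate expression tables with methylation-linked suppression, and
RNA-modification site tables with expression-linked fractions.

Methylation is simulated at the window level (per-window levels realized as
binomial counts over synthetic cytosine positions) rather than per read;
this supports every downstream statistic at a fraction of the cost.  All
randomness flows from ``SynthConfig.seed``; a fixed seed yields a
byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .genome import GeneModel, GenomeLayout, GenomicInterval, merge_intervals
from .svtools import SVRecord

__all__ = ["SynthConfig", "generate"]

CONDITIONS = ("wild", "cultivar")


@dataclass
class SynthConfig:
    """Knobs of the planted-truth generator.

    Defaults are the desk-scale study conditions: a 2 x 10-Mb genome, 1000
    genes, 500 SVs with 86.6% placed in differential-TAD regions, 55% of TAD
    boundaries co-occurring with an SV, differential-TAD blocks covering
    ~60% of the genome, CG/CHG/CHH methylomes with planted |delta| = 0.4
    DMRs at ~70x pooled window coverage, insertion-carried AMRs, and
    methylation-linked expression suppression.
    """

    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: {"chrA01": 10_000_000,
                                                         "chrA02": 10_000_000})
    # genes
    n_genes: int = 1000
    gene_mean_length: int = 3000
    # TADs
    tad_bin: int = 20_000
    tad_mean_size: int = 200_000
    diff_block_domains: int = 4
    diff_region_frac: float = 0.6
    stage: str = "10DPA"
    # SVs
    n_sv: int = 500
    sv_type_probs: dict = field(default_factory=lambda: {"INS": 0.48, "DEL": 0.505,
                                                         "INV": 0.015})
    sv_mean_length: int = 800
    p_link: float = 0.866
    p_boundary_sv: float = 0.55
    boundary_sv_halfwidth: int = 200
    boundary_margin: int = 10_300
    # methylome
    meth_window: int = 1000
    n_meth_replicates: int = 3
    sites_per_window: int = 2
    site_coverage_mean: float = 12.0
    island_frac: dict = field(default_factory=lambda: {"CG": 0.20, "CHG": 0.15,
                                                       "CHH": 0.02})
    island_level: tuple = (0.50, 0.85)
    background_level: tuple = (0.02, 0.12)
    n_random_dmr: dict = field(default_factory=lambda: {"CG": 120, "CHG": 80, "CHH": 80})
    dmr_delta: float = 0.4
    # cascade planting
    n_amg_genes: int = 40
    n_indel_dmg_genes: int = 40
    n_dmg_genes: int = 40
    n_sv_only_genes: int = 40
    amr_ins_length: int = 1200
    amr_level: tuple = (0.55, 0.90)
    suppress_amg: float = 6.0
    suppress_indel_dmg: float = 6.0
    suppress_dmg: float = 2.8
    suppress_sv_only: float = 1.5
    # compartments
    pc1_bin: int = 40_000
    pc1_noise_sd: float = 0.3
    n_switch_segments: int = 6
    # expression
    n_expr_replicates: int = 3
    expr_log2_mean: float = 3.5
    expr_log2_sd: float = 1.5
    expr_rep_log2_sd: float = 0.25
    cascade_min_log2_tpm: float = 3.0
    # RNA modifications
    m5c_prob: float = 0.78
    m6a_prob_given_m5c: float = 0.78
    m6a_prob_given_not_m5c: float = 0.21
    m6a_sites_mean: float = 1.0
    m5c_sites_mean: float = 7.0
    mod_beta: tuple = (2.0, 2.0)
    mod_coverage_mean: float = 40.0
    n_dml: int = 300
    dml_delta: float = 0.3
    mod_expr_link: float = 0.8

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        for key in ("island_level", "background_level", "amr_level", "mod_beta"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def validate(self) -> None:
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        for name in ("p_link", "p_boundary_sv", "diff_region_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        n_windows = sum(l // self.meth_window for l in self.chrom_lengths.values())
        planted = sum(self.n_random_dmr.values()) + self.n_indel_dmg_genes + self.n_dmg_genes
        if planted > n_windows:
            raise ValueError("more planted DMRs than available windows")
        n_cascade = (self.n_amg_genes + self.n_indel_dmg_genes
                     + self.n_dmg_genes + self.n_sv_only_genes)
        if n_cascade > self.n_genes:
            raise ValueError("more cascade genes than genes")
        if abs(sum(self.sv_type_probs.values()) - 1.0) > 1e-9:
            raise ValueError("sv_type_probs must sum to 1")


# ---------------------------------------------------------------------------
# interval-set helpers (all lists assumed merged & sorted)
# ---------------------------------------------------------------------------

def _subtract(base: list[GenomicInterval], minus: list[GenomicInterval]) -> list[GenomicInterval]:
    minus = merge_intervals(minus)
    out = []
    for iv in base:
        pieces = [(iv.start, iv.end)]
        for m in minus:
            if m.chrom != iv.chrom:
                continue
            new = []
            for s, e in pieces:
                if m.end <= s or m.start >= e:
                    new.append((s, e))
                    continue
                if m.start > s:
                    new.append((s, m.start))
                if m.end < e:
                    new.append((m.end, e))
            pieces = new
        out.extend(GenomicInterval(iv.chrom, s, e) for s, e in pieces if e > s)
    return out


def _sample_position(rng: np.random.Generator, intervals: list[GenomicInterval],
                     margin: int = 0) -> tuple[str, int]:
    """Length-weighted uniform position from an interval set, leaving
    ``margin`` bp free at each interval end."""
    usable = [iv for iv in intervals if iv.length > 2 * margin]
    if not usable:
        raise ValueError("no room left to place a feature")
    lengths = np.array([iv.length - 2 * margin for iv in usable], dtype=float)
    idx = rng.choice(len(usable), p=lengths / lengths.sum())
    iv = usable[idx]
    pos = int(rng.integers(iv.start + margin, iv.end - margin))
    return iv.chrom, pos


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate(config: SynthConfig, outdir) -> dict:
    """Write the full synthetic bundle into ``outdir``; return a manifest
    dict with file paths and the planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    layout = GenomeLayout(config.chrom_lengths)
    genes = _make_genes(rng, layout, config)
    tads, diff_blocks = _make_tads(rng, layout, config)
    svs, sv_truth, cascade = _make_svs(rng, layout, config, genes, tads, diff_blocks)
    dmr_truth = _make_dmr_plan(rng, layout, config, genes, cascade)
    pc1_tracks, switch_truth = _make_pc1(rng, layout, config, genes)
    expr, samples, expr_truth, mod_frames, dml_truth = _make_expression_and_mods(
        rng, config, genes, cascade)

    paths = _write_bundle(outdir, config, layout, genes, tads, svs, dmr_truth,
                          cascade, pc1_tracks, expr, samples, mod_frames, rng)

    truth = {
        "p_link": config.p_link,
        "p_boundary_sv": config.p_boundary_sv,
        "differential_regions": [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end} for iv in diff_blocks
        ],
        "sv_linked": sv_truth,
        "amr_carrier_svs": cascade["amr_svs"],
        "planted_dmrs": dmr_truth["records"],
        "cascade_genes": {k: cascade[k] for k in
                          ("amg_genes", "indel_dmg_genes", "dmg_genes", "sv_only_genes")},
        "expression_effects": expr_truth,
        "switch_segments": switch_truth,
        "planted_dmls": dml_truth,
    }
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    paths["truth"] = str(truth_path)
    config.to_yaml(outdir / "config.yaml")
    paths["config"] = str(outdir / "config.yaml")
    paths["truth_dict"] = truth
    return paths


def _make_genes(rng, layout: GenomeLayout, config: SynthConfig) -> list[GeneModel]:
    total = layout.total_length
    genes = []
    gene_no = 0
    for chrom in layout.names:
        length = layout.length(chrom)
        n_chrom = int(round(config.n_genes * length / total))
        slot = length // n_chrom
        for k in range(n_chrom):
            gene_no += 1
            slot_start = k * slot
            glen = int(np.clip(rng.lognormal(np.log(config.gene_mean_length), 0.4),
                               400, slot - 4200))
            start = int(rng.integers(slot_start + 2100, slot_start + slot - glen - 2100))
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(np.arange(1, max(2, glen // 100)), size=2 * n_exons - 2,
                                      replace=False)) * 100 if n_exons > 1 else np.array([])
            exons = []
            bounds = [0] + [int(c) for c in cuts] + [glen]
            for e in range(n_exons):
                s, t = bounds[2 * e], bounds[2 * e + 1]
                if t > s:
                    exons.append(GenomicInterval(chrom, start + s, start + t))
            if not exons:
                exons = [GenomicInterval(chrom, start, start + glen)]
            genes.append(GeneModel(f"g{gene_no:05d}",
                                   GenomicInterval(chrom, start, start + glen), strand, exons))
    return genes


def _make_tads(rng, layout, config):
    """Per-condition TAD partitions; differential blocks get their interior
    boundaries shifted by two calling bins in the cultivar."""
    from .chromatin3d import TadDomain

    bin_ = config.tad_bin
    tads = {c: [] for c in CONDITIONS}
    diff_blocks = []
    for chrom in layout.names:
        length = layout.length(chrom)
        # domain edges on the calling grid, sizes ~ tad_mean_size
        edges = [0]
        while edges[-1] < length:
            size = max(3, int(round(rng.normal(config.tad_mean_size / bin_,
                                               config.tad_mean_size / bin_ / 4))))
            edges.append(min(length, edges[-1] + size * bin_))
        # a truncated terminal domain shorter than 3 bins cannot absorb a
        # 2-bin boundary shift: fold it into its neighbour
        if len(edges) > 2 and edges[-1] - edges[-2] < 3 * bin_:
            del edges[-2]
        n_dom = len(edges) - 1
        block = config.diff_block_domains
        is_diff = np.zeros(n_dom, dtype=bool)
        k = 0
        while k + block <= n_dom:
            if rng.random() < config.diff_region_frac:
                is_diff[k:k + block] = True
            k += block
        edges_b = list(edges)
        k = 0
        while k + block <= n_dom:
            if is_diff[k]:
                shift = bin_ * 2 * (1 if rng.random() < 0.5 else -1)
                for j in range(k + 1, k + block):  # interior boundaries only
                    edges_b[j] = edges[j] + shift
                diff_blocks.append(GenomicInterval(chrom, edges[k], edges[k + block]))
            k += block
        for cond, ed in (("wild", edges), ("cultivar", edges_b)):
            for i in range(n_dom):
                tads[cond].append(TadDomain(GenomicInterval(chrom, ed[i], ed[i + 1]),
                                            condition=cond, stage=config.stage))
    return tads, merge_intervals(diff_blocks)


def _deep_pools(layout, config, tads, diff_blocks):
    """Interval sets safely inside / outside the differential regions and
    away from every TAD-boundary neighbourhood."""
    edges = set()
    for cond in CONDITIONS:
        for dom in tads[cond]:
            edges.add((dom.interval.chrom, dom.interval.start))
            edges.add((dom.interval.chrom, dom.interval.end))
    margin = config.boundary_margin
    forbidden = [GenomicInterval(c, max(0, e - margin), e + margin) for c, e in sorted(edges)]
    genome = [GenomicInterval(c, 0, layout.length(c)) for c in layout.names]
    deep_diff = _subtract(diff_blocks, forbidden)
    deep_cons = _subtract(_subtract(genome, diff_blocks), forbidden)
    return sorted(edges), deep_diff, deep_cons


def _region_has(intervals, chrom, start, end):
    return any(iv.chrom == chrom and iv.start <= start and end <= iv.end for iv in intervals)


def _make_svs(rng, layout, config, genes, tads, diff_blocks):
    edges, deep_diff, deep_cons = _deep_pools(layout, config, tads, diff_blocks)
    records: list[SVRecord] = []
    linked_flags: dict[str, bool] = {}
    sv_no = 0

    def next_id():
        nonlocal sv_no
        sv_no += 1
        return f"sv{sv_no:05d}"

    # --- boundary-linked SVs: cover an exact fraction of boundaries
    n_edges = len(edges)
    n_cover = int(round(config.p_boundary_sv * n_edges))
    cover_idx = rng.choice(n_edges, size=n_cover, replace=False)
    half = config.boundary_sv_halfwidth
    diff_set = diff_blocks
    for i in sorted(cover_idx):
        chrom, e = edges[i]
        start = max(0, e - half)
        end = min(layout.length(chrom), e + half)
        sv = SVRecord(next_id(), "DEL", GenomicInterval(chrom, start, end),
                      end - start, source="sim")
        records.append(sv)
        linked_flags[sv.id] = any(sv.interval.overlaps(b) for b in diff_set)

    n_geo_linked = sum(linked_flags.values())
    n_boundary = len(records)
    n_rest = config.n_sv - n_boundary
    if n_rest < 0:
        raise ValueError("n_sv too small for the requested boundary coverage")
    target_linked_rest = int(round(config.p_link * config.n_sv)) - n_geo_linked
    if not 0 <= target_linked_rest <= n_rest:
        raise ValueError("p_link infeasible given boundary-SV geometry; "
                         "adjust n_sv, p_link or diff_region_frac")
    rest_linked = np.zeros(n_rest, dtype=bool)
    rest_linked[rng.choice(n_rest, size=target_linked_rest, replace=False)] = True

    # --- cascade gene selection (genes deep inside/outside differential regions)
    def deep_genes(pool):
        out = []
        for g in genes:
            fp = g.footprint(2000 + config.amr_ins_length)
            if _region_has(pool, fp.chrom, fp.start, fp.end):
                out.append(g)
        return out

    diff_genes = deep_genes(deep_diff)
    cons_genes = deep_genes(deep_cons)
    rng.shuffle(diff_genes)
    rng.shuffle(cons_genes)
    n_cascade = (config.n_amg_genes + config.n_indel_dmg_genes
                 + config.n_dmg_genes + config.n_sv_only_genes)

    cascade_sv_slots = config.n_amg_genes + config.n_indel_dmg_genes + config.n_sv_only_genes
    slot_linked = rest_linked[:cascade_sv_slots]
    # DMG-only genes carry no SV; their region placement follows p_link too
    dmg_linked = rng.random(config.n_dmg_genes) < config.p_link

    def take_gene(linked: bool) -> GeneModel:
        pool = diff_genes if linked else cons_genes
        if not pool:
            raise ValueError("not enough deep genes to plant the cascade")
        return pool.pop()

    cascade = {"amg_genes": [], "indel_dmg_genes": [], "dmg_genes": [], "sv_only_genes": [],
               "amr_svs": []}
    slot = 0
    for _ in range(config.n_amg_genes):
        gene = take_gene(bool(slot_linked[slot]))
        up = gene.upstream(2000)
        if gene.strand == "+":
            pos = gene.tss - 1600
        else:
            pos = gene.interval.end + 400
        sv = SVRecord(next_id(), "INS", GenomicInterval(up.chrom, pos, pos + 1),
                      config.amr_ins_length, source="sim")
        records.append(sv)
        linked_flags[sv.id] = bool(slot_linked[slot])
        cascade["amg_genes"].append(gene.gene_id)
        cascade["amr_svs"].append({"sv_id": sv.id, "gene": gene.gene_id,
                                   "chrom": sv.meth_span.chrom,
                                   "span_start": sv.meth_span.start,
                                   "span_end": sv.meth_span.end})
        slot += 1
    for _ in range(config.n_indel_dmg_genes):
        gene = take_gene(bool(slot_linked[slot]))
        body = gene.interval
        start = body.start + max(1, body.length // 4)
        length = min(800, max(100, body.length // 3))
        sv = SVRecord(next_id(), "DEL", GenomicInterval(body.chrom, start, start + length),
                      length, source="sim")
        records.append(sv)
        linked_flags[sv.id] = bool(slot_linked[slot])
        cascade["indel_dmg_genes"].append(gene.gene_id)
        slot += 1
    for _ in range(config.n_sv_only_genes):
        gene = take_gene(bool(slot_linked[slot]))
        body = gene.interval
        start = body.start + max(1, body.length // 3)
        length = min(600, max(100, body.length // 3))
        sv = SVRecord(next_id(), "DEL", GenomicInterval(body.chrom, start, start + length),
                      length, source="sim")
        records.append(sv)
        linked_flags[sv.id] = bool(slot_linked[slot])
        cascade["sv_only_genes"].append(gene.gene_id)
        slot += 1
    for k in range(config.n_dmg_genes):
        gene = take_gene(bool(dmg_linked[k]))
        cascade["dmg_genes"].append(gene.gene_id)

    # --- remaining random SVs
    sv_types = sorted(config.sv_type_probs)
    type_p = np.array([config.sv_type_probs[t] for t in sv_types])
    # keep random SVs out of the planted genes' neighbourhoods
    reserved = []
    by_id = {g.gene_id: g for g in genes}
    for key in ("amg_genes", "indel_dmg_genes", "dmg_genes", "sv_only_genes"):
        for gid in cascade[key]:
            fp = by_id[gid].footprint(2000 + config.amr_ins_length)
            reserved.append(GenomicInterval(fp.chrom, fp.start, fp.end + 2000))
    free_diff = _subtract(deep_diff, reserved)
    free_cons = _subtract(deep_cons, reserved)
    for linked in rest_linked[cascade_sv_slots:]:
        sv_type = sv_types[int(rng.choice(len(sv_types), p=type_p))]
        length = int(np.clip(rng.exponential(config.sv_mean_length), 50, 5000))
        pool = free_diff if linked else free_cons
        chrom, pos = _sample_position(rng, pool, margin=length + 10)
        if sv_type == "INS":
            interval = GenomicInterval(chrom, pos, pos + 1)
        else:
            interval = GenomicInterval(chrom, pos, pos + length)
        sv = SVRecord(next_id(), sv_type, interval, length, source="sim")
        records.append(sv)
        linked_flags[sv.id] = bool(linked)

    sv_truth = {sv_id: bool(flag) for sv_id, flag in sorted(linked_flags.items())}
    return records, sv_truth, cascade


def _make_dmr_plan(rng, layout, config, genes, cascade):
    """Choose planted-DMR windows: cascade CG-DMRs over the planted genes'
    promoters plus random DMRs per context elsewhere."""
    window = config.meth_window
    by_id = {g.gene_id: g for g in genes}
    records = []
    used = set()

    def promoter_window(gene: GeneModel) -> tuple[str, int]:
        up = gene.upstream(2000)
        mid = (up.start + up.end) // 2
        return gene.interval.chrom, (mid // window) * window

    for key in ("indel_dmg_genes", "dmg_genes"):
        for gid in cascade[key]:
            chrom, start = promoter_window(by_id[gid])
            used.add((chrom, start))
            records.append({"chrom": chrom, "start": start, "end": start + window,
                            "context": "CG", "delta": config.dmr_delta,
                            "direction": "hyper-in-cultivar", "gene": gid})

    reserved = []
    for key in ("amg_genes", "indel_dmg_genes", "dmg_genes", "sv_only_genes"):
        for gid in cascade[key]:
            fp = by_id[gid].footprint(2000 + config.amr_ins_length)
            reserved.append(fp)
    for context in sorted(config.n_random_dmr):
        n = config.n_random_dmr[context]
        placed = 0
        while placed < n:
            chrom = layout.names[int(rng.integers(len(layout.names)))]
            start = int(rng.integers(layout.length(chrom) // window)) * window
            if (chrom, start) in used:
                continue
            win = GenomicInterval(chrom, start, start + window)
            if any(win.overlaps(r) for r in reserved):
                continue
            used.add((chrom, start))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            records.append({"chrom": chrom, "start": start, "end": start + window,
                            "context": context, "delta": sign * config.dmr_delta,
                            "direction": "hyper-in-cultivar" if sign > 0 else "hypo-in-cultivar",
                            "gene": ""})
            placed += 1
    return {"records": records}


def _make_pc1(rng, layout, config, genes):
    """PC1 bedGraph tracks: density-correlated signal, random per-condition
    per-chromosome sign, planted >=2-bin switch runs in the cultivar."""
    bin_ = config.pc1_bin
    tracks = {c: [] for c in CONDITIONS}  # list of (interval, value)
    switch_truth = []
    gene_bp: dict[str, np.ndarray] = {}
    for chrom in layout.names:
        n_bins = -(-layout.length(chrom) // bin_)
        cover = np.zeros(n_bins)
        for g in genes:
            if g.interval.chrom != chrom:
                continue
            b0, b1 = g.interval.start // bin_, (g.interval.end - 1) // bin_
            for b in range(b0, b1 + 1):
                s = max(g.interval.start, b * bin_)
                e = min(g.interval.end, (b + 1) * bin_)
                cover[b] += e - s
        gene_bp[chrom] = cover

    for chrom in layout.names:
        length = layout.length(chrom)
        n_bins = -(-length // bin_)
        dens = gene_bp[chrom]
        base = (dens - dens.mean()) / (dens.std() + 1e-9)
        base = base + rng.normal(0.0, config.pc1_noise_sd, size=n_bins)
        signs = {c: (1.0 if rng.random() < 0.5 else -1.0) for c in CONDITIONS}
        values = {c: signs[c] * base for c in CONDITIONS}
        # planted switches: flip a few >=2-bin runs in the cultivar
        n_runs = config.n_switch_segments // len(layout.names)
        flipped = np.zeros(n_bins, dtype=bool)
        values["cultivar"] = values["cultivar"].copy()
        placed = 0
        attempts = 0
        while placed < n_runs and attempts < 1000:
            attempts += 1
            run = int(rng.integers(2, 5))
            b0 = int(rng.integers(0, max(1, n_bins - run)))
            # keep planted runs separated so none cancels or fuses another
            lo, hi = max(0, b0 - 1), min(n_bins, b0 + run + 1)
            if flipped[lo:hi].any():
                continue
            # a clean >=2-bin switch needs one uniform-sign run in the wild track
            seg = values["wild"][b0:b0 + run]
            if not (np.all(seg > 0) or np.all(seg < 0)):
                continue
            values["cultivar"][b0:b0 + run] = -values["cultivar"][b0:b0 + run]
            flipped[b0:b0 + run] = True
            switch_truth.append({"chrom": chrom, "start": b0 * bin_,
                                 "end": min(length, (b0 + run) * bin_), "n_bins": run})
            placed += 1
        for cond in CONDITIONS:
            for b in range(n_bins):
                iv = GenomicInterval(chrom, b * bin_, min(length, (b + 1) * bin_))
                tracks[cond].append((iv, float(values[cond][b])))
    return tracks, switch_truth


def _make_expression_and_mods(rng, config, genes, cascade):
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)
    mu = rng.normal(config.expr_log2_mean, config.expr_log2_sd, size=n)
    idx = {gid: i for i, gid in enumerate(gene_ids)}
    cascade_ids = set()
    for key in ("amg_genes", "indel_dmg_genes", "dmg_genes", "sv_only_genes"):
        cascade_ids.update(cascade[key])
    for gid in cascade_ids:
        mu[idx[gid]] = max(mu[idx[gid]], config.cascade_min_log2_tpm)

    factor = np.ones(n)
    effects = []
    for key, f in (("amg_genes", config.suppress_amg),
                   ("indel_dmg_genes", config.suppress_indel_dmg),
                   ("dmg_genes", config.suppress_dmg),
                   ("sv_only_genes", config.suppress_sv_only)):
        for gid in cascade[key]:
            factor[idx[gid]] = f
            effects.append({"gene": gid, "category": key, "factor": f})

    # RNA modification presence (shared across conditions), fractions per condition
    has_m5c = rng.random(n) < config.m5c_prob
    p_m6a = np.where(has_m5c, config.m6a_prob_given_m5c, config.m6a_prob_given_not_m5c)
    has_m6a = rng.random(n) < p_m6a
    a, b = config.mod_beta

    dml_candidates = [i for i in range(n) if has_m6a[i] and gene_ids[i] not in cascade_ids]
    dml_idx = set(rng.choice(dml_candidates, size=min(config.n_dml, len(dml_candidates)),
                             replace=False).tolist())

    mod_rows = {c: [] for c in CONDITIONS}
    max_frac = {c: np.zeros(n) for c in CONDITIONS}
    dml_truth = []
    glen = {g.gene_id: g.interval.length for g in genes}
    for i, gid in enumerate(gene_ids):
        tlen = max(300, glen[gid])
        site_plan = []  # (position, type, base_fraction, is_dml)
        if has_m6a[i]:
            n_sites = 1 + int(rng.poisson(config.m6a_sites_mean))
            positions = sorted(rng.choice(tlen, size=n_sites, replace=False).tolist())
            fracs = rng.beta(a, b, size=n_sites)
            dml_site = int(rng.integers(n_sites)) if i in dml_idx else -1
            for s, (pos, fr) in enumerate(zip(positions, fracs)):
                site_plan.append((pos, "m6A", fr, s == dml_site))
        if has_m5c[i]:
            n_sites = 1 + int(rng.poisson(config.m5c_sites_mean))
            positions = sorted(rng.choice(tlen, size=n_sites, replace=False).tolist())
            fracs = rng.beta(a, b, size=n_sites)
            for pos, fr in zip(positions, fracs):
                site_plan.append((pos, "m5C", fr, False))
        for pos, mod_type, base_fr, is_dml in site_plan:
            frs = {"wild": base_fr, "cultivar": base_fr}
            if is_dml:
                sign = 1.0 if base_fr < 0.5 else -1.0
                frs["cultivar"] = float(np.clip(base_fr + sign * config.dml_delta, 0.02, 0.98))
                dml_truth.append({"transcript": gid, "position": int(pos), "type": mod_type,
                                  "fraction_wild": float(frs["wild"]),
                                  "fraction_cultivar": float(frs["cultivar"])})
            for cond in CONDITIONS:
                cov = int(rng.poisson(config.mod_coverage_mean)) + 10
                modified = int(rng.binomial(cov, frs[cond]))
                mod_rows[cond].append((gid, int(pos), mod_type, modified, cov,
                                       modified / cov))
                if mod_type == "m6A":
                    max_frac[cond][i] = max(max_frac[cond][i], frs[cond])

    # expression tables: suppression in cultivar + modification-linked boost
    samples = []
    columns = {}
    for cond in CONDITIONS:
        mean_tpm = np.power(2.0, mu)
        if cond == "cultivar":
            mean_tpm = mean_tpm / factor
        mean_tpm = mean_tpm * np.exp(config.mod_expr_link * max_frac[cond])
        for rep in range(1, config.n_expr_replicates + 1):
            name = f"{cond}_r{rep}"
            noise = np.power(2.0, rng.normal(0.0, config.expr_rep_log2_sd, size=n))
            columns[name] = mean_tpm * noise
            samples.append({"sample": name, "accession": cond,
                            "tissue": config.stage, "replicate": rep})
    expr = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    samples_df = pd.DataFrame(samples)
    mod_frames = {
        cond: pd.DataFrame(rows, columns=["transcript", "position", "type",
                                          "modified", "coverage", "fraction"])
        for cond, rows in mod_rows.items()
    }
    return expr, samples_df, effects, mod_frames, dml_truth


def _make_methylomes(rng, layout, config, dmr_truth, cascade, outdir):
    """Emit cytosine reports: 3 replicates x 2 conditions, all contexts in
    one file per replicate.  Returns the paths."""
    window = config.meth_window
    contexts = ("CG", "CHG", "CHH")
    paths = {c: [] for c in CONDITIONS}

    # per-context per-window baseline levels and site positions (shared)
    site_pos: dict[str, dict[str, np.ndarray]] = {}
    levels = {}
    for context in contexts:
        site_pos[context] = {}
        levels[context] = {}
        for chrom in layout.names:
            n_win = -(-layout.length(chrom) // window)
            island = rng.random(n_win) < config.island_frac[context]
            lo, hi = config.background_level
            ilo, ihi = config.island_level
            base = np.where(island, rng.uniform(ilo, ihi, n_win), rng.uniform(lo, hi, n_win))
            levels[context][chrom] = {c: base.copy() for c in CONDITIONS}
            offs = rng.integers(0, window, size=(n_win, config.sites_per_window))
            pos = (np.arange(n_win)[:, None] * window + offs).ravel()
            site_pos[context][chrom] = np.sort(
                pos[pos < layout.length(chrom)].astype(np.int64))

    # apply planted DMRs (delta on the cultivar level)
    for rec in dmr_truth["records"]:
        context, chrom = rec["context"], rec["chrom"]
        w = rec["start"] // window
        lev = levels[context][chrom]
        base = float(np.clip(lev["wild"][w], 0.03, 0.5))  # anchor low for clean +/- delta
        lev["wild"][w] = base if rec["delta"] > 0 else base + abs(rec["delta"])
        lev["cultivar"][w] = base + rec["delta"] if rec["delta"] > 0 else base

    # AMR spans: highly methylated CG sites present only in the carrier (cultivar)
    amr_sites = []
    for amr in cascade["amr_svs"]:
        span_pos = np.arange(amr["span_start"] + 25, amr["span_end"], 50, dtype=np.int64)
        level = rng.uniform(*config.amr_level)
        amr_sites.append((amr["chrom"], span_pos, level))

    for cond in CONDITIONS:
        for rep in range(1, config.n_meth_replicates + 1):
            frames = []
            for context in contexts:
                for chrom in layout.names:
                    pos = site_pos[context][chrom]
                    lev = levels[context][chrom][cond]
                    widx = pos // window
                    p = lev[widx]
                    cov = rng.poisson(config.site_coverage_mean, size=pos.size)
                    meth = rng.binomial(cov, p)
                    frames.append(pd.DataFrame({
                        "chrom": chrom, "pos": pos,
                        "strand": np.where(np.arange(pos.size) % 2 == 0, "+", "-"),
                        "meth": meth, "unmeth": cov - meth,
                        "context": context, "trinuc": context,
                    }))
            if cond == "cultivar":
                for chrom, span_pos, level in amr_sites:
                    cov = rng.poisson(config.site_coverage_mean, size=span_pos.size) + 4
                    meth = rng.binomial(cov, level)
                    frames.append(pd.DataFrame({
                        "chrom": chrom, "pos": span_pos,
                        "strand": "+", "meth": meth, "unmeth": cov - meth,
                        "context": "CG", "trinuc": "CG",
                    }))
            df = pd.concat(frames, ignore_index=True)
            df = df.sort_values(["chrom", "pos", "context"], kind="stable").reset_index(drop=True)
            path = outdir / f"meth_{cond}_rep{rep}.cytosine.tsv"
            gio.write_cytosine_report(df, path)
            paths[cond].append(str(path))
    return paths


def _write_bundle(outdir, config, layout, genes, tads, svs, dmr_truth,
                  cascade, pc1_tracks, expr, samples, mod_frames, rng):
    paths = {}
    layout_path = outdir / "layout.tsv"
    pd.DataFrame({"chrom": layout.names,
                  "length": [layout.length(c) for c in layout.names]}
                 ).to_csv(layout_path, sep="\t", index=False)
    paths["layout"] = str(layout_path)

    genes_path = outdir / "genes.gff3"
    gio.write_gff3_genes(genes, genes_path)
    paths["genes"] = str(genes_path)

    # two jittered callsets plus the merged truth
    jitter = rng.integers(-50, 51, size=len(svs))
    callset_b = []
    for sv, j in zip(svs, jitter):
        start = int(np.clip(sv.interval.start + int(j), 0,
                            layout.length(sv.interval.chrom) - sv.interval.length))
        interval = GenomicInterval(sv.interval.chrom, start, start + sv.interval.length)
        callset_b.append(SVRecord(sv.id + "_b", sv.sv_type, interval, sv.length, source="callerB"))
    callset_a = [SVRecord(sv.id, sv.sv_type, sv.interval, sv.length, source="callerA")
                 for sv in svs]
    gio.write_sv_table(callset_a, outdir / "svs_callsetA.tsv")
    gio.write_sv_table(callset_b, outdir / "svs_callsetB.tsv")
    gio.write_sv_table(svs, outdir / "svs_truth.tsv")
    paths["sv_callsets"] = [str(outdir / "svs_callsetA.tsv"), str(outdir / "svs_callsetB.tsv")]
    paths["svs_truth"] = str(outdir / "svs_truth.tsv")

    for cond in CONDITIONS:
        tad_path = outdir / f"tads_{cond}.bed"
        gio.write_intervals([d.interval for d in tads[cond]], tad_path,
                            names=[f"{cond}_tad{i}" for i in range(len(tads[cond]))])
        paths[f"tads_{cond}"] = str(tad_path)
        pc1_path = outdir / f"pc1_{cond}.bedgraph"
        gio.write_intervals([iv for iv, _ in pc1_tracks[cond]], pc1_path,
                            values=[v for _, v in pc1_tracks[cond]])
        paths[f"pc1_{cond}"] = str(pc1_path)
        mod_path = outdir / f"rnamod_{cond}.tsv"
        gio.write_rnamod_table(mod_frames[cond], mod_path)
        paths[f"rnamod_{cond}"] = str(mod_path)

    expr_path = outdir / "expression.tsv"
    gio.write_expression(expr, expr_path)
    paths["expression"] = str(expr_path)
    samples_path = outdir / "samples.tsv"
    samples.to_csv(samples_path, sep="\t", index=False)
    paths["samples"] = str(samples_path)

    paths["cytosine"] = _make_methylomes(rng, layout, config, dmr_truth, cascade, outdir)
    return paths
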