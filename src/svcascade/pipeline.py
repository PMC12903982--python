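"""End-to-end pipeline: SV merging/annotation -> TAD and compartment
comparison -> DMR/AMR calling -> DEGs and RNA-mod statistics -> gene cascade
classification -> summary report.

Every number in the summary report is recomputable from the per-stage TSVs
written alongside it; the report holds no report-only computation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .cascade import classify_genes, expression_impact_by_category, find_dpgs
from .chromatin3d import (TadDomain, assign_compartments, boundary_sv_window_stats,
                          detect_switch_segments, differential_regions,
                          fraction_svs_in_regions, match_tads, sv_counts_per_tad)
from .genome import GenomeLayout
from .methylome import call_amrs, call_dmls, call_dmrs, pool_window_methylation, tile_windows
from .svtools import merge_svs, annotate_sv_context
from .transcriptomics import co_modification_sets, compute_degs

logger = logging.getLogger("svcascade")

ALL_STAGES = ("svs", "tads", "compartments", "dmr", "amr", "degs", "mods", "cascade")


@dataclass
class RunConfig:
    """Input paths, thresholds and stage toggles for one pipeline run."""

    outdir: str
    layout_path: str
    genes_path: str
    sv_callset_paths: list = field(default_factory=list)
    tad_paths: dict = field(default_factory=dict)          # condition -> BED
    pc1_paths: dict = field(default_factory=dict)          # condition -> bedGraph
    cytosine_paths: dict = field(default_factory=dict)     # condition -> [reports]
    expression_path: str = ""
    samples_path: str = ""
    rnamod_paths: dict = field(default_factory=dict)       # condition -> TSV
    seed: int = 0
    stages: tuple = ALL_STAGES
    # thresholds (defaults documented in the respective modules)
    min_coverage: int = 5
    dmr_window: int = 1000
    amr_window: int = 100
    amr_freqc_min: float = 0.2
    amr_overlap_min: float = 0.9
    tad_tolerance: int = 20_000
    boundary_window: int = 10_000_000
    boundary_width: int = 20_000
    sv_merge_dist: int = 1000
    footprint_flank: int = 2000
    min_tpm: float = 1.0

    @classmethod
    def from_bundle(cls, bundle_dir, outdir,
                    conditions=("wild", "cultivar"), **overrides) -> "RunConfig":
        """Build a config from a synthetic bundle directory (file-name
        conventions of :func:`svcascade.simulate.generate`)."""
        b = Path(bundle_dir)
        cyt = {c: sorted(str(p) for p in b.glob(f"meth_{c}_rep*.cytosine.tsv"))
               for c in conditions}
        return cls(
            outdir=str(outdir),
            layout_path=str(b / "layout.tsv"),
            genes_path=str(b / "genes.gff3"),
            sv_callset_paths=[str(b / "svs_callsetA.tsv"), str(b / "svs_callsetB.tsv")],
            tad_paths={c: str(b / f"tads_{c}.bed") for c in conditions},
            pc1_paths={c: str(b / f"pc1_{c}.bedgraph") for c in conditions},
            cytosine_paths=cyt,
            expression_path=str(b / "expression.tsv"),
            samples_path=str(b / "samples.tsv"),
            rnamod_paths={c: str(b / f"rnamod_{c}.tsv") for c in conditions},
            **overrides,
        )


def _require(stage: str, *paths) -> None:
    for p in paths:
        flat = p if isinstance(p, (list, tuple)) else [p]
        for one in flat:
            if not one or not Path(one).exists():
                raise FileNotFoundError(f"stage {stage!r}: missing input {one!r}")


def _need(state: dict, stage: str, dependency: str):
    if dependency not in state:
        raise RuntimeError(f"stage {stage!r} requires outputs of stage {dependency!r}, "
                           "which is disabled or failed")
    return state[dependency]


def gene_density_per_bin(genes, layout: GenomeLayout, bin_size: int) -> pd.DataFrame:
    """Gene-covered bp per fixed-size bin (track used to orient PC1)."""
    rows = []
    for chrom in layout.names:
        length = layout.length(chrom)
        n_bins = -(-length // bin_size)
        cover = np.zeros(n_bins)
        for g in genes:
            if g.interval.chrom != chrom:
                continue
            b0, b1 = g.interval.start // bin_size, (g.interval.end - 1) // bin_size
            for b in range(b0, b1 + 1):
                s = max(g.interval.start, b * bin_size)
                e = min(g.interval.end, (b + 1) * bin_size)
                cover[b] += e - s
        for b in range(n_bins):
            rows.append({"chrom": chrom, "start": b * bin_size,
                         "end": min(length, (b + 1) * bin_size), "density": cover[b]})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; write per-stage TSVs and a
    Markdown + JSON summary report; return the report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conditions = list(config.tad_paths) or ["wild", "cultivar"]
    layout_df = pd.read_csv(config.layout_path, sep="\t")
    layout = GenomeLayout(list(zip(layout_df["chrom"], layout_df["length"])))
    genes = gio.read_gff3_genes(config.genes_path, layout=layout)

    state: dict = {}
    report: dict = {"thresholds": {
        k: getattr(config, k) for k in (
            "min_coverage", "dmr_window", "amr_window", "amr_freqc_min",
            "amr_overlap_min", "tad_tolerance", "boundary_window", "boundary_width",
            "sv_merge_dist", "footprint_flank", "min_tpm")
    }}

    for stage in config.stages:
        logger.info("stage %s: starting", stage)
        if stage == "svs":
            _require(stage, config.sv_callset_paths)
            callsets = [gio.read_sv_table(p, layout=layout) for p in config.sv_callset_paths]
            merged = merge_svs(callsets, max_dist=config.sv_merge_dist)
            context = annotate_sv_context(merged, genes)
            gio.write_sv_table(merged, outdir / "merged_svs.tsv")
            ctx_df = pd.DataFrame({"id": list(context), "context": list(context.values())})
            ctx_df.to_csv(outdir / "sv_context.tsv", sep="\t", index=False)
            type_counts = pd.Series([sv.sv_type for sv in merged]).value_counts().to_dict()
            ctx_counts = ctx_df["context"].value_counts().to_dict()
            state["svs"] = {"merged": merged, "context": context}
            report["svs"] = {"n_merged": len(merged),
                             "by_type": {t: int(type_counts.get(t, 0))
                                         for t in ("INS", "DEL", "INV")},
                             "by_context": {k: int(v) for k, v in sorted(ctx_counts.items())},
                             "context_denominator": len(merged)}
        elif stage == "tads":
            _require(stage, list(config.tad_paths.values()))
            svs = _need(state, stage, "svs")["merged"]
            doms = {}
            for cond in conditions:
                ivs = gio.read_intervals(config.tad_paths[cond], dialect="domainBED",
                                         layout=layout)
                doms[cond] = [TadDomain(iv, condition=cond) for iv in ivs]
            comparisons = match_tads(doms[conditions[0]], doms[conditions[1]],
                                     tolerance=config.tad_tolerance)
            regions = differential_regions(comparisons)
            per_domain, enrich = sv_counts_per_tad(svs, comparisons)
            frac = fraction_svs_in_regions(svs, regions)
            windows_df, mean_prop = boundary_sv_window_stats(
                comparisons, svs, layout, window=config.boundary_window,
                boundary_width=config.boundary_width)
            per_domain.to_csv(outdir / "tad_comparison.tsv", sep="\t", index=False)
            gio.write_intervals(regions, outdir / "differential_regions.bed")
            windows_df.to_csv(outdir / "boundary_windows.tsv", sep="\t", index=False)
            counts = {
                cond: {
                    "conserved": int(((comparisons["condition"] == cond)
                                      & (comparisons["label"] == "conserved")).sum()),
                    "differential": int(((comparisons["condition"] == cond)
                                         & (comparisons["label"] == "differential")).sum()),
                } for cond in conditions
            }
            state["tads"] = {"comparisons": comparisons, "regions": regions}
            report["tads"] = {
                "counts": counts, "sv_enrichment": enrich,
                "pct_svs_in_differential_regions": 100.0 * frac,
                "mean_boundary_sv_proportion_pct": 100.0 * mean_prop,
                "n_windows": int(windows_df["proportion"].notna().sum()),
            }
        elif stage == "compartments":
            _require(stage, list(config.pc1_paths.values()))
            density = gene_density_per_bin(
                genes, layout,
                bin_size=_pc1_bin_size(config.pc1_paths[conditions[0]]))
            labelled = {}
            for cond in conditions:
                track = gio.read_intervals(config.pc1_paths[cond], dialect="bedGraph",
                                           layout=layout)
                pc1 = pd.DataFrame({"chrom": [iv.chrom for iv, _ in track],
                                    "start": [iv.start for iv, _ in track],
                                    "end": [iv.end for iv, _ in track],
                                    "pc1": [v for _, v in track]})
                labelled[cond] = assign_compartments(pc1, density["density"].to_numpy())
                labelled[cond].to_csv(outdir / f"compartments_{cond}.tsv", sep="\t",
                                      index=False)
            segments = detect_switch_segments(labelled[conditions[0]],
                                              labelled[conditions[1]])
            segments.to_csv(outdir / "switch_segments.tsv", sep="\t", index=False)
            state["compartments"] = {"segments": segments}
            cls_counts = segments["class"].value_counts().to_dict()
            report["compartments"] = {
                "segments_by_class": {k: int(cls_counts.get(k, 0))
                                      for k in ("A2B", "B2A", "stableA", "stableB")}}
        elif stage == "dmr":
            _require(stage, [p for ps in config.cytosine_paths.values() for p in ps])
            calls = {
                cond: pd.concat([gio.read_cytosine_report(p, min_coverage=config.min_coverage)
                                 for p in config.cytosine_paths[cond]], ignore_index=True)
                for cond in conditions
            }
            windows = tile_windows(layout, config.dmr_window)
            all_dmrs = []
            counts = {}
            for context in ("CG", "CHG", "CHH"):
                pooled = {cond: pool_window_methylation(calls[cond], windows, context)
                          for cond in conditions}
                dmrs = call_dmrs(pooled[conditions[0]], pooled[conditions[1]], context)
                counts[context] = len(dmrs)
                all_dmrs.append(dmrs)
            dmr_df = pd.concat(all_dmrs, ignore_index=True)
            dmr_df.to_csv(outdir / "dmrs.tsv", sep="\t", index=False)
            state["dmr"] = {"dmrs": dmr_df, "calls": calls}
            report["dmr"] = {"counts_by_context": counts}
        elif stage == "amr":
            calls = _need(state, stage, "dmr")["calls"]
            svs = _need(state, stage, "svs")["merged"]
            indels = [sv for sv in svs if sv.is_indel]
            windows100 = tile_windows(layout, config.amr_window)
            amr_frames = []
            for cond in conditions:
                pooled = pool_window_methylation(calls[cond], windows100, context=None)
                amrs = call_amrs(pooled, indels, freqc_min=config.amr_freqc_min,
                                 overlap_min=config.amr_overlap_min)
                amrs["condition"] = cond
                amr_frames.append(amrs)
            amr_df = pd.concat(amr_frames, ignore_index=True)
            amr_df.to_csv(outdir / "amrs.tsv", sep="\t", index=False)
            state["amr"] = {"amrs": amr_df}
            report["amr"] = {"n_windows": len(amr_df),
                             "n_linked_svs": int(amr_df["sv_id"].nunique())}
        elif stage == "degs":
            _require(stage, config.expression_path, config.samples_path)
            expr = gio.read_expression(config.expression_path)
            samples = gio.read_sample_sheet(config.samples_path)
            group = {cond: samples.loc[samples["accession"] == cond, "sample"].tolist()
                     for cond in conditions}
            degs = compute_degs(expr, group[conditions[0]], group[conditions[1]],
                                min_tpm=config.min_tpm)
            degs.to_csv(outdir / "degs.tsv", sep="\t")
            state["degs"] = {"degs": degs, "expr": expr, "groups": group}
            status = degs["status"].value_counts().to_dict()
            report["degs"] = {k: int(status.get(k, 0))
                              for k in ("up", "down", "ns", "not_expressed")}
        elif stage == "mods":
            _require(stage, list(config.rnamod_paths.values()))
            sites = {cond: gio.read_rnamod_table(config.rnamod_paths[cond])
                     for cond in conditions}
            dmls = call_dmls(sites[conditions[0]], sites[conditions[1]])
            dmls.to_csv(outdir / "dmls.tsv", sep="\t", index=False)
            expr_state = _need(state, stage, "degs")
            mean_tpm = expr_state["expr"][expr_state["groups"][conditions[1]]].mean(axis=1)
            comods = {}
            for cond in conditions:
                m6a = set(sites[cond].loc[sites[cond]["type"] == "m6A", "transcript"])
                m5c = set(sites[cond].loc[sites[cond]["type"] == "m5C", "transcript"])
                _, stats = co_modification_sets(m6a, m5c, mean_tpm)
                comods[cond] = {"pct_m6a_also_m5c": stats["pct_m6a_also_m5c"],
                                "pct_m5c_also_m6a": stats["pct_m5c_also_m6a"],
                                "n_both": stats["n_both"]}
            state["mods"] = {"dmls": dmls, "sites": sites}
            dml_counts = (dmls.groupby("type").size().to_dict() if len(dmls) else {})
            report["mods"] = {"n_dml": len(dmls),
                              "dml_by_type": {k: int(v) for k, v in sorted(dml_counts.items())},
                              "co_modification": comods}
        elif stage == "cascade":
            svs = _need(state, stage, "svs")["merged"]
            dmrs = _need(state, stage, "dmr")["dmrs"]
            amrs = _need(state, stage, "amr")["amrs"]
            degs = _need(state, stage, "degs")["degs"]
            labels = classify_genes(genes, svs, dmrs, amrs,
                                    footprint_flank=config.footprint_flank)
            dpgs = find_dpgs(dmrs, genes, window=config.footprint_flank)
            summary, tests = expression_impact_by_category(labels, degs)
            labels.to_csv(outdir / "gene_labels.tsv", sep="\t")
            summary.to_csv(outdir / "category_summary.tsv", sep="\t", index=False)
            tests.to_csv(outdir / "category_tests.tsv", sep="\t", index=False)
            state["cascade"] = {"labels": labels, "summary": summary, "tests": tests}
            cat_counts = labels["category"].value_counts().to_dict()
            report["cascade"] = {
                "n_dpg": len(dpgs),
                "categories": {k: int(cat_counts.get(k, 0)) for k in
                               ("InDel-AMG", "InDel-DMG", "DMG", "SV-gene", "genome-wide")},
                "impact": summary.to_dict(orient="records"),
                "pairwise_tests": tests.to_dict(orient="records"),
            }
        else:
            raise ValueError(f"unknown stage {stage!r}")
        logger.info("stage %s: done", stage)

    _write_report(report, outdir)
    report["_state"] = state
    return report


def _pc1_bin_size(path) -> int:
    first = pd.read_csv(path, sep="\t", header=None, nrows=1)
    return int(first.iloc[0, 2] - first.iloc[0, 1])


def _write_report(report: dict, outdir: Path) -> None:
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    lines = ["# svcascade summary report", ""]
    for section, payload in report.items():
        lines.append(f"## {section}")
        lines.append("```json")
        lines.append(json.dumps(payload, indent=1, sort_keys=True, default=float))
        lines.append("```")
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))
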