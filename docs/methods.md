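# Methods

`svcascade` implements a gene-regulatory cascade analysis for two-accession
plant genome comparisons: structural variation (SV) → 3D-genome remodeling
(TADs, A/B compartments) → DNA and RNA methylation divergence → gene
expression change. This note records the statistical models, default
parameters, the synthetic-data model used for validation, and the design
choices made where the design was genuinely open.

## Coordinate model

All coordinates inside the package are 0-based half-open; conversions to
1-based inclusive conventions (GFF3, Bismark-style cytosine reports) occur
only in `svcascade.io` at file boundaries, and all conversions are exact
inverses. Insertions are anchored on the reference as 1-bp intervals
`[pos, pos+1)` carrying the inserted-sequence length, so every overlap
computation treats the three SV types uniformly.

For acquired-methylation (AMR) overlap only, an InDel exposes a *methylation
span*: the deleted interval for a deletion, and `[pos, pos+length)` for an
insertion. This is the interval the variant sequence occupies in the
coordinate frame of the accession that actually carries that sequence —
where its cytosines exist and can be methylated. Without this convention a
100-bp window could never lie 90% inside a 1-bp insertion anchor and
insertion-borne AMRs would be undetectable by construction.

## Window methylation and DMR calling

Per-cytosine counts (coverage strictly greater than 5 reads after
filtering) are pooled across strands and replicates into non-overlapping
1-kb windows per sequence context. Each window's 2×2 table
(methylated/unmethylated × condition) is tested with a two-sided Fisher
exact test; q-values are Benjamini–Hochberg across all tested windows of
the context. Windows with zero pooled coverage in either condition are
excluded from testing and from the multiplicity count. A window is a DMR
when it passes both the context-specific effect-size and significance
thresholds:

| context | min &#124;Δ freqC&#124; | max q |
|---------|------------------------|-------|
| CG      | 0.20                   | 0.05  |
| CHG     | 0.15                   | 0.01  |
| CHH     | 0.10                   | 0.01  |

The Fisher p-value is computed with exact integer arithmetic: point-mass
numerators `C(t_A,k)·C(t_B,m−k)` over the common denominator `C(N,m)`, with
the two-sided tail summing masses `≤` the observed mass decided by exact
integer comparison. This removes the floating-point tie-breaking epsilon a
generic implementation needs and lets the test agree with brute-force
hypergeometric enumeration to better than 1e-12 (a property the test suite
enforces on random tables with margins up to 200).

A per-replicate regression-based test is deliberately out of scope; the
pooled design matches how replicate bisulfite libraries of the same tissue
are usually combined. The multiplicity correction is pluggable (any
`p → q` callable), with BH as the dependency-free default.

Differential RNA-methylation loci (DMLs) use the same exact test on
(modified, unmodified) read counts of matched transcript sites, BH-adjusted
per modification type, with thresholds |Δ fraction| ≥ 0.20 and q < 0.05.

## AMR (acquired methylation region) detection

The genome is tiled into 100-bp windows; a window of the carrier methylome
is an InDel-AMR iff its pooled freqC is strictly greater than 0.2 **and**
the best InDel's methylation span covers at least 90% of the window. The
boundary case (exactly 90%) is accepted; both thresholds are parameters and
the caller is provably monotone in both. Inversions are rejected: acquired
methylation is defined for variant sequence gained or lost, not rearranged.
freqC thresholds are on the 0–1 scale throughout (0.2 = 20% methylation).

## TAD comparison and SV co-occurrence

The package operates on domain calls, not contact matrices. A domain is
*conserved* when the other condition has a domain with both boundaries
within a tolerance of one calling bin (20 kb default); otherwise
*differential*. This boundary-matching classifier replaces a
contact-matrix test: it is symmetric, assigns every domain exactly one
label, and accepts externally supplied labels as a bypass. The
*differential-region set* is the merged union of differential domains of
both conditions.

SV statistics on top of the comparison:

* **Per-domain counts** — an SV is "in" a domain on ≥ 1 bp overlap of its
  reference interval (insertions via their 1-bp anchor); conserved vs
  differential count distributions are compared with a Welch two-tailed
  t-test.
* **Accumulated fraction** — fraction of SVs overlapping the
  differential-region set by ≥ 1 bp.
* **Boundary co-occurrence** — boundaries are 20-kb intervals centred on
  every distinct domain edge (both conditions pooled); the genome is tiled
  into 10-Mb windows and the per-window proportion of boundaries
  overlapping ≥ 1 SV is averaged, unweighted, over windows that contain at
  least one boundary (windows without boundaries are excluded rather than
  counted as zero).
* **Density profile** — SV midpoints accumulated over length-normalised
  domain bodies (50 bins) with half-length flanks, reported per Mb,
  separately for conserved and differential domains.

## A/B compartments

PC1 values are defined only up to sign per chromosome, so each
chromosome's track is oriented to correlate positively (Pearson, whole
chromosome, not per arm) with gene density; bins with oriented PC1 > 0 are
A, < 0 are B, exactly 0 (or an all-zero chromosome) are NA. Switch
segmentation finds maximal runs of bins labelled A in one condition and B
in the other: runs of ≥ 2 bins are A2B/B2A switches; single-bin flips and
unchanged bins are stable, classed by the initial (condition-A) label so
that segment classes partition the non-NA bins; NA bins break runs.

## Differential expression and gene categories

The DE stand-in computes `log2FC = log2((mean TPM_B + 1)/(mean TPM_A + 1))`
(pseudocount 1) and a Welch two-tailed t-test on log2(TPM+1) across
replicates (≥ 2 per condition), BH-adjusted; a gene is up/down when
|log2FC| ≥ 1 and q < 0.05. Genes below 1 TPM in every sample are
`not_expressed` and excluded from testing and multiplicity. "Expressed in
at least one material" is operationalised as TPM ≥ 1 in ≥ 1 sample
(configurable). Externally computed DEG tables with the same columns drop
in anywhere a DEG frame is expected: the cascade logic is agnostic to the
DE engine, and a negative-binomial count model can replace the stand-in
without touching anything downstream.

Gene integration uses a *footprint*: gene body plus 2 kb upstream
(strand-aware), harmonised with the DPG definition (DMR within 2 kb
upstream of the TSS); a body-only mode is provided. Flags: `sv_gene`
(footprint overlaps an SV), `dmg` (overlaps a DMR), `indel_dmg` (both,
with the SV restricted to InDels), `indel_amg` (overlaps an AMR window).
The resolved category takes the highest priority among
InDel-AMG > InDel-DMG > DMG > SV-gene > genome-wide. Expression impact per
category is summarised on |log2FC| (genes with expression only), with all
pairwise Welch tests BH-adjusted.

Region DEG proportions (e.g. inside inversions) report
`100 × DEGs / expressed genes` truncated — not rounded — to two decimals
(matching the convention of the numbers they reproduce: 78/801 →
9.73%), alongside full precision.

SV merging is type-aware single-linkage on start positions within 1 kb
(transitive); the representative keeps the leftmost start and the longest
length, with source callsets concatenated. Inversions additionally require
≥ 0.5 reciprocal overlap to merge, so a megabase inversion cannot absorb an
unrelated small one that merely starts nearby. Gene-context annotation
assigns one category per SV with priority
exon > intron > upstream > downstream > intergenic (1-kb strand-aware
flanks; ties across genes broken by nearest TSS; a gene without exon
records is treated as all-exonic with a warning).

## The synthetic-data generator

`SynthConfig`/`generate` emit a complete two-condition bundle with planted
ground truth. Defaults are the study conditions the package validates
against and are not tuned per run:

* **Scale** — 2 chromosomes × 10 Mb, 1000 genes, 500 SVs, ~100 TADs per
  condition (mean 200 kb on a 20-kb grid); full generate+pipeline run in
  well under a minute on one CPU.
* **TADs** — blocks of 4 consecutive domains become differential with
  probability 0.6 (differential regions cover ~60% of the genome,
  consistent with chromosome-level differential coverage seen in real
  wild/cultivar comparisons); inside a block the cultivar's interior
  boundaries shift by two calling bins (40 kb), beyond the matching
  tolerance, while conserved domains are copied exactly.
* **SVs** — 86.6% of SVs are placed inside differential regions
  (`p_link = 0.866`) and 55% of TAD boundaries receive a co-occurring SV
  (`p_boundary_sv = 0.55`), the two co-location rates the analysis should
  recover. Boundary-covering SVs are placed first; the remaining SVs are
  placed deep inside (or outside) the differential regions, away from all
  boundary neighbourhoods, with the linked count completing `p_link`
  exactly, so the realized fraction is controlled and falls inside its own
  binomial confidence band.
* **Methylomes** — methylation is simulated at the window level: per-window
  baseline levels (CG/CHG/CHH island fractions 0.20/0.15/0.02; islands
  0.50–0.85, background 0.02–0.12) realised as binomial counts over
  synthetic cytosines (2 sites per kb per context, ~12× per site, 3
  replicates per condition — pooled window coverage ≈ 72×). Planted DMRs
  shift the cultivar level by ±0.4 from a low anchor; AMR-carrier
  insertions contribute 50-bp-spaced CG sites at 0.55–0.90 methylation
  present *only* in the carrier's reports. Per-read simulation is omitted
  deliberately: every downstream statistic consumes window counts.
* **Expression** — per-gene baselines are log-normal (log2 mean 3.5,
  sd 1.5); replicates multiply by 2^N(0, 0.25). Genes with a planted
  promoter hyper-DMR or AMR in the cultivar are suppressed by factors 6
  (InDel-DMG, InDel-AMG), 2.8 (DMG-only) and 1.5 (SV-only), producing the
  cascade ordering InDel-DMG ≈ InDel-AMG > DMG > genome-wide.
* **RNA modifications** — m5C presence 0.78; m6A presence 0.78 given m5C
  and 0.21 otherwise, so ~93% of m6A transcripts are also m5C-modified and
  ~78% of m5C transcripts carry m6A, matching the observed co-modification
  ranges. Site fractions are Beta(2,2); expression is multiplied by
  `exp(0.8 × max m6A fraction)`; 300 planted DMLs shift one site's
  fraction by 0.3 between conditions.

What the generator does **not** emulate: sequence-level signal (no
FASTA/reads), linkage between methylation contexts, TE annotations,
spatially autocorrelated methylation beyond the window level, per-read
bisulfite conversion error, more than one developmental stage by default,
and the contact matrices behind the TAD/PC1 calls. Passing tests therefore
demonstrate that the statistics recover planted structure from well-formed
inputs — not that the upstream callers the real analysis depends on are
reliable.

## Numerical choices and degenerate inputs

* Exact integer arithmetic for the Fisher test (no tie epsilon); BH via
  statsmodels; Welch tests return (0, 1) for equal-mean zero-variance
  groups, (∞, 0) for unequal-mean zero-variance groups, and NaN when a
  group has fewer than two observations (such groups are reported
  descriptively and excluded from tests).
* "Greater than 0.2" and "coverage > 5" are strict inequalities; "overlap
  exceeding 90%" is implemented as ≥ 0.9 (boundary accepted, parameter).
* Fraction-bin boundaries are lower-inclusive; a maximum modification
  fraction of exactly 0.5 is High.
* Terminal partial windows are retained in all tilings; a domain shorter
  than one calling bin is never emitted by the generator.
* Empty interval files are valid (warning logged); an empty SV set is an
  error where a fraction of SVs would be undefined.
* All randomness flows from a single seed through `numpy`'s Generator;
  identical seed and configuration give byte-identical bundles and
  identical reports.

## Known limitations

* The boundary-matching TAD classifier cannot see intensity changes inside
  unchanged boundaries; a contact-matrix differential test would.
* The Welch-on-log2 DE stand-in underuses count information at low
  expression; it exists to keep the cascade self-contained and swappable.
* AMR detection on deletions inherits whatever methylation the deleted
  sequence carried — windows methylated for reasons unrelated to the SV
  still qualify, which inflates InDel-AMG counts in methylation-dense
  regions (visible in the synthetic runs, and presumably in real data).
* With two 10-Mb chromosomes the 10-Mb boundary windows reduce to two
  observations; the boundary co-occurrence mean is correspondingly coarse
  at desk scale.
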