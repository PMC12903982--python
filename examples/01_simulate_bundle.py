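"""Generate a small planted-truth multi-omics bundle and inspect the truth.

The generator emits every track the pipeline consumes (gene models, SV
callsets, TAD/PC1 calls per condition, replicate cytosine reports,
expression and RNA-modification tables) plus a truth.json recording what
was planted where.
"""

import json
import tempfile
from pathlib import Path

from svcascade import SynthConfig, generate

config = SynthConfig(
    seed=11,
    chrom_lengths={"chrA01": 2_000_000, "chrA02": 2_000_000},
    n_genes=200, n_sv=120,
    n_random_dmr={"CG": 25, "CHG": 15, "CHH": 15},
    n_amg_genes=8, n_indel_dmg_genes=8, n_dmg_genes=8, n_sv_only_genes=8,
    n_dml=40,
)

with tempfile.TemporaryDirectory() as tmp:
    paths = generate(config, Path(tmp) / "bundle")
    truth = paths["truth_dict"]
    linked = truth["sv_linked"]
    print(f"files written: {sum(1 for k in paths if k != 'truth_dict')} tracks")
    print(f"SVs planted: {len(linked)}; fraction inside differential-TAD "
          f"regions: {sum(linked.values()) / len(linked):.3f} "
          f"(planted p_link = {truth['p_link']})")
    print(f"planted DMR windows: {len(truth['planted_dmrs'])}")
    print(f"insertions carrying methylated sequence (AMR carriers): "
          f"{len(truth['amr_carrier_svs'])}")
    print(f"planted differential RNA-methylation loci: {len(truth['planted_dmls'])}")

# The linked fraction sits at the configured co-location rate: that rate is
# what the TAD stage of the pipeline should recover from the emitted files.
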