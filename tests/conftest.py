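import numpy as np
import pandas as pd
import pytest

from svcascade import (GeneModel, GenomeLayout, GenomicInterval, RunConfig,
                       SynthConfig, generate, run_pipeline)


@pytest.fixture
def layout():
    return GenomeLayout({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def toy_genes():
    return [
        GeneModel("gA", GenomicInterval("chr1", 10_000, 14_000), "+",
                  [GenomicInterval("chr1", 10_000, 11_000),
                   GenomicInterval("chr1", 12_000, 14_000)]),
        GeneModel("gB", GenomicInterval("chr1", 50_000, 53_000), "-",
                  [GenomicInterval("chr1", 50_000, 53_000)]),
    ]


def small_config(seed: int = 7) -> SynthConfig:
    """Scaled-down generator settings for fast unit tests."""
    return SynthConfig(
        seed=seed,
        chrom_lengths={"chrA01": 2_000_000, "chrA02": 2_000_000},
        n_genes=200, n_sv=120,
        n_random_dmr={"CG": 25, "CHG": 15, "CHH": 15},
        n_amg_genes=8, n_indel_dmg_genes=8, n_dmg_genes=8, n_sv_only_genes=8,
        n_dml=40, n_switch_segments=4,
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_bundle")
    paths = generate(small_config(), outdir)
    return outdir, paths


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Default-scale bundle: the study conditions of the simulator."""
    outdir = tmp_path_factory.mktemp("default_bundle")
    paths = generate(SynthConfig(seed=1), outdir)
    return outdir, paths


@pytest.fixture(scope="session")
def default_report(default_bundle, tmp_path_factory):
    bundle_dir, _ = default_bundle
    outdir = tmp_path_factory.mktemp("default_out")
    config = RunConfig.from_bundle(bundle_dir, outdir)
    return run_pipeline(config), outdir
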