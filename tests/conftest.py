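"""Shared fixtures: small simulated datasets and hand-built features."""

import pytest

from strainlift import simdata
from strainlift.models import GenomeInterval, LiftedFeature


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully featured simulation configuration."""
    return simdata.SimConfig(
        n_chromosomes=2,
        chromosome_length=40_000,
        n_genes=16,
        n_lines=3,
        samples_per_line=(2, 3),
        n_shared_strain_variants=60,
        n_private_noise_per_line=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_pair(small_config):
    return simdata.simulate_genome_pair(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_pair):
    return simdata.simulate_cohort(small_config, small_pair)


@pytest.fixture
def toy_features():
    """One gene G1 with exon E1 [100,200) inside its span [100,600)."""
    exon = LiftedFeature(
        kind="exon",
        interval=GenomeInterval("chr1", 100, 200),
        exon_id="E1",
        gene_id="G1",
        gene_name="Abc",
        strand="+",
        percent_identity=99.5,
    )
    gene = LiftedFeature(
        kind="gene",
        interval=GenomeInterval("chr1", 100, 600),
        exon_id="",
        gene_id="G1",
        gene_name="Abc",
        strand="+",
        percent_identity=None,
    )
    return [exon, gene]
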