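import pytest

from gaschip.simulate import (
    SimConfig,
    plant_motifs,
    plant_sites,
    simulate_genome_and_genes,
)


@pytest.fixture(scope="session")
def paper_scale_cohort():
    """Full 105-site synthetic cohort with the study's category and motif
    composition, plus its ground truth."""
    config = SimConfig(seed=11)
    genome, genes = simulate_genome_and_genes(config)
    sites, truth = plant_sites(config, genome, genes)
    sites, truth = plant_motifs(sites, config, truth)
    return config, genome, genes, sites, truth


@pytest.fixture()
def small_config():
    """A fast small-cohort configuration for tests that rebuild datasets."""
    return SimConfig(
        seed=5,
        n_chroms=2,
        chrom_length=400_000,
        n_genes=8,
        category_counts={
            "intergenic": 5,
            "upstream_lt10kb": 3,
            "intron1": 3,
            "internal_intron": 4,
        },
        motif_class_counts={"canonical": 5, "general_only": 6, "none": 4},
    )
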