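import pytest

from pancore import orthologs, pangenome, synthetic


@pytest.fixture(scope="session")
def tiny_config():
    # n_softcore=0 because the softcore occupancy band is empty below 20 genomes
    return synthetic.SimulationConfig(
        n_clades=2, genomes_per_clade=5,
        n_core=15, n_softcore=0, n_shell=10, n_cloud=5, n_hgt=3,
        n_ecosnp=2, n_ecosnp_families=2, n_outlier_genomes=1,
        gene_length_mean=360.0, gene_length_sd=60.0,
        within_clade_mut_rate=0.0, between_clade_mut_rate=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_config):
    return synthetic.simulate_pangenome(tiny_config)


@pytest.fixture(scope="session")
def tiny_kept(tiny_sim):
    genomes, truth = tiny_sim
    kept, _ = pangenome.quality_filter(genomes.gene_counts())
    return genomes.subset(kept)


@pytest.fixture(scope="session")
def tiny_graph(tiny_kept):
    return orthologs.build_similarity_graph(tiny_kept)


@pytest.fixture(scope="session")
def tiny_clusters(tiny_graph):
    return orthologs.mcl_cluster(tiny_graph)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_clusters, tiny_kept):
    return pangenome.build_presence_matrix(tiny_clusters, tiny_kept)
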