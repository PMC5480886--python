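import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

from bsamap import (  # noqa: E402
    RunConfig, SimConfig, make_gene_models, make_genome, make_pools,
    mutagenize, run_pipeline, sample_pooled_reads, simulate_cross,
)


def tiny_sim_config(seed: int = 7, **kw) -> SimConfig:
    base = dict(
        seed=seed,
        n_chromosomes=2,
        chrom_lengths=300_000,
        ems_snp_count=150,
        wt_divergence_count=40,
        causal_chrom=1,
        population_size=400,
        n_genes_per_chromosome=6,
        causal_window_genes=8,
        causal_window_bp=120_000,
    )
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_config():
    return tiny_sim_config()


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    """A complete small simulated study, built once per session."""
    genome = make_genome(tiny_config)
    genes = make_gene_models(genome, tiny_config)
    truth = mutagenize(genome, tiny_config, genes)
    individuals = simulate_cross(truth, tiny_config)
    pools = make_pools(individuals, tiny_config)
    obs = sample_pooled_reads(truth, pools, tiny_config)
    return {
        "config": tiny_config, "genome": genome, "genes": genes, "truth": truth,
        "individuals": individuals, "pools": pools, "obs": obs,
    }


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory):
    """One full desk-scale pipeline run (10 x 5 Mb, ~2,300 EMS SNPs)."""
    outdir = tmp_path_factory.mktemp("desk_run")
    rc = RunConfig(sim=SimConfig(seed=1), outdir=str(outdir))
    return rc, run_pipeline(rc)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250930)
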