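import pytest

from lncisland.simulate import SimulationConfig


def small_sim_config(seed: int = 11) -> SimulationConfig:
    """Reduced study for fast end-to-end tests (one 500-kb chromosome)."""
    return SimulationConfig(
        seed=seed,
        n_chromosomes=1,
        chrom_length=500_000,
        n_coding_genes=8,
        n_antisense=2,
        n_intergenic=4,
        n_intronic=2,
        n_monoexonic=2,
        n_noise_monoexonic=18,
        n_decoys=1,
        n_condition_specific=1,
    )


@pytest.fixture(scope="session")
def small_sim_dir(tmp_path_factory):
    from lncisland.simulate import simulate_all

    out = tmp_path_factory.mktemp("smallsim")
    simulate_all(small_sim_config(), out)
    return out


@pytest.fixture(scope="session")
def small_pipeline(small_sim_dir, tmp_path_factory):
    from lncisland.pipeline import run_on_simulated

    out = tmp_path_factory.mktemp("smallout")
    return run_on_simulated(small_sim_dir, out), out
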