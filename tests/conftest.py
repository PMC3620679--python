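import numpy as np
import pytest

from recspot import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def scaled_set_sizes(n_genes: int) -> dict[str, int]:
    """Default set sizes rescaled to a smaller gene universe."""
    return {k: max(5, v * n_genes // 1800) for k, v in sd.DEFAULT_SET_SIZES.items()}


@pytest.fixture
def small_config():
    """A small genome (2 x 8 Mb) that keeps full runs under a second."""
    return sd.GeneratorConfig(
        n_chromosomes=2,
        chromosome_length=8_000_000,
        n_genes=400,
        set_sizes=scaled_set_sizes(400),
        seed=11,
    )


@pytest.fixture
def small_bundle(small_config, tmp_path):
    d = tmp_path / "bundle"
    sd.simulate_bundle(small_config, d)
    return d


def run_config_for(bundle_dir, seed=11, **overrides):
    from recspot.workflow import RunConfig

    kwargs = dict(
        map_path=str(bundle_dir / "map.tsv"),
        genes_path=str(bundle_dir / "genes.bed"),
        sets_path=str(bundle_dir / "sets.tsv"),
        rates_path=str(bundle_dir / "rates.tsv"),
        branches_path=str(bundle_dir / "branches.tsv"),
        fasta_path=str(bundle_dir / "regions.fa"),
        rmsk_path=str(bundle_dir / "rmsk.tsv"),
        fragile_path=str(bundle_dir / "fragile.bed"),
        seed=seed,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)
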