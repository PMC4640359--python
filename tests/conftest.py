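import pytest

from crpcnet.synthetic import SyntheticDesign


@pytest.fixture
def tiny_design():
    """A miniature study that keeps end-to-end tests fast."""
    return SyntheticDesign(
        n_genes=60,
        n_tfs=5,
        n_samples_per_condition=20,
        interactome_nodes=200,
        hub_degree=50,
        tf_out_degree_range=(1, 5),
        gainer_targets=(1, 8),
        seed=7,
    )


@pytest.fixture
def grn_bench_design():
    """Scaled GRN benchmark: 20 TFs, 100 targets, 50 samples per condition."""
    def make(seed: int) -> SyntheticDesign:
        return SyntheticDesign(n_genes=120, seed=seed)

    return make
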