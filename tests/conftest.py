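import copy

import pytest

from editome import synthdata as syn


def small_config(seed: int = 7) -> syn.SynthConfig:
    return syn.SynthConfig(
        genome_length=60_000,
        n_chromosomes=2,
        n_edit_sites=150,
        n_specific_sites=21,
        n_snp_decoys=30,
        n_utr3_sites=6,
        mean_depth=30,
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    """Reference + truth on a 60 kb genome (shared, treat as read-only)."""
    ref = syn.generate_reference(small_cfg)
    truth = syn.plant_truth(ref, small_cfg)
    return ref, truth


@pytest.fixture(scope="session")
def small_sam(small_bundle, small_cfg, tmp_path_factory):
    """One simulated liver sample over the small bundle."""
    ref, truth = small_bundle
    path = tmp_path_factory.mktemp("sam") / "liver_s1.sam"
    syn.simulate_reads(ref, truth, "liver", "liver_s1", small_cfg, path)
    return path


@pytest.fixture()
def fresh_cfg():
    return small_config()
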