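import pytest

from tssoverlap.simulate import SimConfig, generate


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down cohort: 30 pairs over 3 groups of 4 libraries."""
    from tssoverlap.simulate import LibraryGroup

    return SimConfig(
        seed=7,
        n_pairs=30,
        n_constitutive_pairs=3,
        n_switch_pairs=3,
        n_singleton_genes=10,
        library_groups=[
            LibraryGroup("tissue", 4, 0.9),
            LibraryGroup("cellline", 4, 0.9),
            LibraryGroup("cancer", 4, 0.9),
        ],
        n_ase_libraries=3,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """The standard scenario (200 pairs, 3 x 10 libraries)."""
    return generate(SimConfig(seed=11))
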