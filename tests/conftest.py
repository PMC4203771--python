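import pytest

from cfnipt import SimulationConfig, make_layout, simulate_bin_counts

# Toy genome: six equal 3 Mb autosomes, 10 bins each at the default 300 kb
# width.  Two chromosomes reuse the trisomy target names so the default
# trisomy map applies unchanged.
TOY_CHROMS = [
    ("chr1", 3_000_000),
    ("chr2", 3_000_000),
    ("chr3", 3_000_000),
    ("chr4", 3_000_000),
    ("chr18", 3_000_000),
    ("chr21", 3_000_000),
]


@pytest.fixture(scope="session")
def toy_layout():
    return make_layout(TOY_CHROMS, bin_size=300_000)


@pytest.fixture(scope="session")
def toy_cohort(toy_layout):
    """A small full cohort (euploid + both trisomies) on the toy genome."""
    config = SimulationConfig(
        n_euploid=40,
        n_t18=3,
        n_t21=5,
        reads_per_sample=400_000,
        seed=11,
    )
    counts, labels = simulate_bin_counts(config, toy_layout)
    return config, counts, labels
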