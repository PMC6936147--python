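from pathlib import Path

import pytest

from dytidriver import DyTidriver, SyntheticConfig, simulate_cohort

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def toy_paths(data_dir):
    """The committed 6-gene / 3-patient end-to-end fixture."""
    return {
        "mutations": data_dir / "toy_mutations.tsv",
        "tumor_expr": data_dir / "toy_tumor_expr.tsv",
        "tissue_expr": data_dir / "toy_tissue_expr.tsv",
        "network": data_dir / "toy_network.tsv",
        "benchmark": data_dir / "toy_benchmark.txt",
    }


@pytest.fixture(scope="session")
def toy_model(toy_paths) -> DyTidriver:
    # with only 3 samples the sample-sd z-score is bounded by 2/sqrt(3) < 2,
    # so the toy runs at a cutoff of 1.0
    return DyTidriver.from_files(
        toy_paths["mutations"],
        toy_paths["tumor_expr"],
        toy_paths["network"],
        [toy_paths["tissue_expr"]],
        zscore_cutoff=1.0,
    )


@pytest.fixture(scope="session")
def toy_results(toy_model):
    return toy_model.fit()


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 50-gene / 20-patient synthetic cohort."""
    return simulate_cohort(SyntheticConfig.small(seed=7))
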