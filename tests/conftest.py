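import pandas as pd
import pytest

from stabbench import curation, splitting
from stabbench.synthetic_data import SyntheticConfig, generate_dataset

#: Desk-scale generator config reused across tests. Smaller than the
#: generator defaults (fewer domains/mutants) so the suite stays fast;
#: the domain-count threshold is scaled with the mutant counts.
SMALL_CONFIG = SyntheticConfig(
    n_domains=12,
    n_homolog_pairs=3,
    mutants_per_domain=(60, 90),
    seed=101,
)

SMALL_THRESHOLDS = curation.CurationThresholds(min_seqs_per_domain=40)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_curated(small_dataset):
    records, _ = small_dataset
    curated, summary = curation.curate(records, SMALL_THRESHOLDS)
    return curated, summary


@pytest.fixture(scope="session")
def small_assignment(small_curated):
    curated, _ = small_curated
    return splitting.make_assignment(curated, splitting.SplitConfig(seed=7))


@pytest.fixture()
def toy_measurements():
    """Handmade measurement table: 2 domains, replicate structure known."""
    rows = [
        # domain A: two replicates of one variant, one singleton
        ("A", "A_v1", "ACDEFGHIKL", "r1", 4.0, 3.0, False),
        ("A", "A_v1", "ACDEFGHIKL", "r2", 6.0, 3.2, False),
        ("A", "A_v2", "ACDEFGHIKM", "r1", 2.5, 2.4, False),
        # domain B: three identical replicates
        ("B", "B_v1", "WYVTSRQPNM", "r1", 1.0, 1.5, True),
        ("B", "B_v1", "WYVTSRQPNM", "r2", 1.0, 1.5, True),
        ("B", "B_v1", "WYVTSRQPNM", "r3", 1.0, 1.5, True),
    ]
    df = pd.DataFrame(rows, columns=curation.MEASUREMENT_COLUMNS)
    df.attrs["n_raw_rows"] = len(df)
    df.attrs["drop_log"] = {}
    return df


def write_raw_csv(path, rows, columns=None):
    """Raw CSV in the synthetic (identity) column layout."""
    columns = columns or curation.MEASUREMENT_COLUMNS
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path
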