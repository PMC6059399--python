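import numpy as np
import pandas as pd
import pytest

from skinid import OtuTable, generate_cohort, to_relative_abundance
from skinid.simulate import default_cohort_config, noisy_cohort_config


def make_table(counts: dict[str, list[float]], owners: dict[str, str],
               periods: dict[str, str] | None = None,
               otu_ids: list[str] | None = None,
               value_kind: str = "counts") -> OtuTable:
    """Hand-build a small OtuTable: counts maps sample_id -> vector."""
    if counts:
        n = len(next(iter(counts.values())))
        otu_ids = otu_ids or [f"OTU{i+1:04d}" for i in range(n)]
    elif otu_ids is None:
        raise ValueError("empty table needs explicit otu_ids")
    data = pd.DataFrame(counts, index=otu_ids, dtype=float)
    meta = pd.DataFrame({
        "sample_id": list(counts),
        "individual_id": [owners[s] for s in counts],
        "timepoint": list(range(1, len(counts) + 1)),
        "period": [(periods or {}).get(s, "year1") for s in counts],
    }).set_index("sample_id")
    return OtuTable(data=data, metadata=meta, value_kind=value_kind)


@pytest.fixture(scope="session")
def toy_table() -> OtuTable:
    """4 individuals x 3 timepoints, 6 OTUs, separable but not trivially so."""
    rng = np.random.default_rng(42)
    counts = {}
    owners = {}
    base = {
        "A": [800, 100, 60, 30, 8, 2],
        "B": [700, 150, 90, 20, 0, 40],
        "C": [850, 50, 30, 60, 10, 0],
        "D": [600, 250, 70, 40, 25, 15],
    }
    for ind, b in base.items():
        for t in range(3):
            noise = rng.poisson(np.asarray(b))
            counts[f"{ind}{t+1}"] = noise.tolist()
            owners[f"{ind}{t+1}"] = ind
    return make_table(counts, owners)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(default_cohort_config(seed=0))


@pytest.fixture(scope="session")
def default_rel(default_cohort):
    table, _ = default_cohort
    return to_relative_abundance(table)


@pytest.fixture(scope="session")
def noisy_cohort():
    return generate_cohort(noisy_cohort_config(seed=0))


@pytest.fixture(scope="session")
def noisy_rel(noisy_cohort):
    table, _ = noisy_cohort
    return to_relative_abundance(table)
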