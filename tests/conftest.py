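import numpy as np
import pandas as pd
import pytest

from metabodyn.table import MetaboliteTable, Stage


def make_table(
    values: np.ndarray,
    days,
    replicates=None,
    stage: Stage = Stage.RAW,
    metabolite_names=None,
    classes=None,
):
    """Build a MetaboliteTable from a plain array for tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    days = list(days)
    assert len(days) == n
    if replicates is None:
        seen: dict = {}
        replicates = []
        for d in days:
            seen[d] = seen.get(d, 0) + 1
            replicates.append(seen[d])
    names = metabolite_names or [f"m{j}" for j in range(p)]
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "day": days,
            "replicate": replicates,
        }
    )
    vdf = pd.DataFrame(values, index=samples["sample_id"].to_numpy(), columns=names)
    ann = pd.DataFrame(
        {
            "metabolite": names,
            "class": classes if classes is not None else ["other"] * p,
            "id_level": ["unknown"] * p,
        }
    )
    return MetaboliteTable(values=vdf, samples=samples, metabolites=ann, stage=stage)


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture(scope="session")
def small_dataset():
    """Default-condition synthetic dataset at reduced size, shared."""
    from metabodyn.simulate import SimulationConfig, simulate_metabolome

    return simulate_metabolome(SimulationConfig(seed=42, n_metabolites=120))


@pytest.fixture(scope="session")
def small_processed(small_dataset):
    from metabodyn.preprocess import preprocess

    return preprocess(small_dataset.table)
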