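from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stablephos import (
    Collection,
    DatasetTable,
    GeneratorConfig,
    SiteId,
    generate_collection,
    generate_eval_dataset,
    run_identification,
)


def make_table(dataset_id: str, rows: dict[str, list[float | None]], conditions: list[str]) -> DatasetTable:
    """Small hand-built dataset: rows maps 'PROT_S1'-style ids to value lists
    (None = missing)."""
    from stablephos import parse_site_id

    index = pd.Index([parse_site_id(s) for s in rows])
    data = pd.DataFrame(
        [[np.nan if v is None else float(v) for v in vals] for vals in rows.values()],
        index=index,
        columns=conditions,
    )
    return DatasetTable(dataset_id=dataset_id, data=data)


def set_partitions(items: list):
    """All set partitions of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study: 20 datasets, 5,000 sites, 5% stable core."""
    config = GeneratorConfig()
    collection, truth = generate_collection(config)
    return config, collection, truth


@pytest.fixture(scope="session")
def default_run(default_sim):
    _, collection, _ = default_sim
    return run_identification(collection)


@pytest.fixture(scope="session")
def eval_data(default_sim):
    config, _, truth = default_sim
    return generate_eval_dataset(config, truth, n_samples_per_condition=4, n_conditions=4)


@pytest.fixture
def small_collection():
    """Three tiny datasets with controlled membership."""
    d1 = make_table(
        "d1",
        {"A_S1": [0.1, -0.2], "B_T2": [1.5, None], "C_Y3": [0.0, 0.3]},
        ["c1", "c2"],
    )
    d2 = make_table(
        "d2",
        {"A_S1": [-0.05, 0.1, 0.2], "B_T2": [2.0, 0.5, None]},
        ["c1", "c2", "c3"],
    )
    d3 = make_table("d3", {"A_S1": [0.2], "D_S4": [-1.0]}, ["c1"])
    return Collection(datasets=[d1, d2, d3])
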