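"""Shared fixtures: a small synthetic dataset generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from closecall import SyntheticConfig, extract_features, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_groups=2, individuals_per_group=4,
                           calls_per_context=5, seed=4)


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    """(annotations, dataset_dir) for 2 groups x 4 individuals x 3 contexts."""
    root = tmp_path_factory.mktemp("small_ds")
    annotations = generate_dataset(small_config, root)
    return annotations, root


@pytest.fixture(scope="session")
def small_features(small_dataset) -> pd.DataFrame:
    annotations, root = small_dataset
    return extract_features(annotations, root)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_feature_table(rng: np.random.Generator, n_groups: int = 2,
                       individuals_per_group: int = 4, calls_per_ind: int = 6,
                       n_predictors: int = 3, individual_sd: float = 0.0,
                       group_sd: float = 0.0,
                       predictor_names: list[str] | None = None) -> pd.DataFrame:
    """Numeric feature table with nested factors and iid N(0,1) residuals."""
    names = predictor_names or [f"x{j}" for j in range(n_predictors)]
    rows = []
    for g in range(n_groups):
        g_off = rng.normal(0, group_sd, size=len(names))
        for i in range(individuals_per_group):
            i_off = g_off + rng.normal(0, individual_sd, size=len(names))
            for c in range(calls_per_ind):
                vals = i_off + rng.normal(size=len(names))
                row = {"group_id": f"g{g}", "individual_id": f"g{g}i{i}",
                       "sex": "F" if i % 2 else "M",
                       "context": ["digging", "searching", "moving"][c % 3]}
                row.update(dict(zip(names, vals)))
                rows.append(row)
    return pd.DataFrame(rows)
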