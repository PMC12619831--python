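"""Shared fixtures: small hand-built tables and seeded synthetic datasets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metabopanel.preprocess import MetaboliteTable, PreprocessPipeline
from metabopanel.synthetic_data import (
    PlantedEffect,
    SyntheticSpec,
    generate_dataset,
)

settings.register_profile("suite", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("suite")


def make_table(values, lod=None, creatinine=None) -> MetaboliteTable:
    """Build a MetaboliteTable from a plain array/DataFrame with defaults."""
    frame = values if isinstance(values, pd.DataFrame) else pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"S{i}" for i in range(len(values))],
        columns=[f"M{j}" for j in range(np.asarray(values).shape[1])],
    )
    lod = pd.Series(0.0, index=frame.columns) if lod is None else pd.Series(lod, index=frame.columns)
    creat = (pd.Series(1.0, index=frame.index) if creatinine is None
             else pd.Series(creatinine, index=frame.index))
    return MetaboliteTable(values=frame, lod=lod, creatinine=creat)


def planted_two_group(seed: int, n_per_group: int = 20, n_metabolites: int = 100,
                      n_planted: int = 3, effect: float = 1.5,
                      alternate_sign: bool = True):
    """A DM2-vs-DN dataset with the first ``n_planted`` metabolites shifted
    in DN; censoring disabled so the planted set survives filtering."""
    planted = tuple(
        PlantedEffect(j, "DN", effect * (-1 if (alternate_sign and j % 2 == 0) else 1))
        for j in range(n_planted)
    )
    spec = SyntheticSpec(n_per_group=n_per_group, n_metabolites=n_metabolites,
                         planted=planted, censor_quantile=0.0, seed=seed)
    table, meta = generate_dataset(spec)
    ids = meta.table.index[meta.groups.isin(["DM2", "DN"])]
    sub = MetaboliteTable(table.values.loc[ids], table.lod, table.creatinine.loc[ids])
    return sub, meta.groups.loc[ids], meta.table.loc[ids]


@pytest.fixture
def toy_table() -> MetaboliteTable:
    rng = np.random.default_rng(7)
    vals = np.exp(rng.normal(1.0, 1.0, size=(12, 6)))
    return make_table(vals, creatinine=np.full(12, 2.0))


@pytest.fixture
def processed_two_group():
    table, labels, _ = planted_two_group(seed=11, n_metabolites=30)
    return PreprocessPipeline().fit_transform(table), labels
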