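import numpy as np
import pandas as pd
import pytest

from scentmark import PeakTable, SimulationConfig, simulate_dataset
from scentmark.pipeline import marks_similarity_analysis


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset (25 bees, 59 compounds)."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def marks_result(default_dataset):
    """Marks-only similarity analysis of the default dataset."""
    return marks_similarity_analysis(default_dataset.peak_table)


def make_table(areas, nests, sources, compound_names=None, kovats=None,
               classes=None):
    """Assemble a small PeakTable from plain lists (rows = samples)."""
    areas = np.asarray(areas, dtype=float)
    n, p = areas.shape
    sample_ids = [f"S{i}" for i in range(n)]
    compound_names = compound_names or [f"c{j}" for j in range(p)]
    kovats = kovats or [2000.0 + 100 * j for j in range(p)]
    classes = classes or ["alkane"] * p
    areas_df = pd.DataFrame(areas, index=pd.Index(sample_ids, name="sample_id"),
                            columns=compound_names)
    meta = pd.DataFrame({"nest_id": nests, "source": sources},
                        index=pd.Index(sample_ids, name="sample_id"))
    annot = pd.DataFrame(
        {"compound_class": classes,
         "chain_length": [20 + j for j in range(p)],
         "db_position": pd.array([None] * p, dtype="Int64"),
         "kovats": kovats},
        index=pd.Index(compound_names, name="name"))
    return PeakTable(areas_df, meta, annot)


@pytest.fixture
def toy_table():
    return make_table
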