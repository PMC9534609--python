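import numpy as np
import pytest
from hypothesis import settings

from heartsel.data import ClinicalTable
from heartsel.synthetic import SynthConfig, generate_clinical

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_table():
    """80-row, 5-feature synthetic table with 2 informative features."""
    table, informative = generate_clinical(
        SynthConfig(n=80, d=5, k_informative=2, effect_size=1.5, missing_rate=0.05, seed=11)
    )
    return table, informative


@pytest.fixture
def clean_table():
    """Preprocessed-shape table: no missing cells, values in [0, 1]."""
    table, _ = generate_clinical(
        SynthConfig(n=120, d=6, k_informative=3, effect_size=1.5, missing_rate=0.0, seed=5)
    )
    lo = table.values.min(axis=0)
    hi = table.values.max(axis=0)
    table.values = (table.values - lo) / (hi - lo)
    return table


def make_table(values, labels=None, mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    if labels is None:
        labels = np.zeros(values.shape[0], dtype=int)
    return ClinicalTable(values=values, missing_mask=mask, labels=labels)
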