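import numpy as np
import pytest

from mucodyn.model_core import GrowthParams, TemperatureProfile
from mucodyn.network_inference import AbundanceTable
from mucodyn.synthetic_data import (
    CorrelationBlock,
    SynthSpec,
    gen_abundance_table,
    gen_growth_params,
)


@pytest.fixture
def single_growth():
    return [GrowthParams("a", 1.0, 25.0, 2.0)]


@pytest.fixture
def constant_profile():
    return TemperatureProfile(mean_temp=25.0, amplitude=0.0)


@pytest.fixture
def toy_table():
    """5 samples x 3 taxa, plain percentages."""
    values = np.array(
        [
            [10.0, 20.0, 70.0],
            [20.0, 10.0, 70.0],
            [30.0, 40.0, 30.0],
            [40.0, 30.0, 30.0],
            [50.0, 45.0, 5.0],
        ]
    )
    return AbundanceTable(
        sample_ids=[f"s{i}" for i in range(5)],
        taxon_ids=["A", "B", "C"],
        values=values,
    )


@pytest.fixture
def zone_tables():
    """Two 6-sample zone tables over a shared 10-taxon namespace."""
    inner = gen_abundance_table(
        SynthSpec(n_samples=6, n_taxa=10, blocks=[CorrelationBlock((0, 1, 2), 0.95)], seed=11)
    )
    outer = gen_abundance_table(
        SynthSpec(n_samples=6, n_taxa=10, blocks=[CorrelationBlock((3, 4), 0.95)], seed=22)
    )
    return inner, outer


@pytest.fixture
def zone_growth(zone_tables):
    inner, _ = zone_tables
    return gen_growth_params(10, seed=33, taxon_ids=inner.taxon_ids)
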