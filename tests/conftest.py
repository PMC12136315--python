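import numpy as np
import pytest
from hypothesis import settings

from pumptwin import synthdata
from pumptwin.deviation import InfusionRecord

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def table2_records(set_dose: float) -> list[InfusionRecord]:
    """The printed repeated-infusion actuals of one set-dose row."""
    tab = synthdata.table_fixture("table2")
    row = tab[tab.set_dose_U == set_dose]
    return [
        InfusionRecord(index=i, commanded_dose=set_dose, delivered_dose=a)
        for i, a in enumerate(row.actual_dose_U)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def biased_series_spec():
    """Shipped 120-infusion under-delivery scenario: 2 U commands with a
    3.5% mean deficit and 0.01 U weighing noise."""
    return synthdata.GeneratorSpec(
        n_infusions=120, commanded_dose=2.0, bias_fraction=0.035, noise_sd=0.01, seed=7
    )
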