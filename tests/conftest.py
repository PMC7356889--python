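import numpy as np
import pytest

from fffmon.batch import TimeSeries
from fffmon.synthetic import CampaignSpec, default_contaminations, generate_campaign


def make_ts(values, dt=1.0, name="sig", lot=None, **kw):
    values = np.asarray(values, dtype=float)
    return TimeSeries(name, np.arange(values.size) * dt, values, lot_id=lot, **kw)


@pytest.fixture(scope="session")
def small_campaign():
    """8 clean lots; shared across read-only tests."""
    spec = CampaignSpec(n_lots=8, master_seed=42)
    return generate_campaign(spec)


@pytest.fixture(scope="session")
def contaminated_campaign():
    """12 lots with the three default planted abnormalities."""
    spec = CampaignSpec(
        n_lots=12, contaminations=default_contaminations(12), master_seed=7
    )
    return generate_campaign(spec)
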