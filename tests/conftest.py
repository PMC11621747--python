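import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cultrans import ABMParams, LongitudinalPanel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_params() -> ABMParams:
    """Very small simulator configuration for fast structural tests."""
    return ABMParams(
        n_groups=4, group_size=20, n_partners=5, burn_in_years=30, record_years=20
    )


def build_panel(rows, contacts, n_contacts=None):
    """Assemble a LongitudinalPanel from explicit row dicts and contact lists."""
    records = pd.DataFrame(
        rows,
        columns=[
            "year",
            "id",
            "age",
            "group",
            "variant",
            "prev_variant",
            "learned",
            "innovated",
            "migrated",
        ],
    )
    contacts = np.asarray(contacts, dtype=np.int64)
    return LongitudinalPanel(
        records=records,
        contacts=contacts,
        n_contacts=n_contacts if n_contacts is not None else contacts.shape[1],
    )


@pytest.fixture
def single_row_panel():
    """One non-migrating, non-innovating learner: contacts 20 x variant 0 and
    10 x variant 1, own previous variant 0, adopted variant 0."""
    return build_panel(
        [(1, 0, 5, 0, 0, 0, 1, 0, 0)],
        [[0] * 20 + [1] * 10],
    )
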