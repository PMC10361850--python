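import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import fedqi as fq

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


def toy_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a small cohort frame from sparse row dicts; unspecified fields
    get benign defaults."""
    defaults = dict(
        year="2017", age_band="50-59", histology="ductal", grade="moderate",
        pt="<2cm", pn="pN0", her2="negative", er="positive", pr="positive",
        country="NL", preop_mri=False, pst=False, mri_around_pst=False,
        mastectomy=False, immediate_reconstruction=False, bct=False,
        postop_radiotherapy=False, distant_metastasis=False, dcis_only=False,
        any_reconstruction=False, any_operation=False, n_breast_operations=0,
    )
    frame = pd.DataFrame([{**defaults, **row} for row in rows])
    return fq.schema.coerce_frame(frame)


@pytest.fixture(scope="session")
def small_scenario():
    """A default-margins two-country scenario at reduced size."""
    nl = fq.default_config("NL", n_patients=3000, seed=101)
    no = fq.default_config("NO", n_patients=1500, seed=102)
    return fq.make_two_country_scenario(nl, no)


@pytest.fixture(scope="session")
def small_nodes(small_scenario):
    a, b = small_scenario
    return [fq.RegistryNode("NL", a.frame), fq.RegistryNode("NO", b.frame)]


@pytest.fixture(scope="session")
def small_model(small_nodes):
    return fq.federated_fit(small_nodes, "NL")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
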