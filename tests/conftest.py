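import numpy as np
import pandas as pd
import pytest

from epilocus import classify_contexts, make_reference
from epilocus.nome import CloneCallMatrix


@pytest.fixture(scope="session")
def region_i():
    return make_reference("region_I", 7)


@pytest.fixture(scope="session")
def region_ii():
    return make_reference("region_II", 7)


@pytest.fixture(scope="session")
def site_map_i(region_i):
    return classify_contexts(region_i)


def matrix_from_calls(site_map, endog, treated=True, access=None):
    """Build a CloneCallMatrix directly from 0/1/NaN arrays (test helper)."""
    endog = np.atleast_2d(np.asarray(endog, dtype=float))
    n = len(endog)
    ids = pd.Index([f"c{i}" for i in range(n)], name="clone")
    endo_cols = list(site_map.offsets(site_map.hcg))[: endog.shape[1]]
    if access is None:
        access_df = pd.DataFrame(index=ids, columns=list(site_map.offsets(site_map.gch)), dtype=float)
    else:
        access = np.atleast_2d(np.asarray(access, dtype=float))
        access_df = pd.DataFrame(access, index=ids,
                                 columns=list(site_map.offsets(site_map.gch))[: access.shape[1]])
    qc = pd.DataFrame({"conversion_rate": 0.99, "qc_pass": True,
                       "aligned": True, "n_mismatches": 0}, index=ids)
    return CloneCallMatrix(
        site_map=site_map,
        treated=treated,
        endogenous=pd.DataFrame(endog, index=ids, columns=endo_cols),
        accessibility=access_df,
        qc=qc,
    )
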