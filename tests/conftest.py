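import numpy as np
import pandas as pd
import pytest

import matnet as mn


@pytest.fixture(scope="session")
def default_community():
    """One default synthetic community (table, taxonomy, ground truth)."""
    spec = mn.CommunitySpec()
    table, tax, planted = mn.generate_community(spec, 7)
    return spec, table, tax, planted


@pytest.fixture(scope="session")
def fitted_default(default_community):
    """Full pipeline fit of the default community."""
    spec, table, tax, planted = default_community
    res = mn.CooccurrenceNetworkModel(table, tax).fit()
    return spec, table, tax, planted, res


@pytest.fixture()
def counts_table():
    data = pd.DataFrame(
        [[2, 2, 0], [1, 0, 3], [5, 5, 10]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3"],
    )
    return mn.AbundanceTable(data, mode="counts")


@pytest.fixture()
def simple_taxonomy():
    return mn.TaxonomyMap.from_lineages({
        "t1": "d__Bacteria;p__P;c__C;o__O;f__F;g__GenusA;s__",
        "t2": "d__Bacteria;p__P;c__C;o__O;f__F;g__;s__",
        "t3": "d__Bacteria;p__P;c__C;o__O;f__F;g__GenusB;s__",
    })
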