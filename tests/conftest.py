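import dendropy
import numpy as np
import pandas as pd
import pytest

from nichetraits.io_formats import EnvironmentTable, parse_module_definition


@pytest.fixture
def small_env() -> EnvironmentTable:
    """Nine samples across three ecosystems, two variables, one missing cell."""
    rng = np.random.default_rng(7)
    samples = [f"s{i}" for i in range(9)]
    values = pd.DataFrame(
        rng.uniform(size=(9, 2)),
        index=pd.Index(samples, name="sample_id"),
        columns=["pH", "MAT"],
    )
    values.iloc[4, 0] = np.nan
    ecosystem = pd.Series(
        ["forest"] * 3 + ["grassland"] * 3 + ["wetland"] * 3,
        index=values.index,
        name="ecosystem",
    )
    return EnvironmentTable(values, ecosystem)


@pytest.fixture
def three_step_module():
    """K1 ; K2|K3 ; K4+K5 — exercises alternatives and an AND-complex."""
    return parse_module_definition("Mtoy", "K1;K2|K3;K4+K5")


@pytest.fixture
def balanced_four_tip_tree() -> dendropy.Tree:
    return dendropy.Tree.get(
        data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick", preserve_underscores=True
    )
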