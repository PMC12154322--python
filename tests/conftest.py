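import pandas as pd
import pytest

import adrisk


@pytest.fixture
def worked_df() -> pd.DataFrame:
    """Eight-instance worked-example panel with CI scores and labels."""
    return adrisk.worked_example()


@pytest.fixture
def default_cfg() -> adrisk.RunConfig:
    return adrisk.default_config()


@pytest.fixture
def worked_csv(tmp_path, worked_df):
    """The worked example written to disk as a cohort CSV."""
    path = tmp_path / "worked.csv"
    worked_df.to_csv(path, index=False)
    return path
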