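import pandas as pd
import pytest

from ecotox.data_model import (
    load_reference_tables,
    load_survey_bcf,
    load_survey_biometrics,
    load_survey_enzymes,
    load_survey_tissue_summary,
)
from ecotox.io_cli import tissue_records_from_frame


@pytest.fixture(scope="session")
def tables():
    return load_reference_tables()


@pytest.fixture(scope="session")
def survey_frame() -> pd.DataFrame:
    return load_survey_tissue_summary()


@pytest.fixture(scope="session")
def survey_records(survey_frame):
    return tissue_records_from_frame(survey_frame)


@pytest.fixture(scope="session")
def survey_bcf() -> pd.DataFrame:
    return load_survey_bcf()


@pytest.fixture(scope="session")
def survey_biometrics() -> pd.DataFrame:
    return load_survey_biometrics()


@pytest.fixture(scope="session")
def survey_enzymes() -> pd.DataFrame:
    return load_survey_enzymes()


@pytest.fixture
def survey_csv(tmp_path, survey_frame):
    path = tmp_path / "tissue.csv"
    survey_frame.to_csv(path, index=False)
    return path


def cell(frame: pd.DataFrame, element: str, site: str, tissue: str) -> pd.Series:
    sub = frame[
        (frame.element == element) & (frame.site == site) & (frame.tissue == tissue)
    ]
    assert len(sub) == 1
    return sub.iloc[0]
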