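import json
from importlib import resources

import pytest

from lifescreen import load_schema


@pytest.fixture(scope="session")
def schema():
    return load_schema()


@pytest.fixture()
def low_risk_record():
    """A textbook all-green respondent (bundled example record)."""
    text = (resources.files("lifescreen") / "data" / "example_response.json"
            ).read_text("utf-8")
    return json.loads(text)
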