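import pytest
from hypothesis import settings

from oncoharmonizer import load_demo_schema

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def demo_schema():
    return load_demo_schema()
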