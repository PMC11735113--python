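import pytest

from appcap import default_scenario
from appcap.synth import SynthSpec, synth_bundle


@pytest.fixture
def config():
    return default_scenario()


@pytest.fixture(scope="session")
def synth_files(tmp_path_factory):
    """A full synthetic area (41 PCNs) written to disk once per session."""
    out = tmp_path_factory.mktemp("synth")
    bundle = synth_bundle(SynthSpec(), n_pcns=41, seed=123, out_dir=out)
    return bundle
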