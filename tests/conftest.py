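import pytest

from genx.extraction import default_rules
from genx.preprocessing import Section, sentences_from_section


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture
def make_sentence():
    def _make(text, section=Section.INCLUSION, trial_id="NCT00000001"):
        sents = sentences_from_section(trial_id, section, text)
        assert len(sents) == 1, f"expected one sentence, got {len(sents)}"
        return sents[0]

    return _make
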