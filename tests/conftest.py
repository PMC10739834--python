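import pytest

from veristyle.corpus import Corpus, Statement
from veristyle.resources import fixture_resources


@pytest.fixture(scope="session")
def resources():
    return fixture_resources()


@pytest.fixture()
def tiny_corpus():
    """Four hand-written statements, two per veracity label."""
    return Corpus(name="tiny", statements=[
        Statement(id="t1", subject_id="s1", domain="memory",
                  veracity="truthful", text="I went to the market. It was busy."),
        Statement(id="t2", subject_id="s2", domain="memory",
                  veracity="truthful", text="We saw Mary at the harbor on Monday."),
        Statement(id="d1", subject_id="s3", domain="memory",
                  veracity="deceptive", text="They never visited the old garden."),
        Statement(id="d2", subject_id="s4", domain="memory",
                  veracity="deceptive", text="He thought the letter was lost."),
    ])
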