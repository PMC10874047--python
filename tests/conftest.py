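import pytest

from screensieve import Corpus, Label, Record, SynthConfig, generate


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Three records, one per label state."""
    return Corpus(
        [
            Record("a", title="Dialectical behaviour therapy trial",
                   abstract="A randomized trial.", doi="10.1000/a",
                   label=Label.RELEVANT),
            Record("b", title="Cognitive therapy outcomes",
                   abstract="An observational study.", doi="10.1000/b",
                   label=Label.IRRELEVANT),
            Record("c", title="Unrelated engineering paper",
                   abstract="Bridges and trusses.", doi="10.1000/c",
                   label=Label.NOISY),
        ]
    )


@pytest.fixture
def labeled_synth():
    """Small fully labeled synthetic corpus with clear topical signal."""
    config = SynthConfig(
        n_records=200, n_relevant=8, signal_strength=0.8,
        fully_labeled=True, seed=7,
    )
    return generate(config)
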