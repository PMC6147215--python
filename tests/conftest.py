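import pytest

import doctriage as dt


@pytest.fixture
def tiny_corpus() -> dt.LabeledCorpus:
    docs = [
        dt.Document("d1", "CHD7 binds CHD8.", "The CHD7–CHD8 complex is stable. It binds DNA.", dt.Label.POSITIVE),
        dt.Document("d2", "A study of yeast.", "Nothing interacts here. Plain biology text.", dt.Label.NEGATIVE),
        dt.Document("d3", "Utp6–Utp21 interaction", "The Utp6–Utp21 interaction is affected by mutation.", dt.Label.POSITIVE),
        dt.Document("d4", "Control article", "E. coli protein X interacts with Y.", dt.Label.NEGATIVE),
        dt.Document("d5", "CheA–CheY binding interactions", "CheA–CheY binding interactions are described.", dt.Label.POSITIVE),
        dt.Document("d6", "Unlabeled article", "No label was assigned to this abstract."),
    ]
    return dt.LabeledCorpus("tiny", docs)


@pytest.fixture
def preprocessed_tiny(tiny_corpus) -> dt.LabeledCorpus:
    return dt.LabeledCorpus(
        tiny_corpus.name, [dt.preprocess_document(d) for d in tiny_corpus]
    )


@pytest.fixture
def separable_corpus() -> dt.LabeledCorpus:
    """Small fully separable synthetic corpus, preprocessed."""
    spec = dt.SyntheticSpec(n_docs=80, signal_rate=1.0, noise_rate=0.0, seed=11)
    corpus = dt.generate_corpus(spec)
    corpus.documents = [dt.preprocess_document(d) for d in corpus]
    return corpus


@pytest.fixture
def separable_vocab(separable_corpus) -> dt.Vocabulary:
    return dt.build_vocab(separable_corpus)
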