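from datetime import date

import numpy as np
import pytest

from litpriority import preprocess, synth
from litpriority.corpus_io import DocumentRecord, StudyPeriod


@pytest.fixture
def worked_example():
    return synth.worked_example_fixture()


@pytest.fixture(scope="session")
def planted_corpus():
    """Six planted topics, uniform volume (10 docs per topic per window)."""
    spec = synth.SyntheticSpec(
        k_true=6, seed=11, docs_per_window=np.full((6, 10), 10.0)
    )
    return synth.generate_corpus(spec)


@pytest.fixture(scope="session")
def planted_term_matrix(planted_corpus):
    records, _ = planted_corpus
    stops = preprocess.default_stop_list()
    docs = [preprocess.tokenize_and_lemmatize(r.abstract, stops) for r in records]
    vocab = preprocess.build_vocabulary(docs)
    return preprocess.build_tfidf(docs, vocab, doc_ids=[r.doc_id for r in records])


@pytest.fixture
def small_period():
    return StudyPeriod(date(2020, 1, 24), date(2020, 4, 2), date(2019, 12, 12))


def make_record(doc_id="d0", abstract="some viral abstract text", day=date(2020, 2, 1),
                language_tag="en"):
    return DocumentRecord(doc_id=doc_id, abstract=abstract, pub_date=day,
                          language_tag=language_tag)
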