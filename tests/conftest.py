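import numpy as np
import pytest

from voices import corpus, synthetic


def make_doc(tokens, respondent="r0", question="q", mtg="Adrenal", mask=None):
    """Build a prepared Document from explicit tokens (default: no stop words)."""
    return corpus.Document(
        respondent_id=respondent, question_id=question, mtg=mtg,
        raw_text=" ".join(tokens), tokens=list(tokens),
        stopword_mask=list(mask) if mask is not None else [False] * len(tokens),
    )


@pytest.fixture
def doc_factory():
    return make_doc


@pytest.fixture(scope="session")
def small_cohort():
    spec = synthetic.CohortSpec(n_respondents=120, seed=3)
    return synthetic.generate_cohort(spec)


@pytest.fixture(scope="session")
def text_spec():
    return synthetic.default_text_spec(k_true=3, seed=3)


@pytest.fixture(scope="session")
def prepared_corpus(small_cohort, text_spec):
    docs = synthetic.generate_open_text(text_spec, small_cohort)
    return corpus.prepare(docs)


@pytest.fixture(scope="session")
def background(text_spec):
    return synthetic.generate_background_corpus(text_spec, 20_000)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
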