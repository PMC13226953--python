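import numpy as np
import pytest

import speechmark as sm


@pytest.fixture(scope="session")
def toy_source():
    """Tiny hand-built embedding table used by the semantic-feature tests."""
    return sm.TableEmbeddingSource(
        {
            "a": np.array([1.0, 0.0]),
            "b": np.array([0.0, 1.0]),
            "c": np.array([1.0, 1.0]),
            "d": np.array([1.0, 0.0]),
        }
    )


@pytest.fixture(scope="session")
def small_corpus():
    """Four-group corpus small enough for fast end-to-end tests."""
    cfg = sm.SyntheticCorpusConfig(
        profiles=(
            sm.wa_like_profile(),
            sm.control_profile("HCA", "aphasia"),
            sm.ssd_like_profile(),
            sm.control_profile("HCS", "psychiatric"),
        ),
        n_participants_per_group=4,
        words_per_task=60,
        vocab_size=200,
        n_topics=6,
        embed_dim=32,
        seed=11,
    )
    return sm.generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_task_table(small_corpus):
    return sm.task_feature_table(
        small_corpus.transcripts, small_corpus.parses, small_corpus.embedding_source
    )


def make_parsed(rows):
    """Build a ParsedSentence from (form, upos, head, deprel) tuples."""
    return sm.ParsedSentence(
        [
            sm.ParseToken(index=i + 1, form=f, upos=u, head=h, deprel=d)
            for i, (f, u, h, d) in enumerate(rows)
        ]
    )
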