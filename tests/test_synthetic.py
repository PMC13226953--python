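"""Synthetic corpus generator: determinism, tree validity, realized contrasts."""

import numpy as np
import pytest
from scipy import stats as sps

import speechmark as sm
from speechmark.synthetic import ConfigError, Vocabulary, make_vocabulary


def two_group_config(**kw):
    defaults = dict(
        profiles=(sm.wa_like_profile(), sm.ssd_like_profile()),
        n_participants_per_group=5,
        words_per_task=50,
        vocab_size=200,
        n_topics=6,
        embed_dim=32,
        seed=3,
    )
    defaults.update(kw)
    return sm.SyntheticCorpusConfig(**defaults)


class TestConfigValidation:
    def test_bad_probability_names_field(self):
        with pytest.raises(ConfigError, match="topic_jump_prob"):
            sm.GroupProfile(name="X", topic_jump_prob=1.5)

    def test_short_sentences_rejected(self):
        with pytest.raises(ConfigError, match="sentence_len_mean"):
            sm.GroupProfile(name="X", sentence_len_mean=1.0)

    def test_single_profile_rejected(self):
        with pytest.raises(ConfigError, match="profiles"):
            sm.SyntheticCorpusConfig(profiles=(sm.wa_like_profile(),))

    def test_embed_dim_below_topics_rejected(self):
        with pytest.raises(ConfigError, match="embed_dim"):
            two_group_config(embed_dim=4, n_topics=6)


class TestDeterminismAndCounts:
    def test_same_seed_byte_identical(self, tmp_path):
        c1 = sm.generate_corpus(two_group_config())
        c2 = sm.generate_corpus(two_group_config())
        assert c1.chat_texts == c2.chat_texts
        assert c1.metadata.equals(c2.metadata)
        for iid in c1.parses:
            assert c1.parses[iid] == c2.parses[iid]
        for w in c1.embedding_table:
            assert np.array_equal(c1.embedding_table[w], c2.embedding_table[w])
        sm.write_corpus(c1, tmp_path / "a")
        sm.write_corpus(c2, tmp_path / "b")
        for f1 in sorted((tmp_path / "a").rglob("*")):
            if f1.is_file():
                f2 = tmp_path / "b" / f1.relative_to(tmp_path / "a")
                assert f1.read_bytes() == f2.read_bytes()

    def test_different_seed_differs(self):
        c1 = sm.generate_corpus(two_group_config(seed=3))
        c2 = sm.generate_corpus(two_group_config(seed=4))
        assert c1.chat_texts != c2.chat_texts

    def test_counts_forced_by_config(self):
        corpus = sm.generate_corpus(two_group_config())
        assert len(corpus.transcripts) == 10
        assert len(corpus.instances()) == 20
        assert len(corpus.parses) == 20
        assert len(corpus.metadata) == 10

    def test_every_instance_has_parse_and_embeddings(self):
        corpus = sm.generate_corpus(two_group_config())
        for inst in corpus.instances():
            assert inst.instance_id in corpus.parses
            parse_forms = [f for s in corpus.parses[inst.instance_id] for f in s.forms()]
            assert parse_forms == inst.all_tokens()
            for w in inst.all_tokens():
                assert w.lower() in corpus.embedding_table


class TestSentenceGeneration:
    def _vocab(self, n_topics=4):
        rng = np.random.default_rng(0)
        return make_vocabulary(200, n_topics, rng)

    def test_tree_is_single_rooted_and_valid(self):
        vocab = self._vocab()
        rng = np.random.default_rng(1)
        profile = sm.ssd_like_profile()
        for _ in range(200):
            _, parsed, _ = sm.generate_sentence(profile, 0, rng, vocab, 4)
            roots = [t for t in parsed.tokens if t.head == 0]
            assert len(roots) == 1  # validation also ran in the constructor

    def test_zero_clause_prob_means_no_clausal_arcs(self):
        vocab = self._vocab()
        rng = np.random.default_rng(2)
        profile = sm.GroupProfile(name="X", clause_embed_prob=0.0)
        clausal = {"csubj", "ccomp", "xcomp", "advcl", "acl"}
        for _ in range(100):
            _, parsed, _ = sm.generate_sentence(profile, 0, rng, vocab, 4)
            assert not any(t.deprel.split(":")[0] in clausal for t in parsed.tokens)

    def test_certain_clause_prob_means_clausal_arc(self):
        vocab = self._vocab()
        rng = np.random.default_rng(3)
        profile = sm.GroupProfile(name="X", clause_embed_prob=1.0, sentence_len_mean=8)
        clausal = {"csubj", "ccomp", "xcomp", "advcl", "acl"}
        for _ in range(100):
            _, parsed, _ = sm.generate_sentence(profile, 0, rng, vocab, 4)
            assert any(t.deprel.split(":")[0] in clausal for t in parsed.tokens)

    def test_length_distribution_mean(self):
        vocab = self._vocab()
        rng = np.random.default_rng(4)
        profile = sm.GroupProfile(name="X", sentence_len_mean=8, sentence_len_sd=2)
        lengths = [
            len(sm.generate_sentence(profile, 0, rng, vocab, 4)[0]) for _ in range(1000)
        ]
        assert 7.5 <= np.mean(lengths) <= 8.5
        assert min(lengths) >= 2

    def test_no_adjacent_duplicates_in_clean_stream(self):
        vocab = self._vocab()
        rng = np.random.default_rng(5)
        profile = sm.wa_like_profile()
        for _ in range(200):
            tokens, _, _ = sm.generate_sentence(profile, 0, rng, vocab, 4)
            for a, b in zip(tokens, tokens[1:]):
                assert a.lower() != b.lower()

    def test_bad_topic_state_rejected(self):
        vocab = self._vocab()
        with pytest.raises(ConfigError):
            sm.generate_sentence(sm.wa_like_profile(), 9, np.random.default_rng(0), vocab, 4)


class TestEmbeddingTableOp:
    def test_zero_noise_same_topic_identical(self):
        table = sm.generate_embedding_table(40, 4, 16, 0.0, seed=0)
        words = sorted(table)
        same_topic = [w for i, w in enumerate(words) if i % 4 == 0]
        v0 = table[same_topic[0]]
        for w in same_topic[1:]:
            assert sm.cosine_similarity(v0, table[w]) == pytest.approx(1.0)

    def test_unit_norms(self):
        table = sm.generate_embedding_table(50, 5, 32, 0.4, seed=1)
        for v in table.values():
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)

    def test_cross_topic_near_orthogonal(self):
        table = sm.generate_embedding_table(8, 4, 256, 0.0, seed=2)
        words = sorted(table)
        centroids = [table[words[i]] for i in range(4)]
        for i in range(4):
            for j in range(i + 1, 4):
                assert abs(sm.cosine_similarity(centroids[i], centroids[j])) < 0.3

    def test_dim_below_topics_rejected(self):
        with pytest.raises(ConfigError):
            sm.generate_embedding_table(10, 8, 4, 0.1, seed=0)


class TestRealizedContrasts:
    def test_repetition_rate_contrast(self):
        """Realized immediate-duplicate counts track the configured rates."""
        profiles = (
            sm.GroupProfile(name="A", repetition_rate=100.0),
            sm.GroupProfile(name="B", repetition_rate=0.0),
        )
        cfg = sm.SyntheticCorpusConfig(
            profiles=profiles, n_participants_per_group=2, words_per_task=2500,
            tasks_per_participant=(("T", "open_ended"),),
            vocab_size=200, n_topics=4, embed_dim=16, seed=7,
        )
        corpus = sm.generate_corpus(cfg)
        rates = {}
        for t in corpus.transcripts:
            inst = t.task_instances[0]
            rates.setdefault(t.group, []).append(sm.repetition_frequency(inst))
        assert min(rates["A"]) > max(rates["B"])
        assert np.mean(rates["A"]) == pytest.approx(100.0 / 1.1, rel=0.35)
        assert np.mean(rates["B"]) == 0.0

    def test_severity_couples_to_disturbance(self):
        """Severity correlates with realized repetition + drift burden when
        severity_loc increases with disturbance strength."""
        low = sm.control_profile("LOW")
        high = sm.wa_like_profile("HIGH")
        cfg = sm.SyntheticCorpusConfig(
            profiles=(low, high), n_participants_per_group=30,
            tasks_per_participant=(("T", "open_ended"),), words_per_task=120,
            vocab_size=200, n_topics=6, embed_dim=32, seed=13,
        )
        corpus = sm.generate_corpus(cfg)
        src = corpus.embedding_source
        sev, burden = [], []
        for t in corpus.transcripts:
            inst = t.task_instances[0]
            wavg, _, _, _ = sm.word_similarity_stats(inst.tokens_per_utterance(), src)
            sev.append(t.severity)
            burden.append(sm.repetition_frequency(inst) + 100 * (1 - wavg))
        r, p = sps.pearsonr(sev, burden)
        assert r > 0
        assert p < 0.01


class TestMonotonicity:
    def test_word_similarity_decreases_with_topic_jump(self):
        """Mean adjacent-word similarity is rank-decreasing in topic_jump_prob."""
        levels = [0.0, 0.1, 0.3, 0.6, 0.9]
        level_means = []
        for level in levels:
            vals = []
            for rep in range(20):
                profiles = (
                    sm.GroupProfile(name="G", topic_jump_prob=level, within_topic_noise=0.2),
                    sm.GroupProfile(name="H", topic_jump_prob=level, within_topic_noise=0.2),
                )
                cfg = sm.SyntheticCorpusConfig(
                    profiles=profiles, n_participants_per_group=1,
                    tasks_per_participant=(("T", "open_ended"),), words_per_task=150,
                    vocab_size=150, n_topics=6, embed_dim=24,
                    seed=1000 + 37 * rep + int(level * 100),
                )
                corpus = sm.generate_corpus(cfg)
                src = corpus.embedding_source
                for t in corpus.transcripts:
                    wavg, _, _, _ = sm.word_similarity_stats(
                        t.task_instances[0].tokens_per_utterance(), src
                    )
                    vals.append(wavg)
            level_means.append(np.mean(vals))
        rho, p = sps.spearmanr(levels, level_means)
        assert rho < 0
        assert p < 0.01
        # strict decrease across the level means
        assert all(a > b for a, b in zip(level_means, level_means[1:]))
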