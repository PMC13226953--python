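"""Complexity metrics against hand computations and a brute-force oracle."""

import itertools
import math

import numpy as np
import pytest

import speechmark as sm
from speechmark.syntactic import (
    CLAUSAL_RELATIONS,
    DEPREL_REGISTRY,
    UPOS_TAGS,
    canonical_deprel,
)

from conftest import make_parsed


def brute_force_metrics(sentences):
    """Independent arc-enumeration oracle for MDD/ADJD/LEFT/CLS/NDD.

    Works directly on (index, head) pairs with explicit loops; shares no
    code with the implementation.
    """
    distances, lefts, adjacents = [], 0, 0
    clauses_per_sentence = []
    ndd_terms = []
    for sent in sentences:
        sent_d = []
        n_clausal = 0
        root_pos = None
        for tok in sent.tokens:
            if tok.head == 0:
                root_pos = tok.index
                continue
            d = tok.index - tok.head
            sent_d.append(abs(d))
            if d < 0:
                lefts += 1
            if abs(d) == 1:
                adjacents += 1
            if tok.deprel.split(":")[0] in ("csubj", "ccomp", "xcomp", "advcl", "acl"):
                n_clausal += 1
        distances.extend(sent_d)
        clauses_per_sentence.append(1 + n_clausal)
        if sent_d:
            mdd_s = sum(sent_d) / len(sent_d)
            ndd_terms.append(abs(math.log(mdd_s / math.sqrt(root_pos * len(sent.tokens)))))
    mdd = sum(distances) / len(distances) if distances else 0.0
    return {
        "MDD": mdd,
        "ADJD": adjacents / len(distances) if distances else 0.0,
        "LEFT": lefts / len(distances) if distances else 0.0,
        "CLS": sum(clauses_per_sentence) / len(clauses_per_sentence),
        "NDD": sum(ndd_terms) / len(ndd_terms) if ndd_terms else 0.0,
    }


def all_rooted_trees(n):
    """Every head vector over n tokens that forms a single rooted tree."""
    for heads in itertools.product(range(n + 1), repeat=n):
        if sum(1 for h in heads if h == 0) != 1:
            continue
        if any(h == i + 1 for i, h in enumerate(heads)):
            continue
        ok = True
        for i in range(n):
            seen = set()
            cur = heads[i]
            while cur != 0:
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
                cur = heads[cur - 1]
            if not ok:
                break
        if ok:
            yield heads


DEPRELS_CYCLE = ["nsubj", "obj", "advcl", "amod", "ccomp", "det"]


def tree_from_heads(heads):
    rows = []
    for i, h in enumerate(heads):
        rel = "root" if h == 0 else DEPRELS_CYCLE[i % len(DEPRELS_CYCLE)]
        rows.append((f"w{i}", "NOUN", h, rel))
    return make_parsed(rows)


class TestOracleEquivalence:
    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_exhaustive_trees_match_oracle(self, n):
        """MDD/ADJD/LEFT/CLS/NDD agree with brute force on all rooted trees."""
        for heads in all_rooted_trees(n):
            sent = tree_from_heads(heads)
            prof = sm.complexity_metrics([sent])
            oracle = brute_force_metrics([sent])
            for key, expected in oracle.items():
                assert getattr(prof, key) == pytest.approx(expected, abs=1e-12), (
                    f"{key} mismatch on heads={heads}"
                )

    def test_six_token_sample_matches_oracle(self):
        trees = [tree_from_heads(h) for h in itertools.islice(all_rooted_trees(6), 0, 3000, 7)]
        prof = sm.complexity_metrics(trees)
        oracle = brute_force_metrics(trees)
        for key, expected in oracle.items():
            assert getattr(prof, key) == pytest.approx(expected, abs=1e-12)


class TestDependencyDistances:
    def test_adjacent_pair(self):
        sent = make_parsed([("a", "NOUN", 2, "nsubj"), ("b", "VERB", 0, "root")])
        assert sm.dependency_distances(sent) == [(1, "left", "nsubj")]

    def test_hand_enumerated_arcs(self):
        sent = make_parsed(
            [("a", "NOUN", 3, "nsubj"), ("b", "NOUN", 3, "obj"),
             ("c", "VERB", 0, "root"), ("d", "ADV", 3, "advmod")]
        )
        arcs = sm.dependency_distances(sent)
        assert [a[0] for a in arcs] == [2, 1, 1]
        assert [a[1] for a in arcs] == ["left", "left", "right"]

    def test_single_token_has_no_arc(self):
        sent = make_parsed([("ok", "INTJ", 0, "root")])
        assert sm.dependency_distances(sent) == []

    def test_punct_arcs_excluded(self):
        sent = make_parsed(
            [("go", "VERB", 0, "root"), (".", "PUNCT", 1, "punct")]
        )
        assert sm.dependency_distances(sent) == []


class TestComplexityMetrics:
    def test_all_adjacent_pairs_give_unit_mdd(self):
        sents = [
            make_parsed([("a", "NOUN", 2, "nsubj"), ("b", "VERB", 0, "root")])
            for _ in range(3)
        ]
        prof = sm.complexity_metrics(sents)
        assert prof.MDD == 1.0
        assert prof.ADJD == 1.0

    def test_len_is_mean_words(self):
        s4 = make_parsed([("w", "NOUN", 2, "nsubj"), ("v", "VERB", 0, "root"),
                          ("x", "NOUN", 2, "obj"), ("y", "ADV", 2, "advmod")])
        s6 = make_parsed([("a", "NOUN", 2, "nsubj"), ("b", "VERB", 0, "root"),
                          ("c", "DET", 4, "det"), ("d", "NOUN", 2, "obj"),
                          ("e", "ADJ", 4, "amod"), ("f", "ADV", 2, "advmod")])
        assert sm.complexity_metrics([s4, s6]).LEN == 5.0

    def test_clause_count_from_clausal_arcs(self):
        sent = make_parsed(
            [("a", "NOUN", 2, "nsubj"), ("b", "VERB", 0, "root"),
             ("c", "VERB", 2, "advcl"), ("d", "NOUN", 5, "nsubj"),
             ("e", "VERB", 2, "ccomp"), ("f", "ADV", 5, "advmod")]
        )
        assert sm.complexity_metrics([sent]).CLS == 3.0

    def test_lxd_counts_content_words(self):
        sent = make_parsed(
            [("the", "DET", 2, "det"), ("cat", "NOUN", 3, "nsubj"),
             ("sat", "VERB", 0, "root"), ("it", "PRON", 3, "obj")]
        )
        assert sm.complexity_metrics([sent]).LXD == pytest.approx(0.5)

    def test_permutation_invariance(self, small_corpus):
        parses = next(iter(small_corpus.parses.values()))
        a = sm.complexity_metrics(parses).to_dict()
        b = sm.complexity_metrics(list(reversed(parses))).to_dict()
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12)

    def test_invariant_relations(self, small_corpus):
        for parses in list(small_corpus.parses.values())[:8]:
            p = sm.complexity_metrics(parses)
            assert 0 <= p.LEFT <= 1 and 0 <= p.ADJD <= 1
            assert p.CLS >= 1
            assert p.CLL <= p.LEN + 1e-12
            if p.ADJD == 1:
                assert p.MDD == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sm.complexity_metrics([])


class TestRelationFrequencies:
    def test_pos_scaled_per_1000(self):
        rows = [("w%d" % i, "NOUN" if i < 4 else "VERB", 0 if i == 0 else 1,
                 "root" if i == 0 else "dep") for i in range(10)]
        _, pos = sm.relation_frequencies([make_parsed(rows)])
        assert pos["NOUN"] == pytest.approx(400.0)

    def test_absent_label_is_zero_and_registry_complete(self, small_corpus):
        parses = next(iter(small_corpus.parses.values()))
        dep, pos = sm.relation_frequencies(parses)
        assert set(dep) == set(DEPREL_REGISTRY)
        assert len(dep) == 63
        assert set(pos) == set(UPOS_TAGS)
        assert dep["flat:foreign"] == 0.0

    def test_frequencies_sum_to_1000(self, small_corpus):
        parses = next(iter(small_corpus.parses.values()))
        dep, pos = sm.relation_frequencies(parses)
        assert sum(pos.values()) == pytest.approx(1000.0, abs=1e-6)
        assert sum(dep.values()) == pytest.approx(1000.0, abs=1e-6)

    def test_unknown_subtype_maps_to_base(self):
        assert canonical_deprel("obl:npmod") == "obl"
        assert canonical_deprel("nmod:poss") == "nmod:poss"
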