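"""Syntactic complexity metrics and relation/POS frequency profiles.

From Universal-Dependencies parses this module computes nine
(morpho-)syntactic complexity metrics —

LEN   mean words per sentence
LXD   lexical density: content words / words
MDD   mean dependency distance, pooled over all non-punctuation arcs
NDD   normalised dependency distance: |ln(MDD_s / sqrt(root_pos * len_s))|
      per sentence (Lei & Jockers normalisation), averaged over sentences
ADJD  proportion of arcs with distance exactly 1
LEFT  proportion of arcs whose dependent precedes its head
MOD   nominal-modifier arcs (nmod/amod bases) per 1000 words
CLS   mean clauses per sentence: 1 + clausal-dependent arcs
CLL   mean clause length: words / clauses

— plus per-1000-word frequencies of the 63 UD dependency relations
(subtypes included) and of the 17 universal POS tags.  Dependency distance
is the absolute difference between the linear positions of a dependent and
its head; long distances load working memory, so these metrics index the
structural complexity of spontaneous speech.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

from .corpus_io import ParsedSentence

logger = logging.getLogger(__name__)

#: The 17 universal POS tags.
UPOS_TAGS = (
    "ADJ", "ADP", "ADV", "AUX", "CCONJ", "DET", "INTJ", "NOUN", "NUM",
    "PART", "PRON", "PROPN", "PUNCT", "SCONJ", "SYM", "VERB", "X",
)

#: The 37 universal dependency relations.
_UD_BASE = (
    "acl", "advcl", "advmod", "amod", "appos", "aux", "case", "cc", "ccomp",
    "clf", "compound", "conj", "cop", "csubj", "dep", "det", "discourse",
    "dislocated", "expl", "fixed", "flat", "goeswith", "iobj", "list",
    "mark", "nmod", "nsubj", "nummod", "obj", "obl", "orphan", "parataxis",
    "punct", "reparandum", "root", "vocative", "xcomp",
)

#: Documented UD subtypes carried in the fixed registry (26), bringing the
#: registry to 63 labels.  Unknown subtypes are mapped to their base.
_UD_SUBTYPES = (
    "acl:relcl", "advcl:relcl", "advmod:emph", "advmod:lmod", "aux:pass",
    "cc:preconj", "compound:lvc", "compound:prt", "compound:redup",
    "csubj:outer", "csubj:pass", "det:numgov", "det:nummod", "det:poss",
    "expl:impers", "expl:pass", "expl:pv", "flat:foreign", "flat:name",
    "nmod:poss", "nmod:tmod", "nsubj:outer", "nsubj:pass", "obl:agent",
    "obl:arg", "obl:lmod",
)

DEPREL_REGISTRY: tuple[str, ...] = _UD_BASE + _UD_SUBTYPES
assert len(DEPREL_REGISTRY) == 63

#: Content-word tags for lexical density.
CONTENT_TAGS = frozenset({"NOUN", "PROPN", "VERB", "ADJ", "ADV"})

#: Clausal-dependent relations: each such arc introduces one clause beyond
#: the main clause.
CLAUSAL_RELATIONS = frozenset({"csubj", "ccomp", "xcomp", "advcl", "acl"})


def deprel_base(label: str) -> str:
    return label.split(":", 1)[0]


def canonical_deprel(label: str) -> str:
    """Map a deprel label into the fixed registry (subtype kept if known)."""
    if label in DEPREL_REGISTRY:
        return label
    base = deprel_base(label)
    if base in DEPREL_REGISTRY:
        logger.debug("unknown deprel subtype %r mapped to %r", label, base)
        return base
    logger.debug("unknown deprel %r mapped to 'dep'", label)
    return "dep"


@dataclass
class SyntacticProfile:
    LEN: float
    LXD: float
    MDD: float
    NDD: float
    ADJD: float
    LEFT: float
    MOD: float
    CLS: float
    CLL: float
    deprel_freq: dict[str, float] = field(default_factory=dict)
    pos_freq: dict[str, float] = field(default_factory=dict)

    def to_dict(self, include_frequencies: bool = True) -> dict[str, float]:
        out = {
            "LEN": self.LEN, "LXD": self.LXD, "MDD": self.MDD,
            "NDD": self.NDD, "ADJD": self.ADJD, "LEFT": self.LEFT,
            "MOD": self.MOD, "CLS": self.CLS, "CLL": self.CLL,
        }
        if include_frequencies:
            out.update({f"dep_{k}": v for k, v in self.deprel_freq.items()})
            out.update({f"pos_{k}": v for k, v in self.pos_freq.items()})
        return out


def dependency_distances(
    sentence: ParsedSentence, exclude_punct: bool = True
) -> list[tuple[int, str, str]]:
    """(distance, direction, deprel) for every non-root token.

    distance = |dependent position - head position|; direction is "left"
    when the dependent precedes its head.  Arcs labelled ``punct`` are
    excluded from distance-based metrics by default because punctuation in
    speech transcripts is a transcription artifact.
    """
    out: list[tuple[int, str, str]] = []
    for tok in sentence.tokens:
        if tok.head == 0:
            continue
        if exclude_punct and deprel_base(tok.deprel) == "punct":
            continue
        distance = abs(tok.index - tok.head)
        direction = "left" if tok.index < tok.head else "right"
        out.append((distance, direction, tok.deprel))
    return out


def _sentence_words(sentence: ParsedSentence, exclude_punct: bool = True) -> int:
    if not exclude_punct:
        return len(sentence.tokens)
    return sum(1 for t in sentence.tokens if t.upos != "PUNCT")


def complexity_metrics(
    sentences: Sequence[ParsedSentence],
    *,
    mod_relations: frozenset[str] = frozenset({"nmod", "amod"}),
    exclude_punct: bool = True,
) -> SyntacticProfile:
    """The nine complexity metrics plus relation/POS frequency profiles."""
    if not sentences:
        raise ValueError("complexity_metrics requires at least one sentence")

    total_words = 0
    total_content = 0
    total_clauses = 0
    all_distances: list[int] = []
    n_adjacent = 0
    n_left = 0
    n_mod = 0
    ndd_terms: list[float] = []

    for sent in sentences:
        n_words = _sentence_words(sent, exclude_punct)
        total_words += n_words
        total_content += sum(
            1
            for t in sent.tokens
            if t.upos in CONTENT_TAGS and (not exclude_punct or t.upos != "PUNCT")
        )
        arcs = dependency_distances(sent, exclude_punct)
        clauses = 1 + sum(1 for _, _, rel in arcs if deprel_base(rel) in CLAUSAL_RELATIONS)
        total_clauses += clauses
        for dist, direction, rel in arcs:
            all_distances.append(dist)
            if dist == 1:
                n_adjacent += 1
            if direction == "left":
                n_left += 1
            if deprel_base(rel) in mod_relations:
                n_mod += 1
        if arcs and n_words > 0:
            mdd_s = sum(d for d, _, _ in arcs) / len(arcs)
            ndd_terms.append(abs(math.log(mdd_s / math.sqrt(sent.root_position * n_words))))

    n_arcs = len(all_distances)
    mdd = sum(all_distances) / n_arcs if n_arcs else 0.0
    ndd = sum(ndd_terms) / len(ndd_terms) if ndd_terms else 0.0
    deprel_freq, pos_freq = relation_frequencies(sentences)

    return SyntacticProfile(
        LEN=total_words / len(sentences),
        LXD=total_content / total_words if total_words else 0.0,
        MDD=mdd,
        NDD=ndd,
        ADJD=n_adjacent / n_arcs if n_arcs else 0.0,
        LEFT=n_left / n_arcs if n_arcs else 0.0,
        MOD=1000.0 * n_mod / total_words if total_words else 0.0,
        CLS=total_clauses / len(sentences),
        CLL=total_words / total_clauses if total_clauses else 0.0,
        deprel_freq=deprel_freq,
        pos_freq=pos_freq,
    )


def relation_frequencies(
    sentences: Sequence[ParsedSentence],
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-1000-token frequencies of deprel labels and UPOS tags.

    Every registry label / tag is present (0 when unobserved) so feature
    vectors align across corpora.  Each token carries exactly one relation
    (the root token carries ``root``), so each map sums to 1000.
    """
    if not sentences:
        raise ValueError("relation_frequencies requires at least one sentence")
    dep_counts = dict.fromkeys(DEPREL_REGISTRY, 0)
    pos_counts = dict.fromkeys(UPOS_TAGS, 0)
    total = 0
    for sent in sentences:
        for tok in sent.tokens:
            total += 1
            dep_counts[canonical_deprel(tok.deprel)] += 1
            if tok.upos in pos_counts:
                pos_counts[tok.upos] += 1
            else:
                logger.debug("unknown UPOS %r counted as X", tok.upos)
                pos_counts["X"] += 1
    scale = 1000.0 / total if total else 0.0
    return (
        {k: v * scale for k, v in dep_counts.items()},
        {k: v * scale for k, v in pos_counts.items()},
    )
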