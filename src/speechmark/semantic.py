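"""Local semantic-similarity features of spontaneous speech.

Semantic coherence is proxied by cosine similarity between embeddings of
adjacent speech units.  Two families of features are computed per task
instance:

* word level — the cosine similarity between each word's embedding and the
  embedding of the word directly after it, aggregated into a mean
  (``wordAvg``) and variance (``wordVar``);
* sentence level — each sentence is embedded and compared with the
  sentence *w* positions later for window sizes w in {1, 2, 3} (window 1
  compares a sentence only with its immediate successor), yielding a mean
  and variance per window: six features (``sbertAvgWindow1..3``,
  ``sbertVarWindow1..3``).

Low mean adjacent-word similarity indicates topic drift / derailment;
high variance indicates unstable, fluctuating lexical-semantic selection.
The frequency of immediate word repetitions (removed during cleaning but
counted) is retained as a separate per-1000-words feature.

Features are *absent* (``None``), never zero, when no comparable pair
exists; downstream assembly treats absence as missing data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import EmbeddingSource, TaskInstance

logger = logging.getLogger(__name__)

WINDOWS = (1, 2, 3)


class ZeroVectorError(ValueError):
    """Cosine similarity is undefined for a zero vector."""


@dataclass
class SemanticProfile:
    wordAvg: float | None
    wordVar: float | None
    n_word_pairs: int
    n_word_pairs_skipped: int
    window_means: dict[int, float | None]
    window_vars: dict[int, float | None]
    n_sentence_pairs: dict[int, int]

    def to_dict(self) -> dict[str, float | None]:
        out = {"wordAvg": self.wordAvg, "wordVar": self.wordVar}
        for w in WINDOWS:
            out[f"sbertAvgWindow{w}"] = self.window_means.get(w)
            out[f"sbertVarWindow{w}"] = self.window_vars.get(w)
        return out


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """cos(u, v) = u.v / (|u||v|), clipped to [-1, 1] against rounding."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ZeroVectorError("cosine similarity undefined for zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def _mean_var(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    # population variance: the observed pair set is the whole population
    return float(arr.mean()), float(arr.var())


def word_similarity_stats(
    token_groups: Iterable[Sequence[str]],
    source: EmbeddingSource,
    *,
    cross_boundaries: bool = False,
) -> tuple[float | None, float | None, int, int]:
    """Mean/variance of consecutive-word cosine similarity.

    Pairs are formed between each word and the word directly after it.  By
    default pairs do not cross utterance boundaries (consecutive words in
    different turns are not adjacent speech); ``cross_boundaries=True``
    chains all groups into one stream.  Pairs with an out-of-vocabulary
    member are skipped and counted, never replaced by zero vectors.

    Returns (wordAvg, wordVar, n_pairs, n_skipped); the statistics are
    ``None`` when no pair could be scored.
    """
    groups = [list(g) for g in token_groups]
    if cross_boundaries:
        groups = [[t for g in groups for t in g]]
    sims: list[float] = []
    skipped = 0
    for group in groups:
        for a, b in zip(group, group[1:]):
            va = source.word_vector(a)
            vb = source.word_vector(b)
            if va is None or vb is None:
                skipped += 1
                continue
            try:
                sims.append(cosine_similarity(va, vb))
            except ZeroVectorError:
                skipped += 1
    if not sims:
        return None, None, 0, skipped
    mean, var = _mean_var(sims)
    return mean, var, len(sims), skipped


def sentence_similarity_stats(
    sentences: Sequence[Sequence[str]],
    source: EmbeddingSource,
    windows: Sequence[int] = WINDOWS,
    *,
    mode: str = "lag",
) -> tuple[dict[int, float | None], dict[int, float | None], dict[int, int]]:
    """Moving-window sentence similarity statistics.

    For window size w the default ``lag`` mode pairs sentence i with
    sentence i+w (window 1 = immediate successor); ``all_pairs`` mode
    instead pairs every two sentences at most w apart.  Sentences with no
    embeddable word are skipped.  Statistics for a window are ``None``
    when it has no pair (fewer than w+1 embeddable sentences).
    """
    if mode not in ("lag", "all_pairs"):
        raise ValueError(f"unknown window mode {mode!r}")
    vecs = []
    for sent in sentences:
        v = source.sentence_vector(list(sent))
        if v is not None:
            vecs.append(v)
        else:
            logger.debug("sentence with no embeddable word skipped: %r", sent)
    means: dict[int, float | None] = {}
    vars_: dict[int, float | None] = {}
    counts: dict[int, int] = {}
    for w in windows:
        if mode == "lag":
            pairs = [(i, i + w) for i in range(len(vecs) - w)]
        else:
            pairs = [
                (i, j)
                for i in range(len(vecs))
                for j in range(i + 1, min(i + w + 1, len(vecs)))
            ]
        sims = [cosine_similarity(vecs[i], vecs[j]) for i, j in pairs]
        counts[w] = len(sims)
        if sims:
            means[w], vars_[w] = _mean_var(sims)
        else:
            means[w], vars_[w] = None, None
    return means, vars_, counts


def semantic_profile(
    instance: TaskInstance,
    source: EmbeddingSource,
    *,
    sentences: Sequence[Sequence[str]] | None = None,
    cross_boundaries: bool = False,
    window_mode: str = "lag",
) -> SemanticProfile:
    """All eight semantic features for one task instance."""
    from .corpus_io import instance_sentences

    wavg, wvar, n_pairs, n_skip = word_similarity_stats(
        instance.tokens_per_utterance(), source, cross_boundaries=cross_boundaries
    )
    sents = sentences if sentences is not None else instance_sentences(instance)
    means, vars_, counts = sentence_similarity_stats(sents, source, mode=window_mode)
    return SemanticProfile(
        wordAvg=wavg,
        wordVar=wvar,
        n_word_pairs=n_pairs,
        n_word_pairs_skipped=n_skip,
        window_means=means,
        window_vars=vars_,
        n_sentence_pairs=counts,
    )


def repetition_frequency(instance: TaskInstance) -> float:
    """Immediate-repetition rate per 1000 words of the original stream.

    Repetitions were removed before ``word_count`` was fixed, so the
    denominator restores them: 1000 * reps / (word_count + reps).
    """
    denom = instance.word_count + instance.repetition_count
    if denom == 0:
        return 0.0
    return 1000.0 * instance.repetition_count / denom


def incomplete_frequency(instance: TaskInstance) -> float:
    """Incomplete-word rate per 1000 words, computed like repetitions."""
    denom = instance.word_count + instance.incomplete_count
    if denom == 0:
        return 0.0
    return 1000.0 * instance.incomplete_count / denom
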