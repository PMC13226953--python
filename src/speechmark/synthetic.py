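"""Synthetic multi-group speech corpora with controllable linguistic contrasts.

Clinical speech corpora (aphasia banks, psychiatric interview datasets) are
access-restricted, so the pipeline is exercised on generated corpora that
emulate the *contrasts* such data exhibit rather than natural language
itself: topic drift (per-word probability of jumping to a new topic
vector), immediate word repetition, incomplete words, sentence length,
subordinate-clause density, the noun/pronoun mixture, and a per-participant
severity score whose distribution is set per group.

Each participant receives a CHAT-like surface transcript (with injected
disfluencies and interviewer turns), a matching dependency parse of the
*cleaned* token stream for every task instance, and a row of metadata.
A synthetic embedding table places every content word near its topic
centroid, so embedding-based coherence features respond to topic drift by
construction.  Surface vocabulary is pronounceable nonsense words plus a
closed function-word list; no pretrained resource is involved.

Sentences are built from hand-written dependency templates (simple clause,
clause + nominal modifiers, clause + subordinate clause), which guarantees
well-formed single-rooted trees and directly controllable clause counts
and modifier frequencies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import (
    ParsedSentence,
    ParseToken,
    PreprocessOptions,
    TableEmbeddingSource,
    TaskInstance,
    Transcript,
    Utterance,
    clean_utterance_line,
    write_conllu,
    write_embedding_table,
)

PRONOUNS = ("I", "you", "he", "she", "it", "we", "they")
DETERMINERS = ("the", "a")
MARKS = ("that", "because", "while")
RESERVED_FORMS = frozenset(
    w.lower() for w in PRONOUNS + DETERMINERS + MARKS
) | frozenset({"uh", "um", "er", "ah", "mhm", "hmm"})

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"

#: POS composition of the content vocabulary.
_POS_SHARES = (("NOUN", 0.40), ("VERB", 0.25), ("ADJ", 0.20), ("ADV", 0.15))

_TASK_PROMPTS = {
    "open_ended": "tell me about it",
    "picture": "describe what you see in the picture",
}


class ConfigError(ValueError):
    """A generator configuration field is invalid."""


@dataclass(frozen=True)
class GroupProfile:
    """Generator parameters controlling one group's linguistic signature.

    ``topic_jump_prob`` is the per-content-word probability of switching to
    a different topic vector (semantic derailment); ``within_topic_noise``
    spreads word vectors around their topic centroid; ``repetition_rate``
    and ``incomplete_rate`` are expected disfluency events per 1000 words;
    ``severity_loc``/``severity_scale`` parametrise the per-participant
    severity score, drawn from a normal left-censored at 0 (matching the
    zero-inflated clinician severity ratings of healthy controls).
    """

    name: str
    topic_jump_prob: float = 0.1
    within_topic_noise: float = 0.25
    repetition_rate: float = 5.0
    incomplete_rate: float = 2.0
    sentence_len_mean: float = 8.0
    sentence_len_sd: float = 2.5
    clause_embed_prob: float = 0.3
    noun_weight: float = 1.5
    pronoun_weight: float = 1.5
    severity_loc: float = 0.5
    severity_scale: float = 0.5
    dataset: str = "synthetic"

    def __post_init__(self) -> None:
        for fld in ("topic_jump_prob", "clause_embed_prob"):
            v = getattr(self, fld)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{fld} must be in [0, 1], got {v}")
        for fld in (
            "within_topic_noise", "repetition_rate", "incomplete_rate",
            "noun_weight", "pronoun_weight", "severity_scale",
        ):
            v = getattr(self, fld)
            if v < 0:
                raise ConfigError(f"{fld} must be >= 0, got {v}")
        if self.sentence_len_mean < 2:
            raise ConfigError(
                f"sentence_len_mean must be >= 2, got {self.sentence_len_mean}"
            )
        if self.noun_weight + self.pronoun_weight <= 0:
            raise ConfigError("noun_weight + pronoun_weight must be positive")
        if not self.name:
            raise ConfigError("name must be nonempty")


@dataclass(frozen=True)
class SyntheticCorpusConfig:
    profiles: tuple[GroupProfile, ...]
    n_participants_per_group: int = 10
    tasks_per_participant: tuple[tuple[str, str], ...] = (
        ("AboutYourself", "open_ended"),
        ("CatRescue", "picture"),
    )
    vocab_size: int = 400
    n_topics: int = 8
    embed_dim: int = 64
    seed: int = 0
    words_per_task: int = 180
    #: optional per-task profile-field overrides, e.g. a prompt that
    #: systematically lowers coherence: {"AboutYourself": {"topic_jump_prob": 0.4}}
    task_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    filler_rate: float = 10.0  # filler insertions per 1000 words

    def __post_init__(self) -> None:
        if len(self.profiles) < 2:
            raise ConfigError("profiles must contain at least 2 entries")
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ConfigError(f"profile names must be unique, got {names}")
        if self.n_participants_per_group < 1:
            raise ConfigError("n_participants_per_group must be positive")
        if not self.tasks_per_participant:
            raise ConfigError("tasks_per_participant must be nonempty")
        if self.embed_dim < 2:
            raise ConfigError("embed_dim must be >= 2")
        if self.embed_dim < self.n_topics:
            raise ConfigError("embed_dim must be >= n_topics")
        for fld in ("vocab_size", "n_topics", "words_per_task"):
            if getattr(self, fld) < 1:
                raise ConfigError(f"{fld} must be positive")


@dataclass
class Vocabulary:
    """Nonsense content words organised by topic and POS, plus the table."""

    topic_pos_words: list[dict[str, list[str]]]  # [topic][upos] -> words

    def words(self) -> list[str]:
        return [w for topic in self.topic_pos_words for ws in topic.values() for w in ws]


@dataclass
class SyntheticCorpus:
    transcripts: list[Transcript]
    chat_texts: dict[str, str]  # participant_id -> raw CHAT-like text
    parses: dict[str, list[ParsedSentence]]  # instance_id -> parses
    embedding_table: dict[str, np.ndarray]
    metadata: pd.DataFrame
    config: SyntheticCorpusConfig

    @property
    def embedding_source(self) -> TableEmbeddingSource:
        return TableEmbeddingSource(self.embedding_table)

    def instances(self) -> list[TaskInstance]:
        return [i for t in self.transcripts for i in t.task_instances]

    def severity_of(self) -> dict[str, float]:
        return dict(zip(self.metadata["participant_id"], self.metadata["severity"]))


# ---------------------------------------------------------------------------
# vocabulary and embeddings


def _nonsense_word(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(
        rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
        for _ in range(n_syllables)
    )


def make_vocabulary(vocab_size: int, n_topics: int, rng: np.random.Generator) -> Vocabulary:
    seen: set[str] = set(RESERVED_FORMS)
    words: list[str] = []
    while len(words) < vocab_size:
        w = _nonsense_word(rng, int(rng.integers(2, 4)))
        if w not in seen:
            seen.add(w)
            words.append(w)
    topic_pos: list[dict[str, list[str]]] = [
        {pos: [] for pos, _ in _POS_SHARES} for _ in range(n_topics)
    ]
    # deterministic round-robin over topics within POS blocks
    start = 0
    for pos, share in _POS_SHARES:
        count = max(n_topics * 2, int(round(vocab_size * share)))
        block = words[start:start + count]
        start += len(block)
        for i, w in enumerate(block):
            topic_pos[i % n_topics][pos].append(w)
    for t, pools in enumerate(topic_pos):
        for pos, pool in pools.items():
            if len(pool) < 2:
                raise ConfigError(
                    f"vocab_size {vocab_size} too small for {n_topics} topics "
                    f"(topic {t} has {len(pool)} {pos} words)"
                )
    return Vocabulary(topic_pos)


def _topic_centroids(n_topics: int, embed_dim: int, rng: np.random.Generator) -> np.ndarray:
    c = rng.standard_normal((n_topics, embed_dim))
    return c / np.linalg.norm(c, axis=1, keepdims=True)


def _embed(centroid: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    v = centroid + noise * rng.standard_normal(centroid.shape)
    n = float(np.linalg.norm(v))
    if n == 0.0:  # pragma: no cover - measure-zero event
        return _embed(centroid, noise, rng)
    return v / n


def generate_embedding_table(
    vocab_size: int,
    n_topics: int,
    embed_dim: int,
    within_topic_noise: float,
    seed: int,
) -> dict[str, np.ndarray]:
    """Stand-alone topic-structured embedding table over a generated vocabulary.

    Each word is assigned to one topic; its vector is the unit-normalised
    sum of the topic centroid and isotropic Gaussian noise.  Centroids are
    random unit vectors, hence mutually near-orthogonal when
    ``embed_dim >> n_topics``.
    """
    if embed_dim < n_topics:
        raise ConfigError(f"embed_dim ({embed_dim}) must be >= n_topics ({n_topics})")
    for fld, v in (("vocab_size", vocab_size), ("n_topics", n_topics), ("embed_dim", embed_dim)):
        if v < 1:
            raise ConfigError(f"{fld} must be positive, got {v}")
    if within_topic_noise < 0:
        raise ConfigError(f"within_topic_noise must be >= 0, got {within_topic_noise}")
    rng = np.random.default_rng(seed)
    centroids = _topic_centroids(n_topics, embed_dim, rng)
    table: dict[str, np.ndarray] = {}
    for i in range(vocab_size):
        topic = i % n_topics
        table[f"w{i:04d}"] = _embed(centroids[topic], within_topic_noise, rng)
    return table


def _corpus_embedding_table(
    vocab: Vocabulary,
    config: SyntheticCorpusConfig,
    noise: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    centroids = _topic_centroids(config.n_topics, config.embed_dim, rng)
    table: dict[str, np.ndarray] = {}
    for t, pools in enumerate(vocab.topic_pos_words):
        for pool in pools.values():
            for w in pool:
                table[w] = _embed(centroids[t], noise, rng)
    # closed-class words get their own stable random directions
    for w in (*PRONOUNS, *DETERMINERS, *MARKS):
        table[w.lower()] = _embed(
            rng.standard_normal(config.embed_dim)
            / np.sqrt(config.embed_dim), 1.0, rng,
        )
    return table


# ---------------------------------------------------------------------------
# sentence generation


@dataclass
class _Node:
    upos: str
    deprel: str
    head: "_Node | None"
    form: str = ""


def _skeleton(
    profile: GroupProfile, rng: np.random.Generator
) -> list[_Node]:
    """Build a dependency-tree skeleton (POS + deprel, no forms) in linear order."""
    length = max(2, int(round(rng.normal(profile.sentence_len_mean, profile.sentence_len_sd))))
    has_sub = rng.random() < profile.clause_embed_prob
    if has_sub:
        sub_len = max(1, min(length - 1, max(2, int(round(length * 0.4)))))
        main_len = max(1, length - sub_len)
    else:
        sub_len, main_len = 0, length

    pron_p = profile.pronoun_weight / (profile.noun_weight + profile.pronoun_weight)

    def clause(n: int, root_rel: str, outer_head: "_Node | None") -> list[_Node]:
        verb = _Node("VERB", root_rel, outer_head)
        if n == 1:
            return [verb]
        if rng.random() < pron_p:
            subj = _Node("PRON", "nsubj", verb)
        else:
            subj = _Node("NOUN", "nsubj", verb)
        if n == 2:
            return [subj, verb]
        obj = _Node("NOUN", "obj", verb)
        pre_subj: list[_Node] = []
        pre_obj: list[_Node] = []
        post_obj: list[_Node] = []
        tail: list[_Node] = []
        have_det = {id(subj): subj.upos == "PRON", id(obj): False}
        for _ in range(n - 3):
            options: list[tuple[str, float]] = [("amod_obj", 1.0), ("advmod", 1.0)]
            options.append(("nmod_obj", profile.noun_weight))
            if not have_det[id(obj)]:
                options.append(("det_obj", 0.8))
            if subj.upos == "NOUN":
                options.append(("amod_subj", 0.7))
                if not have_det[id(subj)]:
                    options.append(("det_subj", 0.8))
            labels, weights = zip(*options)
            w = np.asarray(weights) / sum(weights)
            choice = labels[int(rng.choice(len(labels), p=w))]
            if choice == "amod_obj":
                pre_obj.append(_Node("ADJ", "amod", obj))
            elif choice == "advmod":
                tail.append(_Node("ADV", "advmod", verb))
            elif choice == "nmod_obj":
                rel = "nmod:poss" if rng.random() < 0.3 else "nmod"
                post_obj.append(_Node("NOUN", rel, obj))
            elif choice == "det_obj":
                have_det[id(obj)] = True
                pre_obj.insert(0, _Node("DET", "det", obj))
            elif choice == "amod_subj":
                pre_subj.append(_Node("ADJ", "amod", subj))
            elif choice == "det_subj":
                have_det[id(subj)] = True
                pre_subj.insert(0, _Node("DET", "det", subj))
        return [*pre_subj, subj, verb, *pre_obj, obj, *post_obj, *tail]

    main = clause(main_len, "root", None)
    main_verb = next(n for n in main if n.deprel == "root")
    nodes = list(main)
    if has_sub:
        rel = "advcl" if rng.random() < 0.5 else "ccomp"
        if sub_len == 1:
            nodes += clause(1, rel, main_verb)
        else:
            sub = clause(sub_len - 1, rel, main_verb)
            sub_verb = next(n for n in sub if n.deprel == rel)
            nodes += [_Node("SCONJ", "mark", sub_verb), *sub]
    return nodes


def generate_sentence(
    profile: GroupProfile,
    topic_state: int,
    rng: np.random.Generator,
    vocab: Vocabulary,
    n_topics: int,
) -> tuple[list[str], ParsedSentence, int]:
    """Generate one sentence: surface tokens, its parse, the new topic state.

    Content-word forms are filled in surface order under the topic-drift
    process: with probability ``topic_jump_prob`` per content word the
    topic state jumps to a different topic, and the word is sampled from
    the current topic's pool for its POS.  Immediate duplicate forms are
    resampled so the clean stream never contains adjacent repetitions
    (injected disfluencies are therefore exactly recoverable).
    """
    if not 0 <= topic_state < n_topics:
        raise ConfigError(f"topic_state {topic_state} out of range [0, {n_topics})")
    nodes = _skeleton(profile, rng)
    prev_form: str | None = None
    for node in nodes:
        if node.upos == "PRON":
            node.form = str(rng.choice(PRONOUNS))
        elif node.upos == "DET":
            node.form = str(rng.choice(DETERMINERS))
        elif node.upos == "SCONJ":
            node.form = str(rng.choice(MARKS))
        else:
            if n_topics > 1 and rng.random() < profile.topic_jump_prob:
                topic_state = int((topic_state + 1 + rng.integers(n_topics - 1)) % n_topics)
            pool = vocab.topic_pos_words[topic_state][node.upos]
            form = str(rng.choice(pool))
            for _ in range(10):
                if prev_form is None or form.lower() != prev_form.lower():
                    break
                form = str(rng.choice(pool))
            node.form = form
        prev_form = node.form

    index_of = {id(n): i + 1 for i, n in enumerate(nodes)}
    tokens = [
        ParseToken(
            index=i + 1,
            form=n.form,
            upos=n.upos,
            head=0 if n.head is None else index_of[id(n.head)],
            deprel=n.deprel,
        )
        for i, n in enumerate(nodes)
    ]
    parsed = ParsedSentence(tokens)
    return parsed.forms(), parsed, topic_state


def _inject_disfluencies(
    clean: Sequence[str],
    profile: GroupProfile,
    filler_rate: float,
    rng: np.random.Generator,
) -> list[str]:
    """Insert repetitions, incomplete-word fragments and fillers."""
    out: list[str] = []
    for tok in clean:
        if rng.random() < filler_rate / 1000.0:
            out.append("um")
        if rng.random() < profile.incomplete_rate / 1000.0 and len(tok) > 2:
            out.append(tok[: max(1, len(tok) // 2)] + "-")
        out.append(tok)
        if rng.random() < profile.repetition_rate / 1000.0:
            out.append(tok)
    return out


# ---------------------------------------------------------------------------
# corpus generation


def _effective_profile(profile: GroupProfile, config: SyntheticCorpusConfig, task_id: str, task_type: str) -> GroupProfile:
    overrides: dict[str, float] = {}
    for key in (task_type, task_id):
        if key in config.task_overrides:
            overrides.update(config.task_overrides[key])
    return dataclasses.replace(profile, **overrides) if overrides else profile


def generate_corpus(config: SyntheticCorpusConfig) -> SyntheticCorpus:
    """Generate a full synthetic corpus, deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    noise = float(np.mean([p.within_topic_noise for p in config.profiles]))
    vocab = make_vocabulary(config.vocab_size, config.n_topics, rng)
    table = _corpus_embedding_table(vocab, config, noise, rng)
    opts = PreprocessOptions()

    transcripts: list[Transcript] = []
    chat_texts: dict[str, str] = {}
    parses: dict[str, list[ParsedSentence]] = {}
    meta_rows: list[dict] = []

    for profile in config.profiles:
        for p_idx in range(config.n_participants_per_group):
            pid = f"{profile.name}{p_idx + 1:03d}"
            severity = max(0.0, float(rng.normal(profile.severity_loc, profile.severity_scale)))
            lines: list[str] = [
                f"@Participant: {pid}",
                f"@Group: {profile.name}",
                f"@Dataset: {profile.dataset}",
                f"@Severity: {severity:.4f}",
            ]
            instances: list[TaskInstance] = []
            for task_id, task_type in config.tasks_per_participant:
                eff = _effective_profile(profile, config, task_id, task_type)
                prompt = _TASK_PROMPTS.get(task_type, "tell me about it")
                lines.append(f"@Task: {task_id} {task_type} | {prompt}")
                lines.append(f"*INV: {prompt} ?")
                instance_id = f"{pid}__{task_id}"
                topic_state = int(rng.integers(config.n_topics))
                inst = TaskInstance(
                    instance_id=instance_id,
                    participant_id=pid,
                    task_id=task_id,
                    task_type=task_type,
                    utterances=[],
                    task_description=prompt,
                )
                sent_parses: list[ParsedSentence] = []
                n_words = 0
                while n_words < config.words_per_task:
                    clean, parsed, topic_state = generate_sentence(
                        eff, topic_state, rng, vocab, config.n_topics
                    )
                    dirty = _inject_disfluencies(clean, eff, config.filler_rate, rng)
                    body = " ".join(dirty) + " ."
                    lines.append(f"*PAR: {body}")
                    res = clean_utterance_line(body, opts)
                    if res.tokens != clean:  # pragma: no cover - internal consistency
                        raise AssertionError(
                            f"cleaning did not recover the generated sentence: "
                            f"{res.tokens} != {clean}"
                        )
                    inst.utterances.append(Utterance("PAR", res.tokens, body))
                    inst.repetition_count += res.n_repetitions
                    inst.incomplete_count += res.n_incomplete
                    inst.filler_count += res.n_fillers
                    inst.symbol_count += res.n_symbols
                    sent_parses.append(parsed)
                    n_words += len(clean)
                inst.word_count = sum(len(u.tokens) for u in inst.utterances)
                instances.append(inst)
                parses[instance_id] = sent_parses
            lines.append("@End")
            chat_texts[pid] = "\n".join(lines) + "\n"
            transcripts.append(
                Transcript(
                    participant_id=pid,
                    group=profile.name,
                    dataset=profile.dataset,
                    task_instances=instances,
                    severity=severity,
                )
            )
            meta_rows.append(
                {
                    "participant_id": pid,
                    "group": profile.name,
                    "dataset": profile.dataset,
                    "severity": round(severity, 4),
                    "tasks": ";".join(f"{t}:{ty}" for t, ty in config.tasks_per_participant),
                }
            )

    metadata = pd.DataFrame(meta_rows)
    return SyntheticCorpus(
        transcripts=transcripts,
        chat_texts=chat_texts,
        parses=parses,
        embedding_table=table,
        metadata=metadata,
        config=config,
    )


def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> None:
    """Write transcripts, parses, embeddings and metadata as plain text."""
    out = Path(out_dir)
    (out / "transcripts").mkdir(parents=True, exist_ok=True)
    (out / "parses").mkdir(parents=True, exist_ok=True)
    for pid, text in corpus.chat_texts.items():
        (out / "transcripts" / f"{pid}.cha").write_text(text, encoding="utf-8")
    for instance_id, sents in corpus.parses.items():
        write_conllu(sents, out / "parses" / f"{instance_id}.conllu")
    write_embedding_table(corpus.embedding_table, out / "embeddings.txt")
    corpus.metadata.to_csv(out / "metadata.csv", index=False)


# ---------------------------------------------------------------------------
# group presets (study conditions)


def wa_like_profile(name: str = "WA", dataset: str = "aphasia") -> GroupProfile:
    """Fluent-aphasia-like signature: heavy repetition, strong topic drift,
    noisy lexical selection, shorter and structurally simpler sentences,
    pronoun-heavy output, high severity."""
    return GroupProfile(
        name=name, dataset=dataset,
        topic_jump_prob=0.5, within_topic_noise=0.35,
        repetition_rate=80.0, incomplete_rate=15.0,
        sentence_len_mean=7.0, sentence_len_sd=2.5, clause_embed_prob=0.15,
        noun_weight=1.0, pronoun_weight=2.0,
        severity_loc=2.2, severity_scale=0.8,
    )


def ssd_like_profile(name: str = "SSD", dataset: str = "psychiatric") -> GroupProfile:
    """Thought-disorder-like signature: mild drift, low repetition, longer
    and clause-denser sentences, noun-heavy output; severity distribution
    matches clinician ratings of a mildly affected group (mean 1.10,
    SD 0.94, left-censored at 0)."""
    return GroupProfile(
        name=name, dataset=dataset,
        topic_jump_prob=0.15, within_topic_noise=0.25,
        repetition_rate=5.0, incomplete_rate=5.0,
        sentence_len_mean=9.0, sentence_len_sd=3.0, clause_embed_prob=0.35,
        noun_weight=2.0, pronoun_weight=1.0,
        severity_loc=1.10, severity_scale=0.94,
    )


def control_profile(name: str = "HC", dataset: str = "synthetic") -> GroupProfile:
    """Healthy-control signature: minimal drift and disfluency; severity
    left-censored normal with mean 0.11, SD 0.32 (mostly zeros)."""
    return GroupProfile(
        name=name, dataset=dataset,
        topic_jump_prob=0.05, within_topic_noise=0.2,
        repetition_rate=2.0, incomplete_rate=1.0,
        sentence_len_mean=10.0, sentence_len_sd=3.0, clause_embed_prob=0.3,
        noun_weight=1.5, pronoun_weight=1.5,
        severity_loc=0.108, severity_scale=0.315,
    )


def default_config(seed: int = 0, n_participants_per_group: int = 10) -> SyntheticCorpusConfig:
    """Two datasets x patient/control groups, mirroring the study design."""
    return SyntheticCorpusConfig(
        profiles=(
            wa_like_profile(),
            control_profile("HCA", "aphasia"),
            ssd_like_profile(),
            control_profile("HCS", "psychiatric"),
        ),
        n_participants_per_group=n_participants_per_group,
        seed=seed,
    )
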