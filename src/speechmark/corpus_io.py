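"""Reading, cleaning and representing speech transcripts, parses and embeddings.

Spontaneous-speech transcripts arrive in a CHAT-like dialogue format:
speaker-prefixed lines (``*PAR:`` for the participant, ``*INV:`` for the
interviewer) with inline annotation symbols, optionally organised into task
blocks by ``@Task:`` headers.  Only the participant's speech is analysed;
interviewer turns, annotation symbols, filler words, immediate word
repetitions and incomplete (truncation-marked) words are removed before
feature extraction, with exact accounting of everything that was removed so
that repetition and incomplete-word rates can be reported as features in
their own right.

Dependency parses are exchanged as CoNLL-U; word embeddings are accessed
through the :class:`EmbeddingSource` contract so that any vector backend
(a plain-text table for tests, a pretrained model in real use) can stand
behind the semantic features.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np

logger = logging.getLogger(__name__)

PARTICIPANT_PREFIX = "*PAR:"
INTERVIEWER_PREFIX = "*INV:"

#: Default filler lexicon.  The set is configurable and logged with every
#: run; discourse markers such as "like" and "well" are deliberately not
#: removed by default because they are frequently contentful in speech.
DEFAULT_FILLERS = frozenset({"uh", "um", "er", "ah", "mhm", "hmm"})

#: Annotation-symbol patterns stripped from utterances before tokenisation:
#: bracketed codes ``[+ gram]``, angle-bracket retracing ``<...>``, pause
#: marks ``(..)``, event codes ``&=laughs`` / ``&-um``, and ``+...`` shift
#: codes.  Each pattern must consume whole symbols, not word characters.
DEFAULT_SYMBOL_PATTERNS = (
    r"\[[^\]]*\]",
    r"<|>",
    r"\(\.+\)",
    r"&[=\-~]?\S+",
    r"\+\S+",
)

_PUNCT_STRIP = ".,!?;:\"'`“”‘’"


class CorpusFormatError(ValueError):
    """Raised when an input file violates its format contract."""


class EmptyTranscriptError(ValueError):
    """Raised when a transcript contains no usable participant speech."""


@dataclass(frozen=True)
class PreprocessOptions:
    """Cleaning rules applied to participant utterances.

    ``truncation_marker`` identifies incomplete words by a trailing marker
    (CHAT-style ``wor-``); plain text without such annotation simply yields
    zero incompletes.  ``collapse_repetitions`` removes immediate,
    case-insensitive duplications of the same word form within an utterance
    (a run of k identical tokens counts as k-1 repetitions).
    """

    filler_lexicon: frozenset[str] = DEFAULT_FILLERS
    symbol_patterns: tuple[str, ...] = DEFAULT_SYMBOL_PATTERNS
    truncation_marker: str = "-"
    collapse_repetitions: bool = True
    case_insensitive_repetition: bool = True

    def describe(self) -> dict:
        return {
            "filler_lexicon": sorted(self.filler_lexicon),
            "symbol_patterns": list(self.symbol_patterns),
            "truncation_marker": self.truncation_marker,
            "collapse_repetitions": self.collapse_repetitions,
        }


@dataclass
class CleanResult:
    tokens: list[str]
    n_original: int
    n_symbols: int
    n_fillers: int
    n_incomplete: int
    n_repetitions: int


@dataclass
class Utterance:
    """One speaker turn, after cleaning."""

    speaker: str
    tokens: list[str]
    raw_text: str

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


@dataclass
class TaskInstance:
    """A participant's response to one elicitation task.

    ``word_count`` counts cleaned participant words; ``repetition_count``
    and ``incomplete_count`` record what the cleaning removed, so rates per
    1000 words of the *original* stream remain computable.
    """

    instance_id: str
    participant_id: str
    task_id: str
    task_type: str  # "open_ended" | "picture"
    utterances: list[Utterance]
    word_count: int = 0
    repetition_count: int = 0
    incomplete_count: int = 0
    filler_count: int = 0
    symbol_count: int = 0
    task_description: str | None = None

    def tokens_per_utterance(self) -> list[list[str]]:
        return [u.tokens for u in self.utterances]

    def all_tokens(self) -> list[str]:
        return [t for u in self.utterances for t in u.tokens]


@dataclass
class Transcript:
    """All of one participant's task instances plus group metadata."""

    participant_id: str
    group: str
    dataset: str
    task_instances: list[TaskInstance]
    severity: float | None = None

    def __post_init__(self) -> None:
        for inst in self.task_instances:
            if inst.participant_id != self.participant_id:
                raise ValueError(
                    f"task instance {inst.instance_id} belongs to "
                    f"{inst.participant_id}, not {self.participant_id}"
                )


@dataclass(frozen=True)
class ParseToken:
    index: int  # 1-based position
    form: str
    upos: str
    head: int  # 0 = root, else 1-based index of the head token
    deprel: str


@dataclass
class ParsedSentence:
    """A Universal-Dependencies parse of one sentence: a single rooted tree."""

    tokens: list[ParseToken]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.tokens)
        if n == 0:
            raise CorpusFormatError("empty sentence")
        for pos, tok in enumerate(self.tokens, start=1):
            if tok.index != pos:
                raise CorpusFormatError(
                    f"token indices not contiguous: expected {pos}, got {tok.index}"
                )
            if not (0 <= tok.head <= n):
                raise CorpusFormatError(
                    f"token {tok.index} has dangling head {tok.head}"
                )
            if tok.head == tok.index:
                raise CorpusFormatError(f"token {tok.index} is its own head")
        roots = [t for t in self.tokens if t.head == 0]
        if len(roots) != 1:
            raise CorpusFormatError(f"expected exactly one root, found {len(roots)}")
        # cycle check: walk each token up to the root
        for tok in self.tokens:
            seen = set()
            cur = tok.head
            while cur != 0:
                if cur in seen:
                    raise CorpusFormatError(f"cycle through token {tok.index}")
                seen.add(cur)
                cur = self.tokens[cur - 1].head

    @property
    def root_position(self) -> int:
        return next(t.index for t in self.tokens if t.head == 0)

    def forms(self) -> list[str]:
        return [t.form for t in self.tokens]


class EmbeddingSource(Protocol):
    """Vector backend contract used by the semantic features.

    ``word_vector`` returns ``None`` for out-of-vocabulary forms;
    ``sentence_vector`` returns ``None`` when no component is available.
    Returned vectors always have length ``dim``.
    """

    dim: int

    def word_vector(self, form: str) -> np.ndarray | None: ...

    def sentence_vector(self, forms: Sequence[str]) -> np.ndarray | None: ...


class TableEmbeddingSource:
    """Embeddings backed by an in-memory word -> vector table.

    Sentence vectors are the unit-normalised mean of the present word
    vectors (absent when no word is in vocabulary) — the simplest
    composition consistent with cosine comparison of sentences.
    """

    def __init__(self, table: Mapping[str, np.ndarray]):
        if not table:
            raise CorpusFormatError("embedding table is empty")
        dims = {len(v) for v in table.values()}
        if len(dims) != 1:
            raise CorpusFormatError(f"inconsistent embedding dimensions: {sorted(dims)}")
        self.dim = dims.pop()
        self._table = {w: np.asarray(v, dtype=float) for w, v in table.items()}

    def __contains__(self, form: str) -> bool:
        return form.lower() in self._table

    def word_vector(self, form: str) -> np.ndarray | None:
        return self._table.get(form.lower())

    def sentence_vector(self, forms: Sequence[str]) -> np.ndarray | None:
        vecs = [v for v in (self.word_vector(f) for f in forms) if v is not None]
        if not vecs:
            return None
        mean = np.mean(vecs, axis=0)
        norm = float(np.linalg.norm(mean))
        if norm == 0.0:
            return None
        return mean / norm


# ---------------------------------------------------------------------------
# cleaning


def clean_tokens(raw_tokens: Sequence[str], opts: PreprocessOptions) -> CleanResult:
    """Apply the cleaning rules to a raw token sequence of one utterance.

    Removal order: annotation symbols, fillers, incomplete words, then
    immediate-repetition collapse.  The counters satisfy the conservation
    identity  cleaned + symbols + fillers + incompletes + repetitions =
    original token count.
    """
    symbol_res = [re.compile(p) for p in opts.symbol_patterns]
    n_symbols = n_fillers = n_incomplete = 0
    kept: list[str] = []
    for raw in raw_tokens:
        tok = raw
        for rx in symbol_res:
            tok = rx.sub("", tok)
        tok = tok.strip()
        if not tok:
            n_symbols += 1
            continue
        # strip clause-edge punctuation but preserve a trailing truncation marker
        is_incomplete = len(tok) > 1 and tok.endswith(opts.truncation_marker)
        stripped = tok.strip(_PUNCT_STRIP) if not is_incomplete else tok
        if not stripped:
            n_symbols += 1
            continue
        if is_incomplete:
            n_incomplete += 1
            continue
        if stripped.lower() in opts.filler_lexicon:
            n_fillers += 1
            continue
        kept.append(stripped)

    n_repetitions = 0
    if opts.collapse_repetitions:
        collapsed: list[str] = []
        for tok in kept:
            prev = collapsed[-1] if collapsed else None
            same = (
                prev is not None
                and (tok.lower() == prev.lower() if opts.case_insensitive_repetition else tok == prev)
            )
            if same:
                n_repetitions += 1
            else:
                collapsed.append(tok)
        kept = collapsed

    return CleanResult(
        tokens=kept,
        n_original=len(raw_tokens),
        n_symbols=n_symbols,
        n_fillers=n_fillers,
        n_incomplete=n_incomplete,
        n_repetitions=n_repetitions,
    )


def clean_utterance_line(line: str, opts: PreprocessOptions) -> CleanResult:
    """Clean the body of a speaker line (prefix already removed)."""
    return clean_tokens(line.split(), opts)


# ---------------------------------------------------------------------------
# CHAT-like transcript reading


def _finish_instance(inst: TaskInstance) -> TaskInstance:
    inst.word_count = sum(len(u.tokens) for u in inst.utterances)
    return inst


def read_chat_transcript(
    path: str | Path,
    opts: PreprocessOptions | None = None,
    *,
    default_task_id: str = "Unspecified",
    default_task_type: str = "open_ended",
) -> Transcript:
    """Read a CHAT-like transcript file into a cleaned :class:`Transcript`.

    Recognised header lines: ``@Participant:``, ``@Group:``, ``@Dataset:``,
    ``@Severity:``, and ``@Task: <task_id> <task_type> [| description]``
    which opens a new task block.  ``*INV:`` lines are discarded;
    ``*PAR:`` lines are cleaned per ``opts``.  Utterances whose cleaned
    token list is empty are dropped (with the removal still counted).
    """
    path = Path(path)
    opts = opts or PreprocessOptions()
    participant_id = path.stem
    group = "unknown"
    dataset = "unknown"
    severity: float | None = None

    instances: list[TaskInstance] = []
    current: TaskInstance | None = None

    def open_task(task_id: str, task_type: str, description: str | None) -> TaskInstance:
        inst = TaskInstance(
            instance_id=f"{participant_id}__{task_id}",
            participant_id=participant_id,
            task_id=task_id,
            task_type=task_type,
            utterances=[],
            task_description=description,
        )
        instances.append(inst)
        return inst

    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line == "@End":
            continue
        if line.startswith("@Participant:"):
            participant_id = line.split(":", 1)[1].strip()
        elif line.startswith("@Group:"):
            group = line.split(":", 1)[1].strip()
        elif line.startswith("@Dataset:"):
            dataset = line.split(":", 1)[1].strip()
        elif line.startswith("@Severity:"):
            severity = float(line.split(":", 1)[1].strip())
        elif line.startswith("@Task:"):
            body = line.split(":", 1)[1].strip()
            desc = None
            if "|" in body:
                body, desc = (s.strip() for s in body.split("|", 1))
            parts = body.split()
            task_id = parts[0]
            task_type = parts[1] if len(parts) > 1 else default_task_type
            current = open_task(task_id, task_type, desc)
        elif line.startswith(INTERVIEWER_PREFIX):
            continue  # interviewer speech is removed wholesale
        elif line.startswith(PARTICIPANT_PREFIX):
            if current is None:
                current = open_task(default_task_id, default_task_type, None)
            body = line[len(PARTICIPANT_PREFIX):].strip()
            res = clean_utterance_line(body, opts)
            current.repetition_count += res.n_repetitions
            current.incomplete_count += res.n_incomplete
            current.filler_count += res.n_fillers
            current.symbol_count += res.n_symbols
            if res.tokens:
                current.utterances.append(
                    Utterance(speaker="PAR", tokens=res.tokens, raw_text=body)
                )
            else:
                logger.debug("%s:%d: utterance empty after cleaning", path, lineno)
        elif line.startswith("@"):
            continue  # other headers ignored
        else:
            raise CorpusFormatError(f"{path}:{lineno}: unrecognised line {line!r}")

    instances = [_finish_instance(i) for i in instances]
    instances = [i for i in instances if i.utterances]
    if not instances:
        raise EmptyTranscriptError(f"no participant speech in {path}")
    return Transcript(
        participant_id=participant_id,
        group=group,
        dataset=dataset,
        task_instances=instances,
        severity=severity,
    )


def read_plain_task(
    path: str | Path,
    participant_id: str,
    task_id: str,
    task_type: str = "open_ended",
    opts: PreprocessOptions | None = None,
) -> TaskInstance:
    """Read a plain per-task text file (one utterance per line)."""
    path = Path(path)
    opts = opts or PreprocessOptions()
    inst = TaskInstance(
        instance_id=f"{participant_id}__{task_id}",
        participant_id=participant_id,
        task_id=task_id,
        task_type=task_type,
        utterances=[],
    )
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        res = clean_utterance_line(line, opts)
        inst.repetition_count += res.n_repetitions
        inst.incomplete_count += res.n_incomplete
        inst.filler_count += res.n_fillers
        inst.symbol_count += res.n_symbols
        if res.tokens:
            inst.utterances.append(Utterance("PAR", res.tokens, line))
    if not inst.utterances:
        raise EmptyTranscriptError(f"no usable speech in {path}")
    return _finish_instance(inst)


# ---------------------------------------------------------------------------
# sentence splitting


def split_sentences(text: str, terminators: str = ".!?") -> list[str]:
    """Split text on sentence-ending punctuation.

    Terminators are kept with their sentence; empty segments are discarded
    and a trailing segment without a terminator is retained.
    """
    out: list[str] = []
    buf: list[str] = []
    for ch in text:
        buf.append(ch)
        if ch in terminators:
            seg = "".join(buf).strip()
            if seg.strip(terminators + " "):
                out.append(seg)
            buf = []
    tail = "".join(buf).strip()
    if tail.strip(terminators + " "):
        out.append(tail)
    return out


def instance_sentences(instance: TaskInstance) -> list[list[str]]:
    """Sentences of a task instance as token lists.

    Utterance boundaries always act as sentence boundaries; cleaned
    utterance text is additionally split on internal terminators.
    """
    sentences: list[list[str]] = []
    for utt in instance.utterances:
        for seg in split_sentences(utt.text):
            toks = [t.strip(_PUNCT_STRIP) for t in seg.split()]
            toks = [t for t in toks if t]
            if toks:
                sentences.append(toks)
    return sentences


# ---------------------------------------------------------------------------
# CoNLL-U


def read_conllu(path: str | Path) -> list[ParsedSentence]:
    """Read a CoNLL-U file, skipping comments, multiword ranges, empty nodes."""
    path = Path(path)
    sentences: list[ParsedSentence] = []
    rows: list[ParseToken] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip():
            if rows:
                _append_sentence(sentences, rows, path)
                rows = []
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise CorpusFormatError(f"{path}:{lineno}: expected >= 8 columns")
        tid = cols[0]
        if "-" in tid or "." in tid:
            continue  # multiword-token range / empty node
        try:
            rows.append(
                ParseToken(
                    index=int(tid),
                    form=cols[1],
                    upos=cols[3],
                    head=int(cols[6]),
                    deprel=cols[7],
                )
            )
        except ValueError as exc:
            raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc
    if rows:
        _append_sentence(sentences, rows, path)
    return sentences


def _append_sentence(out: list[ParsedSentence], rows: list[ParseToken], path: Path) -> None:
    # re-index contiguously in case multiword rows were skipped
    remap = {tok.index: i + 1 for i, tok in enumerate(rows)}
    fixed = [
        replace(tok, index=remap[tok.index], head=0 if tok.head == 0 else remap.get(tok.head, -1))
        for tok in rows
    ]
    try:
        out.append(ParsedSentence(fixed))
    except CorpusFormatError as exc:
        raise CorpusFormatError(f"{path}: sentence {len(out) + 1}: {exc}") from exc


def write_conllu(sentences: Iterable[ParsedSentence], path: str | Path) -> None:
    path = Path(path)
    lines: list[str] = []
    for i, sent in enumerate(sentences, 1):
        lines.append(f"# sent_id = {i}")
        lines.append("# text = " + " ".join(sent.forms()))
        for tok in sent.tokens:
            lines.append(
                "\t".join(
                    [
                        str(tok.index),
                        tok.form,
                        "_",
                        tok.upos,
                        "_",
                        "_",
                        str(tok.head),
                        tok.deprel,
                        "_",
                        "_",
                    ]
                )
            )
        lines.append("")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# embedding tables


def load_embedding_table(path: str | Path) -> TableEmbeddingSource:
    """Load a whitespace-delimited text vector table (word then floats)."""
    path = Path(path)
    table: dict[str, np.ndarray] = {}
    dim: int | None = None
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        word, vals = parts[0], parts[1:]
        if dim is None:
            dim = len(vals)
            if dim == 0:
                raise CorpusFormatError(f"{path}:{lineno}: no vector components")
        elif len(vals) != dim:
            raise CorpusFormatError(
                f"{path}:{lineno}: expected {dim} components, got {len(vals)}"
            )
        try:
            table[word] = np.array([float(v) for v in vals])
        except ValueError as exc:
            raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc
    if not table:
        raise CorpusFormatError(f"{path}: empty embedding table")
    return TableEmbeddingSource(table)


def write_embedding_table(table: Mapping[str, np.ndarray], path: str | Path) -> None:
    path = Path(path)
    lines = [
        w + " " + " ".join(f"{x:.8f}" for x in np.asarray(v))
        for w, v in table.items()
    ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# corpus directory layout


@dataclass
class LoadedCorpus:
    """A corpus read back from its on-disk layout.

    Layout: ``transcripts/<pid>.cha`` (CHAT-like), ``parses/<instance>.conllu``,
    ``embeddings.txt`` (optional), ``metadata.csv`` (optional; columns
    participant_id, group, dataset, severity).
    """

    transcripts: list[Transcript]
    parses: dict[str, list[ParsedSentence]]
    source: TableEmbeddingSource | None
    metadata: "object | None"  # pandas.DataFrame when present

    def instances(self) -> list[TaskInstance]:
        return [i for t in self.transcripts for i in t.task_instances]

    def severity_of(self) -> dict[str, float]:
        return {
            t.participant_id: t.severity
            for t in self.transcripts
            if t.severity is not None
        }


def read_corpus_dir(path: str | Path, opts: PreprocessOptions | None = None) -> LoadedCorpus:
    """Load a corpus directory written by the generator (or hand-assembled)."""
    import pandas as pd

    path = Path(path)
    tdir = path / "transcripts"
    if not tdir.is_dir():
        raise CorpusFormatError(f"{path}: no transcripts/ directory")
    transcripts = [
        read_chat_transcript(f, opts) for f in sorted(tdir.glob("*.cha"))
    ]
    parses: dict[str, list[ParsedSentence]] = {}
    pdir = path / "parses"
    if pdir.is_dir():
        for f in sorted(pdir.glob("*.conllu")):
            parses[f.stem] = read_conllu(f)
    source = None
    if (path / "embeddings.txt").exists():
        source = load_embedding_table(path / "embeddings.txt")
    metadata = None
    if (path / "metadata.csv").exists():
        metadata = pd.read_csv(path / "metadata.csv")
    return LoadedCorpus(transcripts, parses, source, metadata)


# ---------------------------------------------------------------------------
# cleaned-transcript JSON export


def instance_to_dict(inst: TaskInstance) -> dict:
    return {
        "instance_id": inst.instance_id,
        "participant_id": inst.participant_id,
        "task_id": inst.task_id,
        "task_type": inst.task_type,
        "utterances": [u.tokens for u in inst.utterances],
        "word_count": inst.word_count,
        "repetition_count": inst.repetition_count,
        "incomplete_count": inst.incomplete_count,
        "filler_count": inst.filler_count,
        "symbol_count": inst.symbol_count,
    }


def write_cleaned_json(transcripts: Iterable[Transcript], path: str | Path) -> None:
    payload = [
        {
            "participant_id": t.participant_id,
            "group": t.group,
            "dataset": t.dataset,
            "severity": t.severity,
            "task_instances": [instance_to_dict(i) for i in t.task_instances],
        }
        for t in transcripts
    ]
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")
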