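"""Zero-shot transcript classification harness.

An instruction-tuned language model can be prompted to assign a speech
transcript to a diagnostic category without any task-specific training.
This module implements the protocol around such a model: prompt
construction (a system message with the classification instructions —
optionally *guided* by typical speech characteristics of the target
groups — and a user message containing the task description and the
cleaned transcript), stateless per-instance invocation (the model context
is reset before each prediction), label parsing with a single retry,
task-level accuracy bookkeeping split by task type, and a summary of
participant severity scores grouped by predicted class.

The model itself is behind the :class:`GenerationBackend` contract; the
package ships deterministic scripted backends for testing and an HTTP
adapter skeleton for any local text-generation server.  Greedy decoding
(temperature 0) is the default for reproducibility.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .corpus_io import TaskInstance

logger = logging.getLogger(__name__)

DEFAULT_GUIDANCE = {
    "WA": (
        "fluent but semantically unstable speech; frequent immediate word "
        "repetitions; word-finding difficulty with incomplete words; "
        "simplified sentence structure; pronoun-heavy reference"
    ),
    "SSD": (
        "grammatically complex sentences with tangential or loosely "
        "connected ideas; gradual topic drift across sentences; "
        "noun-heavy, low-repetition output"
    ),
    "HCA": "coherent, well-organised speech with few disfluencies",
    "HCS": "coherent, well-organised speech with few disfluencies",
}

PARSE_OK = "ok"
PARSE_RETRY = "fallback"
PARSE_FAIL = "unparsable"
FAILED = "failed"


@dataclass(frozen=True)
class PromptSpec:
    contrast: tuple[str, str]
    guided: bool = False
    label_tokens: tuple[str, str] | None = None
    guidance: Mapping[str, str] = field(default_factory=lambda: DEFAULT_GUIDANCE)
    template_id: str = "v1"
    label_aliases: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = self.labels
        if len(set(l.lower() for l in labels)) != 2 or not all(labels):
            raise ValueError(f"label tokens must be two distinct nonempty strings: {labels}")

    @property
    def labels(self) -> tuple[str, str]:
        return self.label_tokens if self.label_tokens else self.contrast


class GenerationBackend(Protocol):
    """Text-generation contract: stateless between calls."""

    def generate(self, system_text: str, user_text: str, **options) -> str: ...


class ScriptedBackend:
    """Deterministic mock driven by a responder function of the prompts."""

    def __init__(self, responder: Callable[[str, str], str]):
        self._responder = responder

    def generate(self, system_text: str, user_text: str, **options) -> str:
        return self._responder(system_text, user_text)


class ConstantBackend:
    """Always answers with the same text."""

    def __init__(self, text: str):
        self._text = text

    def generate(self, system_text: str, user_text: str, **options) -> str:
        return self._text


class HTTPBackend:
    """Minimal adapter for a local OpenAI-style chat-completions server.

    Sends {"messages": [...], "temperature": 0} to ``url`` and expects
    ``choices[0].message.content`` in the JSON reply.  Each call opens a
    fresh connection, so no conversational state can leak between
    predictions.
    """

    def __init__(self, url: str, model: str | None = None, timeout: float = 120.0):
        self.url = url
        self.model = model
        self.timeout = timeout

    def generate(self, system_text: str, user_text: str, **options) -> str:
        import urllib.request

        payload = {
            "messages": [
                {"role": "system", "content": system_text},
                {"role": "user", "content": user_text},
            ],
            "temperature": options.get("temperature", 0),
        }
        if self.model:
            payload["model"] = self.model
        req = urllib.request.Request(
            self.url,
            data=json.dumps(payload).encode(),
            headers={"Content-Type": "application/json"},
        )
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            body = json.loads(resp.read())
        return body["choices"][0]["message"]["content"]


def oracle_backend(corpus_instances: Sequence[tuple[TaskInstance, str]], spec: "PromptSpec") -> ScriptedBackend:
    """Mock that always answers the true label, keyed on the built prompt."""
    answers = {
        build_prompt(inst, spec)[1]: label for inst, label in corpus_instances
    }
    return ScriptedBackend(lambda system, user: answers[user])


# ---------------------------------------------------------------------------
# prompts


def _load_template(name: str) -> str:
    return resources.files("speechmark.templates").joinpath(f"{name}.txt").read_text()


def build_prompt(instance: TaskInstance, spec: PromptSpec) -> tuple[str, str]:
    """System and user messages for one task instance.

    The user message is the brief task description followed by the
    cleaned transcript, one utterance per line.  Deterministic: the same
    instance and spec always produce identical prompts.
    """
    label_a, label_b = spec.labels
    if spec.guided:
        template = _load_template("guided")
        system = template.format(
            label_a=label_a,
            label_b=label_b,
            guidance_a=spec.guidance.get(label_a, "no description available"),
            guidance_b=spec.guidance.get(label_b, "no description available"),
        )
    else:
        template = _load_template("unguided")
        system = template.format(label_a=label_a, label_b=label_b)
    description = instance.task_description
    if not description:
        logger.debug("instance %s has no task description; generic fallback", instance.instance_id)
        description = "The speaker responded to a spontaneous speech task."
    lines = [f"Task given to the speaker: {description}", "", "Transcript:"]
    lines += [u.text for u in instance.utterances]
    return system, "\n".join(lines)


def parse_label(output_text: str, label_tokens: Sequence[str],
                aliases: Mapping[str, Sequence[str]] | None = None) -> tuple[str | None, str]:
    """Case-insensitive search for exactly one label token in the output.

    Returns (label, status): status ``ok`` when exactly one label (or one
    of its aliases) occurs, ``unparsable`` when none or both occur.
    """
    text = output_text.lower()
    found: list[str] = []
    for label in label_tokens:
        tokens = [label] + list((aliases or {}).get(label, ()))
        if any(t.lower() in text for t in tokens):
            found.append(label)
    if len(found) == 1:
        return found[0], PARSE_OK
    return None, PARSE_FAIL


# ---------------------------------------------------------------------------
# runner


@dataclass
class InstancePrediction:
    instance_id: str
    participant_id: str
    task_type: str
    true_label: str
    predicted: str | None
    raw_output: str
    status: str  # ok | fallback | unparsable | failed


@dataclass
class ZeroShotResult:
    spec: PromptSpec
    predictions: list[InstancePrediction]

    def _accuracy(self, preds: Sequence[InstancePrediction]) -> tuple[float | None, int, int]:
        parsed = [p for p in preds if p.status in (PARSE_OK, PARSE_RETRY)]
        unparsable = sum(1 for p in preds if p.status in (PARSE_FAIL, FAILED))
        if not parsed:
            return None, 0, unparsable
        correct = sum(1 for p in parsed if p.predicted == p.true_label)
        return correct / len(parsed), len(parsed), unparsable

    def accuracy_table(self) -> pd.DataFrame:
        """Accuracy for open-ended tasks, picture tasks, and all tasks.

        The denominator counts parsed instances only; unparsable and
        failed instances are reported alongside.
        """
        rows = []
        for scope in ("open_ended", "picture", "all"):
            preds = (
                self.predictions
                if scope == "all"
                else [p for p in self.predictions if p.task_type == scope]
            )
            acc, n, bad = self._accuracy(preds)
            rows.append(
                {"tasks": scope, "accuracy": acc, "n_scored": n, "n_unparsable": bad}
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "contrast": list(self.spec.contrast),
            "guided": self.spec.guided,
            "template_id": self.spec.template_id,
            "accuracy": self.accuracy_table().to_dict(orient="records"),
            "predictions": [vars(p) for p in self.predictions],
        }


def run_zeroshot(
    instances: Sequence[tuple[TaskInstance, str]],
    spec: PromptSpec,
    backend: GenerationBackend,
    *,
    max_retries: int = 1,
) -> ZeroShotResult:
    """Classify every task instance independently.

    ``instances`` pairs each task instance with its true group label
    (only instances of the contrast's groups are classified).  Backend
    failures mark the instance failed and the run continues.  Unparsable
    outputs get one retry, then are excluded from accuracy denominators.
    """
    preds: list[InstancePrediction] = []
    for inst, true_label in instances:
        if true_label not in spec.contrast:
            continue
        system, user = build_prompt(inst, spec)
        raw = ""
        label: str | None = None
        status = PARSE_FAIL
        for attempt in range(1 + max_retries):
            try:
                raw = backend.generate(system, user)
            except Exception as exc:  # noqa: BLE001 - backend errors must not kill the run
                logger.warning("backend failure on %s: %s", inst.instance_id, exc)
                status = FAILED
                break
            label, status = parse_label(raw, spec.labels, spec.label_aliases)
            if status == PARSE_OK:
                if attempt > 0:
                    status = PARSE_RETRY
                break
        preds.append(
            InstancePrediction(
                instance_id=inst.instance_id,
                participant_id=inst.participant_id,
                task_type=inst.task_type,
                true_label=true_label,
                predicted=label,
                raw_output=raw,
                status=status,
            )
        )
    return ZeroShotResult(spec=spec, predictions=preds)


# ---------------------------------------------------------------------------
# severity by predicted class


def severity_by_prediction(
    result: ZeroShotResult,
    severity: Mapping[str, float],
) -> pd.DataFrame:
    """Severity-score summary per predicted class.

    Task instances are partitioned by predicted label; for each partition
    the participant severity scores are summarised (n, mean, quartiles).
    A location-shift row reports the difference of medians between the
    two predicted classes (first label minus second).  Instances without
    a severity score or without a parsed prediction are excluded and
    counted in the ``n_excluded`` attribute of the returned frame.
    """
    rows = []
    excluded = 0
    groups: dict[str, list[float]] = {label: [] for label in result.spec.labels}
    for p in result.predictions:
        if p.predicted is None or p.participant_id not in severity:
            excluded += 1
            continue
        groups[p.predicted].append(float(severity[p.participant_id]))
    for label, vals in groups.items():
        if not vals:
            logger.warning("no instances predicted as %s; summary absent", label)
            continue
        arr = np.asarray(vals)
        q1, q2, q3 = np.percentile(arr, [25, 50, 75])
        rows.append(
            {"predicted": label, "n": len(arr), "mean": float(arr.mean()),
             "q1": q1, "median": q2, "q3": q3}
        )
    frame = pd.DataFrame(rows)
    label_a, label_b = result.spec.labels
    if set(frame.get("predicted", [])) == {label_a, label_b}:
        med = frame.set_index("predicted")["median"]
        frame.attrs["median_difference"] = float(med[label_a] - med[label_b])
    frame.attrs["n_excluded"] = excluded
    return frame
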