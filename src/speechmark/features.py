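"""Task-level feature extraction: one named feature vector per task instance.

Joins the three feature families — syntactic (9 complexity metrics + 63
deprel + 17 POS frequencies), semantic (8 similarity features) and
repetition/incomplete rates — into a tidy table with one row per task
instance.  Missing values (a feature whose defining pair set is empty,
e.g. window-3 similarity on a two-sentence task) are NaN, to be imputed
downstream from training folds only.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import EmbeddingSource, ParsedSentence, TaskInstance, Transcript
from .semantic import incomplete_frequency, repetition_frequency, semantic_profile
from .syntactic import complexity_metrics

SYNTACTIC_SET = "syntactic"
SEMANTIC_SET = "semantic"
REPETITION_SET = "repetition"
FEATURE_SETS = (SYNTACTIC_SET, SEMANTIC_SET, REPETITION_SET)


def extract_task_features(
    instance: TaskInstance,
    parses: Sequence[ParsedSentence] | None,
    source: EmbeddingSource | None,
    feature_sets: Iterable[str] = FEATURE_SETS,
    *,
    include_incomplete: bool = True,
    window_mode: str = "lag",
) -> dict[str, float]:
    """Compute the requested feature blocks for one task instance."""
    feature_sets = set(feature_sets)
    unknown = feature_sets - set(FEATURE_SETS)
    if unknown:
        raise ValueError(f"unknown feature sets: {sorted(unknown)}")
    out: dict[str, float] = {}
    if SYNTACTIC_SET in feature_sets:
        if parses is None:
            raise ValueError(f"no parses supplied for instance {instance.instance_id}")
        out.update(complexity_metrics(parses).to_dict())
    if SEMANTIC_SET in feature_sets:
        if source is None:
            raise ValueError(
                f"semantic features requested but no embedding source given "
                f"(instance {instance.instance_id})"
            )
        prof = semantic_profile(instance, source, window_mode=window_mode)
        out.update({k: (math.nan if v is None else v) for k, v in prof.to_dict().items()})
    if REPETITION_SET in feature_sets:
        out["repetitionFreq"] = repetition_frequency(instance)
        if include_incomplete:
            out["incompleteFreq"] = incomplete_frequency(instance)
    return out


def task_feature_table(
    transcripts: Sequence[Transcript],
    parses: Mapping[str, Sequence[ParsedSentence]] | None,
    source: EmbeddingSource | None,
    feature_sets: Iterable[str] = FEATURE_SETS,
    **kwargs,
) -> pd.DataFrame:
    """Tidy per-task-instance feature table for a whole corpus.

    Columns: participant_id, group, dataset, task_id, task_type,
    word_count, then one column per feature.
    """
    rows: list[dict] = []
    for transcript in transcripts:
        for inst in transcript.task_instances:
            inst_parses = None
            if parses is not None:
                inst_parses = parses.get(inst.instance_id)
            feats = extract_task_features(inst, inst_parses, source, feature_sets, **kwargs)
            rows.append(
                {
                    "instance_id": inst.instance_id,
                    "participant_id": inst.participant_id,
                    "group": transcript.group,
                    "dataset": transcript.dataset,
                    "task_id": inst.task_id,
                    "task_type": inst.task_type,
                    "word_count": inst.word_count,
                    **feats,
                }
            )
    return pd.DataFrame(rows)


ID_COLUMNS = (
    "instance_id", "participant_id", "group", "dataset",
    "task_id", "task_type", "word_count",
)


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLUMNS]
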