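"""Participant-level feature tables per classification contrast.

Classification is performed at participant level: task-instance feature
vectors are averaged within each participant, weighted by the cleaned word
count of the task instance (longer speech samples yield more reliable
estimates).  A feature missing in some tasks is aggregated over the tasks
where it is present; it stays missing only when absent everywhere.

Contrasts spanning the two source datasets (patient-vs-patient and
control-vs-control comparisons) are restricted to open-ended speech tasks,
because different picture-description prompts are less comparable across
corpora than different open-ended prompts.  Within-dataset contrasts use
all tasks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_SETS, feature_columns

logger = logging.getLogger(__name__)

TASK_FILTERS = ("auto", "all", "open_ended_only")


@dataclass
class FeatureTable:
    """Participant-level rows for one contrast, plus provenance."""

    data: pd.DataFrame  # participant_id, group, dataset, weight + features
    feature_names: list[str]
    contrast: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    @property
    def y(self) -> pd.Series:
        return self.data["group"]

    @property
    def participants(self) -> pd.Series:
        return self.data["participant_id"]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)
        sidecar = Path(path).with_suffix(".provenance.json")
        sidecar.write_text(json.dumps(self.provenance, indent=1, default=str))


def aggregate_participant(
    task_vectors: Sequence[tuple[Mapping[str, float], float]],
) -> dict[str, float]:
    """Word-count-weighted mean of task-level feature maps.

    ``task_vectors`` is a list of (feature map, word_count).  Per feature,
    the weighted mean is taken over the tasks where the feature is present
    (not NaN); if every weight among those tasks is zero the unweighted
    mean is used (logged).  A feature absent in all tasks stays NaN.
    """
    if not task_vectors:
        raise ValueError("aggregate_participant requires at least one task vector")
    names: list[str] = []
    for fmap, _ in task_vectors:
        for k in fmap:
            if k not in names:
                names.append(k)
    out: dict[str, float] = {}
    for name in names:
        vals, weights = [], []
        for fmap, w in task_vectors:
            v = fmap.get(name)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            vals.append(float(v))
            weights.append(float(w))
        if not vals:
            out[name] = float("nan")
        elif sum(weights) > 0:
            out[name] = float(np.average(vals, weights=weights))
        else:
            logger.warning("all task weights zero for feature %r; unweighted mean", name)
            out[name] = float(np.mean(vals))
    return out


def build_feature_table(
    task_table: pd.DataFrame,
    contrast: Sequence[str],
    feature_sets: Iterable[str] = FEATURE_SETS,
    task_filter: str = "auto",
) -> FeatureTable:
    """Assemble the participant-level table for one contrast.

    ``task_table`` is the tidy per-task-instance table from
    :func:`speechmark.features.task_feature_table`.  ``task_filter="auto"``
    resolves to ``open_ended_only`` when the contrast's groups span more
    than one dataset, else ``all``.
    """
    contrast = tuple(contrast)
    if len(contrast) not in (2, 3):
        raise ValueError(f"contrast must name 2 or 3 groups, got {contrast}")
    if task_filter not in TASK_FILTERS:
        raise ValueError(f"task_filter must be one of {TASK_FILTERS}")
    present = set(task_table["group"])
    missing = [g for g in contrast if g not in present]
    if missing:
        raise ValueError(f"contrast group(s) {missing} absent from table")

    sub = task_table[task_table["group"].isin(contrast)].copy()
    datasets = set(sub["dataset"])
    if task_filter == "auto":
        task_filter = "open_ended_only" if len(datasets) > 1 else "all"
    if task_filter == "open_ended_only":
        sub = sub[sub["task_type"] == "open_ended"]
        if sub.empty:
            raise ValueError("no open-ended task instances for this contrast")

    cols = _select_feature_columns(task_table, feature_sets)
    rows = []
    for pid, grp in sub.groupby("participant_id", sort=True):
        vectors = [
            (row[cols].to_dict(), float(row["word_count"]))
            for _, row in grp.iterrows()
        ]
        agg = aggregate_participant(vectors)
        rows.append(
            {
                "participant_id": pid,
                "group": grp["group"].iloc[0],
                "dataset": grp["dataset"].iloc[0],
                "weight": float(grp["word_count"].sum()),
                **agg,
            }
        )
    data = pd.DataFrame(rows)
    n_missing = int(data[cols].isna().sum().sum())
    provenance = {
        "contrast": list(contrast),
        "feature_sets": sorted(set(feature_sets)),
        "task_filter": task_filter,
        "n_participants": len(data),
        "n_missing_cells": n_missing,
        "imputation": "training-fold median at model time" if n_missing else "none needed",
    }
    return FeatureTable(data=data, feature_names=cols, contrast=contrast, provenance=provenance)


def _select_feature_columns(task_table: pd.DataFrame, feature_sets: Iterable[str]) -> list[str]:
    feature_sets = set(feature_sets)
    unknown = feature_sets - set(FEATURE_SETS)
    if unknown:
        raise ValueError(f"unknown feature sets: {sorted(unknown)}")
    all_cols = feature_columns(task_table)
    syntactic = [
        c for c in all_cols
        if c in ("LEN", "LXD", "MDD", "NDD", "ADJD", "LEFT", "MOD", "CLS", "CLL")
        or c.startswith(("dep_", "pos_"))
    ]
    semantic = [
        c for c in all_cols
        if c in ("wordAvg", "wordVar")
        or c.startswith(("sbertAvgWindow", "sbertVarWindow"))
    ]
    repetition = [c for c in all_cols if c in ("repetitionFreq", "incompleteFreq")]
    out: list[str] = []
    if "syntactic" in feature_sets:
        out += syntactic
    if "semantic" in feature_sets:
        out += semantic
    if "repetition" in feature_sets:
        out += repetition
    if not out:
        raise ValueError(f"no feature columns found for sets {sorted(feature_sets)}")
    return out
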