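"""Quantify how the elicitation prompt shifts coherence features.

Different open-ended prompts systematically move connectedness features
even within one group, so diagnostic claims must control for task. The
analysis runs within-participant Wilcoxon signed-rank tests per group and
feature, with Benjamini-Hochberg FDR correction across the family.
"""

import speechmark as sm

# the second task's prompt induces stronger topic drift for everyone
config = sm.SyntheticCorpusConfig(
    profiles=(sm.ssd_like_profile(), sm.control_profile("HCS", "psychiatric")),
    n_participants_per_group=25,
    tasks_per_participant=(("HowsItGoing", "open_ended"), ("AboutYourself", "open_ended")),
    task_overrides={"AboutYourself": {"topic_jump_prob": 0.45}},
    words_per_task=150,
    seed=5,
)
corpus = sm.generate_corpus(config)
task_table = sm.task_feature_table(
    corpus.transcripts, corpus.parses, corpus.embedding_source
)

res = sm.task_effect_analysis(
    task_table,
    features=("wordAvg", "wordVar"),
    tasks=("AboutYourself", "HowsItGoing"),
    groups=("SSD", "HCS"),
)
print(res.table.to_string(index=False))
print(
    "\n-> 'reject' marks group x feature pairs whose task difference survives\n"
    "   FDR control: the drift-inducing prompt lowers mean word similarity in\n"
    "   both groups - a task effect, not a diagnostic effect."
)
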