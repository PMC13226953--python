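"""Classify participants with balanced leave-one-participant-out CV.

The protocol: features aggregated to participant level (word-count
weighted), groups balanced by undersampling, 3 undersampling draws x 5
CV repeats = 15 run accuracies, representative confusion matrix, and
additive tree-path attribution for feature importance.
"""

import speechmark as sm

config = sm.SyntheticCorpusConfig(
    profiles=(sm.wa_like_profile(), sm.ssd_like_profile()),
    n_participants_per_group=12,
    words_per_task=150,
    seed=11,
)
corpus = sm.generate_corpus(config)
task_table = sm.task_feature_table(
    corpus.transcripts, corpus.parses, corpus.embedding_source
)

# cross-dataset contrast -> open-ended tasks only, automatically
table = sm.build_feature_table(task_table, ("WA", "SSD"))
print(f"participant table: {len(table.data)} rows, task filter: "
      f"{table.provenance['task_filter']}")

spec = sm.ExperimentSpec(contrast=("WA", "SSD"), model="rf", base_seed=0)
result = sm.run_experiment(spec, table)

print(f"\nmean accuracy over {len(result.runs)} runs: "
      f"{result.mean_accuracy:.3f} (SD {result.accuracy_sd:.3f}, "
      f"chance {result.chance_level:.2f})")
print("\nrepresentative confusion matrix (rows = true class):")
print(result.confusion())
print("\ntop 5 features by mean |attribution|:")
report = result.attribution_report(top_k=5)
for name in report.top_features:
    print(f"  {name:20s} {report.scores[name]:.4f}")
print("\n-> repetition rate, adjacent-word similarity and the noun/pronoun\n"
      "   mixture carry the group contrast, mirroring how they were generated.")
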