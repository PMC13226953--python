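"""Zero-shot classification of task instances via a generation backend.

Each task instance is classified independently (context reset between
predictions) from a two-part prompt: system instructions (optionally
guided by typical group characteristics) and the cleaned transcript.
Scripted mock backends make the harness testable without any model; the
HTTPBackend adapter plugs in any local chat-completions server.
"""

import speechmark as sm
from speechmark.zeroshot import ConstantBackend, oracle_backend

config = sm.SyntheticCorpusConfig(
    profiles=(sm.ssd_like_profile(), sm.control_profile("HCS", "psychiatric")),
    n_participants_per_group=6,
    words_per_task=80,
    seed=3,
)
corpus = sm.generate_corpus(config)
spec = sm.PromptSpec(contrast=("SSD", "HCS"), guided=True)

instances = [
    (inst, t.group) for t in corpus.transcripts for inst in t.task_instances
]
system, user = sm.build_prompt(instances[0][0], spec)
print("system prompt:\n" + system)
print("user prompt (first 2 lines):\n" + "\n".join(user.splitlines()[:2]))

result = sm.run_zeroshot(instances, spec, oracle_backend(instances, spec))
print("\naccuracy with a truth-answering mock backend:")
print(result.accuracy_table().to_string(index=False))

severity = sm.severity_by_prediction(result, corpus.severity_of())
print("\nseverity scores by predicted class:")
print(severity.to_string(index=False))
print(f"median difference (SSD - HCS): {severity.attrs['median_difference']:.2f}")
print("\n-> instances predicted as the disordered class carry higher severity\n"
      "   scores: predictions track graded disturbance, not just the label.")

baseline = sm.run_zeroshot(instances, spec, ConstantBackend("SSD"))
print("\nconstant-label baseline accuracy (= class prevalence):")
print(baseline.accuracy_table().to_string(index=False))
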