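"""Generate a small synthetic speech corpus with two contrasted groups.

The generator emulates the contrasts clinical speech data exhibit —
repetition rate, topic drift, sentence structure, severity scores —
without any natural-language resource: every downstream stage can be
exercised on it.
"""

import speechmark as sm

config = sm.SyntheticCorpusConfig(
    profiles=(sm.wa_like_profile(), sm.ssd_like_profile()),
    n_participants_per_group=3,
    words_per_task=60,
    seed=42,
)
corpus = sm.generate_corpus(config)

print(f"participants: {len(corpus.transcripts)}, task instances: {len(corpus.instances())}")
pid = corpus.transcripts[0].participant_id
print(f"\nfirst lines of {pid}'s transcript (raw CHAT-like text):")
print("\n".join(corpus.chat_texts[pid].splitlines()[:8]))

inst = corpus.transcripts[0].task_instances[0]
print(f"\ncleaned words: {inst.word_count}, repetitions removed: {inst.repetition_count}, "
      f"incomplete words removed: {inst.incomplete_count}")
print("-> the aphasia-like profile injects ~80 immediate repetitions per 1000 words;")
print("   the cleaning pipeline removes them but keeps the count as a feature.")

# write the corpus as plain-text files (transcripts, CoNLL-U parses,
# embedding table, metadata) for the CLI stages:
sm.write_corpus(corpus, "scratch/example_corpus")
print("\nwrote scratch/example_corpus/ (transcripts/, parses/, embeddings.txt, metadata.csv)")
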