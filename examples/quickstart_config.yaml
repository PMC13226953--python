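# Small end-to-end configuration: two datasets x patient/control groups.
# Run with:  speechmark run-all --config examples/quickstart_config.yaml \
#                --out scratch/quickstart --seed 7
seed: 7
simulate:
  profiles:
    - {preset: wa_like, name: WA, dataset: aphasia}
    - {preset: control, name: HCA, dataset: aphasia}
    - {preset: ssd_like, name: SSD, dataset: psychiatric}
    - {preset: control, name: HCS, dataset: psychiatric}
  n_participants_per_group: 4
  words_per_task: 60
  vocab_size: 200
  n_topics: 6
  embed_dim: 32
  tasks_per_participant:
    - [AboutYourself, open_ended]
    - [CatRescue, picture]
classify:
  - contrast: [WA, SSD]
    model: rf
    n_undersample_runs: 1
    n_cv_repeats: 1
  - contrast: [SSD, HCS]
    model: nb
    n_undersample_runs: 3
    n_cv_repeats: 5
task_effects:
  features: [wordAvg, wordVar]
  tasks: [AboutYourself, CatRescue]
  groups: [SSD, HCS]
zeroshot:
  contrast: [WA, SSD]
  guided: false
  backend: oracle
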