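# Demo cohort for the CLI:
#   nleeg simulate --spec examples/cohort_demo.yaml --out runs/cohort
#   nleeg extract  --in runs/cohort --out runs/tables
#   nleeg stats    --features runs/tables/features.tsv --psd runs/tables/psd.tsv \
#                  --ratings runs/cohort/ratings.tsv --out runs/reports
# (or: nleeg run-all --spec examples/cohort_demo.yaml --out runs)
seed: 7
groups:
  - {name: control, n_subjects: 4}
  - {name: schizophrenia, n_subjects: 4}
  - {name: mTBI, n_subjects: 4}
  - {name: stroke, n_subjects: 4}
  - {name: coma, n_subjects: 4}
design:
  stimuli: [barking, laughter]
  n_epochs: 2
  epoch_s: 15.0
  rest_s: 40.0
  include_rest_open: false
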