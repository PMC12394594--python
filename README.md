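# emotrans

Analyses of emotion-transition likelihood ratings and their relation to
loneliness, packaged as a tested, reusable pipeline:

- **Core data model** (`emotrans.data`) — long-format rating records
  (participant × target × from-state × to-state × 0–100 rating),
  20-item loneliness-scale scoring with configurable reverse keys,
  transition enumeration, and endpoint-valence classification
  (PP/PN/NP/NN, neutral-involving excluded from valence analyses).
- **Synthetic multi-study generator** (`emotrans.simulate`) — seven-study
  suites with plantable, recoverable effect structure (atypicality,
  anchoring, volatility, anti-positivity, rating compression), so every
  downstream stage is validated by parameter and sign recovery.
- **Typicality and IS-RSA** (`emotrans.typicality`) — per-participant
  typicality indices (include-self or leave-one-out), intersubject
  similarity matrices, and an Anna-Karenina IS-RSA with Mantel
  permutation inference.
- **Mixed models** (`emotrans.lmm`) — a from-scratch Gaussian linear mixed
  model with crossed random intercepts, profiled REML estimation, Wald
  inference, and simple slopes. Fits with tens of thousands of rows run in
  well under a second via the Woodbury identity on the random-level inner
  matrix.
- **Study-level analyses** (`emotrans.analyses`) — ground-truth prediction
  accuracy, self-anchoring, valence-category simple slopes, and rating-SD
  confidence, each yielding effect sizes for pooling.
- **Meta-analysis** (`emotrans.meta`) — random-effects pooling with REML
  between-study variance, Wald CIs, I², and Fisher-z handling of
  correlation-type effects.
- **Pipeline + CLI** (`emotrans.pipeline`, `emotrans.cli`) — end-to-end
  orchestration with deterministic seeding, effects CSV, meta JSON, forest
  CSVs, a run manifest, and a sign-pattern report.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (design counts,
oracle equivalence against closed forms and independent implementations,
type-I control simulations, sign/parameter recovery, determinism); the
simulation-heavy tests take a few minutes.

## CLI

```bash
# write a synthetic seven-study suite (CSV pairs + provenance JSON)
emotrans simulate --seed 1 --out synthetic_data --n-scale 0.25

# full pipeline: simulate, analyze every study, pool, report
emotrans run-all --seed 1 --out emotrans_out --n-perm 1000 --n-scale 0.25

# analyze one study from the CSV schema
emotrans analyze --ratings r.csv --participants p.csv --config study.yaml --seed 1

# pool an effects CSV and print the result table
emotrans meta --effects emotrans_out/effects.csv --out meta.json
emotrans report --meta-json meta.json
```

Input schema (UTF-8 CSV): ratings
`study_id,participant_id,target,from_state,to_state,rating`; participants
`study_id,participant_id,item_1..item_20` (or `loneliness_total`)
`,completion_fraction`. The study config (YAML/JSON) lists the emotion set
with valences plus `include_same_state`, `reverse_keys`,
`completion_threshold`.

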