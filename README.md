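# audiomem

Simulation and permutation-based analysis of a spatialized-sound pairing
game (an audio adaptation of the card game "Memory") played on a 5×5
speaker board. The package provides:

- **`audiomem.task_model`** — the board and game rules: a 5×5 grid whose
  centre block is a reserved feedback speaker, two difficulty conditions
  (4 pairs / 8 apertures and 12 pairs / 24 apertures), seeded random
  sound-pair assignments, and validated attempt-by-attempt session state.
- **`audiomem.indices`** — three behavioral indices computed from a
  session's attempt log: cumulative **score** (+10 per match, −1/−2 for
  re-touching one/two previously touched blocks in a miss), mean
  **number of attempts** between a pair's full discovery and its match,
  and the **audio-anchor** count of consecutive attempts starting at the
  same block.
- **`audiomem.agents`** — parameterized synthetic agents (encoding
  probability, per-attempt forgetting, anchor propensity, exploration
  policy) and a cohort generator emulating a two-group × two-condition
  within-subject design with an age covariate. Group defaults are
  documented calibration constants, not estimates of human behavior.
- **`audiomem.permstats`** — a from-scratch permutation-inference stack:
  Welch-t permutation tests (exhaustive or Monte-Carlo with the add-one
  correction), two-factor mixed-design permutation ANOVA with partial
  η², a distance-based multivariate permutation test (Gower-centered
  pseudo-F partition, sequential sums of squares, optional covariate and
  strata), Cohen's d and Bonferroni correction.
- **`audiomem.cli_io`** — YAML configuration, plain-text serialization
  (CSV / JSONL logs, YAML layouts), worked-example fixtures, and the
  end-to-end pipeline.

## Command-line usage

```sh
# simulate a synthetic cohort (index table + per-session logs + manifest)
audiomem simulate --out out/ --seed 1

# score session logs into the per-session index table
audiomem score out/logs/*.csv --out indices.csv

# run the permutation cascade (multivariate test -> follow-up ANOVAs ->
# Bonferroni-corrected post hoc t-tests)
audiomem analyze out/cohort.csv --out results/ --n-perm 5000 --seed 1

# pretty-print a saved results table
audiomem report results/results.csv

# write the canonical worked-example logs
audiomem fixtures --out fixtures/
```

A YAML config (`audiomem --config config.yaml …`) can set every knob:
group parameter distributions, board aperture coordinates per condition,
permutation counts, seeds, permutation scheme (`raw` or Freedman–Lane
`residual`), strata restriction and the distance choice. The schema is
documented in `audiomem/cli_io/config.py`. All outputs are reproducible
byte-for-byte from the config seeds.

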