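# seqmeg

Detection of fast spontaneous sequences of state representations in
sensor-level neurophysiological (MEG-like) time series.

The package implements an end-to-end analysis for a six-state sequential
decision task:

1. **Task & behavior** (`seqmeg.task`) — the six-state two-action maze
   (deterministic "up"/"down" transitions, drifting rewards in [−5, +5]
   pence, per-trial "neg" states that flip the sign of the running total),
   trial/session generation, and four behavioral choice models (Plan, Qfirst,
   Qall, Greedy) with maximum-likelihood fitting and BIC comparison.
2. **Synthetic sensor data** (`seqmeg.synth`) — localizer epochs with evoked
   responses peaking 200 ms post-onset, and planning-period recordings with
   planted sequential reactivations (configurable state-to-state lag, default
   40 ms; forward or reverse along the task graph) on temporally
   autocorrelated AR(1) sensor noise, plus a ground-truth event log.
3. **Preprocessing** (`seqmeg.preprocess`) — anti-aliased decimation (e.g.
   600 → 100 Hz) and 0.5 Hz first-order IIR high-pass (zero-phase by
   default).
4. **Decoding** (`seqmeg.decode`) — one lasso logistic regression model per
   state trained on the single 200 ms localizer sample (134 slopes + an
   unpenalized intercept at the default sensor count), constrained balanced
   cross-validation with label-shuffle maximal-statistic thresholds,
   time-point-wise sigmoid decoding into state-probability matrices, and
   leave-one-subject-out penalty selection by group sequenceness.
5. **Sequenceness** (`seqmeg.seqness`) — the lagged forward/reverse
   cross-correlation statistic (forward − reverse per lag), its length-n
   generalization, pairwise (edge-level) sequenceness, state-identity
   permutation nulls built from relabeling equivalence classes of the
   transition matrix (the default graph yields 30 classes → 28 shuffles →
   two-tailed level 1/28 ≈ 0.036) with per-lag and global maximal-statistic
   thresholds, a sample-order shuffle baseline (demonstrably
   anticonservative on autocorrelated data), and an explicit-loop oracle
   used for verification.
6. **Group statistics** (`seqmeg.stats`) — the random-intercept model
   (ML, profiled variance ratio, Wald p; optional fixed-slope covariate),
   the chosen-vs-unchosen tuple contrast, subject-mean OLS regression, and
   the one-way ANOVA across directed task edges.
7. **Pipeline & CLI** (`seqmeg.pipeline`, `seqmeg.cli`) — seeded,
   deterministic orchestration from a single YAML config.

## CLI

```bash
seqmeg run-all --outdir out/ --seed 1            # full synthetic pipeline
seqmeg simulate --outdir out/sim --seed 1        # write HDF5 recordings
seqmeg preprocess --infile in.h5 --outfile out.h5 --target-fs 100
seqmeg decode --localizer loc.h5 --planning p1.h5 --planning p2.h5 --outdir out/
seqmeg seqness --probabilities out/probabilities.csv --outfile curves.csv
seqmeg permtest --probabilities out/probabilities.csv --outfile null.json
seqmeg behavior --sessions out/sessions.csv --outfile behavior.json
seqmeg report --indir out/
```

A YAML config (see `seqmeg.pipeline.PipelineConfig` for all keys and
defaults) can be passed with `--config`; `--seed` overrides the config seed.
Reruns with the same seed produce byte-identical summary tables.

## Conventions

- Task states are 1-indexed (`S1`..`S6`) in the task/behavior layer; decoded
  probability matrices and transition matrices use 0-based columns
  (state k ↔ column k−1).
- The transition matrix `T` is row-stochastic with 0.5 on each of the two
  out-edges per state. Forward sequenceness at lag Δ is the mean over states
  of the correlation between `(X @ T)` at time t and `X` at t + Δ; a planted
  forward chain yields positive forward sequenceness.
- The default graph is the circulant {i→i+1, i→i+4 (mod 6)}; it can be
  overridden via `edge_spec` in configs.
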