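# gazeseq

Sequential-context analysis of diagnostic reader studies from gaze
scanpaths. The package quantifies visual search behavior by the
Minkowski–Bouligand (box-counting) fractal dimension of gaze
trajectories, builds lag-structured datasets pairing each diagnostic
decision with the behavior, decisions and case properties of up to five
preceding cases, and tests/predicts sequential dependence via
autocorrelation functions, multifactor fixed-effects ANOVA, and
per-reader leave-one-case-out random-forest classification. A simulator
generates complete synthetic reader studies with an injectable
sequential context bias so the whole pipeline can be exercised and
validated end to end.

## Modules

| module | role |
|---|---|
| `gazeseq.synthetic_study` | case sets (exact pathology quotas), reader tiers, fixation–saccade scanpaths with a complexity knob, decisions with tunable pull toward the previous decision (`bias_alpha`) |
| `gazeseq.gaze_io` | tab-separated gaze/readings/cases/FD tables, dual-display scanpath assembly into one global frame |
| `gazeseq.fractal` | scanpath rasterization, dyadic box counting, log–log OLS fractal dimension |
| `gazeseq.sequence_context` | rating → group/ordinal codings, density groupings, session-aware lag-pair datasets, biased-ACF with ±1.96/√n bands |
| `gazeseq.variance_analysis` | partial (drop-one) F tests for continuous/categorical/interaction terms |
| `gazeseq.prediction` | leave-one-case-out prediction, support-weighted f-score, marginal random-chance baseline, per-lag/per-tier reports |
| `gazeseq.pipeline` / `gazeseq.cli` | end-to-end orchestration with config echo and a hash manifest |

## CLI

Each stage is a subcommand of `gazeseq`:

```sh
gazeseq simulate --readers 3,4,3 --cases 100 --seed 1 --out-dir out/
gazeseq fd out/gaze.tsv --grid-size 512 --out out/fd.tsv
gazeseq pairs out/readings.tsv out/cases.tsv out/fd.tsv --lag 2 --out out/pairs.tsv
gazeseq acf out/readings.tsv out/cases.tsv out/fd.tsv --max-lag 20 --out out/acf.tsv
gazeseq anova out/readings.tsv out/cases.tsv out/fd.tsv --terms F0,P0,D1 --lag 1 --out out/anova.tsv
gazeseq predict out/readings.tsv out/cases.tsv out/fd.tsv --lags 0,1,2 --out out/predict.tsv
gazeseq run --config config.yaml
```

`gazeseq run` executes every stage from a YAML config (sections `seed`,
`out_dir`, `study`, `fractal`, `pairs`, `acf`, `anova`, `predict`),
echoes the config into every output header, and writes a
`manifest.json` with a SHA-256 hash per output file. Identical configs
produce byte-identical bundles.

## Conventions

- Coordinates are pixels, origin top-left, y down; dual displays are
  concatenated side by side into one global frame.
- Ratings {none, 2, 3, 4A, 4B, 4C, 5} map to groups N/B/M and to ordinal
  codes 0–6 (a 6-level merge of {4C, 5} is available).
- Densities 1–4 group as fatty / fibroglandular / heterogeneous-dense.
- Lag-pair rows never span a session boundary; each break restarts the
  lag structure.
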