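# gazeflow

Scanpath transition analysis for eye-tracking studies of medical image
interpretation. The package segments a stimulus into areas of interest (AOIs)
in two ways — researcher-defined lead rectangles (top-down) and a uniform
grid whose cell size is derived from DBSCAN clustering of the fixation points
(bottom-up) — builds AOI-to-AOI transition matrices per participant group,
and tests group differences with a Hellinger-distance statistic against a
participant-shuffling permutation null. Conventional repeated-measures
statistics (per-stimulus McNemar on interpretation accuracy, paired Wilcoxon
on fixation count and duration, Bonferroni control) and a full synthetic
study simulator are included, so every stage is testable end to end without
any external data.

## Modules

| Module | Purpose |
| --- | --- |
| `gazeflow.io` | Read/validate/write fixation tables (TSV/CSV), stimulus layouts and answer keys (YAML), result tables |
| `gazeflow.aoi` | DBSCAN clustering, k-distance knee eps selection, grid derivation, lead AOIs, fixation-to-AOI assignment |
| `gazeflow.transitions` | Transition count matrices, Markov chains, flattened joint distributions, Hellinger distance |
| `gazeflow.permutation` | Observed group distance + permutation null, add-one p-values, standardized deviation d |
| `gazeflow.clinical` | Response scoring against an answer key, McNemar, Wilcoxon signed-rank, Bonferroni |
| `gazeflow.simulate` | Synthetic studies: group Markov chains over AOIs, truncated within-AOI scatter, log-normal durations, counterbalanced order groups |
| `gazeflow.pipeline` / `gazeflow.cli` | One-config orchestration with deterministic per-cell seeding; `gazeflow` console command |

## CLI

```bash
# generate a synthetic study (fixations.tsv, responses.tsv, layout.yaml, answer_key.yaml)
gazeflow simulate --seed 1 --out study/

# derive the data-driven grid AOIs
gazeflow segment --fixations study/fixations.tsv --layout study/layout.yaml \
    --scheme grid --out aois.csv

# full analysis: permutation tests per stimulus x scheme x comparison,
# plus accuracy (McNemar) and fixation-metric (Wilcoxon) tables
gazeflow analyze --fixations study/fixations.tsv --layout study/layout.yaml \
    --responses study/responses.tsv --answer-key study/answer_key.yaml \
    --scheme lead --scheme grid --comparison order --comparison accuracy \
    --n-perm 10000 --seed 1 --out results/

# type-I error / power study of the permutation test
gazeflow calibrate --seed 1 --replicates 50 --out calibration.csv
```

`permutation_results.csv` has one row per (stimulus, scheme, comparison)
with columns `n1, n2, M, SD, d, Hd, p, n_perm, seed`: the observed Hellinger
distance `Hd`, the null mean `M` and standard deviation `SD`, the
null-standardized deviation `d = (Hd - M) / SD`, and the add-one empirical
p-value (never exactly 0; the floor is `1 / (n_perm + 1)`).

## Conventions

- Coordinates are screen pixels, origin top-left, y increasing downward;
  all rectangles are half-open `[x0, x1) x [y0, y1)`.
- Transitions are consecutive fixation pairs within one trial only;
  self-transitions count. Group distributions are grand-total-normalized
  flattened transition matrices pooled over the group's participants.
- Permutations shuffle participants while preserving the original group
  sizes; every randomized quantity is reproducible from a master seed.
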