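# cooppool

Group-testing toolkit for pooled screening of cooperative compound
interactions. Instead of measuring all C(n, 2) candidate pairs of a
library one by one, the library is pooled into blocks of a covering
design so that every pair shares at least one pool; positive pools are
then resolved to the responsible pair (or lone active compound, or
triple) with far fewer follow-up measurements than the naive approach.

The package provides:

- **`cooppool.pool_design`** — covering-design construction (randomized
  greedy with restarts, and a swap local search), coverage certification,
  and the Schönheim lower bound. Supports pair and triple coverage and
  coverage multiplicities.
- **`cooppool.deconvolution`** — two deconvolution engines for a positive
  pool: *iterative sectioning* (recursive splitting into three overlapping
  subsets of size ⌈2k/3⌉ whose statuses are propagated by logical
  implication, so redundant measurements are pruned) and *one-step
  signature decoding* (a fixed family of subsets whose positive/negative
  pattern uniquely identifies a lone active pair). Handles multiple pairs
  per pool, single quenchers, and three-way interactions.
- **`cooppool.assay_model`** — a phenomenological luminescence-quenching
  model: additive Stern–Volmer background from inactive compounds,
  threshold calls, Monte-Carlo false-positive rates per pool size, and the
  expected-experiment trade-off used to choose the pool size.
- **`cooppool.simulator`** — end-to-end synthetic campaigns: plant
  cooperative entities, build a design, screen every pool through the
  assay model, deconvolve the positives with either engine (or test all
  pairs in parallel), and report experiment counts and recovery metrics.
- **`cooppool.gcms_diff`** — reaction-vs-controls comparison of GC-MS
  peak tables: greedy retention-time matching with optional spectral
  cosine veto, flagging prominent new peaks, batch processing over a
  (pair × acceptor) grid.

## Command line

```sh
# build a pooling design for 100 compounds in pools of 10 covering all pairs
cooppool design --n 100 --k 10 --t 2 --restarts 1000 --seed 1 -o design.json

# certify coverage of an existing design
cooppool verify --design design.json

# resolve a positive pool, answering +/- at the prompt
# (or replay recorded outcomes with --outcomes outcomes.jsonl)
echo '[0,1,2,3,4,5,6,7,8,9]' > group.json
cooppool deconvolve --group group.json --mode iterative --find-all

# simulate screening campaigns from a YAML config
cooppool simulate --config campaign.yaml -o results/

# tabulate the pool-size trade-off at a 0.5% per-pair hit rate
cooppool tradeoff --n 100 --p 0.005 --k-min 4 --k-max 20 -o tradeoff.csv

# flag new peaks in a reaction run relative to its controls
cooppool gcms-diff --reaction rxn.csv --controls blank.csv ctrl.csv -o report.json
```

Example campaign config:

```yaml
n: 100
k: 10
seed: 7
replicates: 20
strategies: [iterative, onestep, parallel]
truth: {n_pairs: 15, hub_bias: 0.0}
model: {threshold: 60.0, readout_noise_sd: 0.0}
```

## File formats

- Libraries: CSV/TSV with `id,label`.
- Designs: JSON `{"n":…,"k":…,"t":…,"lam":…,"blocks":[[…],…]}`; plate-map
  CSV (`block,position,id,label`) for bench use.
- Deconvolution session logs: JSON lines, one record per query
  `{"set":[…],"result":"+|-","level":…,"implied":…}`.
- Peak tables: CSV `run_id,rt_min,intensity[,mz_bin_0,…]`.
- Campaign configs: YAML; results as JSON plus a CSV summary.
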