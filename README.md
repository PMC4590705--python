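# mutexsl

Inference of candidate synthetic-lethal (SL) gene pairs from mutual
exclusivity of somatic alteration events in tumour cohorts, with
validation against cell-line essentiality screens.

The pipeline:

1. **Event calling** (`mutexsl.io_events`) — reads gene × sample TSV
   matrices (GISTIC-discretized copy number in {−2…2}; expression
   z-scores), calls four binary event types (AMP/DEL at ±2, UP/DOWN at
   |z| ≥ 2), and merges them into composite *loss* (DEL ∪ DOWN) and
   *gain* (AMP ∪ UP) profiles over the pooled union of genomic and
   expression samples.
2. **Exclusivity screen** (`mutexsl.mutex`) — for each query gene A
   (loss) against each gene B (gain or loss), computes the
   hypergeometric lower-tail p-value of the observed co-occurrence
   count (log-space sum, numerically exact for extreme exclusivity),
   filters, ranks by p-value, and summarizes per-gene-A proportions.
3. **Essentiality validation** (`mutexsl.validation`) — given a
   GARP-style gene × cell-line score table (lower = more essential) and
   cell-line deficiency annotations: top-quartile χ² enrichment of
   candidates, Spearman agreement between ME ranks and reverse GE ranks
   (K − essentiality rank, top-K only), one-way ANOVA vs a control
   line, and a paired t-test between isogenic lines.
4. **Synthetic data** (`mutexsl.simulate`) — seeded generators for
   cohorts with planted mutually exclusive pairs (joint probability
   ε·f_a·f_b; ε = 1 independent, ε = 0 perfectly exclusive, split
   across genomic/expression channels and partially disjoint assay
   subsets) and for essentiality screens with partner scores depressed
   in deficient lines, plus truth-aware recovery metrics.
5. **CLI** (`mutexsl.cli`) — subcommands `call-events`, `screen`,
   `validate`, `simulate`, `run-all`.

## CLI quick start

Everything below runs offline on simulated data:

```sh
# simulate a cohort with one perfectly exclusive planted pair + a screen
mutexsl simulate --seed 7 --n-samples 500 \
    --planted QA:0.3:QB:0.3:0.0 \
    --n-screen-genes 1000 --deficient DEF:QA \
    --out-dir out/sim

# call events and write the cohort manifest
mutexsl call-events -i sim:out/sim/gistic.tsv:out/sim/zscores.tsv \
    --out-dir out/events

# screen a gene-A panel (one symbol per line) and rank candidates
printf 'QA\n' > out/panel.txt
mutexsl screen -i sim:out/sim/gistic.tsv:out/sim/zscores.tsv \
    --panel out/panel.txt --alpha 1.0 --out-dir out/screen

# validate the ranked candidates against the essentiality screen
mutexsl validate --candidates out/screen/candidates.pooled.tsv \
    --garp out/sim/garp.tsv --annotations out/sim/annotations.tsv \
    --k 250 --out-dir out/validate

# or all of the above in one step
mutexsl run-all --seed 7 --planted QA:0.3:QB:0.3:0.0 \
    --deficient DEF:QA --out-dir out/run
```

Real cohorts are supplied as the same TSV dialect (first column gene
symbols, header row sample IDs); multiple cohorts are passed as repeated
`-i COHORT:CN_PATH[:EXPR_PATH]` specs and screened pooled or per-cohort
(`--scope`). Exit codes: 0 success, 2 configuration error, 3 I/O error,
4 data-validation error.

## Notes on conventions

- "At least two standard deviations" is read inclusively (|z| ≥ 2);
  copy-number events require the exact ±2 codes.
- Samples assayed on both platforms appear once in the pooled universe;
  a sample lacking an assay is event-free for that assay.
- Ranking ties break by descending n_b, then gene B symbol.
- GE ranks use K = 5000 by default while enrichment uses a configurable
  quartile fraction (0.25); the two are deliberately independent knobs.
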