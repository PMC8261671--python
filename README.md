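# mrbpome

Differential mRNA-binding proteome (mRBPome) analysis from RNA-interactome
capture (RIC) protein quantification tables.

Given protein-level peak-area tables from one or more label-free
quantification methods (e.g. TOP3 / iBAQ / LFQ), the pipeline:

1. **filters and normalizes** — minimum-peptide filter, per-sample
   total-area normalization to 10⁶ with a pseudocount-1 log2 layer, a
   ≥3-fold enrichment filter against poly(A)-competition controls, and a
   replicate-presence filter;
2. **calls differential RNA association** — the average pairwise log2
   fold-change between unpaired replicates, a resampling null built by
   shuffling the pooled pairwise fold-changes (10,000 random experiments),
   an FDR-vs-threshold grid in 0.5 steps, and a linear FDR ~ fold-change
   model used to assign an FDR percentage to every protein (significant at
   FDR ≤ 5%);
3. **integrates methods** — consensus calls for proteins selected by at
   least two quantification methods with concordant direction;
4. **set statistics** — log-space hypergeometric overlap tests and
   over-representation analysis (GMT gene sets, minimum category size,
   Benjamini–Hochberg adjustment);
5. **paralog specialization** — classification of paralog pairs against an
   RBP/differential set, Mann–Whitney abundance comparison of one-in-pair
   members vs their partners, and ORA of unique differential paralogs
   against all paired proteins;
6. **synthetic data** — a fully seeded generator producing RIC-like
   multi-method datasets (3 biological replicates × 2 conditions plus
   matched competition controls, lognormal abundance, method-specific
   effect scaling, abundance-dependent dropout) with per-protein ground
   truth, used for recovery and calibration testing.

## CLI

All stages are exposed under one executable:

```sh
mrbpome simulate --n-proteins 1000 --seed 1 --out-dir sim/
mrbpome preprocess --quant sim/quant_TOP3.tsv --design sim/design_TOP3.tsv \
    --out filtered.tsv --report stages.tsv
mrbpome differential --quant sim/quant_TOP3.tsv --design sim/design_TOP3.tsv \
    --n-experiments 10000 --seed 1 --out diff_TOP3.tsv --null-model null.json
mrbpome consensus diff_TOP3.tsv diff_LFQ.tsv diff_iBAQ.tsv --out consensus.tsv
mrbpome enrich --foreground fg.txt --gmt sets.gmt --background bg.txt --out ora.tsv
mrbpome overlap --set1 a.txt --set2 b.txt --universe-size 6725
mrbpome paralogs --pairs pairs.tsv --rbp-set rbp.txt \
    --differential-set diff.txt --abundance abundance.tsv --out-dir paralogs/
mrbpome run --config config.yaml --out-dir results/
```

`run` is driven by one YAML config, e.g.

```yaml
seed: 1
simulation: {n_proteins: 1000}        # or `inputs:` with per-method files
# inputs:
#   TOP3: {quant: top3.tsv, design: top3_design.tsv}
#   LFQ:  {quant: lfq.tsv,  design: lfq_design.tsv}
preprocess: {min_peptides: 2, ratio: 3.0, min_reps: 2}
differential: {n_experiments: 10000, tail_mode: signed, fdr_cutoff: 5.0}
consensus: {min_methods: 2}
```

Identical config + seed ⇒ byte-identical result files.

### Tail modes

`tail_mode: signed` (default) builds the FDR grid on thresholds −10..10 and
uses a mirrored model for negative fold-changes; it stays calibrated when
total-area normalization shifts the null off zero (strong one-sided changes
alter column totals). `tail_mode: folded` uses |fold-change| on a 0..10
grid. The linear model is fit on the grid's transition region by default
(`fit_region: full` fits the whole grid).

## File formats

* **Quantification table** — TSV with `protein_id`, one raw-area column per
  sample, optional `<sample>.peptides` columns (or one `peptides` column
  applied to all samples). Blank cells read as 0 ("not identified").
* **Sample design** — TSV with `sample_id, condition, assay, replicate,
  method`; condition ∈ {untreated, stress}, assay ∈ {biological,
  competition_control}.
* **Gene sets** — standard GMT. **Paralog pairs** — two-column TSV.

To use MaxQuant `proteinGroups.txt`, export the `Majority protein IDs`
column as `protein_id`, one `iBAQ <sample>` / `LFQ intensity <sample>`
column per declared sample, and `Peptides <sample>` as
`<sample>.peptides`; vendor files are not parsed directly.

## Tests and acceptance

```sh
python -m pytest tests/            # unit + property + acceptance suites
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` covers: the published-scale hypergeometric
worked example, normalization conservation, oracle equivalence of the FDR
grid / OLS fit / hypergeometric tail / exact Mann–Whitney against
independent brute-force implementations, null calibration and parameter
recovery on simulated data, the hand-computed 8-protein filter fixture,
and byte-level run determinism.
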