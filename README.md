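# mircontext

Gene-context confounder analysis for miRNA/siRNA high-throughput
perturbation experiments.

High-throughput small-RNA perturbation experiments (microarray or
proteomics readouts of transfection or inhibition assays) are confounded by
target-site-independent, gene-context features: 3' UTR length and
conservation, mRNA expression level, competition with endogenous miRNAs,
target dilution, and platform-specific detection bias. `mircontext`
implements, as a tested and reusable pipeline:

- **canonical seed-site targeting** — stringent 8mer / 7mer-m8 / 7mer-A1
  site detection on 3' UTRs and classification of genes into
  T±Endo / NT±Endo groups against the top expressed endogenous miRNA
  families (`mircontext.seed`);
- **gene-context features** — UTR length / conservation / expression
  binning (empirical quantiles or fixed published cuts), sliding-window
  promoter CpG classification, housekeeping/developmental labels
  (`mircontext.features`);
- **non-parametric subgroup testing** — one-sided Wilcoxon / KS
  down-regulation tests per subgroup, per-sample variants with sample-level
  scores, experiment-vs-sample trend counts and correlations, the
  endogenous-competition test, and feature-characteristic tests
  (`mircontext.grouptests`);
- **binding, dilution, and platform bias** — AGO-binding calls from mapped
  read depths with long-vs-short Fisher enrichment, per-sample
  target-dilution correlation, and down-regulation enrichment across
  expression subgroups with per-platform linear fits (`mircontext.clip`);
- **linear models** — min-max-normalized factor construction
  (ln3, cs3, exp, #site_m, #endo_m, #site_s, p_ma, e_oe, ts_score), OLS
  main-effect and all-second-order-interaction fits (`mircontext.regression`);
- **synthetic studies** — a fully seeded generator of genomes, small RNAs
  with planted (and verified) seed sites, and perturbation experiments with
  planted knockdown, competition, dilution, and platform-bias effects, so
  every stage runs and is validated without any external data
  (`mircontext.simulate`);
- **I/O** — FASTA, tab-delimited gene × sample matrices, BED5 read
  positions, ranking and per-site score tables, plus log-ratio
  preprocessing (log2→log10, inhibition negation) (`mircontext.io`,
  `mircontext.datamodel`).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence of the seed scanner, exact rank-test enumeration, null
calibration of all subgroup tests, planted-effect sign recovery by the
regression, platform-bias and competition reproduction, and the
published trend-correlation values). The statistical acceptance tests run
simulations and take a few minutes.

## Command line

Every analysis is exposed through one CLI:

```sh
# generate a complete synthetic study with planted effects
mircontext simulate --seed 1 --n-genes 2000 --n-samples 5 --out-dir study/

# compute and discretize the gene-context features
mircontext features --utr-fasta study/utrs.fa \
    --conservation study/conservation.tsv --expression study/genes.tsv \
    --promoter-fasta study/promoters.fa --out study/features.tsv

# subgroup down-regulation scan (heatmap input)
mircontext scan --utr-fasta study/utrs.fa --rna-fasta study/exo_rnas.fa \
    --table study/log_ratios.tsv --platform microarray --assay transfection \
    --features-table study/features.tsv --out study/scan.tsv
```

Other subcommands: `test` (alias of `scan`), `competition`, `parclip`,
`dilution`, `enrichment`, `regress`, and `trend`. Run
`mircontext COMMAND --help` for the flags. Outputs are tab-delimited,
deterministically sorted, and stamped with a version/seed/config-hash
header comment. Exit codes: 0 success, 1 data error, 2 usage error.

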