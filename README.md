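# pancub

Pangenome codon-usage-bias analysis. `pancub` stratifies genes by their
presence across strains (strain-specific → core), quantifies codon usage
bias per gene with four measures (CAI, CDC, Wright's Nc and the
composition-corrected Nc′, plus RSCU and positional GC contents), and
diagnoses the relative contributions of mutation and selection per gene
set:

- **ENC-plot** — deviation of estimated Nc from the mutation-only
  expectation `2 + x + 29/(x² + (1−x)²)` at `x = GC3`, with a threshold
  sweep of deviated fractions per set;
- **neutrality-plot** — OLS regression of GC12 on GC3 (slope 1 = pure
  mutation pressure, 0 = full selective constraint);
- **correspondence analysis** of the gene × 59-codon RSCU matrix with
  Spearman correlations between axis 1 and configurable factors;
- **CUB–expression correlation** per gene set;
- **tRNA–RSCU cosine similarity** per gene set (strict Watson–Crick
  mapping; wobble rules opt-in);
- one-way ANOVA summaries across sets.

A synthetic pangenome generator with known mutation/selection ground truth
(presence spectrum, per-gene GC3 pressure, selection coupled to presence
and expression, matching tRNA table) stands in for real genome collections
and backs the test suite end to end.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (analytic fixed
points, brute-force oracle equivalence, 20-seed parameter recovery,
structural checks); the rest are per-module unit and property tests.

## CLI

```sh
# generate a synthetic pangenome with ground truth
pancub simulate --out-dir sim/ --n-strains 10 --n-families 500 --seed 1

# run the full analysis on it
pancub all --fasta-dir sim/ --out-dir out/ \
    --clusters sim/clusters.tsv --expression sim/expression.tsv \
    --trna sim/trna.tsv

# or drive everything from a flat key=value config file
pancub all --config run.cfg
```

Other subcommands: `cluster` (built-in greedy stand-in clusterer),
`partition`, `metrics`, `diagnose`. Inputs are per-strain CDS multi-FASTA
files plus optional tab-separated tables (ortholog clusters, expression,
tRNA copy numbers by anticodon, an exclusion id list). All reports are
TSV; a JSON run manifest records versions, seed and parameters. Exit
codes: 0 success, 2 validation error, 3 I/O error.

Key defaults follow the published conventions: genes shorter than 100
codons are excluded, the ENC-plot deviation threshold is 0.15, and at 26
strains the presence classes are 1 / 2–9 / 10–17 / 18–25 / 26.

## Layout

```
src/pancub/
  genetic_code.py       genetic-code bookkeeping (families, 59 informative codons)
  io_formats.py         FASTA/TSV readers and writers with validation
  pangenome.py          clustering stand-in, presence classes, rarefaction curves
  codon_metrics.py      RSCU, CAI, Nc, Nc', CDC, rescaling, cosine similarity
  selection_analysis.py ENC-plot, neutrality-plot, COA, correlations, ANOVA
  synthetic_data.py     seeded pangenome generator with ground truth
  cli.py                click commands and the pipeline orchestrator
```
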