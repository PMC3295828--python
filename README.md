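# syserr

Detection, characterization and correction of **systematic base-call errors**
in aligned short-read sequencing data.

Systematic errors are genomic positions at which base-call errors from many
independent reads pile up far beyond the background rate, typically
concentrated on a single sequencing direction and enriched for a GGT sequence
context with a T>G substitution. They are easily mistaken for heterozygous
sites (or rare variants, or RNA-editing events). This package provides:

- **`syserr.pileup`** — SAM ingestion, per-site pileups split by read
  orientation, overlapping mate-pair detection, and classification of the two
  calls each overlapping pair makes at a position into *reference-pair* /
  *SNP-pair* / *error-pair* (plus a *discordant* category), with a background
  per-pair error-rate estimator.
- **`syserr.stats`** — detection statistics and summaries: expected
  error-proportion histogram under binomial error, exact binomial site
  p-values with Bonferroni annotation, a quality-conditioned Poisson-binomial
  p-value computed by an O(n²) dynamic program, a chi-square
  strand-directionality screen for datasets without overlapping mates, motif
  counts around annotated sites, substitution spectra, a GGT-restricted
  annotation, and closed-form replication/strand-coincidence probabilities.
- **`syserr.syscall`** — a logistic-regression classifier that partitions
  candidate heterozygous sites into *heterozygous sites* vs *systematic
  errors* from six features (two upstream reference bases and the site base
  in the error-enriched direction, the per-direction mismatch-proportion
  difference and magnitude, and a paired-t statistic contrasting site vs
  neighboring quality scores). Training uses high-certainty labels from
  overlapping mate pairs; classification works on single-end data. Models
  are trained by a hand-rolled Newton/IRLS maximum-likelihood fit (ridge
  fallback under perfect separation) at several read-subsampling fractions,
  giving a coverage-keyed model bank; prediction picks the model nearest the
  dataset's mean coverage and thresholds the posterior at 0.5.
- **`syserr.simdata`** — a deterministic read simulator (FASTA + aligned SAM
  + truth table) with planted heterozygous sites and systematic-error sites
  (one-strand error concentration, GGT-context preference, T>G-biased
  substitutions, locally depressed quality scores), used by the test suite so
  no external data is needed.
- **`syserr.cli`** — the `syserr` command-line tool.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked closed
forms, FWER control, DP-vs-enumeration equivalence, histogram conservation,
classifier benchmarks across coverages, parameter recovery, replication,
determinism).

## CLI

```sh
# simulate a dataset with planted sites
syserr simulate --out sim/ --seed 1 --genome-length 50000 --coverage 40 \
    --n-het 30 --n-syserr 30 --frag-min 90 --frag-max 130

# pair-based binomial/Bonferroni annotation of systematic errors
syserr annotate --sam sim/reads.sam --ref sim/ref.fa --out annotated.tsv \
    --bed-out significant.bed

# chi-square directionality screen (no overlapping mates required)
syserr scan --sam sim/reads.sam --ref sim/ref.fa --out scan.tsv

# train the coverage-stratified classifier bank, then classify candidates
syserr train --sam sim/reads.sam --ref sim/ref.fa --out-model bank.json --seed 5
syserr classify --sam sim/reads.sam --ref sim/ref.fa --model-bank bank.json \
    --out-prefix calls
# -> calls.heterozygous.tsv, calls.systematic_errors.tsv, calls.rejects.tsv

# characterization report: proportion histogram, motif counts, spectrum
syserr report --sam sim/reads.sam --ref sim/ref.fa --out-prefix report
```

All user-facing coordinates are 1-based (0-based half-open internally); every
output starts with a `#` header recording the tool version, invocation and
parameters. Model banks are human-readable JSON.

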