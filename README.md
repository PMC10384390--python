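# mrscan

A two-sample Mendelian randomization (2SMR) toolkit for metabolite- and
molecular-trait epidemiology, built to run entirely offline on GWAS
summary-statistic files:

- **Summary-statistics I/O** — delimited tables (TSV/CSV, optionally
  gzipped) with configurable column mapping, validated into typed records
  (1-based coordinates, single-nucleotide biallelic variants by default).
- **Instrument selection** — genome-wide significance filter (default
  p < 5×10⁻⁸), MHC exclusion (chr6:26,000,000–34,000,000, closed interval),
  greedy LD clumping (default r² < 0.001 in a 10 Mb window), and proxy-SNP
  substitution (default r² ≥ 0.8) against an abstract LD-lookup contract fed
  by files or the simulator — no reference-panel downloads.
- **Harmonization** — three palindromic-SNP strategies: (1) assume forward
  strand, (2) infer strand from effect-allele frequencies with a
  configurable ambiguity window (default: drop EAF in [0.42, 0.58]),
  (3) drop all palindromic SNPs. Non-palindromic variants are reconciled by
  allele labels (swap / strand complement / both), and irreconcilable
  variants are dropped with an audit trail rather than raised.
- **Estimators** — Wald ratio, IVW (fixed and multiplicative random
  effects), Egger regression, weighted/simple median, weighted/simple mode;
  bootstrap SEs with mandatory seeds.
- **Sensitivity** — Cochran's Q, Egger intercept test, per-SNP
  directionality (Steiger) filtering, leave-one-out, and single-SNP
  analyses.
- **Phenome-wide scan** — batch 2SMR over an exposure × outcome grid with
  Bonferroni family-wise control and Miami-plot data export.
- **Literature triangulation** — overlap of exposure-side triple objects
  with outcome-side triple subjects, one-sided Fisher-exact enrichment, and
  network export (TSV + JSON).
- **Synthetic data** — paired exposure/outcome summary statistics under a
  linear IV model with configurable causal effect, pleiotropy and
  instrument strength, block-diagonal LD references, and planted-overlap
  triple fixtures.
- **Diagnostics** — forest, scatter, funnel and leave-one-out plots; every
  figure's numbers are also written as a plot-data TSV.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (estimator
oracles, type-I error and coverage calibration, harmonization truth table,
clumping brute-force equivalence, Steiger and triangulation checks, and a
family-wise error simulation).

## Command line

```bash
# simulate a fixture with known truth
mrscan simulate --n-snp 24 --theta -0.3 --seed 1 --out-dir fixtures/

# full single-pair analysis: tables + 4 diagnostic figures + audit bundle
mrscan run --exposure fixtures/exposure.tsv --outcome fixtures/outcome.tsv \
    --methods ivw_re,egger,weighted_median,weighted_mode --seed 1 \
    --out-dir results/run1

# individual stages
mrscan select-instruments --exposure exp.tsv --p-threshold 5e-8 \
    --clump-r2 0.001 --ld-ref ld.tsv --out instruments.tsv
mrscan harmonize --exposure exp.tsv --outcome out.tsv --mode 2 \
    --ambiguity-window 0.08 --out audit.tsv
mrscan sensitivity --exposure exp.tsv --outcome out.tsv --out sens.tsv

# phenome-wide scan over directories of summary-statistic files
mrscan phewas --exposures exp_dir/ --outcomes out_dir/ --alpha 0.05 \
    --out scan.tsv --miami-dir miami/

# semantic-triple triangulation
mrscan triangulate --exposure-triples exp_triples.tsv \
    --outcome-triples out_triples.tsv --out-dir network/

# family-wise threshold for a scan grid
mrscan bonferroni --n-exposures 825 --n-outcomes 236   # -> 2.57e-07
```

Summary-statistic files need columns for snp_id, chrom, pos,
effect_allele, other_allele, beta, se, pval (eaf and n optional); pass
`--column-map mapping.yaml` to translate other header dialects. Triple
tables use columns `subject predicate object local_count local_total
global_count global_total`. LD references are either a long
`snp_a snp_b r2 [aligned]` table or a square labeled r² matrix.

## Python API

```python
import mrscan as m

cfg = m.SimulationConfig(n_snp=50, theta=0.2, seed=1)
exposure, outcome, truth = m.simulate_sumstats(cfg)

instruments, audit = m.select_instruments(exposure, outcome=outcome)
h = m.harmonize_set(instruments, outcome, mode=2)
results = m.run_mr(h, ["ivw_re", "egger", "weighted_median"], seed=1)
report = m.sensitivity_report(h)
```
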