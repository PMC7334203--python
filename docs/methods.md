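# Methods

## Generative model of the assay

The simulator emulates the physical chain from serum to sequencer for a
bead-based, barcoded-scFv immunoassay. For sample *j* and marker (scFv
target) *k*:

1. **Abundance.** Control samples draw antigen abundance
   `A_{jk} ~ LogNormal(mu_k, sigma_k)` (natural-log parameters). Case
   samples multiply the same draw by `2^{e_k}`, where `e_k` is the
   per-marker effect in log2 units. Log-normality is the conventional model
   for serum-protein concentrations across individuals; the effect enters
   multiplicatively because differential abundance is a fold change.
2. **Capture.** With every barcoded antibody present in excess, the number
   of barcode molecules retained on the beads is
   `N_{jk} ~ Poisson(s · A_{jk})` with capture scale `s` (molecules per
   abundance unit, default 1). Antibody excess is what makes the expected
   captured count proportional to antigen amount — the linearity the whole
   readout rests on.
3. **PCR.** Each captured molecule is amplified through a Galton–Watson
   branching process: in each of `c` cycles (default 18, the assay's
   adapter-PCR program) every molecule duplicates independently with
   probability `p` (per-cycle efficiency, default 0.9), so
   `E[post-PCR] = N · (1+p)^c`. Modeling PCR stochastically rather than as
   a deterministic multiplier preserves the count overdispersion that makes
   the precision (CV) analysis meaningful. Above a configurable threshold
   (10^5 molecules) the per-cycle binomial is replaced by its normal
   approximation for speed; at `p = 1` the variance is zero, so the
   approximation stays exact (1 molecule × 18 perfect cycles = 2^18 =
   262 144).
4. **Sequencing.** A fixed read budget per sample (default 10^5) is
   allocated multinomially over markers in proportion to post-PCR molecule
   counts. Each read is the first `read_length` nt (default 54) of the
   marker's 68-nt oligo, insert-first, so the 8-nt tag occupies read
   positions 35–42. Substitutions are i.i.d. per base (default 10^-3).
   Qualities are two-level — Q37 by default, Q12 for a background fraction
   of bases (default 2%) and, with probability 0.9, at substituted
   positions — which is deliberately minimal: just enough structure to
   exercise the every-base-Q30 filter in both directions. A configurable
   fraction of reads (default 1%) carries the Casava-1.8 chastity-failure
   flag (`1:Y:0:INDEX`) in its header.

Every intermediate (true abundance, captured, post-PCR, reads emitted) is
written to a ledger, so the counting pipeline can be audited cell-for-cell.

Randomness is hierarchical: a master seed spawns independent per-sample
streams (`numpy` `SeedSequence.spawn`), so adding a sample never perturbs
another sample's reads, and identical configurations yield byte-identical
FASTQ files (gzip mtime pinned to 0).

### What the generator does not emulate

Indels, optical duplicates, index hopping, paired-end reads,
instrument-specific quality profiles, bead-saturation kinetics,
cross-reactive antibody binding, and batch effects are all out of model.
Passing tests therefore demonstrate the *pipeline's* correctness and the
statistical behaviour of the readout under idealized noise — not
performance on real instrument data, where error structure is richer and
antibody specificity is imperfect.

## Counting pipeline

Per read, in order: chastity filter (header flag `N` required; a missing
filter field counts as a pass by default), per-base quality filter, length
check (read must cover tag_end), tag extraction at 1-based positions
35–42, tag assignment. Each read increments exactly one accounting cell —
`assigned`, `chastity_failed`, `quality_failed`, `too_short`, or
`unassigned` — so accounting partitions the total exactly on every input;
the partition is asserted at the end of every counting run.

Decisions where the readout convention was genuinely open:

- **"over Q30"** is implemented as `>= 30` by default (standard Q30-filter
  usage) with a `strict_over` switch for the literal `> 30` reading; both
  boundary behaviours are tested. The filter covers the whole read by
  default, with a tag-region-only option for sensitivity studies.
- **Tag matching** is exact by default — the conservative reading of a
  tag-counting pipeline. A 1-mismatch mode exists but refuses to run on
  panels with minimum pairwise distance < 3, where correction would be
  ambiguous.
- **Unassigned tags** are retained in a top-N orphan-tag report per sample
  for contamination debugging.

Counting is single-pass, streaming, and order-independent: permuting input
reads leaves the count matrix unchanged, and merged partial runs equal a
single pass.

## Statistics

- **Median normalization:** sample *j* is scaled by `M / m_j`, `m_j` the
  sample's median count over scFvs, `M` the median of the `m_j`. This keeps
  values on the count scale, makes every sample's median exactly `M`, and
  is idempotent. A pseudocount of 1 precedes the log2 transform so
  zero counts (possible at low depth) stay finite.
- **Classification:** linear-kernel soft-margin SVM, cost 1, all features
  (no pre-selection). Leave-one-out: for each sample, fit on the others and
  record the held-out signed decision value. Features are z-scored with
  training-fold statistics only, eliminating the leakage that naive global
  scaling introduces. The *n* pooled decision values give one ROC; AUC is
  the tie-corrected Mann–Whitney statistic computed from midranks, which
  equals all-pairs enumeration with ties counted ½ (asserted against a
  brute-force oracle and scikit-learn in the tests).
- **PCA:** centered and unit-variance scaled by default (switchable);
  zero-variance features are dropped with a warning when scaling. The first
  3 components are reported for visualization.
- **Precision:** CV% = 100 · sd / mean per scFv across technical
  replicates, with the sample (n−1) standard deviation — the standard
  choice for 10 replicates — on median-normalized counts by default (raw
  optional). A zero mean leaves the CV undefined (NaN-flagged).

## Parameter defaults

| parameter | default | units / rationale |
|---|---|---|
| n_case / n_control | 10 / 10 | the assay's cohort test size |
| n_markers | 17 | panel size |
| abundance_mu | linspace(ln 10³, ln 10⁵) | three decades of captured-molecule scale across the panel |
| abundance_sigma | 0.5 | ln-scale SD ≈ 53% between-subject CV, realistic for serum proteins |
| capture_scale | 1.0 | molecules per abundance unit |
| PCR cycles / efficiency | 18 / 0.9 | cycle count from the assay protocol; efficiency a realistic per-cycle duplication probability |
| reads_per_sample | 10⁵ | typical per-sample share of a pooled mid-output run |
| sub_error_rate | 10⁻³ | order of Illumina substitution rates |
| q_hi / q_lo / q_lo_frac | 37 / 12 / 0.02 | two-level quality model |
| chastity_fail_rate | 0.01 | small, nonzero to exercise the filter |
| min_phred | 30 | every base ≥ Q30 |
| pseudocount / svm_cost | 1 / 1 | conventional defaults |

## Problem sizes used in tests and the acceptance script

FASTQ-level tests run small cohorts (2–4 samples, 600–2 000 reads/sample),
which fully exercises the read path; statistical studies (null calibration
over 50 cohorts, the power grid over 20 seeds × 4 effect sizes, precision
over 10 replicates × 3 depths) use the simulator's count-level fast path —
abundance → capture → PCR → multinomial read allocation — which produces
exactly the matrix the FASTQ route yields on an error-free channel, an
equality the counter's oracle test establishes separately. This keeps the
statistical studies at full depth (10⁵ reads/sample) without materializing
tens of millions of reads.

## Known limitations

- The barcode and scaffold sequences of any particular real panel are
  input data; the generator produces structurally equivalent panels, not
  the sequences of any published assay.
- The two-level quality model makes the every-base-Q30 pass rate a direct
  function of `q_lo_frac` (0.98⁵⁴ ≈ 34% at the defaults); real instrument
  pass rates vary along the read cycle.
- Simulated replicate CVs bottom out at the counting-noise floor
  (≈ 2–4% at 10⁵ reads/sample); real assays can beat this at high depth
  per marker and lose to it through liquid-handling variance.
- AUC confidence intervals, feature selection, multiclass staging, and
  batch correction are out of scope.
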