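# Methods

This note records the models, conventions and numerical choices behind
`isncrna`, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates and category attribution

All internal coordinates are 0-based half-open; GFF3 (1-based closed)
and wiggle (1-based) are converted at the reader/writer boundary so a
single convention holds everywhere else.

Every genomic position is attributed to exactly one of five categories:
ncRNA, exon, intron, pseudogene/repeat, or intergenic. Annotation layers
overlap (snoRNAs sit in introns, repeats inside genes), so attribution
uses a fixed precedence, by default `ncRNA > exon > intron >
pseudogene_repeat`. The order is a modelling choice, not a property of
the data, and is therefore config-overridable; ncRNA-first matches a
workflow whose object of study is the ncRNA complement. Attribution is
deliberately strand-blind — a read or position inside an annotation on
either strand takes that annotation's category — while the novelty
filter (below) is strand-aware. This pair of choices lets antisense
transcripts (e.g. a candidate antisense to an intron) be counted as
"intronic" in genomic summaries yet still be retained as novel.

## Coverage and multi-mapped reads

A read mapping to `n_hits` loci contributes `1/n_hits` to every base of
each placement, on the placement's strand. Coverage mass is therefore
conserved exactly: summed coverage equals summed read lengths (verified
to 1e-6 over 10,000 reads). Read-level genomic distributions weight each
placement by `1/n_hits` and attribute it by whole-placement
classification; nucleotide-level distributions count positions covered
on either strand once. Tracks are dense per-chromosome float vectors —
exact and simple at the megabase scales this package targets.

## Transfrags and the novelty filter

A transfrag is a maximal run of same-strand positions with coverage
greater than zero; no gap-joining is applied (a gap tolerance would be a
different model of transcript continuity and is intentionally absent —
the run definition keeps the calling equivalent to a trivially
verifiable linear scan, which the tests exploit).

Novelty filters, in order:

1. mean per-base coverage < 6 → rejected. "Coverage" is the **mean**
   over the run; the maximum is available by config
   (`coverage_stat="max"`) since either reading of a scalar per-transfrag
   coverage is defensible.
2. length < 36 nt (one read length) → rejected.
3. same-strand overlap with an annotated **ncRNA** locus → rejected.
   Exon, intron and repeat overlaps do not reject: retained candidates
   are expected in introns (either strand), overlapping exons, and in
   intergenic space. The category set is config-overridable.

Retained transfrags shorter than 70 nt — the lower bound of the
intermediate-size class — are extended in the strand-aware 3' direction
to 70 nt (probe-design convenience), clipped at chromosome ends. The
pre-extension interval and coverage statistics are kept on the
transfrag, and re-filtering uses them, which makes `filter_novel`
idempotent even when an extension would otherwise touch a downstream
annotation.

Novel transfrags are called per sample; same-strand overlapping novel
transfrags are merged across samples before counting (the merged mean
coverage is the length-weighted mean of the parts — a bookkeeping
approximation, not a re-measurement).

**Detection rate.** A known locus counts as detected when any transfrag
(any sample) overlaps it on the same strand by more than
`min_fraction_covered` of the locus length, default 0 (any overlap),
since no overlap fraction is part of the filter definition. Rates are
`round(100 · detected / known, 2)`. The summary row totals the nine
intermediate-size classes; 21U-RNAs and miRNAs fall below the size
selection and are reported as individual rows outside the total.

**TSS profiling.** For each known is-ncRNA locus with an overlapping
same-strand transfrag of mean coverage ≥ 6, the profile reports the
strand-aware offset of the most-5' qualifying transfrag end from the
annotated TSS (negative = upstream) and whether any qualifying transfrag
spans the TSS. The histogram's empirical mode is reported rather than a
hard-coded peak position.

## Microarray normalization

**Quantile.** log2 transform, then each array's values are replaced by
the rank-wise mean of all arrays' sorted values; ties receive the mean
of the reference values they span (average ranks interpolated on the
reference grid). The defining property — identical sorted columns — is
tested to 1e-9; the procedure is idempotent on its own output and
equivariant under sample permutation.

**GRSN.** The global rank-invariant set normalization used here is
re-specified from its core idea rather than transcribed from any
published implementation: (1) log2 transform; (2) reference profile =
per-probe mean across arrays; (3) drop the top and bottom 5% of probes
by reference intensity (extremes have trivially stable ranks); (4) the
invariant set is the 10% of remaining probes with the smallest
cross-array rank spread (max rank − min rank); (5) per array, the
deviation from the reference is lowess-smoothed against reference
intensity on the invariant set (`frac=0.4`, 2 robustifying iterations,
constant extrapolation beyond the set's intensity range) and subtracted
genome-wide. Published GRSN variants differ in details (trimmed means,
iteration schedules); those refinements are approximated by the single
lowess pass. The invariant set must hold at least 10 probes (and the
matrix at least 20), otherwise the method errors out — with few probes
the invariant-set concept is meaningless. The benchmark requirement is
that a planted uniform +1 log2 array shift is removed to < 0.05 median
absolute residual, and that an intensity-dependent distortion
(`d(x) = 0.2·x` on the log scale) is reduced.

Both normalizers are also exposed as scikit-learn transformers
(`fit`/`transform` on array-by-probe matrices) so they compose with
sklearn pipelines; the rest of the workflow is interval and counting
logic and is deliberately not forced into an estimator shape.

## The three-criterion screen

Run on a normalized (log2) matrix with a declared strain → (untreated,
UV) sample pairing:

- **(i) fold change:** |log2 FC| ≥ log2 1.5 in at least one strain pair.
  The comparison includes the boundary ("at least 1.5-fold") and guards
  it with a 1e-9 tolerance against log/exp round-trip error.
- **(ii) variability:** coefficient of variation across **all** arrays,
  computed on the linear scale (back-transformed from log2; log-scale CV
  by config), must exceed the median CV of all probes. The median is
  taken over the full probe universe supplied — excluding control probes
  is the caller's responsibility.
- **(iii) consistency:** the direction (sign only, not magnitude) of the
  wild-type UV response must agree between array and the sequencing
  proxy (per-sample mean transfrag coverage over the probe interval in
  the full pipeline). Probes without sequencing signal fail — an
  undetected transcript cannot corroborate a direction.

The screen is threshold-based by design; no p-values and hence no
multiple-testing correction are involved. The candidate set is the union
over the quantile and GRSN paths, each record annotated with its
contributing path(s); both screens must share one probe universe.

## qPCR quantification

Per replicate, ΔCt = Ct(target) − Ct(reference transcript), pairing
target and reference wells by replicate index (standard one-step qRT-PCR
practice). ΔΔCt = mean ΔCt(condition) − mean ΔCt(calibrator);
rq = 2^−ΔΔCt, exactly 1 for the calibrator. Replicate spread is the SEM
of the per-replicate back-transformed values 2^−(ΔCt_i − mean
ΔCt(calibrator)) — i.e. error bars on the fold-change scale, the common
presentation — rather than a back-transformed SEM of ΔΔCt. Significance
is a two-sided two-sample t-test on the ΔCt replicate sets (Ct space is
approximately normal; Welch correction off by default, available by
flag), starred at 0.05 / 0.01 / 0.001. With a single replicate the point
estimate is produced and SEM/p are NaN. No amplification-efficiency
correction is applied: the model is pure 2^−ΔΔCt.

## Survival assay statistics

Survival per replicate is `100 · survived / (survived + arrested)`;
duplicate plates (optional `plate` column) are pooled within a replicate
before the percentage is taken. Curves report mean ± SEM per condition
and dose. The pooled comparison against control is a two-sided paired
t-test with (dose, replicate) as the pairing unit over the shared dose
range — pairing removes the dose main effect; its size under the null is
verified by simulation (type-I error 0.05 ± 0.02 at 1000 trials).
Per-dose unpaired t-tests complement it when single doses matter.
Degenerate cases: identical pairs → p = 1 with a warning; constant
non-zero paired difference (possible with discrete counts) → p = 0 with
a warning, since the t statistic diverges. This is a binary endpoint
(development beyond L4), not time-to-event, so no survival-curve
(Kaplan–Meier) machinery applies.

## Synthetic data: what it emulates, and what it does not

Defaults are desk-scale study conditions chosen so the full pipeline
runs in seconds while preserving the statistical structure the analysis
assumes:

- **Genome:** 2 × 1 Mb chromosomes; known ncRNA classes at one-fifth of
  the real inventory's per-class counts (e.g. 27 snoRNAs, 126 tRNAs, 12
  uncharacterized is-ncRNAs, plus below-size 21U-RNAs and miRNAs); 40
  coding genes with exon/intron structure; 30 repeat regions; features
  non-overlapping within category, snoRNAs 50% intronic.
- **Novel loci:** 30 planted loci of 70–500 nt, placed intergenic (60%),
  intronic on either strand (30%) and exon-overlapping (10%), never
  overlapping annotated ncRNA; half are UV-responsive with fold 2–4 in
  the UV conditions.
- **Reads:** 36 nt, per-locus counts Poisson around a target mean
  coverage (lognormal across known loci, median 40; novel loci clipped
  to ≥ 12 so the coverage ≥ 6 filter is comfortably exercised), uniform
  start positions with a 20% 5'-anchored fraction. 25% of expressed
  known is-ncRNA loci are "processed": their reads start 20–60 nt
  downstream of the annotated TSS, setting the generator's TSS-coverage
  target at 75%. 8% of locus reads are multi-mapped with explicit decoy
  placements inside repeats (n_hits 2–3), exercising the 1/n path
  against known truth; 1500 background reads per sample add noise below
  the coverage cut-off. This yields ~40–50k reads per condition — two
  orders of magnitude below a real lane, which is the main reason
  absolute counts (novel transcripts, candidates) are not comparable to
  a real study, only the per-stage behaviours are.
- **Microarray:** one probe per known is-ncRNA locus and per discovered
  novel transcript (~225 probes; the probe set is tied to actual loci
  rather than padded to a fixed count so ground-truth linkage stays
  exact). Intensities are log-normal around true abundance (σ = 0.15 in
  log2); one array receives an intensity-dependent distortion
  (log-scale ·1.1) to give GRSN something to correct. The screen's
  sequencing proxy in the pipeline comes from actual read coverage, not
  from a parallel noise draw.
- **qPCR / survival:** Ct = baseline − log2(expression) + N(0, 0.1);
  survival counts are binomial (n = 60, 3 replicates) under a logistic
  dose-response (d50 = 120 J/m², slope 30), knockdowns shifting d50 by
  −35/−35/−15.

Not emulated: sequence content (no GC bias, no mismatches — alignment is
out of scope and reads are consumed pre-aligned), transcript splicing,
probe cross-hybridisation, amplification efficiency drift, and real
library-size effects. Passing tests therefore demonstrate the
correctness and calibration of the computations on data with the assumed
structure, not robustness to artefacts absent from that structure.

## Numerical choices

- Detection percentages round half-even to 2 decimals (none of the
  benchmark values sit on a rounding boundary).
- The fold-change boundary uses a 1e-9 absolute tolerance in log2 space.
- The sequencing log-ratio uses an ε of 1e-12 on both counts, so 0/0 →
  direction 0 → consistency fails, while x/0 saturates to a definite
  direction.
- Lowess: `frac=0.4`, `it=2`, constant extrapolation outside the
  invariant set's intensity range.
- All randomness flows through one `numpy.random.Generator` passed
  explicitly; a seed fully determines every output, and the end-to-end
  run is byte-reproducible.

## Known limitations

- Headline counts from any real study depend on its full-depth
  libraries and complete genome annotation; the desk-scale generator
  reproduces behaviours and calibrations, not absolute counts.
- The merged novel transfrag's mean coverage is a length-weighted
  approximation.
- GRSN is a faithful re-specification of the rank-invariant idea, not a
  line-by-line port of any published implementation.
- The screen's consistency criterion is direction-only on the wild-type
  pair; extending it to magnitude or both strains is config work left to
  the user because no quantitative rule is part of the method
  definition.
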