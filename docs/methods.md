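# Methods

## The screen model

`visscreen` analyses resistance screens in which a clonal cell population
carries random, unique retroviral integrations. Under drug selection, a
clone whose integration perturbs a resistance-relevant gene expands; its
integration locus is then detected in more treated samples (frequency) and
at higher normalized read depth (coverage) than in untreated controls.
The package treats the aligner as external: it consumes alignment records
(SAM or in-memory frames with chromosome, leftmost 0-based position,
orientation, MAPQ) and produces locus × sample matrices, per-locus
statistics, candidate genes, and a single-cell validation.

## Synthetic data generator

The generator exists so that every downstream stage has decidable ground
truth; it is first-class, tested code.

**Selection.** Each sample evolves independently from the same baseline by
discrete passages of fitness-weighted multinomial resampling
(Wright–Fisher with selection): at each passage clone weights are
`abundance × fitness(treatment)`, renormalized, and `population_size`
cells are drawn multinomially. This is the simplest model that produces
both deterministic enrichment/depletion and neutral drift. Defaults:
two passages per month (cultures split biweekly), eight passages for a
two-or-more-month treatment window, and a population of 2×10⁴ cells — the
seeding scale of one 24-well culture. Baseline clone abundances are
symmetric Dirichlet (concentration 1 by default, giving the broad clone-
size spectrum of a transduced pool; tests that require every clone to be
sequenced use a higher concentration).

**Sequencing.** Reads are drawn per clone proportionally to abundance.
Alignment positions sit at the integration point plus a sonication offset
bounded by `offset_spread` (default 500 bp, emulating ~1 kb fragments) on
the genomic side of the junction, so true loci always collapse within one
1000 bp window and clustering correctness is decidable from truth. MAPQ is
a mixture (95% at 60, 5% uniform on 0–19) purely to exercise the quality
filter. Read sequences are LTR + random flank + linker truncated to the
read length; sequence content is synthetic (alignment is never
re-performed), and `emit_reads=False` skips sequence construction when
only alignments are needed. Base-level error models, PCR duplicates, and
real vector sequence are deliberately out of scope, so passing tests say
nothing about aligner behaviour or chemistry artefacts on real data —
only about everything downstream of alignment.

**Determinism.** Every top-level operation takes one integer seed;
per-sample streams are split from a `numpy.random.SeedSequence`, so fixed
seeds give byte-identical outputs regardless of sample order.

**Single-cell matrices.** Each gene has a per-population probability of
being expressed in a cell; expressed counts are 1 + negative binomial
(gamma–Poisson) scaled by a log-normal per-cell library factor. Because
any nonzero count clears a 1 CPM threshold at realistic library sizes, the
planted probability *is* the expected positive fraction, which makes the
fraction-positive test directly checkable against binomial error bounds.

## Read preparation

Adapters are found by a semiglobal edit-distance search (substitutions and
indels). A match is accepted when its distance is at most
`floor(error_rate × matched_adapter_length)` with the length measured on
the adapter side; adapters may run off the read start (5′) or end (3′)
down to a minimum overlap of 3 nt, which prevents spurious 1-nt matches.
Selection is a total order — smallest distance, then leftmost span (5′) or
rightmost-starting span (3′), then smaller end, then longer matched
portion — so results are reproducible and equal a brute-force enumeration
of all spans (verified in tests and the acceptance sweep). Defaults:
error rate 0.25, minimum trimmed length 36 bp, untrimmed reads discarded.
Paired-end mates are trimmed independently; quality trimming, demultiplexing
and UMIs are out of scope.

## VIS calling

Alignments from **all** samples are pooled before clustering so locus
identities are shared across the cross-sample matrix; per-sample
clustering followed by interval matching was rejected as under-specified.
Within a chromosome, sorted positions chain into one locus while
consecutive gaps are ≤ `window_bp` (default 1000, **closed** boundary: a
gap of exactly 1000 bp merges; the boundary is covered by an explicit
test). Clustering is orientation-agnostic; per-locus orientation tallies
are recorded. The representative position is the lower median of member
read positions. RPM uses VIS-assigned reads per sample as denominator
(recorded in the output metadata), so per-sample RPM sums to 10⁶ exactly
whenever the sample has any assigned reads. Detection defaults to ≥ 1
read (configurable `min_reads_detect`). Nearest-gene distance is 0 inside
a gene, otherwise the gap to the closer interval edge; ties go to the
smaller gene start, then the lexicographically smaller name. Coordinates
are 0-based half-open everywhere; BED output is native.

## Screen statistics

The cascade removes (1) loci detected in exactly one sample, (2) loci not
detected in both biological replicates under any condition, and (3) loci
lacking both-replicate detection within a single non-control treatment —
cross-treatment mixing does not qualify, and control-only concordance does
not qualify at stage 3 (a documented interpretation; the alternative
reading would keep control-private loci that can never yield a candidate).
No FDR correction is applied in this module: replicate concordance is the
design's surrogate control, and the two-tier thresholds (exploratory
p < 0.1, significant p < 0.05) are exposed in the config.

The frequency test is a two-sided Fisher exact test computed by exact
rational enumeration under the probability-mass rule (sum of all tables
with probability ≤ the observed table's); exact integer arithmetic keeps
tie handling unambiguous at any table size the screen produces, and the
test suite cross-checks against an independent library implementation.
The coverage test is a pooled-variance Student t-test (Welch behind a
switch) on per-sample RPM with undetected samples contributing RPM 0 —
including zeros keeps group sizes fixed and couples the two tests
coherently; a detected-only mode exists behind a config switch. Zero
pooled variance with equal means gives t = 0, p = 1; with unequal means
the result is flagged degenerate (p = 0). Timepoints are pooled within
treatment groups throughout.

**Candidate selection.** A locus qualifies for a discovery treatment
(fulvestrant, ribociclib) when either test reaches at least the
exploratory tier **in the enriched direction** (including
exclusive-to-treated detection). Requiring enrichment is a deliberate
design choice: resistance acts by clonal expansion, and the expansion of
resistant clones mechanically depletes every neutral locus in
compositional (RPM) terms, so a direction-blind rule would flag the
entire neutral background through the coverage test. `require_enriched`
can be switched off to study depleted loci. Qualifying loci collapse to
their nearest gene (unannotated loci keep their locus id); loci remain
distinct in all outputs because different loci near one gene can behave
oppositely, and gene-level flags are any-locus aggregates. Verification
counts, per gene, the held-out treatment groups (abemaciclib,
palbociclib, fulvestrant+ribociclib) with ≥ 1 detected sample at any
supporting locus: all groups / one-or-two groups / none.

## Single-cell validation

Counts are CPM-normalized per cell (zero-count cells excluded with a
warning); a cell is positive at CPM ≥ threshold (default 1, closed
boundary, boundary-tested). Populations are compared per gene with the
Pearson chi-squared test on the 2×2 positive/negative table without
continuity correction (Yates behind a flag), Bonferroni-corrected with
m = the number of genes actually tested in the run (not the full
candidate count — only recognized genes are testable). Gene matching is
case-sensitive after an explicit, auditable alias map. Concordance labels
each gene `consistent`/`opposite` by comparing the RNA direction
(resistant vs parental positive fraction) with the screen direction for
the designated treatment, or `not_in_screen`.

## Numerical and testing choices

* Exact arithmetic (`fractions.Fraction`, `math.comb`) for the Fisher
  enumeration; everything else in float64.
* The acceptance experiments run at the discovery design's scale
  (41 discovery-arm samples plus 19 controls, 300 clones, 5×10⁴ reads per
  sample, 2×10⁴ cells, 8 passages, fitness 1.6 for planted clones) —
  chosen as the study conditions, with clones planted ≥ 5 kb apart so
  locus↔clone identity is decidable.
* Oracles are independent routes: graph transitive closure (scipy
  csgraph) for clustering, brute-force span enumeration for the adapter
  search, library Fisher/t/chi-squared implementations for the statistics.
* Known limitations: no paired-end merging or junction refinement from
  soft clips; no PCR-duplicate or UMI modelling; the generator's
  compositional behaviour is idealized (no technical inter-sample
  correlation), so real-data false-positive rates will be higher than the
  planted-truth rates reported by the acceptance script; the headline
  locus counts of any particular real screen depend on its library
  complexity and are not reproducible from synthetic data — only the
  bookkeeping identities among them are checked.
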