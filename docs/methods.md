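# Methods

This note documents the statistical procedures implemented in `galdiv`,
the choices made where conventions differ between tools, and what the
synthetic-data generator does and does not emulate.

## Data model

Genotypes are diploid biallelic calls coded 0 (homozygous for allele A),
1 (heterozygous), 2 (homozygous for allele B) or missing, in a dense
samples × markers matrix.  Allele A of a marker is the first allele
observed in the input file, which makes the coding deterministic; a
monomorphic marker gets the placeholder `"0"` for its unobserved allele
(PED cannot name an allele never seen).  Marker positions are 1-based
base pairs, strictly increasing within each of the chicken autosomes
1–28; all downstream coordinates inherit this convention.  Half-calls
(one allele missing) are conservatively treated as missing, with a
warning.

## Quality control

Three filters run in a fixed order: (1) animals with more than 10%
missing genotypes, (2) markers with call rate below 95% among the
surviving animals, (3) markers with minor allele frequency below 5%,
pooled over the surviving animals.  The order is a design choice — the
marker statistics then describe exactly the cohort that is analyzed —
and is recorded in the QC report.  All inequalities are strict, so items
exactly at a threshold are kept, matching the usual "< 95%" / "more than
10%" phrasing of such filters.  MAF is pooled rather than per breed
because the filter is applied once to the combined dataset.

## Diversity indices

Per breed: MAF = min(p, 1−p) from within-breed allele frequencies;
Ho = heterozygote fraction per marker; He = 2pq.  Means and SDs for
MAF/Ho/He are taken across markers, for F_HOM across individuals
(population SDs, ddof = 0; the two axes match the magnitudes such survey
tables report).

F_HOM for animal *i* is (O_i − E_i)/(L_i − E_i) with O_i its observed
homozygote count, L_i its typed-marker count and
E_i = Σ_j [1 − 2 p_j q_j c_j] the Hardy–Weinberg expectation, with the
small-sample factor c_j = 2n_j/(2n_j − 1) (n_j = animals typed at marker
j in the frequency cohort).  Two choices are exposed rather than fixed
silently, with defaults:

* `freq_scope="within_breed"` — expectations from the breed's own
  frequencies.  This is the only scope under which outbred commercial
  stocks can show slightly negative F_HOM alongside Ho > He, the pattern
  such surveys report; a `"global"` scope is kept for sensitivity checks.
* `correction=True` — the 2n/(2n−1) factor, matching the convention of
  the standard genotype-analysis tools, and making F̂ unbiased around 0
  for a cohort in Hardy–Weinberg equilibrium.

Individuals whose denominator L−E vanishes (fully fixed cohorts) get NaN
and are excluded from the summary.

## ROH calling

Five constraints define a valid run (defaults in parentheses): minimum
SNP count (100), minimum length (1,000 kb), maximum heterozygous calls
(1), maximum missing calls (2), mean density of at most 100 kb per SNP,
and no inter-SNP gap above 1,000 kb.

**Segment mode** (default) is the exact semantics: candidate runs are
the *maximal* index ranges satisfying all five constraints — valid
ranges contained in no larger valid range.  The implementation sweeps
each chromosome once: gaps first split it into blocks, a two-pointer
pass finds the largest het/missing-feasible end for every start, a
density walk-down finds the largest fully valid end M(a), and a range
(a, M(a)) is emitted exactly when M(a) exceeds every earlier M — which
provably enumerates the maximal set.  Overlapping candidates (possible
when the het/missing budget can be spent on either side) are resolved
longest-first in bp, ties to the leftmost, so output is deterministic.
The test suite checks this caller against a brute-force enumerator over
all index pairs.

**Window mode** approximates the sliding-window heuristic of the classic
tools: 50-SNP windows are scored homozygous when they hold ≤ 1 het and
≤ 2 missing; a SNP is in-run when ≥ 5% of its covering windows are
homozygous; maximal in-run stretches are then subjected to the five
constraints.  Window size and hit threshold are those tools' defaults
and are exposed as parameters.  The two modes exist because published
parameterizations describe windows while stating the constraints at the
run level; segment mode is the testable canonical semantics.

Run length is `end_bp − start_bp` of the first/last SNP — the convention
under which published island lengths equal end minus start exactly — and
the same convention is used for islands.  Length classes are
right-closed: ≤ 5, (5,10], (10,15], (15,20], (20,25], (25,30], > 30 Mb.

F_ROH divides an animal's summed ROH length by the genome length covered
by the array: the constant 944,270 kb when the map spans chicken
autosomes 1–28, otherwise the summed per-chromosome map span (max − min
position), logged when used.

## Incidence track and islands

Each mapped SNP is scored by the number of animals whose ROH cover it
(closed interval; per-animal coverage is merged first so an animal can
never count twice), divided by the number of animals.  Islands are the
SNPs at or above the empirical (1 − top_fraction) quantile of that
track — default top_fraction 0.001, i.e. the top 0.1% tail, the reading
adopted for the ambiguous "top 0.999%" phrasing seen in print; the
quantile is taken over all mapped SNPs including zero-incidence ones.
Selected SNPs on a chromosome merge into one island while consecutive
selected SNPs are within `merge_gap_kb` (default 1 Mb, mirroring the ROH
gap parameter; no published merge rule exists).  A track with all
proportions equal is rejected as degenerate unless forced.  Annotation
reports any BED/GFF3 feature whose closed interval intersects the
island's closed span.

## Structure

* **IBS**: per marker typed in both animals, allele sharing is
  (2 − |g_a − g_b|)/2; distance is 1 minus the mean (pairwise deletion,
  the behavior of the standard tools).
* **Classical MDS**: eigendecomposition of B = −½ J D² J; coordinates
  are eigenvectors scaled by √eigenvalue; axes with non-positive
  eigenvalues are dropped (k is reduced with a warning if needed).
  Breed-level summaries embed individuals then average coordinates per
  breed (a flag averages distances first instead).
* **Reynolds distance**: the large-sample ratio estimator
  θ = Σ_l 2(p_x − p_y)² / Σ_l 2(1 − p_x p_y − q_x q_y), skipping loci
  undefined in either breed; `linearized=True` returns −ln(1 − θ).  The
  fully bias-corrected (sample-size weighted) variant is out of scope.
* **Neighbor-joining**: standard Q-criterion agglomeration.  Ties are
  broken by the first minimal pair in current label order so the result
  is deterministic; negative branch-length estimates are clamped to zero
  with a warning.  Newick output carries 6 significant digits and quotes
  labels containing metacharacters.  On additive matrices NJ is exact,
  which the tests verify against random trees and an independent library
  implementation.

## Synthetic-data generator

The generator produces the statistical structure the analysis assumes,
with exact truth:

* **Map**: uniform random positions, strictly increasing, deterministic
  under seed.
* **Allele frequencies**: ancestral p₀ ~ Beta(α, β) (default uniform,
  giving a mean MAF of 0.25, in the range arrays show after
  ascertainment); each breed drifts via the Balding–Nichols kernel
  p ~ Beta(p₀(1−c)/c, (1−p₀)(1−c)/c), so Var(p|p₀) = c·p₀(1−p₀) and the
  expected squared frequency difference between two breeds is
  2c·E[p₀(1−p₀)].  Breeds may share an intermediate clade pool
  (two-stage drift) to model recently diverged breed pairs.
* **Genotypes**: site-wise HWE-with-F draws (p² + Fpq, 2pq(1−F),
  q² + Fpq) plus i.i.d. missingness.  There is *no linkage
  disequilibrium*: runs of homozygosity arise only from explicit
  injection, never from background, which keeps the truth set exact.
* **Autozygous injection**: planned segments are placed uniformly over
  the feasible (non-overlapping) offsets of a chromosome, so realized
  coverage equals planned coverage; within a span every marker is set
  homozygous with the allele drawn by its frequency (so injected runs
  match real autozygosity's allele composition), missing calls inside
  the span are overwritten, and the two markers flanking the span are
  forced heterozygous.  The sharp double-het flanks are a deliberate
  idealization: they make truth boundaries exact, and bound a segment
  caller's overshoot at one flanking SNP (it may absorb one het but not
  two).  Near-adjacent spans are merged in the truth table so flanks
  never fall inside another segment.  Fixed-locus plans with a
  per-animal carrier probability create designed islands.
* **Study fixture**: 27 breeds (23 "local" at 20–24 animals with
  autozygous coverage F\* from 0.10 to 0.60, two clade pairs; 4
  "commercial" at 9–13 animals with F\* ≈ 0.03) on 5 chromosomes × 1,000
  SNPs × 40 Mb, background missingness 0.2%, plus one designed hotspot
  (chromosome 3, 15–21 Mb) carried by 90% of animals.  A breed's F\* is
  realized purely as injected coverage, which is what makes *both*
  F_HOM and F_ROH estimate F\*: the homozygosity excess and the run
  coverage are the same signal.  Site-wise inbreeding (F > 0 without
  runs) remains available for testing F_HOM in isolation.

Because the generator is site-wise, passing tests demonstrate the
estimators' and caller's correctness on their own model, not robustness
to LD, genotyping error, ascertainment bias or soft run boundaries —
real arrays have all four.  In particular real ROH boundaries are
diffuse, so the one-interval boundary guarantee is a property of the
truth-set design, not of field data.

## Problem sizes and numerical choices

Default analysis sizes were chosen so a full synthetic study runs in
seconds: the study fixture is 5,000 SNPs × ~550 animals; estimator
recovery uses 20,000 markers × 24 animals per cohort (10 replicates);
caller-vs-brute-force equivalence uses 200 random chromosomes of up to
500 SNPs.  Parameter-recovery tolerances (±0.05 on F) reflect the
binomial sampling noise at those sizes.  Quantiles use numpy's default
linear interpolation; distance matrices are symmetrized after BLAS
accumulation; MDS treats eigenvalues below a 1e−12 relative tolerance
as null.  Pipeline outputs are written atomically and a manifest records
versions, parameters and input checksums, so identical runs are
byte-identical.

## Known limitations

No LD or pedigree simulation; no sex chromosomes; no genotyping-error
model; no Hardy–Weinberg or relatedness QC; binary PLINK and VCF input
are out of scope (PED/MAP and a TSV table are supported); ADMIXTURE-type
model-based clustering and neighbor-net splits graphs are intentionally
not implemented; database (gene/QTL) lookups are replaced by overlap
against user-supplied interval files.
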