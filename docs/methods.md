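# Methods

## Problem and model

Cells in an scRNA-seq library should cover gene bodies in a broadly similar
way; RNA degradation, incomplete reverse transcription, and some capture
failures instead concentrate a cell's reads at one end of transcripts
(typically 3′). `skewc` treats this as a robust outlier-detection problem in
coverage-profile space: the bulk of cells follow one prototypical profile,
and a contaminating fraction deviates from it. The pipeline is

1. per-cell gene body coverage (100 percentile bins, 5′→3′),
2. reduction to 10 decile means,
3. a single trimmed Gaussian fit that retains the best-fitting
   `h = floor(n*(1-alpha))` cells (typical) and trims the rest (skewed).

## Gene-body binning

Each transcript's exonic (mRNA) bases are walked 5′→3′ in transcript
orientation and base `i` (0-based, of `L`) is assigned to bin
`floor(i * 100 / L) + 1`. This rule is deterministic, conserves bases
(bin sizes sum to `L`), and keeps all bins within one base of each other
(`floor(L/100)` or `ceil(L/100)` bases per bin). For a minus-strand
transcript, bin 1 sits at the genomic right end. One subtlety follows from
the rule rather than from the implementation: flipping a transcript's strand
reverses the bin order *exactly* (bin k ↔ 101−k per base) only when
`100 | L`; otherwise single bases at fractional bin boundaries shift by one
bin, because the forward walk places boundaries at ceilings and the
reflected walk at floors. The test suite asserts exact reversal for
divisible lengths and a ±1-bin bound in general.

Transcripts with `L < min_mrna_length` (default 100, i.e. at least one base
per bin) are skipped with a logged census. The index is persisted as a
versioned TSV under `reference/<bedname>.idx` with a SHA-256 digest of the
source model; loading against a model with a different digest raises a
stale-index error rather than silently mixing annotations. The format is
this package's own — it makes no attempt to be byte-compatible with any
other tool's index, whose layout is unpublished.

rRNA/tRNA exclusion follows `intersectBed -split -v -s -wa` semantics: a
transcript is removed iff ≥1 exonic base overlaps an exclusion record's
exonic base on the same strand; intron-only overlap does not count. The
implementation is cross-checked in tests against both a per-base
set-intersection oracle and `bedtools intersect` itself.

## Coverage computation

Eligible alignments are primary, mapped, non-duplicate records (secondary
and supplementary alignments are excluded to avoid double-counting
multi-mappers; no MAPQ threshold by default, flag-exposed). Every aligned
reference base (CIGAR M/=/X; N and D advance the reference but cover
nothing) that falls on an indexed exonic base increments that base's bin,
once per transcript indexing it — a base shared by k overlapping transcripts
contributes k counts, the "sum over genes" reading of aggregate gene body
coverage. Raw counts are normalized to sum to one. Sum-normalization (rather
than max-normalization) keeps decile means comparable across cells; the
classification itself is scale-covariant through the Gaussian fit, so the
typical/skewed partition is the contract, not the absolute values. Cells
with zero indexed coverage yield an all-zero vector, are flagged degenerate,
excluded from clustering, and reported separately — they cannot be scored.

Batch runs key every cell by its BAM filename stem and write stores sorted
by cell ID, so output is byte-identical regardless of worker count or file
order. One corrupt BAM fails only its own cell and lands in a failures
manifest. Stores are written in two dialects: a TSV (`cell_id` + 100
values) and an R-assignment file (`coverage.r`) for compatibility with
downstream consumers of that format.

## Trimmed clustering

With rows summing to one, the 10 decile means sum to 0.1, so the sample
covariance always has one (near-)zero eigenvalue. The eigenvalue-ratio
constraint `max/min <= restr_factor` (default 50) handles this directly: the
constrained MLE clips the spectrum to `[m, c*m]` with the truncation point
`m` minimizing `sum_j log(d*_j) + d_j/d*_j`, whose optimum lies among
`{d_j, d_j/c}`. Clustering in the 10-dimensional decile space (not the raw
100 bins) keeps this covariance estimation stable at cohort sizes of tens to
hundreds of cells.

The solver runs classical concentration steps: initialize μ, Σ from a
random (d+1)-subset; score all points; retain the `h` highest-density
points (ties broken by a canonical row order); refit with eigenvalue
clipping; iterate until the retained set is stable; keep the best of
`n_starts` (default 64) restarts. Restart subsets are drawn from a
lexicographic ordering of the rows, which makes results equivariant under
row permutation at fixed seed; the retained/trimmed partition is also
invariant under affine scaling of the data. On every random instance small
enough to enumerate (n ≤ 12, d ≤ 2), the solver attains the exhaustive
subset optimum to ≤ 1e-8; defaults `max_iter=100`, `seed=1` are exposed on
the CLI.

The trim-count convention is `n_skewed = n - floor(n*(1-alpha))`.
Consequently a 930-cell cohort at α = 0.04 yields 38 skewed cells; a
897/33 split of 930 cells corresponds to no floor/ceil trimming of 930 at
α = 0.04 and is not reproducible under this (or any rounding) convention —
the package documents its convention and applies it uniformly.

## Automatic trimming level

The classification-trimmed-likelihood curve evaluates the objective at each
grid α (default grid 0, 0.05, …, 0.30, shared seed). A point worth stating
explicitly: this objective is **not** monotone in α in general. It is a sum
of log-densities, and on decile-mean data the per-cell log-densities are
strongly positive (coordinates of order 10⁻², covariance eigenvalues of
order 10⁻⁶), so once genuine outliers are exhausted, trimming well-fitting
cells removes large positive terms faster than the tightened fit adds them —
the curve rises while true outliers remain and flattens or falls after.
The selection rule is therefore the point of maximum discrete curvature
(the largest drop in slope, ties toward smaller α), recorded in output
metadata as `curvature-elbow-v1`. This elbow coincides with the curve's peak
when the curve peaks and with the knee when it is monotone, so it covers
both geometries. On planted cohorts of 90 typical + 10 half-strength skewed
cells it selects α = 0.10 in 20/20 seeds.

## Synthetic data

The fixture generator emulates the two populations the QC targets. The
typical profile is a gentle mid-gene bump (1 + 0.5·sin(πx), normalized) —
real aggregate coverage is roughly flat mid-gene and depressed at both ends.
Skewed cells mix that prototype with a geometric end-loaded profile
(decay 0.05 per bin, i.e. mass concentrated in roughly the terminal 20
bins) with mixing weight `skew_strength`; 3′ loading is the default because
it is the canonical degradation signature. Per-cell noise is Dirichlet with
concentration `noise_concentration * profile` (default 2000, giving ≈20%
coefficient of variation per bin) — vectors are non-negative and sum to one
by construction. Default cohort: 90 typical + 10 skewed at strength 0.5,
which is linearly separable in decile space by an independent
nearest-centroid check.

BAM fixtures place reads of fixed length (default 60) by sampling a
gene-body bin from the cell's profile, then a start base within it; reads
spanning introns get N gaps. A truth table records each read's barcode and
exact covered genomic bases, enabling per-base pileup oracles. Toy genomes
are two 100 kb contigs. What these fixtures do *not* model: sequencing
error, quality strings, UMIs/duplicates, multi-mapping ambiguity, realistic
transcript-abundance skew, or overlapping gene models — so passing tests
demonstrate the counting, clustering and plumbing are correct, not that any
particular real dataset will show a given typical/skewed split.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of ~100 cells, toy models of ≤ 10
transcripts, and per-cell BAMs of ≤ 200 reads — large enough to exercise
every code path and small enough to verify against brute-force oracles
(exhaustive subset enumeration is feasible only to n ≈ 12). Floating-point
tie-breaks in retention are resolved by canonical row rank; the
trimmed-likelihood oracle comparison uses an absolute tolerance of 1e-8;
normalized vectors are checked to sum to 1 within 1e-9. Plots are rendered
with pinned PNG metadata and fixed geometry so re-rendering is
byte-identical.

## Known limitations

* Exact numeric agreement with other gene-body-coverage implementations is
  not promised: the base→bin rule and minimum-length filter vary across
  tools and are frequently unpublished.
* k is fixed at 1 (one typical component plus trimmed outliers); cohorts
  containing two legitimate sub-populations with different coverage shapes
  would need k > 1 model selection, which is out of scope.
* The automatic α rule is a declared heuristic with a plugin point
  (`selection_rule_id`); other rules can be swapped in.
* Annotation objects are written as JSON (a documented twin of serialized
  R objects); no .rds binaries are emitted.
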