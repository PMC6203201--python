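# Methods

This note documents the models, conventions and numerical choices behind
`apakit`, and what the synthetic-data generator does and does not emulate.

## Coordinates and orientation

Atlas coordinates are 1-based and inclusive on both ends; BED export
converts to 0-based half-open. All "proximal/distal" language is defined in
transcript orientation: for a minus-strand gene the proximal site (first
reached during transcription) is the genomically rightmost one. Sequence
windows are specified as offsets from the representative cleavage position
(`rep_pos`) in transcript orientation, inclusive of both endpoints, so the
downstream 20–40 nt window is 21 nt long. Minus-strand windows are mirrored
genomically and reverse-complemented. Motif windows anchor on `rep_pos`
rather than the cluster midpoint; for the narrow clusters typical of
poly(A)-site atlases the two differ by a few nucleotides at most, and the
window widths used here (21–100 nt) make the profiles insensitive to that
choice. All motif logic operates on the RNA alphabet; DNA input is converted
(T→U) at read time. A window that runs off a contig is returned truncated
together with an explicit flag — never silently clipped.

## APA quantification

Sites are filtered to annotation classes TE/EX/IN with at least 10 counts
summed over all samples (inclusive threshold). For a two-site gene,
RUD = distal/(proximal+distal) per replicate; replicate RUDs are averaged
within condition *before* differencing, and a gene is lengthened when
ΔRUD = mean(B) − mean(A) exceeds +0.05 strictly (shortened below −0.05).
The strict comparison carries a 1e-9 epsilon so that values equal to the
threshold up to float representation are not called. A replicate with zero
proximal+distal counts yields a missing RUD, not 0 — a zero-coverage library
carries no usage information and a planted 0 would manufacture shifts; a
gene needs at least one defined replicate per condition to be called.

UTR-APA vs UR-APA follows the proximal site's annotation class: TE → UTR-APA,
EX or IN → UR-APA.

Genes with more than two retained sites are summarized by relative site
usage (per-site count over gene total), computed per replicate and averaged
within condition, so each condition's usage vector sums to 1. Because no
standard shift rule exists for multi-site genes, the package calls them
lengthened when the distal-most site gains more than the threshold in usage
while at least one upstream site loses usage (mirrored for shortened); this
is an explicit extension, reported in the same table but never entering the
two-site cohort percentages.

Gene-level expression counts aggregate *pre-filter* site counts: the
≥10-count gate exists to stabilize usage ratios, and expression estimates
should not depend on it. Cohort percentages are rounded to the nearest
integer for reporting and undefined (NA) when the denominator is zero.

## Decay model

After transcription shutoff, count(t) = c0·e^(−kt). The fit is ordinary
least squares of ln(count) on t over timepoints with positive counts;
zero-count timepoints are dropped rather than pseudocounted — a pseudocount
would bias k by an amount that depends on the arbitrary constant, while the
≥3-point gate already guards degenerate fits. The log base is immaterial to
R² and to t½; natural log makes k directly per-hour. R² is computed on the
log scale, the scale of the fit. Quality gates, applied in order: ≥1
positive timepoint pair, ≥10 counts at t = 0, ≥3 positive timepoints,
R² > 0.6, k > 0. Half-life t½ = ln 2/k is reported whenever k > 0, but only
`ok` fits enter group comparisons. Each replicate is fit separately and
half-lives are replicate-averaged afterwards; counts are fit raw, with no
cross-sample normalization (an explicit size-factor vector can be applied
upstream for spike-in designs). Proximal-vs-distal stability is compared per
condition by Wilcoxon signed-rank over genes with both isoforms passing QC;
with fewer than 5 pairs only descriptive medians are reported.

## Motif profiling

The strongest-signal hexamer represents a site annotated with several.
Canonical = {AAUAAA, AUUAAA}; the "other" vocabulary is the 19 documented
non-canonical PAS hexamers (configurable); a hexamer outside both sets is
treated as "other" with a warning. UGUA is counted by exact match at every
offset of the −100..−1 window (overlaps counted, N never matches).
Downstream composition uses the +20..+40 window: %U, %U+G and presence of a
UUUU run; truncated windows compute fractions over the available length.
Group comparisons use two-tailed Fisher's exact test for categorical
features — UGUA as presence/absence, matching the "fraction of genes with a
motif" framing — and the unpaired rank-sum test for the continuous U/UG
fractions.

## Splice-site PWMs

5′ sites are 9 nt (3 exonic + 6 intronic), 3′ sites 23 nt (20 intronic +
3 exonic). PWM probabilities are Laplace-smoothed counts,
(count + c)/(n + 4c), with pseudocount c = 1 by default (c = 0 supported for
exact-formula checks); N-containing training sequences are dropped with a
tally. Sequences are scored by the sum of per-position log10 probabilities —
order-equivalent to the raw product but immune to underflow at length 23.
Per-position information content is 2 + Σ p·log2 p bits (0·log 0 ≡ 0),
ranging 0–2. Groups are compared by one-way ANOVA on log10 scores with
Tukey HSD pairwise adjustment; log scores were chosen because raw
probabilities are heavy-tailed across a 23-position product.

## Statistics kernel

Fisher's two-tailed p sums all tables at fixed margins with point
probability ≤ the observed (the convention of standard tools); a table with
a zero margin carries no information and returns p = 1 with a warning.
Hypergeometric overlap reports the upper tail including the observed
intersection. Paired rank tests with ≤20 nonzero differences use exact
sign-flip enumeration (meet-in-the-middle over subset rank sums), which
remains exact under tied differences where the tabulated null does not;
larger samples use the tie-corrected normal approximation. Unpaired tests
delegate to the exact/asymptotic Mann-Whitney machinery. The gene-set test
compares in-set vs out-of-set log fold-changes by rank-sum, requiring ≥5
usable genes on each side, with BH correction across sets.
Median-of-ratios size factors follow the standard construction: per-gene
geometric-mean reference over genes positive in every sample, per-sample
median ratio.

## Synthetic-data generator

The generator emulates the hierarchical structure 3′-end counting imposes:
per gene and sample a negative-binomial total depth (dispersion/size 10 by
default; Poisson in the infinite-dispersion limit), split multinomially
across the gene's sites by the condition's true usage vector. Planted
shifts move `delta_rud_effect` of usage mass from the proximal to the
distal site (or back); baseline usage is drawn with enough headroom that
the shift stays inside [0,1], and any vector still escaping is floored at
0.01, renormalized, and recorded in the truth table. Defaults — 1000 genes,
2 sites/gene, 2 replicates/condition, mean depth 500, 30% lengthened / 5%
shortened, effect 0.3 — describe a small cohort that runs in seconds while
giving the 0.05 caller clear signal. Decay time courses evaluate
c0·2^(−t/t½) at 0/2/4/8 h with Poisson sampling (or exactly, for
closed-form tests).

Sequence simulation builds each site's −100..+45 transcript-space region
from a deliberately U-free A/C/G background, then plants the assigned
hexamer in −50..−10, optionally one UGUA in −100..−1 (kept clear of the
hexamer), and draws the +20..+40 window iid at the configured U/G
composition. The U-free background guarantees that planted-motif truth is
exact — no spurious UGUA, UUUU or canonical hexamer can arise by chance —
at the cost of realism: real 3′-flanking sequence is U-rich, so passing
tests demonstrate operator correctness and calibrated group tests, not
detection power against genomic background composition. Splice-site
sequences are drawn per position from (1−w)·PWM + w·uniform; w = 0
reproduces the training motif, w = 1 is uniform sequence.

None of the generators simulate raw reads, alignment artifacts, internal
priming, library-size imbalance between conditions, or biological
covariance between APA shift and expression level; results on real data
additionally depend on upstream alignment and atlas quality.

## Problem sizes

The test suite and the acceptance script use cohorts of 300–1000 genes,
500 decay isoforms and 200-sequence splice-site groups — sizes at which
every recovery statistic is stable across seeds while the full run takes
seconds.

## Known limitations

* Differential expression is plumbing only (median-of-ratios + log2FC);
  dispersion modeling and shrinkage are out of scope and pluggable.
* Shift calling uses the fixed ΔRUD > 0.05 rule with no per-gene
  significance test; replicate concordance enters only through averaging.
* Multi-site shift calls are a documented extension, not a standard method.
* PWM training assumes pre-extracted fixed-length windows; no coordinate
  lifting from annotation is performed.
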