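# Methods

This note documents the models, conventions and numerical choices behind
`genomepam`, and what the synthetic-data tests do and do not establish
about real data.

## Coordinates, strands and alphabets

All coordinates are 0-based half-open; 1-based numbers appear only in
display fields (spacer mismatch positions, PAM positions).  Genome
sequences are uppercase over {A, C, G, T, N}; other IUPAC ambiguity
codes are collapsed to N on load.  Any scanning window that contains an
N is skipped outright — an N never equals an ACGT base and never counts
as a "mismatch", so excluding such windows avoids inflating both
occurrence counts and mismatch-class backgrounds.

A k-mer's occurrence count is `fwd(w) + fwd(revcomp(w))`: one count per
strand per locus, because a protospacer target exists independently on
each strand.  A palindromic k-mer at one locus therefore counts twice.
Overlapping occurrences all count.  The same convention backs the
Hamming-neighborhood census, so its distance-0 bin always equals the
k-mer census count.

PAM positions are numbered outward from the spacer: 1..10 into the 3′
flank for Cas9-like enzymes, −10..−1 in the 5′ flank for Cas12a-like
enzymes (−1 adjacent to the spacer).  Flanks are always stored in
protospacer orientation, so a minus-strand site's 3′ flank is the
reverse complement of the genomic bases 5′ of the hit interval.

## Target matching

Matching is substitution-only (no bulges): the cleavage data this
pipeline consumes is itself called with a ≤6-substitution criterion, and
indel-tolerant alignment would change the identity of the PAM-side
flank.  Spacers of 21–22 nt may carry IUPAC degenerate bases (e.g. a 5′
Y); a genomic base inside the degenerate set matches at zero cost.
Sites whose 10-nt flank windows run off the chromosome or contain N are
dropped and counted in the log.

Integration events are assigned to the nearest candidate target within
25 bp of the protospacer interval (configurable).  The cut site sits
near the PAM-proximal end of the protospacer, so a tolerance of roughly
one protospacer length is generous without being promiscuous; exact
equidistant ties break deterministically to the lowest
(chrom, start, strand), with a warning.

## PCV

PCV(p) is the captured fraction of PAM sequence *p* divided by its
background fraction.  Two choices deserve comment:

- **Background population.**  The default background is the PAM-window
  L-mers of *all candidate genomic targets of the spacer* (the ≤max-mm
  template set) — i.e. what the capture experiment could actually have
  drawn from — rather than genome-wide L-mer frequencies.  For a repeat
  with near-random flanks the two are close; for a skewed flank
  population the target-set background is the right denominator.  A
  whole-genome multiset can be supplied instead, since the background is
  an explicit argument.
- **Weighting.**  Captured fractions are read-weighted by default,
  matching the weighting used for the sequence logos; a site-count mode
  exists for sensitivity analysis.  PCV is invariant to uniform scaling
  of read counts.

PAMs with zero background fraction are reported as undefined (NaN), not
infinite; PAMs captured with zero weight get relative PCV −inf, rendered
as missing in exports.  No pseudocounts are added by default (a
pseudocount argument exists).  Invariants maintained on every run: the
captured and background fractions each sum to 1, the background-weighted
mean PCV is 1 (±1e−6), and the maximum relative PCV is 0.

## The motif table

The enrichment statistic is the **edited value**: for the k sibling
motifs of one comparison window, `value_i = sites_i + reads_i ·
max(sites)/max(reads)`, so the rescaled read totals span the same range
as the site counts.  If all read counts are zero the scale factor is 0
and the values reduce to site counts (with a warning).

Significance within a window is a goodness-of-fit Pearson chi-square:
observed = the k edited values rounded to integers, expected =
proportional to the k genomic background target counts, df = k−1,
two-sided.  An earlier 2×k contingency formulation (second row =
background − edited) was rejected during development: because the edited
value folds read weight into pseudo-counts that can approach or exceed
the background, the floored remainder row made the test wildly
anti-conservative — a uniform-flank null at 50% capture produced
p ≈ 1e−27.  The goodness-of-fit reading of "edited value against the
genomic background counts among all motifs" is calibrated on the null
(uniform flanks give p near 1) while leaving real enrichment signals
astronomically significant.  Motifs with zero background are dropped
from a window (their expected count is undefined); a window with fewer
than two informative motifs has an undefined p.

The search: step 1 evaluates all 4 bases at each of the 10 PAM window
positions (40 candidates) and seeds at the position with the smallest
window p-value; each later round evaluates 4 candidate bases on the 5′
side and 4 on the 3′ side of the current motif and keeps the more
significant side.  Within a window the recorded motif is the base with
the largest edited value per background target (observed/expected
enrichment), breaking ties by percent edited and then lexicographically
— the procedure is fully deterministic.  Extension continues to the
window boundaries; the full trace is always emitted.

The **retained** (reported) motifs must pass a Bonferroni-corrected gate
(α = 0.01 divided by the number of candidates in that round — there is
no published threshold, so a conservative default is used) *and*
strictly increase the fraction of genomic background targets edited.
For a PAM-less enzyme this leaves at most the seed step, and in seeded
practice nothing.  Edited sites include mismatch sites by default (the
published totals are target-wide); a perfect-only switch exists.
Percentages are reported to one decimal, rounded half-up (1103/1681 →
65.6, 449/477 → 94.1).

## Comparative metrics

Relative activity is an enzyme's perfect-match site count over the
wild-type reference's; relative specificity is its perfect/mismatch
ratio over the high-fidelity reference's.  Ratios with zero denominators
are NaN, never inf.

Downsampling draws reads without replacement from the site × read-count
table (multivariate hypergeometric), detecting a site when it receives
≥ min_reads (default 1).  This is a desk-scale proxy with an exact
sampling distribution — it does not re-run read-level site calling, so
it reproduces full-pipeline downsampling curves qualitatively, not
numerically.  At full depth it returns the exact site counts; the
detection frequency of a singleton-read site at depth n of N is n/N.

Window profiles bin a site's reads into the fixed-size window (default
5 Mb) containing its protospacer start — windows are three orders of
magnitude longer than sites, so edge assignment is immaterial.  The last
window of each chromosome may be short.  Proportions are normalized per
sample; a sample is compared to the arithmetic mean of reference
replicate proportions per window, log2-transformed.  Reference-zero
windows are missing (NaN); sample-zero over positive reference is −inf.

## The simulator

`simulate` emulates the assay's data-generating process, not its
chemistry: a uniform-random background genome; planted non-overlapping
targets on random strands, each with independent uniform 10-nt flanks;
a fraction of copies carrying 1–6 spacer substitutions biased (60%)
toward spacer positions 8–11, where mismatch sites typically
accumulate; an IUPAC pattern → activity map anchored at the
spacer-proximal flank end (most specific matching pattern wins); capture
of active sites with probability 0.9 by default; and per-site reads from
a negative binomial with size 2 — read counts per site in real capture
data span orders of magnitude, so a Poisson would be far too tight —
conditioned on ≥1, with the mean scaled by activity and by a 0.3
per-mismatch penalty so on/off metrics have tunable ground truth.

Defaults (2,000 perfect + 400 mismatch targets, depth 100, capture 0.9)
are desk-scale stand-ins for an assay that sees thousands of perfect
repeats per cell.  Recovery experiments size the planted population so
~500 edited sites are captured per run (≈36,000 targets on a ≈4.3 Mb
genome for PAMs with 1/64 match probability), then run the full
pipeline: genome scan for background templates, capture, motif table.

What passing these tests shows: the census/matching code agrees with
brute force; the statistics recover planted PAM architectures (NGG,
NNGRRT, 5′-TTTN, NNNNRYAC) and stay quiet on PAM-less models.  What they
do not show: robustness to real-genome features absent from the
simulation — non-uniform base composition, repeat-family structure and
assembly gaps in flanks, chromatin effects on capture, PCR/UMI
artifacts, or bulge-mediated off-targets.

## Known limitations

- Substitution-only matching; bulged targets are invisible.
- Single-motif output: a disjunctive PAM (two unrelated accepted motifs)
  yields only the dominant branch of the seed-extension path.
- The read-scaled edited value mixes two evidence types; its chi-square
  p-values are calibrated against a uniform null but, like the original
  statistic, should be read as rankings rather than exact error rates
  when read counts are heavily overdispersed.
- The downsampling and window-profile modules operate on site tables,
  not raw reads.
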