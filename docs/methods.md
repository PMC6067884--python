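# Methods

This note documents the models, default parameters and numerical
choices behind each component, what the synthetic-data generator does
and does not emulate, and the open design decisions we resolved.

## Read waterfall

Reads are assigned by sequential elimination over an ordered reference
list; a read belongs to the first category whose aligner call matches
it, and to `unaligned` if nothing does. The partition is checked to be
exhaustive and disjoint on every run: an aligner whose matched and
unmatched sets overlap or miss reads aborts the run with the offending
ids, rather than silently double-counting.

Alignment is deliberately behind a contract. Short-read alignment is a
solved problem and not this package's contribution; production runs can
feed any external aligner's matched/unmatched sets through the same
bookkeeping. The shipped matcher declares a match iff the read occurs
as an exact substring of a reference or of its reverse complement
(references are concatenated with `#` separators so matches cannot span
two sequences), which is exact for the error-free synthetic dialect.

The titer proxy divides pathogen-assigned reads (de novo transcriptome
plus annotated transcripts, pooled) by pathogen plus host-*mRNA* reads.
Host ncRNA and genome-aligned reads are excluded from the denominator
by default because the proxy is defined over transcriptome-aligned
reads; the role tags on `ReferenceSet` make other conventions a
one-line change. A zero denominator raises rather than returning a
sentinel — a sample with no host or pathogen transcriptome reads has no
meaningful titer.

## Decontamination

Threshold semantics are part of the contract and are boundary-tested:

| filter | rule | boundary |
|---|---|---|
| taxon | remove if any hit e ≤ 1e-40 to a disallowed taxon | inclusive |
| control expression | remove if total TPM = 0 or control share > 10% | strict > |
| host-region masking | mask bases in hits with e < 1e-10 | strict < |
| unannotated assignment | classify if length > 300 bp and e < 1e-10 | strict both |

Transcripts with no homology hits are retained by the taxon filter
(absence of a database hit is not evidence of contamination), and
transcripts absent from the expression matrix are retained by the
expression filter for the same reason. Masking merges overlapping
1-based inclusive intervals and never changes sequence length or id.
Each stage partitions its input exactly (checked), and each stage is
idempotent, so re-running a stage on its own output removes nothing.

Taxon labels are supplied by the caller alongside each hit. Resolving
them from a live taxonomy service would tie results to a database
version; a static mapping keeps runs reproducible. The control-share
rule uses sums (control TPM summed over control samples relative to TPM
summed over all samples), not per-sample means. No deduplication is
attempted between the de novo transcriptome and the annotated
transcript set; the waterfall order already ensures a read counts only
once.

## Expression analysis

TPM is computed per sample as `1e6 * (count/length) / Σ(count/length)`;
all-zero samples stay all-zero instead of dividing by zero. The
expression filter uses inclusive boundaries ("at least"). The transform
is log2 with pseudocount 1 — the conventional zero-safe choice for
expression heatmaps — followed by per-transcript mean centering.

Complete-linkage clustering is implemented in-package rather than
wrapped, because the deterministic tie-break is part of the contract:
among pairs at the minimal inter-cluster distance (max pairwise member
distance), the lexicographically smallest (node id, node id) pair
merges first, with leaves numbered by input row order and merge `s`
creating node `n + s` (the scipy id convention). The implementation is
the straightforward O(n³) agglomeration over a distance matrix updated
by elementwise maximum, which is exact and fast at the matrix sizes
this package clusters (hundreds to low thousands of rows). Tests check
merge-for-merge agreement against both an independently written
brute-force oracle and scipy's `linkage` on tie-free data. Distances:
euclidean on the log-centered matrix (default) or 1 − Pearson
correlation; the choice is exposed because published heatmaps rarely
state their metric. Heatmap columns are ordered by ascending fungal
titer, ties broken by sample id.

The two-group one-way ANOVA is computed vectorized from sums of
squares, with `F = MS_between / MS_within` on (1, n−2) degrees of
freedom; identical group means (including all-constant rows) give
F = 0, p = 1. Cadaver samples are excluded from differential tests by
construction of the sample filters, since post-mortem RNA degradation
confounds expression differences. Fisher enrichment uses the two-sided
point-probability convention (sum of tables no more probable than the
observed one), and BH adjustment runs over exactly the tested terms.

## Death timing

The native DAM resolution is 30 s bins; a death call is the end time of
the surviving last nonzero bin, so calls are accurate to one bin and
sub-bin timing is not inferred. The correction for spurious post-mortem
signals is an iterated trailing-gap rule: while the event-to-event gap
between the last candidate and the previous nonzero bin exceeds 24 h
(strictly), the candidate is discarded. Iteration lets stacked
artifacts collapse onto the true last movement; the number of discarded
events is reported so corrected calls are auditable. A gap of exactly
24 h is kept. The rule automates what is otherwise a manual
re-assignment; whether a manual curator would ever move a call earlier
than the penultimate event is unknowable, so the automated rule is
declared, not inferred.

Offsets are signed hours relative to the light→dark transition: deaths
in photophase map to negative values (−2 means 2 h before sunset),
deaths in scotophase to positive values, giving a range of
(−light_hours, +dark_hours]. Under constant darkness, offsets are
computed against projected subjective transitions from the phase
anchor. Cohort gating is tested by a KS statistic of
hours-since-transition against uniform(0, 24): gated LD cohorts reject,
sporadic DD cohorts do not. Rebinning to 15–30 min windows sums counts
and conserves totals exactly (a trailing partial window is kept).
Monitor files follow the TriKinetics tab-delimited dialect (10 metadata
columns, then 32 channel counts per row); rows whose status field is
not 1 are excluded with a warning tally, and wrong column counts or
non-monotone timestamps abort with the line number.

## Probe selection

k-mer counting is canonical: each N-free window contributes one count
to the lexicographically smaller of the window and its reverse
complement, because a FISH probe targets double-stranded DNA. Ties in
abundance are broken lexicographically for determinism. A streaming
mode processes contigs in chunks overlapping by k−1 and returns
identical counts to the in-memory mode. The probe report's melting
temperature uses the Wallace 2(A+T) + 4(G+C) rule — a coarse screen,
labelled approximate, not a nearest-neighbour calculation. Probe
specificity screening against the host genome is composable (run
`count_kmers` on the host) but not a shipped feature.

## Synthetic-data generator

The generator emulates the statistical structure of the study design at
desk scale; every generator is a pure function of its config (seed
included).

* **References/reads**: uniform-random ACGT references (so cross-
  category 30-mer collisions are absent in practice), error-free reads
  as exact 100 bp substrings, multinomial category mixtures. The
  default schedule moves the pathogen share from 0 (24 h) through trace
  (48 h) and substantial (72 h) to dominant in cadavers, with 1.5%
  unalignable "junk" reads emulating the residual read class. An
  optional uniform substitution rate exists for robustness tests.
* **Expression**: the 42-sample design (3 controls × 5 timepoints, 21
  exposed, 6 cadavers). A logistic latent titer, midpoint 72 h and
  scale 8 h, is ~0 at 24–48 h and ~1 by 96 h, reproducing the observed
  late detection of fungal reads. Group i scales with titer, group ii
  with titer only while the host lives, group iii only after death;
  background transcripts are constant in infected samples.
  Multiplicative lognormal noise at CV 0.2 by default. Control leakage
  of fungal transcripts defaults to 0 and is exposed as a knob because
  no quantitative leakage rate is established.
* **DAM**: per-bin Poisson counts at a 3:1 photophase:scotophase rate
  ratio (0.6 vs 0.2 per 30 s bin; a conventional, documented choice),
  80% mortality between days 4 and 7, deaths gated into [−5, 0] h
  before sunset under 12:12 LD and uniform over the day under DD, a
  guaranteed movement in the death bin and none after it. Spurious
  events are planted as single count-1 bins 25 h after death.
* **Genome**: planted repeats occupy distinct k-aligned slots, which
  guarantees non-overlap deterministically at any copy number (the
  slight positional regularity is irrelevant to counting).

What the generator does **not** emulate: sequencing errors and quality
scores, GC/coverage bias, realistic fungal gene content, paralogy and
shared sequence between host and pathogen, partially penetrant
infections, or activity rhythms beyond a square-wave photoperiod
response. Passing tests therefore demonstrate correctness of the
bookkeeping, thresholds and inference rules under clean conditions —
not robustness to alignment ambiguity or biological heterogeneity,
which enter through the pluggable aligner and user-supplied homology
hits in real use.

## Problem sizes and calibration checks

The test suite and acceptance script run at sizes chosen to exercise
every code path while completing in well under a minute each: 10⁵ reads
for waterfall label recovery, 50 random 12-row matrices for clustering
oracle equivalence, 5000 null transcripts for ANOVA type-I calibration
(expected rejection 5% ± 3 SE at α = 0.05), all 2×2 tables with total
n ≤ 12 for Fisher enumeration, 200-fly cohorts (20 with planted
artifacts) for death calling, 20-seed replicates of 40-fly cohorts for
the LD/DD gating contrast, and an 18-mer planted 50 times in 1 Mb
(tests) or 11,000 times in 2 Mb (acceptance script) for probe
selection.
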