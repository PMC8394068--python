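# Methods

This note documents the models, parameter choices and numerical decisions
behind `stescan`, and what the synthetic-data tests do and do not
establish about real data.

## Window scoring and the threshold

The scan scores each window of length W = 22 (the query motif length)
ungapped: +5 per identical unambiguous base, −4 per mismatch, and any
non-ACGT character mismatches everything. The score of a window with
*m* identities is therefore

    S(m) = 5m − 4(22 − m) = 9m − 88,

a strictly increasing function of *m*, so every score threshold is an
identity threshold: S ≥ 56 ⇔ m ≥ 16 ⇔ 72.7 % identity. The +5/−4 values
are the classic DNA match/mismatch weights (EDNAFULL-style); they are the
unique small-integer pair for which the calibrated threshold of 56 sits
exactly on the 16-of-22 boundary implied by the 72.7 % matches that the
screen is designed to admit. Because only the induced identity threshold
matters, any scheme with the same m-boundary behaves identically.

`calibrate_threshold` sweeps every integer threshold from −88 to 110 and
returns the **largest** value at which each labelled reference yields
exactly its expected merged-hit count. Largest is the conservative end of
the feasible band: it trades missed ancient, highly divergent copies for
fewer false positives. Merged-hit counts are non-increasing in the
threshold over the informative range (T ≥ 0); below zero essentially all
windows are accepted and overlap-merging collapses them into one cluster
per strand, so counts there carry no calibration signal. The raw
(unmerged) accepted-window count is monotone everywhere.

Overlapping accepted windows on the same strand merge into one hit,
represented by the best-scoring window (leftmost on ties). This matches
how distinct motif copies are counted: a true copy produces a short run
of above-threshold windows, not several independent hits.

## LUR extraction rules

Only protein-coding and rRNA features bound an unassigned region. tRNAs
neither split nor mask a region (a gap containing tRNAs is one contiguous
LUR), and features classified `orf_uncertain` or `other` never bound one;
reclassification of inconsistently annotated DUI ORFs is driven by a
user-editable override table rather than guessed from qualifiers. All
gaps at or above `min_length` (default 100 bp, configurable) are
reported, plus always the single longest — a deliberate superset, since
no unambiguous per-genome selection rule exists and downstream filtering
is cheap. Internal coordinates are 0-based half-open with wrapped
intervals (`end ≤ start`) on circular genomes; written reports are
1-based inclusive.

## The null model

The significance question is: given that a putative STE with percent
identity *p* was observed in a LUR of length *L* and composition
π = (π_T, π_C, π_G, π_A), how often would random sequence do as well?
Each of `n_reps` = 1000 replicates draws L i.i.d. bases from π (or from
the flat 0.25 model), and every window with at least
k = ⌈(p − 0.05)·W/100⌉ identities counts as a hit — overlapping windows
included, no merging, forward orientation only (compositions are reported
for the strand carrying the putative STE; a both-strand null is available
behind a flag). The pseudo p-value is the fraction of replicates with ≥ 1
hit; significance is flagged at raw pseudo-p ≤ 0.05 with no
multiple-testing correction (a Bonferroni column is emitted for
transparency but not used for the flag). The 0.05 subtracted in the
percent-to-k conversion absorbs one-decimal rounding of reported
percentages; it maps 72.7 → 16, 77.3 → 17, 81.8 → 18, 95.5 → 21, 100 → 22.
Published compositions rounded to three decimals may sum to 0.999 or
1.001; sums within 0.005 of 1 are renormalized, anything further off is
rejected.

Because bases are i.i.d., the identity count of one window is
Poisson-binomial with per-position success probability π(motif base).
`window_match_prob_exact` builds the distribution by dynamic programming
over the 22 positions (exact to floating precision), and
`expected_total_hits` = n_reps·(L − W + 1)·P(m ≥ k) is exact despite
window overlap, by linearity of expectation. This analytic oracle is the
primary correctness check on the Monte-Carlo machinery: simulated totals
must sit within sampling error of it for every configuration. The
distribution of *replicates with ≥ 1 hit* has no comparably clean closed
form under window dependence; the independence approximation
1 − (1 − P)^(L−W+1) is used only for sanity checks, never reported.

Per-replicate randomness derives from the master seed by spawning one
`numpy.random.SeedSequence` child per replicate index, making replicates
independent and the whole run exactly reproducible.

## Similarity and flanks

Two measures are reported. Ungapped identity applies to equal-length
windows. For elements of unequal length (known divergent STEs run 22–24
bp) a global pairwise alignment is used: match +5, mismatch −4, affine
gaps −10/−0.5, with percent = matches / **all** alignment columns, so an
alignment of 24 columns with 15 matches reports 62.5 %. Pairwise global
alignment replaces multiple alignment here because every reported
similarity is a pairwise percent against the known motif; exact column
placement can differ from any particular multiple-aligner output by a
column or so, and the percentages are treated as descriptive. The 30 bp
flank 5′ of each hit (on the hit's strand, truncated at sequence
boundaries, wrapped on circular records) is reported with its adenine
fraction and longest adenine run; these are descriptive statistics only —
no significance test is attached, since the biological claim they inform
(adenine tracts upstream of mytilid STEs) is qualitative.

## Phylogeny

p-distances with pairwise deletion: per pair, columns where either
sequence has a gap or ambiguity are dropped; a pair with no comparable
columns is an error, not a zero. Neighbor-joining is the classical
Saitou–Nei agglomeration with the Q-criterion; ties are broken by the
lexicographically smallest leaf label carried by each cluster, making the
tree deterministic. Negative branch lengths are clamped to zero with the
deficit moved to the sibling edge, preserving the joined pair's total.
Bootstrap support resamples alignment columns with replacement and counts
the fraction of replicate trees containing each original bipartition,
reported as integer percentages. The tree is an overview device — p-
distance NJ underestimates divergence at depth, which is acceptable for
displaying which lineages carry STE-like signatures but not for dating or
rigorous systematics.

## Synthetic data: what it emulates, and what it does not

The generator lays out a circular genome from a configurable gene
template (default: 13 OXPHOS protein genes, 2 rRNAs, 22 tRNAs of typical
lengths, the arrangement ending in the two rRNAs) separated by fixed
20 bp low-complexity GC spacers, followed by a single unannotated region
of specified length and composition — the spacers guarantee the LUR is
unambiguously the longest unannotated stretch, keeping ground truth
unique. Motif copies are planted by overwriting a window with a degraded
copy holding exactly *m* identities; mismatch positions are chosen
uniformly without replacement and substituted bases never equal the
motif base (no divergence model is imposed beyond the identity count,
since none is known for putative STEs). A rotation parameter moves the
sequence origin, producing origin-wrapping LURs for circularity tests.

Default LUR composition (0.30, 0.15, 0.20, 0.35) reflects the AT-rich
control regions in the published compositions. The generator does **not**
emulate codon structure, tRNA cloverleaves, repeats, length
heterogeneity within a genome, or recombination/masculinization events.
Passing the synthetic round-trips therefore shows that extraction,
scanning, calibration and counting are correct under the stated
composition model — it does not show that real annotations are clean, and
real GenBank records with inconsistent feature types still need the
override table.

## Problem sizes and numerics

Monte-Carlo runs use the published design throughout: 1000 replicates
per configuration, full-length LURs (557–4620 bp). The whole 19-row grid
under both composition modes completes in well under a minute on one
core, as window identity counting is vectorized over strided window
views. Planted-motif recovery tests use 100 LURs of 2000 bp with one
copy at every identity level 14–22; the expected background false-hit
rate at the 16/22 threshold is below 0.1 per LUR for the compositions
used, and observed counts are checked against the analytic expectation
rather than assumed zero. The alignment oracle in the tests enumerates
affine-gap alignments recursively for strings up to 12 bp; the NJ
correctness tests reconstruct 100 random additive trees of 5–8 taxa and
additionally cross-check topology against an independent NJ
implementation on generic matrices.
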