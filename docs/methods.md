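# Methods

## Restriction digest and fragment identity

A genome is tiled by cutting at every occurrence of the enzyme recognition
sequence; the boundary for an occurrence starting at position *s* is
`s + cut_offset`, collected for occurrences of the site and of its reverse
complement on the forward strand, deduplicated and sorted. For palindromic
sites (the default `CATG`, cut offset 4, NlaIII-style) the two strands
coincide; for non-palindromic sites the union is the safe superset.
Overlapping occurrences each contribute a boundary. IUPAC codes in the
recognition sequence are honoured, with one deliberate asymmetry: code `N`
matches any base including a literal `N`, but a literal `N` in the genome
is matched *only* by code `N`, so runs of assembly `N`s cannot create
spurious cut sites.

Fragment ids are dense integers per chromosome in coordinate order, with a
gap inserted between chromosomes. This makes `|id_i − id_j| == 1`
equivalent to genomic adjacency — the property the self-ligation and
continuous-fragment filters rely on — and guarantees fragments on
different chromosomes are never "adjacent".

## Read decomposition and filters

Reads are split with the same cut convention as the digest, so each ligated
fragment of a concatemer becomes one piece carrying the recognition-site
remnant, and pieces are assigned to fragments by exact lookup of the
fragment sequence or its reverse complement. Exact-match assignment
replaces read alignment at desk scale; fragments with non-unique sequences
are excluded from the index as ambiguous rather than guessed.

Filters, in order: (1) a read whose first assigned fragment is not the
viewpoint is rejected as off-target; (2) members within
`self_ligation_window` fragments of the viewpoint (default 1, i.e. the
viewpoint and both immediate neighbours) are removed as self-ligation /
undigested bait products; (3) runs of consecutive members that are
genomically adjacent collapse to the first member of the run — such runs
are partial-digest neighbours travelling as one piece of chromatin, not
independent contacts; (4) exact duplicate members are dropped. Steps 3–4
are iterated to a fixpoint so that no retained chain ever contains a
consecutive genomically-adjacent pair, even when a removal or
deduplication brings two such members together. Rejections are categorised
counts satisfying `reads_in = retained + off_target + empty_after_filter`.
PCR-duplicate removal (identical viewpoint + member tuple) exists behind a
flag and defaults off.

## Pairwise profiles

`first_only` (default) counts one contact per chain — the first digested
fragment behind the viewpoint — matching conventional 4C-style profiles;
`all_members` counts every distinct member and is provided for sensitivity
analysis. CPM-in-cis divides by the total count on the viewpoint
chromosome only; trans fragments are retained and scaled by the same
factor (the denominator is cis by definition), with a flag to drop them.
Per-fragment values are the base representation; fixed windows of k
fragments (default 30) are exported as count tables for external
differential testing, which this package deliberately does not
re-implement.

## Three-way matrices

Fragments map to bins by midpoint, half-open bins of 3/5/10 kb (or any
user resolution) over an analysis window. Per chain, either the unordered
pair of the first two members or all unordered pairs of distinct members
(each pair + the viewpoint = one triple) increment the matrix; pairs with
a fragment outside the window are skipped, two fragments in one bin
increment the diagonal once. Counting is unordered — each co-occurrence
counted once — which makes "a total of 1,000,000" unambiguous;
normalization multiplies by `1e6 / total`. Subtraction requires two
normalized matrices on an identical grid. Loop calling thresholds *raw*
counts (≥ 5 inclusive, off-diagonal) with no adjacent-bin merging. No
Hi-C-style balancing (ICE/KR) is applied; these matrices are
viewpoint-conditioned counts, not genome-wide contact maps.

## VP-SOI resampling test

Chains partition by whether any member's fragment midpoint lies in the SOI
interval. The positive profile is per-read presence/absence per bin
(fraction of positive reads touching the bin), not fragment counts. The
null profile resamples, in each of `n_iterations` (default 1,000)
iterations, `|positive|` negative reads without replacement and removes
one uniformly chosen member from each sampled read — the removed fragment
plays the role of the SOI fragment that every positive read carries. Mean
and *population* (n-denominator) standard deviation per bin across
iterations give `z = (f⁺ − μ)/σ`.

**Cardinality-weighted sampling.** A read enters the positive set with
probability roughly proportional to its number of ligated fragments (each
fragment is one chance to hit the SOI), so positive reads carry more
residual fragments than a uniformly drawn negative read minus one. The
default therefore draws negative reads with probability proportional to
their member count (size-biased sampling without replacement via
exponential/Efraimidis–Spirakis keys); under independence, a size-biased
read with a uniformly removed member is distributed exactly like a
positive read's non-SOI remainder, which is what makes the null z-scores
centre on zero for libraries with mixed cardinality. Uniform sampling
remains available (`weighting="uniform"`) but is anti-conservative when
cardinality varies. Sampling with replacement is behind a flag for the
case `|negative| < |positive|`.

Numerical details: σ = 0 yields an undefined z — labelled random when
f⁺ = μ, otherwise cooperative/competitive by sign with `+inf`/`-inf`
sentinels in tabular output. Bins overlapping the viewpoint fragment or
the SOI are excluded from classification (their signal is trivially
induced). The default threshold |z| ≥ 2 is a configuration value surfaced
in the run metadata, not a significance guarantee: with ~100 bins an
unstructured library produces a handful of |z| ≥ 2 calls by chance, and no
multiple-testing correction is applied. The RNG is a seeded PCG64
generator; identical seed and inputs give bit-identical results.

## Synthetic generator

The generator emulates the structure of a viewpoint-primed multi-contact
library over one dense locus, with defaults chosen once as the emulated
study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| locus length | 500 kb | sub-TAD analysis window scale |
| mean fragment spacing | 150 bp | a 4-cutter's expected spacing |
| viewpoint | 250 kb (centre) | symmetric decay coverage |
| decay exponent α | 1.0 | canonical sub-Mb contact decay, P ∝ d^−α |
| fragments per read k | 1–5, probs (.15,.25,.25,.20,.15) | concatemer reads, mean ≈ 2.9 |
| min fragment length | 30 bp | keeps exact-match assignment unambiguous |
| sequencing errors | 0 | assignment is exact-match; rate is a knob |

Recognition sites are planted at exponential spacing and the intervening
random sequence is scrubbed of accidental occurrences (both strands), so
the digest of the emitted FASTA reproduces the planted boundaries exactly
and all fragment sequences are unique. Reads are the viewpoint fragment
plus k partners drawn with weight `d^−α` (distance floored at one fragment
spacing; the viewpoint and its immediate neighbours are excluded — those
partners would be discarded by the self-ligation filter). An optional
boundary multiplies cross-boundary weights by an insulation factor
γ ∈ (0, 1]; `emit_condition_pair` builds matched libraries differing only
in γ (e.g. γ_wt = 1.0 vs γ_ko = 0.5) from a split seed stream. Planted
triads multiply the partner weight of interval B by β once a fragment of
interval A has been drawn, and symmetrically — a deliberately simple
mechanism whose expected co-occurrence is analytically checkable (joint
probability scales by β; marginals are nearly untouched for small
intervals).

What the generator does *not* emulate: polymer physics beyond a power
law, replicate-level biological variability, PCR duplication, sequencing
errors or mapping ambiguity, trans chromosomes, and viewpoint-specific
primer artifacts. Passing tests therefore demonstrate correctness of the
computation and calibration of the statistic under the generative model's
assumptions, not robustness to every artifact of real libraries.

## Statistical checks and problem sizes

The acceptance-level tests run the full pipeline (FASTQ-free, in-memory):
null calibration uses 20 replicate libraries of 20,000 reads (no triads)
and requires the pooled z over classified bins to have mean within ±0.3
with ≥ 90% of |z| < 3; planted-effect recovery uses β = 4 and β = 0.25
triads between the 270–275 kb SOI and the 230–235 kb third site, 20
replicates each, requiring |z| ≥ 2 at the third-site bin in ≥ 90% of
replicates; the insulation contrast compares matched 10,000-read libraries
at γ = 1.0 vs 0.5 and requires the cross-boundary sum of the KO − WT
normalized 5-kb matrix difference to be negative. The SOI and third-site
positions were fixed by a pre-run power calculation (the competitive
direction bounds the achievable deficit by the baseline bin frequency, so
both intervals sit within ~20 kb of the viewpoint where baseline
frequencies support detection). The 2-negative-read enumeration oracle
checks the resampler against the exact removal distribution (mean 0.5,
sd √0.125) within three standard errors at 1,000 iterations.

## Known limitations

- Exact-match assignment cannot place reads with sequencing errors; real
  libraries need an aligner upstream (chains can be imported as TSV).
- The z-scores are per-bin and uncorrected; treat isolated |z| ≥ 2 calls
  as candidates, not discoveries.
- Off-target filtering does not distinguish trans-chromosomal fragments;
  they simply never match the viewpoint-first rule or the cis window.
- Loop calling reports raw-count bins on a single matrix; pooling of
  replicates, if any, must happen upstream.
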