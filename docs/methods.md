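# Methods

## Scope and model

`nucpos` analyses nucleosome organization from paired-end MNase-seq. The
underlying model is the standard ensemble-average picture of chromatin: each
sequenced fragment is one nucleosome's protected DNA in one cell, its
midpoint approximates that nucleosome's dyad, and the per-base dyad
frequency across the population describes positioning. Well-phased genes
show a nucleosome-depleted region (NDR) over the promoter, a strongly
positioned +1 nucleosome just inside the coding region, and a downstream
array whose center-to-center spacing is the nucleosome repeat length (NRL).

Read alignment and RNA-seq quantification are out of scope: the package
consumes aligned proper pairs (SAM/BAM) and differential-expression gene
lists (TSV), and a GFF3/FASTA annotation pair.

## Coordinates and dyad assignment

All internal coordinates are 0-based half-open; GFF3/SAM 1-based
conventions exist only at the I/O boundary. The fragment span is leftmost
mate start plus template length (ISIZE), without CIGAR reconciliation.
The dyad of `[start, end)` is `floor((start + end − 1)/2)`. For even-length
fragments the true midpoint falls between two bases and the floor picks the
left one; this deterministic tie-break breaks exact strand-mirror symmetry
by 1 bp for even lengths (the mirror-symmetry property test therefore uses
odd-length fragments), and is far below every tolerance used elsewhere.

Duplicate fragments are retained (MNase-seq coverage is count-based) and no
mapping-quality filter is applied by default (`min_mapq=0`).

## Size selection, profiles, normalization

Nucleosomal fragments are selected at 150 ± 30 bp, inclusive on both
bounds ([120, 180]). Gene-anchored profiles place offset 0 on the anchor
(the A of the ATG, the last base of the stop codon, or a previously
assigned +1 summit) and orient downstream positive on both strands. Bins
beyond chromosome ends are masked. Aggregates over genes are the per-bin
mean of the valid per-gene raw counts followed by a single window-mean
normalization (figure-style path); clustering and classification instead
normalize each gene's profile to mean 1 so sequencing depth cannot drive
either. Normalization is idempotent and scale-invariant by construction.

The CHR/DNA ratio divides two normalized profiles bin-wise and masks bins
where the naked-DNA control falls below a floor (default 0.05 after
normalization) instead of dividing; the naked control is depth-normalized
by the same window-mean rule before division.

## Smoothing and peak calling

Smoothing uses the Epanechnikov kernel K(u) = 0.75(1 − u²), |u| ≤ 1,
sampled at 1-bp bins with bandwidth 30 and weights normalized to sum 1.
Masked bins are excluded and the kernel mass renormalized over the valid
support, so constant profiles are unchanged everywhere, the output never
exceeds the input maximum, and total signal is conserved away from mask
edges.

Peaks are strict local maxima of the smoothed profile; equal-value plateaus
report their leftmost bin and segment edges are never summits. A noise
floor removes shallow maxima: `noise_frac` (default 0.05) times a reference
level. Two references exist:

- **mean** (default): 5% of the window mean. Appropriate for deeply covered
  aggregate profiles, and the package's reading of the otherwise undefined
  "0.05" in the kernel-estimation step it reimplements — an assumption, and
  configurable.
- **max**: 5% of the profile maximum, used by the per-gene classification
  path. On sparse single-gene profiles a mean-referenced floor cannot work:
  an isolated background dyad produces a kernel-density maximum at roughly
  6–13% of the window mean while true nucleosome peaks sit near 300%, and
  both scale with depth together, so no sequencing depth separates them at
  5%-of-mean. Referencing the maximum makes the floor scale with the peaks
  it is meant to protect and cleanly removes background maxima.

## +1 assignment and NRL estimation

The +1 nucleosome is the first called peak at offset ≥ 0 within a search
limit (default 300 bp) of the ATG. A configuration flag restores the
literal upstream ("5′") reading, but the default follows the observed
first-coding-nucleosome geometry (+60 bp in the system emulated here).
Genes with no qualifying peak are flagged "no +1" and excluded from
+1-anchored aggregates.

NRL is the OLS slope of cumulative distance from the +1 summit against
nucleosome index over the first five peaks at/downstream of the +1
(option: the five tallest downstream peaks in positional order). The
intercept is estimated freely and reported together with r²; the estimate
is invariant under translation of all summits, exact on periodic input.

## NDR measurement

`ndr_metrics` reports the maximal contiguous run of CHR/DNA bins below a
depletion threshold (default 0.8) upstream of the +1 peak — center and
width; ties go to the run nearest the promoter. The pipeline feeds it an
*occupancy-level* ratio: dyad tracks are first convolved with a 147-bp
nucleosome footprint, then aggregated, normalized, and divided. At the
occupancy level the depleted run measures nucleosome-free DNA between the
−1 and +1 footprint edges, which is what "a ~170 bp NDR" denotes, and the
measurement is robust to positioning jitter and depth; a raw dyad-level
ratio would instead measure the gap between dyad density tails, which
widens as positioning tightens. Raw-ratio input remains possible.

## Differential positioning

Per gene and replicate, both conditions' profiles over (0, min(gene length
− 1, 1000)) bp 3′ of the ATG are per-gene normalized, smoothed, and peak
called. Summits are paired by a maximum-cardinality, minimum-total-distance
assignment (Hungarian algorithm) with an 85 bp pairing cap (≈ half an NRL).
Greedy nearest-first pairing was considered and rejected: it is not
equivalent to the assignment optimum (e.g. a = {0, 5}, b = {4, 9}: greedy
pairs (5,4) + (0,9) for total 10 against the unique optimum 8), and the
assignment solution is the one our brute-force oracle tests verify.

A pair is *nonmatching* when |summit shift| > 10 bp or max/min height ratio
> 2 (strict inequalities — a 10-bp shift or exactly twofold change still
matches); unpaired peaks are nonmatching by definition. Heights come from
depth-free normalized profiles, so the twofold rule is scale-free. A gene
is called when every replicate comparison (replicate r of A vs replicate r
of B; a pooled mode sums replicates first) counts ≥ 3 nonmatching
nucleosomes whose reference summit (side A where present) lies in the
window. Calls are symmetric in A/B, monotone in every threshold, and a
self-comparison yields zero calls.

A consequence of the strict rule worth knowing: a uniform +3 bp NRL
expansion accumulates to >10 bp only from the 5th nucleosome on, producing
at most two nonmatching peaks within 1 kb — deliberately below the 3-peak
calling threshold, so a global spacing drift alone does not flag genes.

## Clustering and enrichment

Per-gene normalized profile matrices cluster with Lloyd's k-means
(k-means++ seeding, Euclidean distance, k = 5, best of 100 restarts, fixed
seed 1729, via scikit-learn). Overlap significance between gene sets uses
the upper-tail hypergeometric probability computed through scipy's stable
survival function; raw p-values are reported by default (matching how such
overlap statistics are conventionally quoted), with optional two-sided and
Benjamini–Hochberg variants for batch queries. The enrichment background is
a parameter: stage-restricted backgrounds can change borderline results
materially, so no default other than the full annotation is assumed.

## Synthetic data model

The generator emits per-gene cassettes on one chromosome: a 600 bp AT-rich
upstream block (87% AT) holding the promoter NDR, the gene body (70% AT),
and a 100 bp spacer; strands are drawn 50/50 and minus-strand cassettes are
mirrored. Sequence is i.i.d. per base at the configured AT fraction — only
AT content matters to any pipeline stage. Gene lengths are Normal(1500,
400) truncated at 800 bp (a gene-dense, small-gene genome; the floor
guarantees ≥ 4 genic nucleosomes so planted summit shifts always fit).

Per condition, each gene's architecture is: +1 dyad at ATG + 60 bp, genic
dyads one NRL apart while a full footprint fits (NRL 170 bp growth, 173 bp
mound), a −1 dyad at −250 bp and a −2 one NRL further upstream. The
−250/+60 flanks leave 310 − 147 ≈ 163 bp of nucleosome-free promoter DNA,
the emulated ~170 bp NDR. Planted remodeling (an exact gene count at the
configured fraction) takes one of four modes in the altered condition:
`summit_shift` (+2..+4 shifted 20 bp), `nrl_expand` (spacing → 181 bp),
`height_change` (3× occupancy on +2..+4), `phase_scramble` (±50 bp uniform
per nucleosome).

Fragments: per gene, a multinomial split of `fragments_per_gene` over its
nucleosomes (weighted by occupancy), centers = dyad + Normal(0, 15) per
fragment (cell-to-cell jitter; per fragment, not per gene, matching the
ensemble-average reading of dyad maps), lengths Normal(150, 12) truncated
to [100, 220], plus a 2% uniform background (size-selected nucleosomal
libraries are overwhelmingly nucleosomal). The naked control draws uniform
positions thinned with retention 1 − c·AT(fragment), c = 0.3 by default.
Expression sets flag genes DE with probability q + coupling·(1 − q) when
remodeled and q otherwise, so coupling 0 is exact independence and
coupling 1 nests the remodeled set inside the DE set; DE genes split
~0.585/0.415 into up/down lists. Everything is reproducible from a single
seed through keyed integer RNG streams (condition/replicate indices), so
replicates differ only by stream.

What the generator does *not* emulate: MNase sequence preference beyond AT
thinning, PCR duplicates, mappability artefacts, sub-nucleosomal particle
classes, fuzzy position-shifting between cell subpopulations, or
covariance between expression level and occupancy. Passing tests therefore
demonstrate correctness and statistical power of the pipeline under the
stated noise model, not performance on real libraries.

## Problem sizes and defaults used in checks

The test and acceptance runs use cohorts of 150–300 genes at the default
200 fragments/gene for aggregate-level recoveries (NRL within ±2 bp across
planted 160–190 bp; +1 at 60 ± 3 bp; NDR width 170 ± 15 bp) — at that
depth each aggregated nucleosome collects thousands of dyads, so aggregate
summits are sub-bp accurate. Per-gene classification cohorts (1000 genes,
100 remodeled) run at 900 fragments/gene, ≈ 0.4 dyads/bp: genome-wide
MNase-seq libraries of the kind emulated here reach ≥ 1 dyad/bp, and
per-gene summit standard errors shrink as jitter/√(dyads per nucleosome),
so 900/gene is a deliberately conservative stand-in for realistic coverage
that keeps runtimes in seconds. Null calibration uses 200 sequence-free
cohorts of 2000 genes; upper-tail hypergeometric p-values are discrete and
slightly conservative, which the KS uniformity check tolerates at these
sizes.

## Numerical choices and degenerate inputs

- Plateau peaks take the leftmost bin; window edges are never summits.
- Profiles with no signal (all-zero window) normalize to an error in the
  library API but are treated as "no peaks" by the classification path, so
  unexpressed/uncovered genes compare as matching-empty, not as remodeled.
- `chr_dna_ratio` refuses unnormalized inputs and masks naked-control bins
  below the floor rather than dividing.
- NRL regression raises (reporting the count found) when fewer than
  `n_nucs` peaks lie downstream of the +1.
- bedGraph output covers every base (zero runs included, run-length
  merged), making write∘read the identity on per-base vectors.
- k-means determinism comes from a fixed seed and restart count; empty
  clusters are handled by scikit-learn's standard relocation.

## Known limitations

- The +1 definition and the 300 bp search limit assume promoter-proximal
  phasing; genes with delocalized 5′ nucleosomes are flagged rather than
  called.
- The 85 bp pairing cap ties the matcher to mono-nucleosome scale moves;
  whole-array slides larger than half an NRL register as gain/loss pairs.
- Enrichment p-values are raw by default and conditional on the chosen
  background; stage-specific expression backgrounds are the caller's
  responsibility.
- The classification window (0, 1000) bp 3′ of the ATG truncates at short
  genes' ends, so very short genes can contribute at most their own peak
  count and are conservatively hard to call.
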