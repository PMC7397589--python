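# Methods

This note documents the models, defaults and design choices behind
`loopspread`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic data generator

The generator (`loopspread.synthetic`) emulates the statistical structure of
binned ChIP-seq and Hi-C data from a compact two-chromosome genome
(2 × 2 Mb by default; ChIP bins 40 bp, Hi-C bins 2 kb).

**Genome layout.** Heterochromatin domains (default 24 of 20–50 kb) are
placed without overlap, separated by at least 30 kb of euchromatin, with
random slack distributed between gaps. Each border independently carries a
Beaf32 site with probability `fraction_beaf_borders` (0.5, so that both
flanked and unflanked border groups are populated). Type-2 insulator sites
(GAF or dCTCF, 100 total) sit in euchromatin; a fraction
(`fraction_looped_type2`, 0.5) is placed 20–200 kb from a Beaf32-bearing
border and joined to it by a planted loop. CP190 co-occupies 70% of all
insulator sites; cohesin sites and control cohesin–cohesin loops (unaffected
by depletion) provide negative controls. One gene TSS is placed 200–600 bp
from every Type-2 site, plus 150 background TSSs. Micro-domains (default 50)
are centered on looped Type-2 sites; each spans an integer number of
nucleosome mers (uniform 2–8, one mer = 200 bp). Compartments are an
alternating A/B checkerboard of 100-kb blocks; TADs partition each
chromosome into 40–120 kb blocks on the Hi-C grid.

**ChIP counts.** Expected per-bin enrichment over a flat background: the
heterochromatin fold (6) inside domains, the micro-domain fold (3) inside
planted micro-domains, 1 elsewhere; input and total-H3 tracks are flat. The
depleted condition (KD) attenuates the micro-domain *excess*:
enr = 1 + (3 − 1)·`kd_micro_loss` (0.3 → 1.6), so that all-folds-at-1 is an
exact null. KD additionally gains border spreading at Beaf32-flanked borders
only: the euchromatin-side enrichment is multiplied by
1 + (`kd_spread_gain` − 1)·exp(−d/`spread_length`) (gain 2, decay length
1 kb). The looping mutant mirrors the KD micro-domain loss but has no border
gain unless configured. Counts are Poisson with a per-bin gamma efficiency
factor of shape 1/`dispersion` (0.1) that is drawn **once per bin and shared
across conditions**, modeling bin-specific mappability/accessibility.
Marginally each track is negative-binomial with variance
mean + dispersion·mean²; conditionally on the bin total, the treatment count
is exactly binomial — the regime the enrichment caller models. Independent
per-condition overdispersion would instead make the conditional
beta-binomial and no binomial-based caller could control FDR at these
depths.

**Hi-C.** Expected contact is `hic_depth`·(d+1)^(−α) (α = 1, depth 500 at
the diagonal) times a compartment factor (1 + 0.6 for same-label bins), a
TAD factor (1 + 1.0 within a TAD) and a loop factor (`loop_strength` 4 on
the 3 × 3 pixel neighborhood of each planted anchor pair, multiplied by
`kd_loop_loss` 0.5 in KD for Beaf32-anchored loops only). Counts are
Poisson, sampled on the upper triangle and mirrored.

**Expression.** Genes with a TSS within 1 kb of a planted micro-domain are
up-regulated 2-fold in KD and mutant; all values carry log-normal noise
(σ = 0.1 on the natural-log scale).

**What the generator does not emulate:** read-level artifacts (mappability
holes beyond the shared gamma factor, duplicates, GC bias), replicate-level
biological variance, trans contacts, realistic sequence. Passing tests
demonstrate correctness of the *method chain* under the stated noise model,
not performance on real libraries.

## Micro-domain calling

* **Heterochromatin HMM** — 2-state Gaussian HMM (hmmlearn) on the
  3-bin-smoothed log2((chip+1)/(input·s+1)) ratio, s the library-size ratio;
  the higher-mean state is heterochromatin; domains < 5 kb are dropped. If
  the state means are separated by < 0.5 log2 units the track is considered
  domain-free (this is what a constant track produces). Smoothing uses edge
  padding so chromosome ends are not pulled toward zero.
* **Binomial mixture** — EM on bins with n\_i > 0 (≥ 100 required),
  initialized from the 25th/95th percentiles of t/n, converged when the
  relative log-likelihood change is < 1e-8; components ordered
  θ\_bg < θ\_enr; a fit with |θ\_enr − θ\_bg| < 1e-4 is flagged degenerate.
  The log-likelihood trace is stored and asserted non-decreasing.
* **Calling** — p = upper-tail Bin(n, θ\_bg) of ≥ t; BH over informative
  bins; enriched ⇔ q < FDR and t/n > θ\_bg. Differential labels come from
  the WT-vs-KD run (decrease) and its label swap (increase); a bin
  significant in both directions is set to `none` and counted.
* **Assembly** — qualifying bins (enriched-over-input AND decrease-in-KD by
  default; the disjunction is available via `require="or"`) outside
  heterochromatin are merged allowing **one** interior non-qualifying bin
  (`max_gap_bins=1`): a nucleosome array with a single noisy bin is still
  one array, and a zero-gap rule fragments true domains into a matched call
  plus spurious remnants. Calls shorter than 120 bp (`size_min_bp`) are
  dropped — below half a nucleosome mer a run cannot represent an array.
  Both defaults are configurable. Domain q = minimum bin q; n\_mers =
  round(size/200), floor 1.
* **Swap control** — each swap splits every track into two pseudo-replicates
  by binomial count-splitting and exchanges condition labels between halves;
  the two pseudo-conditions then have identical expected counts in every
  bin, so swap detections estimate false calls. (A half-genome label
  exchange is not a null for consistent effects: detections in the
  unswapped half persist, saturating the estimate near 0.5 regardless of the
  caller's FDR.)

## Spreading statistics

Borders are oriented so profiles run heterochromatin → euchromatin;
insulator presence is a site midpoint within ±500 bp of the border
(configurable). The spreading test compares per-border mean
library-normalized signal in the 0–4 kb euchromatin window, WT vs KD, by
Wilcoxon signed-rank (Pratt zero handling, exact null for n ≤ 25 via
dynamic-programming convolution over signed ranks); groups under 10 borders
are flagged instead of tested. TSS quintile enrichment ranks TSSs by
Δ(KD − WT) signal in ±1 kb with a deterministic (Δ, chrom, position)
tie-break, and Fisher-tests each (quintile, factor) 2 × 2 with
Haldane-corrected log odds. Arrangement enrichment tests the euchromatin gap
opposite a single Beaf32-bearing border (either gap for `both`/`none`)
against the `none` reference class. Error bars on distance histograms use a
half-genome split, as single pooled tracks carry no replicate structure.

## Hi-C engineering and LRI scores

* **Balancing** — symmetric scaling to unit row sums by the damped
  fixed-point iteration x ← x/√(x∘Ax) (the balanced matrix is the same one
  the Knight–Ruiz Newton scheme produces, since the symmetric scaling is
  unique); tol 1e-10 on the max row-sum deviation, masked bins are
  zero-coverage rows plus the bottom coverage percentile (1%).
  Non-convergence raises an error carrying the iteration trace.
* **O/E** — per-diagonal mean of unmasked balanced entries; empty or
  zero-mean diagonals get a log-log interpolated estimate and are flagged.
  Per-diagonal O/E means are exactly 1 wherever defined.
* **Zone geometry** (echoed into all outputs): APA window half-width 10
  bins, center/corner block 3 bins, LRI-1 flank block 10 bins. LRI-2
  averages the block strictly between the anchors *minus a 2-bin margin
  around each anchor* — without the margin the focal loop's own pixels leak
  into the domain-level score and ΔLRI-2 inherits an echo of the loop
  signal. LRI-3 uses the local corner background (standard APA); LRI-1/2 are
  log2 against the global distance expectation of 1.
* **TAD strength** — log2 of within-TAD O/E over border-straddling O/E at
  distance-matched separations (weighted by within-pair counts per
  distance).
* **Compartments** — leading eigenvector of the Pearson correlation of O/E
  rows, per chromosome; sign oriented by an active-chromatin proxy track
  (gene density in the pipeline); A = positive.
* **ΔLRI** — per-pair score(KD) − score(WT) on O/E matrices, so raw-depth
  differences cancel (verified by 2× down-sampling).

## GSEA loop prediction

Per-gene statistics aggregate the ΔLRI of all (Beaf32 site, gene TSS) pairs
separated by > 5 kb (≤ 250 kb). Aggregation defaults are per metric: **min**
for ΔLRI-3 (micro-domain loss tracks the most-impaired loop) and **mean**
for ΔLRI-1/2 (compartment/TAD context is an average property; an extreme
over a variable number of pairs would re-import pair-count structure into a
context metric and mimic signal). The enrichment score is the weighted KS
running sum (hit weights |s|^p, p = 1, normalized over hits; miss step
−1/(N−|S|)); significance is permutation of set membership
(p = (1 + #{|ES\_perm| ≥ |ES\_obs|})/(1 + n\_perm), 1000 permutations,
seeded), with NES = ES/mean|ES\_perm|. A "corrected Fisher" leading-edge
test (top half vs bottom half × in-set) is reported alongside, as the
permutation and Fisher nulls answer slightly different questions and
neither is canonical.

## Numerical choices and degenerate inputs

Pseudocount 1 in all log-ratios; Haldane–Anscombe 0.5 on zero cells of odds
ratios; exact Wilcoxon used below n = 25 (DP over doubled midranks, so ties
are handled exactly conditional on the realized ranks), tie- and
zero-corrected normal approximation above; all-zero paired differences give
p = 1 with a flag; empty interval sets round-trip as zero-length BED files;
anchors map to the Hi-C bin containing the site midpoint; all randomness
flows from explicit integer seeds and identical seeds give byte-identical
outputs, including the on-disk dataset and every pipeline table.

## Problem sizes

Tests and the acceptance script run the default 2 × 2 Mb genome
(100k ChIP bins, 2 × 1000-bin Hi-C matrices): large enough for > 5 kb loops,
16-kb-scale repressive domains and 2–8-mer micro-domains, while a full
pipeline pass takes seconds. Recovery and GSEA checks use 10 seeds; null
calibration uses 20.

## Known limitations

The binomial mixture assumes the overdispersion shared between libraries;
condition-specific overdispersion would require a beta-binomial test. The
HMM caller has Gaussian emissions on the smoothed log-ratio and will merge
heterochromatin domains separated by gaps comparable to the smoothing
window. LRI-1 flank blocks can intersect other planted loops in dense loop
fields; the mean-aggregation default absorbs most but not all of this
contamination. The swap control assumes count-splitting validity (Poisson
thinning), which holds for the generator's Poisson-gamma counts but only
approximately for arbitrary real libraries. Balancing a finite matrix with
a strong distance decay leaves a mild positional structure in O/E
(interior near-diagonal blocks average ~2–3% below 1, chromosome ends
above), which appears as a small constant negative offset in LRI-1/2 block
scores; it is identical across conditions and cancels exactly in ΔLRI.
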