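# Methods

This note documents the models behind each stage, the parameters that
matter, the synthetic scenario used for validation, and the numerical
and design choices made where more than one defensible option existed.

## Signal model

All tracks are dense per-base arrays of **read 3´-terminal nucleotide
counts**, one array per chromosome strand (stored as strand-separated
bedGraph pairs, reverse-strand values positive). Term-seq and short-
read DirectRNA protocols mark the transcript 3´ terminus with the
first sequenced base, so single-nucleotide resolution is meaningful
and the "strongest nucleotide" apex rule is well defined. Coordinates
are 0-based half-open internally; bedGraph is read/written 0-based
half-open, GFF3 1-based inclusive, TSS/position TSVs 1-based —
conversions happen only at the I/O boundary.

## Consensus 3´-end calling

1. **Raw peaks** per replicate via `scipy.signal.find_peaks` with
   width (1, ∞), prominence unconstrained, relative height 0.75.
   Plateau maxima yield one candidate whose apex is the
   strand-downstream-most plateau position, pre-aligning raw calling
   with the downstream tie rule used in curation. Peak extents follow
   scipy's width-crossing convention: the walk from the apex stops at
   the first sample at or below height − 0.75·prominence (a sample
   exactly at the reference height is the included boundary).
2. **Matching**: greedy nearest-apex one-to-one matching with a 100-nt
   tolerance (the same spatial scale as cluster collapse). Exact
   minimum-weight matching is unnecessary at realistic peak densities;
   ties break deterministically by coordinate.
3. **IDR**: replicate heights are rank-transformed to pseudo-uniform
   values (ties — ubiquitous with small integer counts — are broken by
   an infinitesimal jitter from a fixed internal generator, keeping
   the pipeline seed-free and byte-reproducible; without it, tied
   pairs sit exactly on the z₁=z₂ diagonal and the correlated
   component absorbs pure noise). The two-component Gaussian copula
   mixture (reproducible: mean (μ, μ), variance σ², correlation ρ;
   irreproducible: standard normal, independent) is fitted by
   **pseudo-likelihood EM**: after every 8 EM passes the latent
   z-scores are re-derived by inverting the current mixture marginal
   G(z) = π·Φ((z−μ)/σ) + (1−π)·Φ(z) at the rank values, for up to 200
   refreshes. A fixed standard-normal quantile transform overstates π
   by ≈0.1 at realistic mixtures because neither component then has
   the marginal the model assumes. Identifiability floors μ ≥ 0.5 and
   ρ ≥ 0.2 keep pure-noise input off the degenerate ridge where the
   two components coincide and π is arbitrary; ρ is capped at 0.999.
   Four fixed EM starts are run and the best fit kept, compared by the
   Jacobian-corrected copula log-likelihood (comparable across latent
   scales). Local IDR is the posterior probability of the
   irreproducible component; global IDR is the running mean of local
   IDR in ascending order. On the reference mixture (500 pairs, 60%
   reproducible at ρ=0.95) the fitted π is mildly conservative
   (underestimates by up to ~0.07) — a known property of the
   pseudo-likelihood estimator at this sample size.
   Fallback: with < 10 matched pairs or degenerate (constant) scores
   the model is not fitted; all matched pairs are retained
   (presence-in-both-replicates criterion) and the output flagged.
4. **Curation**: pairs with global IDR ≤ 0.05 (the cutoff is exposed
   as a parameter) become provisional ends at the rounded
   strand-downstream midpoint of the two apexes; the final coordinate
   is the maximum of the mean-across-replicates signal within the
   union of the matched extents, ties broken strand-downstream;
   single-linkage clusters at ≤ 100 bp collapse to the
   highest-scoring member (score = apex height, since curation is
   defined on the strongest signal nucleotide, not peak area).

## Rho termination scoring

Windows are strand-oriented, half-open, 800 nt (`w`), with the focal
position assigned to the **upstream** window (on +: upstream
[p−w+1, p], downstream [p+1, p+w]; mirrored on −). Windows wrap on
circular genomes (the default for bacterial chromosomes) and truncate
on linear ones.

- **Rho score** R = (BCM_ds/BCM_us)/(Unt_ds/Unt_us). If any of the
  four counts is zero, +1 is added to all four *for the score only* —
  never for the test — keeping R finite without perturbing inference.
  All-zero counts leave R undefined (NaN, logged).
- **Significance** is the one-sided Fisher exact upper tail for
  downstream enrichment in the BCM row, summed in log space from
  log-gamma terms (exact to the enumeration oracle at small margins,
  stable to p ≥ 1e-320). One-sided matches the directional definition
  of R; a zero margin returns p = 1 by convention. Because reads are
  treated as independent draws, the test assumes each read is an
  independent molecule — true for these protocols at realistic
  sequencing depths, but the p-values would overstate significance on
  data where reads are correlated within transcripts.
- **Genome scan**: rolling cumulative sums give all four windows in
  O(L) per strand; positions with fewer than `min_total_reads = 20`
  raw reads across the windows are skipped, and the Fisher test runs
  only for candidates with R above the positivity threshold. The
  threshold interprets "positive Rho score" as **R > 1** (the
  directional claim; R is strictly positive whenever defined), with
  the stricter descriptive R > 2 available via `positive_threshold`.
- **Region calling** selects representatives greedily by ascending
  p-value — ranked on log₁₀p, since around strong sites the plain
  double-precision p underflows to exactly 0 over a wide span and
  would tie arbitrarily — suppressing qualifying positions within
  ±800 nt of a selected representative on the same strand.

The reported coordinates approximate processed RNA 3´ ends rather than
the actual termination sites; recovering the true (pre-exonuclease)
termination point is out of scope.

## Positional classification and UTR selection

Classes relative to annotated mRNA ORF/tRNA/rRNA/sRNA features
(flank = 50 bp): *primary* — same strand within (g3´, g3´+50];
*antisense* — opposite strand within [start−50, end+50) (one widened
interval, not two separate flanks); *internal* — same strand inside
the feature excluding its 3´-terminal coordinate; *orphan* — none.
Labels are not exclusive (an end can be primary for one gene and
internal to the next); orphan stands alone. The feature's own
3´-terminal base is deliberately in no class. "Highest score" in the
primary definition is implemented as a per-gene *dominant* flag on the
strongest primary end rather than as part of the class predicate, so
multi-labeling remains possible.

The 5´UTR/ORF-internal selection takes candidates in
[start codon − 200 bp, stop codon] (strand-oriented, stop codon's
final base included), finds the nearest strictly-upstream same-strand
feature among TSSs and mRNA stop-codon boundaries, and then: a stop
codon eliminates the end unless a TSS lies ≤ 200 nt upstream or the
stop belongs to an annotated leader peptide (the 16-gene allowlist
*mgtL … uof* ships as a default); independently, a TSS 1–20 nt
upstream eliminates the end. Equidistant TSS/stop ties keep the end
(TSS wins); an end with no upstream feature at all — only possible on
truncated synthetic inputs — keeps, recorded under the TSS rule.
`no_candidate_gene` is recorded with decision "eliminate", meaning
only that the end is outside the candidate set.

## C:G profiling

Sequences ±600 nt around each position are taken in transcript
orientation (reverse-complemented on −, because Rut sites are defined
on the nascent RNA) and tiled into 48 non-overlapping 25-nt windows.
The per-window statistic is count(C)/count(G); windows with zero G are
recorded as missing and excluded from the cross-region mean rather
than pseudocounted (a pseudocount would bias the ratio toward 1);
exclusion counts are reported. Note E[C/G] over 25-nt windows of a
uniform genome is ≈1.2, not 1 (Jensen's inequality on the ratio), so
flatness — not unit value — is the meaningful control property; the
test suite checks that every control window mean lies inside the
simultaneous 99% bootstrap band around the pooled control mean.
Random-coordinate controls are uniform over positions and strands,
reproducible for a fixed seed.

## Overlap statistics

`compare_lists(A, B, d)` counts A-positions within d of a B-position
(strand-matched by default), computes B's merged stranded footprint at
d (clipped on linear genomes, wrapped on circular ones), and evaluates
the upper hypergeometric tail over N = 2L stranded positions (N = L
with strand matching off). The tail is summed in log space from
log-gamma terms. The comparison is non-commutative by construction —
several A coordinates can be near one B coordinate — so reports
include both directions. No multiple-testing correction is applied
across comparisons.

## Synthetic scenario

The generator emulates the data the pipeline consumes, with planted
truth for recovery testing. Defaults (the conditions used throughout
the tests): 100-kb circular genome; 20 non-overlapping genes on both
strands (CDS 930–1800 nt, 5´UTR 90–140 nt, ≥1.2-kb spacing); 30
planted terminator 3´ ends — every gene ends in one (30 nt past the
stop codon), five genes carry an extra 5´UTR site (60 nt upstream of
the start codon) and five an extra ORF-internal site — of which 8 are
rho-type (readthrough f = 0.1 untreated → f_bcm = 0.8 under BCM) and
22 intrinsic (f = f_bcm = 0.05). A 150-nt C-rich element
(P(C) = 0.45, P(G) = 0.10 on the sense strand) is planted immediately
upstream of each rho site.

Term-seq replicates place Poisson read counts at each site with
shared-plus-replicate lognormal intensity (σ = 0.5, shared fraction
0.9, mean 200 reads scaled by termination efficiency) and ±1-nt
jitter, over Poisson background (0.01 reads/nt/strand) plus
replicate-specific spurious peaks (5×10⁻⁵ per nt, mean 15 reads) —
so reproducibility, not height alone, separates signal from noise. An
optional geometric 3´→5´ smear models exonucleolytic trimming of
Rho-terminated ends; it is off by default so that recovery acceptance
stays crisp at ±1 nt.

DirectRNA samples are built from a large molecule population sampled
shallowly: ~30,000 transcripts per gene initiate at the TSS and
terminate at each planted site with probability 1−f (untreated) or
1−f_bcm (BCM), read-through molecules running 900 nt past the gene-end
terminator; each molecule contributes Poisson(2×10⁻⁴ per nt) sequenced
3´ ends uniformly along its extent (~6 reads/nt of covered genome).
The population must be large relative to read depth: each read then
approximates an independent molecule, which is what the Fisher test
assumes. Planted sites are spaced so that no two sit in each other's
(w, w+200] band, where the windowed statistic genuinely smears signal
from a neighboring true site past the suppression radius — the
scenario measures false positives, not window bleed.

All randomness derives from one seeded generator: identical configs
produce byte-identical files.

**What passing tests do and do not show.** The scenario exercises
sharp, well-separated sites at comfortable depth on a single circular
chromosome. It does not emulate ragged 3´-end families from partial
exonucleolytic decay, overlapping operons and antisense transcription
units, sequencing-depth gradients, mapping artifacts, or
condition-dependent expression — so recovery rates here bound what the
method can do under its own assumptions, not its performance on real
libraries.

## Known limitations

- Exactly two Term-seq replicates are supported (pairwise IDR pooling
  for more is out of scope); a single replicate requires an explicit
  escape hatch and skips the reproducibility model.
- The IDR mixing weight is mildly conservative at a few hundred pairs.
- Fisher significance treats reads as independent molecules (see
  above).
- The intrinsic-terminator hairpin score column in the classification
  output is reserved for an externally supplied value; no hairpin
  thermodynamics are computed here.
- Single-chromosome analyses only; multi-chromosome inputs are handled
  one chromosome at a time.
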