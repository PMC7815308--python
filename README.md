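# endcall

Tools for mapping and interpreting bacterial RNA 3´ ends: reproducible
3´-end calling from Term-seq replicates, Rho-dependent termination
scoring from ±bicyclomycin DirectRNA-seq, positional classification of
3´ ends against a genome annotation, C:G sequence profiling around
termination sites, and overlap statistics between stranded coordinate
lists — plus a synthetic-data generator with planted ground truth so
every stage can be exercised on a laptop.

It is written for bacterial transcriptomics work where transcription
termination — intrinsic (hairpin/U-tract) or Rho-dependent — and RNA
processing leave single-nucleotide 3´-end signatures in sequencing
data.

## The statistics at the core

**Consensus 3´-end calling.** Candidate peaks are detected per
replicate on dense per-base 3´-end count tracks with
`scipy.signal.find_peaks` (width (1, ∞), unconstrained prominence,
relative height 0.75 — settings suited to the high, sharp peaks of
Term-seq). Matched peak pairs across replicates are scored with an
irreproducible-discovery-rate (IDR) copula mixture: ranks are mapped
to latent z-scores, and a two-component model

> reproducible ~ BVN((μ, μ), σ², ρ)  vs.  irreproducible ~ BVN(0, I)

is fitted by pseudo-likelihood EM. Pairs passing a global IDR cutoff
(default 0.05) are refined to the strongest signal nucleotide (ties
broken toward the strand-downstream position) and collapsed so that no
two consensus ends lie within 100 bp (highest score wins).

**Rho score.** For a position *p*, read counts in 800-nt windows
upstream/downstream are collected in BCM-treated and untreated
samples, and

> R = (BCM_ds / BCM_us) / (Untreated_ds / Untreated_us)

Bicyclomycin inhibits Rho, so R > 1 indicates Rho-dependent
readthrough (R > 2 at least two-fold). Significance is a one-sided
Fisher exact test on [[BCM_ds, BCM_us], [Unt_ds, Unt_us]], computed by
log-space hypergeometric tail summation (stable to p ≥ 1e-320). Rho
termination regions are positions with R > 1 and p < 1e-4, reported as
the most significant position within ±800 nt.

**Overlap significance.** Two stranded coordinate lists are compared
at distance *d*: k of n list-A positions fall within the K-position
stranded footprint of list B, out of N = 2L stranded positions (the
genome doubled for the two orientations); P(X ≥ k) is the upper
hypergeometric tail.

## Worked example

```bash
python examples/02_call_consensus_ends.py
```

```
strand +: raw peaks (996, 974), 632 matched pairs, 13 reproducible (pi=0.021, rho=0.92)
strand -: raw peaks (1011, 1011), 634 matched pairs, 17 reproducible (pi=0.027, rho=0.93)

consensus 3' ends: 30
planted ends recovered within +/-2 nt: 30/30
```

The simulator planted 30 terminator 3´ ends among ~1000 raw peaks per
replicate strand (mostly background); the IDR model estimates that
only ~2–3% of matched pairs are reproducible, and exactly those
survive — all 30 planted ends are recovered at single-nucleotide
accuracy.

```bash
python examples/03_rho_termination_scan.py
```

```
positions scored: 199,465
Rho termination regions called: 8
planted rho-type sites: 8
     1489-  R=  8.06  p=0  <- planted rho site
     4645+  R=  7.39  p=1.27e-76  <- planted rho site
    ...
```

All eight BCM-sensitive (rho-type) planted sites are called within a
few nucleotides, with Rho scores near the planted readthrough contrast
(0.8/0.1 = 8); the 22 BCM-insensitive intrinsic sites score near 1 and
are not called.

The other examples (`examples/0*.py`) cover simulation, positional
classification with the 5´UTR/ORF-internal selection, C:G profiling,
and overlap statistics. The `endcall` command exposes the same
operations as subcommands (`simulate`, `call-ends`, `rho-scan`,
`annotate-rho`, `classify`, `cg-profile`, `compare`); run
`endcall --help`.

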