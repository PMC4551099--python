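# Methods

This note documents the models and procedures implemented in `clonelib`,
the defaults they ship with, the numerical conventions, and what the
synthetic-data tests do and do not demonstrate about real data.

## Sequence handling

Clone sequences are IUPAC DNA ('U' treated as 'T', '-' as gap). Primer
sites are located by degenerate matching: a window matches a pattern if
at most `max_mismatch` positions fall outside the pattern symbol's
allowed base set ('N' matches anything). Reverse primers, written 5'→3'
as synthesized, are matched through the reverse complement of their
pattern, and the hit is recorded on the forward strand. Coordinates are
0-based half-open throughout.

Primer sequences are **configuration, not constants**: the shipped
defaults (109F `ACKGCTCAGTAACACGT`, 915R `GTGCTCCCCCGCCAATTCCT`, 27F,
907R) are standard published sequences, and any study-specific variant
should be supplied via `primers.forward` / `primers.reverse` in the run
config. Two candidate sites for a primer are an error, never a silent
first-hit pick — a mis-anchored extraction would silently corrupt the
downstream G+C percentage.

Region extraction returns the subsequence strictly between the primer
sites. Regions longer than the target length (default 800 bp) are
center-cropped; regions up to 20 bp shorter are kept with a warning
flag (published "800 bp" region lengths are nominal — reported G+C
values are frequently not multiples of 1/800); anything shorter is an
error.

**G+C percentage** is `100·(G+C+S)/(GC-informative bases)`, where S
(G-or-C) is GC-certain and counts in both numerator and denominator;
other ambiguity codes are excluded from both so they cannot bias P_GC.
A flag switches the denominator to all bases. Values are reported to
2 decimal places.

## OTU clustering

Distances on pre-aligned sequences are uncorrected p-distances with
pairwise gap deletion: columns gapped in either sequence of a pair are
excluded, distance = mismatches / compared columns. Model-corrected
distances (Jukes–Cantor, Kimura, composite-likelihood) were deliberately
not used: at the 3 % divergence where OTU calls are made, corrections
differ from p-distance by an order of magnitude less than the threshold,
and p-distance has no model parameters to leave unspecified.

Clustering is agglomerative with **average linkage** (unweighted mean of
all original pairwise distances between clusters; furthest-neighbor
available via `linkage="complete"`). Merging stops when the smallest
inter-cluster average exceeds the threshold. Ties are broken by the
lexicographically smallest pair of cluster representative ids, making
partitions bit-reproducible across platforms. Average linkage is the
common default of clone-library clustering tools, but it is a
convention, not a derived fact; the tests cross-check partitions against
scipy's UPGMA on tie-free matrices and against an independently coded
exhaustive oracle at small n. OTU ids are assigned by decreasing
abundance, ties by smallest member id.

## Diversity statistics

For an abundance vector `a` with `n` OTUs and `N = Σaᵢ` clones,
`F_k` = number of OTUs seen exactly k times:

* **Coverage**: default variant `1 − n/N` (the form printed in many
  survey tables); classic Good `1 − F₁/N` via `variant="singleton"`.
  Both appear in the report table because the two variants genuinely
  disagree on mid-coverage libraries and source tables are not always
  internally consistent about which they used.
* **Chao1** (bias-corrected): `S + F₁(F₁−1)/(2(F₂+1))`, defined at
  F₂ = 0 where the classic `S + F₁²/2F₂` diverges. The 95 % CI uses the
  log-normal construction on `T = estimate − S` with the standard
  bias-corrected variance; F₁ = 0 collapses the CI to (S, S).
* **Shannon**: `H′ = −Σ pᵢ ln pᵢ` (natural log), CI from the
  first-order analytic variance `(Σ pᵢ ln²pᵢ − H′²)/N`; a seeded
  multinomial bootstrap CI is available as an alternative. The analytic
  CI is degenerate for single-OTU libraries (H′ = 0 exactly).
* **Coleman rarefaction**: `E[S|m] = S − Σᵢ (1 − m/N)^{aᵢ}`. This is
  the *exact* expected richness when each clone is independently
  retained with probability m/N, and an approximation to fixed-depth
  (hypergeometric) rarefaction — e.g. 1.5 vs the exact 5/3 on the
  library [2,2] at depth 2. The Monte-Carlo oracle in the tests
  simulates the inclusion scheme (for which the curve is the exact
  mean); a separate enumeration test pins down the hypergeometric gap.
  At m = N the curve equals S exactly.

## qPCR cell-abundance model

Cell density = copy density / per-genome copy number. Defaults: 3.6
(bacterial 16S, the rrn-operon average of genome surveys), 1.2
(archaeal 16S), 1.0 (*mcrA*, *dsrB*). Domain fraction =
`100·A/(A+B)`; guild fraction = `100·copies/host-cells` under the
single-copy assumption. Fractions are computed from unrounded
intermediates and rounded (1 dp) only for reporting; densities report
at 2 significant figures.

Two uncertainty columns are emitted: `cells_sd` (copy sd scaled by the
copy number — the linear-propagation result) and `cells_sd_unscaled`
(copy sd carried through unchanged, a convention some published tables
follow). Choosing between them is a reporting decision, not a modelling
one, so both are provided.

**Half-rounding convention**: `round_sig` quantizes to 12 significant
digits first (so binary float noise cannot tip an exact half) and then
rounds halves toward zero — 3.75 → 3.7 at 2 s.f. This matches the
half-resolution used in the qPCR summary tables this module mirrors.

## Growth-temperature regression

For each temperature kind k ∈ {min, opt, max}, ordinary least squares
of T_k on P_GC over the packaged calibration table (28 phylotypes and
strains, P_GC 51.88–65.87 %). Fitted slopes are 4.38 / 4.96 / 4.89 °C
per %GC with RMSE ≤ 0.31 °C and max |residual| ≤ 0.5 °C on the
calibration set; a non-positive slope is rejected outright, since the
underlying GC–temperature correlation is positive and a negative fit
can only mean corrupted input. Parenthetical experimentally observed
temperatures of cultured strains are carried in `observed_*` columns
for comparison and never enter the fit; one genome-derived row is
flagged as such.

Predictions are affine in P_GC, rounded to whole °C for reporting
(consistent with ±1 °C reproduction tolerance, which absorbs whether
P_GC was rounded to 2 dp before or after applying the equations).
Lifestyle classes are assigned from T_opt at the conventional,
configurable cutoffs 15 / 45 / 80 °C (boundaries belong to the warmer
class); the literature uses these categories without crisp definitions,
so the thresholds are parameters, not claims. Predictions outside the
40–80 % GC hull warn as extrapolations. `loo_validate` refits with each
calibration row held out and reports per-kind residuals.

## Composition tables

Clone → taxon assignments aggregate to counts and percentages per
(year, domain), or pooled across years. Percentages use
**largest-remainder apportionment** at 0.1 % granularity (ties to the
larger count, then input order), so every grouping sums to exactly
100.0; the two-group integer ratio uses the same rule at 1 %
granularity. Output ordering is deterministic (year, domain, decreasing
count, taxon), making the table invariant to input order.

## Synthetic-data generator

`simulate_library` emits N primer-flanked clone sequences from k
centroid regions:

* **Abundances**: one clone guaranteed per OTU, the remaining N − k
  multinomial on geometric, log-series, or uniform rank weights —
  spanning the observed shapes of real libraries (one dominant OTU with
  a singleton tail vs near-even).
* **G+C planting**: per-OTU G+C targets are met with exact base counts
  (non-integer targets resolve to the nearest count; the truth table
  records the realized value, and tests compare against realized, not
  requested).
* **Divergence planting**: centroids derive from a shared backbone by
  edits at OTU-private (disjoint) position sets sized to
  `round(inter_divergence/2 · L)`, so pairwise centroid divergence is
  at least the planted value; clones derive from centroids by
  `round(intra_divergence · L)` point substitutions. All edits are
  G+C-preserving swaps (A↔T, G↔C), so divergence never perturbs the
  planted G+C.
* **Determinism**: a single `numpy` Generator seeded from the spec; no
  global random state; same seed ⇒ identical bytes.

Defaults mirror a low-diversity archaeal chimney library: 3 OTUs, 96
clones, 800 bp region, divergences (0.005, 0.10), per-OTU G+C spanning
52–66 %. `simulate_qpcr` draws
`copies = cells · copies-per-genome · exp(N(0, σ))` per replicate
(default σ = 0.2, a typical qPCR between-replicate spread), with a
2005-like default panel of true densities.

Not emulated — and therefore not demonstrated by passing tests:
chimeric amplicons, indels and alignment error, PCR primer bias,
non-lognormal qPCR error, and taxonomically structured divergence
(mutations are uniform over positions). Planted-truth recovery shows
the estimators are correct under their own assumptions, not that those
assumptions hold for any particular chimney.

## Test problem sizes and stochastic tolerances

Property tests run on libraries of N ≤ 120 and distance matrices of
n ≤ 12 (n ≤ 6 for the exhaustive clustering oracle); Monte-Carlo
oracles use 10⁴ draws; recovery tests use 200–500 seeded replicates.
The qPCR recovery check asserts the mean signed log-deviation of the
four per-target replicate medians within `2σ/√500`: a per-target bound
at that width would be under two standard errors of a sample median
(SE ≈ 1.25σ/√n) and fail roughly one seed in nine by chance, whereas
the panel-level statistic puts the same bound beyond three standard
errors.
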