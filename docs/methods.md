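# Methods

## Scope and data model

The package analyses skipped-exon (SE, cassette) events only. An event is a
cassette exon with two flanking constitutive exons on one contig, with
per-replicate inclusion (IJC) and skipping (SJC) junction counts for two
conditions. Coordinates are 0-based half-open internally; GTF output is
converted to 1-based closed at the boundary. "Upstream"/"downstream" always
refer to transcript orientation, so minus-strand events store the upstream
exon at the genomically higher coordinates, and all sequence retrieval is
strand-aware (minus-strand fetches return the reverse complement).

## PSI from junction counts

PSI is estimated from junction counts only, correcting for the unequal
number of junctions supporting each isoform:

    PSI = (IJC / lI) / (IJC / lI + SJC / lS)

with effective form lengths `lI = 2` (two inclusion junctions) and
`lS = 1` (one skipping junction) by default. A replicate with
IJC = SJC = 0 is missing; condition means are taken over informative
replicates only. The synthetic count model is the exact inverse: total
informative reads `N ~ Poisson(depth)` per replicate and
`IJC ~ Binomial(N, ψ·lI / (ψ·lI + (1−ψ)·lS))`, so the estimator must undo
the length bias (at ψ = 0.5 the raw inclusion-read fraction is 2/3). An
optional beta-binomial dispersion knob adds between-replicate
overdispersion for stress-testing; the default is pure binomial noise,
a declared assumption rather than an inference from data.

## Differential splicing test

Differential splicing between two replicated conditions is a
likelihood-ratio test under a beta-binomial model of the inclusion-read
probability θ (a monotone transform of PSI, so the test is invariant to
the form lengths). The alternative fits (θ₁, θ₂, φ) by maximum likelihood
(L-BFGS-B with analytic gradients; logit-parametrized θ and φ); the null
refits a single shared θ *at the dispersion estimated under the
alternative*. Re-estimating φ freely under the null would let the null
absorb the condition difference as overdispersion and destroy power, so
the dispersion is treated as a shared nuisance estimated once under the
richer model. The statistic 2·(ℓ₁ − ℓ₀), clipped at zero, is referred to
χ²(1). With identical replicates the dispersion MLE is zero and the test
coincides with the pooled binomial LRT (verified to 4 decimal places in
log p). Events with an all-zero condition are untestable (missing
p-value).

Known limitation: with only three replicates per condition the dispersion
is weakly identified, and on strongly overdispersed data the test is
anticonservative (measured ~0.14–0.19 at nominal 0.05 for φ = 0.02,
3+3 replicates). On the default binomial-noise conditions it is
calibrated (KS-uniform null p-values; BH discovery fraction at or below
the nominal level).

## Filters

Multiple testing uses Benjamini–Hochberg over non-missing p-values.
Thresholds are applied with the printed boundary semantics:

- main significance: total JC (Σ IJC+SJC over replicates) **≥ 50 in both
  conditions**, FDR **< 0.05**, |ΔPSI| **≥ 0.10**;
- map test set: same JC and FDR, relaxed |ΔPSI| **≥ 0.05**;
- map background: JC filter plus FDR **> 0.1** and |ΔPSI| **< 0.05**.

The JC filter is read as "sum over replicates within each condition",
required of both conditions — the most literal reading; both the statistic
and the threshold are configurable. ΔPSI is sample1 − sample2 with sample1
always the differentiated control, so a knockdown shift toward the
proliferative state carries the same sign as the D−P program.

## Concordance integration

Quadrant analysis pairs each event's program ΔPSI (x) with its knockdown
ΔPSI (y). Events with a zero coordinate have no quadrant and are excluded.
The congruent subset is UR ∪ LL; Pearson r² and the OLS slope (y on x,
intercept fitted; configurable to through-origin) are computed on that
subset only, requiring ≥ 3 points. Overlaps of significant event sets are
scored with the upper-tail hypergeometric probability P(X ≥ overlap);
an observed overlap of zero has probability 1 by definition.

Regulation calls use the same FDR/|ΔPSI| thresholds as the main filters:
knockdown ΔPSI ≥ +0.10 with FDR < 0.05 means the RBP activates the exon
(its loss lowers inclusion), ≤ −0.10 means repression, anything else is
unregulated. The normalized effect ΔPSI_KD / ΔPSI_program is clipped to
±1.5 (configurable) so near-zero program effects cannot dominate the
heatmap; its sign encodes concordance. Heatmap rows are
program-significant events split by program direction (D-included /
D-skipped), ordered deterministically by the per-RBP label vector
(lexicographic: activated < repressed < unregulated) then |program ΔPSI|
descending, with per-label-vector cluster sizes reported. Condition-mean
PSI matrices are row z-scored (constant rows → zeros) and clustered
agglomeratively with Euclidean distance and average linkage (declared
defaults; the linkage heights are validated against an O(n³) reference).

## Splicing maps

Motif patterns are alternations of chains of IUPAC words and bounded
spacers, written `WORD(N{min,max}WORD)*` with `|` between full variants;
`U` is normalized to `T` and a bare `N` inside a word matches any base.
The built-in registry covers CACN{3,15}CAC (RBPMS), YGCYN{5,20}YGCY
(MBNL), GCATG (RBFOX), ACTAA|CTAAC (QK), and linked dimers join two
patterns with a 5–25 nt spacer (cross-product of variants).

Matching enumerates every admissible spacer length at every start
(overlaps allowed) via a forward/backward reachability pass over word
occurrence lists — exact and equivalent to brute-force enumeration
(property-tested against an independent enumerator). Coverage is the
union of *word* positions of all matches; spacer positions are
unconstrained sequence and are not covered (configurable, since the
reference toolkit's exact semantics are not public). Sliding-window
coverage (window 31 nt, odd) reports the percentage of in-range window
positions covered, computed over each full feature so windows truncate
only at real feature boundaries (renormalized denominator, no zero
padding).

The standardized axis has 1540 positions in 8 segments: upstream exon
last 135 | upstream intron first/last 250 | cassette exon first/last 135
| downstream intron first/last 250 | downstream exon first 135. When a
cassette exon or intron is shorter than twice its segment length, each of
its two segments keeps floor(L/2) positions (aligned to its splice site)
and the rest are masked, so no nucleotide is counted twice; a flanking
exon (one segment only) simply truncates at min(L, 135).

Significance per position is a label-permutation test: the statistic is
mean test coverage − mean background coverage over valid (unmasked)
events; the null shuffles events between the sets (sizes preserved,
default 1000 iterations); one-sided p-values use the +1 correction
(b+1)/(n+1) for enrichment and depletion separately, flagged at
p ≤ α = 0.05. Backgrounds larger than 2000 events are seeded-downsampled
first. Positions with no valid event in either set carry no flag.

Peak calling declares a peak when ≥ 5 contiguous positions within one
segment are flagged, the mean coverage difference over the run is
≥ 1 percentage point, and at least half of each set's events contribute
valid sequence at those positions. The magnitude floor matters because
flags alone appear at the α rate in correlated runs, and planting itself
leaves a sub-point compositional footprint (inserted word bases shift
local base composition slightly) that a large background set can detect;
the support floor excludes heavily masked positions where small effective
sample sizes make mean differences unstable. A point-mutated control
pattern (central base of every word substituted to a base its IUPAC class
excludes: C→G, G→C, A→T, T/Y→A) preserves length and spacer structure but
produces no peaks on planted data.

## Synthetic study generator

The generator defines the study conditions the tests run under. Defaults:
3 replicates, depth 100 informative reads/event/replicate, half the
events program-regulated with |ΔPSI_D−P| uniform on [0.1, 0.6] (random
sign), and per-RBP knockdown effects on half of the program events with
congruent fractions {RBPMS 0.986, RBFOX2 0.91, MBNL 0.87, QK 0.81} —
emulating the observed ordering in which the master regulator is almost
perfectly aligned with the program and co-regulators progressively less
so — and knockdown slope 1.0. A concordant knockdown moves PSI toward the
proliferative state by slope × program ΔPSI; antagonistic effects move it
the other way and are clipped to [0, 1], so realized antagonistic effects
can be slightly attenuated near the PSI boundaries (which also makes
estimated congruent fractions among *significant* events run a couple of
points above the planted truth value). Truth labels derive from the
realized effect sign.

Each event is an event-sized minigene on its own contig (flanking exons
90–300 nt, introns 500–1500 nt, cassette exons 60–240 nt, GC 0.5, random
strand); short features are deliberately generable to exercise masking.
Activated events receive 3 concrete instances of the RBP's pattern
(uniform over IUPAC classes and gap lengths) at non-overlapping offsets in
the first 250 nt of the downstream intron; repressed events in the last
250 nt of the upstream intron or inside the exon (random choice). Planted
positions are recorded in the truth table; accidental background matches
are left alone — they are part of the null. Junction counts for each
contrast draw the D-control arm independently (contrasts are independent
experiments in this design; control replicates are not shared across
contrasts). All randomness flows from one root seed via named per-stage
substreams, and a fixed seed reproduces byte-identical outputs.

What the generator does *not* emulate: read-level artifacts (alignment,
mapping bias), shared control replicates across contrasts, realistic
genomic base composition or repeat structure, overdispersed counts (off
by default), correlated regulation across events, and non-SE event types.
Passing tests therefore demonstrate correctness of the estimators and
tests under the declared statistical model, not robustness to real-data
artifacts.

## Pipeline and problem sizes

`run_all` executes simulate → quantify → concord → map_motifs from a
single YAML config; every output TSV is hashed (SHA-256) into a manifest,
and identical config + seed reproduce identical manifests. Validation
runs before any compute (fatal findings abort; an even map window is
bumped to the next odd value with a warning). Exit codes: 0 ok, 1 user
error, 2 internal (stage) error; partial outputs are retained and the
failing stage is named.

The acceptance runs use 500 events at depth 10⁴ for estimator inversion,
2000 null events for calibration, 500 regulated events at depth 500 for
concordance recovery, and 20 seeded map runs of 300 planted test events
versus 2000 background events at 1000 permutation iterations — sizes
chosen so each property is measured with comfortable statistical margin
while the whole suite stays fast on a single CPU.
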