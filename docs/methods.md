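# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `ratecmp`, and what the simulation-based tests do and
do not demonstrate about real data.

## Alignments and column filtering

The unit of computation is a per-locus codon alignment over
`{A, C, G, T, N, -}` with one species label per record; a species may carry
several records (paralogs). `N` is treated as missing data throughout.
*Complete deletion* removes every column (or codon column) containing a gap
or `N` in any record; it is idempotent and may empty an alignment. The
deletion unit is a parameter: codon-unit deletion is the default ahead of
Nei–Gojobori counting (which needs intact codons), nucleotide-unit ahead of
tree building. Whether deletion is applied per locus before concatenation
or on the concatenated matrix is also open in principle; the pipeline
default is per-locus-then-concatenate, and both orderings are exposed.
Reading frame is assumed to start at column 1 — no frame detection.

## Divergence estimators

**K2P.** Transition proportion P and transversion proportion Q over the
comparable positions (pairwise deletion of gapped/ambiguous sites inside
the estimator; in the pipeline, complete deletion upstream makes this a
no-op), then `d = −½ ln[(1−2P−Q)√(1−2Q)]`. The correction is undefined
when `1−2P−Q ≤ 0` or `1−2Q ≤ 0`; such values are returned as NaN with a
`saturated` flag, never as numeric sentinels.

**NG86.** Synonymous site count of a codon: per position, the fraction of
the single-nucleotide changes that are synonymous among the changes that do
not create a stop codon (stop-bound changes are excluded from numerator
*and* denominator, so each position contributes sites that still sum to 1
and per-codon S + N = 3). Site totals are averaged between the two
sequences. Differences between codons differing at k positions are
averaged with equal weights over the k! substitution pathways that avoid
stop codons; codon pairs whose every pathway crosses a stop are skipped and
counted, as are codons containing gaps/ambiguity or stops. pS = S_diff /
S_sites, and dS = −¾ ln(1 − 4pS/3) is undefined (flagged) for pS ≥ 3/4.
Program suites differ in stop-codon conventions at exactly these points;
the exhaustive enumeration oracle in the test suite defines this package's
ground truth. Only the standard genetic code is wired in by default; the
code table is injectable (the standard code is also correct for the
chloroplast genes of the target design).

## Rate estimation

**Outgroup track.** For focal species A, B and outgroup O, each estimator's
species-collapsed pairwise values feed `d_A = (d_AB + d_AO − d_BO)/2`,
`d_B = (d_AB + d_BO − d_AO)/2`. The identity `d_A + d_B = d_AB` holds to
floating-point round-off (asserted at 1e-12). Negative decomposed rates
are legitimate "other lineage faster" evidence: they are retained for the
sign test and paired t-test but flagged, and an option excludes them.
Undefined pairwise inputs make the estimator undefined for that locus;
such loci are excluded from the affected comparison cell and logged, never
silently dropped.

**Paralogs.** Species-level pairwise distances are the arithmetic mean of
the defined record-pair distances. Because the decomposition is linear in
its three inputs, averaging distances before decomposing equals averaging
the per-paralog decomposed rates; the equivalence is asserted by test, so
the choice of order is immaterial.

**ML track.** Branch lengths on a fixed topology (by default the NJ
topology of the locus) are maximized under K80 with Felsenstein pruning on
site patterns; a species' rate is its terminal branch length, averaged over
paralog tips. Only the nucleotide-scale estimator d is produced this way;
NG86-scale values always come from the outgroup track, and each row of the
rate table records which method produced it. A codon-level branch model is
deliberately out of scope — the ML variant here is a nucleotide-model
simplification, so its outputs are method-variant analogues, not
re-implementations, of codon-model branch lengths.

Optimization is by coordinate sweeps (bounded Brent per branch, lengths in
[0, 20], xatol 1e-10), declaring convergence when the sweep improves the
log-likelihood by less than 1e-8; κ can be fixed or profiled (bounded
search on log κ in [0.02, 100]). A basal bifurcation is collapsed first so
that every optimized edge of an unrooted topology is identifiable. With
exactly two taxa only the tip-to-tip total is identifiable; it is optimized
as one quantity and split evenly, and callers should interpret only the
sum (it equals the closed-form K2P distance when κ is profiled).

## Tree building and clade sampling

Neighbor joining follows Saitou–Nei: join the pair minimizing
`Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`; ties break to the lowest
(row, column) index pair, deterministically. Negative estimated branch
lengths are clamped to 0 with the deficit transferred to the sister branch
(standard practice). NJ is exact on additive matrices, which the test
suite exercises with random trees of up to 8 taxa; an independent NJ
implementation (scikit-bio) serves as a topology cross-check on noisy
matrices.

Bootstrap supports resample nucleotide columns (not codons) with
replacement, rebuild the NJ tree per replicate, and report for each
internal bipartition of the full-data tree the percentage of replicates
containing it. Replicates with a saturated distance entry are discarded
and counted. Supports are written as internal node labels in Newick.

Orthologous clade sampling returns the *maximal* monophyletic clades whose
tip species cover a required set and whose subtending support is strictly
greater than the threshold (default 50, strict per the sampling rule).
"Neighboring homologs" as outgroup proxy is interpreted as the sister-group
tips; a `radius` option widens the neighborhood by walking further up,
since the neighborhood's exact extent is underdetermined.

## Comparison statistics

The sign test is the exact one-sided binomial tail
`P(X ≥ k | n, ½) = Σ_{i≥k} C(n,i)/2^n`, computed with exact integer
rationals (no floating summation), with ties removed from n. One-sided is
the default and the reporting convention: the published p-values that the
acceptance suite replays are one-sided tails (e.g. 33 of 34 gives
35/2³⁴ ≈ 2.04e-9). The paired t-test is `t = mean/(sd/√n)`, df = n−1,
one-sided for the annual-faster alternative (two-sided by flag); zero
variance yields a flagged degenerate result. The through-origin regression
uses perennial rate as response and annual as predictor, so a slope below 1
matches "annuals faster"; both the no-intercept R² (1 − RSS/Σy²) and the
squared Pearson correlation are always reported because published analyses
are ambiguous about which convention their R² follows. No multiple-testing
correction is applied (matching the design being emulated); a Bonferroni
option exists but is off by default.

The pooled sign test aggregates k and n over all comparison cells. Cells
share species and loci, so under the clock null the pooled test is
anti-conservative; it is reported as a directionality summary, not an
calibrated test.

## The simulator

Codon sequences evolve by exact Gillespie simulation: per codon, each of
the nine single-nucleotide neighbours is proposed at relative rate κ
(transitions) or 1 (transversions); changes to stop codons are rejected
outright and nonsynonymous changes are accepted with probability ω. The
process is normalized so that the mean accepted rate over a uniform
distribution of sense codons equals one substitution per site per unit
branch length; branch lengths are therefore in expected accepted
substitutions per nucleotide site at the start of the branch (composition
drift makes realized counts deviate by ~1–3% on deep branches, within the
tolerances asserted). Codons with zero accepted rate (Met, Trp at ω = 0)
simply never move.

The default topology mirrors the study design —
`(Os, (At, (Mt, (Vv, Pt))))`, with the dicot subtree clock-like (equal
root-to-tip heights: At 0.15, Mt 0.11 + 0.04, Vv/Pt 0.07 + 0.04 + 0.04) so
that terminal multipliers alone set the annual/perennial rate ratio and the
multiplier-1 configuration is an exact clock control. Defaults: κ = 2,
ω = 0.2, 85 loci × 300 codons, locus rate factors gamma with shape 2 and
mean 1 shared by all branches of a locus (the knob that generates
across-locus rate correlation between species), annual multipliers 1.5,
no paralogs. Multipliers act on terminal branches only — where along the
tree a life-history rate shift acts is unknowable from the emulated design,
and terminal-only is the minimal choice.

Presets:

* `nuclear_hk` — the defaults above: moderately deep divergence,
  modest synonymous saturation.
* `chloroplast` — 34 loci × 310 codons targeting a synonymous rate 1/4 and
  nonsynonymous rate 1/3 of nuclear. ω is raised by (1/3)/(1/4) = 4/3 and
  the branch scale is computed analytically from the model's mean weighted
  synonymous/nonsynonymous proposal rates to compensate for the rate-share
  shift the ω change induces under the total-rate normalization.
* `saturated` — branch scale 1.8 on a shallow-outgroup variant of the
  topology, At multiplier 2.0, locus-factor shape 6. Calibrated once so
  that roughly three quarters of loci show a decomposed synonymous rate
  above 1 on the early-splitting annual branch while outgroup-anchored
  pairwise pS mostly stays below the Jukes–Cantor ceiling. In the
  saturation count, loci whose estimate saturates beyond the ceiling
  (pS ≥ 3/4) are counted as dS > 1 — they exceed it a fortiori — and the
  count is reported over all loci.

Paralogs (when enabled) duplicate a terminal lineage at a uniform random
time along its branch and evolve the two copies independently to the tip.

## What the tests show — and what they do not

The simulator generates gap-free, in-frame, constant-length loci with a
constant ω, no indels, no recombination, no selection heterogeneity among
sites beyond the synonymous/nonsynonymous distinction, and no alignment
error. Passing the recovery tests therefore demonstrates the correctness
of the estimators and statistics under their own model assumptions, not
robustness to misalignment, frame errors or selection regimes absent from
the generative model.

One deliberate consequence of ω < 1 is among-site rate heterogeneity
(synonymous positions evolve ~5× faster than nonsynonymous ones at
ω = 0.2). The K2P and K80 estimators assume homogeneous site rates, so on
deep branches they compress large distances more than small ones — the
familiar saturation bias, visible here as annual/perennial rate ratios
below the simulated multiplier and regression slopes above 1/multiplier.
The clean parameter-recovery tests therefore run at ω = 1 (model-matched),
while the pipeline-level tests assert the qualitative pattern (direction,
significance, slope < 1) under ω = 0.2, which is exactly the regime where
the saturation caveats of the emulated analysis apply. Likewise the
NG86-estimated dN/dS is a biased estimator of the simulator's ω at κ ≠ 1
(transition-rich synonymous changes exceed the site count's opportunity
model), so the convergence test uses a wide tolerance.

Problem sizes in the test and acceptance runs (85 loci × 300 codons for
recovery, 30–50 loci for ML-track checks, 100 bootstrap replicates) were
chosen as the smallest sizes at which the asserted statistics are stable
across seeds; the published design's 1,000 bootstrap replicates remain the
CLI default.

## Known limitations

* The ML track is a nucleotide-model simplification; codon-model branch
  lengths from a dedicated package will differ, especially at high
  divergence.
* Comparison cells are non-independent (two annuals × two perennials share
  lineages, and the pooled sign test shares loci); no attempt is made at
  phylogenetically independent contrasts.
* Undefined (saturated) values are excluded per cell, so heavily saturated
  regimes analyse a non-random subset of loci — mirrored, deliberately, by
  the saturated preset's reporting conventions.
* No gamma rate-heterogeneity correction in K2P/K80; no indel or
  mitochondrial presets.
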