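# Methods

This note documents the statistical model behind `exocnv`, the choices
made where the design was genuinely open, what the synthetic cohorts do
and do not emulate, and the known limitations. Nothing here states an
empirical result that the test-suite or `scripts/acceptance.py` does not
itself compute.

## Depth normalization and the local principal component

Only captured bases are consistently observed in exome data, so every
"genome-wide" average in this package is an average over the capture
footprint (the union of capture targets). A sample's mean depth is its
total aligned base count over the footprint divided by the footprint
length; per-base normalized depth `r_ijk` divides by that mean, making
samples comparable across sequencing yields. Reads are counted per base
when their aligned reference span covers the base — no base-quality
filter, no duplicate handling, strand ignored (a configurable minimum
mapping quality defaults to 0). Coordinates are BED-style half-open
throughout.

Each region's `M × N` normalized matrix is column-centered (per sample)
and summarized by its first principal component across samples, computed
by the alternating power iteration

    t ← R v ,   v ← Rᵀ t / ‖Rᵀ t‖ ,

starting from `v ~ U(0,1)^N`, stopping when successive normalized
iterates differ by less than `tol = 1e-8` in Euclidean norm (default
`max_iter = 1000`; non-convergence is flagged, which also covers the
classic degeneracy of tied leading singular values). Only matrix–vector
products are used, so the region matrix can be streamed one column at a
time and no `M × M` or `N × N` covariance is ever formed. The component
is returned with unit norm — its scale is arbitrary — and its sign is
canonicalized against the per-sample means of the uncentered matrix, so
it is positively oriented with relative copy number and cluster order is
stable downstream. Per-region RNG streams are derived as
`run_seed XOR blake2s(region_id)`, making results independent of scan
order.

Why this works at all deserves a sentence: a CNV or a batch effect is a
per-sample *multiplicative* factor, which per-sample centering would
annihilate if depth were flat along the region. Real capture depth has a
strong per-base profile (probe affinity, edge effects), and the
(multiplicative sample factor) × (varying base profile) interaction is
exactly the rank-one structure whose right singular vector the power
iteration extracts.

## Global PCs and projection

The regions × samples matrix of stacked local PCs is column-centered
(mirroring the per-region convention) and decomposed by dense SVD — the
power iteration loses accuracy for lower-order components, the exact SVD
does not. The first `K = 50` right singular vectors are the global PCs.
Two refinements matter at cohort scales of a few thousand regions:

* **Across-sample centering before the scan.** Every local PC sits near
  `1/√N` plus deviations; the constant carries no case–control contrast.
  If it is left in, its coupling `⟨FPC_i, GPC_h⟩` has a component shared
  by *all* regions, and projecting out a phenotype-correlated GPC then
  subtracts the same phenotype-aligned pattern from every region's
  predictor — manufacturing genome-wide association instead of removing
  it. The scan therefore works on each FPC's across-sample deviations
  (logistic association itself is shift-invariant).
* **Single-region loading guard.** A component whose squared left
  (region-side) loading concentrates on one region is that region's own
  signal — typically a real common CNV — not cohort-wide technical
  structure. With ~10⁵ regions the noise bulk buries such directions;
  with ~10³ they can outrank it, and projecting one out both erases the
  genuine signal and injects its sample pattern everywhere. Components
  with max squared loading above `max(0.1, 4·ln(R)/R)` are skipped (a
  delocalized component's largest squared loading concentrates near
  `2·ln(R)/R`). Passing `region_loading_cap=None` restores the plain
  SVD.

Projection uses the Rayleigh-quotient form
`v − Σ_h (⟨v, g_h⟩/⟨g_h, g_h⟩) g_h`, exact even for non-normalized
components; it is idempotent, and residuals are orthogonal to the
projected basis to 1e−8.

## Association scan and genomic control

Each adjusted component is tested against the 0/1 phenotype with a
two-parameter logistic regression fitted by Newton/IRLS (tolerance 1e−10
on the log-likelihood, 25 iterations). The predictor is standardized
internally so the complete-separation guard (|β| > 15 with
non-decreasing likelihood) is scale-free; slope and SE are mapped back
exactly. Zero-variance or separated predictors are flagged
non-estimable and excluded from ranking and from λ — assigning them
p = 0 would inflate the scan artificially. Ranks are assigned by
ascending p with ties broken by region id, so the scan is independent of
input order. The Wald test is used because the genomic-control factor

    λ = median(Wald χ²) / 0.454936423120

is defined directly from a χ² statistic; the χ²₁ median is hard-coded to
12 significant digits so λ is bit-stable. QQ tables pair sorted observed
−log₁₀ p with uniform order-statistic expectations −log₁₀((i−½)/n). The
GC diagnostic reports, per 5 %-wide GC bin, the fraction of regions below
a significance threshold (default 1e−4): technical GC bias shows up as
small-p enrichment concentrated in particular GC bands, which projection
should flatten.

Two facts about λ at desk scale, visible in the end-to-end tests: the
median of ~2000 χ² statistics has sampling noise of roughly ±0.1 on λ,
and removing H estimated directions from an N-sample space shrinks the
phenotype-aligned variance of every predictor by about H/N, so a fully
corrected scan sits slightly below 1 — the reason "enough PCs" is chosen
as the H > 0 with λ closest to 1 rather than "λ minimal".

## Copy-number genotyping

Windowed depth (non-overlapping 100-bp windows anchored at the interval
start, trailing partial window dropped, divided by the sample's footprint
mean depth) is optionally GPC-adjusted row-by-row and handed to a
population HMM: Gaussian emissions per copy-number state 0–4 with initial
means CN/2 = {0, 0.5, 1, 1.5, 2} and variances 0.01, shared by the whole
cohort; sticky transitions (`stay_prob = 0.99` per 100-bp step — a
multi-kb CNV spans hundreds of windows); uniform initial state
distribution. EM runs 20 iterations (early stop when the total
log-likelihood improves by < 1e−6), with forward–backward vectorized
across samples; posterior-weighted means and variances are pooled over
all samples, so every sample informs the same clusters, and means are
re-sorted after each M-step so state s always genotypes the s-th cluster.
A state with vanishing posterior mass (relative weight < 1e−8) keeps its
parameters rather than collapsing onto an occupied cluster.

Two optional M-step refinements, both enabled by the pipeline's
genotyping entry point:

* **Affine mean constraint** (`mean_constraint="affine"`): cluster
  positions are tied to a line in copy number, `mean_s = a + b·CN_s/2`
  with `b > 0`, fitted by posterior-weighted least squares. Depth is
  proportional to copy number, so this is the physically right shape; it
  parks unpopulated states (CN 3/4 at a deletion locus) on the line
  instead of letting them migrate into the occupied clusters — the
  classic failure of a free five-state EM when only three states have
  data.
* **Start-probability update** (`update_start_probs=True`): the
  first-window state distribution is re-estimated (Baum–Welch) and
  converges to the population copy-number frequencies.

The per-sample call is the state maximizing the mean posterior across
windows (the locus is genotyped as a single CNV; a Viterbi segmentation
is exposed for within-locus structure but not used for the call); the
maximum is the certainty, calls below the threshold (default 0.9) are
missing, and concordance against truth excludes missing calls from both
numerator and denominator.

Choice of H for genotyping: projecting H estimated directions adds noise
of order √(H/N) of the locus's (large) depth contrast to every window
row. At N = 400 the accuracy optimum sits near the latent structure
dimension (H ≈ 10 here), not at the scan's H; at several-fold larger N
the penalty shrinks and larger H behaves as well or better.

## The synthetic cohort generator

`SimulationConfig` defaults describe a psoriasis-scale capture study of a
common deletion: 700 cases / 800 controls, mean depth uniform on 12–18×
(≥15× typical), a biallelic deletion with allele frequency q = 0.6 under
Hardy–Weinberg (CN 0/1/2 with probabilities q², 2q(1−q), (1−q)²), odds
ratio 1.38 per deletion allele, and two samples per capture array
(batch). Phenotypes follow `logit P(case) = α + ln(OR)·(2−CN)` with α
bisected so the expected case count matches the target; whole phenotype
vectors are redrawn until the case count is exact, which fixes class
sizes without biasing the genotype–phenotype relation (verified: the
realized per-allele OR converges to the target).

Expected depth at base j of region i in sample k is

    mean_depth_k · p_ij · (CN_ik/2 at causal regions)
                 · exp(b[batch(k), i]) · exp(s_k · f(GC_i)) ,

with counts negative-binomial (Var = μ + 0.1·μ²; Poisson when the
overdispersion is 0). The pieces:

* `p_ij` — per-base capture-efficiency profile, log-normal with log-sd
  0.3, normalized to mean 1. See above: without it the method has no
  signal to work with.
* `b` — low-rank batch structure: 10 latent factors (per-batch scores ×
  per-region loadings, overall sd 0.15) plus an independent
  per-(batch, region) residual at one third that scale. Latent factors
  are what makes a few dozen global PCs sufficient for hundreds of
  two-sample batches; fully independent per-(batch, region) draws would
  put every batch direction at noise-bulk singular values and make
  correction unstable at any H.
* `s_k · f(GC)` — GC response: `f` is a smooth quadratic peaking at 45 %
  GC, and the per-batch sensitivities `s` are the first latent factor's
  scores (GC response *is* a dominant axis of capture-efficiency
  variation), optionally shifted between cases and controls
  (`gc_phenotype_shift`, a DNA-source effect). Note that after
  mean-depth normalization the *effective* per-region bias is
  `s_k · (f_i − f̄)` with `f̄` the footprint average — bias diagnostics
  should be read against |f − f̄|, not f.
* Confounding — cases are routed to batch 1 with probability
  `batch_phenotype_confounding`; everyone else is uniform over batches.

Scaled-down cohorts have two artifacts real exomes lack, both consequences
of the causal locus being a visible fraction of the footprint rather than
~0.1 %: a full-length (32.2-kb) deletion shifts carriers' footprint-mean
depth and leaks genotype into every region's normalization, so scan
cohorts embed target-sized causal regions and genotyping cohorts compute
mean depth from the background targets; and a single region's FPC can
crack the global-PC basis (handled by the loading guard above).

What the generator does not emulate: alignment artifacts and mappability,
homology (e.g. to the MHC), duplicated reads, per-base correlation of
noise, population structure, and multi-allelic or complex CNV. Passing
tests therefore demonstrate that the machinery removes the *modelled*
confounders and recovers the *modelled* signal class, not performance on
real cohorts.

## Problem sizes used by the checks

The end-to-end tests and the reproduction script use 2000-region,
400-sample cohorts for scan behaviour (confounding 0.3: uncorrected
λ ≈ 2.5–9 across seeds, corrected λ ≈ 0.9–1.1), and a 501-target cohort
plus one 32.2-kb locus (322 windows) for genotyping (batch sd 0.08,
adjustment H = 10). Discovery power at these sizes is intrinsically
marginal: with OR 1.5 per allele at q = 0.6 and n = 400, the causal
region's Wald z is approximately N(2.8, 1) while the 10th-smallest of
2000 calibrated null p-values corresponds to z ≈ 2.8 — so whether the
causal region lands in the top 10 is close to a coin flip per cohort
draw, and across-seed hit counts reflect that.

## Known limitations

* One CNV class (biallelic deletion) drives the defaults; duplications
  (CN 3/4) are representable but not exercised by the generator.
* The genotyper targets a supplied locus; there is no genome-wide de
  novo segmentation or breakpoint refinement, and no haplotype phasing
  of CNV alleles.
* Regions are processed independently; no merging of adjacent targets
  into CNV-level clusters.
* λ-guided choice of H corrects the scan globally; the optimum H for
  genotype quality at a specific locus can differ (smaller at small N).
* p-values are raw Wald p with ranks; no multiple-testing layer.
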