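"""Synthetic exome-capture cohorts for end-to-end testing of the pipeline.

The generator emulates the structure of a capture-sequencing case-control
study of a common deletion polymorphism:

* copy-number genotypes at causal regions drawn under Hardy-Weinberg
  equilibrium for a biallelic deletion (CN 0/1/2 with frequencies q^2,
  2q(1-q), (1-q)^2);
* case-control phenotypes from a logistic disease model on deletion
  allele count, with the intercept tuned so the expected case count hits
  the target and exact class sizes enforced by rejection;
* per-base read counts that are negative-binomial around an expectation of
  sample mean depth x (CN/2 at causal regions) x a multiplicative
  capture-batch effect x a sample-specific GC-sensitivity effect.

Batches model the capture arrays (two samples hybridized per array by
default); each (batch, region) pair receives an independent log-normal
efficiency draw, and each batch additionally carries a GC sensitivity
that scales a smooth mid-peaked function of region GC.  Confounding with
phenotype is introduced by routing cases into batch 1 with a configurable
probability, so uncorrected association scans inflate and principal-
component correction has real structure to remove.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .depthio import CaptureRegion, DepthTable, Sample, write_manifest

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_depth",
    "simulate_cohort",
    "write_fixture",
    "gc_response",
]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a psoriasis-scale capture study of a common deletion:
    700 cases / 800 controls at >=15x coverage, a causal deletion with
    allele frequency 0.6 and odds ratio 1.38 per deletion allele, and
    two samples per capture array.
    """

    n_case: int = 700
    n_control: int = 800
    n_regions: int = 1000
    region_length: int = 200
    causal_region_ids: list[str] = field(default_factory=list)
    # length of causal regions; None = same as ordinary targets.  A
    # full-size (~32 kb) deletion locus is only appropriate when the
    # simulated footprint is large enough that the locus stays a small
    # fraction of it — otherwise the deletion visibly distorts carriers'
    # footprint-mean depth and with it every region's normalization.
    causal_region_length: int | None = None
    deletion_allele_freq: float = 0.6
    odds_ratio: float = 1.38
    mean_depth_range: tuple[float, float] = (12.0, 18.0)
    batch_count: int | None = None  # default: two samples per capture array
    batch_effect_sd: float = 0.15
    # capture-efficiency batch effects are low-rank: arrays share latent
    # factors (lot, hybridization chemistry, DNA quality), which is what
    # lets a few dozen global PCs absorb the structure of hundreds of
    # two-sample batches; a small independent per-(batch, region) residual
    # sits on top
    batch_factors: int = 10
    batch_phenotype_confounding: float = 0.0  # P(case assigned to batch 1)
    gc_effect_strength: float = 0.1
    # systematic case-control difference in GC sensitivity (DNA-source
    # effect: cases and controls collected or extracted differently respond
    # differently to library GC); 0 disables it
    gc_phenotype_shift: float = 0.0
    overdispersion: float = 0.1
    profile_sd: float = 0.3  # per-base capture-efficiency variation (log scale)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.deletion_allele_freq <= 1.0:
            raise ValueError("deletion_allele_freq must lie in [0, 1]")
        if not 0.0 <= self.batch_phenotype_confounding <= 1.0:
            raise ValueError("batch_phenotype_confounding must lie in [0, 1]")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if self.n_case + self.n_control < 2:
            raise ValueError("need at least 2 samples")
        if min(self.batch_effect_sd, self.gc_effect_strength,
               self.overdispersion, self.profile_sd) < 0:
            raise ValueError("noise scales must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_control

    def resolved_batch_count(self) -> int:
        if self.batch_count is not None:
            return self.batch_count
        return max(1, self.n_samples // 2)


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    regions: list[CaptureRegion]
    samples: list[Sample]  # phenotype + mean_depth populated
    batches: np.ndarray  # per-sample batch index
    truth_genotypes: dict[str, np.ndarray]  # causal region_id -> per-sample CN
    depth: dict[str, np.ndarray]  # region_id -> (length x N) raw counts

    @property
    def sample_order(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def phenotypes(self) -> np.ndarray:
        return np.array([s.phenotype for s in self.samples], dtype=int)

    @property
    def gc_fractions(self) -> dict[str, float]:
        return {r.region_id: r.gc_fraction for r in self.regions}


def simulate_genotypes(freq: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Hardy-Weinberg copy numbers for a biallelic deletion of frequency ``freq``.

    P(CN=0) = q^2, P(CN=1) = 2q(1-q), P(CN=2) = (1-q)^2.
    """
    if not 0.0 <= freq <= 1.0:
        raise ValueError("allele frequency must lie in [0, 1]")
    q = freq
    probs = np.array([q * q, 2 * q * (1 - q), (1 - q) * (1 - q)])
    return rng.choice(3, size=n, p=probs)


def _tune_intercept(allele_counts: np.ndarray, log_or: float, target: int) -> float:
    """Bisect the logistic intercept so the expected case count hits ``target``."""
    n = allele_counts.size
    if not 0 < target < n:
        raise ValueError(f"target case count {target} unattainable with n={n}")

    def expected(alpha: float) -> float:
        return float(np.sum(1.0 / (1.0 + np.exp(-(alpha + log_or * allele_counts)))))

    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _phenotypes_from_alleles(alleles: np.ndarray, log_or: float, target_case_count: int,
                             rng: np.random.Generator,
                             max_attempts: int = 100_000) -> np.ndarray:
    alpha = _tune_intercept(alleles, log_or, target_case_count)
    p = 1.0 / (1.0 + np.exp(-(alpha + log_or * alleles)))
    for _ in range(max_attempts):
        y = (rng.random(alleles.size) < p).astype(int)
        if int(y.sum()) == target_case_count:
            return y
    raise RuntimeError(
        f"could not realize exactly {target_case_count} cases in {max_attempts} draws"
    )


def simulate_phenotypes(genotypes: np.ndarray, odds_ratio: float, target_case_count: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Case-control labels from a logistic model on deletion allele count.

    ``logit P(case) = alpha + ln(OR) * (2 - CN)``, with alpha tuned by
    bisection so the expected case count equals the target; whole phenotype
    vectors are then redrawn until the realized case count is exact
    (rejection by class), keeping class sizes fixed without biasing the
    genotype-phenotype relationship.
    """
    genotypes = np.asarray(genotypes, dtype=int)
    return _phenotypes_from_alleles(2 - genotypes, float(np.log(odds_ratio)),
                                    target_case_count, rng)


def gc_response(gc_fraction) -> np.ndarray:
    """Smooth quadratic GC response, peaking at mid GC (~0.45) and falling
    toward the extremes — the shape along which capture efficiency is most
    sensitive to library GC composition."""
    gc = np.asarray(gc_fraction, dtype=float)
    return 1.0 - ((gc - 0.45) / 0.25) ** 2


def _draw_counts(mu: np.ndarray, overdispersion: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts with Var = mu + overdispersion * mu^2
    (Poisson when overdispersion is 0)."""
    if overdispersion == 0.0:
        return rng.poisson(mu)
    size = 1.0 / overdispersion
    if np.all(mu > 0):
        return rng.negative_binomial(size, size / (size + mu))
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(size, size / (size + mu[pos]))
    return out


def simulate_depth(config: SimulationConfig, regions: list[CaptureRegion],
                   mean_depths: np.ndarray, batches: np.ndarray,
                   truth_genotypes: dict[str, np.ndarray],
                   rng: np.random.Generator,
                   phenotypes: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Per-region raw count matrices (region length x N samples).

    Expected depth at base j for sample k in region i is

        mean_depth_k * p_ij * (CN_ik / 2 if causal else 1)
                     * exp(b[batch(k), i]) * exp(s_k * f(GC_i))

    where p_ij is the region's per-base capture-efficiency profile
    (log-normal with log-sd ``profile_sd``, normalized to mean 1 — real
    capture depth varies strongly along a target, and it is this profile
    that lets sample-level multiplicative effects survive per-sample
    centering), b is the batch-region efficiency effect and s_k * f the GC
    channel.  The batch effect is low-rank: ``batch_factors`` latent
    factors shared across regions (per-batch scores x per-region loadings,
    overall sd ``batch_effect_sd``) plus an independent per-(batch, region)
    residual at one third of the factor scale.  GC response is itself one
    of those latent factors — the first factor's region loading is the
    deterministic mid-peaked curve ``gc_effect_strength * f(GC_i)`` and its
    per-batch scores are the GC sensitivities — reflecting that library GC
    response is a dominant axis of capture-efficiency variation.  On top of
    the batch-level sensitivity, ``gc_phenotype_shift`` adds a systematic
    case-control sensitivity difference (DNA-source effect).  Counts are
    negative-binomial with the configured overdispersion.
    """
    n = mean_depths.size
    n_batches = int(batches.max()) + 1
    L = config.batch_factors
    use_gc_factor = L > 0 and config.gc_effect_strength > 0
    factor_scores = rng.normal(size=(n_batches, L)) if L else None
    # per-sample GC sensitivity: factor-1 scores at batch level (or a
    # standalone batch draw when factorless), plus the case-control shift
    if use_gc_factor:
        gc_sens = config.gc_effect_strength * factor_scores[batches, 0]
    else:
        gc_sens = rng.normal(0.0, config.gc_effect_strength, size=n_batches)[batches]
    if config.gc_phenotype_shift != 0.0 and phenotypes is not None:
        gc_sens = gc_sens + config.gc_phenotype_shift * np.asarray(phenotypes, dtype=float)
    n_rand = L - 1 if use_gc_factor else L
    rand_sd = config.batch_effect_sd / np.sqrt(max(n_rand, 1))
    resid_sd = config.batch_effect_sd / 3.0
    depth: dict[str, np.ndarray] = {}
    for region in regions:
        b = rng.normal(0.0, resid_sd, size=n_batches)
        if L:
            loadings = rng.normal(size=L) * rand_sd
            if use_gc_factor:
                b = b + factor_scores[:, 1:] @ loadings[1:]
            else:
                b = b + factor_scores @ loadings
        log_effect = b[batches]
        if region.gc_fraction is not None and np.any(gc_sens):
            log_effect = log_effect + gc_sens * gc_response(region.gc_fraction)
        cn_factor = np.ones(n)
        if region.region_id in truth_genotypes:
            cn_factor = truth_genotypes[region.region_id] / 2.0
        per_sample = mean_depths * cn_factor * np.exp(log_effect)
        if config.profile_sd > 0:
            profile = np.exp(rng.normal(0.0, config.profile_sd, size=region.length))
            profile /= profile.mean()
        else:
            profile = np.ones(region.length)
        mu = profile[:, None] * per_sample[None, :]
        depth[region.region_id] = _draw_counts(mu, config.overdispersion, rng)
    return depth


def _make_regions(config: SimulationConfig, rng: np.random.Generator) -> list[CaptureRegion]:
    """Capture targets laid head-to-tail on one synthetic chromosome, with
    GC fractions drawn Beta(5, 5) — mid-heavy, like exonic targets."""
    regions = []
    pos = 0
    causal = set(config.causal_region_ids)
    for i in range(config.n_regions):
        rid = f"region_{i:05d}"
        length = config.region_length
        if rid in causal and config.causal_region_length is not None:
            length = config.causal_region_length
        gc = float(np.clip(rng.beta(5, 5), 0.05, 0.95))
        regions.append(CaptureRegion("chrS", pos, pos + length, rid, gc))
        pos += length + 100  # 100-bp gap between targets
    return regions


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a full cohort: regions, genotypes, phenotypes, batches, depth."""
    rng = np.random.default_rng(config.seed)
    regions = _make_regions(config, rng)
    known = {r.region_id for r in regions}
    missing = [c for c in config.causal_region_ids if c not in known]
    if missing:
        raise ValueError(f"causal region ids not among simulated regions: {missing}")

    n = config.n_samples
    truth: dict[str, np.ndarray] = {
        rid: simulate_genotypes(config.deletion_allele_freq, n, rng)
        for rid in config.causal_region_ids
    }
    if truth:
        # phenotype from the summed deletion allele count across causal loci
        total_alleles = np.sum([2 - g for g in truth.values()], axis=0)
        y = _phenotypes_from_alleles(total_alleles, float(np.log(config.odds_ratio)),
                                     config.n_case, rng)
    else:
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, size=config.n_case, replace=False)] = 1

    # capture-array batches; cases routed to batch 1 (index 0) with the
    # configured confounding probability, everyone else uniform
    n_batches = config.resolved_batch_count()
    batches = rng.integers(0, n_batches, size=n)
    if config.batch_phenotype_confounding > 0 and n_batches > 1:
        confounded = (y == 1) & (rng.random(n) < config.batch_phenotype_confounding)
        batches[confounded] = 0

    mean_depths = rng.uniform(*config.mean_depth_range, size=n)
    samples = [
        Sample(f"S{i:04d}", int(y[i]), None, float(mean_depths[i])) for i in range(n)
    ]
    depth = simulate_depth(config, regions, mean_depths, batches, truth, rng,
                           phenotypes=y)
    return SimulatedCohort(config, regions, samples, batches, truth, depth)


def write_fixture(cohort: SimulatedCohort, directory, header_lines=()) -> dict[str, str]:
    """Write the cohort in the standard text dialects.

    Emits ``regions.bed`` (with GC in column 5), ``manifest.tsv``,
    ``depth.tsv`` (one combined per-base table, columns = samples) and
    ``truth.tsv``; re-reading reproduces the cohort exactly.  Returns the
    path of each file.
    """
    directory = Path(directory)
    os.makedirs(directory, exist_ok=True)
    paths = {
        "bed": str(directory / "regions.bed"),
        "manifest": str(directory / "manifest.tsv"),
        "depth": str(directory / "depth.tsv"),
        "truth": str(directory / "truth.tsv"),
    }
    with open(paths["bed"], "w") as out:
        for r in cohort.regions:
            gc = "NA" if r.gc_fraction is None else repr(float(r.gc_fraction))
            out.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{gc}\n")
    for s in cohort.samples:
        # relative path: keeps the fixture relocatable and byte-stable
        s.depth_source = "depth.tsv"
    write_manifest(cohort.samples, paths["manifest"], header_lines)
    order = cohort.sample_order
    chroms, pos, rows = [], [], []
    for r in cohort.regions:
        chroms.extend([r.chrom] * r.length)
        pos.extend(range(r.start, r.end))
        rows.append(cohort.depth[r.region_id])
    table = DepthTable(np.array(chroms), np.array(pos, dtype=np.int64),
                       np.vstack(rows), order)
    table.write(paths["depth"], header_lines)
    with open(paths["truth"], "w") as out:
        out.write("sample_id\tregion_id\tcopy_number\n")
        for rid, genos in cohort.truth_genotypes.items():
            for sid, g in zip(order, genos):
                out.write(f"{sid}\t{rid}\t{int(g)}\n")
    return paths
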