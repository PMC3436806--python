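"""End-to-end orchestration: depth matrices -> local PCs -> global PCs ->
association scan across an H grid -> copy-number genotyping at a locus.

This is the programmatic surface the CLI wraps; it works on in-memory
cohorts (e.g. :class:`~exocnv.simulate.SimulatedCohort`) or on the file
dialects of :mod:`~exocnv.depthio`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import assoc, genotype, pca
from .depthio import CaptureRegion, DepthTable, Sample

logger = logging.getLogger("exocnv")

DEFAULT_H_GRID = (0, 5, 20, 40, 50)
DEFAULT_K = 50

__all__ = [
    "LocalPCStack",
    "ScanOutput",
    "compute_local_pcs",
    "run_scan",
    "genotype_locus",
    "DEFAULT_H_GRID",
    "DEFAULT_K",
]


@dataclass
class LocalPCStack:
    """Stacked per-region first PCs: rows = regions, columns = samples."""

    region_ids: list[str]
    matrix: np.ndarray  # R x N
    converged: np.ndarray  # per-region bool
    sample_order: list[str]
    dropped: list[str] = field(default_factory=list)  # zero-variance regions


@dataclass
class ScanOutput:
    H: int
    results: list[assoc.AssociationResult]
    inflation: assoc.InflationReport
    qq: np.ndarray


def _region_matrices(regions, samples, depth, depth_table):
    """Yield (region, raw M x N matrix) from whichever source is provided."""
    if depth is not None:
        for region in regions:
            yield region, depth[region.region_id]
    else:
        for region in regions:
            yield region, depth_table.region_matrix(region)


def populate_mean_depths(samples: list[Sample], regions: list[CaptureRegion],
                         depth=None, depth_table: DepthTable | None = None) -> np.ndarray:
    """Fill each sample's mean capture-footprint depth from raw counts."""
    total_len = sum(r.length for r in regions)
    totals = np.zeros(len(samples), dtype=float)
    for _, raw in _region_matrices(regions, samples, depth, depth_table):
        totals += raw.sum(axis=0)
    if np.any(totals == 0):
        bad = [samples[i].sample_id for i in np.nonzero(totals == 0)[0]]
        raise ValueError(f"samples with zero capture depth: {bad}")
    means = totals / total_len
    for s, m in zip(samples, means):
        s.mean_depth = float(m)
    return means


def compute_local_pcs(regions: list[CaptureRegion], samples: list[Sample],
                      depth=None, depth_table: DepthTable | None = None,
                      seed: int = 0, tol: float = 1e-8,
                      max_iter: int = 1000) -> LocalPCStack:
    """First local PC for every region with depth variance.

    ``depth`` maps region_id -> raw count matrix (length x N); otherwise a
    shared :class:`DepthTable` is consulted.  Samples must carry
    ``mean_depth`` (see :func:`populate_mean_depths`).  Regions whose
    centered normalized matrix is all zero carry no information and are
    dropped with a warning.
    """
    mean_depths = np.array([s.mean_depth for s in samples], dtype=float)
    if np.any(~np.isfinite(mean_depths)) or np.any(mean_depths <= 0):
        raise ValueError("populate mean depths before computing local PCs")
    ids, rows, flags, dropped = [], [], [], []
    for region, raw in _region_matrices(regions, samples, depth, depth_table):
        norm = raw / mean_depths[None, :]
        centered = pca.center_columns(norm)
        if not np.any(centered):
            dropped.append(region.region_id)
            continue
        lp = pca.first_pc_power_iteration(
            centered,
            tol=tol,
            max_iter=max_iter,
            rng_seed=pca.region_seed(seed, region.region_id),
            region_id=region.region_id,
            orient=norm.mean(axis=0),
        )
        ids.append(region.region_id)
        rows.append(lp.vector)
        flags.append(lp.converged)
    if dropped:
        logger.warning("dropped %d zero-variance regions (e.g. %s)",
                       len(dropped), dropped[:3])
    if not rows:
        raise ValueError("no region retained: all depth matrices were constant")
    return LocalPCStack(ids, np.vstack(rows), np.array(flags, dtype=bool),
                        [s.sample_id for s in samples], dropped)


def run_scan(stack: LocalPCStack, phenotypes: np.ndarray,
             H_grid=DEFAULT_H_GRID, K: int = DEFAULT_K,
             gc_fractions: dict[str, float] | None = None,
             region_loading_cap: float | None = 0.1):
    """Global PCs once, then one association scan per H in the grid.

    Returns ``(GlobalPCSet, {H: ScanOutput})``.  K is capped by the stack
    dimensions only through an explicit error, mirroring the preconditions
    of the SVD step.  ``region_loading_cap`` (see
    :func:`~exocnv.pca.compute_global_pcs`) keeps single-locus directions —
    real CNV signals — out of the technical-structure basis.
    """
    R, N = stack.matrix.shape
    if K > min(R, N):
        raise ValueError(
            f"K={K} global PCs need at least K regions and K samples "
            f"(have R={R}, N={N}); lower K"
        )
    if max(H_grid) > K:
        raise ValueError(f"H grid {H_grid} exceeds K={K}")
    # Work on each FPC's across-sample deviations: the constant component of
    # an FPC (every local PC sits near 1/sqrt(N) + deviations) carries no
    # case-control contrast, but if left in, its coupling with a
    # phenotype-correlated global PC subtracts the same phenotype-aligned
    # pattern from every region's predictor and manufactures genome-wide
    # association.  Logistic association itself is invariant to the shift.
    matrix = stack.matrix - stack.matrix.mean(axis=1, keepdims=True)
    gpcs = pca.compute_global_pcs(matrix, K, stack.sample_order,
                                  region_loading_cap=region_loading_cap)
    outputs: dict[int, ScanOutput] = {}
    for H in H_grid:
        adjusted = pca.project_out_matrix(matrix, gpcs, H)
        pairs = list(zip(stack.region_ids, adjusted))
        results, inflation = assoc.scan(pairs, phenotypes, H, gc_fractions)
        qq = assoc.qq_table([r.p_value for r in results if r.estimable])
        outputs[H] = ScanOutput(H, results, inflation, qq)
        logger.info("H=%d: lambda=%.3f over %d regions", H,
                    inflation.lambda_gc, inflation.n_regions)
    return gpcs, outputs


def genotype_locus(locus: CaptureRegion, samples: list[Sample],
                   gpcs: pca.GlobalPCSet | None, H: int = 0,
                   depth=None, depth_table: DepthTable | None = None,
                   window_size: int = 100,
                   model: genotype.CopyNumberModel | None = None,
                   threshold: float = 0.9,
                   mean_constraint: str = "affine",
                   update_start_probs: bool = True):
    """Window, adjust and genotype one locus; returns (calls, fit, windows).

    ``depth`` may be the locus's raw per-base matrix directly, or a
    region_id-keyed dict, or absent (read from ``depth_table``).
    """
    if isinstance(depth, dict):
        depth = depth[locus.region_id]
    if depth is None and depth_table is not None:
        depth = depth_table.region_matrix(locus)
    windows = genotype.build_window_matrix(depth, locus, samples, window_size)
    if H > 0:
        if gpcs is None:
            raise ValueError("global PCs required for H > 0")
        windows = genotype.adjust_window_matrix(windows, gpcs, H)
    fit = genotype.fit_population_hmm(windows, model,
                                      mean_constraint=mean_constraint,
                                      update_start_probs=update_start_probs)
    calls = genotype.call_genotypes(fit, windows.sample_order, threshold)
    return calls, fit, windows
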