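"""Principal-component machinery for depth normalization.

Two levels of structure are extracted from the cohort:

* a *local* first principal component (FPC) per capture region — the
  dominant across-sample direction of the region's centered per-base
  normalized depth matrix, i.e. the region's one-number depth summary per
  sample.  It is computed by an alternating power iteration that streams
  matrix-vector products and never forms the M x M or N x N covariance
  matrix.
* *global* principal components (GPCs) of the regions x samples matrix of
  stacked FPCs, computed by a dense SVD.  They capture cohort-wide
  technical structure — capture-batch effects, GC sensitivity — and are
  projected out of the local components before association testing.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LocalPC",
    "GlobalPCSet",
    "AdjustedPC",
    "center_columns",
    "first_pc_power_iteration",
    "compute_global_pcs",
    "project_out",
    "region_seed",
]


@dataclass
class LocalPC:
    """First principal component of one region: one entry per sample."""

    region_id: str
    vector: np.ndarray
    n_iterations: int
    converged: bool


@dataclass
class GlobalPCSet:
    """The first K right singular vectors of the centered FPC stack."""

    components: np.ndarray  # K x N, orthonormal rows, decreasing singular value
    singular_values: np.ndarray
    sample_order: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.components.shape[0]

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        if np.any(np.diff(self.singular_values) > 1e-9):
            raise ValueError("singular values must be non-increasing")


@dataclass
class AdjustedPC:
    """A local PC with the first H global PCs projected out."""

    region_id: str
    H: int
    vector: np.ndarray


def region_seed(run_seed: int, region_id: str) -> int:
    """Stable per-region RNG seed: run seed XOR a digest of the region id.

    Makes region-level results independent of scan order and of Python's
    per-process string-hash salt.
    """
    digest = hashlib.blake2s(region_id.encode(), digest_size=4).digest()
    return (int(run_seed) ^ int.from_bytes(digest, "little")) & 0x7FFFFFFF


def center_columns(matrix: np.ndarray) -> np.ndarray:
    """Subtract each column's mean; columns of the result have zero mean."""
    matrix = np.asarray(matrix, dtype=float)
    return matrix - matrix.mean(axis=0, keepdims=True)


def first_pc_power_iteration(
    matrix: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    rng_seed: int = 0,
    region_id: str = "",
    orient: np.ndarray | None = None,
) -> LocalPC:
    """Dominant right singular direction of a column-centered matrix.

    Alternating update from a random start v with entries uniform on (0, 1):

        t <- R v ;  v <- R^T t / ||R^T t||

    iterated until successive normalized iterates are within ``tol``
    (Euclidean), or ``max_iter`` is hit (returned with ``converged=False``,
    which also covers the classic power-iteration degeneracy of tied top
    singular values).  Each step needs only matrix-vector products, so R can
    be streamed one column at a time; R R^T / R^T R are never materialized.

    The returned vector has unit norm.  Its sign is canonicalized against
    ``orient`` (typically the per-sample means of the *uncentered* region
    matrix, so the component is positively oriented with relative copy
    number); without ``orient``, the largest-magnitude entry is made
    positive.
    """
    R = np.asarray(matrix, dtype=float)
    if R.ndim != 2 or R.size == 0:
        raise ValueError("matrix must be a non-empty 2-D array")
    if not np.any(R):
        raise ValueError(f"degenerate region {region_id or '<anonymous>'}: all-zero matrix")
    n = R.shape[1]
    rng = np.random.default_rng(rng_seed)
    v = rng.uniform(0.0, 1.0, size=n)
    v /= np.linalg.norm(v)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        t = R @ v
        u = R.T @ t
        norm = np.linalg.norm(u)
        if norm == 0.0:
            # start vector orthogonal to the row space; re-randomize
            v = rng.uniform(0.0, 1.0, size=n)
            v /= np.linalg.norm(v)
            continue
        v_new = u / norm
        if np.linalg.norm(v_new - v) < tol:
            v = v_new
            converged = True
            break
        v = v_new
    if orient is not None:
        if float(np.dot(v, orient)) < 0:
            v = -v
    elif v[np.argmax(np.abs(v))] < 0:
        v = -v
    return LocalPC(region_id, v, iterations, converged)


def compute_global_pcs(
    local_pcs: np.ndarray,
    K: int,
    sample_order: list[str] | None = None,
    center: bool = True,
    region_loading_cap: float | None = None,
) -> GlobalPCSet:
    """First K right singular vectors of the stacked local-PC matrix.

    ``local_pcs`` is regions x samples (one row per region's FPC).  Columns
    are centered before the SVD, mirroring the per-region centering
    convention.  The dense SVD is deliberate: it is exact for the lower-order
    components where the power iteration loses accuracy.

    ``region_loading_cap`` guards against single-locus leakage: a component
    whose squared left-singular loading on any single region exceeds the cap
    is carried by that one region rather than by cohort-wide technical
    structure — typically the depth signature of a real common CNV.  With
    few regions such a direction can outrank the noise bulk; projecting it
    out would both erase the genuine signal and inject its (possibly
    phenotype-correlated) sample pattern into every other region's test.
    Capped components are skipped and the next shared components returned.
    """
    stack = np.asarray(local_pcs, dtype=float)
    if K < 1 or K > min(stack.shape):
        raise ValueError(f"K={K} outside [1, min(R, N)={min(stack.shape)}]")
    if center:
        stack = center_columns(stack)
    u, s, vt = np.linalg.svd(stack, full_matrices=False)
    if region_loading_cap is not None:
        # a delocalized component's largest squared loading concentrates
        # near 2 ln(R)/R, so the effective cap never drops below twice that
        # and the guard stays meaningful from tens to tens of thousands of
        # regions
        R = stack.shape[0]
        cap = max(region_loading_cap, 4.0 * np.log(max(R, 2)) / R)
        shared = (u**2).max(axis=0) <= cap
        vt, s = vt[shared], s[shared]
        if shared.size - int(shared.sum()):
            import logging

            logging.getLogger("exocnv").info(
                "skipped %d single-region components in the global SVD",
                shared.size - int(shared.sum()),
            )
    if vt.shape[0] < K:
        raise ValueError(f"only {vt.shape[0]} shared components available for K={K}")
    return GlobalPCSet(vt[:K].copy(), s[:K].copy(), sample_order or [])


def project_out(vector: np.ndarray, gpcs: GlobalPCSet, H: int,
                region_id: str = "") -> AdjustedPC:
    """Remove the span of the first H global PCs from a sample-space vector:

        v_adj = v - sum_h ( <v, g_h> / <g_h, g_h> ) g_h

    The Rayleigh-quotient form keeps the operator exact even if components
    are not normalized.  H = 0 is the identity.
    """
    if H < 0 or H > gpcs.K:
        raise ValueError(f"H={H} outside [0, K={gpcs.K}]")
    v = np.asarray(vector, dtype=float).copy()
    for h in range(H):
        g = gpcs.components[h]
        v -= (np.dot(v, g) / np.dot(g, g)) * g
    return AdjustedPC(region_id, H, v)


def project_out_matrix(rows: np.ndarray, gpcs: GlobalPCSet, H: int) -> np.ndarray:
    """Vectorized :func:`project_out` applied to every row of ``rows``."""
    if H < 0 or H > gpcs.K:
        raise ValueError(f"H={H} outside [0, K={gpcs.K}]")
    out = np.asarray(rows, dtype=float).copy()
    for h in range(H):
        g = gpcs.components[h]
        out -= np.outer(out @ g / np.dot(g, g), g)
    return out


def write_local_pcs(region_ids, matrix, converged, sample_ids, path,
                    header_lines=()) -> None:
    """Local-PC TSV: one row per region, columns = samples, plus a
    converged flag column."""
    with open(path, "w") as out:
        for line in header_lines:
            out.write(f"# {line}\n")
        out.write("region_id\t" + "\t".join(sample_ids) + "\tconverged\n")
        for rid, row, flag in zip(region_ids, matrix, converged):
            vals = "\t".join(repr(float(v)) for v in row)
            out.write(f"{rid}\t{vals}\t{int(flag)}\n")


def write_global_pcs(gpcs: GlobalPCSet, path, header_lines=()) -> None:
    """Global-PC TSV: rows = samples, columns = GPC_1..GPC_K; singular
    values in a comment line."""
    with open(path, "w") as out:
        for line in header_lines:
            out.write(f"# {line}\n")
        out.write("# singular_values\t"
                  + "\t".join(repr(float(s)) for s in gpcs.singular_values) + "\n")
        out.write("sample_id\t" + "\t".join(f"GPC_{h+1}" for h in range(gpcs.K)) + "\n")
        sample_ids = gpcs.sample_order or [f"s{i}" for i in range(gpcs.components.shape[1])]
        for k, sid in enumerate(sample_ids):
            vals = "\t".join(repr(float(v)) for v in gpcs.components[:, k])
            out.write(f"{sid}\t{vals}\n")
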