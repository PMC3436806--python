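"""Absolute copy-number genotyping at a locus from windowed read depth.

The locus is tiled with non-overlapping 100-bp windows; each sample's mean
raw depth per window is divided by its capture-footprint mean depth, so a
diploid window sits near 1.0, a heterozygous deletion near 0.5 and a
homozygous deletion near 0.  After optionally projecting out global PCs,
all samples are genotyped jointly with a population hidden Markov model:

* hidden states are copy numbers 0..4 with Gaussian emissions shared
  across the whole cohort (initial means CN/2 = 0, 0.5, 1, 1.5, 2);
* a sticky transition matrix (``stay_prob`` on the diagonal) models the
  spatial coherence of a CNV across adjacent windows;
* expectation maximization re-estimates each state's mean and variance
  from posterior-weighted window depths pooled over samples, so every
  sample informs the same clusters.

Each sample's copy number is the state maximizing its mean posterior
across windows; that maximum is the call's certainty, and calls below a
certainty threshold are set missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .depthio import CaptureRegion, Sample
from .pca import GlobalPCSet, project_out_matrix

__all__ = [
    "WindowDepthMatrix",
    "CopyNumberModel",
    "HMMFit",
    "GenotypeCalls",
    "build_window_matrix",
    "adjust_window_matrix",
    "fit_population_hmm",
    "call_genotypes",
    "concordance",
    "viterbi_path",
]

N_STATES = 5  # copy numbers 0..4


@dataclass
class WindowDepthMatrix:
    """Windows x samples normalized depth over one genomic interval."""

    region: CaptureRegion
    values: np.ndarray  # W x N
    window_starts: np.ndarray  # absolute start of each window
    window_size: int = 100
    sample_order: list[str] = field(default_factory=list)
    H: int = 0  # number of global PCs already projected out

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_starts = np.asarray(self.window_starts, dtype=np.int64)
        if self.values.shape[0] != self.window_starts.size:
            raise ValueError("one start per window required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window depths must be finite")


@dataclass
class CopyNumberModel:
    """Shared Gaussian emission clusters per copy-number state 0..4.

    ``start_probs`` is the distribution over states at the first window;
    it starts uniform and, when the EM is asked to update it, converges to
    the population copy-number frequencies (each sample occupies
    essentially one state across a locus, so the prior acts as the cluster
    weight).
    """

    means: np.ndarray = field(default_factory=lambda: np.arange(N_STATES) / 2.0)
    variances: np.ndarray = field(default_factory=lambda: np.full(N_STATES, 0.01))
    stay_prob: float = 0.99
    em_iterations: int = 20
    start_probs: np.ndarray = field(
        default_factory=lambda: np.full(N_STATES, 1.0 / N_STATES))

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.start_probs = np.asarray(self.start_probs, dtype=float)
        if self.means.size != N_STATES or self.variances.size != N_STATES:
            raise ValueError(f"model must have exactly {N_STATES} states (CN 0..4)")
        if self.start_probs.size != N_STATES or abs(self.start_probs.sum() - 1) > 1e-9:
            raise ValueError("start_probs must be a distribution over the 5 states")
        if np.any(np.diff(self.means) <= 0):
            raise ValueError("state means must be strictly increasing")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")
        if not 0.0 < self.stay_prob < 1.0:
            raise ValueError("stay_prob must lie in (0, 1)")

    @property
    def transition_matrix(self) -> np.ndarray:
        off = (1.0 - self.stay_prob) / (N_STATES - 1)
        A = np.full((N_STATES, N_STATES), off)
        np.fill_diagonal(A, self.stay_prob)
        return A


@dataclass
class HMMFit:
    """Fitted model, per-sample-per-window posteriors and the EM audit trail."""

    model: CopyNumberModel
    posteriors: np.ndarray  # N x W x 5, rows sum to 1
    log_likelihoods: list[float]
    iteration_trail: list[dict]  # per-iteration means/variances/weights


@dataclass
class GenotypeCalls:
    sample_order: list[str]
    copy_number: np.ndarray  # int, -1 = missing
    certainty: np.ndarray
    threshold: float

    @property
    def missing(self) -> np.ndarray:
        return self.copy_number < 0

    @property
    def missing_rate(self) -> float:
        return float(self.missing.mean())


def build_window_matrix(depth, interval: CaptureRegion, samples: list[Sample],
                        window_size: int = 100, depth_source=None) -> WindowDepthMatrix:
    """Mean raw depth per non-overlapping window / sample mean depth.

    ``depth`` may be a precomputed per-base raw matrix (interval length x N)
    or ``None``, in which case per-base depth is pulled from
    ``depth_source`` / each sample's own source.  Windows are anchored at
    the interval start; a trailing partial window is dropped.
    """
    W = interval.length // window_size
    if W < 1:
        raise ValueError(
            f"interval {interval.region_id} ({interval.length} bp) shorter than one "
            f"{window_size}-bp window"
        )
    if depth is None:
        from .depthio import per_base_depth

        cols = []
        for s in samples:
            src = depth_source if depth_source is not None else s.depth_source
            cols.append(per_base_depth(src, interval, s.sample_id))
        depth = np.column_stack(cols)
    depth = np.asarray(depth, dtype=float)
    if depth.shape[0] != interval.length:
        raise ValueError("depth matrix rows must equal interval length")
    mean_depths = np.array([s.mean_depth for s in samples], dtype=float)
    if np.any(~np.isfinite(mean_depths)) or np.any(mean_depths <= 0):
        raise ValueError("all samples need a positive mean_depth")
    used = depth[: W * window_size].reshape(W, window_size, -1).mean(axis=1)
    values = used / mean_depths[None, :]
    starts = interval.start + window_size * np.arange(W)
    return WindowDepthMatrix(interval, values, starts, window_size,
                             [s.sample_id for s in samples], H=0)


def adjust_window_matrix(matrix: WindowDepthMatrix, gpcs: GlobalPCSet,
                         H: int) -> WindowDepthMatrix:
    """Project the first H global PCs out of every window's across-sample row."""
    if gpcs.sample_order and matrix.sample_order and gpcs.sample_order != matrix.sample_order:
        raise ValueError("sample order of window matrix and global PCs differ")
    adjusted = project_out_matrix(matrix.values, gpcs, H)
    return replace(matrix, values=adjusted, H=H)


def _log_emissions(values: np.ndarray, model: CopyNumberModel) -> np.ndarray:
    """W x N x S Gaussian log-densities."""
    x = values[:, :, None]
    var = model.variances[None, None, :]
    mu = model.means[None, None, :]
    return -0.5 * (np.log(2.0 * math.pi * var) + (x - mu) ** 2 / var)


def _forward_backward_all(values: np.ndarray, model: CopyNumberModel):
    """Vectorized forward-backward over all samples at once.

    ``values``: W x N.  Returns (posteriors N x W x S, total log-lik).
    """
    logb = _log_emissions(values, model)  # W x N x S
    shift = logb.max(axis=2, keepdims=True)
    b = np.exp(logb - shift)  # W x N x S
    W, N, S = b.shape
    A = model.transition_matrix
    alpha = np.empty((W, N, S))
    c = np.empty((W, N))
    a = b[0] * model.start_probs[None, :]
    c[0] = a.sum(axis=1)
    alpha[0] = a / c[0][:, None]
    for t in range(1, W):
        a = (alpha[t - 1] @ A) * b[t]
        c[t] = a.sum(axis=1)
        alpha[t] = a / c[t][:, None]
    beta = np.empty((W, N, S))
    beta[-1] = 1.0
    for t in range(W - 2, -1, -1):
        beta[t] = ((b[t + 1] * beta[t + 1]) @ A.T) / c[t + 1][:, None]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    ll = float(np.log(c).sum() + shift.sum())
    return np.swapaxes(gamma, 0, 1), ll


def _mstep_free(flat_gamma, flat_x, weights, means, variances, min_variance):
    """Independent posterior-weighted mean/variance per state."""
    floor = max(1e-9, 1e-8 * weights.sum())
    for s in range(N_STATES):
        w = weights[s]
        if w < floor:
            continue  # frozen: no data currently supports this state
        m = float(flat_gamma[:, s] @ flat_x / w)
        v = float(flat_gamma[:, s] @ (flat_x - m) ** 2 / w)
        means[s] = m
        variances[s] = max(v, min_variance)
    return means, variances


def _mstep_affine(flat_gamma, flat_x, weights, means, variances, min_variance):
    """Generalized M-step with cluster positions tied affinely to copy number:
    mean_s = a + b * CN_s/2, b > 0.

    Read depth is proportional to copy number, so the cluster positions of a
    real locus lie on a line in CN; fitting (a, b) by posterior-weighted
    least squares keeps states with no supporting samples (e.g. CN 3/4 at a
    deletion locus) parked on that line instead of migrating into an
    occupied neighbour's cluster, which is the classic failure of a free
    5-state EM when only 2-3 states are populated.
    """
    c = np.arange(N_STATES) / 2.0
    floor = max(1e-9, 1e-8 * weights.sum())
    u = np.where(weights > floor, weights / variances, 0.0)  # per-state LS weight
    if np.count_nonzero(u) < 2:
        # a line needs two supported states; fall back to the free update
        return _mstep_free(flat_gamma, flat_x, weights, means, variances,
                           min_variance)
    xbar = np.where(weights > floor,
                    (flat_gamma.T @ flat_x) / np.maximum(weights, 1e-300), 0.0)
    A = np.array([[u.sum(), u @ c], [u @ c, u @ c**2]])
    rhs = np.array([u @ xbar, (u * c) @ xbar])
    try:
        a, b = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        return means, variances
    b = max(b, 1e-3)  # preserve strictly increasing means
    means = a + b * c
    for s in range(N_STATES):
        if weights[s] < floor:
            continue
        v = float(flat_gamma[:, s] @ (flat_x - means[s]) ** 2 / weights[s])
        variances[s] = max(v, min_variance)
    return means, variances


def fit_population_hmm(matrix: WindowDepthMatrix,
                       model: CopyNumberModel | None = None,
                       ll_tol: float = 1e-6,
                       min_variance: float = 1e-6,
                       mean_constraint: str = "free",
                       update_start_probs: bool = False) -> HMMFit:
    """Fit the shared emission clusters by EM and return per-sample posteriors.

    The E-step runs forward-backward per sample with the current shared
    emissions; the M-step re-estimates the state means and variances from
    posterior-weighted window values pooled over all samples (population
    clustering).  ``mean_constraint`` selects the M-step: ``"free"`` updates
    each state independently (means re-sorted afterwards so state s always
    genotypes the s-th depth cluster); ``"affine"`` ties cluster positions
    to a line in copy number (see :func:`_mstep_affine`), the recommended
    mode for genotyping a locus where not all five states are populated.
    ``update_start_probs`` additionally re-estimates the first-window state
    distribution (Baum-Welch), which converges to the population
    copy-number frequencies and stops unpopulated states from competing at
    full uniform prior weight for windows between occupied clusters.
    A state with vanishing posterior mass keeps its current parameters
    instead of collapsing to NaN.  Runs ``model.em_iterations`` EM rounds,
    stopping early once the total log-likelihood improves by less than
    ``ll_tol``.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("population HMM needs at least 2 samples")
    if mean_constraint not in ("free", "affine"):
        raise ValueError(f"unknown mean_constraint {mean_constraint!r}")
    mstep = _mstep_free if mean_constraint == "free" else _mstep_affine
    model = model or CopyNumberModel()
    model = replace(model, means=model.means.copy(), variances=model.variances.copy())
    values = matrix.values  # W x N
    gamma, ll = _forward_backward_all(values, model)
    lls = [ll]
    trail = []
    for _ in range(model.em_iterations):
        weights = gamma.sum(axis=(0, 1))  # S
        flat_gamma = gamma.transpose(1, 0, 2).reshape(-1, N_STATES)  # (W*N) x S
        flat_x = values.reshape(-1)
        means, variances = mstep(flat_gamma, flat_x, weights,
                                 model.means.copy(), model.variances.copy(),
                                 min_variance)
        start_probs = model.start_probs.copy()
        if update_start_probs:
            start_probs = gamma[:, 0, :].mean(axis=0)
            start_probs = np.maximum(start_probs, 1e-6)
            start_probs /= start_probs.sum()
        order = np.argsort(means)
        means, variances = means[order], variances[order]
        weights, start_probs = weights[order], start_probs[order]
        # enforce strict ordering against exact ties
        for s in range(1, N_STATES):
            if means[s] <= means[s - 1]:
                means[s] = means[s - 1] + 1e-9
        model = replace(model, means=means, variances=variances,
                        start_probs=start_probs)
        trail.append({
            "means": means.copy(),
            "variances": variances.copy(),
            "weights": weights / weights.sum(),
        })
        gamma, ll = _forward_backward_all(values, model)
        lls.append(ll)
        if abs(lls[-1] - lls[-2]) < ll_tol:
            break
    return HMMFit(model, gamma, lls, trail)


def call_genotypes(fit: HMMFit, sample_order: list[str] | None = None,
                   threshold: float = 0.9) -> GenotypeCalls:
    """Summarize posteriors into one copy-number call per sample.

    The per-sample mean posterior across windows is the genotype evidence
    for the single CNV spanning the locus; its argmax is the call and its
    maximum the certainty.  Calls with certainty below ``threshold`` are
    set missing (copy number -1).
    """
    mean_post = fit.posteriors.mean(axis=1)  # N x S
    cn = mean_post.argmax(axis=1).astype(int)
    certainty = mean_post.max(axis=1)
    cn[certainty < threshold] = -1
    n = mean_post.shape[0]
    return GenotypeCalls(sample_order or [f"s{i}" for i in range(n)],
                         cn, certainty, threshold)


def concordance(calls: GenotypeCalls, truth) -> tuple[float | None, float]:
    """(accuracy over non-missing calls, missing rate) against truth genotypes.

    ``truth`` maps sample_id -> copy number, or is an array aligned with
    ``calls.sample_order``.  Missing calls are excluded from the accuracy
    numerator and denominator; with no non-missing calls the accuracy is
    undefined (``None``).
    """
    if isinstance(truth, dict):
        t = np.array([truth[s] for s in calls.sample_order], dtype=int)
    else:
        t = np.asarray(truth, dtype=int)
    if t.size != calls.copy_number.size:
        raise ValueError("truth must cover every sample")
    called = ~calls.missing
    if not called.any():
        return None, calls.missing_rate
    acc = float((calls.copy_number[called] == t[called]).mean())
    return acc, calls.missing_rate


def viterbi_path(values: np.ndarray, model: CopyNumberModel,
                 sample: int) -> np.ndarray:
    """Most likely copy-number path along windows for one sample.

    Exposed for within-locus segmentation; the single-CNV genotype call
    uses the mean posterior instead.
    """
    logb = _log_emissions(values, model)[:, sample, :]  # W x S
    logA = np.log(model.transition_matrix)
    W = logb.shape[0]
    delta = np.log(model.start_probs) + logb[0]
    back = np.zeros((W, N_STATES), dtype=int)
    for t in range(1, W):
        scores = delta[:, None] + logA
        back[t] = scores.argmax(axis=0)
        delta = scores.max(axis=0) + logb[t]
    path = np.empty(W, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(W - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def write_genotype_tsv(calls: GenotypeCalls, path, H: int = 0, locus: str = "",
                       header_lines=()) -> None:
    """Genotype TSV: sample_id, copy_number (NA when missing), certainty."""
    with open(path, "w") as out:
        for line in header_lines:
            out.write(f"# {line}\n")
        out.write("sample_id\tcopy_number\tcertainty\tH\tlocus\n")
        for sid, cn, cert in zip(calls.sample_order, calls.copy_number, calls.certainty):
            cn_str = "NA" if cn < 0 else str(int(cn))
            out.write(f"{sid}\t{cn_str}\t{repr(float(cert))}\t{H}\t{locus}\n")


def write_cluster_tsv(fit: HMMFit, path, header_lines=()) -> None:
    """Per-EM-iteration audit of cluster means, variances and weights."""
    with open(path, "w") as out:
        for line in header_lines:
            out.write(f"# {line}\n")
        out.write("iteration\tstate\tmean\tvariance\tweight\n")
        for it, step in enumerate(fit.iteration_trail, start=1):
            for s in range(N_STATES):
                out.write(f"{it}\t{s}\t{repr(float(step['means'][s]))}\t"
                          f"{repr(float(step['variances'][s]))}\t"
                          f"{repr(float(step['weights'][s]))}\n")


def write_vcf(calls: GenotypeCalls, locus, path, header_lines=()) -> None:
    """Single symbolic-allele VCF record for the locus with a per-sample
    integer CN FORMAT field (missing calls are '.')."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for line in header_lines:
            out.write(f"##comment={line}\n")
        for cn in range(N_STATES):
            out.write(f"##ALT=<ID=CN{cn},Description=\"Copy number {cn}\">\n")
        out.write("##FORMAT=<ID=CN,Number=1,Type=Integer,"
                  "Description=\"Absolute copy number call\">\n")
        out.write(f"##contig=<ID={locus.chrom}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(calls.sample_order) + "\n")
        alts = ",".join(f"<CN{cn}>" for cn in range(N_STATES) if cn != 2)
        fields = "\t".join("." if cn < 0 else str(int(cn)) for cn in calls.copy_number)
        out.write(f"{locus.chrom}\t{locus.start + 1}\t{locus.region_id}\tN\t{alts}\t"
                  f".\tPASS\tEND={locus.end}\tCN\t{fields}\n")
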