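"""Group spatial ICA with ICASSO stability and back-reconstruction.

The decomposition treats timepoints as channels and voxels as samples
(spatial ICA): per-subject temporal PCA, temporal concatenation across
subjects, a group PCA step (expectation-maximization algorithm), infomax ICA
repeated with random initializations (ICASSO), aggregation of components as
cluster centrotypes with a stability index I_q per component, and GICA
back-reconstruction of subject-specific spatial maps and time courses.
Component time courses are screened with spectral criteria (low-frequency
power ratio, dynamic range) to mark intrinsic connectivity networks.

Scale is fully configurable; the desk-scale defaults (subject PCA 30, group
PCA 12, 10 components, 10 ICASSO runs) keep the identical algorithmics
tractable on synthetic cohorts, while full-scale settings (120/100/100/20)
remain available through the same arguments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from scipy.stats import skew

from .simulate import SubjectTimeSeries

__all__ = [
    "SubjectPCA",
    "GroupPCA",
    "GroupICAResult",
    "ComponentSpectralMetrics",
    "subject_pca",
    "group_pca_concat",
    "infomax_ica",
    "icasso_stability",
    "back_reconstruct",
    "spectral_icn_metrics",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA stages
# ---------------------------------------------------------------------------

@dataclass
class SubjectPCA:
    reduced: np.ndarray       # (n_components, n_voxels)
    basis: np.ndarray         # (T, n_components), orthonormal columns
    eigenvalues: np.ndarray   # all T eigenvalues of the temporal covariance
    n_components: int
    subject_id: str = ""

    @property
    def explained_fraction(self) -> float:
        total = self.eigenvalues.sum()
        return float(self.eigenvalues[: self.n_components].sum() / total) if total > 0 else 1.0


def subject_pca(ts: SubjectTimeSeries, n_components: int) -> SubjectPCA:
    """Temporal PCA of one subject: reduce T timepoints to the top directions.

    Each voxel's temporal mean is subtracted, then the T x T temporal
    covariance is eigendecomposed (via SVD of the demeaned matrix). Retained
    components are ordered by decreasing variance; the discarded eigenvalue
    sum equals the reconstruction error.
    """
    data = ts.data - ts.data.mean(axis=1, keepdims=True)  # demean each voxel over time
    t = data.shape[1]
    if n_components > t:
        raise ValueError(f"n_components={n_components} exceeds {t} timepoints")
    xt = data.T  # (T, V)
    u, s, _ = np.linalg.svd(xt, full_matrices=False)
    eig = s ** 2
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds achievable rank {rank}"
        )
    basis = u[:, :n_components]
    reduced = basis.T @ xt  # (n_components, V)
    return SubjectPCA(
        reduced=reduced, basis=basis, eigenvalues=eig,
        n_components=n_components, subject_id=ts.subject_id,
    )


@dataclass
class GroupPCA:
    reduced: np.ndarray    # (n_group_components, n_voxels)
    basis: np.ndarray      # (sum of subject components, n_group_components)
    block_slices: list[slice]  # rows of `basis` belonging to each subject
    n_iterations: int = 0


def _em_pca_subspace(
    x: np.ndarray, n_components: int, max_iter: int = 500, tol: float = 1e-6,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Principal subspace of the row-space of x (channels x samples) via EM.

    Roweis' EM algorithm for PCA: alternate latent inference and basis update
    without ever forming the channels x channels covariance. Returns an
    orthonormal (channels x n_components) basis and the iteration count.
    Convergence is declared when the largest principal angle between
    successive subspaces falls below ``tol``.
    """
    rng = np.random.default_rng(seed)
    n_chan = x.shape[0]
    w = rng.normal(size=(n_chan, n_components))
    w, _ = np.linalg.qr(w)
    prev = w
    for it in range(1, max_iter + 1):
        z = np.linalg.solve(w.T @ w, w.T @ x)       # E-step
        w = (x @ z.T) @ np.linalg.inv(z @ z.T)      # M-step
        w, _ = np.linalg.qr(w)
        # subspace change: largest principal angle via singular values of overlap
        sv = np.linalg.svd(prev.T @ w, compute_uv=False)
        angle = float(np.arccos(np.clip(sv.min(), -1.0, 1.0)))
        prev = w
        if angle < tol:
            break
    return w, it


def group_pca_concat(
    subjects: list[SubjectPCA],
    n_group_components: int,
    method: str = "em",
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> GroupPCA:
    """Concatenate subject-reduced data across time and reduce with group PCA.

    The subject-reduced matrices are stacked row-wise (concatenated time) and
    the stacked channel dimension reduced to ``n_group_components`` with the
    EM algorithm (or an exact SVD with ``method='svd'``). Deterministic up to
    component sign for a fixed subject order.
    """
    if not subjects:
        raise ValueError("no subjects supplied")
    n_vox = {s.reduced.shape[1] for s in subjects}
    if len(n_vox) != 1:
        raise ValueError(f"inconsistent voxel dimensions across subjects: {sorted(n_vox)}")
    stacked = np.vstack([s.reduced for s in subjects])
    slices, start = [], 0
    for s in subjects:
        slices.append(slice(start, start + s.n_components))
        start += s.n_components
    if n_group_components > stacked.shape[0]:
        raise ValueError(
            f"n_group_components={n_group_components} exceeds stacked dimension {stacked.shape[0]}"
        )
    if method == "em":
        basis, n_it = _em_pca_subspace(
            stacked, n_group_components, max_iter=max_iter, tol=tol, seed=seed
        )
        # rotate the EM subspace basis to principal axes (ordered by variance)
        proj = basis.T @ stacked
        u, _, _ = np.linalg.svd(proj @ proj.T)
        basis = basis @ u
        n_iterations = n_it
    elif method == "svd":
        u, _, _ = np.linalg.svd(stacked, full_matrices=False)
        basis = u[:, :n_group_components]
        n_iterations = 0
    else:
        raise ValueError(f"unknown method {method!r}")
    reduced = basis.T @ stacked
    return GroupPCA(reduced=reduced, basis=basis, block_slices=slices,
                    n_iterations=n_iterations)


# ---------------------------------------------------------------------------
# Infomax ICA
# ---------------------------------------------------------------------------

class ICAConvergenceWarning(UserWarning):
    pass


def infomax_ica(
    group_reduced: np.ndarray,
    n_components: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
    learning_rate: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Infomax ICA (natural-gradient, logistic nonlinearity) on group-reduced data.

    ``group_reduced`` is channels x samples (components of the group PCA over
    voxels). Data are whitened internally; the infomax update
    ΔW ∝ (I + (1 − 2y) u') W with y = logistic(u) drives W toward a separating
    matrix for super-Gaussian sources (spatial maps are sparse, hence
    super-Gaussian). Returns (sources, mixing, converged): sources are
    n_components x samples with unit variance and positive skewness; mixing
    satisfies group_reduced ≈ mixing @ sources. Non-convergence within
    ``max_iter`` returns the partial result with a warning.
    """
    x = np.asarray(group_reduced, dtype=float)
    if x.ndim != 2:
        raise ValueError("group_reduced must be 2-D (channels x samples)")
    n_chan, n_samp = x.shape
    if n_components > n_chan:
        raise ValueError(f"n_components={n_components} exceeds {n_chan} channels")
    rng = np.random.default_rng(seed)

    mean = x.mean(axis=1, keepdims=True)
    xc = x - mean
    u_pca, s_pca, _ = np.linalg.svd(xc, full_matrices=False)
    k_white = (u_pca[:, :n_components] / s_pca[:n_components]).T * np.sqrt(n_samp)
    xw = k_white @ xc  # (n_components, n_samp), identity covariance

    w = np.linalg.qr(rng.normal(size=(n_components, n_components)))[0]
    eye = np.eye(n_components)
    lrate = learning_rate
    converged = False
    block = max(8, int(np.sqrt(n_samp / 3)))
    prev_delta = np.inf
    for _ in range(max_iter):
        w_old = w.copy()
        perm = rng.permutation(n_samp)
        for start in range(0, n_samp, block):
            idx = perm[start:start + block]
            u = w @ xw[:, idx]
            y = 1.0 / (1.0 + np.exp(-u))
            grad = (len(idx) * eye + (1.0 - 2.0 * y) @ u.T) @ w
            w = w + lrate * grad / len(idx)
            if not np.isfinite(w).all():
                raise FloatingPointError("infomax diverged; lower the learning rate")
        delta = float(np.linalg.norm(w - w_old))
        if delta < tol:
            converged = True
            break
        if delta > 1e3:
            lrate *= 0.5
            w = np.linalg.qr(rng.normal(size=(n_components, n_components)))[0]
            prev_delta = np.inf
            continue
        # anneal: oscillating weight updates mean the step size is too large
        if delta >= prev_delta:
            lrate *= 0.9
        prev_delta = delta
    if not converged:
        warnings.warn(
            f"infomax did not converge within {max_iter} iterations (Δ={delta:.2e})",
            ICAConvergenceWarning,
        )
    sources = w @ xw
    # unit variance and positive-skew sign convention
    sd = sources.std(axis=1, keepdims=True)
    sources = sources / sd
    flip = np.where(skew(sources, axis=1) < 0, -1.0, 1.0)
    sources = sources * flip[:, None]
    # mixing back in the original (unwhitened) channel space, by least squares
    mixing = xc @ np.linalg.pinv(sources)
    return sources, mixing, converged


# ---------------------------------------------------------------------------
# ICASSO
# ---------------------------------------------------------------------------

@dataclass
class GroupICAResult:
    group_maps: np.ndarray               # (n_components, n_voxels) centrotype maps
    mixing: np.ndarray                   # (group channels, n_components)
    stability_iq: np.ndarray             # (n_components,)
    n_subject_pcs: int
    n_group_pcs: int
    n_ica_runs: int
    retained: np.ndarray = field(default=None)  # I_q > iq_threshold
    iq_threshold: float = 0.8
    subject_maps: dict[str, np.ndarray] = field(default_factory=dict)
    subject_timecourses: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        iq = np.asarray(self.stability_iq, dtype=float)
        if ((iq < -1e-9) | (iq > 1 + 1e-9)).any():
            raise ValueError("stability_iq must lie in [0, 1]")
        if self.retained is None:
            self.retained = iq > self.iq_threshold


def icasso_stability(
    group_pca: GroupPCA,
    n_components: int,
    n_runs: int = 20,
    seed: int = 0,
    iq_threshold: float = 0.8,
    n_subject_pcs: int | None = None,
    **ica_kwargs,
) -> GroupICAResult:
    """Repeat infomax ICA with random initializations and cluster the components.

    Components pooled over runs are clustered (average linkage on
    1 − |correlation| of maps, cut at ``n_components`` clusters). Each
    cluster's stability index I_q is its mean intra-cluster similarity minus
    its mean similarity to components outside the cluster; the aggregate map
    is the cluster centrotype (the member with the highest intra-minus-extra
    similarity sum). Components with I_q ≤ ``iq_threshold`` are flagged for
    exclusion. Runs that fail to converge are dropped (and logged); fewer
    than 2 surviving runs is an error.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    rng = np.random.default_rng(seed)
    all_sources = []
    run_of = []
    n_survived = 0
    for _ in range(n_runs):
        run_seed = int(rng.integers(2**31))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ICAConvergenceWarning)
            sources, _, converged = infomax_ica(
                group_pca.reduced, n_components, seed=run_seed, **ica_kwargs
            )
        if not converged:
            logger.warning("dropping non-converged ICASSO run (seed %d)", run_seed)
            continue
        all_sources.append(sources)
        run_of.extend([n_survived] * n_components)
        n_survived += 1
    if n_survived < 2:
        raise RuntimeError(f"only {n_survived} ICASSO runs converged; need at least 2")

    pool = np.vstack(all_sources)  # (n_survived * C, V)
    sim = np.abs(np.corrcoef(pool))
    np.fill_diagonal(sim, 1.0)
    dist = squareform(1.0 - sim, checks=False)
    link = linkage(dist, method="average")
    clusters = fcluster(link, t=n_components, criterion="maxclust")

    maps, iqs = [], []
    for c in range(1, clusters.max() + 1):
        inside = np.where(clusters == c)[0]
        outside = np.where(clusters != c)[0]
        if inside.size > 1:
            intra_block = sim[np.ix_(inside, inside)]
            intra = (intra_block.sum() - inside.size) / (inside.size * (inside.size - 1))
        else:
            intra = 1.0
        extra = sim[np.ix_(inside, outside)].mean() if outside.size else 0.0
        iqs.append(float(np.clip(intra - extra, 0.0, 1.0)))
        # centrotype: member maximizing intra-similarity minus extra-similarity sums
        score = sim[np.ix_(inside, inside)].sum(axis=1) - (
            sim[np.ix_(inside, outside)].sum(axis=1) if outside.size else 0.0
        )
        maps.append(pool[inside[int(np.argmax(score))]])

    order = np.argsort(iqs)[::-1]
    group_maps = np.asarray(maps)[order]
    iq = np.asarray(iqs)[order]
    mixing = group_pca.reduced @ np.linalg.pinv(group_maps)
    return GroupICAResult(
        group_maps=group_maps, mixing=mixing, stability_iq=iq,
        n_subject_pcs=n_subject_pcs or -1, n_group_pcs=group_pca.reduced.shape[0],
        n_ica_runs=n_survived, iq_threshold=iq_threshold,
    )


# ---------------------------------------------------------------------------
# Back-reconstruction
# ---------------------------------------------------------------------------

def back_reconstruct(
    result: GroupICAResult,
    group_pca: GroupPCA,
    subject_pcas: list[SubjectPCA],
    subjects: list[SubjectTimeSeries],
) -> GroupICAResult:
    """GICA back-reconstruction of subject spatial maps and time courses.

    With stacked subject-PCA data ≈ H·G (group PCA) and G ≈ A·S (ICA), the
    subject block satisfies d_i ≈ (U_i H_i A) S, so the subject time course
    matrix is TC_i = U_i H_i A (T x C, one column per component) and subject
    maps are the least-squares regression of the subject data onto TC_i.
    Results are stored on ``result`` keyed by subject id.
    """
    a = result.mixing  # (group channels, C)
    for idx, (spc, ts) in enumerate(zip(subject_pcas, subjects)):
        if spc.basis is None:
            raise ValueError(f"subject {spc.subject_id}: missing PCA basis")
        data = ts.data - ts.data.mean(axis=1, keepdims=True)
        if float(np.abs(data).max() or 0.0) == 0.0:
            raise ValueError(f"subject {ts.subject_id}: zero-variance data")
        h_i = group_pca.basis[group_pca.block_slices[idx], :]  # (n_sub_pc, g)
        tc = spc.basis @ h_i @ a  # (T, C)
        maps = np.linalg.lstsq(tc, data.T, rcond=None)[0]  # (C, V)
        result.subject_timecourses[ts.subject_id] = tc
        result.subject_maps[ts.subject_id] = maps
    return result


# ---------------------------------------------------------------------------
# Spectral ICN screening
# ---------------------------------------------------------------------------

@dataclass
class ComponentSpectralMetrics:
    power_ratio: float     # power below 0.10 Hz over power in 0.15-0.25 Hz
    dynamic_range: float   # max(P) - min(P) over the Welch spectrum
    is_icn: bool


def spectral_icn_metrics(
    timecourse: np.ndarray,
    tr_seconds: float,
    low_band_hz: float = 0.10,
    noise_band_hz: tuple[float, float] = (0.15, 0.25),
    nperseg: int = 64,
    power_ratio_min: float = 2.0,
    dynamic_range_min: float = 0.0,
) -> ComponentSpectralMetrics:
    """Welch-spectrum screening of a component time course.

    power_ratio is the integrated power below ``low_band_hz`` divided by the
    integrated power in ``noise_band_hz``; an intrinsic network's time course
    is dominated by low-frequency fluctuations, so its ratio is high.
    dynamic_range is the spread max(P) − min(P) of the spectrum. The
    denominator is floored at a small fraction of total power so the ratio
    stays finite. Welch settings: Hann window, segment length 64, 50% overlap.
    """
    x = np.asarray(timecourse, dtype=float).ravel()
    if x.size < 64:
        raise ValueError("need a time course of at least 64 samples")
    fs = 1.0 / tr_seconds
    if fs / 2 < noise_band_hz[1]:
        raise ValueError(
            f"Nyquist {fs / 2:.3f} Hz below the {noise_band_hz[1]} Hz band edge"
        )
    f, p = sp_signal.welch(x, fs=fs, window="hann", nperseg=min(nperseg, x.size))
    low = p[f < low_band_hz].sum()
    high = p[(f >= noise_band_hz[0]) & (f <= noise_band_hz[1])].sum()
    floor = 1e-12 * p.sum()
    ratio = float(low / max(high, floor))
    drange = float(p.max() - p.min())
    return ComponentSpectralMetrics(
        power_ratio=ratio,
        dynamic_range=drange,
        is_icn=(ratio > power_ratio_min) and (drange >= dynamic_range_min),
    )


def match_components(
    estimated_maps: np.ndarray, reference_maps: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of estimated to reference spatial maps by |correlation|."""
    k_ref = reference_maps.shape[0]
    corr = np.corrcoef(reference_maps, estimated_maps)[:k_ref, k_ref:]
    row, col = linear_sum_assignment(-np.abs(corr))
    return col, np.abs(corr[row, col])
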