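"""Synthetic multi-subject BOLD-like cohorts with planted connectivity states.

Every downstream stage of the pipeline (QC, group ICA, static FC, windowed FC,
state clustering, group statistics) is exercised against cohorts generated here,
for which the ground truth — spatial source maps, the hidden Markov state
sequence, per-state source covariances, occupancies and motion traces — is known
exactly.

The generative model: each subject has ``n_sources`` spatially independent
sources (disjoint smooth blobs over ``n_voxels`` voxels). A first-order Markov
chain over ``n_states`` planted covariance states drives the source time
courses: at each timepoint the source vector is drawn from a zero-mean Gaussian
with the active state's covariance. Voxel data are the spatial mixing of the
source courses plus i.i.d. Gaussian noise. Motion parameters are a smooth
random walk with occasional spikes so that framewise-displacement QC has
something to find.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "Cohort",
    "generate_state_sequence",
    "make_state_covariances",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the acquisition this pipeline targets: 295 retained
    volumes at TR = 0.906 s, two groups of equal size, and four recurring
    connectivity states with a sticky (stay probability 0.95) Markov chain,
    giving geometric dwell times with mean 20 TR (~18 s).
    """

    n_subjects_per_group: int = 10
    n_sources: int = 10
    n_voxels: int = 500
    n_timepoints: int = 295
    tr_seconds: float = 0.906
    n_states: int = 4
    stay_probability: float = 0.95
    noise_sd: float = 0.2
    motion_spike_rate: float = 0.02
    group_effect: float = 0.0
    seed: int = 0
    state_rank: int = 3  # rank of the low-rank factor behind each state covariance

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")
        if not (0.0 < self.stay_probability < 1.0):
            raise ValueError("stay_probability must lie in (0, 1)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.motion_spike_rate <= 1.0):
            raise ValueError("motion_spike_rate must lie in [0, 1]")
        if self.n_sources > self.n_voxels:
            raise ValueError("n_sources cannot exceed n_voxels")

    @property
    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic matrix with ``stay_probability`` on the diagonal."""
        k = self.n_states
        if k == 1:
            return np.ones((1, 1))
        off = (1.0 - self.stay_probability) / (k - 1)
        tm = np.full((k, k), off)
        np.fill_diagonal(tm, self.stay_probability)
        return tm


@dataclass
class SubjectTimeSeries:
    """One subject's voxels-by-time data matrix; the pipeline's atomic input."""

    data: np.ndarray  # (n_voxels, n_timepoints)
    tr_seconds: float
    subject_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D voxels x timepoints matrix")
        if not np.isfinite(self.data).all():
            raise ValueError(f"subject {self.subject_id}: non-finite values in data")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    source_maps: np.ndarray                      # (n_sources, n_voxels)
    state_covariances: list[np.ndarray]          # per state (n_sources, n_sources)
    state_covariances_case: list[np.ndarray]     # case-group covariances (== control unless group_effect)
    state_sequences: dict[str, np.ndarray]       # subject -> (T,) labels in 1..n_states
    source_timecourses: dict[str, np.ndarray]    # subject -> (n_sources, T)
    true_occupancy: pd.DataFrame                 # subjects x states
    true_mean_dwell: pd.DataFrame                # subjects x states, in TR units (NaN if unvisited)
    motion_traces: dict[str, np.ndarray]         # subject -> (6, T) [rot x3 (rad), trans x3 (mm)]

    def state_correlations(self, group: str = "control") -> list[np.ndarray]:
        covs = self.state_covariances if group == "control" else self.state_covariances_case
        out = []
        for c in covs:
            d = np.sqrt(np.diag(c))
            out.append(c / np.outer(d, d))
        return out


@dataclass
class Cohort:
    subjects: list[SubjectTimeSeries]
    table: pd.DataFrame          # subject_id, group, age, sex, deprivation_decile
    truth: GroundTruth
    config: SyntheticConfig


def generate_state_sequence(
    transition_matrix: np.ndarray,
    n_timepoints: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Sample a label sequence (1-based) from a first-order Markov chain.

    The start state is drawn uniformly. Rows must sum to one; a row that does
    not is rejected with a message naming it.
    """
    tm = np.asarray(transition_matrix, dtype=float)
    if tm.ndim != 2 or tm.shape[0] != tm.shape[1]:
        raise ValueError("transition matrix must be square")
    if (tm < 0).any():
        raise ValueError("transition matrix entries must be non-negative")
    row_sums = tm.sum(axis=1)
    bad = np.where(~np.isclose(row_sums, 1.0, atol=1e-8))[0]
    if bad.size:
        raise ValueError(
            f"transition matrix row {bad[0]} sums to {row_sums[bad[0]]:.6g}, not 1"
        )
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = tm.shape[0]
    labels = np.empty(n_timepoints, dtype=int)
    state = int(rng.integers(k))
    labels[0] = state + 1
    # cumulative rows once; inverse-CDF sampling per step
    cum = np.cumsum(tm, axis=1)
    u = rng.random(n_timepoints - 1)
    for t in range(1, n_timepoints):
        state = int(np.searchsorted(cum[state], u[t - 1], side="right"))
        state = min(state, k - 1)
        labels[t] = state + 1
    return labels


def make_state_covariances(
    n_sources: int,
    n_states: int,
    rank: int = 3,
    diag_load: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Build SPD state covariances from random low-rank factors plus diagonal loading.

    Each state s gets C_s = F_s F_s' + diag_load * I with F_s an
    (n_sources x rank) Gaussian factor, then is rescaled to unit diagonal so
    states differ in correlation *pattern*, not overall power. The low-rank
    construction guarantees SPD and gives strong, distinct off-diagonal
    structure between states (|r| commonly 0.3-0.7), which is the regime in
    which recurring FC states are described.
    """
    rng = np.random.default_rng() if rng is None else rng
    covs = []
    for _ in range(n_states):
        f = rng.normal(size=(n_sources, rank))
        c = f @ f.T + diag_load * np.eye(n_sources)
        d = np.sqrt(np.diag(c))
        covs.append(c / np.outer(d, d))
    return covs


def _spd_check(c: np.ndarray, name: str = "covariance") -> None:
    c = np.asarray(c, dtype=float)
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh(c)
    if w.min() <= 0:
        raise ValueError(f"{name} is not positive definite (min eigenvalue {w.min():.3g})")


def _shift_covariance(c: np.ndarray, shift: float) -> np.ndarray:
    """Additively shift all off-diagonal entries, restoring SPD by eigenvalue floor."""
    out = c + shift * (np.ones_like(c) - np.eye(c.shape[0]))
    w, v = np.linalg.eigh(out)
    if w.min() <= 1e-8:
        w = np.maximum(w, 1e-6)
        out = (v * w) @ v.T
    return out


def _source_maps(n_sources: int, n_voxels: int, rng: np.random.Generator) -> np.ndarray:
    """Disjoint half-cosine blobs plus faint background; sparse → super-Gaussian maps."""
    maps = 0.02 * rng.normal(size=(n_sources, n_voxels))
    width = n_voxels // n_sources
    for s in range(n_sources):
        lo = s * width
        hi = min(lo + width, n_voxels)
        x = np.linspace(0, np.pi, hi - lo)
        maps[s, lo:hi] += np.sin(x)
    return maps


def _motion_trace(
    n_timepoints: int,
    spike_rate: float,
    rng: np.random.Generator,
    trans_step_sd: float = 0.05,
    rot_step_sd: float = 0.001,
) -> np.ndarray:
    """6 x T motion parameters: rotations (rad) rows 0-2, translations (mm) rows 3-5.

    A smooth random walk plus occasional single-frame translation spikes, sized
    so mean framewise displacement sits near 0.3 mm — typical of a paediatric
    cohort passing QC.
    """
    rot = np.cumsum(rng.normal(scale=rot_step_sd, size=(3, n_timepoints)), axis=1)
    trans = np.cumsum(rng.normal(scale=trans_step_sd, size=(3, n_timepoints)), axis=1)
    spikes = rng.random(n_timepoints) < spike_rate
    for t in np.where(spikes)[0]:
        axis = int(rng.integers(3))
        trans[axis, t] += rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 2.5)
    return np.vstack([rot, trans])


def _occupancy_and_dwell(labels: np.ndarray, n_states: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact run-length-weighted occupancy and mean run length per state (TR units)."""
    occ = np.array([(labels == s).mean() for s in range(1, n_states + 1)])
    dwell = np.full(n_states, np.nan)
    # run-length encode
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    for s in range(1, n_states + 1):
        runs = [(e - b) for b, e in zip(starts, ends) if labels[b] == s]
        if runs:
            dwell[s - 1] = float(np.mean(runs))
    return occ, dwell


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a two-group cohort with full ground truth.

    Deterministic: identical (config, seed) gives identical output. Cases and
    controls are drawn from the same generative model unless
    ``config.group_effect`` is non-zero, in which case the case group's state
    covariances receive a per-edge additive shift.
    """
    rng = np.random.default_rng(config.seed)
    maps = _source_maps(config.n_sources, config.n_voxels, rng)
    covs_control = make_state_covariances(
        config.n_sources, config.n_states, rank=config.state_rank, rng=rng
    )
    for i, c in enumerate(covs_control):
        _spd_check(c, f"state {i + 1} covariance")
    if config.group_effect != 0.0:
        covs_case = [_shift_covariance(c, config.group_effect) for c in covs_control]
    else:
        covs_case = [c.copy() for c in covs_control]
    chols = {"control": [np.linalg.cholesky(c) for c in covs_control],
             "case": [np.linalg.cholesky(c) for c in covs_case]}

    tm = config.transition_matrix
    n_total = 2 * config.n_subjects_per_group
    subjects: list[SubjectTimeSeries] = []
    rows = []
    sequences: dict[str, np.ndarray] = {}
    courses: dict[str, np.ndarray] = {}
    motions: dict[str, np.ndarray] = {}
    occ_rows, dwell_rows, ids = [], [], []

    for i in range(n_total):
        group = "case" if i < config.n_subjects_per_group else "control"
        sid = f"sub-{i + 1:03d}"
        labels = generate_state_sequence(tm, config.n_timepoints, rng)
        z = rng.normal(size=(config.n_sources, config.n_timepoints))
        src = np.empty_like(z)
        for s in range(1, config.n_states + 1):
            idx = labels == s
            if idx.any():
                src[:, idx] = chols[group][s - 1] @ z[:, idx]
        data = maps.T @ src
        if config.noise_sd > 0:
            data = data + config.noise_sd * rng.normal(size=data.shape)
        subjects.append(SubjectTimeSeries(data=data, tr_seconds=config.tr_seconds, subject_id=sid))
        sequences[sid] = labels
        courses[sid] = src
        motions[sid] = _motion_trace(config.n_timepoints, config.motion_spike_rate, rng)
        occ, dwell = _occupancy_and_dwell(labels, config.n_states)
        occ_rows.append(occ)
        dwell_rows.append(dwell)
        ids.append(sid)
        rows.append({
            "subject_id": sid,
            "group": group,
            "age": float(np.clip(rng.normal(7.0, 0.45), 6.0, 8.5)),
            "sex": int(rng.random() < 0.45),
            "deprivation_decile": int(rng.integers(1, 11)),
        })

    state_cols = [f"state_{s}" for s in range(1, config.n_states + 1)]
    truth = GroundTruth(
        source_maps=maps,
        state_covariances=covs_control,
        state_covariances_case=covs_case,
        state_sequences=sequences,
        source_timecourses=courses,
        true_occupancy=pd.DataFrame(occ_rows, index=ids, columns=state_cols),
        true_mean_dwell=pd.DataFrame(dwell_rows, index=ids, columns=state_cols),
        motion_traces=motions,
    )
    table = pd.DataFrame(rows)
    return Cohort(subjects=subjects, table=table, truth=truth, config=config)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write a cohort to disk as plain text.

    Layout: per-subject ``<id>_bold.tsv`` (voxels x time, no header),
    ``<id>_motion.par`` (6 whitespace-delimited columns: rotations in radians
    then translations in mm, one row per volume), ``cohort.tsv``, and a
    ``ground_truth/`` directory (JSON scalars + TSV matrices).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for subj in cohort.subjects:
        np.savetxt(outdir / f"{subj.subject_id}_bold.tsv", subj.data, delimiter="\t")
        np.savetxt(outdir / f"{subj.subject_id}_motion.par",
                   cohort.truth.motion_traces[subj.subject_id].T, fmt="%.8f")
    cohort.table.to_csv(outdir / "cohort.tsv", sep="\t", index=False)

    gt = outdir / "ground_truth"
    gt.mkdir(exist_ok=True)
    np.savetxt(gt / "source_maps.tsv", cohort.truth.source_maps, delimiter="\t")
    for s, c in enumerate(cohort.truth.state_covariances, start=1):
        np.savetxt(gt / f"state_{s}_cov.tsv", c, delimiter="\t")
    cohort.truth.true_occupancy.to_csv(gt / "true_occupancy.tsv", sep="\t")
    cohort.truth.true_mean_dwell.to_csv(gt / "true_mean_dwell.tsv", sep="\t")
    seq = pd.DataFrame(cohort.truth.state_sequences)
    seq.to_csv(gt / "state_sequences.tsv", sep="\t", index=False)
    with open(gt / "config.json", "w") as fh:
        json.dump(asdict(cohort.config), fh, indent=2)
    return outdir
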