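"""Population state-space trajectories and their divergence between contexts.

Trial-averaged population activity for cued and self-paced presses is
projected onto a shared 3-PC basis (fit on the concatenation of the two
condition averages), the pointwise Euclidean distance between the two
trajectories quantifies divergence over time, and a trial-label permutation
null (default 100 shuffles, full pipeline re-run per shuffle) calibrates it.
A grand-average subtraction control shows when divergence is not explained
by a simple difference in mean population activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.decomposition import PCA

from .ensembles import PeriEventTensor

__all__ = [
    "TrajectoryResult",
    "fit_trajectories",
    "trajectory_distance",
    "shuffle_null",
    "mean_difference_control",
    "trajectory_analysis",
]


@dataclass
class TrajectoryResult:
    """3-PC condition trajectories, their distance and the permutation null."""

    basis: np.ndarray  # n_components x ROI loading vectors (orthonormal rows)
    trajectories: dict  # condition -> sample x n_components
    distance: np.ndarray  # per sample
    time: np.ndarray
    conditions: tuple[str, str]
    null_distances: Optional[np.ndarray] = None  # n_shuffles x sample
    null_mean: Optional[np.ndarray] = None
    null_sem: Optional[np.ndarray] = None
    mean_diff_control: Optional[np.ndarray] = None  # per sample, z-units

    def summary_frame(self):
        import pandas as pd

        d = dict(time_s=self.time, distance=self.distance)
        if self.null_mean is not None:
            d["null_mean"] = self.null_mean
            d["null_sem"] = self.null_sem
        if self.mean_diff_control is not None:
            d["control"] = self.mean_diff_control
        return pd.DataFrame(d)


def _condition_averages(tensor: PeriEventTensor, conditions, labels=None):
    """Valid-trial averages per condition; labels may override tensor.condition."""
    cond = tensor.condition if labels is None else np.asarray(labels)
    out = []
    for c in conditions:
        mask = tensor.valid & (cond == c)
        if not mask.any():
            raise ValueError(f"condition {c!r} has no valid trials")
        out.append(tensor.data[:, mask].mean(axis=1))
    return out  # each ROI x sample


def _fit_project(avg_a: np.ndarray, avg_b: np.ndarray, n_components: int,
                 basis: Optional[np.ndarray] = None):
    """Fit PCA on the time-concatenated condition averages and project both.

    Rows of the fit matrix are time samples, columns are ROIs; ROI-wise means
    over the concatenation are removed before fitting.  Returns
    (basis, traj_a, traj_b).
    """
    X = np.concatenate([avg_a.T, avg_b.T], axis=0)  # (2*samples) x ROI
    mean = X.mean(axis=0)
    Xc = X - mean
    if basis is None:
        if min(Xc.shape) < n_components:
            raise ValueError(f"rank {min(Xc.shape)} < {n_components} components")
        if not np.any(np.abs(Xc) > 1e-12):
            raise ValueError(f"data rank 0 < {n_components} components")
        pca = PCA(n_components=n_components, svd_solver="full")
        pca.fit(Xc)
        rank = int(np.sum(pca.singular_values_ > 1e-10 * pca.singular_values_[0]))
        if rank < n_components:
            raise ValueError(f"data rank {rank} < {n_components} components")
        basis = pca.components_
    traj_a = (avg_a.T - mean) @ basis.T
    traj_b = (avg_b.T - mean) @ basis.T
    return basis, traj_a, traj_b


def fit_trajectories(tensor: PeriEventTensor,
                     conditions: tuple[str, str] = ("cued", "self_paced"),
                     n_components: int = 3) -> TrajectoryResult:
    """Project both condition-averaged trajectories into a shared 3-PC space."""
    avg_a, avg_b = _condition_averages(tensor, conditions)
    basis, traj_a, traj_b = _fit_project(avg_a, avg_b, n_components)
    dist = trajectory_distance(traj_a, traj_b)
    return TrajectoryResult(basis=basis,
                            trajectories={conditions[0]: traj_a, conditions[1]: traj_b},
                            distance=dist, time=tensor.time, conditions=tuple(conditions))


def trajectory_distance(traj_a: np.ndarray, traj_b: np.ndarray) -> np.ndarray:
    """Pointwise Euclidean distance between two trajectories (per sample)."""
    traj_a, traj_b = np.asarray(traj_a, float), np.asarray(traj_b, float)
    if traj_a.shape != traj_b.shape:
        raise ValueError("trajectories must have the same shape")
    return np.linalg.norm(traj_a - traj_b, axis=1)


def shuffle_null(tensor: PeriEventTensor,
                 conditions: tuple[str, str] = ("cued", "self_paced"),
                 n_shuffles: int = 100, seed: int = 0, n_components: int = 3,
                 refit_basis: bool = True):
    """Trial-label permutation null for the trajectory distance.

    Per shuffle the condition labels of the valid trials are permuted and the
    full pipeline (condition averages, PCA fit unless ``refit_basis=False``,
    projection, distance) is recomputed.  Every permutation is kept, even one
    equal to the identity.  Returns ``(null_distances, null_mean, null_sem)``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    for c in conditions:
        if (tensor.valid & (tensor.condition == c)).sum() < 2:
            raise ValueError(f"condition {c!r} needs >= 2 valid trials")
    rng = np.random.default_rng(seed)
    fixed_basis = None
    if not refit_basis:
        avg_a, avg_b = _condition_averages(tensor, conditions)
        fixed_basis, _, _ = _fit_project(avg_a, avg_b, n_components)

    labels = tensor.condition.copy()
    valid_idx = np.flatnonzero(tensor.valid)
    null = np.empty((n_shuffles, tensor.time.size))
    for s in range(n_shuffles):
        perm = labels.copy()
        perm[valid_idx] = labels[valid_idx][rng.permutation(valid_idx.size)]
        avg_a, avg_b = _condition_averages(tensor, conditions, labels=perm)
        _, ta, tb = _fit_project(avg_a, avg_b, n_components, basis=fixed_basis)
        null[s] = trajectory_distance(ta, tb)
    return null, null.mean(axis=0), null.std(axis=0, ddof=1) / np.sqrt(n_shuffles)


def mean_difference_control(grand_avg_a: np.ndarray, grand_avg_b: np.ndarray) -> np.ndarray:
    """|difference| of the two grand-average population traces, per sample."""
    a, b = np.asarray(grand_avg_a, float), np.asarray(grand_avg_b, float)
    if a.shape != b.shape:
        raise ValueError("grand averages must have the same length")
    return np.abs(a - b)


def trajectory_analysis(tensor: PeriEventTensor,
                        conditions: tuple[str, str] = ("cued", "self_paced"),
                        n_shuffles: int = 100, seed: int = 0,
                        n_components: int = 3, refit_basis: bool = True) -> TrajectoryResult:
    """Trajectories + distance + permutation null + grand-average control."""
    res = fit_trajectories(tensor, conditions, n_components)
    null, nm, ns = shuffle_null(tensor, conditions, n_shuffles=n_shuffles, seed=seed,
                                n_components=n_components, refit_basis=refit_basis)
    avg_a, avg_b = _condition_averages(tensor, conditions)
    res.null_distances, res.null_mean, res.null_sem = null, nm, ns
    res.mean_diff_control = mean_difference_control(avg_a.mean(axis=0), avg_b.mean(axis=0))
    return res
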