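"""Time-resolved linear-SVM population decoding.

Activity is averaged into 66 ms bins (two 30 Hz frames) across a 4 s
peri-event window, classes are balanced by random sub-sampling, and at every
bin an independent linear SVM is trained on the per-trial population vector
with 10-fold cross-validation.  Chance level comes from re-running the whole
procedure with condition labels permuted across trials (one permutation per
repeat, shared across bins).  Three decoders mirror the study's contrasts:

* SVM1  — cued vs self-paced context at the press;
* SVM1b — the same contrast on latency-matched cued trials, scored in a
  cue-period window (−495..−165 ms) that precedes movement;
* SVM2  — press vs baseline (ITI epochs far from any event), pooled contexts.

Weight vectors per bin support comparing the context axis and the action
axis (cosine / rank correlation) and projecting population activity onto
either axis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .behavior import align_events_to_frames, build_trial_table
from .ensembles import PeriEventTensor, build_tensor

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedTensor",
    "DecoderResult",
    "bin_tensor",
    "balance_trials",
    "timebin_decode",
    "shuffled_null",
    "decode_context_at_press",
    "decode_context_cue_period",
    "decode_press_vs_baseline",
    "weight_axis_comparison",
    "project_onto_axis",
    "window_accuracy",
]


@dataclass
class BinnedTensor:
    """ROI x trial x bin activity (within-bin frame means) with trial labels."""

    data: np.ndarray
    bin_centers: np.ndarray  # s relative to the alignment event
    bin_width: float
    labels: np.ndarray  # per trial

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]

    def select_trials(self, idx) -> "BinnedTensor":
        return replace(self, data=self.data[:, idx], labels=self.labels[idx])


@dataclass
class DecoderResult:
    """Per-bin cross-validated accuracy, optional shuffled null, and weights."""

    accuracy: np.ndarray  # per bin, fold-averaged fraction correct
    bin_centers: np.ndarray
    weights: np.ndarray  # bin x ROI (from the fit on all balanced trials)
    intercept: np.ndarray  # per bin
    classes: tuple[str, str]
    n_trials_used: dict  # class -> count (balanced, so equal)
    config_echo: dict
    null_accuracy: Optional[np.ndarray] = None  # repeats x bin
    eval_window: Optional[tuple[float, float]] = None
    eval_accuracy: Optional[float] = None

    @property
    def peak_bin(self) -> int:
        return int(np.argmax(self.accuracy))

    @property
    def peak_time(self) -> float:
        return float(self.bin_centers[self.peak_bin])

    def summary_frame(self):
        import pandas as pd

        d = dict(time_s=self.bin_centers, accuracy=self.accuracy)
        if self.null_accuracy is not None:
            d["null_mean"] = self.null_accuracy.mean(axis=0)
            d["null_p2_5"] = np.percentile(self.null_accuracy, 2.5, axis=0)
            d["null_p97_5"] = np.percentile(self.null_accuracy, 97.5, axis=0)
        return pd.DataFrame(d)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("accuracy", data=self.accuracy)
            h5.create_dataset("bin_centers", data=self.bin_centers)
            h5.create_dataset("weights", data=self.weights)
            h5.create_dataset("intercept", data=self.intercept)
            if self.null_accuracy is not None:
                h5.create_dataset("null", data=self.null_accuracy)
            h5.attrs["classes"] = list(self.classes)


def bin_tensor(tensor: PeriEventTensor, frames_per_bin: int = 2,
               window: tuple[float, float] = (-2.0, 2.0),
               labels: Optional[np.ndarray] = None) -> BinnedTensor:
    """Average a peri-event tensor into non-overlapping frame bins.

    Only valid trials are carried over.  A leftover frame that does not fill
    a whole bin at the window end is dropped (logged).
    """
    sel = (tensor.time >= window[0] - 1e-9) & (tensor.time < window[1] - 1e-9)
    idx = np.flatnonzero(sel)
    n_bins = idx.size // frames_per_bin
    leftover = idx.size - n_bins * frames_per_bin
    if leftover:
        logger.info("dropping %d leftover frame(s) at the window end", leftover)
        idx = idx[:n_bins * frames_per_bin]
    if n_bins == 0:
        raise ValueError("window too short for a single bin")

    valid = tensor.valid
    data = tensor.data[:, valid][:, :, idx]
    R, T = data.shape[0], data.shape[1]
    binned = data.reshape(R, T, n_bins, frames_per_bin).mean(axis=3)
    centers = tensor.time[idx].reshape(n_bins, frames_per_bin).mean(axis=1)
    lab = tensor.condition[valid] if labels is None else np.asarray(labels)[valid]
    return BinnedTensor(data=binned, bin_centers=centers,
                        bin_width=frames_per_bin / tensor.sample_rate, labels=lab)


def balance_trials(labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Indices of a class-balanced subset: min-count per class, sampled
    without replacement."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"expected 2 classes, got {classes.size}")
    if (counts == 0).any():
        raise ValueError("a class has no trials")
    n = counts.min()
    rng = np.random.default_rng(seed)
    picks = [rng.choice(np.flatnonzero(labels == c), size=n, replace=False)
             for c in classes]
    return np.sort(np.concatenate(picks))


def _decode_bins(data: np.ndarray, y: np.ndarray, folds: int, C: float,
                 seed: int, fit_weights: bool):
    """Per-bin CV accuracy (and optional full-fit weights) for binned data."""
    R, T, B = data.shape
    classes, counts = np.unique(y, return_counts=True)
    folds_eff = min(folds, int(counts.min()))
    if folds_eff < folds:
        warnings.warn(f"reducing folds from {folds} to {folds_eff} (small class)")
    if folds_eff < 2:
        raise ValueError("need at least 2 trials per class for cross-validation")
    cv = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed % (2**32))
    splits = list(cv.split(np.zeros(T), y))
    acc = np.empty(B)
    weights = np.empty((B, R)) if fit_weights else None
    intercept = np.empty(B) if fit_weights else None
    for b in range(B):
        X = data[:, :, b].T  # trials x ROIs
        fold_acc = []
        for tr, te in splits:
            clf = SVC(kernel="linear", C=C)
            clf.fit(X[tr], y[tr])
            fold_acc.append(np.mean(clf.predict(X[te]) == y[te]))
        acc[b] = float(np.mean(fold_acc))
        if fit_weights:
            clf = SVC(kernel="linear", C=C)
            clf.fit(X, y)
            weights[b] = clf.coef_[0]
            intercept[b] = clf.intercept_[0]
    return acc, weights, intercept, folds_eff


def timebin_decode(binned: BinnedTensor, folds: int = 10, C: float = 1.0,
                   seed: int = 0) -> DecoderResult:
    """Independent linear SVM per time bin with stratified k-fold CV.

    Features at each bin are the per-trial population vectors of within-bin
    means (one feature per neuron).  ``weights`` come from a final fit on all
    trials at that bin.  Classes are expected to be balanced beforehand
    (see :func:`balance_trials`).
    """
    y = np.asarray(binned.labels)
    classes = tuple(np.unique(y))
    if len(classes) != 2:
        raise ValueError("timebin_decode needs exactly 2 classes")
    acc, w, b0, folds_eff = _decode_bins(binned.data, y, folds, C, seed, fit_weights=True)
    counts = {c: int((y == c).sum()) for c in classes}
    return DecoderResult(accuracy=acc, bin_centers=binned.bin_centers, weights=w,
                         intercept=b0, classes=classes, n_trials_used=counts,
                         config_echo=dict(folds=folds_eff, regularization=C, seed=seed))


def shuffled_null(binned: BinnedTensor, n_repeats: int = 100, folds: int = 10,
                  C: float = 1.0, seed: int = 0) -> np.ndarray:
    """Label-permutation null: repeats x bin accuracies.

    Each repeat permutes the trial labels once (the same permutation across
    all bins, preserving temporal structure) and reruns the full per-bin
    cross-validated decoding.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(binned.labels)
    null = np.empty((n_repeats, binned.n_bins))
    for r in range(n_repeats):
        perm = y[rng.permutation(y.size)]
        null[r], _, _, _ = _decode_bins(binned.data, perm, folds, C,
                                        seed=int(rng.integers(2**31)), fit_weights=False)
    return null


def _balanced_binned(tensor: PeriEventTensor, window, frames_per_bin, seed,
                     labels=None) -> BinnedTensor:
    binned = bin_tensor(tensor, frames_per_bin=frames_per_bin, window=window, labels=labels)
    keep = balance_trials(binned.labels, seed=seed)
    return binned.select_trials(keep)


def decode_context_at_press(tensor: PeriEventTensor, folds: int = 10,
                            n_null: int = 100, C: float = 1.0, seed: int = 0,
                            window: tuple[float, float] = (-2.0, 2.0),
                            frames_per_bin: int = 2) -> DecoderResult:
    """SVM1: cued vs self-paced context from press-aligned activity."""
    binned = _balanced_binned(tensor, window, frames_per_bin, seed)
    res = timebin_decode(binned, folds=folds, C=C, seed=seed)
    if n_null:
        res.null_accuracy = shuffled_null(binned, n_repeats=n_null, folds=folds,
                                          C=C, seed=seed + 1)
    return res


def decode_context_cue_period(tensor: PeriEventTensor,
                              rt_bin: tuple[float, float] = (0.334, 0.666),
                              eval_window: tuple[float, float] = (-0.495, -0.165),
                              folds: int = 10, n_null: int = 100, C: float = 1.0,
                              seed: int = 0,
                              window: tuple[float, float] = (-2.0, 2.0),
                              frames_per_bin: int = 2) -> DecoderResult:
    """SVM1b: context decoding on latency-matched trials, scored pre-press.

    Cued trials are restricted to reaction times inside ``rt_bin`` so that for
    every kept trial the cue (and its response) falls inside or before the
    evaluation window, which itself precedes movement.  The full time-resolved
    curve is computed; ``eval_accuracy`` is the mean accuracy over the bins
    whose centres lie in ``eval_window``.
    """
    cued_ok = (tensor.condition == "cued") & (tensor.reaction_time >= rt_bin[0]) \
        & (tensor.reaction_time <= rt_bin[1])
    keep = cued_ok | (tensor.condition == "self_paced")
    n_cued = int((cued_ok & tensor.valid).sum())
    if n_cued < 2:
        raise ValueError(f"only {n_cued} cued trials in RT bin {rt_bin}")
    sub = tensor.select_trials(keep)
    binned = _balanced_binned(sub, window, frames_per_bin, seed)
    res = timebin_decode(binned, folds=folds, C=C, seed=seed)
    if n_null:
        res.null_accuracy = shuffled_null(binned, n_repeats=n_null, folds=folds,
                                          C=C, seed=seed + 1)
    res.eval_window = eval_window
    res.eval_accuracy = window_accuracy(res, eval_window)
    return res


def baseline_anchor_times(event_log, traces, window: tuple[float, float] = (-2.0, 2.0),
                          min_gap: float = 2.0, n_anchors: Optional[int] = None,
                          seed: int = 0) -> np.ndarray:
    """Anchor times for baseline epochs: >= ``min_gap`` s from every press,
    cue or reward, with full windows inside the session and pairwise
    separation of at least one window half-width."""
    ev = event_log.events
    ev_times = ev.loc[ev["kind"].isin(["press", "cue_onset", "reward"]), "time"].to_numpy()
    t0, t1 = traces.frame_times[0], traces.frame_times[-1]
    grid = np.arange(t0 - window[0] + 0.5, t1 - window[1] - 0.5, 0.25)
    if grid.size == 0 or ev_times.size == 0:
        raise ValueError("session too short for baseline epochs")
    dist = np.min(np.abs(grid[:, None] - ev_times[None, :]), axis=1)
    cand = grid[dist >= min_gap]
    rng = np.random.default_rng(seed)
    cand = cand[rng.permutation(cand.size)]
    min_sep = (window[1] - window[0]) / 2.0
    chosen: list[float] = []
    for c in cand:
        if all(abs(c - x) >= min_sep for x in chosen):
            chosen.append(float(c))
            if n_anchors is not None and len(chosen) >= n_anchors:
                break
    if n_anchors is not None and len(chosen) < n_anchors:
        raise ValueError(f"only {len(chosen)} clean baseline epochs available, "
                         f"need {n_anchors}")
    return np.sort(np.asarray(chosen))


def decode_press_vs_baseline(traces, event_log, folds: int = 10, n_null: int = 100,
                             C: float = 1.0, seed: int = 0,
                             window: tuple[float, float] = (-2.0, 2.0),
                             frames_per_bin: int = 2,
                             artifact_z_threshold: float = 10.0,
                             min_gap: float = 2.0,
                             roi_mask: Optional[np.ndarray] = None) -> DecoderResult:
    """SVM2: press-aligned epochs (contexts pooled) vs quiet ITI baseline.

    Baseline epochs are sampled from inter-trial periods at least ``min_gap``
    seconds from any press, cue or reward, count-matched to the press trials
    and binned identically.
    """
    press = build_tensor(traces, event_log, alignment="press", window=window,
                         artifact_z_threshold=artifact_z_threshold)
    if roi_mask is not None:
        press = press.restrict(roi_mask)
    n_press = int(press.valid.sum())
    anchors = baseline_anchor_times(event_log, traces, window=window,
                                    min_gap=min_gap, n_anchors=None, seed=seed)
    if anchors.size < min(folds, 10):
        raise ValueError(f"insufficient clean ITI: {anchors.size} baseline epochs")

    rate = traces.frame_rate
    n0, n1 = int(round(window[0] * rate)), int(round(window[1] * rate))
    idx, _ = align_events_to_frames(anchors, traces.frame_times)
    z = traces.z if roi_mask is None else traces.z[_as_bool_mask(roi_mask, traces.z.shape[0])]
    base = np.stack([z[:, i + n0:i + n1 + 1] for i in idx], axis=1)

    data = np.concatenate([press.data[:, press.valid], base], axis=1)
    labels = np.array(["press"] * n_press + ["baseline"] * base.shape[1])
    pooled = PeriEventTensor(
        data=data, time=press.time, window=window, sample_rate=rate,
        alignment=np.full(labels.size, "press"), condition=labels,
        reaction_time=np.full(labels.size, np.nan),
        valid=np.ones(labels.size, bool), cell_type=press.cell_type,
        roi_index=press.roi_index)
    binned = _balanced_binned(pooled, window, frames_per_bin, seed)
    res = timebin_decode(binned, folds=folds, C=C, seed=seed)
    if n_null:
        res.null_accuracy = shuffled_null(binned, n_repeats=n_null, folds=folds,
                                          C=C, seed=seed + 1)
    return res


def _as_bool_mask(mask: np.ndarray, n: int) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        return mask
    m = np.zeros(n, bool)
    m[mask] = True
    return m


def window_accuracy(result: DecoderResult, window: tuple[float, float]) -> float:
    """Mean accuracy over the bins whose centres fall in [t0, t1]."""
    sel = (result.bin_centers >= window[0] - 1e-9) & (result.bin_centers <= window[1] + 1e-9)
    if not sel.any():
        raise ValueError("no bins inside the window")
    return float(result.accuracy[sel].mean())


def weight_axis_comparison(result_1: DecoderResult, result_2: DecoderResult,
                           bin_1: Optional[int] = None,
                           bin_2: Optional[int] = None) -> dict:
    """Compare two decoders' weight vectors (e.g. context axis vs action axis).

    Uses the unit-normalised weight vector at each decoder's selected bin
    (default: its peak-accuracy bin).  Returns the cosine similarity, the
    Spearman rank correlation of absolute weights, and an overlay table of
    both weight vectors sorted by the second decoder's |weight|.
    """
    from scipy.stats import spearmanr

    if result_1.weights.shape[1] != result_2.weights.shape[1]:
        raise ValueError("decoders were fit on different ROI sets")
    b1 = result_1.peak_bin if bin_1 is None else bin_1
    b2 = result_2.peak_bin if bin_2 is None else bin_2
    w1 = result_1.weights[b1]
    w2 = result_2.weights[b2]
    n1, n2 = np.linalg.norm(w1), np.linalg.norm(w2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-norm weight vector")
    w1, w2 = w1 / n1, w2 / n2
    rho, _ = spearmanr(np.abs(w1), np.abs(w2))

    import pandas as pd

    order = np.argsort(-np.abs(w2))
    table = pd.DataFrame(dict(roi=order, weight_2=w2[order], weight_1=w1[order]))
    return dict(cosine_similarity=float(w1 @ w2), rank_correlation=float(rho),
                overlay=table)


def project_onto_axis(binned: BinnedTensor, weights: np.ndarray) -> dict:
    """Project per-trial population activity onto a unit weight vector.

    Returns, per trial label, the (mean, sem) projection time course over
    trials of that label.
    """
    weights = np.asarray(weights, float)
    if weights.size != binned.n_rois:
        raise ValueError("weight length must equal the ROI count")
    norm = np.linalg.norm(weights)
    if norm == 0:
        raise ValueError("zero-norm weight vector")
    u = weights / norm
    proj = np.einsum("r,rtb->tb", u, binned.data)  # trial x bin
    out = {}
    for lab in np.unique(binned.labels):
        p = proj[binned.labels == lab]
        out[lab] = (p.mean(axis=0), p.std(axis=0, ddof=1) / np.sqrt(p.shape[0]))
    return out
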