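"""Peri-event tensors, trial averages, Ward ensemble clustering and window
quantifications.

Neural activity is segmented into −5..+5 s windows around cue onsets or
lever presses (30 Hz; trials with over-threshold artifacts or truncated
windows are marked invalid), trial-averaged, and clustered with Ward's
method on Euclidean distances between each neuron's cue-aligned −2..+2 s
average, cut at k = 3.  Cluster labels are then canonicalised by phenotype:
1 = action-timed (press-aligned peaks similar across contexts), 2 =
cue-locked (earliest, cue-dominated peak), 3 = post-action (the remainder).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy import stats

from .behavior import align_events_to_frames, build_trial_table

logger = logging.getLogger(__name__)

__all__ = [
    "PeriEventTensor",
    "ClusterResult",
    "build_tensor",
    "trial_average",
    "grand_average",
    "cluster_neurons",
    "canonicalize_labels",
    "peak_response",
    "window_mean",
    "group_compare",
]


@dataclass
class PeriEventTensor:
    """ROI x trial x sample block of z-scored activity around events.

    ``time`` holds the sample times relative to the alignment event; the
    sample count is round(span * rate) + 1 with the centre sample exactly at
    t = 0.  Invalid trials (artifacts, truncated windows) are kept in the
    array but excluded from every average.
    """

    data: np.ndarray  # ROI x trial x sample, z-units
    time: np.ndarray  # sample times, s relative to event
    window: tuple[float, float]
    sample_rate: float
    alignment: np.ndarray  # per trial: "cue_onset" | "press"
    condition: np.ndarray  # per trial: "cued" | "self_paced" (or custom labels)
    reaction_time: np.ndarray  # per trial, s (NaN if unknown)
    valid: np.ndarray  # per trial
    cell_type: np.ndarray  # per ROI
    roi_index: np.ndarray  # per ROI, indices into the TraceMatrix rows

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    def trial_mask(self, condition: Optional[str] = None,
                   alignment: Optional[str] = None) -> np.ndarray:
        mask = self.valid.copy()
        if condition is not None:
            mask &= self.condition == condition
        if alignment is not None:
            mask &= self.alignment == alignment
        return mask

    def restrict(self, roi_mask: np.ndarray) -> "PeriEventTensor":
        """ROI-subset view; every downstream operation accepts it unchanged."""
        roi_mask = np.asarray(roi_mask)
        if roi_mask.dtype != bool:
            m = np.zeros(self.n_rois, bool)
            m[roi_mask] = True
            roi_mask = m
        if not roi_mask.any():
            raise ValueError("empty ROI selection")
        return replace(self, data=self.data[roi_mask],
                       cell_type=self.cell_type[roi_mask],
                       roi_index=self.roi_index[roi_mask])

    def select_trials(self, trial_mask: np.ndarray) -> "PeriEventTensor":
        trial_mask = np.asarray(trial_mask, bool)
        if not trial_mask.any():
            raise ValueError("empty trial selection")
        return replace(self, data=self.data[:, trial_mask],
                       alignment=self.alignment[trial_mask],
                       condition=self.condition[trial_mask],
                       reaction_time=self.reaction_time[trial_mask],
                       valid=self.valid[trial_mask])

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("data", data=self.data)
            h5.create_dataset("time", data=self.time)
            h5.create_dataset("alignment", data=np.asarray(self.alignment, dtype="S16"))
            h5.create_dataset("condition", data=np.asarray(self.condition, dtype="S16"))
            h5.create_dataset("rt", data=self.reaction_time)
            h5.create_dataset("valid", data=self.valid)
            h5.create_dataset("cell_type", data=np.asarray(self.cell_type, dtype="S8"))
            h5.create_dataset("roi_index", data=self.roi_index)
            h5.attrs["window"] = self.window
            h5.attrs["sample_rate"] = self.sample_rate


@dataclass
class ClusterResult:
    """Ward clustering of trial-averaged responses, with canonical labels."""

    raw_label: np.ndarray  # per ROI, dendrogram cut labels 1..k
    canonical_label: Optional[np.ndarray]  # per ROI in {1, 2, 3}, after canonicalisation
    linkage: np.ndarray  # scipy linkage matrix
    templates: dict  # raw label -> mean windowed trace
    k: int

    def to_frame(self, cell_type: Optional[np.ndarray] = None) -> pd.DataFrame:
        d = dict(roi=np.arange(self.raw_label.size), raw_label=self.raw_label)
        if self.canonical_label is not None:
            d["canonical_label"] = self.canonical_label
        if cell_type is not None:
            d["cell_type"] = cell_type
        return pd.DataFrame(d)


def build_tensor(traces, event_log, alignment: str = "press",
                 window: tuple[float, float] = (-5.0, 5.0),
                 artifact_z_threshold: float = 10.0,
                 rewarded_only: bool = True) -> PeriEventTensor:
    """Segment z-scored traces into peri-event windows around one event type.

    ``alignment`` is ``"press"`` (threshold crossings; rewarded ones only by
    default) or ``"cue_onset"``.  A trial is invalid if its window is
    truncated by the session edges or contains any sample with
    |z| > ``artifact_z_threshold``.
    """
    if alignment not in ("press", "cue_onset"):
        raise ValueError("alignment must be 'press' or 'cue_onset'")
    table = build_trial_table(event_log)
    if alignment == "cue_onset":
        table = table[table["block_type"] == "cued"]
        event_times = table["cue_onset"].to_numpy()
    else:
        if rewarded_only:
            table = table[table["rewarded"]]
        event_times = table["press_time"].to_numpy()
    keep = np.isfinite(event_times)
    table = table[keep]
    event_times = event_times[keep]
    if event_times.size == 0:
        raise ValueError(f"no {alignment} events found")

    rate = traces.frame_rate
    n0, n1 = int(round(window[0] * rate)), int(round(window[1] * rate))
    n_samples = n1 - n0 + 1
    idx, in_span = align_events_to_frames(event_times, traces.frame_times)

    n_frames = traces.z.shape[1]
    data = np.zeros((traces.n_rois, event_times.size, n_samples))
    valid = np.zeros(event_times.size, bool)
    for j, (i0, ok) in enumerate(zip(idx, in_span)):
        if not ok or i0 + n0 < 0 or i0 + n1 >= n_frames:
            continue
        sl = traces.z[:, i0 + n0:i0 + n1 + 1]
        data[:, j] = sl
        valid[j] = np.abs(sl).max() <= artifact_z_threshold
    if not valid.any():
        raise ValueError("no valid trials after edge/artifact exclusion")

    return PeriEventTensor(
        data=data,
        time=np.arange(n0, n1 + 1) / rate,
        window=window,
        sample_rate=rate,
        alignment=np.full(event_times.size, alignment),
        condition=table["block_type"].to_numpy(),
        reaction_time=table["reaction_time"].to_numpy(),
        valid=valid,
        cell_type=np.asarray(traces.cell_type),
        roi_index=np.arange(traces.n_rois),
    )


def trial_average(tensor: PeriEventTensor, condition: Optional[str] = None,
                  alignment: Optional[str] = None) -> np.ndarray:
    """Per-ROI mean over valid (optionally filtered) trials: ROI x sample."""
    mask = tensor.trial_mask(condition, alignment)
    if not mask.any():
        raise ValueError("no valid trials match the filter")
    return tensor.data[:, mask].mean(axis=1)


def grand_average(tensor: PeriEventTensor, condition: Optional[str] = None) -> np.ndarray:
    """Population grand average: mean over ROIs of the trial average."""
    return trial_average(tensor, condition=condition).mean(axis=0)


def _window_slice(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Half-open [t0, t1) sample mask; the t = 0 sample belongs to the post side."""
    t0, t1 = window
    return (time >= t0 - 1e-9) & (time < t1 - 1e-9)


def cluster_neurons(avg: np.ndarray, time: np.ndarray,
                    window: tuple[float, float] = (-2.0, 2.0), k: int = 3) -> ClusterResult:
    """Ward / Euclidean agglomerative clustering of trial-averaged traces.

    ``avg`` is an ROI x sample trial average (canonically cue-aligned, cued
    trials); each neuron's feature vector is its trace within ``window``
    and the dendrogram is cut at exactly ``k`` clusters.
    """
    avg = np.asarray(avg, float)
    if avg.shape[0] < k:
        raise ValueError(f"need at least k={k} neurons, got {avg.shape[0]}")
    sel = _window_slice(np.asarray(time), window)
    feats = avg[:, sel]
    Z = linkage(feats, method="ward", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    templates = {lab: feats[raw == lab].mean(axis=0) for lab in np.unique(raw)}
    return ClusterResult(raw_label=raw, canonical_label=None, linkage=Z,
                         templates=templates, k=k)


def canonicalize_labels(result: ClusterResult,
                        avg_cue_aligned: np.ndarray,
                        avg_press_cued: np.ndarray,
                        avg_press_self: np.ndarray,
                        time: np.ndarray,
                        cue_peak_window: tuple[float, float] = (0.0, 2.0),
                        press_peak_window: tuple[float, float] = (-0.5, 1.5)) -> ClusterResult:
    """Map raw dendrogram labels onto phenotype labels 1/2/3.

    Label 2 goes to the cluster with the largest cue-aligned vs press-aligned
    peak ratio (ties broken by earliest cue-aligned peak); of the remaining
    clusters, label 1 goes to the one whose press-aligned templates peak at
    the press (with cross-context peak similarity breaking latency ties),
    and label 3 to the rest.  Remaining ties fall back to cluster size
    (largest first) and are logged.
    """
    time = np.asarray(time)
    labels = np.unique(result.raw_label)
    if labels.size != result.k:
        warnings.warn("degenerate clustering: fewer distinct labels than k")
    cue_sel = _window_slice(time, cue_peak_window)
    press_sel = _window_slice(time, press_peak_window)

    stats_by_label = {}
    for lab in labels:
        m = result.raw_label == lab
        cue_t = avg_cue_aligned[m].mean(axis=0)
        press_c = avg_press_cued[m].mean(axis=0)
        press_s = avg_press_self[m].mean(axis=0)
        cue_peak = cue_t[cue_sel].max()
        peak_time = time[cue_sel][np.argmax(cue_t[cue_sel])]
        pc, ps = press_c[press_sel].max(), press_s[press_sel].max()
        denom = max(abs(pc), 1e-12)
        press_peak_time = 0.5 * (time[press_sel][np.argmax(press_c[press_sel])]
                                 + time[press_sel][np.argmax(press_s[press_sel])])
        stats_by_label[lab] = dict(size=int(m.sum()),
                                   cue_ratio=cue_peak / denom,
                                   cue_peak_time=peak_time,
                                   press_peak_time=press_peak_time,
                                   press_peak_gap=abs(pc - ps) / max(abs(pc) + abs(ps), 1e-12))

    # label 2: cue-dominated, earliest peak; size as last-resort tie-break
    order2 = sorted(labels, key=lambda L: (-stats_by_label[L]["cue_ratio"],
                                           stats_by_label[L]["cue_peak_time"],
                                           -stats_by_label[L]["size"]))
    lab2 = order2[0]
    rest = [L for L in labels if L != lab2]
    # label 1: action-timed — press-aligned peak at the press in both
    # contexts; cross-context peak similarity breaks latency ties (the gap
    # alone is noise-level whenever context gains are sign-balanced)
    order1 = sorted(rest, key=lambda L: (round(abs(stats_by_label[L]["press_peak_time"]), 1),
                                         stats_by_label[L]["press_peak_gap"],
                                         -stats_by_label[L]["size"]))
    lab1 = order1[0]
    lab3 = [L for L in rest if L != lab1][0] if len(rest) > 1 else lab1
    if len({lab1, lab2, lab3}) < min(3, labels.size):
        logger.info("canonicalisation tie broken by cluster size")

    mapping = {lab1: 1, lab2: 2, lab3: 3}
    canonical = np.array([mapping[L] for L in result.raw_label])
    return replace(result, canonical_label=canonical)


def peak_response(avg: np.ndarray, time: np.ndarray,
                  window: tuple[float, float]) -> np.ndarray:
    """Per-ROI maximum of the trial-averaged trace within [t0, t1)."""
    sel = _window_slice(np.asarray(time), window)
    if not sel.any():
        raise ValueError("peak window does not overlap the tensor window")
    return np.asarray(avg)[:, sel].max(axis=1)


def window_mean(avg: np.ndarray, time: np.ndarray,
                window: tuple[float, float]) -> np.ndarray:
    """Per-ROI time-mean of the trial-averaged trace within [t0, t1)."""
    sel = _window_slice(np.asarray(time), window)
    if not sel.any():
        raise ValueError("window does not overlap the tensor span")
    return np.asarray(avg)[:, sel].mean(axis=1)


def group_compare(*groups, paired: bool = False, parametric: bool = True) -> dict:
    """Two-group or multi-group comparison with the study's test battery.

    Two groups: unpaired Student's t (or Mann-Whitney U when
    ``parametric=False``); paired: paired t or Wilcoxon signed-rank (zsplit
    zero handling, so identical groups give p = 1).  Three or more groups:
    one-way ANOVA with Tukey-Kramer post-hoc comparisons.
    Returns ``{statistic, p_value, test_name[, posthoc]}``.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs >= 2 values")

    if len(groups) >= 3:
        stat, p = stats.f_oneway(*groups)
        posthoc = stats.tukey_hsd(*groups)
        return dict(statistic=float(stat), p_value=float(p),
                    test_name="one_way_anova", posthoc=posthoc)

    a, b = groups
    if paired:
        if a.size != b.size:
            raise ValueError("paired groups must have equal size")
        if parametric:
            stat, p = stats.ttest_rel(a, b)
            name = "paired_t"
        else:
            if np.allclose(a, b):
                return dict(statistic=0.0, p_value=1.0, test_name="wilcoxon_signed_rank")
            stat, p = stats.wilcoxon(a, b, zero_method="zsplit")
            name = "wilcoxon_signed_rank"
    else:
        if parametric:
            stat, p = stats.ttest_ind(a, b)
            name = "students_t"
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            name = "mann_whitney_u"
    return dict(statistic=float(stat), p_value=float(p), test_name=name)
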