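"""Raw fluorescence -> session-wide z-scored ΔF/F.

The chain, applied per ROI:

1. neuropil correction: ``F - r * F_neu`` with r = 0.7;
2. baseline: Gaussian smoothing followed by a 50th-percentile filter in
   non-overlapping 60 s windows, expanded to full length;
3. ΔF/F = 100 * (F - baseline) / baseline (percent); ROIs whose baseline
   dips to zero or below are excluded;
4. z-score with the session-wide mean and SD.

The whole chain is scale-covariant: multiplying raw and neuropil traces by
any positive constant leaves the z-scored output unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "PreprocessConfig",
    "TraceMatrix",
    "neuropil_correct",
    "estimate_baseline",
    "compute_dff",
    "zscore_session",
    "preprocess_session",
]

EXCLUSION_NONE = "none"
EXCLUSION_NEGATIVE_BASELINE = "negative_baseline"
EXCLUSION_ZERO_VARIANCE = "zero_variance"


@dataclass
class PreprocessConfig:
    """Parameters of the ΔF/F chain.

    ``smoothing_sigma`` (s) is the Gaussian width applied before the
    percentile filter.  It should suppress frame noise without smearing
    transients across most of the inter-event interval: once smoothed
    responses occupy over half of a baseline window the median starts
    tracking them, which turns event-rate or amplitude differences between
    task blocks into block-wide baseline (hence ΔF/F) offsets.  0.5 s keeps
    the smeared duty cycle below that breakdown at typical press rates.  ``baseline_mode`` selects how per-window
    percentiles are expanded to a full-length baseline: ``"interp"`` (linear
    between window centres, constant at the ends — the default, avoiding
    step artifacts) or ``"step"`` (piecewise constant).
    """

    neuropil_coefficient: float = 0.7
    baseline_window: float = 60.0
    baseline_percentile: float = 50.0
    smoothing_sigma: float = 0.5
    artifact_z_threshold: float = 10.0
    baseline_mode: str = "interp"

    def __post_init__(self) -> None:
        if not 0.0 <= self.neuropil_coefficient < 1.0:
            raise ValueError("neuropil_coefficient must be in [0, 1)")
        if self.baseline_window <= 0:
            raise ValueError("baseline_window must be positive")
        if not 0.0 < self.baseline_percentile < 100.0:
            raise ValueError("baseline_percentile must be in (0, 100)")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if self.baseline_mode not in ("interp", "step"):
            raise ValueError("baseline_mode must be 'interp' or 'step'")


@dataclass
class TraceMatrix:
    """Session-wide z-scored (and percent ΔF/F) traces for the kept ROIs."""

    z: np.ndarray  # kept ROI x frame, z-units
    dff: np.ndarray  # kept ROI x frame, percent
    kept_rois: np.ndarray  # indices into the source recording
    exclusion_report: np.ndarray  # per source ROI, one of the EXCLUSION_* strings
    frame_rate: float
    frame_times: np.ndarray
    cell_type: np.ndarray  # per kept ROI

    @property
    def n_rois(self) -> int:
        return self.z.shape[0]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("z", data=self.z)
            h5.create_dataset("dff", data=self.dff)
            h5.create_dataset("kept_rois", data=self.kept_rois)
            h5.create_dataset("exclusion_report",
                              data=np.asarray(self.exclusion_report, dtype="S24"))
            h5.create_dataset("frame_times", data=self.frame_times)
            h5.create_dataset("cell_type", data=np.asarray(self.cell_type, dtype="S8"))
            h5.attrs["frame_rate"] = self.frame_rate

    @classmethod
    def from_hdf5(cls, path) -> "TraceMatrix":
        import h5py

        with h5py.File(path, "r") as h5:
            return cls(z=h5["z"][()], dff=h5["dff"][()], kept_rois=h5["kept_rois"][()],
                       exclusion_report=h5["exclusion_report"][()].astype(str),
                       frame_rate=float(h5.attrs["frame_rate"]),
                       frame_times=h5["frame_times"][()],
                       cell_type=h5["cell_type"][()].astype(str))


def neuropil_correct(f: np.ndarray, f_neu: np.ndarray, r: float = 0.7) -> np.ndarray:
    """Subtract ``r`` times the neuropil signal from the raw trace."""
    f = np.asarray(f, float)
    f_neu = np.asarray(f_neu, float)
    if f.shape != f_neu.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {f_neu.shape}")
    return f - r * f_neu


def estimate_baseline(trace: np.ndarray, frame_rate: float,
                      config: PreprocessConfig | None = None) -> np.ndarray:
    """Smoothed, windowed-percentile baseline of a single trace.

    Gaussian-smooths the trace (sigma in seconds), takes the configured
    percentile within non-overlapping ``baseline_window``-second windows (a
    final partial window gets its own percentile), and expands per-window
    values back to full length by linear interpolation between window
    centres (or stepwise, per ``baseline_mode``).
    """
    config = config or PreprocessConfig()
    trace = np.asarray(trace, float)
    win = int(round(config.baseline_window * frame_rate))
    if win <= 0:
        raise ValueError("baseline window shorter than one frame")
    if config.smoothing_sigma > 0:
        smoothed = gaussian_filter1d(trace, sigma=config.smoothing_sigma * frame_rate,
                                     mode="reflect")
    else:
        smoothed = trace

    n = trace.size
    edges = list(range(0, n, win)) + [n]
    if len(edges) >= 3 and edges[-1] - edges[-2] < 1:
        edges.pop(-2)
    values, centers = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        values.append(np.percentile(smoothed[a:b], config.baseline_percentile))
        centers.append((a + b - 1) / 2.0)
    values = np.asarray(values)

    if config.baseline_mode == "step" or len(values) == 1:
        out = np.empty(n)
        for (a, b), v in zip(zip(edges[:-1], edges[1:]), values):
            out[a:b] = v
        return out
    return np.interp(np.arange(n), centers, values)


def compute_dff(trace: np.ndarray, baseline: np.ndarray) -> tuple[np.ndarray, bool]:
    """Percent ΔF/F and a flag for non-positive baseline values.

    Returns ``(dff, ok)``; when ``ok`` is False the baseline reached zero or
    below somewhere and the ROI should be excluded (the returned dff is
    computed with the offending samples masked to NaN).
    """
    trace = np.asarray(trace, float)
    baseline = np.asarray(baseline, float)
    if trace.shape != baseline.shape:
        raise ValueError("trace and baseline must have the same length")
    bad = baseline <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = 100.0 * (trace - baseline) / baseline
    if bad.any():
        dff[bad] = np.nan
        return dff, False
    return dff, True


def zscore_session(trace: np.ndarray) -> np.ndarray:
    """Session-wide z-score; raises on (numerically) zero variance."""
    trace = np.asarray(trace, float)
    sd = trace.std()
    if not np.isfinite(sd) or sd < 1e-12 * max(1.0, abs(trace.mean())):
        raise ValueError("zero-variance trace cannot be z-scored")
    return (trace - trace.mean()) / sd


def preprocess_session(rec, config: PreprocessConfig | None = None) -> TraceMatrix:
    """Apply the full chain to every ROI of a recording.

    ROIs with non-positive baselines or zero residual variance are dropped;
    ``exclusion_report`` records the reason per source ROI and ``kept_rois``
    maps rows of the output back to the recording.
    """
    config = config or PreprocessConfig()
    n = rec.n_rois
    report = np.array([EXCLUSION_NONE] * n, dtype=object)
    z_rows, dff_rows, kept = [], [], []
    for i in range(n):
        corrected = neuropil_correct(rec.raw_f[i], rec.neuropil_f[i],
                                     config.neuropil_coefficient)
        baseline = estimate_baseline(corrected, rec.frame_rate, config)
        dff, ok = compute_dff(corrected, baseline)
        if not ok:
            report[i] = EXCLUSION_NEGATIVE_BASELINE
            continue
        try:
            z = zscore_session(dff)
        except ValueError:
            report[i] = EXCLUSION_ZERO_VARIANCE
            continue
        kept.append(i)
        z_rows.append(z)
        dff_rows.append(dff)
    kept = np.asarray(kept, int)
    n_frames = rec.raw_f.shape[1]
    return TraceMatrix(
        z=np.vstack(z_rows) if z_rows else np.empty((0, n_frames)),
        dff=np.vstack(dff_rows) if dff_rows else np.empty((0, n_frames)),
        kept_rois=kept,
        exclusion_report=report.astype(str),
        frame_rate=rec.frame_rate,
        frame_times=rec.frame_times,
        cell_type=np.asarray(rec.cell_type)[kept] if kept.size else np.array([], dtype=str),
    )
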