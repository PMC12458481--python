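"""Synthetic head-fixed lever-press imaging sessions with planted ground truth.

A session alternates "cued" blocks (lever press within 2 s of an auditory go
cue is rewarded) and "self-paced" blocks (spontaneous presses rewarded after
an inter-trial interval), and each neuron's raw fluorescence is a sum of
calcium-transient kernels triggered by its response archetype:

* ``action``      — a transient at every lever press, in both contexts;
* ``cue``         — a transient at cue onsets only;
* ``post_action`` — a slow transient peaking ~1 s after reward delivery.

On top of the archetype responses the generator can plant context structure:
a multiplicative gain on responses in cued blocks (``context_gain``, applied
with a random ± exponent per neuron so the population mean stays balanced)
and a time-localised "divergence bump" added to press-aligned activity with
opposite sign in the two contexts.  Both are recorded in :class:`GroundTruth`
so downstream analyses can be validated against what was planted.

Raw traces emulate what a Suite2p-style extraction would hand over: a cell
signal contaminated by 0.7× the surrounding neuropil, with slow baseline
drift and white noise, alongside the neuropil trace itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

ARCHETYPES = ("action", "cue", "post_action")
NEUROPIL_CONTAMINATION = 0.7

__all__ = [
    "ARCHETYPES",
    "BehaviorConfig",
    "NeuralConfig",
    "EventLog",
    "BehaviorTruth",
    "SessionRecording",
    "GroundTruth",
    "generate_behavior",
    "generate_traces",
    "generate_session",
    "calcium_kernel",
    "kernel_peak_time",
]


# ---------------------------------------------------------------------------
# configs


def _check_range(name: str, rng_pair) -> tuple[float, float]:
    lo, hi = float(rng_pair[0]), float(rng_pair[1])
    if lo > hi:
        raise ValueError(f"{name}: low > high ({lo} > {hi})")
    if lo < 0:
        raise ValueError(f"{name}: negative bound")
    return lo, hi


@dataclass
class BehaviorConfig:
    """Task parameters for the alternating cued / self-paced block design.

    Defaults follow the behavioural regime of the study the generator
    emulates: three block pairs of ~30 rewards, 4–8 s cued ITI, 1.5–2.5 s
    pre-cue hold, a 2 s cue-response window and a 5 mm press threshold, with
    mean reaction times of 0.30 s (cued, truncated exponential) and 6.0 s
    (self-paced, exponential from trial start).
    """

    n_block_pairs: int = 3
    rewards_per_block: int = 30
    cued_iti_range: tuple[float, float] = (4.0, 8.0)
    self_iti_range: tuple[float, float] = (2.0, 3.0)
    cued_hold_range: tuple[float, float] = (1.5, 2.5)
    self_quiet_range: tuple[float, float] = (1.0, 2.0)
    cue_response_window: float = 2.0
    press_threshold_mm: float = 5.0
    cued_rt_mean: float = 0.30
    self_rt_mean: float = 6.0
    # mean number of unrewarded ITI presses per trial (Poisson); the default
    # of 1 puts the rewarded fraction near 0.5, the regime the task produces.
    unrewarded_press_rate: float = 1.0
    lever_sample_rate: float = 100.0
    lever_amplitude_mm: float = 8.0
    lever_push_duration: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_block_pairs < 1:
            raise ValueError("n_block_pairs must be >= 1")
        if self.rewards_per_block < 1:
            raise ValueError("rewards_per_block must be >= 1")
        for name in ("cued_iti_range", "self_iti_range", "cued_hold_range", "self_quiet_range"):
            setattr(self, name, _check_range(name, getattr(self, name)))
        for name in ("cue_response_window", "press_threshold_mm", "self_rt_mean",
                     "lever_sample_rate", "lever_amplitude_mm", "lever_push_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cued_rt_mean < 0:
            raise ValueError("cued_rt_mean must be >= 0")
        if self.unrewarded_press_rate < 0:
            raise ValueError("unrewarded_press_rate must be >= 0")
        if self.press_threshold_mm >= self.lever_amplitude_mm:
            raise ValueError("press threshold must lie below the push amplitude")


@dataclass
class NeuralConfig:
    """Parameters of the planted neural population.

    ``cluster_proportions`` orders the archetypes (action, cue, post_action).
    ``context_gain`` g plants amplitude differences between contexts: each
    action / post_action neuron's responses in cued blocks are scaled by
    g**s with s = ±1 equiprobable, so half the population is up- and half
    down-modulated (g = 1 disables the effect).  The divergence bump is a
    Gaussian of ``divergence_amplitude`` (ΔF/F fraction) at
    ``divergence_center`` s relative to each rewarded press, added with
    opposite sign in the two contexts (and a random ± per neuron), on a
    ``divergence_fraction`` subset of neurons.  ``context_cells_fraction``
    reserves a sub-population that carries only this bump and no archetype
    response, giving exactly disjoint context and action supports.
    """

    n_neurons: int = 100
    frame_rate: float = 30.0
    cluster_proportions: tuple[float, float, float] = (0.10, 0.65, 0.25)
    context_gain: float = 1.3
    d1_fraction: float = 0.42
    d2_fraction: float = 0.42
    d1_cue_boost: float = 1.8
    d2_post_boost: float = 1.5
    kernel_rise: float = 0.05
    kernel_decay: float = 0.5
    post_action_peak_delay: float = 1.0
    late_rise: float = 0.2
    late_decay: float = 0.8
    late_peak_delay: float = 1.5
    late_amplitude_fraction: float = 0.3
    amplitude_mean: float = 0.5
    amplitude_sd: float = 0.15
    noise_sd: float = 3.0
    baseline_drift_amplitude: float = 5.0
    neuropil_gain: float = 0.5
    divergence_amplitude: float = 0.0
    divergence_center: float = -0.5
    divergence_sigma: float = 0.15
    divergence_fraction: float = 0.5
    context_cells_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        p = np.asarray(self.cluster_proportions, float)
        if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("cluster_proportions must be 3 non-negative values summing to 1")
        if not (self.kernel_rise < self.kernel_decay):
            raise ValueError("kernel_rise must be < kernel_decay")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("d1_fraction", "d2_fraction", "divergence_fraction", "context_cells_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.d1_fraction + self.d2_fraction > 1.0 + 1e-9:
            raise ValueError("d1_fraction + d2_fraction must be <= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


# ---------------------------------------------------------------------------
# containers


@dataclass
class BehaviorTruth:
    """Ground-truth record of what the behaviour generator drew."""

    trials: pd.DataFrame  # one row per rewarded trial, incl. the drawn RT
    press_times: np.ndarray  # all presses (rewarded + unrewarded), sorted
    press_rewarded: np.ndarray  # bool per press


@dataclass
class EventLog:
    """Timestamped behavioural events plus the sampled lever trace."""

    events: pd.DataFrame  # columns: time, kind, block_type, block_index, trial_index
    lever_time: np.ndarray
    lever_position: np.ndarray
    lever_sample_rate: float
    press_threshold_mm: float = 5.0
    truth: Optional[BehaviorTruth] = None

    @property
    def duration(self) -> float:
        return float(self.events["time"].iloc[-1])

    def times(self, kind: str, block_type: Optional[str] = None) -> np.ndarray:
        ev = self.events
        sel = ev["kind"] == kind
        if block_type is not None:
            sel &= ev["block_type"] == block_type
        return ev.loc[sel, "time"].to_numpy()

    def to_csv(self, events_path, lever_path=None) -> None:
        self.events.to_csv(events_path, index=False)
        if lever_path is not None:
            pd.DataFrame({"time_s": self.lever_time,
                          "position_mm": self.lever_position}).to_csv(lever_path, index=False)

    @classmethod
    def from_csv(cls, events_path, lever_path, lever_sample_rate: float = 100.0,
                 press_threshold_mm: float = 5.0) -> "EventLog":
        events = pd.read_csv(events_path)
        lever = pd.read_csv(lever_path)
        return cls(events=events,
                   lever_time=lever["time_s"].to_numpy(),
                   lever_position=lever["position_mm"].to_numpy(),
                   lever_sample_rate=lever_sample_rate,
                   press_threshold_mm=press_threshold_mm)


@dataclass
class SessionRecording:
    """Raw per-ROI fluorescence and neuropil traces with cell-type labels."""

    frame_rate: float
    frame_times: np.ndarray
    raw_f: np.ndarray  # ROI x frame, a.u.
    neuropil_f: np.ndarray  # ROI x frame, a.u.
    cell_type: np.ndarray  # per-ROI label in {"D1", "D2", "unknown"}

    def __post_init__(self) -> None:
        if self.raw_f.shape != self.neuropil_f.shape:
            raise ValueError("raw_f and neuropil_f must have the same shape")
        if self.raw_f.shape[1] != self.frame_times.size:
            raise ValueError("frame_times length must match the frame axis")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_rois(self) -> int:
        return self.raw_f.shape[0]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("raw_f", data=self.raw_f)
            h5.create_dataset("neuropil_f", data=self.neuropil_f)
            h5.create_dataset("frame_times", data=self.frame_times)
            h5.create_dataset("cell_type", data=np.asarray(self.cell_type, dtype="S8"))
            h5.attrs["frame_rate"] = self.frame_rate

    @classmethod
    def from_hdf5(cls, path) -> "SessionRecording":
        import h5py

        with h5py.File(path, "r") as h5:
            return cls(frame_rate=float(h5.attrs["frame_rate"]),
                       frame_times=h5["frame_times"][()],
                       raw_f=h5["raw_f"][()],
                       neuropil_f=h5["neuropil_f"][()],
                       cell_type=h5["cell_type"][()].astype(str))


@dataclass
class GroundTruth:
    """Planted structure of a synthetic recording (the acceptance oracle)."""

    cluster_id: np.ndarray  # per-ROI archetype ("context" for context-only cells)
    context_gain: np.ndarray  # realized per-ROI multiplicative gain on cued responses
    divergence_window: Optional[tuple[float, float]]  # s rel. press, or None
    divergence_support: np.ndarray  # bool per ROI: carries the context bump
    cell_type: np.ndarray
    amplitude: np.ndarray  # per-ROI main transient amplitude (dF/F fraction)
    signal: Optional[np.ndarray] = None  # noiseless dF/F-fraction matrix, ROI x frame

    def to_json(self, path) -> None:
        payload = {
            "cluster_id": self.cluster_id.tolist(),
            "context_gain": self.context_gain.tolist(),
            "divergence_window": list(self.divergence_window) if self.divergence_window else None,
            "divergence_support": self.divergence_support.astype(int).tolist(),
            "cell_type": self.cell_type.tolist(),
            "amplitude": self.amplitude.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        win = tuple(d["divergence_window"]) if d["divergence_window"] else None
        return cls(cluster_id=np.array(d["cluster_id"]),
                   context_gain=np.array(d["context_gain"]),
                   divergence_window=win,
                   divergence_support=np.array(d["divergence_support"], bool),
                   cell_type=np.array(d["cell_type"]),
                   amplitude=np.array(d["amplitude"]))


# ---------------------------------------------------------------------------
# behaviour


def _truncated_exponential(rng: np.random.Generator, mean: float, upper: float,
                           size=None) -> np.ndarray:
    """Inverse-CDF draw from Exp(mean) truncated to [0, upper]."""
    if mean <= 0:
        return np.zeros(size if size is not None else ())
    u = rng.random(size)
    tail = np.exp(-upper / mean)
    return -mean * np.log1p(-u * (1.0 - tail))


def _lever_crossing_offset(cfg: BehaviorConfig) -> float:
    """Time from push onset to the upward threshold crossing of the half-sine."""
    phase = np.arcsin(cfg.press_threshold_mm / cfg.lever_amplitude_mm)
    return cfg.lever_push_duration * phase / np.pi


def generate_behavior(config: BehaviorConfig) -> EventLog:
    """Simulate the alternating-block task and return its event log.

    Blocks alternate cued -> self-paced, starting with a cued block.  Cued
    presses occur at cue onset plus a truncated-exponential reaction time;
    self-paced presses at trial start plus an exponential reaction time.
    Unrewarded presses are sprinkled into inter-trial intervals at
    ``unrewarded_press_rate`` per trial.  The lever trace places a shared
    half-sine push template so the position crosses the 5 mm threshold
    exactly at each press time.
    """
    rng = np.random.default_rng(config.seed)
    min_gap = config.lever_push_duration + 0.1

    rows: list[dict] = []
    truth_rows: list[dict] = []
    presses: list[tuple[float, bool]] = []  # (time, rewarded)

    def add(time, kind, block_type, block_index, trial_index=-1):
        rows.append(dict(time=float(time), kind=kind, block_type=block_type,
                         block_index=int(block_index), trial_index=int(trial_index)))

    t = 0.0
    trial_counter = 0
    for pair in range(config.n_block_pairs):
        for j, block_type in enumerate(("cued", "self_paced")):
            block_index = 2 * pair + j
            add(t, "block_start", block_type, block_index)
            last_press_end = t
            for _ in range(config.rewards_per_block):
                if block_type == "cued":
                    iti = rng.uniform(*config.cued_iti_range)
                    hold = rng.uniform(*config.cued_hold_range)
                    trial_start = t + iti
                    cue = trial_start + hold
                    rt = float(_truncated_exponential(rng, config.cued_rt_mean,
                                                      config.cue_response_window))
                    press = cue + rt
                    reference = cue
                else:
                    # the 1-2 s quiet requirement is honoured by keeping
                    # unrewarded presses out of the pre-press window
                    iti = rng.uniform(*config.self_iti_range)
                    rng.uniform(*config.self_quiet_range)  # stream parity with cued hold
                    trial_start = t + iti
                    rt = float(rng.exponential(config.self_rt_mean))
                    press = trial_start + rt
                    cue = None
                    reference = trial_start

                # unrewarded ITI presses, kept clear of the hold/quiet period
                n_extra = rng.poisson(config.unrewarded_press_rate)
                lo, hi = last_press_end + 0.3, trial_start - 0.2
                extra = np.sort(rng.uniform(lo, hi, size=n_extra)) if hi > lo and n_extra else []
                kept_extra = []
                prev = last_press_end - min_gap
                for te in extra:
                    if te - prev >= min_gap:
                        kept_extra.append(float(te))
                        prev = te

                add(trial_start, "trial_start", block_type, block_index, trial_counter)
                for te in kept_extra:
                    add(te, "press", block_type, block_index, trial_counter)
                    presses.append((te, False))
                if cue is not None:
                    add(cue, "cue_onset", block_type, block_index, trial_counter)
                add(press, "press", block_type, block_index, trial_counter)
                add(press, "reward", block_type, block_index, trial_counter)
                presses.append((press, True))

                truth_rows.append(dict(block_type=block_type, block_index=block_index,
                                       trial_index=trial_counter, trial_start=trial_start,
                                       cue_onset=cue if cue is not None else np.nan,
                                       press_time=press, reaction_time=rt, rewarded=True,
                                       n_presses=1 + len(kept_extra)))
                trial_counter += 1
                t = press
                last_press_end = press

    events = pd.DataFrame(rows).sort_values("time", kind="stable").reset_index(drop=True)

    # lever trace: shared half-sine template at every press
    press_times = np.array([p for p, _ in presses])
    rewarded = np.array([r for _, r in presses])
    order = np.argsort(press_times)
    press_times, rewarded = press_times[order], rewarded[order]

    duration = t + 3.0
    n_lever = int(np.ceil(duration * config.lever_sample_rate)) + 1
    lever_time = np.arange(n_lever) / config.lever_sample_rate
    lever = np.zeros(n_lever)
    offset = _lever_crossing_offset(config)
    for pt in press_times:
        onset = pt - offset
        i0 = max(0, int(np.ceil(onset * config.lever_sample_rate)))
        i1 = min(n_lever, int(np.floor((onset + config.lever_push_duration)
                                       * config.lever_sample_rate)) + 1)
        seg_t = lever_time[i0:i1] - onset
        push = config.lever_amplitude_mm * np.sin(np.pi * seg_t / config.lever_push_duration)
        lever[i0:i1] = np.maximum(lever[i0:i1], push)

    truth = BehaviorTruth(trials=pd.DataFrame(truth_rows),
                          press_times=press_times, press_rewarded=rewarded)
    return EventLog(events=events, lever_time=lever_time, lever_position=lever,
                    lever_sample_rate=config.lever_sample_rate,
                    press_threshold_mm=config.press_threshold_mm, truth=truth)


# ---------------------------------------------------------------------------
# traces


def calcium_kernel(frame_rate: float, rise: float, decay: float) -> np.ndarray:
    """Peak-normalised difference-of-exponentials transient on the frame grid."""
    t_max = decay * np.log(1e4)
    t = np.arange(0.0, t_max, 1.0 / frame_rate)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel (rise >= decay?)")
    return k / peak


def kernel_peak_time(rise: float, decay: float) -> float:
    """Analytic peak latency of the difference-of-exponentials kernel."""
    return float(np.log(decay / rise) / (1.0 / rise - 1.0 / decay))


def generate_traces(events: EventLog, config: NeuralConfig,
                    store_signal: bool = True) -> tuple[SessionRecording, GroundTruth]:
    """Render raw fluorescence + neuropil matrices from an event log.

    Each neuron's noiseless ΔF/F signal is a sum of archetype-triggered
    kernels (with context gains, D1 cue boosts, a late 1–2 s component
    boosted in D2 cells, and the optional ± context bump), carried on a
    per-ROI baseline with slow drift; the raw trace adds 0.7× neuropil
    contamination and white noise, Suite2p style.
    """
    if len(events.events) == 0:
        raise ValueError("empty EventLog")
    duration = events.duration + 5.0
    if duration <= 5.0:
        raise ValueError("EventLog spans no time")

    fps = config.frame_rate
    n_frames = int(np.ceil(duration * fps))
    frame_times = np.arange(n_frames) / fps
    n = config.n_neurons

    ss = np.random.SeedSequence(config.seed)
    rng_assign, rng_amp, rng_noise = [np.random.default_rng(s) for s in ss.spawn(3)]

    # --- population structure
    n_context = int(round(config.context_cells_fraction * n))
    perm = rng_assign.permutation(n)
    context_only = np.zeros(n, bool)
    context_only[perm[:n_context]] = True
    archetype = np.array(ARCHETYPES)[
        rng_assign.choice(3, size=n, p=np.asarray(config.cluster_proportions, float))]
    cluster_id = archetype.copy().astype(object)
    cluster_id[context_only] = "context"
    cluster_id = cluster_id.astype(str)

    u = rng_assign.random(n)
    cell_type = np.where(u < config.d1_fraction, "D1",
                         np.where(u < config.d1_fraction + config.d2_fraction, "D2", "unknown"))

    amplitude = rng_amp.lognormal(mean=np.log(config.amplitude_mean),
                                  sigma=config.amplitude_sd / config.amplitude_mean, size=n)
    gain_sign = rng_amp.choice([-1.0, 1.0], size=n)
    context_gain = np.where(np.isin(cluster_id, ("action", "post_action")),
                            config.context_gain ** gain_sign, 1.0)

    divergence_support = np.zeros(n, bool)
    if config.divergence_amplitude > 0:
        if context_only.any():
            divergence_support[:] = context_only
        else:
            k = int(round(config.divergence_fraction * n))
            divergence_support[rng_amp.permutation(n)[:k]] = True
    div_sign = rng_amp.choice([-1.0, 1.0], size=n)

    # --- event frame indices
    kernel = calcium_kernel(fps, config.kernel_rise, config.kernel_decay)
    late_kernel = calcium_kernel(fps, config.late_rise, config.late_decay)
    peak = kernel_peak_time(config.kernel_rise, config.kernel_decay)
    late_peak = kernel_peak_time(config.late_rise, config.late_decay)
    post_delay = max(0.0, config.post_action_peak_delay - peak)
    late_delay = max(0.0, config.late_peak_delay - late_peak)

    ev = events.events
    press_all = ev.loc[ev.kind == "press", ["time", "block_type"]]
    cue_times = events.times("cue_onset")
    reward = ev.loc[ev.kind == "reward", ["time", "block_type"]]
    rewarded_press = ev.loc[(ev.kind == "press"), :].merge(
        ev.loc[ev.kind == "reward", ["time"]], on="time")  # presses that triggered reward

    def impulses(times, weights) -> np.ndarray:
        out = np.zeros(n_frames)
        idx = np.round(np.asarray(times, float) * fps).astype(int)
        ok = (idx >= 0) & (idx < n_frames)
        np.add.at(out, idx[ok], np.asarray(weights, float)[ok])
        return out

    def cued_mask(df) -> np.ndarray:
        return (df["block_type"] == "cued").to_numpy()

    # divergence bump kernel, symmetric around its centre
    if config.divergence_amplitude > 0:
        half = int(np.ceil(4 * config.divergence_sigma * fps))
        bt = np.arange(-half, half + 1) / fps
        bump = np.exp(-0.5 * (bt / config.divergence_sigma) ** 2)
    else:
        bump = None

    signal = np.zeros((n, n_frames))
    for i in range(n):
        if not context_only[i]:
            a = amplitude[i]
            if cluster_id[i] == "action":
                w = np.where(cued_mask(press_all), context_gain[i], 1.0) * a
                main = np.convolve(impulses(press_all["time"], w), kernel)[:n_frames]
                late_trig, late_w = press_all["time"], w
            elif cluster_id[i] == "cue":
                boost = config.d1_cue_boost if cell_type[i] == "D1" else 1.0
                w = np.full(cue_times.size, a * boost)
                main = np.convolve(impulses(cue_times, w), kernel)[:n_frames]
                late_trig, late_w = cue_times, w
            else:  # post_action
                w = np.where(cued_mask(reward), context_gain[i], 1.0) * a
                main = np.convolve(impulses(reward["time"] + post_delay, w), kernel)[:n_frames]
                late_trig, late_w = reward["time"], w
            signal[i] = main
            late_amp = config.late_amplitude_fraction
            if late_amp > 0:
                if cell_type[i] == "D2":
                    late_amp *= config.d2_post_boost
                signal[i] += np.convolve(
                    impulses(np.asarray(late_trig) + late_delay, late_amp * np.asarray(late_w)),
                    late_kernel)[:n_frames]
        if divergence_support[i] and bump is not None:
            rp = rewarded_press
            sign = np.where(cued_mask(rp), 1.0, -1.0) * div_sign[i]
            imp = impulses(rp["time"] + config.divergence_center,
                           sign * config.divergence_amplitude)
            signal[i] += np.convolve(imp, bump, mode="full")[half:half + n_frames]

    # --- carrier, drift, neuropil, noise
    f0 = rng_amp.uniform(100.0, 200.0, size=n)
    npil_base = rng_amp.uniform(50.0, 100.0, size=n)
    drift_phase = rng_amp.uniform(0, 2 * np.pi, size=n)

    tt = frame_times
    drift = config.baseline_drift_amplitude * (
        np.sin(2 * np.pi * tt / 600.0 + drift_phase[:, None]) + tt / (tt[-1] or 1.0))

    shared = signal.mean(axis=0)
    if shared.size > 1:  # light smoothing of the shared neuropil signal
        w = np.hanning(int(fps) or 1)
        shared = np.convolve(shared, w / w.sum(), mode="same")
    neuropil_f = (npil_base[:, None] * (1.0 + config.neuropil_gain * shared[None, :])
                  + rng_noise.normal(0.0, config.noise_sd, size=(n, n_frames)))
    cell_f = (f0[:, None] * (1.0 + signal) + drift
              + rng_noise.normal(0.0, config.noise_sd, size=(n, n_frames)))
    raw_f = cell_f + NEUROPIL_CONTAMINATION * neuropil_f

    rec = SessionRecording(frame_rate=fps, frame_times=frame_times, raw_f=raw_f,
                           neuropil_f=neuropil_f, cell_type=cell_type)
    div_window = None
    if config.divergence_amplitude > 0:
        div_window = (config.divergence_center - 2 * config.divergence_sigma,
                      config.divergence_center + 2 * config.divergence_sigma)
    truth = GroundTruth(cluster_id=cluster_id, context_gain=context_gain,
                        divergence_window=div_window, divergence_support=divergence_support,
                        cell_type=cell_type.copy(), amplitude=amplitude,
                        signal=signal if store_signal else None)
    return rec, truth


def generate_session(behavior: Optional[BehaviorConfig] = None,
                     neural: Optional[NeuralConfig] = None,
                     store_signal: bool = True):
    """Convenience wrapper: behaviour + traces in one call."""
    behavior = behavior or BehaviorConfig()
    neural = neural or NeuralConfig()
    events = generate_behavior(behavior)
    rec, truth = generate_traces(events, neural, store_signal=store_signal)
    return events, rec, truth
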