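"""Behavioural quantifications and behaviour->imaging alignment.

Covers the session-level task metrics — per-trial reaction times, per-block
push/reward rates and rewarded fractions, lever-trajectory similarity across
contexts — plus press detection from the lever trace and the mapping of
event times onto imaging frames.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "detect_presses",
    "build_trial_table",
    "block_durations",
    "block_metrics",
    "extract_lever_segments",
    "trajectory_similarity",
    "align_events_to_frames",
]


def detect_presses(lever_time: np.ndarray, lever_position: np.ndarray,
                   threshold_mm: float = 5.0) -> np.ndarray:
    """Times of upward threshold crossings of the lever trace.

    A crossing is counted when the position moves from below to at-or-above
    the threshold; it is not re-counted until the lever has returned below
    threshold (debouncing).  Crossing times are linearly interpolated
    between the bracketing samples.
    """
    t = np.asarray(lever_time, float)
    x = np.asarray(lever_position, float)
    if t.size == 0:
        return np.array([])
    above = x >= threshold_mm
    rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    for i in rising:
        x0, x1 = x[i - 1], x[i]
        frac = (threshold_mm - x0) / (x1 - x0) if x1 != x0 else 0.0
        times.append(t[i - 1] + frac * (t[i] - t[i - 1]))
    return np.asarray(times)


def build_trial_table(events) -> pd.DataFrame:
    """Per-trial table with reaction times and reward flags.

    Reaction time is press minus cue onset in cued trials and press minus
    trial start in self-paced trials, using the press that triggered the
    trial's reward (or, for unrewarded trials, the first press after the
    reference event).  A trial whose only presses precede its reference
    event is flagged invalid.

    Accepts an :class:`~leverpop.synthetic.EventLog` or its events frame.
    """
    ev = events.events if hasattr(events, "events") else events
    rows = []
    for (block_index, trial_index), grp in ev[ev["trial_index"] >= 0].groupby(
            ["block_index", "trial_index"], sort=True):
        block_type = grp["block_type"].iloc[0]
        start = grp.loc[grp["kind"] == "trial_start", "time"]
        trial_start = float(start.iloc[0]) if len(start) else np.nan
        cues = grp.loc[grp["kind"] == "cue_onset", "time"]
        cue_onset = float(cues.iloc[0]) if len(cues) else np.nan
        presses = grp.loc[grp["kind"] == "press", "time"].to_numpy()
        rewards = grp.loc[grp["kind"] == "reward", "time"].to_numpy()

        reference = cue_onset if block_type == "cued" else trial_start
        rewarded = rewards.size > 0
        if rewarded:
            # the press that triggered the reward: last press at/before it
            before = presses[presses <= rewards[0] + 1e-9]
            press_time = float(before[-1]) if before.size else np.nan
        else:
            after = presses[presses >= reference]
            press_time = float(after[0]) if after.size else np.nan

        valid = True
        rt = np.nan
        if np.isfinite(press_time) and np.isfinite(reference):
            rt = press_time - reference
            if rt < 0:
                valid = False
                rt = np.nan
        rows.append(dict(block_type=block_type, block_index=int(block_index),
                         trial_index=int(trial_index), trial_start=trial_start,
                         cue_onset=cue_onset, press_time=press_time,
                         reaction_time=rt, rewarded=bool(rewarded),
                         n_presses=int(presses.size), valid=valid))
    return pd.DataFrame(rows)


def block_durations(events) -> pd.DataFrame:
    """Per-block start time, end time and duration (s) from an event log."""
    ev = events.events if hasattr(events, "events") else events
    starts = ev.loc[ev["kind"] == "block_start", ["time", "block_type", "block_index"]]
    starts = starts.sort_values("block_index").reset_index(drop=True)
    session_end = float(ev["time"].max())
    ends = list(starts["time"].iloc[1:]) + [session_end]
    return pd.DataFrame(dict(block_index=starts["block_index"],
                             block_type=starts["block_type"],
                             start=starts["time"].to_numpy(),
                             end=np.asarray(ends),
                             duration=np.asarray(ends) - starts["time"].to_numpy()))


def block_metrics(table: pd.DataFrame, durations: pd.DataFrame) -> pd.DataFrame:
    """Per-block push rate, reward rate (per min) and rewarded fraction.

    ``rewarded_fraction`` is rewarded presses over all presses and is
    reported as NaN (missing, not zero) for a block without presses.
    """
    if (durations["duration"] <= 0).any():
        raise ValueError("block durations must be positive")
    rows = []
    for _, blk in durations.iterrows():
        trials = table[table["block_index"] == blk["block_index"]]
        n_press = int(trials["n_presses"].sum())
        n_reward = int(trials["rewarded"].sum())
        minutes = blk["duration"] / 60.0
        rows.append(dict(block_index=int(blk["block_index"]), block_type=blk["block_type"],
                         n_presses=n_press, n_rewards=n_reward,
                         push_rate=n_press / minutes, reward_rate=n_reward / minutes,
                         rewarded_fraction=(n_reward / n_press) if n_press else np.nan))
    return pd.DataFrame(rows)


def extract_lever_segments(event_log, press_times: np.ndarray | None = None,
                           window: tuple[float, float] = (-0.5, 1.0)) -> np.ndarray:
    """Press-aligned lever-position segments (press x sample).

    Segments truncated by the edges of the lever trace are dropped.  By
    default segments are taken around the log's rewarded press events.
    """
    if press_times is None:
        ev = event_log.events
        rewarded = ev.loc[ev["kind"] == "reward", "time"].to_numpy()
        press_times = rewarded
    rate = event_log.lever_sample_rate
    n0, n1 = int(round(window[0] * rate)), int(round(window[1] * rate))
    segs = []
    for pt in np.asarray(press_times):
        c = int(round(pt * rate))
        if c + n0 < 0 or c + n1 >= event_log.lever_time.size:
            continue
        segs.append(event_log.lever_position[c + n0:c + n1 + 1])
    return np.asarray(segs)


def trajectory_similarity(segments: np.ndarray, context: np.ndarray) -> dict:
    """Pairwise Pearson correlations of press-aligned lever trajectories.

    Returns the full cross-correlation matrix, the mean trajectory per
    context and the correlation between the two context means.  Rows with
    zero variance (flat segments) get NaN correlations.
    """
    segments = np.asarray(segments, float)
    if segments.ndim != 2 or segments.shape[0] < 2:
        raise ValueError("need >= 2 equal-length segments")
    context = np.asarray(context)
    sd = segments.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mat = np.corrcoef(segments)
    mat[sd == 0, :] = np.nan
    mat[:, sd == 0] = np.nan

    labels = np.unique(context)
    means = {lab: segments[context == lab].mean(axis=0) for lab in labels}
    context_correlation = np.nan
    if len(labels) == 2:
        a, b = (means[lab] for lab in labels)
        if a.std() > 0 and b.std() > 0:
            context_correlation = float(np.corrcoef(a, b)[0, 1])
    return dict(cross_corr_matrix=mat, mean_trajectories=means,
                context_correlation=context_correlation)


def align_events_to_frames(event_times: np.ndarray,
                           frame_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map event times to the nearest *preceding* imaging frame.

    The causal convention (never the following frame) keeps peri-event
    windows reproducible.  Returns ``(indices, in_span)``; events outside
    the imaging span are flagged False and given index -1.
    """
    event_times = np.atleast_1d(np.asarray(event_times, float))
    frame_times = np.asarray(frame_times, float)
    idx = np.searchsorted(frame_times, event_times, side="right") - 1
    in_span = (event_times >= frame_times[0]) & (event_times <= frame_times[-1])
    idx[~in_span] = -1
    return idx, in_span
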