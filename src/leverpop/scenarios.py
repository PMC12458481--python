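"""Canonical simulation scenarios used for validation and calibration.

Each scenario builds a synthetic session tailored to one question about the
analysis chain:

* :func:`exchangeable_session` — a population whose press-aligned activity is
  statistically identical across contexts, so condition labels are
  exchangeable and permutation nulls should cover the observed statistics.
  Optionally a time-localised ± context bump is planted on top to test
  divergence detection.  Block timing is matched across contexts (the
  self-paced inter-trial interval is widened to span the cued ITI + hold
  gap) and unrewarded presses, cue cells and slow late components are off,
  because each of those is a *real* context difference a permutation test
  would rightly flag.
* :func:`recovery_session` — three planted archetypes at fixed proportions
  and moderate peak SNR, for clustering-recovery checks.  Cell-type boosts
  and context gains are off so that archetype shape is the only cluster
  structure.
* :func:`axis_dissociation_session` — an action-archetype population plus a
  disjoint set of pure context cells carrying a ± press-time bump, so the
  planted context axis and action axis have non-overlapping neuron supports.
* :func:`ablation_session` — all three archetypes with a context gain on
  action/post-action cells; removing the cue archetype should abolish
  cue-period (pre-movement) context decoding while press-time decoding
  survives.
"""

from __future__ import annotations

from .synthetic import BehaviorConfig, NeuralConfig, generate_session

__all__ = [
    "exchangeable_session",
    "recovery_session",
    "axis_dissociation_session",
    "ablation_session",
]


def _matched_behavior(seed: int, n_block_pairs: int, rewards_per_block: int) -> BehaviorConfig:
    # self-paced press-to-press gaps drawn to span the cued ITI+hold gap
    return BehaviorConfig(n_block_pairs=n_block_pairs,
                          rewards_per_block=rewards_per_block,
                          self_iti_range=(5.5, 10.5), self_rt_mean=0.3,
                          unrewarded_press_rate=0.0, seed=seed)


def exchangeable_session(seed: int, n_neurons: int = 30, n_block_pairs: int = 1,
                         rewards_per_block: int = 12,
                         divergence_amplitude: float = 0.0,
                         divergence_center: float = -0.5,
                         divergence_sigma: float = 0.15,
                         divergence_fraction: float = 0.5,
                         noise_sd: float = 5.0):
    bc = _matched_behavior(seed, n_block_pairs, rewards_per_block)
    nc = NeuralConfig(n_neurons=n_neurons, cluster_proportions=(1.0, 0.0, 0.0),
                      context_gain=1.0, d1_cue_boost=1.0, d2_post_boost=1.0,
                      late_amplitude_fraction=0.0, noise_sd=noise_sd,
                      divergence_amplitude=divergence_amplitude,
                      divergence_center=divergence_center,
                      divergence_sigma=divergence_sigma,
                      divergence_fraction=divergence_fraction,
                      seed=seed + 1)
    return generate_session(bc, nc)


def recovery_session(seed: int, n_neurons: int = 300,
                     proportions: tuple[float, float, float] = (0.10, 0.65, 0.25),
                     noise_sd: float = 25.0):
    """Archetype mixture at peak SNR ~3 (transient ~75 a.u. on this carrier).

    Amplitude heterogeneity is kept small (±10%) so that archetype shape is
    the only planted cluster structure: a broad amplitude spread is nuisance
    structure of its own that a Euclidean k = 3 cut can legitimately latch
    onto instead of the response timing.
    """
    bc = BehaviorConfig(n_block_pairs=2, rewards_per_block=20, seed=seed)
    nc = NeuralConfig(n_neurons=n_neurons, cluster_proportions=proportions,
                      context_gain=1.0, d1_cue_boost=1.0, d2_post_boost=1.0,
                      amplitude_sd=0.05, noise_sd=noise_sd, seed=seed + 1)
    return generate_session(bc, nc)


def axis_dissociation_session(seed: int, n_neurons: int = 120,
                              context_cells_fraction: float = 0.4,
                              divergence_amplitude: float = 0.35,
                              noise_sd: float = 5.0):
    bc = _matched_behavior(seed, n_block_pairs=2, rewards_per_block=20)
    nc = NeuralConfig(n_neurons=n_neurons, cluster_proportions=(0.7, 0.0, 0.3),
                      context_gain=1.0, d1_cue_boost=1.0, d2_post_boost=1.0,
                      late_amplitude_fraction=0.0, noise_sd=noise_sd,
                      context_cells_fraction=context_cells_fraction,
                      divergence_amplitude=divergence_amplitude,
                      divergence_center=0.0, divergence_sigma=0.12,
                      seed=seed + 1)
    return generate_session(bc, nc)


def ablation_session(seed: int, n_neurons: int = 80, context_gain: float = 1.6,
                     noise_sd: float = 5.0):
    # press-to-press gap distributions are matched across contexts (and
    # unrewarded presses disabled): gap asymmetries are genuine context
    # information — previous-trial reward responses intruding pre-press on
    # short self-paced gaps, and block-level baseline offsets from unequal
    # transient duty cycles — that no cue ensemble carries, so they would
    # mask what the ablation is meant to isolate.
    bc = _matched_behavior(seed, n_block_pairs=3, rewards_per_block=25)
    nc = NeuralConfig(n_neurons=n_neurons, cluster_proportions=(0.45, 0.35, 0.20),
                      context_gain=context_gain, late_amplitude_fraction=0.0,
                      noise_sd=noise_sd, seed=seed + 1)
    return generate_session(bc, nc)
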