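"""Synthetic sensor, hidden-state and behavioral data generation.

The generator emulates the statistical structure the downstream analyses
assume, so the whole pipeline is testable without any recording:

* 274 gradiometer channels sampled at 600 Hz;
* category-specific evoked spatial patterns during encoding, peaking near
  170 ms after stimulus onset, plus an earlier attention-related component
  (peak ~125 ms) whose amplitude is *reduced* for the stimulus that will
  later dominate maintenance (the "predominantly maintained", PM, item);
* a retention period whose sensor data is driven by a hidden four-state
  (F/B/C/N) first-order Markov process that re-evokes the category patterns,
  biased toward the trial's PM category;
* inter-trial intervals generated by a separate, mostly-N chain;
* behavioral hit probability increasing with the length of the longest
  replay epoch of the probed category.

All outputs are bit-reproducible given ``(params, seed)``: every source of
randomness draws from a substream derived from ``SimulationParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .containers import (
    BIN_MS,
    CATEGORIES,
    ITI_WINDOW_MS,
    NULL_LABEL,
    RETENTION_WINDOW_MS,
    STATES,
    SensorEpochs,
    ValidationError,
    time_axis,
)
from .design import TrialDesign

__all__ = [
    "SimulationParams",
    "HiddenStateSequence",
    "simulate_category_patterns",
    "assign_predominant",
    "simulate_encoding_epochs",
    "simulate_hidden_state_sequence",
    "simulate_delay_epochs",
    "simulate_behavior",
]

# Substream tags: one fixed integer per independent randomness source, so a
# single params.seed yields mutually independent but reproducible streams.
_S_PATTERNS = 1
_S_ENC_NOISE = 2
_S_STATES = 3
_S_DELAY_NOISE = 4
_S_PM = 5
_S_BEHAVIOR = 6
_S_ITI_STATES = 7
_S_ARTIFACTS = 8


def _default_hidden_transition() -> np.ndarray:
    """Retention-period generator over abstract states (S1, S2, S3, N).

    S1 is mapped per trial to the PM category.  Its high self-transition
    (0.972, mean run ~0.7 s) makes one stimulus dominate maintenance, with
    roughly half the trials containing a dominant-category run longer than
    1100 ms; the two non-dominant categories are entered rarely and replay
    in short bursts.  The stationary null-state occupancy (~22%) matches
    the fraction of retention bins the d* rule rejects, so the rejection
    threshold separates true replay from no-replay bins.  Off-diagonal
    category-to-category transitions are symmetric, so the generator itself
    carries no sequence direction.
    """
    return np.array(
        [
            [0.972, 0.002, 0.002, 0.024],
            [0.028, 0.900, 0.002, 0.070],
            [0.028, 0.002, 0.900, 0.070],
            [0.087, 0.004, 0.004, 0.905],
        ]
    )


def _default_iti_transition() -> np.ndarray:
    """ITI generator: fixation with no mnemonic content, hence mostly N."""
    return np.array(
        [
            [0.30, 0.02, 0.02, 0.66],
            [0.02, 0.30, 0.02, 0.66],
            [0.02, 0.02, 0.30, 0.66],
            [0.01, 0.01, 0.01, 0.97],
        ]
    )


@dataclass
class SimulationParams:
    """Parameters of the synthetic-data generator.

    Attributes
    ----------
    n_channels, fs:
        Sensor-array size and sampling rate (274 channels, 600 Hz).
    evoked_peak_ms, evoked_width_ms:
        Center and Gaussian SD of the category-selective evoked component.
    attention_peak_ms, attention_width_ms:
        Center/SD of the early attention-related component whose amplitude
        differs between PM and non-PM stimuli.
    snr_encoding, snr_replay:
        Peak evoked (resp. replay) amplitude in units of the per-sample
        channel noise SD.
    attention_gain_pm:
        Multiplier (< 1) on the early component of the to-be-PM stimulus:
        the dominant maintenance item is the *weakly attended* one.
    hidden_transition:
        Row-stochastic 4x4 generator over (S1, S2, S3, N); S1 maps to the
        PM category per trial (or to sequence position 1 under position
        coding).
    iti_transition:
        Generator for the inter-trial interval, mostly N by default.
    behavior_intercept, behavior_slope:
        Hit log-odds at zero replay and change in log-odds per ms of the
        longest probe-category replay epoch.
    """

    n_channels: int = 274
    fs: float = 600.0
    evoked_peak_ms: float = 170.0
    evoked_width_ms: float = 40.0
    attention_peak_ms: float = 125.0
    attention_width_ms: float = 25.0
    snr_encoding: float = 1.0
    snr_replay: float = 6.0
    attention_gain_pm: float = 0.6
    noise_sd_t: float = 1e-13
    max_pattern_cos: float = 0.3
    hidden_transition: np.ndarray = field(default_factory=_default_hidden_transition)
    iti_transition: np.ndarray = field(default_factory=_default_iti_transition)
    retention_init: np.ndarray = field(
        default_factory=lambda: np.array([0.60, 0.06, 0.06, 0.28])
    )
    iti_init: np.ndarray = field(
        default_factory=lambda: np.array([0.01, 0.01, 0.01, 0.97])
    )
    behavior_intercept: float = 1.1
    behavior_slope: float = 5e-4
    order_accuracy: float = 0.75
    rt_median_ms: float = 900.0
    rt_sigma: float = 0.3
    rt_replay_coef: float = -5e-5
    artifact_fraction: float = 0.0
    artifact_amplitude_t: float = 2e-11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if self.snr_encoding < 0 or self.snr_replay < 0:
            raise ValidationError("SNR must be nonnegative")
        for name in ("hidden_transition", "iti_transition"):
            m = np.asarray(getattr(self, name), dtype=float)
            _check_stochastic(m, name)
            setattr(self, name, m)

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, tag])

    def replace(self, **kwargs) -> "SimulationParams":
        return dc_replace(self, **kwargs)


def _check_stochastic(m: np.ndarray, name: str = "transition matrix") -> None:
    if m.shape != (4, 4):
        raise ValidationError(f"{name} must be 4x4, got {m.shape}")
    if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        raise ValidationError(f"{name} rows must be nonnegative and sum to 1")


@dataclass
class HiddenStateSequence:
    """Ground-truth state labels for one trial, one per 20 ms bin."""

    trial_id: int
    labels: tuple[str, ...]
    period: str = "retention"


def n_window_bins(window_ms: tuple[float, float] = RETENTION_WINDOW_MS) -> int:
    return int(round((window_ms[1] - window_ms[0]) / BIN_MS))


# ---------------------------------------------------------------------------
# spatial patterns
# ---------------------------------------------------------------------------

def simulate_category_patterns(params: SimulationParams) -> dict[str, np.ndarray]:
    """Three unit-norm channel-space patterns, one per stimulus category.

    Patterns are drawn isotropically and rejection-sampled until every
    pairwise |cosine| is at most ``params.max_pattern_cos``.  Deterministic
    given ``params.seed``.
    """
    if params.n_channels < 3:
        raise ValidationError("need at least 3 channels for 3 patterns")
    rng = params.rng(_S_PATTERNS)
    for _ in range(1000):
        vecs = rng.standard_normal((3, params.n_channels))
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        cos = vecs @ vecs.T
        off = np.abs(cos[np.triu_indices(3, k=1)])
        if np.all(off <= params.max_pattern_cos):
            return dict(zip(CATEGORIES, vecs))
    raise ValidationError(
        f"could not draw patterns with |cos| <= {params.max_pattern_cos}"
    )


def _attention_pattern(params: SimulationParams) -> np.ndarray:
    """Early-component topography (visual attention signal), unit norm.

    Fixed across subjects (it depends only on the channel count): the early
    attention response has a consistent sensor topography in a group, which
    is what makes a group-level PM/non-PM evoked contrast detectable.
    """
    rng = np.random.default_rng([1234, params.n_channels])
    v = rng.standard_normal(params.n_channels)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# PM assignment
# ---------------------------------------------------------------------------

def assign_predominant(
    design: list[TrialDesign], params: SimulationParams
) -> list[TrialDesign]:
    """Choose each trial's to-be-predominant stimulus uniformly over positions.

    The assignment is ground truth linking encoding (reduced early evoked
    amplitude), retention (replay bias) and behavior; it is deterministic in
    ``params.seed`` so every simulation stage agrees on it.
    """
    rng = params.rng(_S_PM)
    out = []
    for t in design:
        out.append(dc_replace(t, pm_position=int(rng.integers(1, 4))))
    return out


def _require_pm(design: list[TrialDesign]) -> None:
    if any(t.pm_position is None for t in design):
        raise ValidationError(
            "design has no PM assignment; call assign_predominant() first"
        )


# ---------------------------------------------------------------------------
# encoding epochs
# ---------------------------------------------------------------------------

def _gauss_kernel(t_ms: np.ndarray, peak: float, width: float) -> np.ndarray:
    """Gaussian evoked kernel, gated to zero before stimulus onset."""
    k = np.exp(-0.5 * ((t_ms - peak) / width) ** 2)
    return np.where(t_ms >= 0, k, 0.0)


def simulate_encoding_epochs(
    design: list[TrialDesign],
    params: SimulationParams,
    t_start_ms: float = -100.0,
    t_end_ms: float = 500.0,
) -> SensorEpochs:
    """One epoch per presented stimulus (three per trial), stimulus-locked.

    Signal model per epoch: ``category_pattern x evoked_kernel(t)`` scaled
    by ``snr_encoding * noise_sd_t``, plus a shared attention component at
    ``attention_peak_ms`` whose amplitude is multiplied by
    ``attention_gain_pm`` for the trial's PM stimulus, plus white Gaussian
    sensor noise.  The epoch includes the closing sample at ``t_end_ms`` so
    the final 20 ms decoding bin has its full complement of samples.
    """
    if not design:
        raise ValidationError("design must be nonempty")
    if params.attention_gain_pm != 1.0:
        _require_pm(design)
    n_samples = int(round((t_end_ms - t_start_ms) * params.fs / 1000.0)) + 1
    t = time_axis(t_start_ms, n_samples, params.fs)
    patterns = simulate_category_patterns(params)
    att = _attention_pattern(params)
    evoked_k = _gauss_kernel(t, params.evoked_peak_ms, params.evoked_width_ms)
    att_k = _gauss_kernel(t, params.attention_peak_ms, params.attention_width_ms)

    n_epochs = 3 * len(design)
    rng = params.rng(_S_ENC_NOISE)
    data = rng.standard_normal((n_epochs, params.n_channels, n_samples))
    data *= params.noise_sd_t

    amp = params.snr_encoding * params.noise_sd_t
    rows = []
    for i, trial in enumerate(design):
        for pos, (cat, persp) in enumerate(trial.sequence, start=1):
            e = 3 * i + (pos - 1)
            is_pm = trial.pm_position == pos
            gain = params.attention_gain_pm if is_pm else 1.0
            data[e] += amp * np.outer(patterns[cat], evoked_k)
            data[e] += amp * gain * np.outer(att, att_k)
            rows.append(
                dict(
                    trial_id=trial.trial_id,
                    run_id=trial.run_id,
                    position=pos,
                    category=cat,
                    perspective=persp,
                    is_pm=bool(is_pm),
                )
            )
    if params.artifact_fraction > 0:
        arng = params.rng(_S_ARTIFACTS)
        n_bad = int(round(params.artifact_fraction * n_epochs))
        bad = arng.choice(n_epochs, size=n_bad, replace=False)
        for e in bad:
            ch = int(arng.integers(params.n_channels))
            s = int(arng.integers(n_samples))
            data[e, ch, s] = params.artifact_amplitude_t
    events = pd.DataFrame(rows)
    return SensorEpochs(
        data=data, time_ms=t, fs=params.fs, alignment="stimulus_onset",
        events=events,
    )


# ---------------------------------------------------------------------------
# hidden states
# ---------------------------------------------------------------------------

def _sample_chains(
    transition: np.ndarray,
    init: np.ndarray,
    n_chains: int,
    n_steps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample ``n_chains`` independent Markov chains of ``n_steps`` states.

    Returns an integer array (n_chains, n_steps) of state indices 0..3.
    Vectorized over chains; the step loop is the only Python-level loop.
    """
    cum_t = np.cumsum(transition, axis=1)
    cum_i = np.cumsum(init)
    out = np.empty((n_chains, n_steps), dtype=np.int64)
    u = rng.random((n_chains, n_steps))
    out[:, 0] = np.searchsorted(cum_i, u[:, 0], side="right").clip(0, 3)
    for s in range(1, n_steps):
        out[:, s] = (
            (u[:, s : s + 1] >= cum_t[out[:, s - 1]]).sum(axis=1).clip(0, 3)
        )
    return out


def _state_map(trial: TrialDesign, position_coding: bool) -> list[str]:
    """Map abstract states (S1, S2, S3, N) to category labels for a trial."""
    if position_coding:
        cats = list(trial.categories)
    else:
        if trial.pm_position is None:
            raise ValidationError(
                "PM-biased generator needs assign_predominant() first"
            )
        pm = trial.pm_category
        others = [c for c in trial.categories if c != pm]
        cats = [pm] + others
    return cats + [NULL_LABEL]


def simulate_hidden_state_sequence(
    design: list[TrialDesign],
    params: SimulationParams,
    position_coding: bool = False,
    n_bins: int | None = None,
    period: str = "retention",
) -> list[HiddenStateSequence]:
    """Per trial, a first-order Markov chain over {F, B, C, N}.

    One label per 20 ms bin of the retention analysis window (150 bins by
    default).  The generator is defined over abstract states (S1, S2, S3, N);
    S1 maps to the trial's PM category (``position_coding=False``) or to
    sequence position 1 (``position_coding=True``), so a position-biased
    generator directly expresses forward/backward replay.
    """
    transition = (
        params.iti_transition if period == "iti" else params.hidden_transition
    )
    init = params.iti_init if period == "iti" else params.retention_init
    _check_stochastic(transition)
    if n_bins is None:
        n_bins = n_window_bins(
            ITI_WINDOW_MS if period == "iti" else RETENTION_WINDOW_MS
        )
    rng = params.rng(_S_ITI_STATES if period == "iti" else _S_STATES)
    idx = _sample_chains(transition, np.asarray(init, float), len(design), n_bins, rng)
    out = []
    for i, trial in enumerate(design):
        smap = _state_map(trial, position_coding)
        labels = tuple(smap[k] for k in idx[i])
        out.append(HiddenStateSequence(trial.trial_id, labels, period=period))
    return out


# ---------------------------------------------------------------------------
# delay epochs
# ---------------------------------------------------------------------------

def _states_to_epochs(
    design: list[TrialDesign],
    states: list[HiddenStateSequence],
    params: SimulationParams,
    window_ms: tuple[float, float],
    alignment: str,
    rng: np.random.Generator,
) -> SensorEpochs:
    if len(states) != len(design):
        raise ValidationError("states not aligned to design")
    fs = params.fs
    n_samples = int(round((window_ms[1] - window_ms[0]) * fs / 1000.0)) + 1
    t = time_axis(window_ms[0], n_samples, fs)
    patterns = simulate_category_patterns(params)
    data = rng.standard_normal((len(design), params.n_channels, n_samples))
    data *= params.noise_sd_t
    amp = params.snr_replay * params.noise_sd_t
    spb = int(round(BIN_MS * fs / 1000.0))  # samples per half-open bin
    for i, (trial, seq) in enumerate(zip(design, states)):
        if seq.trial_id != trial.trial_id:
            raise ValidationError("states not aligned to design (trial ids)")
        for b, lab in enumerate(seq.labels):
            if lab == NULL_LABEL:
                continue
            s0 = b * spb
            data[i, :, s0 : s0 + spb] += amp * patterns[lab][:, None]
    events = pd.DataFrame(
        {"trial_id": [tr.trial_id for tr in design],
         "run_id": [tr.run_id for tr in design]}
    )
    return SensorEpochs(
        data=data, time_ms=t, fs=fs, alignment=alignment, events=events
    )


def simulate_delay_epochs(
    design: list[TrialDesign],
    states: list[HiddenStateSequence],
    params: SimulationParams,
) -> tuple[SensorEpochs, SensorEpochs, list[HiddenStateSequence]]:
    """Retention-period epochs driven by ``states``, plus companion ITI epochs.

    Every 20 ms bin labeled F/B/C contains the matching category pattern at
    ``snr_replay``; N bins are noise only.  ITI epochs are generated from the
    ITI-specific chain (mostly N).  Returns ``(retention, iti, iti_states)``.
    """
    retention = _states_to_epochs(
        design, states, params, RETENTION_WINDOW_MS,
        "last_stimulus_offset", params.rng(_S_DELAY_NOISE),
    )
    iti_states = simulate_hidden_state_sequence(
        design, params, position_coding=True, period="iti"
    )
    rng2 = np.random.default_rng([params.seed, _S_DELAY_NOISE, 2])
    iti = _states_to_epochs(
        design, iti_states, params, ITI_WINDOW_MS,
        "first_stimulus_onset", rng2,
    )
    return retention, iti, iti_states


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def longest_run_ms(labels: tuple[str, ...] | list[str], category: str) -> float:
    """Length (ms) of the longest consecutive run of ``category`` in labels."""
    best = cur = 0
    for lab in labels:
        cur = cur + 1 if lab == category else 0
        best = max(best, cur)
    return best * BIN_MS


def simulate_behavior(
    design: list[TrialDesign],
    states: list[HiddenStateSequence],
    params: SimulationParams,
) -> list[TrialDesign]:
    """Fill behavioral responses from the hidden replay of the probe.

    Detail-test hits are Bernoulli with
    ``logit = behavior_intercept + behavior_slope * longest probe replay (ms)``;
    order responses have a replay-independent accuracy; RTs are lognormal
    with a (negative by default) replay-length coefficient on the log scale.
    """
    if len(states) != len(design):
        raise ValidationError("states not aligned to design")
    rng = params.rng(_S_BEHAVIOR)
    out = []
    for trial, seq in zip(design, states):
        if seq.trial_id != trial.trial_id:
            raise ValidationError("states not aligned to design (trial ids)")
        replay_ms = longest_run_ms(seq.labels, trial.probe_category)
        logit = params.behavior_intercept + params.behavior_slope * replay_ms
        p_hit = 1.0 / (1.0 + np.exp(-logit))
        hit = bool(rng.random() < p_hit)
        # response is the same/different judgment; a hit means it is correct
        detail_response = trial.probe_same if hit else (not trial.probe_same)
        order_ok = rng.random() < params.order_accuracy
        if order_ok:
            order_response = trial.probe_position
        else:
            others = [p for p in (1, 2, 3) if p != trial.probe_position]
            order_response = int(others[int(rng.integers(2))])
        log_rt = (
            np.log(params.rt_median_ms)
            + params.rt_replay_coef * replay_ms
            + params.rt_sigma * rng.standard_normal()
        )
        log_rt_o = (
            np.log(params.rt_median_ms) + params.rt_sigma * rng.standard_normal()
        )
        out.append(
            dc_replace(
                trial,
                detail_response=bool(detail_response),
                detail_rt=float(np.exp(log_rt)),
                order_response=order_response,
                order_rt=float(np.exp(log_rt_o)),
            )
        )
    return out
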