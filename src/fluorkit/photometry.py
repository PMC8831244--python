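"""Trial- and event-level fiber-photometry analysis.

Covers three in vivo paradigms for neuropeptide-sensor photometry:

* optogenetic stimulation trials — 100-ms binning, Savitzky–Golay
  smoothing, median-anchored linear detrend of the 130-s trial window,
  z-scoring against the 10-s pre-stimulus baseline, peak search during the
  laser-on period and exponential rise/decay fits;
* event-locked comparisons (e.g. tail lifting) — pre-event s.d.
  normalisation and pre vs event window means;
* sleep-state transitions — ΔF/F₀ range in a ±15 s window around scored
  hypnogram transitions, and per-state means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fitting import KineticsFit, fit_exp_association
from .traces import (DffTrace, FluorescenceTrace, bin_trace,
                     detrend_linear_median, savgol_smooth, zscore_baseline)

__all__ = [
    "StimTrain", "StimResponse", "Hypnogram", "TransitionDelta",
    "analyze_stim_trial", "event_locked_comparison",
    "state_transition_deltas", "state_mean_dff",
]

STATES = ("wake", "NREM", "REM")


@dataclass
class StimTrain:
    """Optogenetic pulse train: onset (s), frequency (Hz), pulse width (s),
    train duration (s).  Duty cycle frequency·pulse_width must be ≤ 1."""

    onset: float
    frequency: float
    pulse_width: float
    duration: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.frequency * self.pulse_width > 1.0 + 1e-12:
            raise ValueError("duty cycle frequency*pulse_width exceeds 1")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class StimResponse:
    peak_z: float
    rise_fit: KineticsFit
    decay_fit: KineticsFit
    excluded: bool
    z_trace: FluorescenceTrace = None


@dataclass
class Hypnogram:
    """Per-epoch vigilance states ('wake'/'NREM'/'REM'), default 1-s epochs.

    Epoch *k* covers [t0 + k·epoch_length, t0 + (k+1)·epoch_length)."""

    states: list
    epoch_length: float = 1.0
    t0: float = 0.0

    def __post_init__(self):
        if len(self.states) == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be > 0")
        bad = set(self.states) - set(STATES)
        if bad:
            raise ValueError(f"unknown vigilance states: {sorted(bad)}")

    def transition_times(self, from_state: str, to_state: str) -> np.ndarray:
        """Times of epoch boundaries at which from_state -> to_state."""
        s = np.asarray(self.states)
        idx = np.nonzero((s[:-1] == from_state) & (s[1:] == to_state))[0] + 1
        return self.t0 + idx * self.epoch_length

    def state_at(self, times: np.ndarray) -> np.ndarray:
        k = np.floor((np.asarray(times) - self.t0) / self.epoch_length)
        k = np.clip(k.astype(int), 0, len(self.states) - 1)
        return np.asarray(self.states)[k]


@dataclass
class TransitionDelta:
    transition_type: str
    time: float
    delta: float


def analyze_stim_trial(trace: FluorescenceTrace, stim: StimTrain,
                       window_pre: float = 30.0, window_post: float = 90.0,
                       bin_width: float = 0.1,
                       savgol_window: float = 4.0, savgol_order: int = 3,
                       baseline_window: float = 10.0,
                       rise_window: float = 10.0,
                       smooth_decay: bool = True,
                       exclude_below_r2: float = 0.5) -> StimResponse:
    """Full stimulation-trial pipeline on a raw photometry trace.

    Steps: extract [onset − window_pre, onset + window_post) → average in
    ``bin_width`` bins → Savitzky–Golay filter → median-anchored linear
    detrend (medians of the first/last 30 s of the trial window) → z-score
    against the ``baseline_window`` seconds before stimulus onset →
    peak_z = maximum during the laser-on period.  The rise is fitted on
    [onset, onset + rise_window] after a 4-s Savitzky–Golay pass, the decay
    on [offset, post-offset minimum] (smoothed by default).  Trials whose
    rise or decay fit fails or has r² below ``exclude_below_r2`` are
    flagged ``excluded``.
    """
    t_start = stim.onset - window_pre
    t_end = stim.onset + window_post
    if (t_start < trace.t0 - 1e-9
            or t_end > trace.t0 + trace.duration + 1e-9):
        raise ValueError("trial window not covered by trace")

    trial = trace.slice(t_start, t_end)
    trial = bin_trace(trial, bin_width)
    trial = savgol_smooth(trial, savgol_window, savgol_order)
    trial = detrend_linear_median(trial, anchor_width=30.0)
    try:
        z = zscore_baseline(trial, (stim.onset - baseline_window,
                                    stim.onset))
    except ValueError:
        # perfectly flat baseline: keep median subtraction, unit scale
        warnings.warn("zero baseline s.d.; trial z-scored with unit scale")
        idx = trial._window_indices(stim.onset - baseline_window, stim.onset)
        z = FluorescenceTrace(
            trial.values - np.median(trial.values[idx]),
            trial.sampling_rate, t0=trial.t0)

    times = z.times
    on = (times >= stim.onset - 1e-9) & (times <= stim.offset + 1e-9)
    peak_z = float(np.max(z.values[on]))

    rise_seg = z.slice(stim.onset, stim.onset + rise_window)
    rise_seg = savgol_smooth(rise_seg, savgol_window, savgol_order)
    rise_fit = fit_exp_association(rise_seg, None, direction="rise")

    post = z.slice(stim.offset, t_end)
    i_min = int(np.argmin(post.values))
    if i_min < 10:  # too few samples to the minimum; fit what is there
        i_min = min(len(post.values) - 1, 10)
    decay_seg = FluorescenceTrace(post.values[: i_min + 1],
                                  post.sampling_rate, t0=post.t0)
    if smooth_decay and decay_seg.duration > savgol_window:
        decay_seg = savgol_smooth(decay_seg, savgol_window, savgol_order)
    decay_fit = fit_exp_association(decay_seg, None, direction="decay")

    excluded = (not rise_fit.converged or not decay_fit.converged
                or rise_fit.r_squared < exclude_below_r2
                or decay_fit.r_squared < exclude_below_r2)
    return StimResponse(peak_z=peak_z, rise_fit=rise_fit,
                        decay_fit=decay_fit, excluded=excluded, z_trace=z)


def event_locked_comparison(dff: DffTrace, event_onset: float,
                            pre: float = 5.0, event_dur: float = 10.0):
    """Pre-event vs event-window comparison of a ΔF/F₀ trace.

    Returns ``(pre_mean, event_mean, normalized)`` where the means are over
    [onset − pre, onset) and [onset, onset + event_dur) and ``normalized``
    is the trace over both windows divided by the pre-event s.d.
    """
    t0, t1 = event_onset - pre, event_onset + event_dur
    if t0 < dff.t0 - 1e-9 or t1 > dff.t0 + dff.duration + 1e-9:
        raise ValueError("event window not covered by trace")
    pre_seg = dff.slice(t0, event_onset)
    ev_seg = dff.slice(event_onset, t1)
    sd = float(np.std(pre_seg.values, ddof=1))
    if sd <= 0:
        warnings.warn("zero pre-event s.d.; returning unnormalized trace")
        sd = 1.0
    seg = dff.slice(t0, t1)
    normalized = FluorescenceTrace(seg.values / sd, seg.sampling_rate,
                                   t0=seg.t0)
    return (float(np.mean(pre_seg.values)), float(np.mean(ev_seg.values)),
            normalized)


def state_transition_deltas(dff: DffTrace, hypnogram: Hypnogram,
                            transition_type: str, half_window: float = 15.0,
                            two_window: bool = False):
    """ΔF/F₀ deltas at sleep-state transitions of the requested type.

    ``transition_type`` is e.g. ``"NREM->REM"``.  Default delta is the
    unsigned max − min of ΔF/F₀ over the symmetric ±``half_window`` around
    the transition; with ``two_window=True`` it is |mean_post − mean_pre|
    of the two 15-s windows instead.  Transitions closer than
    ``half_window`` to either trace edge are skipped with a warning.
    """
    try:
        from_state, to_state = transition_type.replace("→", "->").split("->")
    except ValueError:
        raise ValueError(f"bad transition_type {transition_type!r}")
    deltas = []
    t_end = dff.t0 + dff.duration
    for t in hypnogram.transition_times(from_state.strip(), to_state.strip()):
        if t - half_window < dff.t0 - 1e-9 or t + half_window > t_end + 1e-9:
            warnings.warn(
                f"transition at t={t:.1f} s within {half_window} s of the "
                "record edge; skipped")
            continue
        if two_window:
            pre = dff.slice(t - half_window, t).values
            post = dff.slice(t, t + half_window).values
            d = abs(float(np.mean(post)) - float(np.mean(pre)))
        else:
            seg = dff.slice(t - half_window, t + half_window).values
            d = float(np.max(seg) - np.min(seg))
        deltas.append(TransitionDelta(transition_type=transition_type,
                                      time=float(t), delta=d))
    return deltas


def state_mean_dff(dff: DffTrace, hypnogram: Hypnogram) -> dict:
    """Mean ΔF/F₀ per vigilance state; NaN for states absent from the
    hypnogram or not covered by the trace."""
    k = np.floor((dff.times - hypnogram.t0) / hypnogram.epoch_length)
    valid = (k >= 0) & (k < len(hypnogram.states))
    states = np.full(len(dff.values), "", dtype=object)
    states[valid] = np.asarray(hypnogram.states, dtype=object)[
        k[valid].astype(int)]
    out = {}
    for s in STATES:
        mask = states == s
        if s not in hypnogram.states or not np.any(mask):
            out[s] = float("nan")
        else:
            out[s] = float(np.mean(dff.values[mask]))
    return out
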