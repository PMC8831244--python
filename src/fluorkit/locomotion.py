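"""Rotary-encoder locomotion analysis and bout-aligned fluorescence.

The treadmill encoder emits a state change per degree of rotation; with the
mouse ~11 cm from the wheel centre each change corresponds to ~2 mm of
travel.  A run bout starts at the first state change that follows a 1-s
quiescent window (≤ 1 change) and is itself followed by ≥ 65 changes
(13 cm) within 5 s.  Bout metrics (peak speed, peak fluorescence z-score)
are taken 2.5–5 s after onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .traces import FluorescenceTrace

__all__ = ["EncoderStream", "RunBout", "encoder_to_speed",
           "detect_run_bouts", "bout_metrics", "correlate_bout_peaks"]

MM_PER_CHANGE_DEFAULT = 2.0  # mm per 1-degree state change (65 changes = 13 cm)


@dataclass
class EncoderStream:
    """Sorted state-change timestamps (s) over a recording of ``duration``."""

    event_times: np.ndarray
    duration: float
    mm_per_change: float = MM_PER_CHANGE_DEFAULT

    def __post_init__(self):
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.mm_per_change <= 0:
            raise ValueError("mm_per_change must be > 0")
        if len(self.event_times):
            if np.any(np.diff(self.event_times) < 0):
                raise ValueError("event_times must be sorted")
            if (self.event_times[0] < 0
                    or self.event_times[-1] > self.duration):
                raise ValueError("event_times outside [0, duration]")


@dataclass
class RunBout:
    onset: float
    peak_speed: float        # cm/s in 100-ms bins
    peak_speed_time: float
    peak_dff_z: float        # s.d. units
    peak_dff_time: float


def encoder_to_speed(stream: EncoderStream,
                     bin_width: float = 0.1) -> FluorescenceTrace:
    """Running-speed trace in cm/s from binned state-change counts."""
    n_bins = int(np.ceil(stream.duration / bin_width))
    if n_bins == 0:
        return FluorescenceTrace(np.zeros(0), 1.0 / bin_width, t0=0.0)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(stream.event_times, bins=edges)
    speed_cm_s = counts * stream.mm_per_change / bin_width / 10.0
    return FluorescenceTrace(speed_cm_s, 1.0 / bin_width,
                             t0=bin_width / 2.0)


def detect_run_bouts(stream: EncoderStream, min_changes: int = 65,
                     run_window: float = 5.0, quiet_window: float = 1.0,
                     max_quiet_changes: int = 1) -> list:
    """Onset times of spontaneous running bouts.

    A state change at time t is a bout onset when the preceding
    ``quiet_window`` [t − 1 s, t) holds at most ``max_quiet_changes``
    changes and [t, t + 5 s) holds at least ``min_changes`` changes
    (the onset change included).  After a detected onset, detection is
    suppressed until ``run_window`` has elapsed so a single bout is not
    counted from several early changes.
    """
    times = stream.event_times
    onsets = []
    suppressed_until = -np.inf
    for i, t in enumerate(times):
        if t < suppressed_until:
            continue
        if t < quiet_window:
            # quiescence cannot be verified before the recording starts
            continue
        n_quiet = np.searchsorted(times, t) - np.searchsorted(
            times, t - quiet_window)
        if n_quiet > max_quiet_changes:
            continue
        n_run = np.searchsorted(times, t + run_window) - i
        if n_run >= min_changes:
            onsets.append(float(t))
            suppressed_until = t + run_window
    return onsets


def bout_metrics(onsets, speed_trace: FluorescenceTrace,
                 z_trace: FluorescenceTrace,
                 metric_window: tuple = (2.5, 5.0)) -> list:
    """Peak speed and peak fluorescence z within 2.5–5 s after each onset.

    ``z_trace`` should be z-scored but not detrended.  Bouts whose metric
    window is not covered by both traces are skipped with a warning.
    """
    lo, hi = metric_window
    bouts = []
    for onset in onsets:
        t0, t1 = onset + lo, onset + hi
        try:
            sp = speed_trace.slice(t0, t1)
            zz = z_trace.slice(t0, t1)
        except ValueError:
            warnings.warn(f"bout at {onset:.2f} s lacks trace coverage; "
                          "skipped")
            continue
        i_sp = int(np.argmax(sp.values))
        i_z = int(np.argmax(zz.values))
        bouts.append(RunBout(
            onset=float(onset),
            peak_speed=float(sp.values[i_sp]),
            peak_speed_time=float(sp.times[i_sp]),
            peak_dff_z=float(zz.values[i_z]),
            peak_dff_time=float(zz.times[i_z]),
        ))
    return bouts


def correlate_bout_peaks(bouts):
    """OLS regression of peak fluorescence z on peak speed across bouts.

    Returns ``(slope, r_squared, F, p)``; the F statistic (= t² for a
    single regressor) tests the slope against zero.
    """
    if len(bouts) < 3:
        raise ValueError("need at least 3 bouts for regression")
    x = np.array([b.peak_speed for b in bouts])
    y = np.array([b.peak_dff_z for b in bouts])
    res = stats.linregress(x, y)
    if res.stderr == 0:
        f = np.inf if res.slope != 0 else 0.0
    else:
        f = (res.slope / res.stderr) ** 2
    return (float(res.slope), float(res.rvalue ** 2), float(f),
            float(res.pvalue))
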