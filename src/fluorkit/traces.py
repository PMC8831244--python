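"""Fundamental fluorescence-trace operations shared by all pipelines.

A :class:`FluorescenceTrace` is a uniformly sampled signal with a sampling
rate and an absolute start time.  The operations here implement the
normalisations used throughout sensor imaging: ΔF/F₀ against a pre-ligand
baseline, fixed-width binning, Savitzky–Golay smoothing, median-anchored
linear detrending, and baseline z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "FluorescenceTrace",
    "DffTrace",
    "ZScoredTrace",
    "compute_dff",
    "bin_trace",
    "detrend_linear_median",
    "zscore_baseline",
    "savgol_smooth",
]


@dataclass
class FluorescenceTrace:
    """Uniformly sampled fluorescence (arbitrary units) versus time.

    Parameters
    ----------
    values : ndarray
        Sample values, finite.
    sampling_rate : float
        Samples per second, > 0.
    t0 : float
        Absolute time of the first sample, seconds.
    annotations : list of (label, start_s, end_s)
        Event/stimulus intervals, each inside the trace extent.
    """

    values: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        t_end = self.t0 + len(self.values) / self.sampling_rate
        for label, start, end in self.annotations:
            if start < self.t0 - 1e-9 or end > t_end + 1e-9:
                raise ValueError(
                    f"annotation {label!r} [{start}, {end}] outside trace "
                    f"extent [{self.t0}, {t_end}]"
                )

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return len(self.values) / self.sampling_rate

    def slice(self, start: float, end: float) -> "FluorescenceTrace":
        """Samples with time in the half-open window [start, end)."""
        idx = self._window_indices(start, end)
        return replace(
            self,
            values=self.values[idx],
            t0=self.t0 + idx.start / self.sampling_rate,
            annotations=[],
        )

    def _window_indices(self, start: float, end: float) -> slice:
        # half-open [start, end); tiny tolerance absorbs float rounding of
        # times constructed as i / fs
        eps = 1e-9
        i0 = int(np.ceil((start - self.t0 - eps) * self.sampling_rate))
        i1 = int(np.ceil((end - self.t0 - eps) * self.sampling_rate))
        i0 = max(i0, 0)
        i1 = min(i1, len(self.values))
        if i1 <= i0:
            raise ValueError(f"window [{start}, {end}) contains no samples")
        return slice(i0, i1)


@dataclass
class DffTrace(FluorescenceTrace):
    """ΔF/F₀ trace: dimensionless fraction (multiply by 100 for percent)."""

    baseline_value: float = np.nan
    baseline_window: tuple = (np.nan, np.nan)


@dataclass
class ZScoredTrace(FluorescenceTrace):
    """Baseline-referenced z-score trace, in units of baseline s.d."""

    baseline_median: float = np.nan
    baseline_sd: float = np.nan
    baseline_window: tuple = (np.nan, np.nan)


def compute_dff(trace, baseline_window=None, n_baseline_points=None,
                event_time=None) -> DffTrace:
    """ΔF/F₀ = (F(t) − F₀)/F₀ with F₀ the mean over a baseline.

    The baseline is specified either as a time window ``baseline_window =
    (start_s, end_s)`` (half-open) or as the ``n_baseline_points`` samples
    immediately before ``event_time`` — e.g. the mean of the ten time points
    immediately before ligand addition.

    Raises
    ------
    ValueError
        If the baseline is empty, outside the trace, or its mean is ≤ 0.
    """
    if baseline_window is not None:
        idx = trace._window_indices(*baseline_window)
        window = (float(baseline_window[0]), float(baseline_window[1]))
    elif n_baseline_points is not None:
        if event_time is None:
            raise ValueError("n_baseline_points requires event_time")
        if n_baseline_points < 1:
            raise ValueError("n_baseline_points must be >= 1")
        i_event = int(np.ceil((event_time - trace.t0 - 1e-9)
                              * trace.sampling_rate))
        i0 = i_event - int(n_baseline_points)
        if i0 < 0 or i_event > len(trace.values):
            raise ValueError("baseline points fall outside the trace")
        idx = slice(i0, i_event)
        window = (trace.t0 + i0 / trace.sampling_rate,
                  trace.t0 + i_event / trace.sampling_rate)
    else:
        raise ValueError("specify baseline_window or n_baseline_points")

    f0 = float(np.mean(trace.values[idx]))
    if f0 <= 0:
        raise ValueError(f"non-positive baseline mean F0={f0}")
    return DffTrace(
        values=(trace.values - f0) / f0,
        sampling_rate=trace.sampling_rate,
        t0=trace.t0,
        annotations=list(trace.annotations),
        baseline_value=f0,
        baseline_window=window,
    )


def bin_trace(trace: FluorescenceTrace, bin_width: float) -> FluorescenceTrace:
    """Average into fixed-width bins; the trailing partial bin is dropped.

    Output sample *i* is the mean of the raw samples in bin *i* and is
    timestamped at the bin centre; the output sampling rate is 1/bin_width.
    """
    n_per = int(round(bin_width * trace.sampling_rate))
    if n_per < 1 or bin_width < 1.0 / trace.sampling_rate - 1e-12:
        raise ValueError("bin_width must be >= one sample period")
    n_bins = len(trace.values) // n_per
    if n_bins == 0:
        raise ValueError("trace shorter than one bin")
    binned = trace.values[: n_bins * n_per].reshape(n_bins, n_per).mean(axis=1)
    return FluorescenceTrace(
        values=binned,
        sampling_rate=trace.sampling_rate / n_per,
        t0=trace.t0 + (n_per - 1) / (2.0 * trace.sampling_rate),
        annotations=list(trace.annotations),
    )


def detrend_linear_median(trace: FluorescenceTrace,
                          anchor_width: float = 30.0) -> FluorescenceTrace:
    """Subtract the line through the medians of the first and last windows.

    The anchors are (centre of the first ``anchor_width`` seconds, median of
    those samples) and likewise for the last window — the median-anchored
    linear detrend used for slowly drifting photometry baselines.
    """
    if trace.duration < 2 * anchor_width:
        raise ValueError("trace shorter than two anchor windows")
    t = trace.times
    first = trace._window_indices(trace.t0, trace.t0 + anchor_width)
    t_end = trace.t0 + trace.duration
    last = trace._window_indices(t_end - anchor_width, t_end)
    m1 = np.median(trace.values[first])
    m2 = np.median(trace.values[last])
    # anchor each median at the median sample time of its window, so a
    # perfectly linear trace detrends to exactly zero
    c1 = float(np.median(t[first]))
    c2 = float(np.median(t[last]))
    line = m1 + (m2 - m1) * (t - c1) / (c2 - c1)
    return replace(trace, values=trace.values - line)


def zscore_baseline(trace: FluorescenceTrace,
                    baseline_window: tuple) -> ZScoredTrace:
    """z[t] = (x[t] − median_baseline) / sd_baseline.

    The reference statistics are the median and the sample (n−1) standard
    deviation of the samples in ``baseline_window``.
    """
    idx = trace._window_indices(*baseline_window)
    base = trace.values[idx]
    med = float(np.median(base))
    sd = float(np.std(base, ddof=1)) if len(base) > 1 else 0.0
    if sd <= 0:
        raise ValueError("degenerate baseline: zero standard deviation")
    return ZScoredTrace(
        values=(trace.values - med) / sd,
        sampling_rate=trace.sampling_rate,
        t0=trace.t0,
        annotations=list(trace.annotations),
        baseline_median=med,
        baseline_sd=sd,
        baseline_window=(float(baseline_window[0]), float(baseline_window[1])),
    )


def savgol_smooth(trace: FluorescenceTrace, window_s: float,
                  polyorder: int = 3) -> FluorescenceTrace:
    """Savitzky–Golay smoothing with a window of ``window_s`` seconds.

    The window length in samples is rounded to the nearest odd integer and
    must exceed ``polyorder``.
    """
    wl = int(round(window_s * trace.sampling_rate))
    if wl % 2 == 0:
        wl += 1
    if wl < 1 or wl <= polyorder:
        raise ValueError(
            f"window of {window_s} s -> {wl} samples; must be odd and "
            f"> polyorder={polyorder}"
        )
    if wl > len(trace.values):
        raise ValueError("smoothing window longer than trace")
    return replace(trace,
                   values=savgol_filter(trace.values, wl, polyorder))
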