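"""Two-photon cortical microdomain pipeline.

From a motion-corrected T×H×W movie of a sensor-expressing field of view
(FOV) the pipeline derives, in order:

1. the FOV-level ΔF/F₀ trace (per-frame mean over all pixels; F₀ = median
   of the frame means during the first anesthetized minute) and the
   first-vs-last-minute ΔF/F₀ difference;
2. the *most-active minute*: the 1-min moving window, within a search
   period, with the highest mean per-frame spatial standard deviation;
3. per-pixel binarized activity over that window,
   b(i,j,t) = 1 iff f(i,j,t) > median_t(f) + s.d._t(f);
4. a σ = 2 px Gaussian smoothing of each binarized frame followed by
   Richardson–Lucy deconvolution with a 39×39 px σ = 20 px Gaussian
   kernel, averaged into a projection image;
5. circular active/inactive ROIs (diameter 12 px) placed greedily on
   percentile bands of the pooled projection-pixel distribution
   (active 70–100, inactive 5–69; pixels below the 5th percentile —
   blood vessels — are never included);
6. pairwise Pearson correlations of the raw ROI traces during the
   most-active minute, summarised within each ROI class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .traces import DffTrace

__all__ = [
    "ImagingMovie", "BinarizedMovie", "MostActiveWindow", "Roi", "RoiSet",
    "CorrelationMatrix", "fov_dff_trace", "first_last_minute_delta",
    "find_most_active_minute", "binarize_window", "gaussian_psf",
    "richardson_lucy_stack", "smooth_and_deconvolve", "identify_rois",
    "extract_roi_traces", "roi_correlation_analysis",
]


@dataclass
class ImagingMovie:
    """Motion-corrected movie: frames (T, H, W), frame rate 4.9–7.5 Hz,
    pixel size 1.27 µm, and the frame at which anesthesia was switched
    off."""

    frames: np.ndarray
    frame_rate: float
    pixel_size_um: float = 1.27
    anesthesia_off_frame: int = 0

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if not (0 <= self.anesthesia_off_frame < len(self.frames)):
            raise ValueError("anesthesia_off_frame outside movie")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frames_per_minute(self) -> int:
        return int(round(60.0 * self.frame_rate))


@dataclass
class BinarizedMovie:
    """{0,1} activity frames restricted to the analysis window Δt."""

    frames: np.ndarray
    window: tuple  # (start_frame, end_frame), half-open


@dataclass
class MostActiveWindow:
    start_frame: int
    n_frames: int
    mean_spatial_sd: float

    @property
    def end_frame(self) -> int:
        return self.start_frame + self.n_frames


@dataclass
class Roi:
    center: tuple       # (row, col) of the anchor pixel; the 12-px circle
    radius_px: float    # is centred on its (row+0.5, col+0.5) corner
    roi_class: str      # 'active' | 'inactive'
    pixels: np.ndarray  # (n, 2) array of (row, col) member pixels


@dataclass
class RoiSet:
    rois: list
    percentile_bands: dict
    projection: np.ndarray = None
    traces: np.ndarray = None  # n_roi x T raw-fluorescence traces

    def by_class(self, roi_class: str):
        return [i for i, r in enumerate(self.rois)
                if r.roi_class == roi_class]


@dataclass
class CorrelationMatrix:
    matrix: np.ndarray
    roi_classes: list
    mean_active_r: float = float("nan")
    mean_inactive_r: float = float("nan")


def fov_dff_trace(movie: ImagingMovie,
                  baseline_minutes: float = 1.0) -> DffTrace:
    """FOV ΔF/F₀: the whole frame is one ROI.

    F(t) is the mean over all pixels of frame t; F₀ is the median of F(t)
    over the anesthetized period (the first ``baseline_minutes`` of
    imaging).
    """
    n_base = int(round(baseline_minutes * 60.0 * movie.frame_rate))
    if movie.n_frames < n_base:
        raise ValueError("movie shorter than the anesthetized baseline")
    f = movie.frames.reshape(movie.n_frames, -1).mean(axis=1)
    f0 = float(np.median(f[:n_base]))
    if f0 <= 0:
        raise ValueError("non-positive baseline F0")
    return DffTrace(values=(f - f0) / f0, sampling_rate=movie.frame_rate,
                    t0=0.0, baseline_value=f0,
                    baseline_window=(0.0, n_base / movie.frame_rate))


def first_last_minute_delta(dff: DffTrace) -> float:
    """mean(ΔF/F₀ of the last minute) − mean(first minute)."""
    n = int(round(60.0 * dff.sampling_rate))
    if len(dff.values) < 2 * n:
        raise ValueError("trace shorter than two minutes")
    return float(np.mean(dff.values[-n:]) - np.mean(dff.values[:n]))


def find_most_active_minute(movie: ImagingMovie,
                            search_start_s: float = 120.0,
                            search_end_s: float = 360.0) -> MostActiveWindow:
    """Select the 1-min moving window with the highest mean spatial s.d.

    The per-frame spatial s.d. (sample s.d. over pixels) is averaged over
    each n-frame window (n = frames per minute) fully inside the search
    period; windows advance one frame at a time and ties go to the
    earliest window.
    """
    n = movie.frames_per_minute
    i0 = int(round(search_start_s * movie.frame_rate))
    i1 = min(int(round(search_end_s * movie.frame_rate)), movie.n_frames)
    i0 = max(i0, 0)
    if i1 - i0 < n:
        raise ValueError("search period shorter than one minute")
    flat = movie.frames[i0:i1].reshape(i1 - i0, -1)
    sd = flat.std(axis=1, ddof=1)
    kernel = np.ones(n) / n
    means = np.convolve(sd, kernel, mode="valid")
    best = int(np.argmax(means))  # argmax returns the earliest maximum
    return MostActiveWindow(start_frame=i0 + best, n_frames=n,
                            mean_spatial_sd=float(means[best]))


def binarize_window(movie: ImagingMovie,
                    window: MostActiveWindow) -> BinarizedMovie:
    """b(i,j,t) = 1 iff f(i,j,t) > median_t(f(i,j,Δt)) + s.d._t(f(i,j,Δt)).

    Median and sample s.d. are temporal, per pixel, over the window Δt;
    the inequality is strict, so constant pixels (s.d. 0) are never 1.
    """
    if window.end_frame > movie.n_frames or window.start_frame < 0:
        raise ValueError("window outside movie")
    sub = movie.frames[window.start_frame:window.end_frame].astype(float)
    med = np.median(sub, axis=0)
    sd = np.std(sub, axis=0, ddof=1)
    b = (sub > med + sd).astype(np.uint8)
    return BinarizedMovie(frames=b,
                          window=(window.start_frame, window.end_frame))


def gaussian_psf(size: int = 39, sigma: float = 20.0) -> np.ndarray:
    """Normalised 2-D Gaussian kernel (default 39×39 px, σ = 20 px)."""
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def _fft_convolve_stack(stack: np.ndarray, kernel_fft: np.ndarray,
                        pad: int, shape) -> np.ndarray:
    """Circular FFT convolution of reflect-padded frames with a centred
    kernel, cropped back to the original frame shape."""
    padded = np.pad(stack, ((0, 0), (pad, pad), (pad, pad)), mode="reflect")
    out = np.fft.irfft2(np.fft.rfft2(padded) * kernel_fft,
                        s=padded.shape[1:])
    return out[:, pad:pad + shape[0], pad:pad + shape[1]]


def richardson_lucy_stack(stack: np.ndarray, psf: np.ndarray,
                          iterations: int = 10,
                          chunk: int = 64) -> np.ndarray:
    """Richardson–Lucy deconvolution of every frame with a shared PSF.

    Iterates est ← est · K*⊛(obs / K⊛est) from a flat 0.5 initial
    estimate.  Convolutions use reflective frame boundaries, which makes a
    flat field an exact fixed point, and a kernel transform precomputed
    once for the whole stack; frames are processed in chunks to bound
    memory.
    """
    stack = np.asarray(stack, dtype=float)
    t, h, w = stack.shape
    kh, kw = psf.shape
    if kh > h or kw > w:
        raise ValueError("PSF larger than frame")
    pad = max(kh, kw) // 2
    ph, pw = h + 2 * pad, w + 2 * pad
    kpad = np.zeros((ph, pw))
    kpad[:kh, :kw] = psf
    # centre the kernel so circular convolution leaves no spatial shift
    kpad = np.roll(kpad, (-(kh // 2), -(kw // 2)), axis=(0, 1))
    k_fft = np.fft.rfft2(kpad)
    k_mirror_fft = np.conj(k_fft)

    out = np.empty_like(stack)
    eps = 1e-12
    for s in range(0, t, chunk):
        obs = stack[s:s + chunk]
        est = np.full_like(obs, 0.5)
        for _ in range(iterations):
            conv = _fft_convolve_stack(est, k_fft, pad, (h, w))
            relative = obs / np.maximum(conv, eps)
            est = est * _fft_convolve_stack(relative, k_mirror_fft, pad,
                                            (h, w))
        out[s:s + chunk] = est
    return np.maximum(out, 0.0)


def smooth_and_deconvolve(binarized: BinarizedMovie,
                          smooth_sigma: float = 2.0,
                          psf_size: int = 39, psf_sigma: float = 20.0,
                          iterations: int = 10):
    """σ = 2 px Gaussian smoothing then Richardson–Lucy deconvolution.

    Returns ``(deconvolved_stack, average_projection)``; smoothed values
    lie in [0, 1] and the projection averages the deconvolved frames.
    """
    frames = binarized.frames.astype(float)
    smoothed = gaussian_filter(frames, sigma=(0.0, smooth_sigma,
                                              smooth_sigma), mode="reflect")
    psf = gaussian_psf(psf_size, psf_sigma)
    deconvolved = richardson_lucy_stack(smoothed, psf, iterations=iterations)
    return deconvolved, deconvolved.mean(axis=0)


def _disk_offsets(diameter: float) -> np.ndarray:
    """Pixel offsets of a circle of the given diameter whose centre sits on
    the (row+0.5, col+0.5) corner of the anchor pixel (even diameters then
    span exactly ``diameter`` pixels)."""
    r = diameter / 2.0
    m = int(np.ceil(r))
    d = np.arange(-m, m + 1)
    dr, dc = np.meshgrid(d, d, indexing="ij")
    inside = (dr - 0.5) ** 2 + (dc - 0.5) ** 2 <= r ** 2
    return np.stack([dr[inside], dc[inside]], axis=1)


def _greedy_place(projection, band_mask, taken, offsets, n_target):
    """Greedily place non-overlapping circles fully inside ``band_mask``,
    highest projection value first."""
    h, w = projection.shape
    # centres whose whole circle lies in-band (and in-frame): AND of the
    # band mask shifted by every circle offset, False-padded at the border
    min_r, max_r = int(offsets[:, 0].min()), int(offsets[:, 0].max())
    min_c, max_c = int(offsets[:, 1].min()), int(offsets[:, 1].max())
    padded = np.zeros((h + max_r - min_r, w + max_c - min_c), dtype=bool)
    padded[-min_r:-min_r + h, -min_c:-min_c + w] = band_mask
    ok = np.ones((h, w), dtype=bool)
    for dr, dc in offsets:
        ok &= padded[dr - min_r:dr - min_r + h, dc - min_c:dc - min_c + w]
    cand = np.argwhere(ok)
    if len(cand) == 0:
        return []
    order = np.argsort(projection[cand[:, 0], cand[:, 1]])[::-1]
    placed = []
    for idx in order:
        r, c = cand[idx]
        rows = r + offsets[:, 0]
        cols = c + offsets[:, 1]
        if taken[rows, cols].any():
            continue
        taken[rows, cols] = True
        placed.append(((int(r), int(c)), np.stack([rows, cols], axis=1)))
        if len(placed) == n_target:
            break
    return placed


def identify_rois(projections, n_active: int = 10, n_inactive: int = 10,
                  diameter_px: float = 12.0,
                  bands: tuple = (5.0, 69.0, 70.0)) -> list:
    """Place circular active/inactive ROIs on percentile bands.

    Percentiles (linear interpolation) are computed on the POOLED pixel
    distribution across all supplied deconvolved projections, so ROI
    classes are comparable across FOVs.  Per FOV, up to ``n_active``
    non-overlapping circles whose pixels all lie in [p70, max] and
    ``n_inactive`` circles with pixels in [p5, p69) are accepted greedily,
    brightest candidate centre first; pixels below the 5th percentile
    (blood vessels) are never part of any ROI.  Fewer qualifying ROIs
    trigger a warning, not an error.

    Returns one :class:`RoiSet` per projection.
    """
    projections = [np.asarray(p, dtype=float) for p in projections]
    if not projections:
        raise ValueError("need at least one projection")
    pooled = np.concatenate([p.ravel() for p in projections])
    p5, p69, p70 = np.percentile(pooled, bands)
    band_info = {"active": (p70, float(pooled.max())),
                 "inactive": (p5, p69), "excluded_below": p5}
    offsets = _disk_offsets(diameter_px)

    roisets = []
    for proj in projections:
        active_band = proj >= p70
        inactive_band = (proj >= p5) & (proj < p69)
        taken = np.zeros(proj.shape, dtype=bool)
        rois = []
        for band_mask, roi_class, n_target in (
                (active_band, "active", n_active),
                (inactive_band, "inactive", n_inactive)):
            placed = _greedy_place(proj, band_mask, taken, offsets, n_target)
            if len(placed) < n_target:
                warnings.warn(
                    f"only {len(placed)}/{n_target} {roi_class} ROIs could "
                    "be placed in the percentile band")
            for center, pixels in placed:
                rois.append(Roi(center=center, radius_px=diameter_px / 2.0,
                                roi_class=roi_class, pixels=pixels))
        roisets.append(RoiSet(rois=rois, percentile_bands=band_info,
                              projection=proj))
    return roisets


def extract_roi_traces(roiset: RoiSet, movie: ImagingMovie,
                       window: MostActiveWindow) -> np.ndarray:
    """Per-frame mean RAW fluorescence of each ROI over the window."""
    sub = movie.frames[window.start_frame:window.end_frame]
    traces = np.empty((len(roiset.rois), len(sub)))
    for i, roi in enumerate(roiset.rois):
        traces[i] = sub[:, roi.pixels[:, 0], roi.pixels[:, 1]].mean(axis=1)
    roiset.traces = traces
    return traces


def roi_correlation_analysis(roiset: RoiSet, movie: ImagingMovie = None,
                             window: MostActiveWindow = None
                             ) -> CorrelationMatrix:
    """Pairwise Pearson correlations of raw ROI traces in the window.

    Pairs involving a constant trace have undefined r and are reported as
    NaN and excluded from the class means (mean off-diagonal r among
    active ROIs and among inactive ROIs).
    """
    if roiset.traces is None:
        if movie is None or window is None:
            raise ValueError("provide movie and window, or pre-extracted "
                             "traces")
        extract_roi_traces(roiset, movie, window)
    traces = roiset.traces
    sd = traces.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(traces)
    mat[sd == 0, :] = np.nan
    mat[:, sd == 0] = np.nan
    np.fill_diagonal(mat, 1.0)
    classes = [r.roi_class for r in roiset.rois]

    def _class_mean(cls):
        idx = [i for i, c in enumerate(classes) if c == cls]
        if len(idx) < 2:
            return float("nan")
        block = mat[np.ix_(idx, idx)]
        off = block[~np.eye(len(idx), dtype=bool)]
        return float(np.nanmean(off)) if np.any(np.isfinite(off)) else \
            float("nan")

    return CorrelationMatrix(matrix=mat, roi_classes=classes,
                             mean_active_r=_class_mean("active"),
                             mean_inactive_r=_class_mean("inactive"))
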