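"""Seeded generators for every input modality, with known ground truth.

No raw recordings accompany the experiments this package analyses, so each
pipeline is exercised on synthetic data that emulates the acquisition it
expects — 400-Hz photometry with exponential stimulus responses and
baseline drift, rotary-encoder event streams with Poisson run bouts,
two-photon movies with latent-driven hotspots, a sigmoidal wake-up ramp
and dark vessels, 550-Hz dual-channel line scans, logistic titrations and
hypnograms with state-locked ΔF/F₀ levels.  Every generator is a pure
function of (seed, parameters) and returns the ground truth it embedded.

Seed splitting: a run-level integer seed is combined with a per-stream
label via :func:`stream_rng`, so independent streams never share a
generator state.
"""

from __future__ import annotations

import zlib

import numpy as np

from .linescan import LINESCAN_RATE, LineScanRecording
from .locomotion import EncoderStream
from .photometry import Hypnogram, StimTrain
from .traces import DffTrace, FluorescenceTrace
from .twophoton import ImagingMovie

__all__ = ["stream_rng", "gen_photometry", "gen_encoder", "gen_movie",
           "gen_linescan", "gen_cell_trace", "gen_dose_response",
           "gen_hypnogram"]


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for (seed, stream-label)."""
    return np.random.default_rng([int(seed) % (2 ** 31),
                                  zlib.crc32(stream.encode())])


def gen_photometry(seed: int, trains=None, sampling_rate: float = 400.0,
                   duration: float = 140.0, baseline: float = 1.0,
                   drift_slope: float = 2e-4, amplitude: float = 0.5,
                   tau_rise: float = 6.77, tau_decay: float = 16.31,
                   noise_sd_frac: float = 0.1):
    """Photometry trace with stimulus-locked exponential responses.

    Each train drives amplitude·(1 − e^(−t/τ_rise)) during the train and
    an e^(−t/τ_decay) return after it, on top of a linearly drifting
    baseline with Gaussian noise of s.d. ``noise_sd_frac`` × the largest
    train amplitude (``amplitude`` may be a scalar or one value per
    train).
    Defaults mirror a 20-Hz, 30-s optogenetic train protocol (rise 6.77 s,
    decay 16.31 s) sampled at 400 Hz.

    Returns ``(FluorescenceTrace, truth_dict)``.
    """
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError("time constants must be > 0")
    if trains is None:
        trains = [StimTrain(onset=40.0, frequency=20.0, pulse_width=0.005,
                            duration=30.0)]
    rng = stream_rng(seed, "photometry")
    amps = np.broadcast_to(np.asarray(amplitude, dtype=float),
                           (len(trains),)) if trains else np.empty(0)
    t = np.arange(int(round(duration * sampling_rate))) / sampling_rate
    values = baseline + drift_slope * t
    for tr, amp in zip(trains, amps):
        rising = (t >= tr.onset) & (t < tr.offset)
        falling = t >= tr.offset
        values[rising] += amp * (
            1.0 - np.exp(-(t[rising] - tr.onset) / tau_rise))
        peak = amp * (1.0 - np.exp(-tr.duration / tau_rise))
        values[falling] += peak * np.exp(-(t[falling] - tr.offset)
                                         / tau_decay)
    noise_ref = float(np.max(amps)) if len(amps) else 1.0
    values += rng.normal(0.0, noise_sd_frac * noise_ref, size=t.shape)
    trace = FluorescenceTrace(
        values=values, sampling_rate=sampling_rate, t0=0.0,
        annotations=[("stim", tr.onset, tr.offset) for tr in trains])
    truth = {"tau_rise": tau_rise, "tau_decay": tau_decay,
             "amplitude": amplitude, "drift_slope": drift_slope,
             "trains": trains}
    return trace, truth


def gen_encoder(seed: int, duration: float = 300.0, bouts=None,
                in_bout_rate: float = 30.0, quiescent_rate: float = 0.2,
                mm_per_change: float = 2.0, guard: float = 3.0):
    """Rotary-encoder event stream with scheduled running bouts.

    ``bouts`` is a list of (start_s, duration_s) or
    (start_s, duration_s, rate); inside a bout the wheel
    turns steadily, so events are quasi-regular at ``in_bout_rate``
    changes/s (10% spacing jitter); outside, stray events are Poisson at
    ``quiescent_rate`` (well under the 1 change/s quiescence criterion),
    with a silent ``guard`` interval cleared before each bout onset.

    Returns ``(EncoderStream, truth_dict)``.
    """
    if bouts is None:
        bouts = [(60.0, 8.0), (150.0, 6.0), (240.0, 10.0)]
    bouts = sorted((s, d, b[2] if len(b) > 2 else in_bout_rate)
                   for b in bouts for s, d in [b[:2]])
    for (s1, d1, _), (s2, _, _) in zip(bouts, bouts[1:]):
        if s1 + d1 + guard > s2:
            raise ValueError("bouts overlap (including the guard interval)")
    for s, d, _ in bouts:
        if s - guard < 0 or s + d > duration:
            raise ValueError("bout outside [guard, duration]")
    rng = stream_rng(seed, "encoder")

    def poisson_times(t0, t1, rate):
        if t1 <= t0 or rate <= 0:
            return np.empty(0)
        n = rng.poisson(rate * (t1 - t0))
        return np.sort(rng.uniform(t0, t1, size=n))

    def running_times(t0, t1, rate):
        n = int(round(rate * (t1 - t0)))
        base = t0 + (np.arange(n) + 0.5) / rate
        jitter = rng.normal(0.0, 0.1 / rate, size=n)
        return np.sort(np.clip(base + jitter, t0, t1 - 1e-9))

    pieces = []
    cursor = 0.0
    for s, d, rate in bouts:
        pieces.append(poisson_times(cursor, s - guard, quiescent_rate))
        pieces.append(running_times(s, s + d, rate))
        cursor = s + d
    pieces.append(poisson_times(cursor, duration, quiescent_rate))
    times = np.sort(np.concatenate(pieces))
    stream = EncoderStream(event_times=times, duration=duration,
                           mm_per_change=mm_per_change)
    truth = {"bout_starts": [s for s, _, _ in bouts],
             "bout_durations": [d for _, d, _ in bouts],
             "bout_rates": [r for _, _, r in bouts]}
    return stream, truth


def _burst_latent(rng, t, hot_window, hot_rate=0.3, cold_rate=0.02,
                  tau_on=0.3, tau_off=1.5, start: float = 0.0):
    """Bursty latent drive in [0, 1]: Poisson events convolved with a fast
    rise / slow decay kernel, denser inside ``hot_window``."""
    rate = np.where((t >= hot_window[0]) & (t < hot_window[1]),
                    hot_rate, cold_rate)
    rate[t < start] = 0.0
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    events = rng.random(len(t)) < rate * dt
    a = np.zeros(len(t))
    level = 0.0
    for i in range(len(t)):
        if events[i]:
            level = 1.0
        else:
            level *= np.exp(-dt / tau_off)
        a[i] = level
    # fast rise smoothing
    k = max(1, int(round(tau_on / dt)))
    a = np.convolve(a, np.ones(k) / k, mode="same")
    return np.clip(a, 0.0, 1.0)


def gen_movie(seed: int, shape=(256, 256), frame_rate: float = 5.0,
              duration: float = 360.0, anesthesia_off_s: float = 60.0,
              background: float = 100.0, ramp_amplitude: float = 0.3,
              ramp_center_s: float = 270.0, ramp_width_s: float = 25.0,
              n_hotspots: int = 12, hotspot_sigma_px: float = 7.0,
              hotspot_amplitude: float = 150.0,
              hot_window=(150.0, 210.0), n_vessels: int = 3,
              vessel_radius_px: float = 8.0, vessel_value: float = 5.0,
              noise_scale: float = 1.0, pixel_size_um: float = 1.27,
              dtype=np.float32):
    """Two-photon movie: ramp + shared-latent hotspots + vessels + noise.

    The frame model is
    ``f = background·(1 + ramp(t)) + Σ_k amp·G_k(i,j)·a(t) + noise`` with
    a sigmoidal wake-up ramp (onset ≈ 1 min after anesthesia off, plateau
    ≈ 4 min later), ``n_hotspots`` Gaussian hotspots sharing one bursty
    latent time course a(t) concentrated in ``hot_window`` (which the
    most-active-minute selector should find), Poisson-like noise
    (Gaussian, variance ∝ mean), and noise-free dark vessel disks
    (never binarized, hence below the 5th projection percentile).

    Returns ``(ImagingMovie, truth_dict)`` with hotspot centres/masks, the
    latent course and the ramp amplitude.
    """
    if hotspot_sigma_px <= 0:
        raise ValueError("hotspot sigma must be > 0")
    rng = stream_rng(seed, "movie")
    h, w = shape
    n_frames = int(round(duration * frame_rate))
    t = np.arange(n_frames) / frame_rate

    ramp = ramp_amplitude / (1.0 + np.exp(-(t - ramp_center_s)
                                          / ramp_width_s))
    latent = _burst_latent(rng, t, hot_window, start=anesthesia_off_s)

    rr, cc = np.mgrid[0:h, 0:w]

    # vessels run perpendicular to the surface: dark disks in the FOV
    vessel = np.zeros((h, w), dtype=bool)
    vr = int(np.ceil(vessel_radius_px))
    vessel_centers = []
    for _ in range(n_vessels):
        r0 = int(rng.integers(vr, h - vr))
        c0 = int(rng.integers(vr, w - vr))
        vessel_centers.append((r0, c0))
        vessel |= (rr - r0) ** 2 + (cc - c0) ** 2 <= vessel_radius_px ** 2

    # hotspots sit in tissue, clear of vessel lumina
    margin = int(np.ceil(3 * hotspot_sigma_px))
    clearance = (vessel_radius_px + 2.0 * hotspot_sigma_px) ** 2
    centers = []
    tries = 0
    while len(centers) < n_hotspots:
        tries += 1
        if tries > 1000 * max(n_hotspots, 1):
            raise ValueError("cannot place hotspots clear of vessels; "
                             "frame too small for the requested geometry")
        r0 = int(rng.integers(margin, h - margin))
        c0 = int(rng.integers(margin, w - margin))
        if any((r0 - vr0) ** 2 + (c0 - vc0) ** 2 < clearance
               for vr0, vc0 in vessel_centers):
            continue
        centers.append((r0, c0))
    centers = np.asarray(centers)
    hot_map = np.zeros((h, w))
    masks = np.zeros((h, w), dtype=bool)
    for r0, c0 in centers:
        g = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2)
                   / (2.0 * hotspot_sigma_px ** 2))
        hot_map = np.maximum(hot_map, g)
        masks |= g > np.exp(-2.0)  # within 2 sigma

    frames = np.empty((n_frames, h, w), dtype=dtype)
    base_t = background * (1.0 + ramp)
    for i in range(n_frames):
        mean = base_t[i] + hotspot_amplitude * hot_map * latent[i]
        frame = mean + rng.normal(0.0, 1.0, size=(h, w)) * (
            noise_scale * np.sqrt(mean))
        frame[vessel] = vessel_value
        frames[i] = np.maximum(frame, 0.0)

    movie = ImagingMovie(frames=frames, frame_rate=frame_rate,
                         pixel_size_um=pixel_size_um,
                         anesthesia_off_frame=int(round(anesthesia_off_s
                                                        * frame_rate)))
    truth = {"hotspot_centers": centers, "hotspot_mask": masks,
             "latent": latent, "ramp_amplitude": ramp_amplitude,
             "hot_window": hot_window, "vessel_mask": vessel}
    return movie, truth


def gen_linescan(seed: int, n_pixels: int = 64, membrane_frac: float = 0.4,
                 duration: float = 5.0, sampling_rate: float = LINESCAN_RATE,
                 arrival: float = 1.0, tau: float = 0.596,
                 amplitude: float = 1.0, baseline: float = 1.0,
                 noise_sd_frac: float = 0.1, red_ramp: float = 0.02,
                 red_noise_sd: float = 0.02, mixing_time: float = 0.0):
    """Dual-channel 550-Hz line scan with mono-exponential membrane rise.

    Membrane pixels rise as amplitude·(1 − e^(−(t−arrival)/τ)) after the
    ligand arrives; cytosol pixels stay flat; the red channel steps to 1
    over ``red_ramp`` seconds at the arrival time.  A nonzero
    ``mixing_time`` emulates slow bath exchange: the green response is
    smeared by a moving average of that width and the red-dye front takes
    equally long to arrive, so such trials fail the dye-latency gate.

    Returns ``(LineScanRecording, truth_dict)``.
    """
    if not 0 <= arrival < duration:
        raise ValueError("arrival outside the recording")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    rng = stream_rng(seed, "linescan")
    n_t = int(round(duration * sampling_rate))
    t = np.arange(n_t) / sampling_rate
    n_mem = int(round(membrane_frac * n_pixels))
    is_mem = np.zeros(n_pixels, dtype=bool)
    is_mem[rng.permutation(n_pixels)[:n_mem]] = True

    green = np.full((n_pixels, n_t), baseline)
    rise = amplitude * (1.0 - np.exp(-np.maximum(t - arrival, 0.0) / tau))
    rise[t < arrival] = 0.0
    if mixing_time > 0:
        k = max(1, int(round(mixing_time * sampling_rate)))
        rise = np.convolve(rise, np.ones(k) / k, mode="full")[:n_t]
    green[is_mem] += rise
    green += rng.normal(0.0, noise_sd_frac * amplitude,
                        size=green.shape)

    red_ramp = max(red_ramp, mixing_time)
    red_step = np.clip((t - arrival) / max(red_ramp, 1e-9), 0.0, 1.0)
    red = np.tile(red_step, (n_pixels, 1))
    red += rng.normal(0.0, red_noise_sd, size=red.shape)

    rec = LineScanRecording(green=green, red=red,
                            sampling_rate=sampling_rate)
    truth = {"tau": tau, "arrival": arrival, "membrane_mask": is_mem,
             "amplitude": amplitude}
    return rec, truth


def gen_cell_trace(seed: int, n_cells: int = 1, baseline: float = 2.0,
                   plateau_dff: float = 9.06, n_baseline: int = 10,
                   n_plateau: int = 30, rise_samples: int = 5,
                   sampling_rate: float = 1.0, noise_frac: float = 0.05):
    """In vitro cell traces: ten-point pre-ligand baseline, then a plateau.

    Emulates epifluorescence time-lapse of sensor-expressing cells:
    ``n_baseline`` samples at ``baseline`` fluorescence, a short rise, and
    ``n_plateau`` samples at baseline·(1 + plateau_dff), all with
    multiplicative Gaussian noise of fraction ``noise_frac``.

    Returns ``(list of FluorescenceTrace, truth_dict)``; the ligand
    arrives at sample index ``n_baseline`` (time n_baseline/rate).
    """
    if plateau_dff <= -1:
        raise ValueError("plateau_dff must exceed -1")
    rng = stream_rng(seed, "cell_trace")
    plateau = baseline * (1.0 + plateau_dff)
    ramp = np.linspace(baseline, plateau, rise_samples + 2)[1:-1]
    clean = np.concatenate([np.full(n_baseline, baseline), ramp,
                            np.full(n_plateau, plateau)])
    traces = []
    for _ in range(n_cells):
        noisy = clean * (1.0 + rng.normal(0.0, noise_frac,
                                          size=clean.shape))
        traces.append(FluorescenceTrace(values=noisy,
                                        sampling_rate=sampling_rate))
    truth = {"plateau_dff": plateau_dff, "baseline": baseline,
             "event_index": n_baseline,
             "plateau_start_index": n_baseline + rise_samples}
    return traces, truth


def gen_dose_response(seed: int, ec50: float = 75e-9, hill: float = 1.0,
                      top: float = 1.0, bottom: float = 0.0,
                      n_doses: int = 8, decades: float = 4.0,
                      noise_frac: float = 0.1):
    """Logistic titration: ``n_doses`` log-spaced over ``decades`` decades
    centred on the EC₅₀, with multiplicative Gaussian noise.

    Returns ``(doses, responses, truth_dict)``; doses in mol/L.
    """
    if n_doses < 4:
        raise ValueError("need at least 4 doses")
    rng = stream_rng(seed, "dose_response")
    log_c = np.log10(ec50)
    doses = np.logspace(log_c - decades / 2.0, log_c + decades / 2.0,
                        n_doses)
    clean = bottom + (top - bottom) / (1.0 + (ec50 / doses) ** hill)
    responses = clean * (1.0 + rng.normal(0.0, noise_frac, size=n_doses))
    truth = {"ec50": ec50, "hill": hill, "top": top, "bottom": bottom}
    return doses, responses, truth


def gen_hypnogram(seed: int, duration: float = 3600.0,
                  epoch_length: float = 1.0,
                  mean_dwell=None, min_dwell: float = 30.0,
                  rem_probability: float = 0.6,
                  wake_level: float = 0.30, nrem_level: float = 0.28,
                  rem_drop: float = 0.20, sampling_rate: float = 10.0,
                  noise_sd: float = 0.0, fixed_state=None):
    """Hypnogram plus a state-modulated ΔF/F₀ trace.

    States cycle wake → NREM → (REM → wake with probability
    ``rem_probability``, else back to wake); dwell times are exponential
    with the given means, floored at ``min_dwell``.  The paired trace sits
    at ``wake_level`` in wake, ``nrem_level`` in NREM and drops by
    ``rem_drop`` at REM onset, recovering at REM offset — the rapid
    decrease/rebound seen across REM episodes.

    Returns ``(Hypnogram, DffTrace, truth_dict)``.
    """
    if mean_dwell is None:
        mean_dwell = {"wake": 120.0, "NREM": 180.0, "REM": 60.0}
    for s, m in mean_dwell.items():
        if s not in ("wake", "NREM", "REM"):
            raise ValueError(f"invalid state name {s!r}")
        if m < epoch_length:
            raise ValueError("dwell means must be >= one epoch")
    rng = stream_rng(seed, "hypnogram")
    n_epochs = int(round(duration / epoch_length))
    if fixed_state is not None:
        if fixed_state not in ("wake", "NREM", "REM"):
            raise ValueError(f"invalid state name {fixed_state!r}")
    states = []
    state = fixed_state or "wake"
    while len(states) < n_epochs:
        dwell = max(min_dwell, rng.exponential(mean_dwell[state]))
        states.extend([state] * max(1, int(round(dwell / epoch_length))))
        if fixed_state is not None:
            continue
        if state == "wake":
            state = "NREM"
        elif state == "NREM":
            state = "REM" if rng.random() < rem_probability else "wake"
        else:
            state = "wake"
    states = states[:n_epochs]
    hyp = Hypnogram(states=states, epoch_length=epoch_length)

    levels = {"wake": wake_level, "NREM": nrem_level,
              "REM": nrem_level - rem_drop}
    n_samples = int(round(duration * sampling_rate))
    t = np.arange(n_samples) / sampling_rate
    k = np.clip((t / epoch_length).astype(int), 0, n_epochs - 1)
    values = np.array([levels[states[i]] for i in k])
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_samples)
    dff = DffTrace(values=values, sampling_rate=sampling_rate, t0=0.0,
                   baseline_value=1.0)
    truth = {"levels": levels, "rem_drop": rem_drop, "states": states}
    return hyp, dff, truth
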