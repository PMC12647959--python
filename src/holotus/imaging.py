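"""Widefield calcium-imaging analysis pipeline.

Processes fluorescence movies of ultrasound-evoked cortical activity into
dF/F responses, maps and metrics. The processing order is fixed (and
enforced by :func:`process_movie`):

1. per-pixel temporal Kalman filtering,
2. moving-percentile baseline -> dF/F (removes bleaching/drift),
3. stimulus-locked cycle averaging,
4. spatial Gaussian smoothing,
5. trace extraction at the target pixel,
6. fluorothermal (FTT) dip correction,
7. temporal Savitzky-Golay smoothing (always after the FTT correction).

dF/F values are expressed in percent throughout; times are anchored to the
stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import ndimage, signal
from scipy.interpolate import interp1d
from skimage.segmentation import flood

from . import thermal

__all__ = [
    "Movie",
    "ActivationResult",
    "PipelineResult",
    "PIPELINE_ORDER",
    "kalman_filter",
    "moving_baseline_dff",
    "cycle_average",
    "smooth_movie",
    "smooth_trace",
    "activated_area",
    "response_metrics",
    "process_movie",
]


@dataclass
class Movie:
    """A T x H x W fluorescence stack with acquisition metadata.

    ``frames`` may hold raw fluorescence (counts) or dF/F in percent,
    depending on the pipeline stage. ``stimulus_starts`` are frame indices
    of ultrasound pulse onsets.
    """

    frames: np.ndarray
    frame_rate: float = 20.0        # Hz
    pixel_size_um: float = 40.0
    stimulus_starts: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int))
    pulse_duration_s: float = 0.15

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W stack")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.stimulus_starts = np.asarray(self.stimulus_starts, dtype=int)
        if self.stimulus_starts.size and not (
                (self.stimulus_starts >= 0).all()
                and (self.stimulus_starts < self.n_frames).all()):
            raise ValueError("stimulus starts must lie within the movie")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def with_frames(self, frames: np.ndarray, **updates) -> "Movie":
        return replace(self, frames=frames, **updates)


def kalman_filter(movie: Movie, gain: float = 0.5) -> Movie:
    """Causal per-pixel recursive temporal filter.

    ``x_hat[t] = gain * x_hat[t-1] + (1 - gain) * x[t]`` seeded with the
    first frame — a fixed-gain steady-state Kalman smoother of the kind
    used for streak-noise suppression in calcium stacks.
    """
    if not 0.0 < gain < 1.0:
        raise ValueError("gain must be in (0, 1)")
    x = movie.frames
    # direct-form IIR: y[t] - gain*y[t-1] = (1-gain) x[t], with y[0] = x[0]
    zi = gain * x[:1]
    y, _ = signal.lfilter([1.0 - gain], [1.0, -gain], x, axis=0, zi=zi)
    return movie.with_frames(y)


def moving_baseline_dff(movie: Movie, percentile: float = 10.0,
                        window_frames: int = 500) -> Movie:
    """dF/F (percent) against a moving low-percentile baseline.

    F0 is the per-pixel ``percentile`` of each non-overlapping
    ``window_frames`` segment, interpolated linearly between segment
    centres (held constant beyond the outermost centres). Removes slow
    drifts such as photobleaching and excitation-power fluctuations.
    """
    if movie.n_frames < 1:
        raise ValueError("empty movie")
    x = movie.frames
    n_seg = max(1, movie.n_frames // window_frames)
    bounds = np.linspace(0, movie.n_frames, n_seg + 1).astype(int)
    centres = (bounds[:-1] + bounds[1:] - 1) / 2.0
    seg_p = np.stack([
        np.percentile(x[b0:b1], percentile, axis=0)
        for b0, b1 in zip(bounds[:-1], bounds[1:])])
    if n_seg == 1:
        f0 = np.broadcast_to(seg_p[0], x.shape)
    else:
        f0 = interp1d(centres, seg_p, axis=0, bounds_error=False,
                      fill_value=(seg_p[0], seg_p[-1]))(
                          np.arange(movie.n_frames))
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 <= 0: not a valid raw-fluorescence "
                         "movie")
    return movie.with_frames(100.0 * (x - f0) / f0)


def cycle_average(movie: Movie, period_s: float = 10.0,
                  n_cycles: int = 20) -> Movie:
    """Average ``n_cycles`` stimulus-locked cycles into one period.

    Cycles start at each stimulus onset; the result is a single-period
    stack whose frame 0 is the stimulus onset. Raises if the stimulus
    schedule does not match the stated period or runs past the movie end.
    """
    fpc = period_s * movie.frame_rate
    if abs(fpc - round(fpc)) > 1e-9:
        raise ValueError("period is not an integer number of frames")
    fpc = int(round(fpc))
    starts = movie.stimulus_starts
    if len(starts) < n_cycles:
        raise ValueError(f"need {n_cycles} stimulus onsets, "
                         f"got {len(starts)}")
    starts = starts[:n_cycles]
    if n_cycles > 1 and not np.all(np.diff(starts) == fpc):
        raise ValueError("stimulus onsets are not spaced by the stated "
                         "period")
    if starts[-1] + fpc > movie.n_frames:
        raise ValueError("last cycle runs past the end of the movie")
    stack = np.mean([movie.frames[s:s + fpc] for s in starts], axis=0)
    return movie.with_frames(stack, stimulus_starts=np.array([0]))


def smooth_movie(movie: Movie, spatial_sigma_px: float = 3.0) -> Movie:
    """Per-frame spatial Gaussian smoothing (sigma in pixels)."""
    if spatial_sigma_px < 0:
        raise ValueError("sigma must be non-negative")
    out = ndimage.gaussian_filter(movie.frames,
                                  sigma=(0.0, spatial_sigma_px,
                                         spatial_sigma_px))
    return movie.with_frames(out)


def smooth_trace(trace: np.ndarray, order: int = 2,
                 length: int = 11) -> np.ndarray:
    """Temporal Savitzky-Golay smoothing of a 1-D trace."""
    if length % 2 == 0 or length <= order:
        raise ValueError("length must be odd and exceed the order")
    return signal.savgol_filter(np.asarray(trace, dtype=float), length,
                                order)


@dataclass
class ActivationResult:
    """Flood-fill activated area around a seed pixel."""

    area_mm2: float
    pixels: np.ndarray          # boolean H x W membership mask
    seed: tuple[int, int]
    threshold_pct: float
    trace: np.ndarray           # dF/F trace (percent) at the seed pixel

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


def activated_area(dff_movie: Movie, seed_point: tuple[int, int],
                   threshold: float = 0.5,
                   window_s: tuple[float, float] = (0.46, 1.0)
                   ) -> ActivationResult:
    """Activated cortical area from a dF/F movie (percent units).

    A pixel qualifies if its dF/F exceeds ``threshold`` percent at any time
    within ``window_s`` (seconds after the stimulus onset); the activated
    area is the 4-connected flood-fill component of qualifying pixels
    containing the seed. A sub-threshold seed yields an empty area.
    """
    if not dff_movie.stimulus_starts.size:
        raise ValueError("movie has no stimulus schedule")
    start = int(dff_movie.stimulus_starts[0])
    row, col = int(seed_point[0]), int(seed_point[1])
    h, w = dff_movie.frames.shape[1:]
    if not (0 <= row < h and 0 <= col < w):
        raise ValueError("seed outside the frame")
    f0 = start + int(round(window_s[0] * dff_movie.frame_rate))
    f1 = start + int(round(window_s[1] * dff_movie.frame_rate))
    if f1 >= dff_movie.n_frames:
        raise ValueError("analysis window runs past the end of the movie")
    peak_map = dff_movie.frames[f0:f1 + 1].max(axis=0)
    supra = peak_map > threshold
    trace = dff_movie.frames[:, row, col]
    if not supra[row, col]:
        mask = np.zeros_like(supra)
    else:
        mask = flood(supra, (row, col), connectivity=1) & supra
    area = mask.sum() * (dff_movie.pixel_size_um / 1e3) ** 2
    return ActivationResult(area_mm2=float(area), pixels=mask,
                            seed=(row, col), threshold_pct=threshold,
                            trace=trace)


def response_metrics(trace: np.ndarray, times: np.ndarray,
                     stimulus_start: float,
                     auc_window: tuple[float, float] = (0.45, 2.0)
                     ) -> dict[str, float]:
    """AUC, peak dF/F and time-to-peak of an evoked response trace.

    AUC is the trapezoidal integral over ``auc_window`` seconds after the
    stimulus start (trace linearly interpolated at the window edges); peak
    and time-to-peak are taken over everything after the start.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    t0, t1 = (stimulus_start + auc_window[0], stimulus_start + auc_window[1])
    if t0 < times[0] or t1 > times[-1]:
        raise ValueError("AUC window exceeds the trace extent")
    grid = np.union1d(times[(times >= t0) & (times <= t1)], [t0, t1])
    auc = np.trapezoid(np.interp(grid, times, trace), grid)
    post = times >= stimulus_start
    i_peak = int(np.argmax(trace[post]))
    peak = float(trace[post][i_peak])
    ttp = float(times[post][i_peak] - stimulus_start)
    return {"auc": float(auc), "peak": peak, "time_to_peak": ttp}


#: The enforced processing order of :func:`process_movie`.
PIPELINE_ORDER = ("kalman", "baseline", "cycle_average", "spatial_smooth",
                  "extract_trace", "ftt_correction", "temporal_smooth")


@dataclass
class PipelineResult:
    """End-to-end pipeline output."""

    dff_movie: Movie                # cycle-averaged, smoothed dF/F stack
    trace: np.ndarray               # FTT-corrected, smoothed seed trace (%)
    trace_uncorrected: np.ndarray   # seed trace before FTT correction (%)
    times: np.ndarray               # s, 0 = stimulus onset
    activation: ActivationResult
    metrics: dict[str, float]


def process_movie(movie: Movie, seed_point: tuple[int, int],
                  kalman_gain: float = 0.5,
                  baseline_percentile: float = 10.0,
                  baseline_window: int = 500,
                  period_s: float = 10.0,
                  n_cycles: int | None = None,
                  spatial_sigma_px: float = 3.0,
                  savgol_order: int = 2, savgol_length: int = 11,
                  area_threshold: float = 0.5,
                  ftt_tau: float = thermal.DEFAULT_TAU,
                  apply_ftt: bool = True,
                  _observer: Callable[[str], None] | None = None
                  ) -> PipelineResult:
    """Run the full fixed-order analysis pipeline on a raw movie.

    The FTT correction anchors a reduced-model temperature transient to
    the measured dF/F at the pulse onset and end, then removes the scaled
    dip from the extracted trace; temporal smoothing always comes last.
    ``_observer`` (internal) is called with each stage name as it runs.
    """
    def note(stage: str) -> None:
        if _observer is not None:
            _observer(stage)

    if n_cycles is None:
        n_cycles = len(movie.stimulus_starts)

    note("kalman")
    m = kalman_filter(movie, kalman_gain)
    note("baseline")
    m = moving_baseline_dff(m, baseline_percentile, baseline_window)
    note("cycle_average")
    m = cycle_average(m, period_s=period_s, n_cycles=n_cycles)
    note("spatial_smooth")
    m = smooth_movie(m, spatial_sigma_px)
    note("extract_trace")
    row, col = int(seed_point[0]), int(seed_point[1])
    trace_raw = m.frames[:, row, col].copy()
    times = m.times  # stimulus onset at t = 0 after cycle averaging

    note("ftt_correction")
    if apply_ftt:
        pulse = movie.pulse_duration_s
        i_sppa = np.where(times < pulse, 1.0, 0.0)
        temp = thermal.reduced_temperature(times, i_sppa, tau=ftt_tau,
                                           gain=1.0)
        dff_on = float(np.interp(0.0, times, trace_raw))
        dff_end = float(np.interp(pulse, times, trace_raw))
        corr = thermal.ftt_correction_trace(temp, dff_on, dff_end,
                                            pulse_duration=pulse)
        trace_corr = thermal.apply_ftt_correction(trace_raw, corr)
    else:
        trace_corr = trace_raw.copy()

    note("temporal_smooth")
    trace_smooth = smooth_trace(trace_corr, savgol_order, savgol_length)

    activation = activated_area(m, seed_point, threshold=area_threshold)
    metrics = response_metrics(trace_smooth, times, stimulus_start=0.0)
    return PipelineResult(dff_movie=m, trace=trace_smooth,
                          trace_uncorrected=trace_raw, times=times,
                          activation=activation, metrics=metrics)
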