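"""Synthetic data with full ground truth.

Generates the two kinds of inputs the analysis consumes:

* :func:`generate_movie` — widefield calcium movies with the statistical
  structure of the real recordings: slow anaesthesia-related resting-state
  background, stimulus-locked evoked dF/F transients with a focal spatial
  footprint, a negative fluorothermal dip during the ultrasound pulse,
  exponential photobleaching, and pixel noise. Every component is returned
  separately so pipeline-recovery tests have exact ground truth.
* :func:`generate_activation_dataset` — (configuration, pressure) dose-
  response tables drawn from a known excitability model, for fitting and
  parameter-recovery tests of the empirical excitation model.

Identical specs and seeds produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .imaging import Movie
from .usem import (ConfigurationFields, ExcitabilitySpec, SigmoidFit,
                   excitability_map, integrate_focal_plane)

__all__ = [
    "SyntheticMovieSpec",
    "GroundTruth",
    "generate_movie",
    "generate_activation_dataset",
]


@dataclass(frozen=True)
class SyntheticMovieSpec:
    """Generative description of a synthetic widefield recording.

    Amplitudes are in percent dF/F; the acquisition geometry and stimulus
    schedule default to the experimental protocol (20 stimuli at 10 s
    intervals, 150 ms pulses, 20 frames/s, 40 um pixels).
    """

    height: int = 64
    width: int = 64
    pixel_size_um: float = 40.0
    frame_rate: float = 20.0
    n_stimuli: int = 20
    period_s: float = 10.0
    pulse_s: float = 0.15
    first_stimulus_s: float = 2.0
    # evoked response: focal Gaussian footprint, fast-rise/slow-decay kernel
    evoked_centre: tuple[int, int] | None = None   # (row, col); None = middle
    evoked_sigma_um: float = 400.0
    evoked_peak_pct: float = 2.0
    evoked_rise_s: float = 0.3
    evoked_decay_s: float = 1.0
    # anaesthesia resting-state background: smooth in space, slow in time
    rest_amp_pct: float = 0.8
    rest_corner_hz: float = 0.15
    rest_corr_um: float = 400.0
    # fluorothermal dip during the pulse
    dip_depth_pct: float = 0.5
    dip_tau_s: float = 0.1
    dip_sigma_um: float = 300.0
    # photobleaching and acquisition noise
    baseline_counts: float = 1000.0
    bleach_tau_s: float = 2000.0
    noise_std_counts: float = 5.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        lead = self.first_stimulus_s * self.frame_rate
        return int(round(lead + self.n_stimuli * self.period_s
                         * self.frame_rate))

    @property
    def stimulus_starts(self) -> np.ndarray:
        step = int(round(self.period_s * self.frame_rate))
        first = int(round(self.first_stimulus_s * self.frame_rate))
        return first + step * np.arange(self.n_stimuli)

    @property
    def centre(self) -> tuple[int, int]:
        if self.evoked_centre is not None:
            return self.evoked_centre
        return (self.height // 2, self.width // 2)


@dataclass
class GroundTruth:
    """The noiseless components that built a synthetic movie (percent dF/F,
    T x H x W unless noted); ``baseline`` is the bleach-scaled raw-count
    surface and ``noiseless`` the full movie before noise."""

    evoked: np.ndarray
    resting: np.ndarray
    dip: np.ndarray
    bleach: np.ndarray              # (T,), multiplicative
    baseline: np.ndarray            # (T, H, W), counts
    noiseless: np.ndarray           # (T, H, W), counts
    evoked_peak_pct: float
    evoked_peak_time_s: float
    centre: tuple[int, int]


def _gaussian_footprint(spec: SyntheticMovieSpec, sigma_um: float
                        ) -> np.ndarray:
    rows = np.arange(spec.height)[:, None] - spec.centre[0]
    cols = np.arange(spec.width)[None, :] - spec.centre[1]
    sigma_px = sigma_um / spec.pixel_size_um
    return np.exp(-(rows**2 + cols**2) / (2.0 * sigma_px**2))


def _evoked_kernel(spec: SyntheticMovieSpec, times: np.ndarray
                   ) -> tuple[np.ndarray, float]:
    """Difference-of-exponentials calcium-indicator kernel, peak 1."""
    k = np.where(times >= 0,
                 np.exp(-times / spec.evoked_decay_s)
                 - np.exp(-times / np.minimum(spec.evoked_rise_s,
                                              0.99 * spec.evoked_decay_s)),
                 0.0)
    peak_t = float(times[np.argmax(k)])
    return k / k.max(), peak_t


def _dip_kernel(spec: SyntheticMovieSpec, times: np.ndarray) -> np.ndarray:
    """First-order heating/cooling transient of the pulse, peak 1."""
    rise = 1.0 - np.exp(-np.clip(times, 0.0, spec.pulse_s) / spec.dip_tau_s)
    peak = 1.0 - np.exp(-spec.pulse_s / spec.dip_tau_s)
    decay = np.where(times > spec.pulse_s,
                     np.exp(-(times - spec.pulse_s) / spec.dip_tau_s), 1.0)
    return np.where(times >= 0, rise * decay / peak, 0.0)


def generate_movie(spec: SyntheticMovieSpec) -> tuple[Movie, GroundTruth]:
    """Synthesize a raw-count movie plus its exact ground truth.

    The generative model is
    ``F = baseline * bleach(t) * (1 + (rest + evoked - dip)/100) + noise``
    with all dF/F components in percent of the local baseline.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.n_frames
    times = np.arange(T) / spec.frame_rate

    # evoked component: kernel per stimulus x spatial footprint
    ev_t = np.zeros(T)
    kernel, peak_t = _evoked_kernel(spec, times)
    for s in spec.stimulus_starts:
        span = T - s
        ev_t[s:] += kernel[:span]
    evoked = (spec.evoked_peak_pct * ev_t[:, None, None]
              * _gaussian_footprint(spec, spec.evoked_sigma_um))

    # fluorothermal dip: same schedule, focal footprint, negative in F
    dip_t = np.zeros(T)
    dipk = _dip_kernel(spec, times)
    for s in spec.stimulus_starts:
        span = T - s
        dip_t[s:] += dipk[:span]
    dip = (spec.dip_depth_pct * dip_t[:, None, None]
           * _gaussian_footprint(spec, spec.dip_sigma_um))

    # resting state: white noise low-passed in time, smoothed in space
    if spec.rest_amp_pct > 0:
        raw = rng.standard_normal((T, spec.height, spec.width))
        sos = signal.butter(2, spec.rest_corner_hz,
                            fs=spec.frame_rate, output="sos")
        rest = signal.sosfiltfilt(sos, raw, axis=0)
        corr_px = spec.rest_corr_um / spec.pixel_size_um
        rest = ndimage.gaussian_filter(rest, sigma=(0.0, corr_px, corr_px))
        rest *= spec.rest_amp_pct / rest.std()
    else:
        rest = np.zeros((T, spec.height, spec.width))

    bleach = np.exp(-times / spec.bleach_tau_s)
    baseline = spec.baseline_counts * bleach[:, None, None] * np.ones(
        (1, spec.height, spec.width))
    noiseless = baseline * (1.0 + (rest + evoked - dip) / 100.0)
    frames = noiseless + spec.noise_std_counts * rng.standard_normal(
        noiseless.shape)

    movie = Movie(frames=frames, frame_rate=spec.frame_rate,
                  pixel_size_um=spec.pixel_size_um,
                  stimulus_starts=spec.stimulus_starts,
                  pulse_duration_s=spec.pulse_s)
    truth = GroundTruth(evoked=evoked, resting=rest, dip=dip, bleach=bleach,
                        baseline=baseline, noiseless=noiseless,
                        evoked_peak_pct=spec.evoked_peak_pct,
                        evoked_peak_time_s=peak_t, centre=spec.centre)
    return movie, truth


def generate_activation_dataset(
        fields: Mapping[str, ConfigurationFields],
        pressures: Mapping[str, Sequence[float]] | Sequence[float],
        spec: ExcitabilitySpec | None = None,
        sigmoid: SigmoidFit | None = None,
        response_scale: float = 3.0,
        sem: float = 0.05,
        seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Dose-response table drawn from a known excitation model.

    Responses are ``response_scale * sigmoid(X(configuration, P))`` plus
    zero-mean Gaussian noise of standard deviation ``sem * response_scale``,
    where X is the focal-plane integral of the excitability map. When no
    sigmoid is given, its midpoint is placed at the median X of the design
    (steepness 4/midpoint), which centres the dose-response transition
    inside the sampled pressure range.

    Returns the dataset and a ground-truth dict with the generating
    ``spec``, ``sigmoid``, ``response_scale`` and per-row ``x`` values.
    """
    spec = spec or ExcitabilitySpec(descriptor="force")
    if not isinstance(pressures, Mapping):
        pressures = {name: pressures for name in fields}
    rows = []
    for name, plist in pressures.items():
        for p in plist:
            x = integrate_focal_plane(
                excitability_map(fields[name], spec, float(p)),
                fields[name].pixel_area)
            rows.append({"configuration": name, "pressure_mpa": float(p),
                         "x": x})
    table = pd.DataFrame(rows)
    if sigmoid is None:
        mid = float(np.median(table["x"]))
        sigmoid = SigmoidFit(midpoint=mid, steepness=4.0 / mid)
    rng = np.random.default_rng(seed)
    clean = response_scale * np.asarray(sigmoid(table["x"].to_numpy()))
    noisy = clean + sem * response_scale * rng.standard_normal(len(clean))
    data = table.assign(response=noisy, sem=sem * response_scale)[
        ["configuration", "pressure_mpa", "response", "sem"]]
    truth = {"spec": spec, "sigmoid": sigmoid,
             "response_scale": response_scale,
             "x": table["x"].to_numpy(), "clean_response": clean}
    return data, truth
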