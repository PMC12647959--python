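"""Ultrasound excitation model (USEM).

An empirical dose-response model that maps simulated acoustic field
descriptors to an activation probability. A pointwise *excitability*
function of one descriptor (peak pressure, radiation-force density, or
intensity as a temperature proxy) is evaluated on the focal plane, giving
an activation probability density (APD) map; the map is integrated over a
3 x 3 mm^2 window and the integral drives a logistic activation
probability. A single parameter set is fitted jointly across stimulation
configurations (single focus and holographic patterns), so differences in
predicted thresholds arise purely from the field geometry.

The model/fit interface follows the statsmodels convention:
``UltrasoundExcitationModel(data, fields, spec).fit()`` returns a
:class:`USEMResults` carrying parameters, fit diagnostics, ``summary()``
and ``plot()``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import acoustics as ac

__all__ = [
    "ExcitabilitySpec",
    "ConfigurationFields",
    "SigmoidFit",
    "USEMResults",
    "UltrasoundExcitationModel",
    "configuration_fields",
    "excitability_map",
    "integrate_focal_plane",
    "activation_probability",
    "fit_usem",
    "unified_force_threshold",
    "validate_activation_dataset",
]

DESCRIPTORS = ("pressure", "force", "intensity")
#: Field-descriptor scaling with drive pressure: |p| is linear in the focal
#: calibration pressure, while force density and intensity are quadratic.
_PRESSURE_EXPONENT = {"pressure": 1, "force": 2, "intensity": 2}


@dataclass(frozen=True)
class ExcitabilitySpec:
    """Pointwise excitability transfer function for one field descriptor.

    ``threshold_linear``: ``E(D) = max(D - threshold, 0)``;
    ``power``: ``E(D) = max(D - threshold, 0) ** exponent``.
    Both are non-negative and non-decreasing in the descriptor ``D``.
    """

    descriptor: str = "force"
    transfer: str = "threshold_linear"
    threshold: float = 0.0
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.descriptor not in DESCRIPTORS:
            raise ValueError(f"unknown descriptor {self.descriptor!r}; "
                             f"expected one of {DESCRIPTORS}")
        if self.transfer not in ("threshold_linear", "power"):
            raise ValueError(f"unknown transfer {self.transfer!r}")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")

    def apply(self, descriptor_map: np.ndarray) -> np.ndarray:
        e = np.clip(descriptor_map - self.threshold, 0.0, None)
        if self.transfer == "power" and self.exponent != 1.0:
            e = e ** self.exponent
        return e


@dataclass(frozen=True)
class ConfigurationFields:
    """Unit-drive focal-plane descriptor maps of one stimulation pattern.

    Maps are stored at a focal calibration pressure of 1 MPa; at drive
    pressure ``P`` (MPa) the pressure map scales by ``P`` and the force /
    intensity maps by ``P**2``.

    Attributes
    ----------
    pressure_map : |p| on the focal plane at 1 MPa calibration, MPa
    force_map : radiation-force density magnitude at 1 MPa, N/m^3
    intensity_map : I_SPPA at 1 MPa, W/cm^2
    beam_force : total beam radiation force (momentum budget P_ac/c)
        at 1 MPa, N
    pixel_area : focal-plane pixel area, m^2
    """

    name: str
    pressure_map: np.ndarray
    force_map: np.ndarray
    intensity_map: np.ndarray
    beam_force: float
    pixel_area: float

    def descriptor_map(self, descriptor: str, pressure_mpa: float
                       ) -> np.ndarray:
        base = {"pressure": self.pressure_map, "force": self.force_map,
                "intensity": self.intensity_map}.get(descriptor)
        if base is None:
            raise ValueError(f"unknown descriptor {descriptor!r}")
        return base * pressure_mpa ** _PRESSURE_EXPONENT[descriptor]

    def total_force(self, pressure_mpa: float) -> float:
        """Beam momentum-budget radiation force at ``pressure_mpa`` (N)."""
        return self.beam_force * pressure_mpa**2


def configuration_fields(geometry: ac.ArrayGeometry,
                         pattern: str = "single",
                         pattern_radius: float = 0.5e-3,
                         medium: ac.Medium = ac.BRAIN,
                         plane_extent: float = 6e-3,
                         spacing: float = 40e-6,
                         seed: int = 0,
                         name: str | None = None) -> ConfigurationFields:
    """Synthesize the focal-plane descriptor maps of one configuration.

    The field is calibrated to 1 MPa peak pressure on the plane; descriptor
    maps at other drives follow from the linear/quadratic scalings.
    """
    holo = ac.make_hologram(geometry, pattern, pattern_radius, seed=seed)
    plane = ac.Grid.centred((plane_extent, plane_extent, 0.0), spacing)
    fld = ac.synthesize_field(geometry, holo, plane, medium,
                              focal_pressure=1e6, compute_velocity=True)
    force = ac.radiation_force(fld, method="absorption")
    f_mag = np.linalg.norm(force.force_density, axis=-1)[:, :, 0]
    i_map = fld.intensity()[:, :, 0] / 1e4  # W/cm^2
    p_map = fld.amplitude[:, :, 0] / 1e6    # MPa
    # windowed to the same 3 x 3 mm focal region as the APD integral, so
    # the total-force and excitability descriptions stay consistent
    beam_f = ac.beam_momentum_force(fld, window=3e-3)
    if name is None:
        name = pattern if pattern == "single" else (
            f"{pattern}-{pattern_radius * 1e3:g}")
    return ConfigurationFields(
        name=name, pressure_map=p_map, force_map=f_mag,
        intensity_map=i_map, beam_force=beam_f,
        pixel_area=plane.spacing[0] * plane.spacing[1])


def excitability_map(fields: ConfigurationFields, spec: ExcitabilitySpec,
                     pressure_mpa: float) -> np.ndarray:
    """Activation probability density (APD) map on the focal plane:
    the excitability transfer applied pointwise to the chosen descriptor
    at the given drive pressure."""
    return spec.apply(fields.descriptor_map(spec.descriptor, pressure_mpa))


def integrate_focal_plane(apd_map: np.ndarray, pixel_area: float,
                          window: float = 3e-3) -> float:
    """Riemann integral of an APD map over a centred square window.

    ``window`` is the side length (m) of the integration area (default the
    3 x 3 mm^2 focal window); raises if it exceeds the map extent.
    """
    ny, nx = apd_map.shape
    pixel = np.sqrt(pixel_area)
    n_px = max(1, int(round(window / pixel)))
    if n_px > min(ny, nx):
        raise ValueError(
            f"integration window {window * 1e3:g} mm exceeds the "
            f"{min(ny, nx) * pixel * 1e3:g} mm focal-plane map")
    cy, cx = ny // 2, nx // 2
    y0, x0 = cy - n_px // 2, cx - n_px // 2
    y0 = int(np.clip(y0, 0, ny - n_px))
    x0 = int(np.clip(x0, 0, nx - n_px))
    sub = apd_map[y0:y0 + n_px, x0:x0 + n_px]
    return float(sub.sum() * pixel_area)


@dataclass(frozen=True)
class SigmoidFit:
    """Logistic activation probability in the integrated descriptor X:
    ``p(X) = floor + (ceiling - floor) / (1 + exp(-k (X - x0)))``."""

    midpoint: float        # x0, units of X
    steepness: float       # k, 1/units of X
    floor: float = 0.0
    ceiling: float = 1.0
    mse: float = np.nan

    def __post_init__(self) -> None:
        if self.ceiling <= self.floor:
            raise ValueError("ceiling must exceed floor")

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        z = self.steepness * (np.asarray(x, dtype=float) - self.midpoint)
        return self.floor + (self.ceiling - self.floor) / (
            1.0 + np.exp(-np.clip(z, -700.0, 700.0)))


def activation_probability(x: float | np.ndarray, fit: SigmoidFit
                           ) -> float | np.ndarray:
    """Logistic activation probability at integrated descriptor value X."""
    out = fit(x)
    return float(out) if np.isscalar(x) else out


def validate_activation_dataset(data: pd.DataFrame) -> pd.DataFrame:
    """Check the (configuration, pressure_mpa, response, sem) table."""
    required = {"configuration", "pressure_mpa", "response"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"activation dataset missing columns {sorted(missing)}")
    if "sem" not in data.columns:
        data = data.assign(sem=0.0)
    if (data["pressure_mpa"] <= 0).any():
        raise ValueError("pressures must be positive")
    if not np.isfinite(data["response"]).all():
        raise ValueError("responses must be finite")
    return data


class UltrasoundExcitationModel:
    """Joint sigmoid dose-response model over stimulation configurations.

    Parameters
    ----------
    data : activation dataset with columns ``configuration``,
        ``pressure_mpa``, ``response`` (peak dF/F, %), optional ``sem``.
    fields : mapping from configuration name to its
        :class:`ConfigurationFields`.
    spec : excitability transfer specification; its ``threshold`` is a free
        parameter of the fit (the spec value serves as the initial guess).

    Responses are normalized to [0, 1] by the dataset maximum before
    fitting; the sigmoid floor is fixed at 0 and the ceiling is fitted.
    """

    def __init__(self, data: pd.DataFrame,
                 fields: Mapping[str, ConfigurationFields],
                 spec: ExcitabilitySpec | None = None) -> None:
        self.data = validate_activation_dataset(
            pd.DataFrame(data).reset_index(drop=True))
        self.spec = spec or ExcitabilitySpec()
        self.fields = dict(fields)
        configs = set(self.data["configuration"])
        unknown = configs - set(self.fields)
        if unknown:
            raise ValueError(f"no fields provided for {sorted(unknown)}")
        if len(configs) < 2:
            raise ValueError("need at least 2 configurations")
        if len(self.data) < 4:
            raise ValueError("need at least 4 (configuration, pressure) rows")

    # -- descriptor integrals ----------------------------------------------

    def integrated_descriptor(self, configuration: str, pressure_mpa: float,
                              threshold: float | None = None) -> float:
        """X(configuration, P): focal-plane integral of the APD map."""
        spec = self.spec if threshold is None else replace(
            self.spec, threshold=threshold)
        fields = self.fields[configuration]
        apd = excitability_map(fields, spec, pressure_mpa)
        return integrate_focal_plane(apd, fields.pixel_area)

    def _x_values(self, threshold: float) -> np.ndarray:
        return np.array([
            self.integrated_descriptor(row.configuration, row.pressure_mpa,
                                       threshold)
            for row in self.data.itertuples()])

    # -- fitting -------------------------------------------------------------

    def fit(self, n_restarts: int = 10, seed: int = 0) -> "USEMResults":
        """Bounded nonlinear least squares with random restarts.

        Free parameters: descriptor threshold theta, sigmoid midpoint x0 and
        steepness k (both fitted in log space), and the ceiling.
        """
        resp = self.data["response"].to_numpy(dtype=float)
        norm = resp.max()
        if norm <= 0:
            raise ValueError("responses must contain positive values")
        y = resp / norm

        # descriptor/X scale references for initialization and bounds
        d_ref = max(float(self.fields[r.configuration].descriptor_map(
            self.spec.descriptor, r.pressure_mpa).max())
            for r in self.data.itertuples())
        x_ref = max(float(self._x_values(0.0).max()), 1e-30)

        def residuals(params: np.ndarray) -> np.ndarray:
            theta, log_x0, log_k, ceiling = params
            x = self._x_values(theta)
            fit = SigmoidFit(midpoint=np.exp(log_x0),
                             steepness=np.exp(log_k),
                             ceiling=max(ceiling, 1e-6))
            return np.asarray(fit(x)) - y

        rng = np.random.default_rng(seed)
        lo = np.array([0.0, np.log(x_ref) - 12.0, np.log(1.0 / x_ref) - 4.0,
                       0.3])
        hi = np.array([0.9 * d_ref, np.log(x_ref) + 2.0,
                       np.log(1.0 / x_ref) + 12.0, 1.5])
        best = None
        for trial in range(max(1, n_restarts)):
            if trial == 0:
                start = np.array([min(self.spec.threshold, 0.5 * d_ref),
                                  np.log(x_ref / 2), np.log(4.0 / x_ref),
                                  1.0])
            else:
                start = rng.uniform(lo, hi)
            try:
                sol = optimize.least_squares(residuals, start,
                                             bounds=(lo, hi),
                                             xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError(
                f"sigmoid fit failed to converge in all {n_restarts} restarts")
        theta, log_x0, log_k, ceiling = best.x
        mse = float(np.mean(best.fun**2))
        fit = SigmoidFit(midpoint=float(np.exp(log_x0)),
                         steepness=float(np.exp(log_k)),
                         ceiling=float(ceiling), mse=mse)
        return USEMResults(model=self, sigmoid=fit, threshold=float(theta),
                           norm=float(norm), mse=mse)


@dataclass
class USEMResults:
    """Fitted USEM: excitability threshold + sigmoid, with diagnostics."""

    model: UltrasoundExcitationModel
    sigmoid: SigmoidFit
    threshold: float     # fitted descriptor threshold theta
    norm: float          # response normalization (dataset max)
    mse: float

    # -- predictions ---------------------------------------------------------

    def predict(self, configuration: str,
                pressures_mpa: Sequence[float]) -> np.ndarray:
        """Activation probability along a pressure axis."""
        x = np.array([self.model.integrated_descriptor(
            configuration, p, self.threshold) for p in pressures_mpa])
        return np.asarray(self.sigmoid(x))

    def predicted_curves(self, pressures_mpa: Sequence[float] | None = None
                         ) -> pd.DataFrame:
        if pressures_mpa is None:
            pmax = self.model.data["pressure_mpa"].max()
            pressures_mpa = np.linspace(0.05, 1.2 * pmax, 60)
        frames = []
        for cfg in sorted(set(self.model.data["configuration"])):
            frames.append(pd.DataFrame({
                "configuration": cfg, "pressure_mpa": pressures_mpa,
                "probability": self.predict(cfg, pressures_mpa)}))
        return pd.concat(frames, ignore_index=True)

    def threshold_pressure(self, configuration: str,
                           probability: float = 0.5,
                           p_max: float | None = None) -> float:
        """Drive pressure at which the predicted activation probability
        crosses ``probability`` of the fitted ceiling (root-finding on the
        monotone dose-response curve)."""
        if p_max is None:
            p_max = 2.0 * float(self.model.data["pressure_mpa"].max())
        target = probability * self.sigmoid.ceiling

        def f(p: float) -> float:
            return float(self.predict(configuration, [p])[0]) - target

        if f(p_max) < 0:
            raise ValueError(
                f"{configuration}: probability {probability} not reached "
                f"below {p_max:g} MPa (sigmoid midpoint outside the "
                "simulated pressure range)")
        return float(optimize.brentq(f, 1e-3, p_max, xtol=1e-4))

    def unified_force_threshold(self, probability: float = 0.5
                                ) -> pd.DataFrame:
        """Total beam radiation force at each configuration's predicted
        activation threshold (momentum budget P_ac/c, in mN)."""
        if self.model.spec.descriptor != "force":
            raise ValueError("unified force threshold requires a "
                             "force-descriptor fit")
        rows = []
        for cfg in sorted(set(self.model.data["configuration"])):
            p_thr = self.threshold_pressure(cfg, probability)
            force_mn = self.model.fields[cfg].total_force(p_thr) * 1e3
            rows.append({"configuration": cfg, "threshold_mpa": p_thr,
                         "total_force_mN": force_mn})
        return pd.DataFrame(rows)

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        buf = io.StringIO()
        spec = self.model.spec
        buf.write("Ultrasound excitation model fit\n")
        buf.write("=" * 47 + "\n")
        buf.write(f"descriptor:          {spec.descriptor}\n")
        buf.write(f"transfer:            {spec.transfer}\n")
        buf.write(f"threshold theta:     {self.threshold:.6g}\n")
        buf.write(f"sigmoid midpoint x0: {self.sigmoid.midpoint:.6g}\n")
        buf.write(f"sigmoid steepness k: {self.sigmoid.steepness:.6g}\n")
        buf.write(f"ceiling:             {self.sigmoid.ceiling:.4f}\n")
        buf.write(f"response norm:       {self.norm:.4g}\n")
        buf.write(f"MSE (normalized):    {self.mse:.4e}\n")
        buf.write(f"n rows:              {len(self.model.data)}\n")
        try:
            for cfg in sorted(set(self.model.data["configuration"])):
                p50 = self.threshold_pressure(cfg)
                buf.write(f"P(50%) {cfg:<16s} {p50:.3f} MPa\n")
        except ValueError:
            pass
        return buf.getvalue()

    def plot(self, ax=None):
        """Dose-response data and fitted curves per configuration."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curves = self.predicted_curves()
        for cfg, grp in curves.groupby("configuration"):
            line, = ax.plot(grp["pressure_mpa"],
                            grp["probability"] * self.norm, label=cfg)
            pts = self.model.data[self.model.data["configuration"] == cfg]
            ax.errorbar(pts["pressure_mpa"], pts["response"],
                        yerr=pts["sem"], fmt="o", color=line.get_color())
        ax.set_xlabel("peak pressure (MPa)")
        ax.set_ylabel("peak activation")
        ax.legend()
        return ax


def fit_usem(data: pd.DataFrame,
             fields: Mapping[str, ConfigurationFields],
             spec: ExcitabilitySpec | None = None,
             n_restarts: int = 10, seed: int = 0) -> USEMResults:
    """Functional wrapper: build the model and fit it."""
    return UltrasoundExcitationModel(data, fields, spec).fit(
        n_restarts=n_restarts, seed=seed)


def unified_force_threshold(results: USEMResults,
                            probability: float = 0.5) -> pd.DataFrame:
    """Module-level alias of :meth:`USEMResults.unified_force_threshold`."""
    return results.unified_force_threshold(probability)
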