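"""From fitted currents to heating predictions and B1,rms exposure limits.

Tip heating at a fixed probe point scales with the square of the RMS wire
current: dT = c_implant·I², with c_implant an implant property (valid at a
stated reference B1,rms and slice-to-tip distance). Calibrating c_implant
against fiber-optic thermometry then yields, for any newly measured
current, both a heating prediction and the maximum allowable B1,rms that
keeps the temperature rise below a target threshold:

    B1,rms_thresh = B1,rms_seq · sqrt(dT_thresh / (c_implant · I²)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import ImplantHeatingModel

__all__ = [
    "ImplantCalibration",
    "HeatingObservation",
    "ThermoTimeSeries",
    "process_thermometry",
    "fit_cimplant",
    "predict_dt",
    "b1_threshold",
    "loo_evaluate",
]


@dataclass
class ImplantCalibration:
    """Proportionality constant between squared current and heating.

    Only meaningful at its stated slice-to-tip distance and reference
    B1,rms; currents entering or leaving the calibration must be
    referenced to ``b1_rms_ref``.
    """

    c_implant: float
    b1_rms_ref: float = 2.29
    slice_distance: float = 33.0
    implant_id: str = ""
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.c_implant < 0:
            raise ValueError("c_implant must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "c_implant_k_per_a2": self.c_implant,
            "b1_rms_ref_ut": self.b1_rms_ref,
            "slice_distance_mm": self.slice_distance,
            "implant_id": self.implant_id,
            "r_squared": self.r_squared,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImplantCalibration":
        return cls(
            c_implant=d["c_implant_k_per_a2"],
            b1_rms_ref=d.get("b1_rms_ref_ut", 2.29),
            slice_distance=d.get("slice_distance_mm", 33.0),
            implant_id=d.get("implant_id", ""),
            r_squared=d.get("r_squared"),
        )


@dataclass
class HeatingObservation:
    """One (fitted current, scaled peak temperature rise) pair."""

    i_mri: float
    dt_thermo: float
    config_label: str = ""

    def __post_init__(self) -> None:
        if self.i_mri < 0:
            raise ValueError("i_mri must be nonnegative")
        if not np.isfinite(self.dt_thermo):
            raise ValueError("dt_thermo must be finite")


@dataclass
class ThermoTimeSeries:
    """Uniformly sampled probe temperature recording.

    ``baseline_window`` seconds of pre-exposure recording precede the
    exposure starting at ``exposure_start`` (s, on the same clock as
    ``time``).
    """

    time: np.ndarray
    temperature: np.ndarray
    baseline_window: float = 300.0
    exposure_start: float = 300.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if self.time.shape != self.temperature.shape or self.time.ndim != 1:
            raise ValueError("time and temperature must be matching 1-D arrays")
        if self.time.size > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("sampling must be uniform and increasing")
        if self.baseline_window > self.exposure_start - self.time[0] + 1e-9:
            raise ValueError("baseline must precede the exposure")

    def baseline_corrected(self) -> np.ndarray:
        """Temperature minus the mean over the baseline window."""
        sel = self.time < self.time[0] + self.baseline_window
        if not sel.any():
            raise ValueError("no samples in the baseline window")
        return self.temperature - self.temperature[sel].mean()

    def exposure_segment(self, duration: float | None = None):
        """(t_rel, dT) during exposure, baseline-corrected."""
        corr = self.baseline_corrected()
        sel = self.time >= self.exposure_start
        if duration is not None:
            sel &= self.time < self.exposure_start + duration
        if not sel.any():
            raise ValueError("no samples in the requested exposure window")
        return self.time[sel] - self.exposure_start, corr[sel]


def process_thermometry(
    series: ThermoTimeSeries,
    reference: ThermoTimeSeries,
    scaling_window: float = 20.0,
):
    """Scaled peak temperature rise of one configuration.

    Both recordings are baseline-corrected; the relative heating scale of
    ``series`` versus the strongest-heating ``reference`` configuration is
    the least-squares scalar between the two curves over the first
    ``scaling_window`` seconds of exposure, and the returned value is that
    scale times the reference's peak exposure temperature rise. Using the
    early-time scale rather than each curve's own noisy peak transfers the
    reference's high-SNR peak to weakly heating configurations.

    Returns ``(dt_scaled_peak, scale)``.
    """
    t_s, y_s = series.exposure_segment(scaling_window)
    t_r, y_r = reference.exposure_segment(scaling_window)
    if t_s.size != t_r.size or not np.allclose(t_s, t_r, rtol=1e-6, atol=1e-9):
        raise ValueError("series and reference must share the sampling grid")
    denom = float(np.dot(y_r, y_r))
    if denom == 0:
        raise ValueError("reference shows no heating in the scaling window")
    scale = float(np.dot(y_r, y_s) / denom)
    _, y_full = reference.exposure_segment()
    peak = float(np.max(y_full))
    return scale * peak, scale


def fit_cimplant(
    observations: list[HeatingObservation],
    b1_rms_ref: float = 2.29,
    slice_distance: float = 33.0,
    implant_id: str = "",
) -> ImplantCalibration:
    """Proportional least-squares fit of c_implant from observation pairs.

    Zero-intercept fit of dT on I² (c = Σ dT·I² / Σ I⁴), reporting the R²
    of the proportional model. Requires at least one nonzero current.
    """
    if not observations:
        raise ValueError("no observations")
    i = np.array([o.i_mri for o in observations])
    dt = np.array([o.dt_thermo for o in observations])
    model = ImplantHeatingModel(
        b1_rms_ref=b1_rms_ref, slice_distance=slice_distance, implant_id=implant_id
    ).fit(i, dt)
    return ImplantCalibration(
        c_implant=model.c_implant_,
        b1_rms_ref=b1_rms_ref,
        slice_distance=slice_distance,
        implant_id=implant_id,
        r_squared=model.r_squared_,
    )


def predict_dt(cal: ImplantCalibration, i_mri: float) -> float:
    """Predicted peak temperature rise c_implant·I² (K)."""
    if i_mri < 0:
        raise ValueError("i_mri must be nonnegative")
    return cal.c_implant * i_mri**2


def b1_threshold(
    cal: ImplantCalibration,
    i_mri: float,
    b1_rms_seq: float | None = None,
    dt_thresh: float = 2.0,
) -> float:
    """Maximum allowable B1,rms (µT) for a target temperature rise (K)."""
    model = ImplantHeatingModel(b1_rms_ref=cal.b1_rms_ref)
    model.c_implant_ = cal.c_implant
    return model.b1_threshold(i_mri, b1_rms_seq, dt_thresh)


def loo_evaluate(observations: list[HeatingObservation]) -> dict:
    """Leave-one-out accuracy of current and heating predictions.

    Each observation is evaluated with c_implant fitted from the N−1
    remaining pairs: the current error |I_mri − I_thermo| with
    I_thermo = sqrt(dT_thermo/c), and the heating error
    |c·I_mri² − dT_thermo|. Returns per-observation errors plus medians
    and ranges. All errors are exactly zero on perfectly proportional
    data.
    """
    n = len(observations)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 observations")
    current_err, heating_err, rows = [], [], []
    for k, obs in enumerate(observations):
        rest = [o for j, o in enumerate(observations) if j != k]
        c = fit_cimplant(rest).c_implant
        i_thermo = float(np.sqrt(max(obs.dt_thermo, 0.0) / c)) if c > 0 else np.nan
        dt_mri = c * obs.i_mri**2
        ce = abs(obs.i_mri - i_thermo)
        he = abs(dt_mri - obs.dt_thermo)
        current_err.append(ce)
        heating_err.append(he)
        rows.append(
            {
                "config_label": obs.config_label,
                "i_mri_a": obs.i_mri,
                "dt_thermo_k": obs.dt_thermo,
                "c_loo_k_per_a2": c,
                "i_thermo_a": i_thermo,
                "dt_mri_k": dt_mri,
                "current_error_a": ce,
                "heating_error_k": he,
            }
        )
    current_err = np.array(current_err)
    heating_err = np.array(heating_err)
    return {
        "per_observation": rows,
        "median_current_error_a": float(np.median(current_err)),
        "current_error_range_a": [float(current_err.min()), float(current_err.max())],
        "median_heating_error_k": float(np.median(heating_err)),
        "heating_error_range_k": [float(heating_err.min()), float(heating_err.max())],
    }
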