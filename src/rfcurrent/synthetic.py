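"""Synthetic scenes, noisy patches and thermometry for desk-scale testing.

Emulates the phantom experiments: a straight wire crossing a 2-mm axial
slice of an ASTM-style gel phantom, imaged with the da-hdrAFI protocol at
body-coil SNR, plus fiber-optic probe recordings of tip heating. Noise is
applied to the raw magnitude signals *before* per-voxel normalization,
since normalization is a processing step, not part of acquisition. All
randomness flows from the single recorded seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import PatchGeometry, SignalPatch, _raw_voxel_signals
from .heating import ThermoTimeSeries
from .sequence import SequenceParams, SliceProfileDictionary, default_dictionary
from .wire_model import WireModelParams

__all__ = [
    "SceneSpec",
    "CurrentProfileSpec",
    "generate_patch",
    "generate_profile_scenes",
    "generate_thermometry",
]

#: Default relative noise level: σ of 1/20 of the strongest unperturbed
#: (background-λb) raw signal, i.e. a null-region voxel SNR of 20 on the
#: strongest of the four signals — emulating body-coil reception.
DEFAULT_NOISE_SIGMA = 0.05


@dataclass
class SceneSpec:
    """Ground truth and acquisition settings of one synthetic slice."""

    params: WireModelParams = field(default_factory=WireModelParams)
    geom: PatchGeometry = field(default_factory=PatchGeometry)
    seq: SequenceParams = field(default_factory=SequenceParams)
    t1_true: float = 1000.0
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    noise_model: str = "gaussian"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


@dataclass
class CurrentProfileSpec:
    """Current amplitude sampled at axial slices along the wire."""

    slice_positions: np.ndarray
    profile: np.ndarray

    def __post_init__(self) -> None:
        self.slice_positions = np.asarray(self.slice_positions, dtype=float)
        self.profile = np.asarray(self.profile, dtype=float)
        if self.slice_positions.shape != self.profile.shape:
            raise ValueError("positions and profile must align")
        if np.any(np.diff(self.slice_positions) <= 0):
            raise ValueError("slice positions must be strictly increasing")

    @property
    def n_slices(self) -> int:
        return self.slice_positions.size


def generate_patch(
    spec: SceneSpec, dictionary: SliceProfileDictionary | None = None
):
    """Generate one noisy SignalPatch plus its ground-truth record.

    Synthesizes the noiseless signed voxel-averaged signals, takes
    magnitudes, adds noise with σ = ``noise_sigma`` times the strongest
    unperturbed (background-λb) raw signal — so the default 0.05 gives a
    null-region voxel SNR of 20 on the strongest of the four signals —
    then normalizes and packages with provenance. With ``noise_sigma = 0``
    the result is identical to the noiseless forward model. Deterministic
    per seed.
    """
    if dictionary is None:
        dictionary = default_dictionary(spec.seq, spec.t1_true)
    raw, degenerate = _raw_voxel_signals(
        spec.params, spec.seq, dictionary, spec.geom
    )
    mags = np.abs(raw)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        background = dictionary.lookup(spec.params.background.lambda_b)
        sigma = spec.noise_sigma * float(np.max(np.abs(background)))
        shape = mags.shape
        if spec.noise_model == "gaussian":
            noisy = np.abs(mags + rng.normal(0.0, sigma, shape))
        else:  # rician: magnitude of complex signal + complex noise
            noisy = np.hypot(
                mags + rng.normal(0.0, sigma, shape),
                rng.normal(0.0, sigma, shape),
            )
    else:
        sigma = 0.0
        noisy = mags
    norm = np.sqrt((noisy**2).sum(axis=-1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        signals = np.where(norm > 0, noisy / norm, np.nan)
    degenerate = degenerate | ~np.isfinite(signals).all(axis=-1)
    signals = np.where(degenerate[..., None], np.nan, signals)
    patch = SignalPatch(
        signals=signals,
        geometry=spec.geom,
        degenerate=degenerate,
        provenance={
            "kind": "synthetic",
            "seed": spec.seed,
            "noise_model": spec.noise_model,
            "noise_sigma": spec.noise_sigma,
            "sigma_absolute": sigma,
        },
    )
    truth = {
        "i_rms_a": spec.params.i_rms,
        "phi_j_prime_rad": spec.params.phi_j_prime,
        "lambda_b": spec.params.background.lambda_b,
        "lambda_b_dx": spec.params.background.lambda_b_dx,
        "lambda_b_dy": spec.params.background.lambda_b_dy,
        "xi_j_rad": spec.params.geometry.xi_j,
        "theta_j_rad": spec.params.geometry.theta_j,
        "x0_mm": spec.params.geometry.x0,
        "y0_mm": spec.params.geometry.y0,
        "t1_ms": spec.t1_true,
        "seed": spec.seed,
    }
    return patch, truth


def generate_profile_scenes(
    profile: CurrentProfileSpec, base: SceneSpec
) -> list[SceneSpec]:
    """One scene per slice of a current profile along the wire.

    Each scene copies ``base`` with that slice's current amplitude and an
    independent per-slice seed derived from the base seed, mirroring the
    design of validating fitted currents against a known current
    distribution along a lead.
    """
    scenes = []
    root = np.random.default_rng(base.seed).integers(0, 2**31 - 1)
    for k, i_k in enumerate(profile.profile):
        p = base.params
        params = WireModelParams(
            i_rms=float(abs(i_k)),
            phi_j_prime=p.phi_j_prime,
            geometry=p.geometry,
            background=p.background,
        )
        scenes.append(
            SceneSpec(
                params=params,
                geom=base.geom,
                seq=base.seq,
                t1_true=base.t1_true,
                noise_sigma=base.noise_sigma,
                noise_model=base.noise_model,
                seed=int((root + k) % (2**31 - 1)),
            )
        )
    return scenes


def generate_thermometry(
    c_implant: float,
    i_rms: float,
    duration: float = 139.0,
    baseline: float = 300.0,
    tau: float = 60.0,
    drift: float = 0.0,
    noise_sd: float = 0.0,
    sample_rate: float = 1.0,
    seed: int | None = None,
) -> ThermoTimeSeries:
    """Synthetic probe recording of tip heating.

    Baseline segment followed by a saturating-exponential temperature rise
    dT(t) = c·I²·(1 − exp(−t/τ)), whose initial slope is proportional to
    c·I² (the short-time inert-phantom regime), plus linear drift and
    Gaussian noise. ``duration`` must exceed the 20-s scaling window.
    """
    if duration <= 20.0:
        raise ValueError("exposure must be longer than the 20-s scaling window")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, baseline + duration, 1.0 / sample_rate)
    temp = drift * t
    exposed = t >= baseline
    te = t[exposed] - baseline
    temp[exposed] += c_implant * i_rms**2 * (1.0 - np.exp(-te / tau))
    if noise_sd > 0:
        temp = temp + rng.normal(0.0, noise_sd, t.shape)
    return ThermoTimeSeries(
        time=t, temperature=temp, baseline_window=baseline, exposure_start=baseline
    )
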