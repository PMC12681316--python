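"""Inversion of the patch forward model (module-surface wrappers).

The heavy lifting lives in :class:`rfcurrent.estimators.WireCurrentFitter`;
this module packages it behind explicit config/result types for scripted
and CLI use.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

from .estimators import WireCurrentFitter, default_bounds, patch_cost
from .forward import PatchGeometry, SignalPatch
from .sequence import SequenceParams, SliceProfileDictionary
from .wire_model import COS_XI_FLOOR, WireModelParams

__all__ = ["FitConfig", "FitResult", "fit_patch", "patch_cost", "default_bounds"]


@dataclass
class FitConfig:
    """Configuration of the differential-evolution inversion.

    Defaults follow the nominal protocol: a population of 61 parameter
    sets over 122 iterations, masking signals within a 4-mm radius of the
    candidate wire position.
    """

    population_size: int = 61
    n_iterations: int = 122
    mask_radius: float = 4.0
    bounds: list | None = None
    center_hint: tuple = (0.0, 0.0)
    cos_xi_floor: float = COS_XI_FLOOR
    polish: bool = False
    t1: float = 1000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mask_radius < 0:
            raise ValueError("mask_radius must be nonnegative")


@dataclass
class FitResult:
    """Outcome of a patch fit."""

    params: WireModelParams
    rms_residual: float
    n_masked_voxels: int
    converged: bool
    identifiable: bool
    diagnostics: dict = dc_field(default_factory=dict)

    @property
    def i_rms(self) -> float:
        return self.params.i_rms

    def to_dict(self) -> dict:
        g, b = self.params.geometry, self.params.background
        return {
            "i_rms_a": self.params.i_rms,
            "i_rms_ma": 1e3 * self.params.i_rms,
            "phi_j_prime_rad": self.params.phi_j_prime,
            "lambda_b": b.lambda_b,
            "lambda_b_dx": b.lambda_b_dx,
            "lambda_b_dy": b.lambda_b_dy,
            "xi_j_rad": g.xi_j,
            "theta_j_rad": g.theta_j,
            "x0_mm": g.x0,
            "y0_mm": g.y0,
            "rms_residual": self.rms_residual,
            "n_masked_voxels": self.n_masked_voxels,
            "converged": self.converged,
            "identifiable": self.identifiable,
            "diagnostics": {
                k: v for k, v in self.diagnostics.items() if k != "cost_trace"
            },
        }


def fit_patch(
    data: SignalPatch,
    seq: SequenceParams | None = None,
    dictionary: SliceProfileDictionary | None = None,
    geom: PatchGeometry | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Estimate the wire current (and nuisance parameters) from a patch."""
    config = config or FitConfig()
    fitter = WireCurrentFitter(
        sequence=seq,
        geometry=geom,
        dictionary=dictionary,
        t1=config.t1,
        population_size=config.population_size,
        n_iterations=config.n_iterations,
        mask_radius=config.mask_radius,
        bounds=config.bounds,
        center_hint=config.center_hint,
        cos_xi_floor=config.cos_xi_floor,
        polish=config.polish,
        seed=config.seed,
    ).fit(data)
    return FitResult(
        params=fitter.params_,
        rms_residual=fitter.rms_residual_,
        n_masked_voxels=fitter.n_masked_voxels_,
        converged=fitter.converged_,
        identifiable=fitter.identifiable_,
        diagnostics=fitter.diagnostics_,
    )
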