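"""Scikit-learn style estimators for current fitting and heating calibration.

`WireCurrentFitter` inverts the patch forward model by differential
evolution, recovering the wire current (and nuisance geometry/background
parameters) from a patch of normalized da-hdrAFI magnitude signals.
`ImplantHeatingModel` is the strictly proportional regression dT = c·I²
linking measured currents to tip heating, from which per-patient B1,rms
exposure limits follow.

Both follow the sklearn estimator contract (``get_params``/``set_params``,
fitted attributes with trailing underscores) so they compose with sklearn
model-selection utilities.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import differential_evolution, least_squares
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin

from .forward import PatchGeometry, SignalPatch, synthesize_patch
from .sequence import SequenceParams, SliceProfileDictionary, default_dictionary
from .wire_model import COS_XI_FLOOR, WireModelParams

__all__ = ["WireCurrentFitter", "ImplantHeatingModel", "default_bounds"]


def default_bounds(center_hint=(0.0, 0.0), hint_radius_vox: float = 1.5,
                   voxel_size: float = 2.0):
    """Default search intervals for the 9 fitted parameters.

    Generous ranges that exclude the perpendicular-wire blind spot; the
    wire-position interval is centered on the user's approximate wire
    location (``center_hint``, mm in patch coordinates).
    """
    hx, hy = center_hint
    w = hint_radius_vox * voxel_size
    # circular parameters get a doubly covered interval so the optimizer
    # never meets an artificial boundary at ±π; reported values are
    # wrapped back into (−π, π]
    return [
        (0.0, 1.0),                # i_rms [A]
        (-2 * math.pi, 2 * math.pi),  # phi_j_prime (circular)
        (0.3, 2.0),                # lambda_b
        (-0.02, 0.02),             # lambda_b_dx [1/mm]
        (-0.02, 0.02),             # lambda_b_dy [1/mm]
        (-math.pi / 3, math.pi / 3),  # xi_j
        (-2 * math.pi, 2 * math.pi),  # theta_j (circular)
        (hx - w, hx + w),          # x0 [mm]
        (hy - w, hy + w),          # y0 [mm]
    ]


class WireCurrentFitter(BaseEstimator):
    """Fit the RF wire current from a patch of normalized MRI signals.

    Minimizes the RMS difference between forward-modeled and observed
    normalized signals over the patch by differential evolution, with a
    dynamic circular mask around each candidate's wire position (signals
    within ``mask_radius`` mm of the fitted wire are excluded from the
    cost, where the infinite-wire model is least valid).

    Parameters
    ----------
    sequence : SequenceParams, optional
        Acquisition parameters; the nominal protocol by default.
    geometry : PatchGeometry, optional
        Patch geometry (12×12 voxels of 2×2 mm by default).
    dictionary : SliceProfileDictionary, optional
        Slice-profile dictionary; built (and cached) from ``sequence`` and
        ``t1`` when omitted.
    t1 : float
        Longitudinal relaxation time of the medium, ms. A fixed known
        input, not a fitted parameter.
    population_size, n_iterations : int
        Differential-evolution budget.
    mask_radius : float
        Radius (mm) of the dynamic mask around the candidate wire position.
    bounds : list of (low, high), optional
        Per-parameter search intervals in the order of
        ``wire_model.PARAM_NAMES``; defaults from :func:`default_bounds`.
    center_hint : (float, float)
        Approximate wire location in patch coordinates (mm); centers the
        (x0, y0) bounds. The one manual input of the workflow.
    cos_xi_floor : float
        Below this fitted |cos ξj| the result is flagged unidentifiable.
    polish : bool
        Run a local refinement from the DE optimum (off by default;
        reported in the diagnostics when used).
    seed : int, optional
        Seed for the stochastic optimizer; results are reproducible per
        seed.

    Attributes
    ----------
    params_ : WireModelParams
        Best-fit parameters (canonicalized to ξj ≥ 0).
    i_rms_ : float
        Fitted RMS wire current, ampere, referenced to the sequence
        B1,rms.
    rms_residual_ : float
        RMS of normalized-signal residuals at the optimum.
    n_masked_voxels_ : int
        Voxels excluded by the dynamic mask at the optimum.
    identifiable_ : bool
        False when |cos ξj| of the fit is below ``cos_xi_floor``.
    converged_ : bool
        Optimizer convergence flag.
    diagnostics_ : dict
        Cost trace, seed, bounds, function-evaluation count, polish flag.
    """

    def __init__(
        self,
        sequence: SequenceParams | None = None,
        geometry: PatchGeometry | None = None,
        dictionary: SliceProfileDictionary | None = None,
        t1: float = 1000.0,
        population_size: int = 61,
        n_iterations: int = 122,
        mask_radius: float = 4.0,
        bounds=None,
        center_hint=(0.0, 0.0),
        cos_xi_floor: float = COS_XI_FLOOR,
        polish: bool = False,
        seed: int | None = None,
    ):
        self.sequence = sequence
        self.geometry = geometry
        self.dictionary = dictionary
        self.t1 = t1
        self.population_size = population_size
        self.n_iterations = n_iterations
        self.mask_radius = mask_radius
        self.bounds = bounds
        self.center_hint = center_hint
        self.cos_xi_floor = cos_xi_floor
        self.polish = polish
        self.seed = seed

    # -- cost ------------------------------------------------------------

    def _resolved(self):
        seq = self.sequence or SequenceParams()
        geom = self.geometry or PatchGeometry()
        dic = self.dictionary or default_dictionary(seq, self.t1)
        return seq, geom, dic

    @staticmethod
    def _as_patch(X, geom: PatchGeometry) -> SignalPatch:
        if isinstance(X, SignalPatch):
            return X
        arr = np.asarray(X, dtype=float)
        if arr.shape != (geom.n_voxels, geom.n_voxels, 4):
            raise ValueError(
                f"expected a SignalPatch or array of shape "
                f"({geom.n_voxels}, {geom.n_voxels}, 4), got {arr.shape}"
            )
        degenerate = ~np.isfinite(arr).all(axis=-1)
        return SignalPatch(arr, geom, degenerate, {"kind": "array"})

    def cost(self, params: WireModelParams, data: SignalPatch) -> float:
        """RMS model–data difference over unmasked, nondegenerate voxels."""
        seq, geom, dic = self._resolved()
        return patch_cost(params, data, seq, dic, geom, self.mask_radius)

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y=None):
        """Run the global fit on a patch.

        ``X`` may be a :class:`SignalPatch` or an (n, n, 4) array of
        per-voxel normalized magnitudes (NaN rows marking degenerate
        voxels). ``y`` is ignored (present for API compatibility).
        """
        seq, geom, dic = self._resolved()
        data = self._as_patch(X, geom)
        if data.degenerate.all():
            raise ValueError("all voxels in the patch are degenerate")
        bounds = self.bounds or default_bounds(self.center_hint,
                                              voxel_size=geom.voxel_size)
        if self.population_size < len(bounds) + 1:
            raise ValueError("population_size must exceed the parameter count")

        xc, yc = geom.voxel_centers()
        valid_data = ~data.degenerate
        obs = data.signals

        def cost_vec(theta):
            try:
                params = WireModelParams.from_array(theta)
                model = synthesize_patch(params, seq, dic, geom)
            except ValueError:
                # infeasible candidate (e.g. background field nonpositive
                # at a patch corner): penalize instead of aborting the run
                return 1e6
            g = params.geometry
            masked = np.hypot(xc - g.x0, yc - g.y0) < self.mask_radius
            ok = valid_data & ~masked & ~model.degenerate
            if not ok.any():
                return 1e6
            res = model.signals[ok] - obs[ok]
            return float(np.sqrt(np.mean(res**2)))

        rng = np.random.default_rng(self.seed)
        lhs = qmc.LatinHypercube(d=len(bounds), seed=rng)
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        init = lo + lhs.random(self.population_size) * (hi - lo)

        trace: list[float] = []
        result = differential_evolution(
            cost_vec,
            bounds,
            maxiter=self.n_iterations,
            init=init,
            strategy="best1bin",
            mutation=(0.5, 1.0),
            recombination=0.7,
            polish=False,
            seed=rng,
            callback=lambda xk, convergence=0.0: trace.append(cost_vec(xk)),
        )
        best_x, best_fun = result.x, float(result.fun)

        if self.polish:
            # local least-squares refinement of the DE optimum on the
            # per-signal residual vector (trust-region reflective; the
            # finite-difference step spans several dictionary grid cells
            # so interpolation kinks do not stall it)
            def resid_vec(theta):
                try:
                    params = WireModelParams.from_array(theta)
                    model = synthesize_patch(params, seq, dic, geom)
                except ValueError:
                    return np.full(obs.size, 1e3)
                g = params.geometry
                masked = np.hypot(xc - g.x0, yc - g.y0) < self.mask_radius
                ok = valid_data & ~masked & ~model.degenerate
                if not ok.any():
                    return np.full(obs.size, 1e3)
                res = np.zeros_like(obs)
                res[ok] = model.signals[ok] - obs[ok]
                return res.ravel()

            lo_b = np.maximum(lo, best_x - 0.5 * (hi - lo))
            hi_b = np.minimum(hi, best_x + 0.5 * (hi - lo))
            ls = least_squares(
                resid_vec, best_x, bounds=(lo_b, hi_b), diff_step=1e-3
            )
            polished_fun = cost_vec(ls.x)
            if polished_fun < best_fun:
                best_x, best_fun = ls.x, polished_fun

        params = WireModelParams.from_array(best_x)
        params = _canonicalize(params)
        g = params.geometry
        masked = np.hypot(xc - g.x0, yc - g.y0) < self.mask_radius

        self.params_ = params
        self.i_rms_ = params.i_rms
        self.rms_residual_ = best_fun
        self.n_masked_voxels_ = int(masked.sum())
        self.identifiable_ = abs(math.cos(g.xi_j)) >= self.cos_xi_floor
        self.converged_ = bool(result.success)
        self.diagnostics_ = {
            "seed": self.seed,
            "bounds": [list(b) for b in bounds],
            "nfev": int(result.nfev),
            "nit": int(result.nit),
            "polish": bool(self.polish),
            "cost_trace": trace,
            "message": str(result.message),
        }
        return self

    def score(self, X, y=None):
        """Negative RMS residual of the fitted model on a patch."""
        if not hasattr(self, "params_"):
            raise AttributeError("fit the estimator before scoring")
        seq, geom, dic = self._resolved()
        return -self.cost(self.params_, self._as_patch(X, geom))


def patch_cost(
    params: WireModelParams,
    data: SignalPatch,
    seq: SequenceParams,
    dictionary: SliceProfileDictionary,
    geom: PatchGeometry,
    mask_radius: float = 4.0,
) -> float:
    """RMS difference between modeled and observed normalized signals.

    The circular mask is evaluated dynamically from the candidate's wire
    position (whole voxels, by center distance). Degenerate voxels in
    either the data or the model are excluded. Exactly zero when ``data``
    was synthesized noiselessly from ``params``.
    """
    model = synthesize_patch(params, seq, dictionary, geom)
    xc, yc = geom.voxel_centers()
    g = params.geometry
    masked = np.hypot(xc - g.x0, yc - g.y0) < mask_radius
    ok = ~data.degenerate & ~model.degenerate & ~masked
    if not ok.any():
        raise ValueError("all voxels masked or degenerate; cost undefined")
    res = model.signals[ok] - data.signals[ok]
    return float(np.sqrt(np.mean(res**2)))


def _canonicalize(params: WireModelParams) -> WireModelParams:
    """Wrap angles into (−π, π] and resolve the (ξj, θj) ↔ (−ξj, θj+π)
    sign degeneracy toward ξj ≥ 0."""
    g = params.geometry
    xi, theta = g.xi_j, g.theta_j
    if xi < 0:
        xi, theta = -xi, theta + math.pi
    theta = math.remainder(theta, 2 * math.pi)
    phi = math.remainder(params.phi_j_prime, 2 * math.pi)
    from .wire_model import WireGeometry

    return WireModelParams(
        i_rms=params.i_rms,
        phi_j_prime=phi,
        geometry=WireGeometry(xi, theta, g.x0, g.y0),
        background=params.background,
    )


class ImplantHeatingModel(RegressorMixin, BaseEstimator):
    """Strictly proportional heating model dT = c_implant · I².

    The temperature rise at a fixed probe point near the implant tip
    scales with the square of the RMS tip current; ``c_implant`` (K/A²) is
    an implant property independent of exposure conditions, valid at the
    stated reference B1,rms and slice-to-tip distance.

    Attributes
    ----------
    c_implant_ : float
        Fitted proportionality constant, K/A².
    r_squared_ : float
        Coefficient of determination of the proportional model.
    """

    def __init__(self, b1_rms_ref: float = 2.29, slice_distance: float = 33.0,
                 implant_id: str = ""):
        self.b1_rms_ref = b1_rms_ref
        self.slice_distance = slice_distance
        self.implant_id = implant_id

    def fit(self, X, y):
        """Least-squares zero-intercept fit of dT on I².

        ``X`` is the array of currents (A), shape (n,) or (n, 1); ``y``
        the peak temperature rises (K). The closed-form solution is
        c = Σ dT_i I_i² / Σ I_i⁴.
        """
        i = np.asarray(X, dtype=float).reshape(-1)
        dt = np.asarray(y, dtype=float).reshape(-1)
        if i.shape != dt.shape or i.size == 0:
            raise ValueError("currents and temperature rises must align")
        if np.all(i == 0):
            raise ValueError("all currents are zero; c_implant undefined")
        i2 = i**2
        self.c_implant_ = float(np.dot(dt, i2) / np.dot(i2, i2))
        pred = self.c_implant_ * i2
        ss_res = float(np.sum((dt - pred) ** 2))
        ss_tot = float(np.sum((dt - dt.mean()) ** 2))
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return self

    def predict(self, X):
        """Predicted temperature rise c·I² (K) for currents ``X`` (A)."""
        if not hasattr(self, "c_implant_"):
            raise AttributeError("fit the model before predicting")
        i = np.asarray(X, dtype=float).reshape(-1)
        return self.c_implant_ * i**2

    def b1_threshold(self, i_mri: float, b1_rms_seq: float | None = None,
                     dt_thresh: float = 2.0) -> float:
        """Maximum allowable B1,rms (µT) for a target temperature rise.

        B1thresh = B1seq · sqrt(dTthresh / (c · I²)). Rescaling the
        current by B1thresh/B1seq and predicting heating returns exactly
        ``dt_thresh``. Returns +inf when ``i_mri`` is zero (the
        measurement implies no limit).
        """
        if not hasattr(self, "c_implant_"):
            raise AttributeError("fit the model before deriving a limit")
        if dt_thresh <= 0:
            raise ValueError("dt_thresh must be positive")
        if i_mri < 0:
            raise ValueError("i_mri must be nonnegative")
        b1_seq = self.b1_rms_ref if b1_rms_seq is None else b1_rms_seq
        if i_mri == 0 or self.c_implant_ == 0:
            return math.inf
        return b1_seq * math.sqrt(dt_thresh / (self.c_implant_ * i_mri**2))
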