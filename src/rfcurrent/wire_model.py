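"""Quasi-static model of the transmit field near a current-carrying wire.

An RF current induced in a wire-like implant (e.g. a DBS lead) perturbs the
transmit field |B1+| in an axial imaging slice. For an infinite straight
wire at angle ``xi_j`` to B0, crossing the slice at ``(x0, y0)``, Ampère's
law gives a transverse (in-plane) field that is purely azimuthal around the
crossing point, with magnitude

    B1j(r, θr) = μ0 μr I cos(ξj) / (2 π r (1 − sin²ξj cos²(θr − θj))),

where (r, θr) are polar coordinates in the axial plane about the crossing
point and θj is the azimuth of the wire's in-plane projection. The factor
in the denominator is the squared ratio of the 3-D distance to the wire to
the in-plane radius; the transverse component of the tilted-wire field
remains exactly azimuthal (the out-of-plane tilt only rotates the field
vector out of the transverse plane, scaling it by cos ξj at fixed 3-D
distance).

The total relative transmit field λ = |B1+|/B1,nom is the magnitude of the
background left-circular field plus the left-circular half of the linearly
polarized wire field:

    λ(r, θr) = λb · sqrt(1 + b² − 2 b sin(θr − φj′)),
    b = B1j(r, θr) / (2 λb B1rms),

with φj′ the phase of the wire current relative to the background B1+.
Since the wire current is induced by the same RF excitation that produces
the background field, the ratio I/B1,nom equals I_rms/B1,rms, so the model
is invariant under joint rescaling of current and reference field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import MM, MU0, MU_R, UT

__all__ = [
    "WireGeometry",
    "BackgroundField",
    "WireModelParams",
    "FieldPoint",
    "wire_field_magnitude",
    "lambda_total",
    "lambda_total_xy",
    "biot_savart_field",
    "COS_XI_FLOOR",
]

#: Below this |cos ξj| the wire field is too weak for the current to be
#: identifiable from magnitude images (perpendicular-wire blind spot).
COS_XI_FLOOR = 0.1


@dataclass
class WireGeometry:
    """Orientation and in-plane position of the wire.

    Parameters
    ----------
    xi_j : float
        Angle between the wire and B0, radians. Must satisfy |xi_j| < π/2;
        a perpendicular wire produces no transverse field and is a declared
        blind spot of the model.
    theta_j : float
        Azimuthal angle of the wire's in-plane projection, radians,
        measured counterclockwise from +x.
    x0, y0 : float
        Offsets of the wire crossing point from the patch origin, mm.
    """

    xi_j: float = 0.0
    theta_j: float = 0.0
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if not abs(self.xi_j) < math.pi / 2:
            raise ValueError(
                f"|xi_j| must be strictly below pi/2, got {self.xi_j!r}"
            )
        if not (np.isfinite(self.x0) and np.isfinite(self.y0)):
            raise ValueError("wire offsets must be finite")


@dataclass
class BackgroundField:
    """Smooth background transmit field over the patch.

    ``lambda_b`` is the background |B1+| in units of the nominal B1+, with
    optional linear spatial gradients (per mm) expanded about the patch
    origin. ``phi_b`` is the background B1+ phase; it does not affect
    magnitude signals and is carried only for parameter-list parity.
    """

    lambda_b: float = 1.0
    lambda_b_dx: float = 0.0
    lambda_b_dy: float = 0.0
    phi_b: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_b <= 0:
            raise ValueError("lambda_b must be positive")

    def local(self, x, y):
        """Background λb at (x, y) mm relative to the patch origin."""
        return self.lambda_b + self.lambda_b_dx * x + self.lambda_b_dy * y


@dataclass
class WireModelParams:
    """The sample-dependent parameters of the forward model.

    ``i_rms`` is the RMS wire current referenced to the sequence's
    background B1,rms; ``phi_j_prime`` is the phase of the wire current
    relative to the background B1+ phase (φj′ = φj − φb), the single phase
    that enters magnitude signals.
    """

    i_rms: float = 0.0
    phi_j_prime: float = 0.0
    geometry: WireGeometry = field(default_factory=WireGeometry)
    background: BackgroundField = field(default_factory=BackgroundField)

    def __post_init__(self) -> None:
        if self.i_rms < 0:
            raise ValueError("i_rms must be nonnegative")

    @property
    def identifiable(self) -> bool:
        """Whether the current is observable (wire not near-perpendicular)."""
        return abs(math.cos(self.geometry.xi_j)) >= COS_XI_FLOOR

    def to_array(self) -> np.ndarray:
        g, b = self.geometry, self.background
        return np.array(
            [
                self.i_rms,
                self.phi_j_prime,
                b.lambda_b,
                b.lambda_b_dx,
                b.lambda_b_dy,
                g.xi_j,
                g.theta_j,
                g.x0,
                g.y0,
            ]
        )

    @classmethod
    def from_array(cls, a) -> "WireModelParams":
        a = np.asarray(a, dtype=float)
        return cls(
            i_rms=float(a[0]),
            phi_j_prime=float(a[1]),
            background=BackgroundField(float(a[2]), float(a[3]), float(a[4])),
            geometry=WireGeometry(float(a[5]), float(a[6]), float(a[7]), float(a[8])),
        )


#: Order of parameters in :meth:`WireModelParams.to_array`.
PARAM_NAMES = (
    "i_rms",
    "phi_j_prime",
    "lambda_b",
    "lambda_b_dx",
    "lambda_b_dy",
    "xi_j",
    "theta_j",
    "x0",
    "y0",
)


@dataclass
class FieldPoint:
    """Polar coordinates in the axial plane about the wire crossing point."""

    r: float
    theta_r: float = 0.0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be positive; the wire axis is singular")


def wire_field_magnitude(point: FieldPoint, geometry: WireGeometry, i_rms: float):
    """In-plane (transverse) field magnitude of the wire current, tesla.

    Evaluates the infinite-straight-wire closed form at ``point``
    (distances in mm). Strictly decreasing in r; zero for a perpendicular
    wire (cos ξj = 0).
    """
    return _wire_field(point.r, point.theta_r, geometry.xi_j, geometry.theta_j, i_rms)


def _wire_field(r, theta_r, xi_j, theta_j, i_rms):
    r = np.asarray(r, dtype=float)
    if np.any(r[np.isfinite(r)] <= 0):
        raise ZeroDivisionError("field is singular on the wire axis (r = 0)")
    sin_xi = math.sin(xi_j)
    geo = 1.0 - sin_xi**2 * np.cos(theta_r - theta_j) ** 2
    return MU0 * MU_R * i_rms * math.cos(xi_j) / (2.0 * math.pi * r * MM * geo)


def lambda_total_xy(x, y, params: WireModelParams, b1_rms_ut: float):
    """Relative total transmit field λ at patch coordinates (x, y) mm.

    ``b1_rms_ut`` is the background B1,rms the current is referenced to, in
    microtesla. Vectorized over x and y. Singular at the wire crossing
    point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    g = params.geometry
    dx = x - g.x0
    dy = y - g.y0
    r = np.hypot(dx, dy)
    theta_r = np.arctan2(dy, dx)
    lam_b = params.background.local(x, y)
    if np.any(lam_b <= 0):
        raise ValueError("background lambda_b must stay positive over the patch")
    if params.i_rms == 0:
        return lam_b * np.ones_like(r)
    # points exactly on the wire axis evaluate to +inf (flagged degenerate
    # downstream) rather than raising, so vectorized patch synthesis can
    # handle a wire crossing a sub-voxel center
    on_axis = r == 0
    with np.errstate(divide="ignore"):
        b1j = _wire_field(np.where(on_axis, np.nan, r), theta_r,
                          g.xi_j, g.theta_j, params.i_rms)
    b = b1j / (2.0 * lam_b * b1_rms_ut * UT)
    lam_sq = 1.0 + b**2 - 2.0 * b * np.sin(theta_r - params.phi_j_prime)
    lam = lam_b * np.sqrt(np.maximum(lam_sq, 0.0))
    return np.where(on_axis, np.inf, lam)


def lambda_total(x: float, y: float, params: WireModelParams, b1_rms_ut: float) -> float:
    """Scalar convenience wrapper around :func:`lambda_total_xy`."""
    return float(lambda_total_xy(x, y, params, b1_rms_ut))


def biot_savart_field(segment_endpoints, i_rms, point, n_steps: int = 20001):
    """Numerically integrated Biot–Savart field of a finite straight segment.

    Serves as an independent ground-truth oracle for the infinite-wire
    closed form. ``segment_endpoints`` is a pair of 3-D points in mm,
    ``point`` a 3-D evaluation point in mm; returns the field vector in
    tesla. Uses midpoint quadrature with ``n_steps`` subdivisions.
    """
    a, b = (np.asarray(e, dtype=float) * MM for e in segment_endpoints)
    p = np.asarray(point, dtype=float) * MM
    if i_rms == 0:
        return np.zeros(3)
    t = (np.arange(n_steps) + 0.5) / n_steps
    pts = a[None, :] + t[:, None] * (b - a)[None, :]
    dl = (b - a) / n_steps
    rvec = p[None, :] - pts
    rmag = np.linalg.norm(rvec, axis=1)
    if np.any(rmag < 1e-12):
        raise ZeroDivisionError("evaluation point lies on the segment")
    integrand = np.cross(np.broadcast_to(dl, rvec.shape), rvec) / rmag[:, None] ** 3
    return MU0 * MU_R * i_rms / (4.0 * math.pi) * integrand.sum(axis=0)
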