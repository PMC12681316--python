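"""Signal model of the dual-angle high-dynamic-range AFI sequence.

da-hdrAFI interleaves two gradient-echo acquisitions with *different* flip
angles and TRs (unlike classic AFI, which repeats the same excitation), and
acquires two such sequences, (a) and (b), for four magnitude images per
slice. The steady-state signals as a function of the local relative
transmit field λ are

    S_{x,1} = [1 − E_{x,2} + (1 − E_{x,1}) E_{x,2} cos(λ α_{x,2})] /
              [1 − E_{x,1} E_{x,2} cos(λ α_{x,1}) cos(λ α_{x,2})] · sin(λ α_{x,1})

and the symmetric expression for S_{x,2}, with E_{x,i} = exp(−TR_{x,i}/T1).
Per-voxel normalization of the 4-vector to unit Euclidean norm removes
receive-field amplitude, proton density and T2* weighting, which is what
makes magnitude-only fitting of the wire current possible.

Slice-profile effects are handled with a precomputed dictionary: for each
center-of-slice λ on a dense grid, the four signals are evaluated at the
through-slice effective flip angles α·λ·p(z) given the excitation profile
p(z) from a Bloch simulation, and averaged over through-plane positions.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "SequenceParams",
    "PulseSpec",
    "SliceProfileDictionary",
    "afi_signals",
    "slice_profile",
    "build_slice_dictionary",
    "lookup_signals",
    "normalize_voxel",
    "default_dictionary",
]


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition parameters of the two da-hdrAFI sequences.

    Defaults are the nominal protocol: flip angles in degrees, repetition
    times in ms, and the nominal B1,rms of the current-measurement sequence
    in µT (the reference that fitted currents are expressed against).
    """

    alpha_a1: float = 45.2
    alpha_a2: float = 69.3
    tr_a1: float = 23.7
    tr_a2: float = 61.5
    alpha_b1: float = 21.9
    alpha_b2: float = 39.0
    tr_b1: float = 26.5
    tr_b2: float = 188.5
    b1_rms_seq: float = 2.29

    def __post_init__(self) -> None:
        for name in ("tr_a1", "tr_a2", "tr_b1", "tr_b2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("alpha_a1", "alpha_a2", "alpha_b1", "alpha_b2"):
            a = getattr(self, name)
            if not 0 < a < 180:
                raise ValueError(f"{name} must lie in (0, 180) degrees")

    def pair(self, which: str):
        """(alpha1_deg, alpha2_deg, tr1, tr2) for sequence 'a' or 'b'."""
        if which == "a":
            return self.alpha_a1, self.alpha_a2, self.tr_a1, self.tr_a2
        if which == "b":
            return self.alpha_b1, self.alpha_b2, self.tr_b1, self.tr_b2
        raise ValueError("which must be 'a' or 'b'")


def afi_signals(lam, t1: float, seq: SequenceParams, which: str):
    """Steady-state signal pair (S1, S2) of one dual-angle AFI sequence.

    ``lam`` is the local relative transmit field (vectorized), ``t1`` the
    longitudinal relaxation time in ms. Returns *signed* steady-state
    amplitudes; measured images are their magnitudes. Both signals vanish
    at λ = 0, and in the fully relaxed limit (TR ≫ T1) reduce to
    sin(λ α1), sin(λ α2).
    """
    if t1 <= 0:
        raise ValueError("t1 must be positive")
    a1_deg, a2_deg, tr1, tr2 = seq.pair(which)
    lam = np.asarray(lam, dtype=float)
    a1 = np.deg2rad(a1_deg) * lam
    a2 = np.deg2rad(a2_deg) * lam
    e1 = np.exp(-tr1 / t1)
    e2 = np.exp(-tr2 / t1)
    c1, c2 = np.cos(a1), np.cos(a2)
    denom = 1.0 - e1 * e2 * c1 * c2
    s1 = (1.0 - e2 + (1.0 - e1) * e2 * c2) / denom * np.sin(a1)
    s2 = (1.0 - e1 + (1.0 - e2) * e1 * c1) / denom * np.sin(a2)
    return s1, s2


def normalize_voxel(signals):
    """Normalize a voxel's 4 signals to unit Euclidean norm.

    Division by sqrt(S_a1² + S_a2² + S_b1² + S_b2²) removes all per-voxel
    multiplicative factors (B1− amplitude, proton density, T2* weighting),
    so the normalized 4-vector depends only on λ and T1. Raises on an
    all-zero voxel, which must be masked upstream.
    """
    s = np.asarray(signals, dtype=float)
    if s.shape[-1] != 4:
        raise ValueError("expected 4 signals per voxel")
    norm = np.sqrt((s**2).sum(axis=-1, keepdims=True))
    if np.any(norm == 0):
        raise ValueError("degenerate all-zero voxel cannot be normalized")
    return s / norm


@dataclass(frozen=True)
class PulseSpec:
    """Excitation pulse for the Bloch slice-profile simulation.

    A Hann-windowed sinc of the given time–bandwidth product, the standard
    product-sequence slice-selective excitation. The through-plane profile
    is evaluated at ``n_positions`` points spanning ``extent_factor`` slice
    thicknesses either side of slice center.
    """

    shape: str = "hann_sinc"
    time_bandwidth: float = 4.0
    n_positions: int = 201
    extent_factor: float = 2.0
    n_segments: int = 256
    ref_flip_deg: float = 10.0

    def __post_init__(self) -> None:
        if self.shape not in ("hann_sinc", "boxcar"):
            raise ValueError(f"unknown pulse shape {self.shape!r}")
        if self.n_positions < 3 or self.n_segments < 8:
            raise ValueError("pulse discretization too coarse")


def slice_profile(pulse: PulseSpec = PulseSpec()):
    """Normalized through-slice flip-angle profile p(z) by Bloch simulation.

    Returns ``(z, p)`` with z in units of the slice thickness over
    ±extent_factor and p(0) = 1. The pulse is played as a hard-pulse train
    at a small reference flip angle; the local effective flip angle is
    recovered from the final magnetization as atan2(|Mxy|, Mz). In the
    small-tip regime the profile is flip-angle independent and is rescaled
    linearly to the nominal flip angles when building the dictionary.

    The degenerate ``boxcar`` shape (ideal rectangular profile, 1 inside
    the slice and 0 outside) bypasses the Bloch simulation; it exists as a
    closed-form reference for testing.
    """
    if pulse.shape == "boxcar":
        z = np.linspace(-pulse.extent_factor, pulse.extent_factor, pulse.n_positions)
        return z, (np.abs(z) <= 0.5).astype(float)
    n = pulse.n_segments
    tau = (np.arange(n) + 0.5) / n
    envelope = np.sinc(pulse.time_bandwidth * (tau - 0.5)) * np.hanning(n + 2)[1:-1]
    envelope = envelope / envelope.sum()

    z = np.linspace(-pulse.extent_factor, pulse.extent_factor, pulse.n_positions)
    # off-resonance per unit (normalized) time at position z (slice-thickness
    # units): the slice-select gradient maps the pulse bandwidth TBW/T onto
    # one slice thickness.
    phi_total = 2.0 * np.pi * pulse.time_bandwidth * z  # radians over the pulse
    dphi = phi_total / n

    alpha_ref = np.deg2rad(pulse.ref_flip_deg)
    m = np.zeros((pulse.n_positions, 3))
    m[:, 2] = 1.0
    cosd, sind = np.cos(dphi / 2.0), np.sin(dphi / 2.0)
    for k in range(n):
        # half precession, nutation about x, half precession (symmetric split)
        mx = m[:, 0] * cosd - m[:, 1] * sind
        my = m[:, 0] * sind + m[:, 1] * cosd
        m[:, 0], m[:, 1] = mx, my
        beta = alpha_ref * envelope[k]
        cb, sb = np.cos(beta), np.sin(beta)
        my = m[:, 1] * cb - m[:, 2] * sb
        mz = m[:, 1] * sb + m[:, 2] * cb
        m[:, 1], m[:, 2] = my, mz
        mx = m[:, 0] * cosd - m[:, 1] * sind
        my = m[:, 0] * sind + m[:, 1] * cosd
        m[:, 0], m[:, 1] = mx, my

    mxy = np.hypot(m[:, 0], m[:, 1])
    alpha_eff = np.arctan2(mxy, m[:, 2])
    center = alpha_eff[pulse.n_positions // 2]
    if center <= 0:
        raise ValueError("degenerate pulse: zero on-resonance flip")
    return z, alpha_eff / center


@dataclass
class SliceProfileDictionary:
    """Precomputed through-plane-averaged signals vs. center-of-slice λ.

    ``signals`` has shape (len(lambda_grid), 4) in the order
    (S_a1, S_a2, S_b1, S_b2); entries are signed through-plane means of the
    steady-state amplitudes. Lookup is linear interpolation, restricted to
    the grid range.
    """

    lambda_grid: np.ndarray
    signals: np.ndarray
    profile_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.lambda_grid.ndim != 1 or np.any(np.diff(self.lambda_grid) <= 0):
            raise ValueError("lambda_grid must be strictly ascending 1-D")
        if self.signals.shape != (self.lambda_grid.size, 4):
            raise ValueError("signals must have shape (len(lambda_grid), 4)")

    @property
    def lambda_max(self) -> float:
        return float(self.lambda_grid[-1])

    def lookup(self, lam):
        """Interpolated 4-signal vector(s) at λ; exact at grid nodes."""
        lam = np.asarray(lam, dtype=float)
        if np.any(lam < self.lambda_grid[0]) or np.any(lam > self.lambda_grid[-1]):
            raise ValueError(
                "lambda outside dictionary range "
                f"[{self.lambda_grid[0]}, {self.lambda_grid[-1]}]"
            )
        out = np.empty(lam.shape + (4,))
        for j in range(4):
            out[..., j] = np.interp(lam, self.lambda_grid, self.signals[:, j])
        return out

    def to_csv(self, path) -> None:
        """Serialize to CSV with a JSON metadata header line."""
        header = "# " + json.dumps(self.profile_meta, sort_keys=True)
        body = np.column_stack([self.lambda_grid, self.signals])
        with open(path, "w") as fh:
            fh.write(header + "\n")
            fh.write("lambda,s_a1,s_a2,s_b1,s_b2\n")
            np.savetxt(fh, body, delimiter=",", fmt="%.10g")

    @classmethod
    def from_csv(cls, path) -> "SliceProfileDictionary":
        with open(path) as fh:
            first = fh.readline()
            meta = json.loads(first[1:].strip()) if first.startswith("#") else {}
            rest = fh.read()
        data = np.loadtxt(_io.StringIO(rest), delimiter=",", skiprows=1)
        return cls(data[:, 0], data[:, 1:], meta)


def build_slice_dictionary(
    seq: SequenceParams,
    pulse: PulseSpec = PulseSpec(),
    t1: float = 1000.0,
    grid=None,
    n_positions: int | None = None,
) -> SliceProfileDictionary:
    """Build the slice-profile dictionary for one parameter set.

    For each λ on ``grid`` (default 0–30 in 0.01 steps, spanning the
    near-wire hotspot's dynamic range) the four signals are evaluated at
    effective flip angles α_{x,i}·λ·p(z) at each of the through-plane
    positions of the Bloch-simulated profile and averaged (signed).
    """
    if n_positions is not None:
        pulse = PulseSpec(
            shape=pulse.shape,
            time_bandwidth=pulse.time_bandwidth,
            n_positions=n_positions,
            extent_factor=pulse.extent_factor,
            n_segments=pulse.n_segments,
            ref_flip_deg=pulse.ref_flip_deg,
        )
    if grid is None:
        grid = np.arange(0.0, 30.0 + 1e-9, 0.01)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly ascending 1-D")

    _, p = slice_profile(pulse)
    # effective center-of-slice λ per through-plane position: λ·p(z)
    lam_eff = grid[:, None] * p[None, :]
    signals = np.empty((grid.size, 4))
    for j, (which, idx) in enumerate([("a", 0), ("a", 1), ("b", 0), ("b", 1)]):
        s1, s2 = afi_signals(lam_eff, t1, seq, which)
        signals[:, j] = (s1 if idx == 0 else s2).mean(axis=1)
    meta = {
        "t1_ms": t1,
        "pulse": pulse.shape,
        "time_bandwidth": pulse.time_bandwidth,
        "n_positions": pulse.n_positions,
        "extent_factor": pulse.extent_factor,
        "sequence": vars(seq) if not hasattr(seq, "__dataclass_fields__") else {
            k: getattr(seq, k) for k in seq.__dataclass_fields__
        },
    }
    return SliceProfileDictionary(grid, signals, meta)


def lookup_signals(dictionary: SliceProfileDictionary, lam):
    """Interpolate the dictionary at λ (module-surface wrapper)."""
    return dictionary.lookup(lam)


@lru_cache(maxsize=4)
def _cached_dictionary(seq: SequenceParams, t1: float) -> SliceProfileDictionary:
    return build_slice_dictionary(seq, t1=t1)


def default_dictionary(
    seq: SequenceParams | None = None, t1: float = 1000.0
) -> SliceProfileDictionary:
    """Dictionary for the default protocol, cached across calls."""
    return _cached_dictionary(seq or SequenceParams(), float(t1))
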