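"""Real spherical/spheroidal harmonic potentials and basis matrices.

The magnetic scalar potential outside the sources is expanded either in
solid spherical harmonics or in prolate spheroidal harmonics.  In the
spheroidal case the radial dependence of the spherical solution,
``(rref/r)^(l+1)`` (internal) and ``(r/rref)^l`` (external), is replaced
by ratios of associated Legendre functions of the second and first kind
evaluated at ``rmaj/c``, normalized to 1 on the reference surface
``rmaj = a``.  Both families reduce to the same functions as the focal
distance ``c`` goes to zero.

The channels x harmonics basis matrix H = [Hin Hout] is assembled by
taking the directional derivative of each potential along every channel
orientation at the channel position (the measured field component, up to
the constant -mu0 which is absorbed into the per-column scales).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, sph_harm_y

from .geometry import ReferenceSpheroid, SensorArray, to_prolate_spheroidal, to_spherical

__all__ = [
    "HarmonicBasis",
    "real_sph_harm",
    "q_ratio",
    "p_ratio",
    "potential_value",
    "build_basis",
]

#: default series truncation tolerance for the Legendre-Q ratio
DEFAULT_TOL = 1e-12
_SERIES_CAP = 200


@dataclass(frozen=True)
class HarmonicBasis:
    """Channels x harmonics matrix with per-column metadata.

    ``matrix`` columns are normalized to unit Euclidean norm; the
    original norms are kept in ``scales`` so that model coefficients can
    be mapped back to Tesla.  ``meta`` is a list of dicts with keys
    ``kind`` ("internal"/"external"), ``l``, ``m`` and ``family``.
    """

    matrix: np.ndarray
    meta: list[dict]
    scales: np.ndarray
    frame: ReferenceSpheroid

    def __post_init__(self) -> None:
        seen = set()
        for col in self.meta:
            key = (col["kind"], col["l"], col["m"])
            if key in seen:
                raise ValueError(f"duplicate harmonic column {key}")
            seen.add(key)
        if np.any(np.asarray(self.scales) <= 0):
            raise ValueError("column scales must be positive")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def _block(self, kind: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.meta) if c["kind"] == kind]
        return self.matrix[:, idx]

    @property
    def internal(self) -> np.ndarray:
        """Hin: columns modelling fields from inside the array."""
        return self._block("internal")

    @property
    def external(self) -> np.ndarray:
        """Hout: columns modelling interference from outside."""
        return self._block("external")


def real_sph_harm(l: int, m: int, theta, phi):
    """Real surface spherical harmonic S_lm, orthonormal on the sphere.

    cos(m phi) branches for m > 0, sin(|m| phi) for m < 0, and the
    zonal harmonic for m = 0.  Vectorized over theta/phi.
    """
    if abs(m) > l:
        raise ValueError(f"|m| = {abs(m)} exceeds l = {l}")
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * np.real(y)
    return np.sqrt(2.0) * (-1.0) ** m * np.imag(y)


def _q_series(l: int, m: int, t, tol: float):
    """Hypergeometric-type series in t**2 entering the Legendre-Q ratio.

    Terms are Gamma((1+l+m)/2+k) Gamma((2+l+m)/2+k) /
    (Gamma(l+3/2+k) k!) t^(2k); gammas in log space.  Converges for
    |t| < 1 (t = c/rmaj); truncated when the next term's relative
    contribution drops below ``tol``.
    """
    t = np.asarray(t, dtype=float)
    s = np.zeros_like(t)
    t2 = t * t
    pw = np.ones_like(t)
    for k in range(_SERIES_CAP):
        lg = (gammaln((1 + l + m) / 2 + k) + gammaln((2 + l + m) / 2 + k)
              - gammaln(l + 1.5 + k) - gammaln(k + 1))
        term = np.exp(lg) * pw
        s = s + term
        if k > 0 and np.all(term <= tol * np.abs(s)):
            return s
        pw = pw * t2
    raise RuntimeError(
        f"Legendre-Q ratio series did not converge at {_SERIES_CAP} terms "
        f"(l={l}, m={m}, max c/rmaj={float(np.max(np.abs(t))):.6f})")


def q_ratio(l: int, m: int, rmaj, c: float, a: float, tol: float = DEFAULT_TOL):
    """Internal spheroidal radial factor Q_l^m(rmaj/c) / Q_l^m(a/c).

    Equals 1 on the reference surface and tends to ``(a/rmaj)^(l+1)``
    as ``c -> 0``.  ``m`` must be non-negative (negative orders share
    the radial part of ``|m|``).
    """
    if m < 0 or m > l:
        raise ValueError("require 0 <= m <= l")
    if tol <= 0:
        raise ValueError("tol must be positive")
    rmaj = np.asarray(rmaj, dtype=float)
    if c <= 0 or a <= c or np.any(rmaj <= c):
        raise ValueError("require rmaj > c and a > c > 0 (use the spherical family at c = 0)")
    pref = (rmaj / a) ** (-l - m - 1) * ((rmaj**2 - c**2) / (a**2 - c**2)) ** (m / 2.0)
    return pref * _q_series(l, m, c / rmaj, tol) / _q_series(l, m, c / a, tol)


def p_ratio(l: int, m: int, rmaj, c: float, a: float):
    """External spheroidal radial factor P_l^m(rmaj/c) / P_l^m(a/c).

    A finite sum (upper index floor((l-m)/2)); equals 1 on the
    reference surface and tends to ``(rmaj/a)^l`` as ``c -> 0``.
    """
    if m < 0 or m > l:
        raise ValueError("require 0 <= m <= l")
    rmaj = np.asarray(rmaj, dtype=float)
    if c <= 0 or a <= c or np.any(rmaj <= c):
        raise ValueError("require rmaj > c and a > c > 0 (use the spherical family at c = 0)")

    def fin(t):
        t = np.asarray(t, dtype=float)
        s = np.zeros_like(t)
        for k in range((l - m) // 2 + 1):
            lg = (gammaln(2 * l - 2 * k + 1) - gammaln(k + 1)
                  - gammaln(l - k + 1) - gammaln(l - 2 * k - m + 1))
            s = s + (-1.0) ** k * np.exp(lg) * t ** (2 * k)
        return s

    pref = (rmaj / a) ** (l - m) * ((rmaj**2 - c**2) / (a**2 - c**2)) ** (m / 2.0)
    return pref * fin(c / rmaj) / fin(c / a)


def _radial_factor(kind: str, family: str, l: int, m: int, coords, frame: ReferenceSpheroid,
                   tol: float = DEFAULT_TOL):
    if family == "spherical":
        r = coords.r
        rref = frame.a
        if kind == "internal":
            with np.errstate(divide="ignore"):
                return (rref / r) ** (l + 1)
        return (r / rref) ** l
    if kind == "internal":
        return q_ratio(l, abs(m), coords.rmaj, frame.c, frame.a, tol=tol)
    return p_ratio(l, abs(m), coords.rmaj, frame.c, frame.a)


def _coords_for(points: np.ndarray, family: str, frame: ReferenceSpheroid):
    # both families share the frame's axes (polar axis = spheroid major
    # axis) so that the spheroidal basis reduces to the spherical one
    # as c -> 0
    if family == "spherical":
        local = (np.atleast_2d(points) - frame.centre) @ frame.frame()
        return to_spherical(local, np.zeros(3))
    return to_prolate_spheroidal(points, frame)


def potential_value(kind: str, family: str, l: int, m: int, points, frame: ReferenceSpheroid):
    """Scalar-potential harmonic at Cartesian ``points``.

    internal: decays with distance (brain-side sources);
    external: grows with distance (interference).  Negative orders use
    the sin branch of the real harmonics with radial ratios at |m|.
    The constant -mu0 is absorbed into basis column scales.
    """
    if kind not in ("internal", "external"):
        raise ValueError(f"unknown kind {kind!r}")
    if family not in ("spherical", "spheroidal"):
        raise ValueError(f"unknown family {family!r}")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    coords = _coords_for(points, family, frame)
    return _radial_factor(kind, family, l, m, coords, frame) * real_sph_harm(l, m, coords.theta, coords.phi)


def _directional_gradient(kind: str, family: str, l: int, m: int,
                          positions: np.ndarray, orientations: np.ndarray,
                          frame: ReferenceSpheroid, step: float) -> np.ndarray:
    """orientation . grad V by central differences along each axis."""
    n = positions.shape[0]
    stencil = np.empty((6, n, 3))
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = step
        stencil[2 * ax] = positions + e
        stencil[2 * ax + 1] = positions - e
    vals = potential_value(kind, family, l, m, stencil.reshape(-1, 3), frame).reshape(6, n)
    grad = np.stack([(vals[0] - vals[1]), (vals[2] - vals[3]), (vals[4] - vals[5])], axis=1) / (2 * step)
    return np.einsum("ij,ij->i", orientations, grad)


def build_basis(array: SensorArray, frame: ReferenceSpheroid, family: str = "spheroidal",
                L_in: int = 9, L_out: int = 2, external_family: str = "spherical",
                grad_step: float | None = None) -> HarmonicBasis:
    """Assemble the channels x harmonics matrix H = [Hin Hout].

    Column ``(kind, l, m)`` holds the field component of that harmonic
    along each channel orientation, evaluated by central finite
    differences of the scalar potential (step ``grad_step``, default
    ``1e-6 * a``).  Columns are ordered internal first (l = 1..L_in,
    m = -l..l) then external, and normalized to unit norm with the
    original norms retained in ``scales``.

    The degree l = 0 carries no field gradient information and is
    excluded from both blocks, giving l**2 + 2l columns per block.  By
    default the external block uses the spherical family regardless of
    the internal one: at L_out = 2 it spans exactly the homogeneous
    fields and first-order gradients that model distant interference.
    """
    if L_in < 1 or L_out < 1:
        raise ValueError("L_in and L_out must be >= 1")
    step = grad_step if grad_step is not None else 1e-6 * frame.a
    if family == "spheroidal":
        rmaj = to_prolate_spheroidal(array.positions, frame).rmaj
        if np.any(rmaj < frame.a):
            warnings.warn(
                f"{int(np.sum(rmaj < frame.a))} channel(s) lie inside the reference spheroid; "
                "internal-series convergence is not guaranteed there", stacklevel=2)

    cols, meta = [], []
    for kind, fam, L in (("internal", family, L_in), ("external", external_family, L_out)):
        for l in range(1, L + 1):
            for m in range(-l, l + 1):
                cols.append(_directional_gradient(kind, fam, l, m, array.positions,
                                                  array.orientations, frame, step))
                meta.append({"kind": kind, "l": l, "m": m, "family": fam})
    H = np.column_stack(cols)
    scales = np.linalg.norm(H, axis=0)
    if np.any(scales == 0):
        raise ValueError("zero-norm harmonic column; check array geometry")
    return HarmonicBasis(matrix=H / scales, meta=meta, scales=scales, frame=frame)
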