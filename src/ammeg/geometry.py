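"""Coordinate systems and sensor-array geometry.

Everything in this package lives in SI units (metres).  Two coordinate
systems are provided: ordinary spherical coordinates and prolate
spheroidal coordinates adapted to a head-shaped reference spheroid
(anterior-posterior axis longer than the other two).  The confocal
"major-axis" radial coordinate ``rmaj`` reduces to the spherical radius
as the focal distance ``c`` goes to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReferenceSpheroid",
    "SensorArray",
    "SphericalCoords",
    "SpheroidalCoords",
    "to_spherical",
    "to_prolate_spheroidal",
    "spheroidal_to_cartesian",
    "fit_reference_spheroid",
    "generate_scalp_array",
    "complete_axes",
]


@dataclass(frozen=True)
class ReferenceSpheroid:
    """Prolate reference spheroid enclosing the brain (or sensor array).

    Parameters
    ----------
    centre : (3,) array
        Centre of the spheroid in metres.
    axis : (3,) array
        Unit vector along the major axis.  The two foci sit at
        ``centre +/- c * axis``.
    a, b : float
        Major and minor semi-axes in metres, ``a >= b > 0``.
    """

    centre: np.ndarray
    axis: np.ndarray
    a: float
    b: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "centre", np.asarray(self.centre, dtype=float))
        ax = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(ax)
        if abs(n - 1.0) > 1e-12:
            raise ValueError(f"axis must be a unit vector (norm {n!r})")
        object.__setattr__(self, "axis", ax)
        if not (self.a >= self.b > 0):
            raise ValueError(f"require a >= b > 0, got a={self.a}, b={self.b}")

    @property
    def c(self) -> float:
        """Focal distance ``sqrt(a**2 - b**2)``."""
        return float(np.sqrt(self.a**2 - self.b**2))

    @property
    def foci(self) -> np.ndarray:
        """(2, 3) array with the two foci."""
        return np.stack([self.centre + self.c * self.axis,
                         self.centre - self.c * self.axis])

    def frame(self) -> np.ndarray:
        """Right-handed orthonormal frame with the major axis third.

        Returns a 3x3 matrix whose columns are (t1, t2, axis); local
        coordinates are ``R.T @ (p - centre)``.
        """
        t1, t2 = complete_axes(self.axis)
        return np.column_stack([t1, t2, self.axis])

    def scaled(self, factor: float) -> "ReferenceSpheroid":
        """Concentric spheroid with both semi-axes scaled by ``factor``."""
        return ReferenceSpheroid(self.centre, self.axis,
                                 self.a * factor, self.b * factor)


@dataclass(frozen=True)
class SensorArray:
    """Channel geometry of an OPM array.

    A *sensor* is a physical device; each of its 1-3 orthogonal
    measurement axes is a *channel*.  Channels of one sensor share a
    position.
    """

    names: list[str]
    positions: np.ndarray      # (n_c, 3) metres
    orientations: np.ndarray   # (n_c, 3) unit vectors
    axes_per_sensor: int = 1
    sensor_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        ori = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        if pos.shape != ori.shape or pos.shape[1] != 3:
            raise ValueError(f"positions {pos.shape} / orientations {ori.shape} must both be (n_c, 3)")
        if len(self.names) != pos.shape[0]:
            raise ValueError("names must align with channel rows")
        norms = np.linalg.norm(ori, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-10):
            raise ValueError("orientations must be unit vectors (tol 1e-10)")
        si = self.sensor_index
        if si is None:
            si = np.arange(pos.shape[0]) // self.axes_per_sensor
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)
        object.__setattr__(self, "sensor_index", np.asarray(si, dtype=int))

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @property
    def n_sensors(self) -> int:
        return int(len(np.unique(self.sensor_index)))


@dataclass(frozen=True)
class SphericalCoords:
    """Spherical coordinates: radius, co-latitude, longitude."""
    r: np.ndarray
    theta: np.ndarray
    phi: np.ndarray


@dataclass(frozen=True)
class SpheroidalCoords:
    """Prolate spheroidal coordinates.

    ``rmaj`` is the confocal major-axis coordinate (half the sum of the
    distances to the two foci, so ``rmaj >= c`` everywhere and
    ``rmaj == a`` on the reference surface); theta/phi are the
    co-latitude and longitude about the major axis.
    """
    rmaj: np.ndarray
    theta: np.ndarray
    phi: np.ndarray


def to_spherical(points: np.ndarray, origin: np.ndarray = (0.0, 0.0, 0.0)) -> SphericalCoords:
    """Cartesian -> spherical about ``origin``.

    ``r = |p - origin|``, ``theta = acos(z'/r)``, ``phi = atan2(y', x')``.
    The origin itself maps to (0, 0, 0) by convention.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(origin, dtype=float)
    r = np.linalg.norm(p, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ct = np.where(r > 0, p[:, 2] / np.where(r > 0, r, 1.0), 1.0)
    theta = np.arccos(np.clip(ct, -1.0, 1.0))
    phi = np.arctan2(p[:, 1], p[:, 0])
    zero = r == 0
    theta = np.where(zero, 0.0, theta)
    phi = np.where(zero, 0.0, phi)
    return SphericalCoords(r=r, theta=theta, phi=phi)


def to_prolate_spheroidal(points: np.ndarray, spheroid: ReferenceSpheroid) -> SpheroidalCoords:
    """Cartesian -> prolate spheroidal coordinates of ``spheroid``.

    Uses the confocal construction: with ``d+``/``d-`` the distances to
    the foci at ``centre +/- c*axis``,

    * ``rmaj = (d+ + d-) / 2``
    * ``cos(theta) = (d- - d+) / (2 c)``  (clamped to [-1, 1])
    * ``phi`` is the azimuth about the major axis in the spheroid frame.

    Degenerate spheroids (``c == 0``) are rejected; use
    :func:`to_spherical` for spheres.
    """
    c = spheroid.c
    if c <= 0:
        raise ValueError("spheroid is degenerate (c = 0); use to_spherical")
    p = np.atleast_2d(np.asarray(points, dtype=float))
    local = (p - spheroid.centre) @ spheroid.frame()  # columns t1, t2, axis
    dplus = np.linalg.norm(local - np.array([0.0, 0.0, c]), axis=1)
    dminus = np.linalg.norm(local + np.array([0.0, 0.0, c]), axis=1)
    rmaj = 0.5 * (dplus + dminus)
    costheta = np.clip((dminus - dplus) / (2.0 * c), -1.0, 1.0)
    theta = np.arccos(costheta)
    phi = np.arctan2(local[:, 1], local[:, 0])
    return SpheroidalCoords(rmaj=rmaj, theta=theta, phi=phi)


def spheroidal_to_cartesian(coords: SpheroidalCoords, spheroid: ReferenceSpheroid) -> np.ndarray:
    """Inverse of :func:`to_prolate_spheroidal` (world-frame points)."""
    c = spheroid.c
    rmaj = np.asarray(coords.rmaj, dtype=float)
    st, ct = np.sin(coords.theta), np.cos(coords.theta)
    rho = np.sqrt(np.maximum(rmaj**2 - c**2, 0.0)) * st
    local = np.column_stack([rho * np.cos(coords.phi), rho * np.sin(coords.phi), rmaj * ct])
    return spheroid.centre + local @ spheroid.frame().T


def complete_axes(radial: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Complete a radial unit vector to an orthonormal triad.

    Given radial ``[p, q, r]`` the first tangential axis is the
    normalized ``[-q, p, 0]`` (zero the third component, swap the
    remaining two and negate the first, so the dot product with the
    original vanishes identically); the second is the cross product of
    the two.  When the radial axis is ``[0, 0, +/-1]`` this construction
    degenerates and ``[1, 0, 0]`` is used as the documented tie-break.
    """
    v = np.asarray(radial, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-8:
        raise ValueError("radial must be a unit vector")
    t1 = np.array([-v[1], v[0], 0.0])
    n = np.linalg.norm(t1)
    if n < 1e-12:
        t1 = np.array([1.0, 0.0, 0.0])
    else:
        t1 = t1 / n
    t2 = np.cross(v, t1)
    t2 = t2 / np.linalg.norm(t2)
    return t1, t2


def _principal_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and principal (largest-variance) direction of a cloud."""
    p = np.asarray(points, dtype=float)
    centre = p.mean(axis=0)
    cov = np.cov((p - centre).T)
    if np.linalg.matrix_rank(cov, tol=1e-12 * max(np.trace(cov), 1e-300)) < 3:
        raise ValueError("degenerate point cloud: covariance rank < 3 (points coplanar or collinear)")
    w, v = np.linalg.eigh(cov)
    axis = v[:, -1]
    if axis[np.argmax(np.abs(axis))] < 0:  # deterministic sign
        axis = -axis
    return centre, axis / np.linalg.norm(axis)


def fit_reference_spheroid(points: np.ndarray, mode: str = "least_squares") -> ReferenceSpheroid:
    """Fit a prolate reference spheroid to a point cloud.

    The axis is the principal direction of the cloud and the centre its
    centroid.  ``least_squares`` minimizes the mean squared algebraic
    residual ``(z^2/a^2 + rho^2/b^2 - 1)^2`` (linear in ``1/a^2``,
    ``1/b^2``); ``enclose`` returns the smallest-volume spheroid in that
    frame containing every point.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if p.shape[0] < 10:
        raise ValueError("need at least 10 points to fit a spheroid")
    centre, axis = _principal_axis(p)
    t1, t2 = complete_axes(axis)
    local = (p - centre) @ np.column_stack([t1, t2, axis])
    z2 = local[:, 2] ** 2
    rho2 = local[:, 0] ** 2 + local[:, 1] ** 2

    if mode == "least_squares":
        # (z^2) * u + (rho^2) * v ~= 1  with u = 1/a^2, v = 1/b^2
        A = np.column_stack([z2, rho2])
        sol, *_ = np.linalg.lstsq(A, np.ones(len(z2)), rcond=None)
        u, v = sol
        if u <= 0 or v <= 0:
            raise ValueError("least-squares spheroid fit produced non-positive axes; cloud too irregular")
        a, b = 1.0 / np.sqrt(u), 1.0 / np.sqrt(v)
    elif mode == "enclose":
        a, b = _enclosing_semi_axes(np.sqrt(z2), np.sqrt(rho2))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if b > a:  # oblate solution: fall back to the tightest sphere in this frame
        r = float(np.sqrt(np.max(z2 + rho2))) if mode == "enclose" else float(np.sqrt(a * b))
        a = b = r
    return ReferenceSpheroid(centre=centre, axis=axis, a=float(a), b=float(b))


def _enclosing_semi_axes(absz: np.ndarray, rho: np.ndarray) -> tuple[float, float]:
    """Smallest-volume (a, b): containment needs b >= max rho/sqrt(1-z^2/a^2)."""
    from scipy.optimize import minimize_scalar

    zmax = float(np.max(absz))
    rmax = float(np.max(rho))
    if rmax == 0:
        return zmax, zmax * 1e-6

    def b_of(a: float) -> float:
        s = 1.0 - (absz / a) ** 2
        s = np.maximum(s, 1e-300)
        return float(np.max(rho / np.sqrt(s)))

    def volume(loga: float) -> float:
        a = np.exp(loga)
        return float(np.log(a) + 2 * np.log(b_of(a)))

    res = minimize_scalar(volume, bounds=(np.log(zmax * (1 + 1e-9)), np.log(10 * (zmax + rmax))),
                          method="bounded", options={"xatol": 1e-12})
    a = float(np.exp(res.x))
    b = b_of(a)
    # guarantee exact containment against round-off
    scale = float(np.max(np.sqrt((absz / a) ** 2 + (rho / b) ** 2)))
    if scale > 1.0:
        a, b = a * scale, b * scale
    return a, b


def _fibonacci_surface(spheroid: ReferenceSpheroid, n: int, phase: float) -> np.ndarray:
    """Quasi-uniform candidate points on the spheroid surface (local frame).

    Fibonacci lattice on the unit sphere, stretched onto the spheroid.
    ``phase`` rotates the spiral about the major axis (seeded jitter).
    """
    i = np.arange(n) + 0.5
    ct = 1.0 - 2.0 * i / n
    st = np.sqrt(1.0 - ct**2)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i + phase
    return np.column_stack([spheroid.b * st * np.cos(phi),
                            spheroid.b * st * np.sin(phi),
                            spheroid.a * ct])


def _surface_normal_local(spheroid: ReferenceSpheroid, local: np.ndarray) -> np.ndarray:
    """Outward unit normal of the spheroid surface at local points."""
    n = np.column_stack([local[:, 0] / spheroid.b**2,
                         local[:, 1] / spheroid.b**2,
                         local[:, 2] / spheroid.a**2])
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def generate_scalp_array(spheroid: ReferenceSpheroid, spacing: float = 0.035,
                         offset: float = 0.0065, axes: int = 1,
                         seed: int = 0) -> SensorArray:
    """Pack point magnetometers on a scalp spheroid.

    Sensors are seeded from a Fibonacci lattice on the spheroid surface
    and thinned greedily so every pair is at least ``spacing`` apart,
    then displaced ``offset`` metres along the outward surface normal
    (stand-off of the sensitive cell from the scalp).  The first channel
    axis of each sensor is the outward normal ("radial"); for 2- and
    3-axis sensors the tangential axes follow :func:`complete_axes`.
    Deterministic for a given seed.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if axes not in (1, 2, 3):
        raise ValueError("axes must be 1, 2 or 3")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    area = 4.0 * np.pi * ((spheroid.a * spheroid.b) ** 1.0 + spheroid.b**2) / 2.0  # crude
    n_cand = max(int(8.0 * area / spacing**2), 64)
    cand = _fibonacci_surface(spheroid, n_cand, phase)
    kept: list[np.ndarray] = []
    for pt in cand:
        if all(np.linalg.norm(pt - k) >= spacing for k in kept):
            kept.append(pt)
    if len(kept) < 2:
        raise ValueError(f"spacing {spacing} m too large for this surface: zero sensors fit")
    local = np.asarray(kept)
    normals_local = _surface_normal_local(spheroid, local)
    R = spheroid.frame()
    pos_sensor = spheroid.centre + (local + offset * normals_local) @ R.T
    normals = normals_local @ R.T

    names, positions, orientations, sensor_idx = [], [], [], []
    suffix = ["RAD", "TAN1", "TAN2"]
    for s, (p, nrm) in enumerate(zip(pos_sensor, normals)):
        t1, t2 = complete_axes(nrm)
        oris = [nrm, t1, t2][:axes]
        for ax, o in enumerate(oris):
            names.append(f"S{s:03d}-{suffix[ax]}")
            positions.append(p)
            orientations.append(o)
            sensor_idx.append(s)
    return SensorArray(names=names, positions=np.asarray(positions),
                       orientations=np.asarray(orientations),
                       axes_per_sensor=axes, sensor_index=np.asarray(sensor_idx))
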