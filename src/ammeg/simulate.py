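"""Synthetic OPM scenarios: lead fields, interference, nonlinearity, noise.

The forward model is the analytic field of a current dipole in a
homogeneous conducting sphere (Sarvas), centred at the reference-
spheroid centroid with radius equal to the minor semi-axis.  Sources are
placed quasi-uniformly on an inner spheroidal surface with
surface-normal orientations, emulating a cortical sheet.  Interference
is a physical static field: a homogeneous component plus a symmetric
traceless first-order gradient (8 degrees of freedom).  Sensor
nonlinearity is a channel-wise multiplicative gain topography drawn
from the same low-order family, which couples interference into spatial
patterns the external model cannot represent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ReferenceSpheroid, SensorArray, _fibonacci_surface, _surface_normal_local
from .projectors import Projector

__all__ = [
    "LeadFieldSet",
    "InterferenceModel",
    "default_head",
    "single_sphere_leadfield",
    "leadfield_matrix",
    "cortical_source_set",
    "interference_topography",
    "random_interference",
    "apply_nonlinearity",
    "worst_case_shielding",
    "white_noise",
    "CORTICAL_SHELLS",
    "cortical_volume_sources",
    "array_with_channel_count",
    "figure2_protocol",
    "figure3_protocol",
    "figure4_protocol",
]

MU0_4PI = 1e-7  # mu0 / 4 pi, T m / A


def default_head() -> ReferenceSpheroid:
    """Scalp reference spheroid used throughout the simulations.

    Major semi-axis 9 cm along +y (anterior-posterior), minor 7 cm:
    adult-head scale with a clearly prolate geometry.
    """
    return ReferenceSpheroid(centre=np.zeros(3), axis=np.array([0.0, 1.0, 0.0]),
                             a=0.09, b=0.07)


@dataclass(frozen=True)
class LeadFieldSet:
    """Lead fields (T per A m) of a set of dipolar sources."""

    matrix: np.ndarray     # (n_c, n_src)
    src_pos: np.ndarray    # (n_src, 3)
    src_ori: np.ndarray    # (n_src, 3) unit

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("lead-field matrix contains non-finite values")


@dataclass(frozen=True)
class InterferenceModel:
    """Static interference field: B0 (3) + symmetric traceless gradient (5).

    ``coeffs`` = [B0x, B0y, B0z, Gxx, Gyy, Gxy, Gxz, Gyz] with
    Gzz = -Gxx - Gyy (divergence-free) and G symmetric (curl-free).
    """

    coeffs: np.ndarray

    def __post_init__(self) -> None:
        co = np.asarray(self.coeffs, dtype=float)
        if co.shape != (8,):
            raise ValueError("coeffs must be an 8-vector")
        object.__setattr__(self, "coeffs", co)

    @property
    def B0(self) -> np.ndarray:
        return self.coeffs[:3]

    @property
    def gradient(self) -> np.ndarray:
        gxx, gyy, gxy, gxz, gyz = self.coeffs[3:]
        return np.array([[gxx, gxy, gxz],
                         [gxy, gyy, gyz],
                         [gxz, gyz, -gxx - gyy]])


def single_sphere_leadfield(array: SensorArray, src_pos, src_ori,
                            sphere_centre) -> np.ndarray:
    """Field of a unit current dipole in a homogeneous conducting sphere.

    Sarvas' closed form, projected onto the channel orientations.
    Radial dipole components are magnetically silent.  Errors if the
    source sits at the sphere centre or outside the sensor shell.
    """
    r0 = np.asarray(src_pos, dtype=float) - np.asarray(sphere_centre, dtype=float)
    q = np.asarray(src_ori, dtype=float)
    if np.linalg.norm(r0) < 1e-12:
        raise ValueError("source at the sphere centre has no magnetic field")
    r = array.positions - np.asarray(sphere_centre, dtype=float)
    rn = np.linalg.norm(r, axis=1)
    # on a spheroidal head some sources sit beyond the *closest* sensors;
    # only sources beyond the outermost sensor shell are rejected
    if np.linalg.norm(r0) >= rn.max():
        raise ValueError("source lies outside (or on) the sensor shell")
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    F = a * (rn * a + rn**2 - r @ r0)
    adotr = np.einsum("ij,ij->i", a_vec, r)
    gradF = ((a**2 / rn + adotr / a + 2 * a + 2 * rn)[:, None] * r
             - (a + 2 * rn + adotr / a)[:, None] * r0)
    qxr0 = np.cross(q, r0)
    B = MU0_4PI / F[:, None] ** 2 * (F[:, None] * qxr0 - (r @ qxr0)[:, None] * gradF)
    return np.einsum("ij,ij->i", array.orientations, B)


def cortical_source_set(spheroid: ReferenceSpheroid, n_src: int = 500,
                        seed: int = 0, scale: float = 0.9) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-uniform dipoles on an inner spheroidal "cortical" surface.

    Sources sit on the spheroid scaled by ``scale`` (default 0.9 of the
    scalp) with orientations along the local surface normal.
    Deterministic for a given seed (the seed rotates the lattice).
    """
    if n_src < 1:
        raise ValueError("n_src must be >= 1")
    inner = spheroid.scaled(scale)
    rng = np.random.default_rng(seed)
    local = _fibonacci_surface(inner, n_src, rng.uniform(0, 2 * np.pi))
    normals = _surface_normal_local(inner, local)
    R = inner.frame()
    return inner.centre + local @ R.T, normals @ R.T


def leadfield_matrix(array: SensorArray, src_pos: np.ndarray, src_ori: np.ndarray,
                     sphere_centre) -> LeadFieldSet:
    """Stack :func:`single_sphere_leadfield` columns for many sources."""
    cols = [single_sphere_leadfield(array, p, o, sphere_centre)
            for p, o in zip(src_pos, src_ori)]
    return LeadFieldSet(matrix=np.column_stack(cols), src_pos=np.asarray(src_pos),
                        src_ori=np.asarray(src_ori))


def interference_topography(array: SensorArray, model: InterferenceModel,
                            origin=None) -> np.ndarray:
    """Channel pattern of a homogeneous-plus-gradient static field.

    value_i = orientation_i . (B0 + G (r_i - r_origin)); the gradient
    expansion point defaults to the array centroid.
    """
    r0 = array.positions.mean(axis=0) if origin is None else np.asarray(origin, dtype=float)
    B = model.B0[None, :] + (array.positions - r0) @ model.gradient.T
    return np.einsum("ij,ij->i", array.orientations, B)


def random_interference(array: SensorArray, rng: np.random.Generator,
                        origin=None) -> np.ndarray:
    """Random low-order interference topography scaled to unit channel rms."""
    # gradient coefficients drawn at head scale so both terms contribute
    co = rng.standard_normal(8)
    co[3:] /= max(np.ptp(np.linalg.norm(array.positions, axis=1)), 0.05)
    topo = interference_topography(array, InterferenceModel(co), origin)
    rms = np.sqrt(np.mean(topo**2))
    if rms == 0:
        raise ValueError("degenerate interference draw")
    return topo / rms


def apply_nonlinearity(E: np.ndarray, n_topo: np.ndarray, e_max: float) -> np.ndarray:
    """Channel-wise multiplicative corruption of interference data.

    The nonlinearity topography is rescaled so its largest channel gain
    error is ``e_max`` (fractional); the output is (I + diag(n)) E.
    """
    if not (0 <= e_max <= 0.2):
        raise ValueError("e_max must lie in [0, 0.2]")
    E = np.asarray(E, dtype=float)
    if e_max == 0:
        return E.copy()
    n = np.asarray(n_topo, dtype=float)
    peak = np.max(np.abs(n))
    if peak == 0:
        raise ValueError("zero nonlinearity topography with e_max > 0")
    n = n * (e_max / peak)
    return (1.0 + n)[:, None] * E.reshape(len(n), -1) if E.ndim > 1 else (1.0 + n) * E


def worst_case_shielding(array: SensorArray, P: Projector, n_interf: int = 50,
                         n_nonlin: int = 20, e_max: float = 0.01,
                         rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Minimum shielding factor over random corrupted interference.

    For each of ``n_interf`` interference topographies and ``n_nonlin``
    independent nonlinearity topographies the shielding factor is
    rms(corrupted) / rms(P corrupted); the minimum (linear, dB) pair is
    returned.  Deterministic given the generator state.
    """
    if n_interf < 1 or n_nonlin < 1:
        raise ValueError("draw counts must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    worst = np.inf
    for _ in range(n_interf):
        topo = random_interference(array, rng)
        for _ in range(n_nonlin):
            if e_max > 0:
                nl = random_interference(array, rng)
                x = apply_nonlinearity(topo, nl, e_max)
            else:
                x = topo
            num = np.sqrt(np.mean(x**2))
            den = np.sqrt(np.mean((P.matrix @ x) ** 2))
            worst = min(worst, num / max(den, 1e-300))
    return float(worst), float(20.0 * np.log10(worst))


def white_noise(n_c: int, n_t: int, sigma: float = 1.0,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """iid Gaussian sensor noise, (n_c, n_t), standard deviation sigma."""
    rng = np.random.default_rng(0) if rng is None else rng
    return sigma * rng.standard_normal((n_c, n_t))


#: shell scales of the cortical-volume emulation: deep cortex / mid
#: cortex / gyral crowns, roughly 3.5 cm to 1 cm below the scalp.
CORTICAL_SHELLS = (0.60, 0.72, 0.85)


def cortical_volume_sources(spheroid: ReferenceSpheroid, n_per_shell: int = 170,
                            seed: int = 0,
                            scales: tuple[float, ...] = CORTICAL_SHELLS
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Sources spread over a depth range emulating a cortical sheet.

    A single shell cannot stand in for a brain: the hardest sources for
    an interference-rejection projector are the deep ones (smooth,
    low-order lead fields) while the hardest for basis convergence are
    the shallow ones.  Concatenates :func:`cortical_source_set` shells
    at the given scalp fractions.
    """
    ps, os_ = [], []
    for i, sc in enumerate(scales):
        p, o = cortical_source_set(spheroid, n_src=n_per_shell, seed=seed + i, scale=sc)
        ps.append(p)
        os_.append(o)
    return np.vstack(ps), np.vstack(os_)


def array_with_channel_count(spheroid: ReferenceSpheroid, n_channels: int,
                             axes: int = 3, seed: int = 0,
                             offset: float = 0.0065) -> SensorArray:
    """Scalp array whose channel count is as close as possible to a target.

    Scans the packing spacing (coarse-to-fine) and returns the array
    with the smallest deviation from ``n_channels``.  Deterministic for
    a given seed.
    """
    from .geometry import generate_scalp_array

    best, best_err = None, np.inf
    for spacing in np.arange(0.055, 0.0099, -0.0005):
        arr = generate_scalp_array(spheroid, spacing=float(spacing), offset=offset,
                                   axes=axes, seed=seed)
        err = abs(arr.n_channels - n_channels)
        if err < best_err:
            best, best_err = arr, err
        if arr.n_channels >= n_channels and err > best_err:
            break
    return best


def figure2_protocol(spheroid: ReferenceSpheroid | None = None, axes=(1, 2, 3),
                     spacing: float = 0.024, L_in: int = 9, L_out: int = 2,
                     n_per_shell: int = 170, seed: int = 0) -> dict[int, dict]:
    """Worst-case lead-field reconstruction per array type.

    For each axis count, builds a scalp array, the spheroidal order
    ``L_in`` basis, both projectors, and the cortical-volume lead
    fields; reports the minimum over sources of the AMM cosine and the
    SSS square-root-of-variance-explained.
    """
    import warnings as _w

    from .geometry import generate_scalp_array
    from .harmonics import build_basis
    from .metrics import leadfield_correlation
    from .projectors import amm_projector, sss_projector

    head = spheroid or default_head()
    pos, ori = cortical_volume_sources(head, n_per_shell=n_per_shell, seed=seed)
    out: dict[int, dict] = {}
    for ax in axes:
        arr = generate_scalp_array(head, spacing=spacing, offset=offset_default(), axes=ax, seed=seed)
        lf = leadfield_matrix(arr, pos, ori, head.centre)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            b = build_basis(arr, head, family="spheroidal", L_in=L_in, L_out=L_out)
            amm_corr = leadfield_correlation(lf, amm_projector(b), "cosine")
            sss_corr = leadfield_correlation(lf, sss_projector(b), "sqrt_ve")
        out[ax] = {
            "n_sensors": arr.n_sensors,
            "n_channels": arr.n_channels,
            "n_sources": lf.matrix.shape[1],
            "amm_worst_cosine": float(np.nanmin(amm_corr)),
            "sss_worst_sqrt_ve": float(np.nanmin(sss_corr)),
        }
    return out


def figure3_protocol(spheroid: ReferenceSpheroid | None = None, axes=(1, 2),
                     e_max_grid=(0.005, 0.01, 0.02, 0.05, 0.1), spacing: float = 0.024,
                     n_interf: int = 50, n_nonlin: int = 20, seed: int = 0) -> list[dict]:
    """Worst-case shielding vs nonlinearity magnitude for AMM and SSS.

    Both projectors see the same interference/nonlinearity draws at
    each grid point (paired comparison).
    """
    import warnings as _w

    from .geometry import generate_scalp_array
    from .harmonics import build_basis
    from .projectors import amm_projector, sss_projector

    head = spheroid or default_head()
    rows = []
    for ax in axes:
        arr = generate_scalp_array(head, spacing=spacing, offset=offset_default(), axes=ax, seed=seed)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            b = build_basis(arr, head, family="spheroidal", L_in=9, L_out=2)
            projs = {"amm": amm_projector(b), "sss": sss_projector(b)}
        for e_max in e_max_grid:
            for name, P in projs.items():
                lin, db = worst_case_shielding(arr, P, n_interf, n_nonlin, e_max,
                                               rng=np.random.default_rng(seed + 1))
                rows.append({"axes": ax, "e_max": e_max, "projector": name,
                             "worst_shielding": lin, "worst_shielding_db": db})
    return rows


def figure4_protocol(channel_counts=(200, 400), axes: int = 3, n_t: int = 1000,
                     reps: int = 50, seed: int = 0,
                     spheroid: ReferenceSpheroid | None = None) -> list[dict]:
    """White-noise reduction of the AMM projector vs channel count."""
    import warnings as _w

    from .harmonics import build_basis
    from .metrics import white_noise_reduction
    from .projectors import amm_projector

    head = spheroid or default_head()
    rows = []
    for i, n_ch in enumerate(channel_counts):
        arr = array_with_channel_count(head, n_ch, axes=axes, seed=seed)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            b = build_basis(arr, head, family="spheroidal", L_in=9, L_out=2)
            P = amm_projector(b)
        wnr = white_noise_reduction(P, n_t=n_t, reps=reps,
                                    rng=np.random.default_rng(seed + 17 + i))
        rows.append({"n_channels": arr.n_channels, "rank": P.rank,
                     "noise_reduction_db": float(wnr),
                     "rank_law_db": float(10 * np.log10(arr.n_channels / P.rank))})
    return rows


def offset_default() -> float:
    """Scalp stand-off of the sensitive cell (6.5 mm)."""
    return 0.0065
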