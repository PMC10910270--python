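"""Spatial projectors built from a harmonic basis.

Two ways of replacing the data with its internal-harmonic model:

* the classic oblique projector ``P = Hin (Rout Hin)^+`` obtained from
  the joint least-squares fit of the internal and external blocks
  (the partitioned-coefficient identity), which reproduces the internal
  span exactly but can amplify noise when the basis is ill-conditioned;
* the orthogonal projector ``P = (Rout Hin)(Rout Hin)^+`` onto the part
  of the internal span orthogonal to the interference span, which never
  increases variance.

``Rout = I - Hout Hout^+`` annihilates the external (interference)
span in both cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import subspace_angles

from .harmonics import HarmonicBasis

__all__ = [
    "Projector",
    "Recording",
    "regularized_pinv",
    "external_rejector",
    "sss_projector",
    "amm_projector",
    "apply_projector",
    "condition_report",
]


@dataclass(frozen=True)
class Recording:
    """Multichannel magnetometer time series (Tesla)."""

    data: np.ndarray          # (n_c, n_t)
    fs: float                 # Hz
    names: list[str]

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.names) != d.shape[0]:
            raise ValueError("channel names must align with data rows")
        object.__setattr__(self, "data", d)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class Projector:
    """Channels x channels projection matrix with a type tag."""

    matrix: np.ndarray
    ptype: str                 # "orthogonal" | "oblique"
    rank: int
    basis_meta: HarmonicBasis | None = None

    def __post_init__(self) -> None:
        if self.ptype not in ("orthogonal", "oblique"):
            raise ValueError(f"unknown projector type {self.ptype!r}")
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))


def regularized_pinv(M: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """SVD pseudoinverse truncating singular values below ``rtol * s_max``."""
    if rtol < 0:
        raise ValueError("rtol must be >= 0")
    U, s, Vt = np.linalg.svd(np.asarray(M, dtype=float), full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.zeros((M.shape[1], M.shape[0]))
    keep = s > rtol * s[0]
    return (Vt[keep].T / s[keep]) @ U[:, keep].T


def external_rejector(basis: HarmonicBasis, rtol: float = 1e-10) -> Projector:
    """Orthogonal projector ``Rout = I - Hout Hout^+`` off the external span."""
    Hout = basis.external
    if Hout.shape[1] == 0:
        raise ValueError("basis has no external block")
    n_c = basis.n_channels
    P = np.eye(n_c) - Hout @ regularized_pinv(Hout, rtol)
    rank = int(round(np.trace(P)))
    return Projector(matrix=P, ptype="orthogonal", rank=rank, basis_meta=basis)


def sss_projector(basis: HarmonicBasis, rtol: float = 1e-10,
                  cond_ceiling: float = 1e10) -> Projector:
    """Oblique projector ``Hin (Rout Hin)^+`` (joint harmonic fit).

    Reproduces the internal span exactly and annihilates the external
    span, but its stability depends on the conditioning of
    ``Rout Hin``; a warning (not an error) is emitted above
    ``cond_ceiling`` and when the fit is under-determined.
    """
    Hin = basis.internal
    Hout = basis.external
    n_c = basis.n_channels
    if n_c < Hin.shape[1] + Hout.shape[1]:
        warnings.warn(
            f"under-determined fit: {n_c} channels < {Hin.shape[1] + Hout.shape[1]} harmonics",
            stacklevel=2)
    Rout = external_rejector(basis, rtol).matrix
    G = Rout @ Hin
    s = np.linalg.svd(G, compute_uv=False)
    if s[-1] == 0 or s[0] / s[-1] > cond_ceiling:
        warnings.warn(
            f"ill-conditioned internal model (cond(Rout Hin) = {s[0] / max(s[-1], 1e-300):.2e}); "
            "the oblique projection may be unstable", stacklevel=2)
    Gp = regularized_pinv(G, rtol)
    P = Hin @ Gp
    rank = int(np.sum(np.linalg.svd(G, compute_uv=False) > rtol * s[0]))
    return Projector(matrix=P, ptype="oblique", rank=rank, basis_meta=basis)


def amm_projector(basis: HarmonicBasis, rtol: float = 1e-10) -> Projector:
    """Orthogonal projector onto ``span(Rout Hin)``.

    Symmetric idempotent, hence it can only ever decrease variance;
    stable for any array design.
    """
    Hin = basis.internal
    Rout = external_rejector(basis, rtol).matrix
    G = Rout @ Hin
    # orthonormalize the columns; truncation keeps the projector exact
    U, s, _ = np.linalg.svd(G, full_matrices=False)
    keep = s > max(rtol, 1e-12) * s[0]
    Uk = U[:, keep]
    P = Uk @ Uk.T
    return Projector(matrix=P, ptype="orthogonal", rank=int(np.sum(keep)), basis_meta=basis)


def apply_projector(P: Projector, X):
    """Apply a projector to a Recording, a basis matrix or a lead-field matrix."""
    if isinstance(X, Recording):
        if X.n_channels != P.matrix.shape[1]:
            raise ValueError(f"projector is {P.matrix.shape}, recording has {X.n_channels} channels")
        return Recording(data=P.matrix @ X.data, fs=X.fs, names=list(X.names))
    X = np.asarray(X, dtype=float)
    arr = np.atleast_2d(X.T).T if X.ndim == 1 else X
    if arr.shape[0] != P.matrix.shape[1]:
        raise ValueError(f"projector is {P.matrix.shape}, operand is {X.shape}")
    out = P.matrix @ arr
    return out[:, 0] if X.ndim == 1 else out


def condition_report(basis: HarmonicBasis) -> dict:
    """Condition numbers and principal angles of the basis blocks.

    The ratio of largest to smallest singular value of [Hin Hout]
    measures how well the array separates brain signal from
    interference; radial-only arrays are notoriously poor here.
    """
    def cond(M: np.ndarray) -> float:
        s = np.linalg.svd(M, compute_uv=False)
        if s[-1] < 1e-15 * s[0]:
            return float("inf")
        return float(s[0] / s[-1])

    Hin, Hout = basis.internal, basis.external
    angles = subspace_angles(Hin, Hout) if Hin.size and Hout.size else np.array([])
    return {
        "cond_internal": cond(Hin),
        "cond_external": cond(Hout),
        "cond_joint": cond(np.hstack([Hin, Hout])),
        "principal_angles": np.sort(angles),
        "min_angle": float(np.min(angles)) if angles.size else float("nan"),
    }
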