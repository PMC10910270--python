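"""Temporal cleaning by canonical correlation between signal spaces.

After the spatial projection, residual interference (e.g. from sensor
nonlinearity or model truncation) leaks into both the retained inner
space and the spaces discarded by the spatial model.  Time courses that
are very highly correlated between the inner space and the intermediate
space are therefore unlikely to be brain signal and can be removed.

The module also provides the closed-form heuristic for the highest
canonical correlation one expects *by chance* between the neural and
intermediate spaces, used to choose the removal threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .harmonics import HarmonicBasis
from .projectors import Recording, amm_projector, external_rejector, regularized_pinv

__all__ = [
    "SpaceDecomposition",
    "HeuristicParams",
    "decompose_spaces",
    "temporal_clean",
    "correlation_limit",
]


@dataclass(frozen=True)
class SpaceDecomposition:
    """Inner / outer / intermediate split of a recording.

    ``inner`` is the brain-signal model orthogonal to interference,
    ``outer`` the interference model, and ``inter`` everything of
    higher spatial order than either; the three sum to the input.
    """

    inner: np.ndarray
    outer: np.ndarray
    inter: np.ndarray


@dataclass(frozen=True)
class HeuristicParams:
    """Inputs of the chance-correlation bound.

    alpha, beta_frac
        Fractions of the neural signal present in the inner and
        intermediate spaces.
    T, tau
        Analysis window length and the longest interval (seconds) over
        which neural activity is expected to stay correlated
        (~0.25 s for an evoked response).
    sigma_x2, sigma_e2
        Neural signal variance and per-channel white noise variance.
    n_c
        Channel count.
    """

    alpha: float
    beta_frac: float
    T: float
    sigma_x2: float
    sigma_e2: float
    n_c: int
    tau: float = 0.25

    def __post_init__(self) -> None:
        if not (0 <= self.alpha <= 1 and 0 <= self.beta_frac <= 1):
            raise ValueError("alpha and beta_frac must lie in [0, 1]")
        if min(self.T, self.tau, self.sigma_x2, self.sigma_e2, self.n_c) < 0:
            raise ValueError("parameters must be non-negative")
        if self.tau > self.T:
            raise ValueError("tau must not exceed the window length T")


def decompose_spaces(Y: Recording, basis: HarmonicBasis, rtol: float = 1e-10) -> SpaceDecomposition:
    """Split a recording into inner, outer and intermediate parts.

    inner = P_amm Y; outer = Hout Hout^+ Y; inter is the remainder.
    The three images are pairwise orthogonal and sum to Y exactly.
    """
    if Y.n_channels != basis.n_channels:
        raise ValueError(f"recording has {Y.n_channels} channels, basis {basis.n_channels}")
    inner = amm_projector(basis, rtol).matrix @ Y.data
    Hout = basis.external
    outer = Hout @ (regularized_pinv(Hout, rtol) @ Y.data)
    return SpaceDecomposition(inner=inner, outer=outer, inter=Y.data - inner - outer)


def _temporal_basis(X: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis (n_t x r) of the row space of X."""
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.empty((X.shape[1], 0))
    return Vt[s > rtol * s[0]].T


def temporal_clean(Y: Recording, basis: HarmonicBasis, limit: float = 0.98,
                   window_s: float | None = None) -> tuple[Recording, list[dict]]:
    """Remove inner-space components temporally shared with the intermediate space.

    Per window the canonical correlations between the temporal subspaces
    of the inner and intermediate data are the singular values of the
    product of their orthonormal temporal bases; every canonical
    direction with correlation >= ``limit`` is projected out of the
    inner-space data.  Returns the cleaned inner-space recording (the
    spatially+temporally modelled data) and a per-window report.
    """
    if not (0 < limit <= 1):
        raise ValueError("limit must lie in (0, 1]")
    n_t = Y.n_samples
    win = n_t if window_s is None else int(round(window_s * Y.fs))
    if win < 2:
        raise ValueError("window must contain at least 2 samples")
    out = np.empty_like(Y.data)
    report: list[dict] = []
    for w, start in enumerate(range(0, n_t, win)):
        sl = slice(start, min(start + win, n_t))
        if sl.stop - sl.start < 2:
            # trailing stub: pass the inner-space data through untouched
            dec = decompose_spaces(Recording(Y.data[:, sl], Y.fs, Y.names), basis)
            out[:, sl] = dec.inner
            continue
        dec = decompose_spaces(Recording(Y.data[:, sl], Y.fs, Y.names), basis)
        Vin = _temporal_basis(dec.inner)
        Vint = _temporal_basis(dec.inter)
        if Vin.shape[1] == 0 or Vint.shape[1] == 0:
            out[:, sl] = dec.inner
            report.append({"window": w, "correlations": np.array([]), "n_removed": 0})
            continue
        A, cc, _ = np.linalg.svd(Vin.T @ Vint)
        cc = np.clip(cc, 0.0, 1.0)
        bad = cc >= limit
        cleaned = dec.inner
        if np.any(bad):
            T = Vin @ A[:, bad]          # orthonormal temporal directions to drop
            cleaned = cleaned - (cleaned @ T) @ T.T
        out[:, sl] = cleaned
        report.append({"window": w, "correlations": cc, "n_removed": int(np.sum(bad))})
    return Recording(data=out, fs=Y.fs, names=list(Y.names)), report


def correlation_limit(p: HeuristicParams) -> float:
    """Upper bound on the chance inner/intermediate canonical correlation.

    rho_max = alpha beta / sqrt((beta^2 + k)(alpha^2 + k)) with
    k = T sigma_e^2 / (tau sigma_x^2 n_c).  Monotone decreasing in k:
    longer windows and noisier channels lower the bound, more channels
    and stronger signal raise it.  A zero signal variance returns 0 by
    continuity.
    """
    if p.sigma_x2 == 0 or p.alpha == 0 or p.beta_frac == 0:
        return 0.0
    if p.sigma_e2 == 0:
        return 1.0 if p.alpha > 0 and p.beta_frac > 0 else 0.0
    k = p.T * p.sigma_e2 / (p.tau * p.sigma_x2 * p.n_c)
    return float(p.alpha * p.beta_frac /
                 np.sqrt((p.beta_frac**2 + k) * (p.alpha**2 + k)))
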