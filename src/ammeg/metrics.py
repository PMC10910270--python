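"""Quantitative read-outs: shielding, reconstruction, noise, evoked stats."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .projectors import Projector, Recording
from .simulate import LeadFieldSet

__all__ = [
    "ShieldingReport",
    "leadfield_correlation",
    "white_noise_reduction",
    "psd_shielding",
    "epoch_tstat",
]


@dataclass(frozen=True)
class ShieldingReport:
    """Per-topography shielding factors with the worst case singled out."""

    linear: np.ndarray
    params: dict

    @property
    def db(self) -> np.ndarray:
        return 20.0 * np.log10(self.linear)

    @property
    def minimum(self) -> float:
        return float(np.min(self.linear))

    @property
    def minimum_db(self) -> float:
        return float(20.0 * np.log10(self.minimum))


def leadfield_correlation(L: LeadFieldSet, P: Projector, mode: str = "cosine") -> np.ndarray:
    """Correlation between each lead field and its projected version.

    ``cosine``: |<l, P l>| / (|l| |P l|); ``sqrt_ve``: square root of the
    variance of l explained by P l, sqrt(max(0, 1 - |l - P l|^2/|l|^2)).
    The two coincide for orthogonal projectors.  Zero-norm lead fields
    (magnetically silent sources) are returned as NaN with a warning.
    """
    if mode not in ("cosine", "sqrt_ve"):
        raise ValueError(f"unknown mode {mode!r}")
    Lm = L.matrix
    if Lm.shape[0] != P.matrix.shape[1]:
        raise ValueError("lead-field rows do not match projector size")
    PL = P.matrix @ Lm
    norms = np.linalg.norm(Lm, axis=0)
    silent = norms == 0
    if np.any(silent):
        warnings.warn(f"{int(np.sum(silent))} silent source(s) flagged NaN", stacklevel=2)
    safe = np.where(silent, 1.0, norms)
    if mode == "cosine":
        pn = np.linalg.norm(PL, axis=0)
        out = np.abs(np.einsum("ij,ij->j", Lm, PL)) / (safe * np.where(pn == 0, 1.0, pn))
        out = np.where(pn == 0, 0.0, out)
    else:
        out = np.sqrt(np.maximum(0.0, 1.0 - np.linalg.norm(Lm - PL, axis=0) ** 2 / safe**2))
    return np.where(silent, np.nan, out)


def white_noise_reduction(P: Projector, n_t: int = 1000, reps: int = 50,
                          sigma: float = 1.0,
                          rng: np.random.Generator | None = None) -> float:
    """Empirical white-noise reduction factor, dB.

    Mean over ``reps`` draws of 20 log10(sigma_noise / sigma_projected),
    with the projected standard deviation pooled over channels and
    samples.  Positive for any orthogonal projector; can be negative
    for an oblique projector on an ill-conditioned basis.
    """
    if reps < 10:
        raise ValueError("need at least 10 repetitions")
    rng = np.random.default_rng(0) if rng is None else rng
    n_c = P.matrix.shape[1]
    vals = np.empty(reps)
    for i in range(reps):
        E = sigma * rng.standard_normal((n_c, n_t))
        vals[i] = 20.0 * np.log10(np.std(E) / np.std(P.matrix @ E))
    return float(np.mean(vals))


def psd_shielding(raw: Recording, cleaned: Recording,
                  nperseg_s: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-frequency shielding factor (dB) of cleaned relative to raw.

    Welch PSDs (Hann window, 50% overlap) per channel, rms amplitude
    across channels per frequency, then 20 log10(amp_raw / amp_clean).
    """
    if raw.fs != cleaned.fs:
        raise ValueError("sampling rates differ")
    if raw.data.shape != cleaned.data.shape:
        raise ValueError("shapes differ")
    nperseg = min(int(round(nperseg_s * raw.fs)), raw.n_samples)
    f, p_raw = welch(raw.data, fs=raw.fs, nperseg=nperseg, axis=1)
    _, p_cln = welch(cleaned.data, fs=cleaned.fs, nperseg=nperseg, axis=1)
    amp_raw = np.sqrt(np.mean(p_raw, axis=0))
    amp_cln = np.sqrt(np.mean(p_cln, axis=0))
    tiny = np.finfo(float).tiny
    return f, 20.0 * np.log10(np.maximum(amp_raw, tiny) / np.maximum(amp_cln, tiny))


def epoch_tstat(Y: Recording, events, pre_s: float, post_s: float
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Across-trial mean and t-statistic around event samples.

    Returns (latencies_s, mean, tstat, n_trials) with mean/tstat shaped
    (n_channels, n_latencies).  Events whose window leaves the record
    are dropped (with a warning); overlapping windows warn too.  Where
    the across-trial standard error is exactly zero the t value is a
    large finite number of the correct sign rather than infinity.
    """
    events = np.asarray(events, dtype=int)
    npre = int(round(pre_s * Y.fs))
    npost = int(round(post_s * Y.fs))
    ok = (events - npre >= 0) & (events + npost < Y.n_samples)
    if np.any(~ok):
        warnings.warn(f"dropped {int(np.sum(~ok))} out-of-bounds event(s)", stacklevel=2)
    events = events[ok]
    if len(events) < 2:
        raise ValueError("need at least 2 in-bounds events")
    if np.any(np.diff(np.sort(events)) < npre + npost + 1):
        warnings.warn("epoch windows overlap", stacklevel=2)
    trials = np.stack([Y.data[:, e - npre:e + npost + 1] for e in events])  # (n_tr, n_c, n_lat)
    n = trials.shape[0]
    mean = trials.mean(axis=0)
    se = trials.std(axis=0, ddof=1) / np.sqrt(n)
    se = np.where(se == 0, np.sqrt(np.finfo(float).tiny), se)
    lat = (np.arange(-npre, npost + 1)) / Y.fs
    return lat, mean, mean / se, n
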