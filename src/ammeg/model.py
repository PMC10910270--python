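"""Model/Results front end tying the pipeline together.

`AdaptiveMultipoleModel` holds the data and the modelling choices
(harmonic family and orders, projector type, temporal threshold);
`fit()` builds the basis, forms the projector, applies it, optionally
runs the temporal cleaning stage, and returns a `MultipoleResults`
carrying the cleaned recording together with diagnostics (condition
numbers, projector rank, variance accounting, removed components).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ReferenceSpheroid, SensorArray, fit_reference_spheroid
from .harmonics import HarmonicBasis, build_basis
from .metrics import psd_shielding
from .projectors import (Projector, Recording, amm_projector, apply_projector,
                         condition_report, sss_projector)
from .temporal import temporal_clean

__all__ = ["AdaptiveMultipoleModel", "MultipoleResults"]


class AdaptiveMultipoleModel:
    """Multipole interference-rejection model of an OPM recording.

    Parameters
    ----------
    recording : Recording
        Channels x samples data in Tesla.
    array : SensorArray
        Channel geometry matching the recording rows.
    spheroid : ReferenceSpheroid, optional
        Reference spheroid of the harmonic frame; fitted to the sensor
        positions (least squares) when omitted.
    method : {"amm", "sss"}
        Orthogonal (adaptive multipole) or oblique (signal space
        separation style) projection.
    family, external_family : {"spheroidal", "spherical"}
        Harmonic family of the internal and external blocks.
    L_in, L_out : int
        Internal / external truncation orders (defaults 9 and 2).
    temporal_limit : float or None
        Canonical-correlation threshold of the temporal stage; None
        disables it (it is only defined for the orthogonal method).
    window_s : float or None
        Temporal-stage window length; None uses the whole recording.
    """

    def __init__(self, recording: Recording, array: SensorArray,
                 spheroid: ReferenceSpheroid | None = None, method: str = "amm",
                 family: str = "spheroidal", external_family: str = "spherical",
                 L_in: int = 9, L_out: int = 2, temporal_limit: float | None = 0.98,
                 window_s: float | None = None):
        if recording.n_channels != array.n_channels:
            raise ValueError("recording channels do not match array channels")
        if method not in ("amm", "sss"):
            raise ValueError(f"unknown method {method!r}")
        if method == "sss" and temporal_limit is not None:
            temporal_limit = None
        self.recording = recording
        self.array = array
        self.spheroid = spheroid or fit_reference_spheroid(array.positions, "least_squares")
        self.method = method
        self.family = family
        self.external_family = external_family
        self.L_in = L_in
        self.L_out = L_out
        self.temporal_limit = temporal_limit
        self.window_s = window_s

    @classmethod
    def from_tsv(cls, recording_path, geometry_path, **kwargs) -> "AdaptiveMultipoleModel":
        """Build the model from recording/geometry TSV files."""
        from .io import read_geometry, read_recording
        return cls(read_recording(recording_path), read_geometry(geometry_path), **kwargs)

    def build(self) -> HarmonicBasis:
        """Assemble (and cache) the harmonic basis."""
        if not hasattr(self, "_basis"):
            self._basis = build_basis(self.array, self.spheroid, family=self.family,
                                      L_in=self.L_in, L_out=self.L_out,
                                      external_family=self.external_family)
        return self._basis

    def fit(self) -> "MultipoleResults":
        basis = self.build()
        projector = (amm_projector(basis) if self.method == "amm"
                     else sss_projector(basis))
        removed: list[dict] = []
        if self.method == "amm" and self.temporal_limit is not None:
            cleaned, removed = temporal_clean(self.recording, basis,
                                              limit=self.temporal_limit,
                                              window_s=self.window_s)
        else:
            cleaned = apply_projector(projector, self.recording)
        return MultipoleResults(model=self, basis=basis, projector=projector,
                                cleaned=cleaned, temporal_report=removed)


@dataclass
class MultipoleResults:
    """Fitted projection with its diagnostics."""

    model: AdaptiveMultipoleModel
    basis: HarmonicBasis
    projector: Projector
    cleaned: Recording
    temporal_report: list[dict] = field(default_factory=list)

    @property
    def variance_ratio(self) -> float:
        """Output variance / input variance (<= 1 for the orthogonal method)."""
        v0 = float(np.var(self.model.recording.data))
        return float(np.var(self.cleaned.data)) / v0 if v0 > 0 else float("nan")

    @property
    def n_removed(self) -> int:
        return int(sum(r.get("n_removed", 0) for r in self.temporal_report))

    def condition_report(self) -> dict:
        return condition_report(self.basis)

    def project_leadfields(self, L: np.ndarray) -> np.ndarray:
        """Premultiply lead fields so the forward model sees the projector."""
        return apply_projector(self.projector, L)

    def shielding_curve(self, nperseg_s: float = 10.0):
        """Per-frequency shielding of the cleaned data relative to the input."""
        return psd_shielding(self.model.recording, self.cleaned, nperseg_s)

    def plot_shielding(self, ax=None, nperseg_s: float = 10.0):
        """Plot the shielding curve (dB vs Hz)."""
        import matplotlib.pyplot as plt
        f, db = self.shielding_curve(nperseg_s)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(f, db)
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("shielding (dB)")
        ax.set_title(f"{self.model.method.upper()} shielding")
        return ax

    def summary(self) -> str:
        m = self.model
        rep = self.condition_report()
        nc = m.recording.n_channels
        exp_wnr = 10.0 * np.log10(nc / max(self.projector.rank, 1))
        lines = [
            "Adaptive multipole model results",
            "=" * 34,
            f"method:              {m.method.upper()} ({self.projector.ptype} projection)",
            f"harmonic family:     internal={m.family}, external={m.external_family}",
            f"orders:              L_in={m.L_in} ({m.L_in**2 + 2 * m.L_in} harmonics), "
            f"L_out={m.L_out} ({m.L_out**2 + 2 * m.L_out} harmonics)",
            f"channels / samples:  {nc} / {m.recording.n_samples} at {m.recording.fs:g} Hz",
            f"reference spheroid:  a={m.spheroid.a * 1e3:.1f} mm, b={m.spheroid.b * 1e3:.1f} mm, "
            f"c={m.spheroid.c * 1e3:.1f} mm",
            f"projector rank:      {self.projector.rank}",
            f"cond(Hin, Hout, H):  {rep['cond_internal']:.3g}, {rep['cond_external']:.3g}, "
            f"{rep['cond_joint']:.3g}",
            f"variance ratio:      {self.variance_ratio:.4f}",
            f"expected noise cut:  {exp_wnr:.2f} dB (rank law, orthogonal projection)",
        ]
        if m.temporal_limit is not None:
            lines.append(f"temporal stage:      limit={m.temporal_limit}, "
                         f"removed {self.n_removed} component(s)")
        else:
            lines.append("temporal stage:      disabled")
        return "\n".join(lines)
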