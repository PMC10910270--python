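"""TSV readers/writers, configuration, and small fixture generation.

Interchange dialect: UTF-8 tab-separated values with a header row and
'.' decimal point.  Geometry files carry columns
``name x y z ox oy oz sensor_id`` (metres, unit orientations);
recordings carry one column per channel and one row per sample, with
the sampling rate in a leading ``# fs_hz=...`` comment line.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import SensorArray
from .projectors import Recording

__all__ = [
    "Config",
    "read_geometry",
    "write_geometry",
    "read_recording",
    "write_recording",
    "make_fixtures",
]

_GEOM_COLS = ["name", "x", "y", "z", "ox", "oy", "oz", "sensor_id"]
_FLOAT_FMT = "%.17g"


def write_geometry(array: SensorArray, path) -> None:
    df = pd.DataFrame({
        "name": array.names,
        "x": array.positions[:, 0], "y": array.positions[:, 1], "z": array.positions[:, 2],
        "ox": array.orientations[:, 0], "oy": array.orientations[:, 1],
        "oz": array.orientations[:, 2],
        "sensor_id": array.sensor_index,
    })
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_geometry(path) -> SensorArray:
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed geometry file {path}: {exc}") from exc
    missing = [c for c in _GEOM_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"geometry file {path} is missing columns {missing}")
    if df[_GEOM_COLS[1:]].isna().any().any():
        bad = int(df[_GEOM_COLS[1:]].isna().any(axis=1).idxmax()) + 2  # header is line 1
        raise ValueError(f"non-finite value in geometry file {path} at line {bad}")
    ori = df[["ox", "oy", "oz"]].to_numpy(float)
    norms = np.linalg.norm(ori, axis=1)
    if np.any(norms == 0):
        raise ValueError(f"zero orientation vector in {path}")
    if np.any(np.abs(norms - 1.0) > 1e-6):
        warnings.warn(f"{path}: orientations deviate from unit norm by up to "
                      f"{float(np.max(np.abs(norms - 1))):.2e}; normalizing", stacklevel=2)
    fix = np.abs(norms - 1.0) > 1e-10  # leave already-unit rows bit-identical
    ori[fix] = ori[fix] / norms[fix, None]
    sid = df["sensor_id"].to_numpy(int)
    counts = np.unique(np.bincount(sid[sid >= 0]))
    axes = int(counts[0]) if len(counts) == 1 else 1
    return SensorArray(names=[str(n) for n in df["name"]],
                       positions=df[["x", "y", "z"]].to_numpy(float),
                       orientations=ori, axes_per_sensor=axes, sensor_index=sid)


def write_recording(rec: Recording, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs_hz={rec.fs!r}\n")
        df = pd.DataFrame(rec.data.T, columns=rec.names)
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_recording(path) -> Recording:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("# fs_hz="):
            raise ValueError(f"{path}: missing '# fs_hz=' header line")
        fs = float(first.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    data = df.to_numpy(float).T
    if np.isnan(data).any():
        bad = int(np.argwhere(np.isnan(data).any(axis=0))[0][0]) + 3
        raise ValueError(f"non-finite sample in {path} near line {bad}")
    return Recording(data=data, fs=fs, names=[str(c) for c in df.columns])


@dataclass
class Config:
    """Normalized run configuration (YAML round-trippable)."""

    family: str = "spheroidal"
    external_family: str = "spherical"
    L_in: int = 9
    L_out: int = 2
    grad_step: float | None = None
    limit: float = 0.98
    window_s: float | None = None
    seed: int = 0
    reps: int = 50
    spheroid: dict | None = None
    io: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def make_fixtures(seed: int, outdir) -> dict:
    """Write a small deterministic scenario for tests and docs.

    60-sensor triaxial array on the default head, 3 cortical sources
    driven by damped sinusoids, one interference topography with a
    50 Hz line, and white noise.  Returns the paths written.
    """
    from .geometry import generate_scalp_array
    from .simulate import (cortical_source_set, default_head, leadfield_matrix,
                           random_interference, white_noise)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    head = default_head()
    array = generate_scalp_array(head, spacing=0.038, offset=0.0065, axes=3, seed=seed)
    pos, ori = cortical_source_set(head, n_src=3, seed=seed)
    lf = leadfield_matrix(array, pos, ori, head.centre)

    fs, n_t = 200.0, 400
    t = np.arange(n_t) / fs
    drive = np.stack([np.sin(2 * np.pi * f0 * t) * np.exp(-t / 1.5)
                      for f0 in (7.0, 11.0, 19.0)])
    brain = lf.matrix @ (5e-8 * drive)
    line = np.outer(random_interference(array, rng), 2e-12 * np.sin(2 * np.pi * 50.0 * t))
    noise = white_noise(array.n_channels, n_t, sigma=3e-13, rng=rng)
    rec = Recording(data=brain + line + noise, fs=fs, names=list(array.names))

    paths = {"array": outdir / "array.tsv", "recording": outdir / "recording.tsv",
             "config": outdir / "config.yaml"}
    write_geometry(array, paths["array"])
    write_recording(rec, paths["recording"])
    Config(seed=seed).dump(paths["config"])
    return paths
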