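"""RF frame container and file dialects.

Beamformed radio-frequency (RF) ultrasound data has no universal on-disk
standard; this module supports two simple dialects for a pre/post
compression frame pair:

* ``raw_binary`` — little-endian float32 samples in column-major (Fortran)
  order, both frames concatenated in one ``.bin`` file, with a YAML sidecar
  (same path plus ``.yaml``) carrying shape, spacings and frequencies.
* ``container`` — an HDF5 file with datasets ``"I1"`` and ``"I2"`` and the
  metadata stored as root attributes.

Convention shared by every module: the first (row) index ``i`` is axial and
increases with depth; the second (column) index ``j`` is lateral.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np
import yaml
from scipy.signal import hilbert

from .exceptions import ConfigError, InputDataError

__all__ = [
    "RFFrame",
    "SPEED_OF_SOUND_M_S",
    "load_rf_pair",
    "save_rf_pair",
    "bmode",
]

#: Default speed of sound used to convert sampling frequency to axial
#: spacing (m/s). Configurable wherever axial spacing is derived.
SPEED_OF_SOUND_M_S = 1540.0

_META_KEYS = (
    "axial_spacing_mm",
    "lateral_spacing_mm",
    "center_frequency_MHz",
    "sampling_frequency_MHz",
)


@dataclass(frozen=True)
class RFFrame:
    """One beamformed RF frame: ``m`` axial samples × ``n`` lateral lines.

    Parameters
    ----------
    samples
        2-D real array, axial along axis 0 (depth), lateral along axis 1.
    axial_spacing_mm
        Sample-to-sample depth spacing, ``c / (2 fs)``.
    lateral_spacing_mm
        Element pitch (line-to-line spacing).
    center_frequency_MHz, sampling_frequency_MHz
        Acquisition metadata.
    """

    samples: np.ndarray
    axial_spacing_mm: float
    lateral_spacing_mm: float
    center_frequency_MHz: float
    sampling_frequency_MHz: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 2 or samples.shape[0] < 2 or samples.shape[1] < 2:
            raise InputDataError(
                f"RF frame must be 2-D with m >= 2 and n >= 2, got shape "
                f"{samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise InputDataError("RF frame contains non-finite samples")
        for key in _META_KEYS:
            value = getattr(self, key)
            if not (np.isfinite(value) and value > 0):
                raise ConfigError(f"{key} must be strictly positive, got {value!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.samples.shape

    @property
    def n_axial(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lateral(self) -> int:
        return self.samples.shape[1]

    def with_samples(self, samples: np.ndarray) -> "RFFrame":
        """Return a copy of this frame carrying new sample data."""
        return replace(self, samples=samples)

    @staticmethod
    def axial_spacing_from_fs(
        sampling_frequency_MHz: float, speed_of_sound_m_s: float = SPEED_OF_SOUND_M_S
    ) -> float:
        """Axial sample spacing in mm: ``c / (2 fs)``."""
        return speed_of_sound_m_s / (2.0 * sampling_frequency_MHz * 1e6) * 1e3


def _metadata_dict(frame: RFFrame) -> dict:
    return {key: float(getattr(frame, key)) for key in _META_KEYS}


def _check_metadata(meta: dict, source: str) -> dict:
    missing = [key for key in _META_KEYS if key not in meta]
    if missing:
        raise ConfigError(f"{source}: missing metadata keys {missing}")
    return {key: float(meta[key]) for key in _META_KEYS}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def save_rf_pair(
    path: str | Path, pre: RFFrame, post: RFFrame, format: str = "container"
) -> Path:
    """Write a pre/post RF frame pair in the selected dialect.

    Returns the path written. Both frames must share shape and metadata.
    """
    path = Path(path)
    if pre.shape != post.shape:
        raise InputDataError(
            f"frame shapes differ: {pre.shape} vs {post.shape}"
        )
    if _metadata_dict(pre) != _metadata_dict(post):
        raise InputDataError("pre/post frames carry different metadata")
    if format == "raw_binary":
        data = np.concatenate(
            [
                np.asfortranarray(pre.samples, dtype="<f4").ravel(order="F"),
                np.asfortranarray(post.samples, dtype="<f4").ravel(order="F"),
            ]
        )
        data.tofile(path)
        meta = _metadata_dict(pre)
        meta["shape"] = [int(pre.n_axial), int(pre.n_lateral)]
        _sidecar_path(path).write_text(yaml.safe_dump(meta))
    elif format == "container":
        with h5py.File(path, "w") as f:
            f.create_dataset("I1", data=pre.samples.astype("<f4"))
            f.create_dataset("I2", data=post.samples.astype("<f4"))
            for key, value in _metadata_dict(pre).items():
                f.attrs[key] = value
    else:
        raise ConfigError(f"unknown RF dialect {format!r}")
    return path


def load_rf_pair(path: str | Path, format: str = "container") -> tuple[RFFrame, RFFrame]:
    """Read a pre/post RF frame pair written by :func:`save_rf_pair`.

    Raises
    ------
    ConfigError
        Missing file, sidecar or metadata keys.
    InputDataError
        Degenerate shape or file size inconsistent with the header.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"RF file not found: {path}")
    if format == "raw_binary":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ConfigError(f"sidecar not found: {sidecar}")
        meta = yaml.safe_load(sidecar.read_text())
        if "shape" not in meta:
            raise ConfigError(f"{sidecar}: missing 'shape'")
        m, n = (int(v) for v in meta["shape"])
        if m < 2 or n < 2:
            raise InputDataError(f"degenerate frame shape ({m}, {n}) in {sidecar}")
        fields = _check_metadata(meta, str(sidecar))
        raw = np.fromfile(path, dtype="<f4")
        if raw.size != 2 * m * n:
            raise InputDataError(
                f"{path}: expected {2 * m * n} float32 samples, found {raw.size}"
            )
        pre = raw[: m * n].reshape((m, n), order="F").astype(float)
        post = raw[m * n :].reshape((m, n), order="F").astype(float)
    elif format == "container":
        with h5py.File(path, "r") as f:
            for name in ("I1", "I2"):
                if name not in f:
                    raise ConfigError(f"{path}: missing dataset {name!r}")
            pre = np.asarray(f["I1"], dtype=float)
            post = np.asarray(f["I2"], dtype=float)
            fields = _check_metadata(dict(f.attrs), str(path))
        if pre.ndim != 2 or min(pre.shape) < 2:
            raise InputDataError(f"degenerate frame shape {pre.shape} in {path}")
    else:
        raise ConfigError(f"unknown RF dialect {format!r}")
    if pre.shape != post.shape:
        raise InputDataError(
            f"{path}: frame shapes differ: {pre.shape} vs {post.shape}"
        )
    return (
        RFFrame(samples=pre, **fields),
        RFFrame(samples=post, **fields),
    )


def bmode(frame: RFFrame, dynamic_range_db: float = 50.0) -> np.ndarray:
    """Log-compressed B-mode image in dB, values in ``[-dynamic_range_db, 0]``.

    The envelope is the magnitude of the axial analytic signal, normalised
    to its maximum, log-compressed and clipped. Invariant to global positive
    scaling of the RF data.
    """
    if not dynamic_range_db > 0:
        raise ConfigError(f"dynamic_range_db must be > 0, got {dynamic_range_db}")
    envelope = np.abs(hilbert(frame.samples, axis=0))
    peak = envelope.max()
    if peak == 0:
        raise InputDataError("all-zero RF frame: B-mode normalisation undefined")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(envelope / peak)
    return np.clip(db, -dynamic_range_db, 0.0)
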