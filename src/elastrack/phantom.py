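"""Synthetic speckle phantoms with known deformation ground truth.

A phantom is a cloud of sub-resolution point scatterers with random
positions and standard-normal amplitudes. Fully developed speckle requires
roughly >= 10 scatterers per resolution cell; the default density is chosen
to satisfy that for the default imaging point-spread function (PSF).

Deformation is applied in closed form to the scatterer positions
(homogeneous-medium simplification):

* ``uniform_compression`` — uniaxial compression by a fraction ``s`` from
  the top surface with Poisson's ratio ``nu``: axial displacement
  ``a(y) = -s * y`` (depth ``y`` from the surface), lateral displacement
  ``l(x) = nu * s * (x - x0)`` about the lateral centre. The implied strain
  tensor is constant: axial ``-s``, lateral ``+nu*s``, both shears zero.
* ``rigid_shift`` — constant displacement in samples/lines.
* ``parametric_inclusion`` — a smooth radial blend between two compression
  levels around a disk; qualitative only (no finite-element accuracy).

Imaging is a separable convolution model: each scatterer contributes its
amplitude times a Gaussian-windowed cosine axially (centre frequency,
fractional bandwidth) and a Gaussian laterally (beamwidth). This stands in
for a full acoustic field simulation; the tracker is agnostic to the RF
generator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ConfigError, InputDataError
from .io import RFFrame, save_rf_pair

__all__ = [
    "ScattererField",
    "DeformationSpec",
    "ImagingPSF",
    "GridGeometry",
    "DisplacementGrids",
    "make_phantom",
    "uniform_compression_field",
    "warp_scatterers",
    "image_scatterers",
    "add_rf_noise",
    "simulate_pair",
    "write_fixture",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridGeometry:
    """Sampling grid of an RF frame in physical units.

    ``axial_mm(i) = i * axial_spacing_mm`` (depth from the compressed top
    surface), ``lateral_mm(j) = j * lateral_spacing_mm``.
    """

    n_axial: int
    n_lateral: int
    axial_spacing_mm: float
    lateral_spacing_mm: float

    @property
    def extent_mm(self) -> tuple[float, float]:
        return (
            (self.n_axial - 1) * self.axial_spacing_mm,
            (self.n_lateral - 1) * self.lateral_spacing_mm,
        )

    @property
    def lateral_center_mm(self) -> float:
        return 0.5 * (self.n_lateral - 1) * self.lateral_spacing_mm


@dataclass(frozen=True)
class ScattererField:
    """Point scatterers within a rectangular extent (axial × lateral, mm)."""

    positions_mm: np.ndarray  # (N, 2): axial, lateral
    amplitudes: np.ndarray  # (N,)
    extent_mm: tuple[float, float]
    fully_developed: bool = True

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions_mm, dtype=float))
        amp = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "positions_mm", pos)
        object.__setattr__(self, "amplitudes", amp)
        if pos.shape[0] == 0:
            raise InputDataError("empty scatterer field")
        if pos.shape[0] != amp.shape[0]:
            raise InputDataError("positions and amplitudes disagree in length")
        if not np.all(np.isfinite(pos)) or not np.all(np.isfinite(amp)):
            raise InputDataError("non-finite scatterer data")

    @property
    def n_scatterers(self) -> int:
        return self.positions_mm.shape[0]


@dataclass(frozen=True)
class ImagingPSF:
    """Separable point-spread function of the convolution imaging model.

    Axially a Gaussian-windowed cosine at ``center_frequency_MHz`` whose
    Gaussian envelope has the stated -6 dB fractional bandwidth; laterally
    a Gaussian with ``lateral_beamwidth_mm`` FWHM. Elevation is ignored.
    Defaults emulate a linear-array acquisition (7.27 MHz centre, 60%
    fractional bandwidth).
    """

    center_frequency_MHz: float = 7.27
    fractional_bandwidth: float = 0.6
    lateral_beamwidth_mm: float = 0.8
    speed_of_sound_m_s: float = 1540.0

    def __post_init__(self) -> None:
        if not (
            self.center_frequency_MHz > 0
            and 0 < self.fractional_bandwidth <= 1
            and self.lateral_beamwidth_mm > 0
            and self.speed_of_sound_m_s > 0
        ):
            raise ConfigError("ImagingPSF parameters must be positive "
                              "(fractional bandwidth in (0, 1])")

    @property
    def wavelength_mm(self) -> float:
        return self.speed_of_sound_m_s / (self.center_frequency_MHz * 1e6) * 1e3

    @property
    def axial_sigma_mm(self) -> float:
        """Std of the axial Gaussian envelope (one-way, in mm of depth)."""
        # FWHM of the Gaussian spectrum equals the fractional bandwidth
        # times f0; sigma_t = sqrt(2 ln 2) / (pi * FWHM_f) for the envelope.
        fwhm_hz = self.fractional_bandwidth * self.center_frequency_MHz * 1e6
        sigma_t = math.sqrt(2.0 * math.log(2.0)) / (math.pi * fwhm_hz)
        return 0.5 * self.speed_of_sound_m_s * sigma_t * 1e3

    @property
    def lateral_sigma_mm(self) -> float:
        return self.lateral_beamwidth_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    def resolution_cell_mm2(self) -> float:
        """Nominal -6 dB resolution-cell area used for the speckle check."""
        axial_fwhm = 2.0 * math.sqrt(2.0 * math.log(2.0)) * self.axial_sigma_mm
        return axial_fwhm * self.lateral_beamwidth_mm


@dataclass(frozen=True)
class DeformationSpec:
    """Closed-form deformation applied to scatterer positions.

    ``applied_strain`` is the fractional compression ``s`` (0–0.2);
    ``poisson_ratio`` the lateral-to-axial coupling ``nu`` in [0, 0.5).
    """

    mode: str = "uniform_compression"
    applied_strain: float = 0.02
    poisson_ratio: float = 0.49
    shift_samples: tuple[float, float] = (0.0, 0.0)
    inclusion_center_mm: tuple[float, float] = (0.0, 0.0)
    inclusion_radius_mm: float = 5.0
    inclusion_strain_ratio: float = 0.5
    inclusion_edge_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("uniform_compression", "rigid_shift", "parametric_inclusion"):
            raise ConfigError(f"unknown deformation mode {self.mode!r}")
        if not 0.0 <= self.applied_strain <= 0.2:
            raise ConfigError(
                f"applied_strain must lie in [0, 0.2], got {self.applied_strain}"
            )
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ConfigError(
                f"poisson_ratio must lie in [0, 0.5), got {self.poisson_ratio}"
            )


@dataclass(frozen=True)
class DisplacementGrids:
    """Ground-truth displacement sampled on an RF grid, in samples/lines."""

    axial: np.ndarray  # a(i, j), axial samples
    lateral: np.ndarray  # l(i, j), lateral lines
    geometry: GridGeometry
    spec: DeformationSpec | None = None

    def strain_truth(self) -> dict[str, np.ndarray]:
        """Analytic strain maps for closed-form deformation modes."""
        shape = self.axial.shape
        if self.spec is None:
            raise ConfigError("no deformation spec attached")
        s, nu = self.spec.applied_strain, self.spec.poisson_ratio
        if self.spec.mode == "rigid_shift":
            zero = np.zeros(shape)
            return {"axial": zero, "lateral": zero.copy(),
                    "axial_shear": zero.copy(), "lateral_shear": zero.copy()}
        if self.spec.mode == "uniform_compression":
            return {
                "axial": np.full(shape, -s),
                "lateral": np.full(shape, nu * s),
                "axial_shear": np.zeros(shape),
                "lateral_shear": np.zeros(shape),
            }
        raise ConfigError(
            f"no closed-form strain truth for mode {self.spec.mode!r}"
        )


def make_phantom(
    extent_mm: tuple[float, float],
    density_per_mm2: float,
    seed: int,
    psf: ImagingPSF | None = None,
) -> ScattererField:
    """Draw a random scatterer field: uniform positions, N(0,1) amplitudes.

    The expected count is ``density * area`` (the realised count is the
    rounded expectation, deterministic under ``seed``). If the density
    falls below ~10 scatterers per PSF resolution cell the field is still
    returned but flagged (``fully_developed=False``) and a warning logged.
    """
    axial_mm, lateral_mm = (float(v) for v in extent_mm)
    if axial_mm <= 0 or lateral_mm <= 0 or density_per_mm2 <= 0:
        raise InputDataError("extent and density must be positive")
    n = int(round(density_per_mm2 * axial_mm * lateral_mm))
    if n == 0:
        raise InputDataError("density too low: zero scatterers")
    rng = np.random.default_rng(seed)
    positions = np.column_stack(
        [rng.uniform(0.0, axial_mm, n), rng.uniform(0.0, lateral_mm, n)]
    )
    amplitudes = rng.standard_normal(n)
    psf = psf or ImagingPSF()
    per_cell = density_per_mm2 * psf.resolution_cell_mm2()
    fully_developed = per_cell >= 10.0
    if not fully_developed:
        logger.warning(
            "scatterer density %.1f/mm^2 gives %.1f per resolution cell "
            "(< 10): speckle is not fully developed", density_per_mm2, per_cell
        )
    return ScattererField(
        positions_mm=positions,
        amplitudes=amplitudes,
        extent_mm=(axial_mm, lateral_mm),
        fully_developed=fully_developed,
    )


def _displacement_mm_at(
    spec: DeformationSpec, axial_mm: np.ndarray, lateral_mm: np.ndarray,
    geometry: GridGeometry,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form displacement (mm) at physical positions."""
    s, nu = spec.applied_strain, spec.poisson_ratio
    if spec.mode == "rigid_shift":
        da, dl = spec.shift_samples
        ax = np.full_like(axial_mm, da * geometry.axial_spacing_mm)
        lat = np.full_like(lateral_mm, dl * geometry.lateral_spacing_mm)
        return ax, lat
    if spec.mode == "uniform_compression":
        ax = -s * axial_mm
        lat = nu * s * (lateral_mm - geometry.lateral_center_mm)
        return ax, lat
    # parametric_inclusion: radial blend between the background strain s and
    # a softer/stiffer level s * ratio inside a disk; qualitative only.
    r = np.hypot(
        axial_mm - spec.inclusion_center_mm[0],
        lateral_mm - spec.inclusion_center_mm[1],
    )
    edge = max(spec.inclusion_edge_mm, 1e-6)
    blend = 0.5 * (1.0 + np.tanh((r - spec.inclusion_radius_mm) / edge))
    local_s = s * (spec.inclusion_strain_ratio + (1.0 - spec.inclusion_strain_ratio) * blend)
    ax = -local_s * axial_mm
    lat = nu * local_s * (lateral_mm - geometry.lateral_center_mm)
    return ax, lat


def uniform_compression_field(
    spec: DeformationSpec, geometry: GridGeometry
) -> DisplacementGrids:
    """Ground-truth displacement grids (samples/lines) for a closed-form spec.

    For ``uniform_compression``: ``a(i) = -s * i`` axial samples and
    ``l(j) = nu * s * (j - j0)`` lateral lines about the lateral centre
    ``j0``; the implied strains are constant by construction.
    """
    i = np.arange(geometry.n_axial)[:, None] * geometry.axial_spacing_mm
    j = np.arange(geometry.n_lateral)[None, :] * geometry.lateral_spacing_mm
    axial_mm_grid = np.broadcast_to(i, (geometry.n_axial, geometry.n_lateral))
    lateral_mm_grid = np.broadcast_to(j, (geometry.n_axial, geometry.n_lateral))
    ax_mm, lat_mm = _displacement_mm_at(spec, axial_mm_grid, lateral_mm_grid, geometry)
    return DisplacementGrids(
        axial=ax_mm / geometry.axial_spacing_mm,
        lateral=lat_mm / geometry.lateral_spacing_mm,
        geometry=geometry,
        spec=spec,
    )


def warp_scatterers(
    scatterers: ScattererField, spec: DeformationSpec, geometry: GridGeometry
) -> ScattererField:
    """Move scatterers by the closed-form displacement at their pre-deformation
    positions; amplitudes are unchanged. Scatterers pushed outside the extent
    are retained (imaging clips them naturally)."""
    ax_mm, lat_mm = _displacement_mm_at(
        spec, scatterers.positions_mm[:, 0], scatterers.positions_mm[:, 1], geometry
    )
    moved = scatterers.positions_mm + np.column_stack([ax_mm, lat_mm])
    outside = (
        (moved[:, 0] < 0) | (moved[:, 0] > scatterers.extent_mm[0])
        | (moved[:, 1] < 0) | (moved[:, 1] > scatterers.extent_mm[1])
    )
    if np.any(outside):
        logger.debug("%d scatterers displaced outside the extent", int(outside.sum()))
    return ScattererField(
        positions_mm=moved,
        amplitudes=scatterers.amplitudes,
        extent_mm=scatterers.extent_mm,
        fully_developed=scatterers.fully_developed,
    )


def image_scatterers(
    scatterers: ScattererField,
    psf: ImagingPSF,
    geometry: GridGeometry,
) -> RFFrame:
    """Render an RF frame as the superposition of per-scatterer PSFs.

    RF(i, j) = sum_k amplitude_k * cos(2 pi f0 * 2 z / c + phase) *
    Gauss_axial(z - z_k) * Gauss_lateral(x - x_k), evaluated on the grid.
    Linear in the amplitudes and shift-equivariant up to grid sampling.
    """
    fs_mhz = psf.speed_of_sound_m_s / (2.0 * geometry.axial_spacing_mm * 1e-3) / 1e6
    if fs_mhz < 4.0 * psf.center_frequency_MHz:
        raise ConfigError(
            f"axial sampling {fs_mhz:.2f} MHz is below 4x the centre frequency "
            f"{psf.center_frequency_MHz} MHz"
        )
    m, n = geometry.n_axial, geometry.n_lateral
    rf = np.zeros((m, n))
    sig_ax = psf.axial_sigma_mm
    sig_lat = psf.lateral_sigma_mm
    # 2 pi * f0 * (2 z / c) expressed per mm of depth
    k_ax = 2.0 * math.pi * 2.0 * psf.center_frequency_MHz * 1e6 / psf.speed_of_sound_m_s * 1e-3
    half_ax = int(math.ceil(4.0 * sig_ax / geometry.axial_spacing_mm))
    half_lat = int(math.ceil(4.0 * sig_lat / geometry.lateral_spacing_mm))
    ax_offsets = np.arange(-half_ax, half_ax + 1)
    lat_offsets = np.arange(-half_lat, half_lat + 1)
    for (z_mm, x_mm), amp in zip(scatterers.positions_mm, scatterers.amplitudes):
        ci = z_mm / geometry.axial_spacing_mm
        cj = x_mm / geometry.lateral_spacing_mm
        i0 = int(round(ci))
        j0 = int(round(cj))
        rows = i0 + ax_offsets
        cols = j0 + lat_offsets
        rmask = (rows >= 0) & (rows < m)
        cmask = (cols >= 0) & (cols < n)
        if not rmask.any() or not cmask.any():
            continue
        rows = rows[rmask]
        cols = cols[cmask]
        dz = rows * geometry.axial_spacing_mm - z_mm
        dx = cols * geometry.lateral_spacing_mm - x_mm
        axial_kernel = np.exp(-0.5 * (dz / sig_ax) ** 2) * np.cos(k_ax * dz)
        lateral_kernel = np.exp(-0.5 * (dx / sig_lat) ** 2)
        rf[np.ix_(rows, cols)] += amp * np.outer(axial_kernel, lateral_kernel)
    return RFFrame(
        samples=rf,
        axial_spacing_mm=geometry.axial_spacing_mm,
        lateral_spacing_mm=geometry.lateral_spacing_mm,
        center_frequency_MHz=psf.center_frequency_MHz,
        sampling_frequency_MHz=fs_mhz,
    )


def add_rf_noise(frame: RFFrame, snr_db: float, seed: int) -> RFFrame:
    """Add white Gaussian noise at the requested RF signal-to-noise ratio.

    The noise std is scaled so ``10 log10(P_signal / P_noise) == snr_db``
    in expectation. ``snr_db = +inf`` returns the frame unchanged. The
    realised peak-SNR (peak signal power over noise power) is logged for
    information; SNR is the controlling parameter.
    """
    if math.isinf(snr_db) and snr_db > 0:
        return frame
    if not np.isfinite(snr_db):
        raise InputDataError(f"snr_db must be finite or +inf, got {snr_db}")
    signal_power = float(np.mean(frame.samples**2))
    if signal_power == 0:
        raise InputDataError("cannot set an SNR on an all-zero frame")
    noise_power = signal_power / 10.0 ** (snr_db / 10.0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, math.sqrt(noise_power), frame.shape)
    psnr_db = 10.0 * math.log10(float(np.max(frame.samples**2)) / noise_power)
    logger.info("added RF noise: SNR %.2f dB (PSNR %.2f dB)", snr_db, psnr_db)
    return frame.with_samples(frame.samples + noise)


def simulate_pair(
    geometry: GridGeometry,
    spec: DeformationSpec,
    seed: int,
    psf: ImagingPSF | None = None,
    density_per_mm2: float = 100.0,
    snr_db: float = math.inf,
) -> tuple[RFFrame, RFFrame, DisplacementGrids]:
    """One pre/post RF pair plus ground-truth displacement grids.

    The same scatterer realisation is imaged before and after the closed-form
    deformation, so the ground-truth strain maps are exact by construction
    regardless of the speckle realisation. Noise (if any) is drawn
    independently for the two frames from ``seed``-derived streams.
    """
    psf = psf or ImagingPSF()
    margin_mm = 3.0 * psf.axial_sigma_mm
    extent = (
        geometry.extent_mm[0] + 2 * margin_mm,
        geometry.extent_mm[1] + 2 * margin_mm,
    )
    scatterers = make_phantom(extent, density_per_mm2, seed, psf)
    # Shift so the imaged grid sits centred inside the (padded) phantom:
    # scatterer coordinates are relative to the grid origin.
    shifted = ScattererField(
        positions_mm=scatterers.positions_mm - margin_mm,
        amplitudes=scatterers.amplitudes,
        extent_mm=extent,
        fully_developed=scatterers.fully_developed,
    )
    pre = image_scatterers(shifted, psf, geometry)
    post = image_scatterers(warp_scatterers(shifted, spec, geometry), psf, geometry)
    if np.isfinite(snr_db):
        pre = add_rf_noise(pre, snr_db, seed=2 * seed + 1)
        post = add_rf_noise(post, snr_db, seed=2 * seed + 2)
    truth = uniform_compression_field(spec, geometry)
    return pre, post, truth


def write_fixture(
    directory: str | Path,
    geometry: GridGeometry,
    spec: DeformationSpec,
    seed: int,
    format: str = "container",
    psf: ImagingPSF | None = None,
    density_per_mm2: float = 100.0,
    snr_db: float = math.inf,
) -> Path:
    """Write a complete fixture: RF pair, ground truth and a YAML manifest.

    Returns the manifest path. Layout: ``rf_pair.<ext>`` (selected dialect),
    ``truth_axial_disp.f32`` / ``truth_lateral_disp.f32`` and the four
    ground-truth strain grids as column-major float32, plus
    ``manifest.yaml`` recording the seed and the full specification.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pre, post, truth = simulate_pair(
        geometry, spec, seed, psf=psf, density_per_mm2=density_per_mm2, snr_db=snr_db
    )
    ext = "bin" if format == "raw_binary" else "h5"
    rf_path = directory / f"rf_pair.{ext}"
    save_rf_pair(rf_path, pre, post, format=format)
    grids = {
        "truth_axial_disp": truth.axial,
        "truth_lateral_disp": truth.lateral,
    }
    try:
        grids.update(
            {f"truth_strain_{k}": v for k, v in truth.strain_truth().items()}
        )
    except ConfigError:
        pass  # no closed-form truth for this mode
    for name, grid in grids.items():
        np.asfortranarray(grid, dtype="<f4").ravel(order="F").tofile(
            directory / f"{name}.f32"
        )
    manifest = {
        "seed": int(seed),
        "format": format,
        "rf_file": rf_path.name,
        "shape": [geometry.n_axial, geometry.n_lateral],
        "axial_spacing_mm": geometry.axial_spacing_mm,
        "lateral_spacing_mm": geometry.lateral_spacing_mm,
        "deformation": {
            "mode": spec.mode,
            "applied_strain": spec.applied_strain,
            "poisson_ratio": spec.poisson_ratio,
            "shift_samples": list(spec.shift_samples),
        },
        "density_per_mm2": density_per_mm2,
        "snr_db": None if math.isinf(snr_db) else snr_db,
        "grids": sorted(grids),
    }
    manifest_path = directory / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path
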