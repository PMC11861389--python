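"""Strain-image evaluation: MAE, MSSIM, elastographic SNR/CNR, ROI sweeps.

Accuracy against a ground-truth strain map is summarised by the mean
absolute error and the mean structural similarity index (11x11 Gaussian
window, sigma 1.5, K1 = 0.01, K2 = 0.03, dynamic range = truth max - min).

Image quality without a ground truth uses elastographic SNR and CNR over
rectangular regions of interest (ROIs):

    SNR = |mean_b| / std_b
    CNR = sqrt( 2 (mean_b - mean_t)^2 / (std_b^2 + std_t^2) )

with b = background, t = target. The sweep protocol evaluates SNR for
every background ROI and CNR for every (target, background) pair — e.g.
30 background ROIs and 4 targets give 30 SNR and 120 CNR values — and
reports mean +/- std per metric. Compressive (negative) background strain
is handled by taking the magnitude of the mean in SNR. CNR of the shear
components is not computed (their target/background contrast is not
physically meaningful in quasi-static elastography).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from skimage.metrics import structural_similarity

from .exceptions import InputDataError, MetricError

__all__ = [
    "ROISpec",
    "ROIStats",
    "MetricReport",
    "mae",
    "mssim",
    "roi_stats",
    "snr",
    "cnr",
    "roi_sweep",
    "roi_grid",
]


@dataclass(frozen=True)
class ROISpec:
    """A rectangular ROI given by its centre and size in mm.

    ``role`` is "background" (used for SNR and as the CNR reference) or
    "target" (CNR only). The default size is the 3x3 mm protocol ROI.
    """

    center_mm: tuple[float, float]  # (axial, lateral)
    size_mm: tuple[float, float] = (3.0, 3.0)
    role: str = "background"

    def __post_init__(self) -> None:
        if self.role not in ("background", "target"):
            raise InputDataError(f"ROI role must be background/target, got {self.role!r}")
        if min(self.size_mm) <= 0:
            raise InputDataError(f"ROI size must be positive, got {self.size_mm}")

    def to_slices(
        self, shape: tuple[int, int], spacings_mm: tuple[float, float]
    ) -> tuple[slice, slice]:
        """Convert to integer row/col slices, rounding toward the inside."""
        slices = []
        for axis in (0, 1):
            lo = (self.center_mm[axis] - 0.5 * self.size_mm[axis]) / spacings_mm[axis]
            hi = (self.center_mm[axis] + 0.5 * self.size_mm[axis]) / spacings_mm[axis]
            start = int(math.ceil(lo))
            stop = int(math.floor(hi)) + 1
            if start < 0 or stop > shape[axis] or stop - start < 2:
                raise InputDataError(
                    f"ROI {self.center_mm}/{self.size_mm} mm falls outside the "
                    f"{shape} map (axis {axis}: samples {start}:{stop})"
                )
            slices.append(slice(start, stop))
        return tuple(slices)


@dataclass(frozen=True)
class ROIStats:
    """Mean and sample standard deviation of strain within one ROI."""

    mean: float
    std: float
    count: int


@dataclass
class MetricReport:
    """Collected evaluation outputs of one strain map."""

    snr_values: list[float] = dataclass_field(default_factory=list)
    cnr_values: list[float] = dataclass_field(default_factory=list)
    mae: float | None = None
    mssim: float | None = None

    @property
    def summary(self) -> dict[str, tuple[float, float]]:
        """mean +/- std per metric with at least one value."""
        out = {}
        for name, values in (("snr", self.snr_values), ("cnr", self.cnr_values)):
            if values:
                arr = np.asarray(values)
                out[name] = (float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0)
        if self.mae is not None:
            out["mae"] = (self.mae, 0.0)
        if self.mssim is not None:
            out["mssim"] = (self.mssim, 0.0)
        return out

    def to_dict(self) -> dict:
        return {
            "snr_values": list(map(float, self.snr_values)),
            "cnr_values": list(map(float, self.cnr_values)),
            "mae": self.mae,
            "mssim": self.mssim,
            "summary": {k: list(v) for k, v in self.summary.items()},
        }


def mae(est: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute elementwise difference between two strain maps."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise InputDataError(f"shape mismatch: {est.shape} vs {truth.shape}")
    return float(np.mean(np.abs(est - truth)))


def mssim(est: np.ndarray, truth: np.ndarray) -> float:
    """Mean structural similarity between estimate and ground truth.

    Gaussian-weighted 11x11 window (sigma 1.5), K1 = 0.01, K2 = 0.03,
    dynamic range taken from the ground-truth map.
    """
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise InputDataError(f"shape mismatch: {est.shape} vs {truth.shape}")
    data_range = float(truth.max() - truth.min())
    if data_range == 0:
        raise InputDataError("constant ground-truth map: MSSIM undefined")
    return float(
        structural_similarity(
            truth,
            est,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
            data_range=data_range,
        )
    )


def roi_stats(
    strain: np.ndarray,
    roi: ROISpec,
    spacings_mm: tuple[float, float],
) -> ROIStats:
    """Mean and sample std of strain within one ROI rectangle."""
    strain = np.asarray(strain, dtype=float)
    si, sj = roi.to_slices(strain.shape, spacings_mm)
    patch = strain[si, sj]
    return ROIStats(
        mean=float(patch.mean()),
        std=float(patch.std(ddof=1)),
        count=int(patch.size),
    )


def snr(bg: ROIStats) -> float:
    """Elastographic SNR: |background mean| / background std.

    The magnitude guards the sign convention of compressive strain.
    """
    if bg.std == 0:
        raise MetricError("zero background std: SNR undefined")
    return abs(bg.mean) / bg.std


def cnr(target: ROIStats, bg: ROIStats) -> float:
    """Elastographic CNR: sqrt(2 (mean_b - mean_t)^2 / (std_b^2 + std_t^2))."""
    denom = bg.std**2 + target.std**2
    if denom == 0:
        raise MetricError("zero variance in both ROIs: CNR undefined")
    return math.sqrt(2.0 * (bg.mean - target.mean) ** 2 / denom)


def roi_sweep(
    strain: np.ndarray,
    backgrounds: list[ROISpec],
    targets: list[ROISpec],
    spacings_mm: tuple[float, float],
    truth: np.ndarray | None = None,
) -> MetricReport:
    """Run the multi-ROI protocol on one strain map.

    Produces one SNR per background ROI and one CNR per (target,
    background) combination; if a ground-truth map is supplied, MAE and
    MSSIM are included too.
    """
    if not backgrounds:
        raise InputDataError("at least one background ROI is required")
    bg_stats = [roi_stats(strain, roi, spacings_mm) for roi in backgrounds]
    tg_stats = [roi_stats(strain, roi, spacings_mm) for roi in targets]
    report = MetricReport(
        snr_values=[snr(s) for s in bg_stats],
        cnr_values=[cnr(t, b) for t in tg_stats for b in bg_stats],
    )
    if truth is not None:
        report.mae = mae(strain, truth)
        report.mssim = mssim(strain, truth)
    return report


def roi_grid(
    axial_range_mm: tuple[float, float],
    lateral_range_mm: tuple[float, float],
    n_axial: int,
    n_lateral: int,
    size_mm: tuple[float, float] = (3.0, 3.0),
    role: str = "background",
) -> list[ROISpec]:
    """Evenly spaced grid of ROI centres spanning the given mm ranges.

    A 6x5 grid reproduces the 30-background-ROI sweep of the evaluation
    protocol.
    """
    ax = np.linspace(*axial_range_mm, n_axial)
    lat = np.linspace(*lateral_range_mm, n_lateral)
    return [
        ROISpec(center_mm=(float(a), float(b)), size_mm=size_mm, role=role)
        for a in ax
        for b in lat
    ]
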