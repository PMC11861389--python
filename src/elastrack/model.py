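"""Model/Results interface over the displacement tracker.

``SpeckleTrackingModel`` bundles an RF frame pair with the tracking
parameters; ``fit()`` runs the integer-lag seeding and the regularized
continuous refinement, and returns a ``SpeckleTrackingResults`` carrying
the displacement estimates, the effective Poisson's-ratio map, the
iteration diagnostics, and accessors for the strain tensor, quality
metrics and a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputDataError
from .initialization import IntegerDisplacementField, dp_initial_displacement
from .io import RFFrame
from .metrics import MetricReport, mae, mssim
from .params import TrackingParams, preset
from .strain import StrainTensor, strain_tensor
from .tracking import DisplacementField, PoissonMap, track

__all__ = ["SpeckleTrackingModel", "SpeckleTrackingResults"]


class SpeckleTrackingModel:
    """Displacement-estimation model for one pre/post RF frame pair.

    Parameters
    ----------
    pre, post
        Beamformed RF frames before/after compression (same shape and
        metadata).
    params
        Tracking parameters; defaults to the "simulated" preset.
    dp_bounds
        Integer (axial, lateral) search half-widths of the seeding stage.
        ``None`` skips seeding and starts from the zero field.
    dp_smoothness
        L1 lag-jump penalty of the seeding stage.
    """

    def __init__(
        self,
        pre: RFFrame,
        post: RFFrame,
        params: TrackingParams | None = None,
        dp_bounds: tuple[int, int] | None = (10, 2),
        dp_smoothness: float = 0.5,
    ) -> None:
        if pre.shape != post.shape:
            raise InputDataError(
                f"frame shapes differ: {pre.shape} vs {post.shape}"
            )
        self.pre = pre
        self.post = post
        self.params = params or preset("simulated")
        self.dp_bounds = dp_bounds
        self.dp_smoothness = dp_smoothness

    @classmethod
    def from_arrays(
        cls,
        pre: np.ndarray,
        post: np.ndarray,
        axial_spacing_mm: float,
        lateral_spacing_mm: float,
        center_frequency_MHz: float = 7.27,
        sampling_frequency_MHz: float = 40.0,
        **kwargs,
    ) -> "SpeckleTrackingModel":
        """Build the model from bare sample grids plus spacings."""
        meta = dict(
            axial_spacing_mm=axial_spacing_mm,
            lateral_spacing_mm=lateral_spacing_mm,
            center_frequency_MHz=center_frequency_MHz,
            sampling_frequency_MHz=sampling_frequency_MHz,
        )
        return cls(
            RFFrame(samples=pre, **meta), RFFrame(samples=post, **meta), **kwargs
        )

    def seed(self) -> IntegerDisplacementField:
        """Integer displacement seed (dynamic programming, or zeros)."""
        if self.dp_bounds is None:
            return IntegerDisplacementField.zeros(self.pre.shape)
        return dp_initial_displacement(
            self.pre, self.post, self.dp_bounds, self.dp_smoothness
        )

    def fit(
        self, init: IntegerDisplacementField | None = None
    ) -> "SpeckleTrackingResults":
        """Run seeding (unless provided) and the continuous refinement."""
        init = init if init is not None else self.seed()
        disp, nu, log = track(self.pre, self.post, init, self.params)
        return SpeckleTrackingResults(
            model=self, init=init, displacement=disp, poisson=nu, log=log
        )


@dataclass
class SpeckleTrackingResults:
    """Estimates and diagnostics of one tracking fit."""

    model: SpeckleTrackingModel
    init: IntegerDisplacementField
    displacement: DisplacementField
    poisson: PoissonMap
    log: list[dict]

    @property
    def cost_trace(self) -> np.ndarray:
        return np.array([entry["cost"] for entry in self.log])

    @property
    def n_iter(self) -> int:
        return int(self.log[-1]["iteration"])

    @property
    def converged(self) -> bool:
        return bool(self.log[-1].get("converged", False))

    def strain(self, kernel: int = 3) -> StrainTensor:
        """Least-squares strain tensor of the fitted displacement field."""
        return strain_tensor(
            self.displacement.a,
            self.displacement.l,
            self.model.pre.axial_spacing_mm,
            self.model.pre.lateral_spacing_mm,
            kernel=kernel,
        )

    def accuracy(
        self, truth: dict[str, np.ndarray], kernel: int = 3
    ) -> dict[str, MetricReport]:
        """MAE/MSSIM per strain component against ground-truth maps."""
        est = self.strain(kernel).components()
        out: dict[str, MetricReport] = {}
        for name, truth_map in truth.items():
            report = MetricReport()
            report.mae = mae(est[name], truth_map)
            report.mssim = mssim(est[name], truth_map)
            out[name] = report
        return out

    def summary(self, interior_margin: float = 0.1) -> str:
        """Readable fit report: iterations, cost, interior mean strains.

        ``interior_margin`` is the border fraction excluded from the
        strain means.
        """
        s = self.strain()
        m, n = s.shape
        mi = max(1, int(interior_margin * m))
        ni = max(1, int(interior_margin * n))
        interior = (slice(mi, m - mi), slice(ni, n - ni))
        lines = [
            "Speckle tracking fit",
            "====================",
            f"frame shape:        {m} x {n}",
            f"iterations:         {self.n_iter} "
            f"({'converged' if self.converged else 'max iterations'})",
            f"initial cost:       {self.cost_trace[0]:.6g}",
            f"final cost:         {self.cost_trace[-1]:.6g}",
            f"seed bounds:        {self.init.search_bounds}",
            "",
            "interior mean strains (dimensionless)",
            f"  axial:         {s.axial[interior].mean():+.5f}",
            f"  lateral:       {s.lateral[interior].mean():+.5f}",
            f"  axial shear:   {s.axial_shear[interior].mean():+.5f}",
            f"  lateral shear: {s.lateral_shear[interior].mean():+.5f}",
            "",
            f"effective Poisson's ratio (median): "
            f"{float(np.median(self.poisson.nu)):.3f}",
        ]
        return "\n".join(lines)
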