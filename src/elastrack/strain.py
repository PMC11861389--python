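"""Least-squares differentiation of displacement fields into strains.

The full 2-D strain tensor of a displacement field (a = axial, l = lateral)
has four components:

* axial strain        = d a / d y
* lateral strain      = d l / d x
* axial shear strain  = d a / d x
* lateral shear strain = d l / d y

Derivatives are per-pixel slopes of a least-squares line fitted over a
short window (default 3 samples — the smallest kernel, chosen to avoid any
non-data-driven smoothing; larger odd kernels are supported but smooth the
strain image). Displacements are converted to millimetres before
differentiation so the shear components, which mix the two axes, come out
dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import InputDataError, ParameterError

__all__ = ["StrainTensor", "least_squares_gradient", "strain_tensor"]


@dataclass(frozen=True)
class StrainTensor:
    """The four dimensionless strain maps of a 2-D displacement field."""

    axial: np.ndarray
    lateral: np.ndarray
    axial_shear: np.ndarray
    lateral_shear: np.ndarray

    def __post_init__(self) -> None:
        shapes = {g.shape for g in (self.axial, self.lateral,
                                    self.axial_shear, self.lateral_shear)}
        if len(shapes) != 1:
            raise InputDataError(f"strain component shapes differ: {shapes}")
        for name in ("axial", "lateral", "axial_shear", "lateral_shear"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise InputDataError(f"non-finite values in {name} strain")

    @property
    def shape(self) -> tuple[int, int]:
        return self.axial.shape

    def components(self) -> dict[str, np.ndarray]:
        return {
            "axial": self.axial,
            "lateral": self.lateral,
            "axial_shear": self.axial_shear,
            "lateral_shear": self.lateral_shear,
        }


def least_squares_gradient(
    field: np.ndarray,
    axis: str,
    kernel: int = 3,
    spacing_mm: float = 1.0,
) -> np.ndarray:
    """Per-pixel least-squares slope along ``axis`` ("axial" or "lateral").

    The slope of the best-fit line over a centred window of ``kernel``
    points is ``sum_t t * f(center + t) / sum_t t^2`` for ``t`` in
    ``-h..h``; for ``kernel=3`` this reduces to the central difference
    ``(f(i+1) - f(i-1)) / 2``. Border pixels take the slope of the nearest
    full window. Exact on linear ramps.
    """
    field = np.asarray(field, dtype=float)
    if kernel < 3 or kernel % 2 == 0:
        raise ParameterError(f"kernel must be odd and >= 3, got {kernel}")
    if not spacing_mm > 0:
        raise ParameterError(f"spacing_mm must be > 0, got {spacing_mm}")
    if axis == "axial":
        ax = 0
    elif axis == "lateral":
        ax = 1
    else:
        raise ParameterError(f"axis must be 'axial' or 'lateral', got {axis!r}")
    if field.shape[ax] < kernel:
        raise InputDataError(
            f"kernel {kernel} exceeds grid size {field.shape[ax]} along {axis}"
        )
    h = kernel // 2
    t = np.arange(-h, h + 1, dtype=float)
    weights = t / np.sum(t * t)
    windows = sliding_window_view(field, kernel, axis=ax)
    valid = windows @ weights  # slope at each full-window centre
    pad = [(0, 0), (0, 0)]
    pad[ax] = (h, h)
    return np.pad(valid, pad, mode="edge") / spacing_mm


def strain_tensor(
    axial_disp: np.ndarray,
    lateral_disp: np.ndarray,
    axial_spacing_mm: float,
    lateral_spacing_mm: float,
    kernel: int = 3,
) -> StrainTensor:
    """Differentiate displacement grids into the four strain components.

    ``axial_disp`` is in axial samples and ``lateral_disp`` in lateral
    lines; both are converted to mm with the respective spacings before
    the least-squares differentiation, so every output is dimensionless.
    """
    if not (axial_spacing_mm > 0 and lateral_spacing_mm > 0):
        raise ParameterError("spacings must be strictly positive")
    a_mm = np.asarray(axial_disp, dtype=float) * axial_spacing_mm
    l_mm = np.asarray(lateral_disp, dtype=float) * lateral_spacing_mm
    return StrainTensor(
        axial=least_squares_gradient(a_mm, "axial", kernel, axial_spacing_mm),
        lateral=least_squares_gradient(l_mm, "lateral", kernel, lateral_spacing_mm),
        axial_shear=least_squares_gradient(a_mm, "lateral", kernel, lateral_spacing_mm),
        lateral_shear=least_squares_gradient(l_mm, "axial", kernel, axial_spacing_mm),
    )
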