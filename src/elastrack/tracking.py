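"""Continuous displacement refinement by regularized energy minimisation.

Starting from an integer-sample seed, the tracker minimises a cost with
four ingredients, evaluated per pixel over the frame pair (I1, I2):

* data fidelity — squared residual between I1 and I2 warped by the total
  displacement, linearised by a first-order Taylor expansion in the
  increments;
* adaptive first-order L1 continuity — displacement derivatives are pulled
  toward locally expected strain offsets (the eps maps) rather than zero;
* second-order L1 continuity — unmixed curvature penalties plus the mixed
  cross-derivative stencils that close the regularization gap the unmixed
  terms leave (each strain component gets regularized in both directions);
* mechanical consistency — the samplewise residual of
  ``d_x l + nu * d_y a`` with the effective Poisson's ratio ``nu``.

Every L1 factor |x| is smoothed to ``sqrt(x^2 + delta^2)``, and the
smoothed cost is minimised by iteratively reweighted least squares: each
outer iteration freezes the IRLS weights and the Taylor linearisation at
the current state, assembles the sparse normal equations over the 2mn
interleaved unknowns (delta-a, delta-l per pixel, column-major over the
grid, which keeps the data block tridiagonal), solves, and folds the
increment into the running displacement. A backtracking step safeguard
keeps the true smoothed cost non-increasing, and the Poisson-ratio map is
re-estimated from the current strains after every accepted step.

Displacements are kept in sample/line units throughout; the effective
Poisson's ratio is unit-free, so no physical spacing enters here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import RectBivariateSpline
from scipy.ndimage import median_filter, uniform_filter
from scipy.sparse.linalg import splu

from .exceptions import (
    AssemblyError,
    DivergenceError,
    ParameterError,
    SolverError,
)
from .initialization import IntegerDisplacementField
from .io import RFFrame
from .params import TrackingParams
from .strain import least_squares_gradient

__all__ = [
    "DisplacementField",
    "AdaptiveEps",
    "PoissonMap",
    "LinearSystem",
    "smooth_abs",
    "warp_and_residual",
    "adaptive_eps",
    "mixed_stencil",
    "assemble_system",
    "assemble_unmixed_system",
    "solve_increment",
    "update_poisson",
    "evaluate_cost",
    "surrogate_cost",
    "track",
]

logger = logging.getLogger(__name__)

#: Axial-strain floor below which the Poisson-ratio update keeps the
#: previous value (the ratio is ill-conditioned there).
POISSON_STRAIN_FLOOR = 1e-4


# ---------------------------------------------------------------------------
# containers


@dataclass
class DisplacementField:
    """Continuous displacement state: totals (a, l) plus increments."""

    a: np.ndarray  # axial displacement, samples
    l: np.ndarray  # lateral displacement, lines
    da: np.ndarray | None = None
    dl: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.l = np.asarray(self.l, dtype=float)
        if self.da is None:
            self.da = np.zeros_like(self.a)
        if self.dl is None:
            self.dl = np.zeros_like(self.l)
        self.da = np.asarray(self.da, dtype=float)
        self.dl = np.asarray(self.dl, dtype=float)
        shapes = {g.shape for g in (self.a, self.l, self.da, self.dl)}
        if len(shapes) != 1:
            raise ParameterError(f"displacement grid shapes differ: {shapes}")
        for name in ("a", "l", "da", "dl"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ParameterError(f"non-finite values in {name}")

    @classmethod
    def from_integer(cls, init: IntegerDisplacementField) -> "DisplacementField":
        return cls(init.a0.astype(float), init.l0.astype(float))

    @property
    def shape(self) -> tuple[int, int]:
        return self.a.shape

    def total(self) -> tuple[np.ndarray, np.ndarray]:
        return self.a + self.da, self.l + self.dl


@dataclass(frozen=True)
class AdaptiveEps:
    """Locally expected first-derivative offsets of the initial field."""

    eps_aa: np.ndarray  # d_y a
    eps_al: np.ndarray  # d_x a
    eps_la: np.ndarray  # d_y l
    eps_ll: np.ndarray  # d_x l

    @classmethod
    def zeros(cls, shape: tuple[int, int]) -> "AdaptiveEps":
        z = np.zeros(shape)
        return cls(z, z.copy(), z.copy(), z.copy())


@dataclass(frozen=True)
class PoissonMap:
    """Pixelwise effective Poisson's ratio, clamped to its bounds."""

    nu: np.ndarray

    @classmethod
    def constant(cls, shape: tuple[int, int], value: float) -> "PoissonMap":
        return cls(np.full(shape, float(value)))


@dataclass(frozen=True)
class LinearSystem:
    """Normal equations of one IRLS step over the interleaved unknowns.

    Ordering: pixel p = j*m + i (column-major), unknown 2p is delta-a and
    2p+1 is delta-l. A is symmetric, positive definite for positive
    weights and l1_delta.
    """

    A: sp.csr_matrix
    rhs: np.ndarray
    shape: tuple[int, int]


# ---------------------------------------------------------------------------
# primitives


def smooth_abs(x, delta: float):
    """Differentiable |x|: value ``sqrt(x^2 + delta^2)`` and its IRLS weight
    ``1 / sqrt(x^2 + delta^2)`` (up to the standard 1/2 IRLS factor)."""
    if not delta > 0:
        raise ParameterError(f"delta must be > 0, got {delta}")
    value = np.sqrt(np.square(x) + delta * delta)
    return value, 1.0 / value


def _frame_samples(frame) -> np.ndarray:
    return frame.samples if isinstance(frame, RFFrame) else np.asarray(frame, float)


def _spline(I2: np.ndarray) -> RectBivariateSpline:
    m, n = I2.shape
    return RectBivariateSpline(np.arange(m), np.arange(n), I2, kx=3, ky=3)


def warp_and_residual(I1, I2, disp: DisplacementField):
    """Data residual and warped image gradients at the current state.

    Returns ``(mu, grad_a, grad_l)`` where ``mu = I1 - I2(i+a, j+l)`` by
    cubic-spline sub-sample evaluation and the gradients are the spline
    derivatives of I2 at the warped coordinates. Pixels warped outside the
    frame are masked: all three outputs are zero there, removing them from
    the data term while the regularizers stay active.
    """
    A = _frame_samples(I1)
    B = _frame_samples(I2)
    m, n = A.shape
    a_tot, l_tot = disp.total()
    ii, jj = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
    Y = ii + a_tot
    X = jj + l_tot
    inside = (Y >= 0) & (Y <= m - 1) & (X >= 0) & (X <= n - 1)
    spl = _spline(B)
    yf, xf = Y.ravel(), X.ravel()
    warped = spl.ev(yf, xf).reshape(m, n)
    grad_a = spl.ev(yf, xf, dx=1).reshape(m, n)
    grad_l = spl.ev(yf, xf, dy=1).reshape(m, n)
    mu = A - warped
    mu[~inside] = 0.0
    grad_a[~inside] = 0.0
    grad_l[~inside] = 0.0
    return mu, grad_a, grad_l


def _edge_backward_diff(field: np.ndarray, axis: int) -> np.ndarray:
    """Backward difference with the first row/column edge-replicated."""
    d = np.diff(field, axis=axis)
    first = np.take(d, [0], axis=axis)
    return np.concatenate([first, d], axis=axis)


def adaptive_eps(init, window: int = 21) -> AdaptiveEps:
    """Moving-window means of the initial field's first derivatives.

    ``init`` may be an integer seed or a continuous field. The four maps
    are 2-D uniform-filter means (``mode="nearest"``) of the
    backward-difference derivatives, so the first-order penalty pulls each
    displacement derivative toward the locally expected strain.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    if isinstance(init, IntegerDisplacementField):
        a, l = init.a0.astype(float), init.l0.astype(float)
    else:
        a, l = init.a.astype(float), init.l.astype(float)

    def windowed(deriv: np.ndarray) -> np.ndarray:
        return uniform_filter(deriv, size=window, mode="nearest")

    return AdaptiveEps(
        eps_aa=windowed(_edge_backward_diff(a, 0)),
        eps_al=windowed(_edge_backward_diff(a, 1)),
        eps_la=windowed(_edge_backward_diff(l, 0)),
        eps_ll=windowed(_edge_backward_diff(l, 1)),
    )


def mixed_stencil(field: np.ndarray, i: int, j: int) -> float:
    """Mixed second difference ``f(i,j) - f(i,j-1) - f(i-1,j) + f(i-1,j-1)``.

    Defined on the 0-based interior (``i >= 1`` and ``j >= 1``); border
    sites are omitted from the cost.
    """
    if i < 1 or j < 1:
        raise ParameterError("mixed stencil requires i >= 1 and j >= 1")
    f = np.asarray(field, dtype=float)
    return float(f[i, j] - f[i, j - 1] - f[i - 1, j] + f[i - 1, j - 1])


# ---------------------------------------------------------------------------
# term machinery
#
# Every regularizer is a set of linear residual rows r = L x + c over the
# interleaved increment vector x, with IRLS weight lam / (2 sqrt(c^2+d^2))
# frozen at x = 0. The stencil tables give (di, dj, coeff) per tap.

_D_Y = ((0, 0, 1.0), (-1, 0, -1.0))
_D_X = ((0, 0, 1.0), (0, -1, -1.0))
_D_YY = ((1, 0, 1.0), (0, 0, -2.0), (-1, 0, 1.0))
_D_XX = ((0, 1, 1.0), (0, 0, -2.0), (0, -1, 1.0))
_D_XY = ((0, 0, 1.0), (0, -1, -1.0), (-1, 0, -1.0), (-1, -1, 1.0))


def _valid_slices(offsets, shape):
    """Interior slice where every tap of the stencil stays on the grid."""
    m, n = shape
    di = [o[0] for o in offsets]
    dj = [o[1] for o in offsets]
    i0, i1 = max(0, -min(di)), m - max(0, max(di))
    j0, j1 = max(0, -min(dj)), n - max(0, max(dj))
    return slice(i0, i1), slice(j0, j1)


def _apply_stencil(field: np.ndarray, offsets) -> np.ndarray:
    """Stencil applied to a base field over its valid interior."""
    si, sj = _valid_slices(offsets, field.shape)
    out = np.zeros((si.stop - si.start, sj.stop - sj.start))
    for di, dj, coeff in offsets:
        out += coeff * field[si.start + di : si.stop + di,
                             sj.start + dj : sj.stop + dj]
    return out


def _stencil_rows(offsets, comp: int, shape):
    """COO pieces of the residual operator L for one scalar stencil term.

    ``comp`` is 0 for the axial increment, 1 for the lateral one. Returns
    (rows, cols, vals, n_rows).
    """
    m, n = shape
    si, sj = _valid_slices(offsets, shape)
    ii, jj = np.meshgrid(
        np.arange(si.start, si.stop), np.arange(sj.start, sj.stop), indexing="ij"
    )
    n_rows = ii.size
    row_idx = np.arange(n_rows)
    rows, cols, vals = [], [], []
    for di, dj, coeff in offsets:
        p = (jj + dj) * m + (ii + di)
        rows.append(row_idx)
        cols.append(2 * p.ravel() + comp)
        vals.append(np.full(n_rows, coeff))
    return (
        np.concatenate(rows),
        np.concatenate(cols),
        np.concatenate(vals),
        n_rows,
    )


def _term_table(params: TrackingParams):
    """(name, lam, offsets, comp, eps-attr) for every scalar L1 term."""
    return (
        ("first_axial_dy", params.wf * params.alpha1s, _D_Y, 0, "eps_aa"),
        ("first_axial_dx", params.wf * params.alpha2s, _D_X, 0, "eps_al"),
        ("first_lateral_dy", params.wf * params.beta1s, _D_Y, 1, "eps_la"),
        ("first_lateral_dx", params.wf * params.beta2s, _D_X, 1, "eps_ll"),
        ("second_axial_dyy", params.ws * params.alpha1s, _D_YY, 0, None),
        ("second_axial_dxx", params.ws * params.alpha2s, _D_XX, 0, None),
        ("second_lateral_dyy", params.ws * params.beta1s, _D_YY, 1, None),
        ("second_lateral_dxx", params.ws * params.beta2s, _D_XX, 1, None),
        ("mixed_axial", params.ws * params.alpha_mix, _D_XY, 0, None),
        ("mixed_lateral", params.ws * params.beta_mix, _D_XY, 1, None),
    )


def _mechanical_pieces(disp: DisplacementField, nu: PoissonMap):
    """Residual offset c and operator COO pieces of the mechanical term.

    r(i,j) = [l(i,j) - l(i,j-1)] + nu(i,j) [a(i,j) - a(i-1,j)] on the
    interior i >= 1, j >= 1, applied to the total field.
    """
    m, n = disp.shape
    si, sj = slice(1, m), slice(1, n)
    nu_in = nu.nu[si, sj]
    c = (disp.l[1:, 1:] - disp.l[1:, :-1]) + nu_in * (
        disp.a[1:, 1:] - disp.a[:-1, 1:]
    )
    ii, jj = np.meshgrid(np.arange(1, m), np.arange(1, n), indexing="ij")
    n_rows = ii.size
    row_idx = np.arange(n_rows)
    taps = (
        (0, 0, 1, np.ones(n_rows)),            # +1 on delta-l(i, j)
        (0, -1, 1, -np.ones(n_rows)),          # -1 on delta-l(i, j-1)
        (0, 0, 0, nu_in.ravel()),              # +nu on delta-a(i, j)
        (-1, 0, 0, -nu_in.ravel()),            # -nu on delta-a(i-1, j)
    )
    rows, cols, vals = [], [], []
    for di, dj, comp, coeff in taps:
        p = (jj + dj) * m + (ii + di)
        rows.append(row_idx)
        cols.append(2 * p.ravel() + comp)
        vals.append(coeff)
    return c.ravel(), (
        np.concatenate(rows),
        np.concatenate(cols),
        np.concatenate(vals),
        n_rows,
    )


def assemble_system(
    I1,
    I2,
    disp: DisplacementField,
    nu: PoissonMap,
    eps: AdaptiveEps,
    params: TrackingParams,
) -> LinearSystem:
    """Normal equations of the IRLS quadratic surrogate at the current state.

    Zero-weight terms are skipped entirely, so the assembly with
    ``alpha_mix = beta_mix = 0`` is bit-identical to the unmixed baseline
    path (:func:`assemble_unmixed_system`).
    """
    m, n = disp.shape
    N = 2 * m * n
    mu, grad_a, grad_l = warp_and_residual(I1, I2, disp)
    for name, g in (("mu", mu), ("grad_a", grad_a), ("grad_l", grad_l)):
        if not np.all(np.isfinite(g)):
            raise AssemblyError(f"non-finite entries in data term ({name})")
    # data block: per-pixel outer products of (grad_a, grad_l); tridiagonal
    # in the interleaved ordering.
    ga = grad_a.ravel(order="F")
    gl = grad_l.ravel(order="F")
    muf = mu.ravel(order="F")
    p = np.arange(m * n)
    rows = np.concatenate([2 * p, 2 * p, 2 * p + 1, 2 * p + 1])
    cols = np.concatenate([2 * p, 2 * p + 1, 2 * p, 2 * p + 1])
    vals = np.concatenate([ga * ga, ga * gl, gl * ga, gl * gl])
    A = sp.coo_matrix((vals, (rows, cols)), shape=(N, N)).tocsr()
    rhs = np.zeros(N)
    rhs[0::2] = muf * ga
    rhs[1::2] = muf * gl

    fields = (disp.a, disp.l)
    for name, lam, offsets, comp, eps_attr in _term_table(params):
        if lam == 0.0:
            continue
        c = _apply_stencil(fields[comp], offsets)
        if eps_attr is not None:
            si, sj = _valid_slices(offsets, disp.shape)
            c = c - getattr(eps, eps_attr)[si, sj]
        if not np.all(np.isfinite(c)):
            raise AssemblyError(f"non-finite residual in term {name}")
        c = c.ravel()
        w = lam / (2.0 * np.sqrt(c * c + params.l1_delta**2))
        r, cidx, v, n_rows = _stencil_rows(offsets, comp, disp.shape)
        L = sp.coo_matrix((v, (r, cidx)), shape=(n_rows, N)).tocsr()
        Lw = L.T @ sp.diags(w)
        A = A + Lw @ L
        rhs -= Lw @ c

    if params.alpha3s > 0.0:
        c, (r, cidx, v, n_rows) = _mechanical_pieces(disp, nu)
        if not np.all(np.isfinite(c)):
            raise AssemblyError("non-finite residual in mechanical term")
        w = params.alpha3s / (2.0 * np.sqrt(c * c + params.l1_delta**2))
        L = sp.coo_matrix((v, (r, cidx)), shape=(n_rows, N)).tocsr()
        Lw = L.T @ sp.diags(w)
        A = A + Lw @ L
        rhs -= Lw @ c

    return LinearSystem(A=A.tocsr(), rhs=rhs, shape=(m, n))


def assemble_unmixed_system(
    I1, I2, disp, nu, eps, params: TrackingParams
) -> LinearSystem:
    """Baseline assembly without the mixed second-derivative terms."""
    return assemble_system(I1, I2, disp, nu, eps, params.without_mixed())


def solve_increment(
    system: LinearSystem, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Solve ``A x = rhs`` by sparse LU and unpack the increment grids.

    The relative residual ``||A x - rhs|| / ||rhs||`` must not exceed
    ``tol`` (a zero right-hand side short-circuits to the zero increment).
    """
    m, n = system.shape
    rhs_norm = np.linalg.norm(system.rhs)
    # a (numerically) zero right-hand side has the zero increment as its
    # solution; skip the factorization, which may be singular without
    # regularization
    scale = np.abs(system.A.data).max(initial=1.0)
    if rhs_norm <= 1e-14 * scale * np.sqrt(system.rhs.size):
        zero = np.zeros((m, n))
        return zero, zero.copy()
    try:
        x = splu(system.A.tocsc()).solve(system.rhs)
    except RuntimeError as exc:
        raise SolverError(
            "sparse factorization failed (matrix singular or indefinite); "
            "ensure the regularization weights and l1_delta are positive"
        ) from exc
    if not np.all(np.isfinite(x)):
        raise SolverError("non-finite solution from the sparse factorization")
    residual = np.linalg.norm(system.A @ x - system.rhs) / rhs_norm
    if residual > tol:
        raise SolverError(
            f"relative residual {residual:.2e} exceeds tol {tol:.2e}"
        )
    da = x[0::2].reshape((m, n), order="F")
    dl = x[1::2].reshape((m, n), order="F")
    return da, dl


def update_poisson(
    disp: DisplacementField, prev: PoissonMap, params: TrackingParams
) -> PoissonMap:
    """Re-estimate the effective Poisson's ratio from the current strains.

    ``nu = -(d_x l) / (d_y a)`` wherever the axial strain magnitude exceeds
    a floor; elsewhere the previous value is kept. The map is 3x3
    median-smoothed and clamped to ``params.nu_bounds``. Both derivatives
    are 3-sample least-squares slopes in sample units — the ratio is
    independent of the physical spacings.
    """
    a_tot, l_tot = disp.total()
    d_ya = least_squares_gradient(a_tot, "axial", 3)
    d_xl = least_squares_gradient(l_tot, "lateral", 3)
    ok = np.abs(d_ya) >= POISSON_STRAIN_FLOOR
    nu = prev.nu.copy()
    nu[ok] = -d_xl[ok] / d_ya[ok]
    nu = median_filter(nu, size=3, mode="nearest")
    return PoissonMap(np.clip(nu, *params.nu_bounds))


# ---------------------------------------------------------------------------
# objectives


def _l1_terms_cost(
    a: np.ndarray, l: np.ndarray, nu: PoissonMap, eps: AdaptiveEps,
    params: TrackingParams,
) -> float:
    """Sum of all smoothed-L1 penalties at a total displacement state."""
    fields = (a, l)
    total = 0.0
    for _name, lam, offsets, comp, eps_attr in _term_table(params):
        if lam == 0.0:
            continue
        r = _apply_stencil(fields[comp], offsets)
        if eps_attr is not None:
            si, sj = _valid_slices(offsets, a.shape)
            r = r - getattr(eps, eps_attr)[si, sj]
        total += lam * float(np.sqrt(r * r + params.l1_delta**2).sum())
    if params.alpha3s > 0.0:
        r = (l[1:, 1:] - l[1:, :-1]) + nu.nu[1:, 1:] * (a[1:, 1:] - a[:-1, 1:])
        total += params.alpha3s * float(
            np.sqrt(r * r + params.l1_delta**2).sum()
        )
    return total


def evaluate_cost(
    I1, I2, disp: DisplacementField, nu: PoissonMap, eps: AdaptiveEps,
    params: TrackingParams,
) -> float:
    """Smoothed objective at the total state ``(a + da, l + dl)``.

    The data term is the true (re-warped) squared residual, masked outside
    the frame; with the mixed weights at zero this is exactly the unmixed
    baseline objective.
    """
    a_tot, l_tot = disp.total()
    mu, _, _ = warp_and_residual(I1, I2, DisplacementField(a_tot, l_tot))
    cost = float(np.sum(mu * mu))
    return cost + _l1_terms_cost(a_tot, l_tot, nu, eps, params)


def surrogate_cost(
    I1, I2, disp: DisplacementField, nu: PoissonMap, eps: AdaptiveEps,
    params: TrackingParams,
) -> float:
    """IRLS quadratic model at increments ``(da, dl)`` about ``(a, l)``.

    The data residual is Taylor-linearised and each L1 penalty is replaced
    by its frozen-weight quadratic ``lam * r^2 / (2 sqrt(r0^2 + delta^2))``
    (additive constants dropped), so the gradient with respect to the
    increment vector x is exactly ``2 (A x - rhs)`` of
    :func:`assemble_system` at the same state.
    """
    mu, grad_a, grad_l = warp_and_residual(
        I1, I2, DisplacementField(disp.a, disp.l)
    )
    r_data = mu - grad_a * disp.da - grad_l * disp.dl
    total = float(np.sum(r_data * r_data)) - float(np.sum(mu * mu))
    fields = (disp.a, disp.l)
    incs = (disp.da, disp.dl)
    delta2 = params.l1_delta**2
    for _name, lam, offsets, comp, eps_attr in _term_table(params):
        if lam == 0.0:
            continue
        c = _apply_stencil(fields[comp], offsets)
        if eps_attr is not None:
            si, sj = _valid_slices(offsets, disp.shape)
            c = c - getattr(eps, eps_attr)[si, sj]
        r = c + _apply_stencil(incs[comp], offsets)
        w = lam / (2.0 * np.sqrt(c * c + delta2))
        total += float(np.sum(w * r * r))
    if params.alpha3s > 0.0:
        a, l = fields
        da, dl = incs
        nu_in = nu.nu[1:, 1:]
        c = (l[1:, 1:] - l[1:, :-1]) + nu_in * (a[1:, 1:] - a[:-1, 1:])
        r = c + (dl[1:, 1:] - dl[1:, :-1]) + nu_in * (da[1:, 1:] - da[:-1, 1:])
        w = params.alpha3s / (2.0 * np.sqrt(c * c + delta2))
        total += float(np.sum(w * r * r))
    return total


# ---------------------------------------------------------------------------
# outer loop


def track(
    I1,
    I2,
    init: IntegerDisplacementField,
    params: TrackingParams,
    normalize: bool = True,
) -> tuple[DisplacementField, PoissonMap, list[dict]]:
    """Refine an integer seed into continuous displacement fields.

    Each outer iteration assembles and solves the IRLS normal equations,
    backtracks the increment until the true smoothed cost does not
    increase, folds it into the running displacement and re-estimates the
    Poisson-ratio map (the update is kept only when it does not increase
    the objective, so the logged cost trace is non-increasing by
    construction). Iteration stops at ``params.n_outer_iters`` or when the
    sup-norm of the applied increment falls below ``params.conv_tol``.

    Frames are normalised by the RMS of I1 (``normalize=True``) so the
    preset weights are meaningful regardless of the RF amplitude scale.

    Returns the displacement field, the final Poisson map and the
    iteration log (cost, step length, increment norms per iteration).
    """
    A = _frame_samples(I1).copy()
    B = _frame_samples(I2).copy()
    if A.shape != B.shape:
        raise ParameterError(f"frame shapes differ: {A.shape} vs {B.shape}")
    if normalize:
        scale = np.sqrt(np.mean(A**2))
        if scale > 0:
            A /= scale
            B /= scale
    disp = DisplacementField.from_integer(init)
    eps = adaptive_eps(init, params.eps_window)
    nu = PoissonMap.constant(disp.shape, params.nu_nominal)
    cost = evaluate_cost(A, B, disp, nu, eps, params)
    log: list[dict] = [
        {"iteration": 0, "cost": cost, "step": 0.0, "max_increment": 0.0}
    ]
    rise_count = 0
    converged = False
    for k in range(1, params.n_outer_iters + 1):
        system = assemble_system(A, B, disp, nu, eps, params)
        da, dl = solve_increment(system)
        step = 1.0
        accepted = False
        tiny = 1e-12 * max(1.0, abs(cost))
        for _ in range(10):
            cand = DisplacementField(disp.a + step * da, disp.l + step * dl)
            c_cand = evaluate_cost(A, B, cand, nu, eps, params)
            if c_cand <= cost + tiny:
                accepted = True
                break
            step *= 0.5
        if c_cand > cost * 1.10:
            rise_count += 1
            if rise_count >= 2:
                raise DivergenceError(
                    f"cost increased by more than 10% in two consecutive "
                    f"iterations (iteration {k})"
                )
        else:
            rise_count = 0
        if not accepted:
            # no descent direction left at this linearisation: converged
            log.append({"iteration": k, "cost": cost, "step": 0.0,
                        "max_increment": 0.0})
            converged = True
            break
        disp = cand
        max_inc = step * max(
            float(np.abs(da).max()), float(np.abs(dl).max())
        )
        nu_new = update_poisson(disp, nu, params)
        c_new = evaluate_cost(A, B, disp, nu_new, eps, params)
        if c_new <= c_cand + tiny:
            nu = nu_new
            cost = c_new
        else:
            cost = c_cand
        log.append(
            {"iteration": k, "cost": cost, "step": step,
             "max_increment": max_inc}
        )
        logger.debug("iteration %d: cost %.6g step %.3g |inc| %.3g",
                     k, cost, step, max_inc)
        if max_inc < params.conv_tol:
            converged = True
            break
    disp = DisplacementField(disp.a, disp.l, da, dl)
    log[-1]["converged"] = converged
    return disp, nu, log
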