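"""Integer-sample displacement seeding by dynamic programming.

The continuous tracker needs gross integer axial/lateral displacement
fields to linearise around. These are estimated per RF column (A-line) by
dynamic programming over a 2-D lattice of (axial, lateral) integer lags:
the per-sample data cost is the squared RF difference at the lagged
position, and consecutive samples along the A-line pay a smoothness
penalty proportional to the L1 distance between their lag pairs. A seed
column (the centre A-line) is solved first; the remaining columns are
solved outward to the left and right, each anchored to its already-solved
neighbour column through an additional per-sample L1 prior. This keeps the
field laterally coherent while every column remains an exact DP optimum of
its own objective.

The data cost is a hybrid: the windowed squared RF difference plus a
weighted windowed squared envelope difference. Pointwise RF matching is
phase-ambiguous — a lag error of one carrier period realigns the cosine
almost perfectly — while the envelope is cycle-unambiguous but coarse;
their sum keeps sample-level precision and suppresses cycle hopping.
Frames (and envelopes) are normalised to unit RMS internally so the
smoothness weight is relative to the per-sample data-cost scale.

The min-convolution with an L1 penalty is computed in O(number of states)
per sample with forward/backward cumulative-minimum passes (a 1-D distance
transform applied separably to the two lag axes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert

from .exceptions import InputDataError
from .io import RFFrame

__all__ = [
    "IntegerDisplacementField",
    "dp_initial_displacement",
    "column_path_cost",
]

logger = logging.getLogger(__name__)

_BIG = 1e6  # data cost assigned to out-of-bounds lag candidates


@dataclass(frozen=True)
class IntegerDisplacementField:
    """Integer axial/lateral lags per pixel, bounded by the search window."""

    a0: np.ndarray  # integer axial lags (samples)
    l0: np.ndarray  # integer lateral lags (lines)
    search_bounds: tuple[int, int]

    def __post_init__(self) -> None:
        a0 = np.asarray(self.a0, dtype=int)
        l0 = np.asarray(self.l0, dtype=int)
        object.__setattr__(self, "a0", a0)
        object.__setattr__(self, "l0", l0)
        if a0.shape != l0.shape:
            raise InputDataError("a0 and l0 shapes differ")
        ba, bl = self.search_bounds
        if np.abs(a0).max(initial=0) > ba or np.abs(l0).max(initial=0) > bl:
            raise InputDataError("integer lags exceed the search bounds")

    @classmethod
    def zeros(cls, shape: tuple[int, int],
              bounds: tuple[int, int] = (0, 0)) -> "IntegerDisplacementField":
        return cls(np.zeros(shape, int), np.zeros(shape, int), bounds)


def _samples(frame) -> np.ndarray:
    return frame.samples if isinstance(frame, RFFrame) else np.asarray(frame, float)


def _l1_min_transform(cost: np.ndarray, weight: float, axis: int) -> np.ndarray:
    """``out[k] = min_k' cost[k'] + weight * |k - k'|`` along ``axis``.

    Forward pass: ``w*k + cummin(cost[k'] - w*k')``; backward pass with the
    reversed sign; the transform is their pointwise minimum. O(K).
    """
    k = np.arange(cost.shape[axis], dtype=float)
    shape = [1] * cost.ndim
    shape[axis] = -1
    k = k.reshape(shape)
    fwd = weight * k + np.minimum.accumulate(cost - weight * k, axis=axis)
    g = cost + weight * k
    bwd = -weight * k + np.flip(
        np.minimum.accumulate(np.flip(g, axis=axis), axis=axis), axis=axis
    )
    return np.minimum(fwd, bwd)


def _normalized_envelopes(A: np.ndarray, B: np.ndarray):
    """Axial analytic-signal magnitudes, unit-RMS normalised by the first."""
    e1 = np.abs(hilbert(A, axis=0))
    e2 = np.abs(hilbert(B, axis=0))
    scale = np.sqrt(np.mean(e1**2))
    if scale > 0:
        e1 = e1 / scale
        e2 = e2 / scale
    return e1, e2


def _column_data_cost(
    I1: np.ndarray, I2: np.ndarray, j: int,
    da: np.ndarray, dl: np.ndarray, support: int,
    envelopes=None, envelope_weight: float = 0.0,
) -> np.ndarray:
    """Hybrid windowed data cost (m, Na, Nl) for column ``j``.

    Mean squared RF difference over ``support`` axial samples centred on
    the lag candidate, plus ``envelope_weight`` times the same measure on
    the envelopes (cycle disambiguation).
    """
    m, n = I1.shape
    rows = np.arange(m)[:, None] + da[None, :]  # (m, Na)
    row_ok = (rows >= 0) & (rows < m)
    rows_c = np.clip(rows, 0, m - 1)
    cost = np.full((m, da.size, dl.size), _BIG)
    for q, lag in enumerate(dl):
        col = j + lag
        if col < 0 or col >= n:
            continue
        c = (I1[:, j, None] - I2[rows_c, col]) ** 2
        if envelopes is not None and envelope_weight > 0:
            e1, e2 = envelopes
            c = c + envelope_weight * (e1[:, j, None] - e2[rows_c, col]) ** 2
        if support > 1:
            c = uniform_filter1d(c, support, axis=0, mode="nearest")
        cost[:, :, q] = np.where(row_ok, c, _BIG)
    return cost


def _solve_column(
    data: np.ndarray, weight: float, prior: np.ndarray | None,
    da: np.ndarray, dl: np.ndarray, pref_order: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact DP over one column; returns (axial lags, lateral lags, cost).

    ``data`` is (m, Na, Nl); ``prior`` an optional (m, Na, Nl) anchor cost
    added per sample. Backtracking recomputes the per-step argmin from the
    stored cumulative tables, breaking final-state ties by preferring the
    smaller-magnitude lag (axial before lateral).
    """
    m = data.shape[0]
    node = data if prior is None else data + prior
    table = np.empty_like(node)
    table[0] = node[0]
    for i in range(1, m):
        msg = _l1_min_transform(table[i - 1], weight, axis=0)
        msg = _l1_min_transform(msg, weight, axis=1)
        table[i] = node[i] + msg
    # tie-broken argmin at the deepest sample
    final = table[m - 1].ravel()
    best = final.min()
    s = pref_order[np.argmax(final[pref_order] == best)]
    ia = np.empty(m, int)
    il = np.empty(m, int)
    ia[m - 1], il[m - 1] = np.unravel_index(s, table.shape[1:])
    dist_a = np.abs(da[:, None] - da[None, :])
    dist_l = np.abs(dl[:, None] - dl[None, :])
    for i in range(m - 2, -1, -1):
        trans = (
            table[i]
            + weight * dist_a[:, ia[i + 1]][:, None]
            + weight * dist_l[:, il[i + 1]][None, :]
        )
        flat = trans.ravel()
        best = flat.min()
        s = pref_order[np.argmax(flat[pref_order] == best)]
        ia[i], il[i] = np.unravel_index(s, trans.shape)
    return da[ia], dl[il], float(final.min())


def dp_initial_displacement(
    I1,
    I2,
    bounds: tuple[int, int],
    smoothness_weight: float = 0.5,
    support: int = 9,
    envelope_weight: float = 2.0,
) -> IntegerDisplacementField:
    """Integer displacement seed for a frame pair by per-column DP.

    Parameters
    ----------
    I1, I2
        Pre/post RF frames (``RFFrame`` or 2-D arrays) of equal shape.
    bounds
        (axial, lateral) half-widths of the integer search window.
    smoothness_weight
        L1 penalty per unit lag jump between consecutive samples, relative
        to the per-sample data-cost scale (frames are RMS-normalised).
    support
        Odd axial window (samples) of the data cost.
    envelope_weight
        Weight of the envelope-difference term relative to the RF term;
        together with ``support`` it resolves the carrier-phase
        (cycle-hopping) ambiguity of pointwise RF matching.
    """
    if support < 1 or support % 2 == 0:
        raise InputDataError(f"support must be odd and >= 1, got {support}")
    A = _samples(I1)
    B = _samples(I2)
    if A.shape != B.shape:
        raise InputDataError(f"frame shapes differ: {A.shape} vs {B.shape}")
    m, n = A.shape
    ba, bl = (int(b) for b in bounds)
    if ba < 0 or bl < 0:
        raise InputDataError("bounds must be non-negative")
    if ba >= m or bl >= n:
        raise InputDataError(
            f"search bounds {bounds} not smaller than the frame {A.shape}"
        )
    if ba == 0 and bl == 0:
        return IntegerDisplacementField.zeros(A.shape, (0, 0))
    if np.ptp(A) == 0 and np.ptp(B) == 0:
        logger.warning("identical constant frames: degenerate matching, "
                       "returning the zero field")
        return IntegerDisplacementField.zeros(A.shape, (ba, bl))
    scale = np.sqrt(np.mean(A**2))
    if scale > 0:
        A = A / scale
        B = B / scale
    envelopes = _normalized_envelopes(A, B) if envelope_weight > 0 else None
    da = np.arange(-ba, ba + 1)
    dl = np.arange(-bl, bl + 1)
    # preference order for ties: smaller |axial| first, then smaller |lateral|
    mag_a, mag_l = np.meshgrid(np.abs(da), np.abs(dl), indexing="ij")
    sa, sl = np.meshgrid(da, dl, indexing="ij")
    pref_order = np.lexsort(
        (sl.ravel(), sa.ravel(), mag_l.ravel(), mag_a.ravel())
    )
    a0 = np.zeros((m, n), int)
    l0 = np.zeros((m, n), int)
    j_seed = n // 2
    data = _column_data_cost(A, B, j_seed, da, dl, support,
                             envelopes, envelope_weight)
    a0[:, j_seed], l0[:, j_seed], _ = _solve_column(
        data, smoothness_weight, None, da, dl, pref_order
    )
    for cols in (range(j_seed + 1, n), range(j_seed - 1, -1, -1)):
        for j in cols:
            j_nb = j - 1 if j > j_seed else j + 1
            prior = smoothness_weight * (
                np.abs(da[None, :, None] - a0[:, j_nb, None, None])
                + np.abs(dl[None, None, :] - l0[:, j_nb, None, None])
            )
            data = _column_data_cost(A, B, j, da, dl, support,
                                     envelopes, envelope_weight)
            a0[:, j], l0[:, j], _ = _solve_column(
                data, smoothness_weight, prior, da, dl, pref_order
            )
    return IntegerDisplacementField(a0, l0, (ba, bl))


def column_path_cost(
    I1,
    I2,
    j: int,
    axial_lags: np.ndarray,
    lateral_lags: np.ndarray,
    smoothness_weight: float = 0.5,
    support: int = 9,
    envelope_weight: float = 2.0,
    prior_lags: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Objective value of an arbitrary lag path down column ``j``.

    Matches the internal DP objective exactly (RMS normalisation and
    windowed data cost included), so DP optimality can be checked against
    candidate paths such as the zero-lag or any constant-lag path.
    """
    A = _samples(I1)
    B = _samples(I2)
    scale = np.sqrt(np.mean(A**2))
    if scale > 0:
        A = A / scale
        B = B / scale
    m = A.shape[0]
    al = np.asarray(axial_lags, int)
    ll = np.asarray(lateral_lags, int)
    da = np.arange(al.min(), al.max() + 1)
    dl = np.arange(ll.min(), ll.max() + 1)
    envelopes = _normalized_envelopes(A, B) if envelope_weight > 0 else None
    data = _column_data_cost(A, B, j, da, dl, support,
                             envelopes, envelope_weight)
    cost = float(
        data[np.arange(m), al - al.min(), ll - ll.min()].sum()
    )
    cost += smoothness_weight * (
        np.abs(np.diff(al)).sum() + np.abs(np.diff(ll)).sum()
    )
    if prior_lags is not None:
        pa, pl = prior_lags
        cost += smoothness_weight * (
            np.abs(al - pa).sum() + np.abs(ll - pl).sum()
        )
    return float(cost)
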