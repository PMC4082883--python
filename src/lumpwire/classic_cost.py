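"""Classical Live Wire local cost function.

The cost of the directed link from pixel ``p`` to an 8-neighbor ``q`` is

    C(p, q) = w_Z * f_Z(q) + w_G * f_G(q) + w_D * f_D(p, q)

with the empirical weights (0.43, 0.43, 0.14).  The three features are

* ``f_Z`` — Laplacian zero-crossing: 0 on zero-crossings of the
  Laplacian-of-Gaussian (points of maximal gradient magnitude), 1 elsewhere;
* ``f_G`` — inverted, max-normalized gradient magnitude, so the strongest
  edges cost 0;
* ``f_D`` — gradient direction: penalizes links that disagree with the local
  edge orientation, ``(2 / 3π) * (arccos d_p + arccos d_q)`` where ``d_p`` and
  ``d_q`` are dot products of the link direction with the unit vectors
  perpendicular to the gradients at ``p`` and ``q``.  The link vector is sign
  flipped so that ``d_p >= 0``, which caps ``f_D`` at 1.

Diagonal links are scaled by sqrt(2) so straight boundary paths are not beaten
by axial staircases.  All costs are kept in floating point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_core import GradientField, IntensityImage, ValidationError
from .livewire import LinkCostGraph, OFFSET_LENGTHS, OFFSETS

#: |L| at or below this is taken as the L(q) = 0 branch.  The discrete LoG
#: of a perfectly flat or linear patch is not exactly zero (kernel truncation
#: leaves ~1e-4 at unit intensity), so the threshold sits above that floor
#: and well below any real Laplacian response.
_LAPLACIAN_ZERO_TOL = 5e-4

_F_D_SCALE = 2.0 / (3.0 * np.pi)


@dataclass(frozen=True)
class BinaryFeatureMap:
    """Per-pixel binary cost feature (0 = edge evidence, 1 = none)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if not np.isin(v, (0.0, 1.0)).all():
            raise ValidationError("binary feature map must contain only 0/1")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ScalarCostMap:
    """Per-pixel scalar cost in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValidationError("scalar cost map values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class CostWeights:
    """Weights of the three cost features; the defaults are the empirical ones."""

    w_z: float = 0.43
    w_g: float = 0.43
    w_d: float = 0.14

    def __post_init__(self) -> None:
        if self.w_z < 0 or self.w_g < 0 or self.w_d < 0:
            raise ValidationError("cost weights must be non-negative")


def laplacian_zero_crossing(img: IntensityImage,
                            sigma: float) -> BinaryFeatureMap:
    """Binary Laplacian-of-Gaussian zero-crossing feature.

    A pixel costs 0 when its LoG response is (numerically) zero, or when the
    response changes sign against any 4-neighbor and this pixel has the
    smaller absolute response — i.e. the crossing is assigned to the side it
    lies closer to.  All other pixels cost 1.
    """
    if sigma <= 0:
        raise ValidationError(f"sigma must be positive, got {sigma}")
    lap = ndimage.gaussian_laplace(img.pixels, sigma=sigma, mode="reflect")
    absl = np.abs(lap)
    crossing = absl <= _LAPLACIAN_ZERO_TOL
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neigh = np.roll(lap, shift, axis=axis)
        nabs = np.roll(absl, shift, axis=axis)
        # the crossing goes to the smaller-|L| side; exact ties to the
        # negative-L side so an antisymmetric step yields a single line
        cand = (lap * neigh < 0) & (
            (absl < nabs) | ((absl == nabs) & (lap < neigh))
        )
        # roll wraps around the image; the wrapped row/col is not a neighbor
        if axis == 0:
            if shift == 1:
                cand[0, :] = False
            else:
                cand[-1, :] = False
        else:
            if shift == 1:
                cand[:, 0] = False
            else:
                cand[:, -1] = False
        crossing |= cand
    return BinaryFeatureMap(np.where(crossing, 0.0, 1.0))


def gradient_magnitude_cost(grad: GradientField) -> ScalarCostMap:
    """``f_G = 1 - G / max(G)``; all ones when the image has no gradient."""
    g = grad.magnitude
    gmax = g.max()
    if gmax == 0:
        return ScalarCostMap(np.ones_like(g))
    return ScalarCostMap(1.0 - g / gmax)


def _dprime(grad: GradientField) -> np.ndarray:
    """Unit vectors perpendicular to the gradient, as (x, y) components.

    Zero-gradient pixels get the zero vector, which yields the neutral
    direction cost d = 0 downstream.
    """
    norm = grad.magnitude
    safe = np.where(norm > 0, norm, 1.0)
    dpx = grad.iy / safe
    dpy = -grad.ix / safe
    dpx[norm == 0] = 0.0
    dpy[norm == 0] = 0.0
    return np.stack([dpx, dpy], axis=-1)


def gradient_direction_cost(grad: GradientField, p: tuple[int, int],
                            q: tuple[int, int]) -> float:
    """Direction cost f_D(p, q) for one link."""
    dr, dc = q[0] - p[0], q[1] - p[1]
    if (dr, dc) not in OFFSETS:
        raise ValidationError(f"{q} is not an 8-neighbor of {p}")
    dp_field = _dprime(grad)
    length = np.hypot(dr, dc)
    ux, uy = dc / length, dr / length  # link direction in (x, y) components
    a_p = dp_field[p[0], p[1], 0] * ux + dp_field[p[0], p[1], 1] * uy
    sign = 1.0 if a_p >= 0 else -1.0
    d_p = sign * a_p
    d_q = sign * (dp_field[q[0], q[1], 0] * ux + dp_field[q[0], q[1], 1] * uy)
    d_p = min(d_p, 1.0)
    d_q = float(np.clip(d_q, -1.0, 1.0))
    return float(_F_D_SCALE * (np.arccos(d_p) + np.arccos(d_q)))


def _direction_cost_stack(grad: GradientField) -> np.ndarray:
    """f_D for every pixel and every neighbor offset, shape (rows, cols, 8).

    Entries whose neighbor falls outside the image are left at 0; the graph
    constructor masks those links anyway.
    """
    dp = _dprime(grad)
    rows, cols = grad.magnitude.shape
    out = np.zeros((rows, cols, 8))
    for k, (dr, dc) in enumerate(OFFSETS):
        length = OFFSET_LENGTHS[k]
        ux, uy = dc / length, dr / length
        a_p = dp[:, :, 0] * ux + dp[:, :, 1] * uy
        sign = np.where(a_p >= 0, 1.0, -1.0)
        d_p = np.clip(sign * a_p, -1.0, 1.0)
        # D'(q): shift the field so slot (r, c) holds the value at (r+dr, c+dc)
        dq_field = np.zeros_like(dp)
        src_r = slice(max(dr, 0), rows + min(dr, 0))
        src_c = slice(max(dc, 0), cols + min(dc, 0))
        dst_r = slice(max(-dr, 0), rows + min(-dr, 0))
        dst_c = slice(max(-dc, 0), cols + min(-dc, 0))
        dq_field[dst_r, dst_c] = dp[src_r, src_c]
        a_q = dq_field[:, :, 0] * ux + dq_field[:, :, 1] * uy
        d_q = np.clip(sign * a_q, -1.0, 1.0)
        out[:, :, k] = _F_D_SCALE * (np.arccos(d_p) + np.arccos(d_q))
    return out


def combine_costs(edge_map: BinaryFeatureMap, f_g: ScalarCostMap,
                  grad: GradientField,
                  w: CostWeights | None = None) -> LinkCostGraph:
    """Weighted combination of the three features into the link-cost graph.

    ``edge_map`` and ``f_g`` are evaluated at the destination pixel ``q``;
    the direction term depends on both endpoints.  Diagonal links are scaled
    by sqrt(2).
    """
    if w is None:
        w = CostWeights()
    shape = edge_map.values.shape
    if f_g.values.shape != shape or grad.magnitude.shape != shape:
        raise ValidationError("feature maps must share one shape")
    static_q = w.w_z * edge_map.values + w.w_g * f_g.values
    f_d = _direction_cost_stack(grad)
    rows, cols = shape
    lc = np.zeros((rows, cols, 8))
    for k, (dr, dc) in enumerate(OFFSETS):
        # destination-pixel features, shifted so slot (r,c) reads q = p+offset
        sq = np.zeros(shape)
        src_r = slice(max(dr, 0), rows + min(dr, 0))
        src_c = slice(max(dc, 0), cols + min(dc, 0))
        dst_r = slice(max(-dr, 0), rows + min(-dr, 0))
        dst_c = slice(max(-dc, 0), cols + min(-dc, 0))
        sq[dst_r, dst_c] = static_q[src_r, src_c]
        cost = sq + w.w_d * f_d[:, :, k]
        if dr != 0 and dc != 0:
            cost = cost * np.sqrt(2.0)
        lc[:, :, k] = cost
    return LinkCostGraph.from_costs(lc)
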