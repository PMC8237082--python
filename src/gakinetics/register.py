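"""Second-order polynomial registration of visit pairs from control points.

Visit-1 and visit-2 en-face data are registered with a full second-order
bivariate polynomial per output coordinate (12 coefficients in total), fitted
by least squares to manually selected corresponding features (e.g. retinal
vessel bifurcations).  The warp maps visit-2 coordinates into the visit-1
reference frame; visit-1 geometry is never resampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .lesion import LesionMask

__all__ = ["PolynomialWarp", "fit_polynomial_warp", "apply_warp"]


def _design(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


@dataclass
class PolynomialWarp:
    """(x, y) -> (x', y') with x' = c0 + c1 x + c2 y + c3 x^2 + c4 xy + c5 y^2."""

    coeff_x: np.ndarray  # (6,)
    coeff_y: np.ndarray  # (6,)
    rms_residual_mm: float = 0.0

    @classmethod
    def identity(cls) -> "PolynomialWarp":
        cx = np.zeros(6)
        cy = np.zeros(6)
        cx[1] = 1.0
        cy[2] = 1.0
        return cls(cx, cy, 0.0)

    def __call__(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        A = _design(pts)
        return np.column_stack([A @ self.coeff_x, A @ self.coeff_y])


def fit_polynomial_warp(
    src_mm: np.ndarray, dst_mm: np.ndarray, order: int = 2
) -> PolynomialWarp:
    """Least-squares polynomial warp mapping ``src`` control points to ``dst``.

    Requires at least 6 non-degenerate pairs (6 coefficients per axis).
    """
    if order != 2:
        raise ValueError("only second-order warps are supported")
    src = np.atleast_2d(np.asarray(src_mm, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_mm, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("control point arrays must both be (n, 2)")
    if len(src) < 6:
        raise ValueError("at least 6 control-point pairs are required")
    A = _design(src)
    if np.linalg.matrix_rank(A) < 6:
        raise ValueError("control points are degenerate (rank-deficient design)")
    cx, *_ = np.linalg.lstsq(A, dst[:, 0], rcond=None)
    cy, *_ = np.linalg.lstsq(A, dst[:, 1], rcond=None)
    warp = PolynomialWarp(cx, cy)
    res = warp(src) - dst
    warp.rms_residual_mm = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return warp


def apply_warp(warp: PolynomialWarp, target, inverse_warp: PolynomialWarp | None = None):
    """Apply a fitted warp to points (exactly) or a mask (resampled).

    For a :class:`LesionMask`, resampling needs the *inverse* mapping (output
    pixel -> input position).  Supply ``inverse_warp`` (typically fitted on the
    swapped control pairs); by default the forward warp's control inverse is
    approximated by fitting a second-order warp to a grid of forward-mapped
    points.  The result is nearest-neighbour sampled and re-binarized.
    """
    if isinstance(target, LesionMask):
        mask = target
        if inverse_warp is None:
            w, h = mask.extent_mm
            gx, gy = np.meshgrid(
                np.linspace(mask.origin_mm[0], mask.origin_mm[0] + w, 12),
                np.linspace(mask.origin_mm[1], mask.origin_mm[1] + h, 12),
            )
            grid = np.column_stack([gx.ravel(), gy.ravel()])
            inverse_warp = fit_polynomial_warp(warp(grid), grid)
        nr, nc = mask.pixels.shape
        xs = mask.origin_mm[0] + (np.arange(nc) + 0.5) * mask.pitch_mm
        ys = mask.origin_mm[1] + (np.arange(nr) + 0.5) * mask.pitch_mm
        gx, gy = np.meshgrid(xs, ys)
        src = inverse_warp(np.column_stack([gx.ravel(), gy.ravel()]))
        rc = mask.to_index(src)
        vals = ndimage.map_coordinates(
            mask.pixels.astype(float), rc.T, order=0, mode="constant", cval=0.0
        )
        out = (vals.reshape(nr, nc) >= 0.5).astype(np.uint8)
        return LesionMask(
            pixels=out,
            pixel_pitch_um=mask.pixel_pitch_um,
            laterality=mask.laterality,
            eye_id=mask.eye_id,
            visit_id=mask.visit_id,
            origin_mm=mask.origin_mm,
        )
    return warp(np.asarray(target, dtype=float))
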