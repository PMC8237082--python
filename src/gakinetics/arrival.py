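"""Arrival-time field of the expanding lesion front.

The visit-1 margin is evolved to the visit-2 margin as a level-set front
moving with speed

    F(x) = max(0, 1 - beta * kappa(x)) * 1[x in Omega_2],

where kappa = div(grad phi / |grad phi|) is the signed curvature of the
evolving front (positive on a convex lesion boundary, e.g. a circle), so
concave (indented) margin segments advance faster than convex ones, and the
indicator confines the front to the follow-up lesion region Omega_2, making
it conform to and stop at the visit-2 margin.  The evolution is the standard
explicit level-set update of dphi/dt = -F |grad phi| with a first-order
Godunov upwind gradient, central-difference curvature, and periodic
signed-distance reinitialization.

For each grid cell of the growth region G = Omega_2 \\ Omega_1 the arrival
time T is recorded as the (sub-step, linearly interpolated) time at which phi
first crosses zero.  Absolute front speed is immaterial downstream: local
growth rates use trajectory arclengths, never T itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .lesion import LesionMask, MarginContour, extract_margins
from .params import GrowthParams

__all__ = ["ArrivalTimeField", "compute_arrival_time"]

_STRUCT8 = np.ones((3, 3), dtype=bool)


def _densify_contours(contours: list[MarginContour], step_mm: float) -> np.ndarray:
    """Sample contour polylines at roughly ``step_mm`` intervals."""
    chunks = []
    for c in contours:
        v = np.vstack([c.vertices, c.vertices[:1]]) if c.closed else c.vertices
        seg = np.hypot(*np.diff(v, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        n = max(int(np.ceil(s[-1] / step_mm)), len(v))
        t = np.linspace(0.0, s[-1], n, endpoint=False)
        chunks.append(
            np.column_stack([np.interp(t, s, v[:, 0]), np.interp(t, s, v[:, 1])])
        )
    if not chunks:
        return np.empty((0, 2))
    return np.vstack(chunks)


@dataclass
class ArrivalTimeField:
    """Arrival times on the working grid, plus the geometry needed to trace.

    ``T`` is 0 inside the visit-1 region, finite on reached cells of the
    growth region, and +inf on unreached cells and outside Omega_2.
    ``T_signed`` equals the initial signed distance inside Omega_1 (negative),
    giving a smooth field for gradient streamlines across the visit-1 margin.
    """

    T: np.ndarray
    T_signed: np.ndarray
    region1: np.ndarray
    region2: np.ndarray
    phi2: np.ndarray  # signed distance to the visit-2 margin (neg. inside)
    h_mm: float
    origin_mm: tuple[float, float]  # physical position of the grid corner
    margin2_samples: np.ndarray  # dense visit-2 margin samples (mm)
    n_steps: int = 0
    t_final: float = 0.0
    n_unreached: int = 0
    _tree2: cKDTree | None = field(default=None, repr=False)
    _grad: tuple | None = field(default=None, repr=False)
    _labels: np.ndarray | None = field(default=None, repr=False)

    # ---- coordinate helpers -------------------------------------------------
    def to_grid(self, points_mm: np.ndarray) -> np.ndarray:
        """Physical (x, y) -> fractional (row, col) on the working grid."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        col = (pts[:, 0] - self.origin_mm[0]) / self.h_mm - 0.5
        row = (pts[:, 1] - self.origin_mm[1]) / self.h_mm - 0.5
        return np.column_stack([row, col])

    def interp_phi2(self, points_mm: np.ndarray) -> np.ndarray:
        rc = self.to_grid(points_mm)
        return ndimage.map_coordinates(self.phi2, rc.T, order=1, mode="nearest")

    def interp_T(self, points_mm: np.ndarray) -> np.ndarray:
        """Validity-weighted bilinear interpolation of the arrival field.

        Cells never reached (or outside Omega_2) carry no time value; their
        bilinear weight is redistributed to the valid corners, so points near
        the visit-2 margin interpolate from covered cells only.
        """
        Tg = self.T_signed
        valid = np.isfinite(Tg)
        rc = self.to_grid(points_mm)
        nr, nc = Tg.shape
        r0 = np.clip(np.floor(rc[:, 0]).astype(int), 0, nr - 2)
        c0 = np.clip(np.floor(rc[:, 1]).astype(int), 0, nc - 2)
        fr = np.clip(rc[:, 0] - r0, 0.0, 1.0)
        fc = np.clip(rc[:, 1] - c0, 0.0, 1.0)
        num = np.zeros(len(rc))
        den = np.zeros(len(rc))
        for dr, dc, w in (
            (0, 0, (1 - fr) * (1 - fc)),
            (0, 1, (1 - fr) * fc),
            (1, 0, fr * (1 - fc)),
            (1, 1, fr * fc),
        ):
            rr, cc = r0 + dr, c0 + dc
            wv = w * valid[rr, cc]
            num += wv * np.where(valid[rr, cc], Tg[rr, cc], 0.0)
            den += wv
        out = np.full(len(rc), np.nan)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        return out

    @property
    def tree2(self) -> cKDTree:
        if self._tree2 is None:
            self._tree2 = cKDTree(self.margin2_samples)
        return self._tree2

    # ---- gradient of the arrival field --------------------------------------
    def _gradient_fields(self):
        """Masked central/one-sided gradients of T_signed, with validity."""
        if self._grad is not None:
            return self._grad
        Tg = self.T_signed
        valid = np.isfinite(Tg)
        h = self.h_mm
        gx = np.zeros_like(Tg)
        gy = np.zeros_like(Tg)
        gval = np.zeros(Tg.shape, dtype=bool)
        for axis, out in ((1, gx), (0, gy)):
            plus = np.roll(Tg, -1, axis=axis)
            minus = np.roll(Tg, 1, axis=axis)
            vplus = np.roll(valid, -1, axis=axis)
            vminus = np.roll(valid, 1, axis=axis)
            # roll wraps around; kill wrapped entries
            if axis == 1:
                vplus[:, -1] = False
                vminus[:, 0] = False
            else:
                vplus[-1, :] = False
                vminus[0, :] = False
            both = valid & vplus & vminus
            fwd = valid & vplus & ~vminus
            bwd = valid & ~vplus & vminus
            out[both] = (plus[both] - minus[both]) / (2 * h)
            out[fwd] = (plus[fwd] - Tg[fwd]) / h
            out[bwd] = (Tg[bwd] - minus[bwd]) / h
            gval |= both | fwd | bwd
        gval &= valid
        self._grad = (gx, gy, gval & np.isfinite(gx) & np.isfinite(gy))
        return self._grad

    def grad_at_many(self, points_mm: np.ndarray) -> np.ndarray:
        """Bilinear gradient of the arrival field at physical points, (n, 2).

        Corner cells with no valid gradient get zero weight; rows with no
        valid corner come back as the zero vector.
        """
        gx, gy, gval = self._gradient_fields()
        rc = self.to_grid(points_mm)
        nr, nc = gx.shape
        r0 = np.clip(np.floor(rc[:, 0]).astype(int), 0, nr - 2)
        c0 = np.clip(np.floor(rc[:, 1]).astype(int), 0, nc - 2)
        fr = np.clip(rc[:, 0] - r0, 0.0, 1.0)
        fc = np.clip(rc[:, 1] - c0, 0.0, 1.0)
        out = np.zeros((len(rc), 2))
        tot = np.zeros(len(rc))
        for dr, dc, w in (
            (0, 0, (1 - fr) * (1 - fc)),
            (0, 1, (1 - fr) * fc),
            (1, 0, fr * (1 - fc)),
            (1, 1, fr * fc),
        ):
            rr, cc = r0 + dr, c0 + dc
            wv = w * gval[rr, cc]
            out[:, 0] += wv * gx[rr, cc]
            out[:, 1] += wv * gy[rr, cc]
            tot += wv
        ok = tot > 0
        out[ok] /= tot[ok, None]
        out[~ok] = 0.0
        return out

    def grad_at(self, point_mm: np.ndarray) -> np.ndarray:
        """Gradient of the arrival field at a single physical point."""
        return self.grad_at_many(np.asarray(point_mm, dtype=float)[None, :])[0]

    # ---- visit-1 component labels propagated over Omega_2 -------------------
    def component_labels(self) -> tuple[np.ndarray, np.ndarray]:
        """(labels1, propagated) component label maps on the working grid.

        ``labels1`` labels the 8-connected visit-1 components (0 = background).
        ``propagated`` assigns every Omega_2 cell the label of the visit-1
        component whose front reaches it first, approximated by the shortest
        geodesic distance within Omega_2 (brush-fire label propagation).
        """
        if self._labels is not None:
            return self._labels
        from skimage.graph import MCP_Geometric

        labels1, n1 = ndimage.label(self.region1, structure=_STRUCT8)
        costs = np.where(self.region2, 1.0, np.inf)
        dists = []
        for k in range(1, n1 + 1):
            mcp = MCP_Geometric(costs)
            starts = np.argwhere(labels1 == k)
            d, _ = mcp.find_costs(starts)
            dists.append(d)
        if n1 == 0:
            propagated = np.zeros_like(labels1)
        else:
            stack = np.stack(dists)
            propagated = np.where(
                self.region2, np.argmin(stack, axis=0) + 1, 0
            ).astype(np.int32)
        self._labels = (labels1.astype(np.int32), propagated)
        return self._labels


def _upwind_grad_norm(phi: np.ndarray, h: float) -> np.ndarray:
    """Godunov upwind |grad phi| for a front moving in -phi direction (F >= 0)."""
    pad = np.pad(phi, 1, mode="edge")
    dmx = (phi - pad[1:-1, :-2]) / h
    dpx = (pad[1:-1, 2:] - phi) / h
    dmy = (phi - pad[:-2, 1:-1]) / h
    dpy = (pad[2:, 1:-1] - phi) / h
    return np.sqrt(
        np.maximum(dmx, 0.0) ** 2
        + np.minimum(dpx, 0.0) ** 2
        + np.maximum(dmy, 0.0) ** 2
        + np.minimum(dpy, 0.0) ** 2
    )


def _curvature(phi: np.ndarray, h: float) -> np.ndarray:
    """Signed curvature div(grad phi/|grad phi|), central differences.

    With phi negative inside the lesion, a convex lesion boundary (a circle)
    has positive curvature.  Clipped to +-1/h (the grid's resolvable limit).
    """
    pad = np.pad(phi, 1, mode="edge")
    px = (pad[1:-1, 2:] - pad[1:-1, :-2]) / (2 * h)
    py = (pad[2:, 1:-1] - pad[:-2, 1:-1]) / (2 * h)
    pxx = (pad[1:-1, 2:] - 2 * phi + pad[1:-1, :-2]) / h**2
    pyy = (pad[2:, 1:-1] - 2 * phi + pad[:-2, 1:-1]) / h**2
    pxy = (pad[2:, 2:] - pad[2:, :-2] - pad[:-2, 2:] + pad[:-2, :-2]) / (4 * h**2)
    g2 = px**2 + py**2
    denom = np.maximum(g2, 1e-12) ** 1.5
    kappa = (pxx * py**2 - 2 * px * py * pxy + pyy * px**2) / denom
    return np.clip(kappa, -1.0 / h, 1.0 / h)


def _sussman_reinit(phi: np.ndarray, h: float, sweeps: int) -> np.ndarray:
    """A few sweeps of PDE-based signed-distance reinitialization."""
    phi0 = phi.copy()
    s = phi0 / np.sqrt(phi0**2 + h**2)
    dtau = 0.5 * h
    for _ in range(sweeps):
        pad = np.pad(phi, 1, mode="edge")
        a = (phi - pad[1:-1, :-2]) / h  # backward x
        b = (pad[1:-1, 2:] - phi) / h  # forward x
        c = (phi - pad[:-2, 1:-1]) / h  # backward y
        d = (pad[2:, 1:-1] - phi) / h  # forward y
        g_pos = np.sqrt(
            np.maximum(np.maximum(a, 0.0) ** 2, np.minimum(b, 0.0) ** 2)
            + np.maximum(np.maximum(c, 0.0) ** 2, np.minimum(d, 0.0) ** 2)
        )
        g_neg = np.sqrt(
            np.maximum(np.minimum(a, 0.0) ** 2, np.maximum(b, 0.0) ** 2)
            + np.maximum(np.minimum(c, 0.0) ** 2, np.maximum(d, 0.0) ** 2)
        )
        G = np.where(phi0 > 0, g_pos - 1.0, np.where(phi0 < 0, g_neg - 1.0, 0.0))
        phi = phi - dtau * s * G
    return phi


def _supersample_region(mask: LesionMask, origin, shape, h: float) -> np.ndarray:
    """Binary region on the working grid: smoothed mask field >= 0.5.

    Uses the same Gaussian-regularized field as the margin extraction, so the
    supersampled region boundary and the sub-pixel contours coincide.
    """
    nr, nc = shape
    xs = origin[0] + (np.arange(nc) + 0.5) * h
    ys = origin[1] + (np.arange(nr) + 0.5) * h
    gx, gy = np.meshgrid(xs, ys)
    vals = mask.interp_field(np.column_stack([gx.ravel(), gy.ravel()]))
    return (vals.reshape(nr, nc) >= 0.5)


def compute_arrival_time(
    mask1: LesionMask,
    mask2: LesionMask,
    params: GrowthParams | None = None,
) -> ArrivalTimeField:
    """Evolve the visit-1 margin to the visit-2 margin; record arrival times.

    ``Omega_1 \\subseteq Omega_2`` is enforced by unioning the visit-1 region
    into the visit-2 region (with a warning if that changes anything).  The
    time axis is normalized so that a flat front moves at unit speed (mm of
    travel per time unit); only its ordering matters downstream.
    """
    params = params or GrowthParams()
    if mask1.pixels.shape != mask2.pixels.shape:
        raise ValueError("visit masks must share a raster shape")
    if not mask2.pixels.any() and not mask1.pixels.any():
        raise ValueError("both masks are empty")
    union = mask2.pixels | mask1.pixels
    if union.sum() != mask2.pixels.sum():
        warnings.warn(
            "visit-2 region did not contain visit-1 region; using their union",
            stacklevel=2,
        )
    mask2u = LesionMask(
        pixels=union,
        pixel_pitch_um=mask2.pixel_pitch_um,
        laterality=mask2.laterality,
        eye_id=mask2.eye_id,
        visit_id=mask2.visit_id,
        origin_mm=mask2.origin_mm,
    )

    h = params.grid_pitch_mm
    # working grid over the padded bounding box of the visit-2 region
    rows, cols = np.nonzero(mask2u.pixels)
    pitch = mask1.pitch_mm
    pad = 6 * h
    x_lo = mask1.origin_mm[0] + max(cols.min() * pitch - pad, 0.0)
    x_hi = mask1.origin_mm[0] + min((cols.max() + 1) * pitch + pad, mask1.extent_mm[0])
    y_lo = mask1.origin_mm[1] + max(rows.min() * pitch - pad, 0.0)
    y_hi = mask1.origin_mm[1] + min((rows.max() + 1) * pitch + pad, mask1.extent_mm[1])
    nc = int(np.ceil((x_hi - x_lo) / h))
    nr = int(np.ceil((y_hi - y_lo) / h))
    origin = (x_lo, y_lo)
    shape = (nr, nc)

    region1 = _supersample_region(mask1, origin, shape, h) if mask1.pixels.any() else np.zeros(shape, bool)
    region2 = _supersample_region(mask2u, origin, shape, h)
    region2 |= region1

    xs = origin[0] + (np.arange(nc) + 0.5) * h
    ys = origin[1] + (np.arange(nr) + 0.5) * h
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])

    # initial signed distance to the sub-pixel visit-1 margin
    contours1 = extract_margins(mask1)
    m1 = _densify_contours(contours1, 0.5 * h)
    if len(m1):
        d1 = cKDTree(m1).query(centers)[0].reshape(shape)
    else:
        d1 = np.full(shape, np.inf)
    phi = np.where(region1, -d1, d1)

    # signed distance to the visit-2 margin (for tracing and hit tests)
    contours2 = extract_margins(mask2u)
    m2 = _densify_contours(contours2, 0.5 * h)
    d2 = cKDTree(m2).query(centers)[0].reshape(shape)
    phi2 = np.where(region2, -d2, d2)

    T = np.full(shape, np.inf)
    T[region1] = 0.0
    arrived = region1.copy()
    growth = region2 & ~region1

    t = 0.0
    n_steps = 0
    stall = 0
    prev_uncovered = int((growth & ~arrived).sum())
    phi0_signed = phi.copy()
    if prev_uncovered > 0 and len(m1):
        for step in range(params.max_steps):
            kappa = _curvature(phi, h)
            F = np.clip(1.0 - params.beta_mm * kappa, 0.0, None)
            F[~region2] = 0.0
            fmax = F.max()
            if fmax <= 0:
                break
            dt = params.cfl * h / fmax
            gnorm = _upwind_grad_norm(phi, h)
            phi_new = phi - dt * F * gnorm
            newly = (~arrived) & (phi_new <= 0) & region2
            if newly.any():
                denom = phi - phi_new
                with np.errstate(divide="ignore", invalid="ignore"):
                    frac = np.where(denom > 0, phi / denom, 1.0)
                frac = np.clip(frac, 0.0, 1.0)
                T[newly] = t + dt * frac[newly]
                arrived |= newly
            t += dt
            phi = phi_new
            n_steps = step + 1
            uncovered = int((growth & ~arrived).sum())
            if uncovered == 0:
                break
            stall = stall + 1 if uncovered == prev_uncovered else 0
            prev_uncovered = uncovered
            if stall >= params.stall_window:
                break
            if params.reinit_interval and (step + 1) % params.reinit_interval == 0:
                phi = _sussman_reinit(phi, h, params.reinit_sweeps)

    T_signed = np.where(region1, np.minimum(phi0_signed, 0.0), T)
    return ArrivalTimeField(
        T=T,
        T_signed=T_signed,
        region1=region1,
        region2=region2,
        phi2=phi2,
        h_mm=h,
        origin_mm=origin,
        margin2_samples=m2,
        n_steps=n_steps,
        t_final=t,
        n_unreached=int((growth & ~arrived).sum()),
    )
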