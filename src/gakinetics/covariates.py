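"""Fovea-centred spatial covariates: eccentricity r, margin angle theta, growth angle psi.

All angles are measured in a fovea-centred frame whose +x axis points nasal
and +y axis points superior.  To pool right (OD) and left (OS) eyes, left-eye
geometry is reflected about the inferior-superior (vertical) axis through the
fovea before any angle is computed; positions *and* direction vectors are
reflected, so downstream code is laterality-blind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FoveaFrame",
    "margin_eccentricity",
    "margin_angle",
    "growth_angle",
]


@dataclass
class FoveaFrame:
    """Fovea position plus laterality; OS geometry is mirrored on entry."""

    fovea_mm: np.ndarray
    laterality: str = "OD"

    def __post_init__(self) -> None:
        self.fovea_mm = np.asarray(self.fovea_mm, dtype=float)
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")

    def normalize_points(self, points_mm: np.ndarray) -> np.ndarray:
        """Map raster-frame points into the laterality-normalized frame."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float)).copy()
        if self.laterality == "OS":
            pts[:, 0] = 2.0 * self.fovea_mm[0] - pts[:, 0]
        return pts

    def normalize_vectors(self, vectors_mm: np.ndarray) -> np.ndarray:
        vec = np.atleast_2d(np.asarray(vectors_mm, dtype=float)).copy()
        if self.laterality == "OS":
            vec[:, 0] *= -1.0
        return vec

    def position_vectors(self, points_mm: np.ndarray) -> np.ndarray:
        """s(p) = normalized point minus fovea."""
        return self.normalize_points(points_mm) - self.fovea_mm


def margin_eccentricity(points_mm: np.ndarray, frame: FoveaFrame) -> np.ndarray:
    """r = |p - fovea| in mm (laterality-invariant)."""
    s = frame.position_vectors(points_mm)
    return np.hypot(s[:, 0], s[:, 1])


def margin_angle(points_mm: np.ndarray, frame: FoveaFrame) -> np.ndarray:
    """Counterclockwise angle of the position vector, degrees in [0, 360).

    0/90/180/270 degrees = nasal/superior/temporal/inferior.  Undefined (NaN)
    where the point coincides with the foveal centre.
    """
    s = frame.position_vectors(points_mm)
    r = np.hypot(s[:, 0], s[:, 1])
    theta = np.degrees(np.arctan2(s[:, 1], s[:, 0])) % 360.0
    theta[theta == 360.0] = 0.0
    return np.where(r > 0, theta, np.nan)


def growth_angle(
    growth_vectors_mm: np.ndarray, position_vectors_mm: np.ndarray
) -> np.ndarray:
    """psi = arccos of the normalized dot product of L(p) and s(p), degrees.

    0 deg is growth directly away from the foveal centre, 180 deg directly
    toward it.  Invariant to rescaling of either vector (so the epsilon
    convention at zero-growth points is harmless).  NaN where the position
    vector vanishes (angle undefined at the foveal centre).
    """
    L = np.atleast_2d(np.asarray(growth_vectors_mm, dtype=float))
    s = np.atleast_2d(np.asarray(position_vectors_mm, dtype=float))
    nL = np.hypot(L[:, 0], L[:, 1])
    ns = np.hypot(s[:, 0], s[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", L, s) / (nL * ns)
    cosang = np.clip(cosang, -1.0, 1.0)
    psi = np.degrees(np.arccos(cosang))
    psi = np.where((nL > 0) & (ns > 0), psi, np.nan)
    return psi
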