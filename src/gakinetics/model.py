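"""The growth model: per-eye estimation of local GA growth kinetics.

:class:`GrowthModel` bundles a registered pair of lesion masks with the fovea
position, laterality and intervisit time; :meth:`GrowthModel.fit` runs the
full per-eye pipeline -- margin extraction and 6-um resampling, arrival-time
front propagation, trajectory tracing, merge exclusion, growth vectors and
rates, and fovea-centred covariates -- and returns a
:class:`GrowthModelResults` holding one record per modeled margin point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrival import ArrivalTimeField, compute_arrival_time
from .covariates import FoveaFrame, growth_angle, margin_angle, margin_eccentricity
from .lesion import (
    GlobalRates,
    LesionMask,
    MarginPointSet,
    extract_margins,
    global_growth_rates,
    lesion_area_mm2,
    resample_margin,
)
from .params import GrowthParams
from .trajectories import (
    GrowthTrajectory,
    flag_merging_points,
    growth_vector,
    local_growth_rate,
    trace_trajectories,
)

__all__ = ["GrowthModel", "GrowthModelResults", "run_growth_model"]

RECORD_COLUMNS = [
    "eye_id",
    "point_index",
    "x_mm",
    "y_mm",
    "v_mm_per_yr",
    "r_mm",
    "theta_deg",
    "psi_deg",
    "merge_excluded",
    "reached_margin",
    "component_id",
    "is_epsilon",
    "arclength_mm",
]


class GrowthModel:
    """Curvature-modulated expanding-front model of GA lesion growth.

    Parameters
    ----------
    mask1, mask2
        Co-registered binary lesion masks at the two visits (visit 1 is the
        reference frame).
    fovea_mm
        Foveal-centre position in the visit-1 frame (e.g. the FAZ centroid).
    dt_years
        Intervisit time in years.
    laterality
        'OD' or 'OS'; left-eye geometry is mirrored about the vertical axis
        through the fovea before angles are computed.  Defaults to the
        visit-1 mask's laterality.
    params
        :class:`~gakinetics.params.GrowthParams`; defaults are the study
        conventions (6-um margin sampling, 6-um working grid, beta = 24 um).
    """

    def __init__(
        self,
        mask1: LesionMask,
        mask2: LesionMask,
        fovea_mm,
        dt_years: float,
        laterality: str | None = None,
        params: GrowthParams | None = None,
    ) -> None:
        if dt_years <= 0:
            raise ValueError("intervisit time must be positive")
        self.mask1 = mask1
        self.mask2 = mask2
        self.fovea_mm = np.asarray(fovea_mm, dtype=float)
        self.dt_years = float(dt_years)
        self.laterality = laterality or mask1.laterality
        self.params = params or GrowthParams()
        self.frame = FoveaFrame(self.fovea_mm, self.laterality)

    @classmethod
    def from_files(
        cls,
        path1,
        path2,
        pixel_pitch_um: float,
        fovea_mm,
        dt_years: float,
        laterality: str = "OD",
        eye_id: str = "eye",
        params: GrowthParams | None = None,
    ) -> "GrowthModel":
        from .lesion import load_lesion_mask

        m1 = load_lesion_mask(path1, pixel_pitch_um, laterality, eye_id, "v1")
        m2 = load_lesion_mask(path2, pixel_pitch_um, laterality, eye_id, "v2")
        return cls(m1, m2, fovea_mm, dt_years, laterality, params)

    def fit(self) -> "GrowthModelResults":
        """Run the full per-eye growth pipeline."""
        p = self.params
        contours1 = extract_margins(self.mask1)
        closed = [c for c in contours1 if c.closed]
        margin = MarginPointSet.concatenate(
            [resample_margin(c, self.mask1, p.spacing_um) for c in closed]
        )
        field_ = compute_arrival_time(self.mask1, self.mask2, p)
        trajs = trace_trajectories(field_, margin.points, p) if len(margin) else []
        flags = flag_merging_points(field_, trajs)
        vectors = [
            growth_vector(t, n, p.epsilon_um)
            for t, n in zip(trajs, margin.normals)
        ]
        v = np.array([local_growth_rate(t, self.dt_years) for t in trajs])
        svec = self.frame.position_vectors(margin.points)
        Lvec = self.frame.normalize_vectors(
            np.array([g.vector_mm for g in vectors]) if vectors else np.empty((0, 2))
        )
        r = margin_eccentricity(margin.points, self.frame)
        theta = margin_angle(margin.points, self.frame)
        psi = growth_angle(Lvec, svec)
        records = pd.DataFrame(
            {
                "eye_id": self.mask1.eye_id,
                "point_index": np.arange(len(margin)),
                "x_mm": margin.points[:, 0],
                "y_mm": margin.points[:, 1],
                "v_mm_per_yr": v,
                "r_mm": r,
                "theta_deg": theta,
                "psi_deg": psi,
                "merge_excluded": flags,
                "reached_margin": np.array([t.reached_margin for t in trajs], bool),
                "component_id": margin.component_id,
                "is_epsilon": np.array([g.is_epsilon for g in vectors], bool),
                "arclength_mm": np.array([t.arclength_mm for t in trajs]),
            },
            columns=RECORD_COLUMNS,
        )
        contours2 = extract_margins(self.mask2)
        rates = global_growth_rates(
            lesion_area_mm2(contours1), lesion_area_mm2(contours2), self.dt_years
        )
        return GrowthModelResults(
            model=self,
            records=records,
            trajectories=trajs,
            field=field_,
            margin=margin,
            global_rates=rates,
        )


@dataclass
class GrowthModelResults:
    """Per-eye growth-model fit: margin-point records plus diagnostics."""

    model: GrowthModel
    records: pd.DataFrame
    trajectories: list[GrowthTrajectory]
    field: ArrivalTimeField
    margin: MarginPointSet
    global_rates: GlobalRates

    @property
    def n_modeled(self) -> int:
        return len(self.records)

    @property
    def n_excluded(self) -> int:
        return int(self.records["merge_excluded"].sum())

    @property
    def n_analyzed(self) -> int:
        return self.n_modeled - self.n_excluded

    @property
    def analyzed(self) -> pd.DataFrame:
        """Records surviving merge exclusion (the analysis set)."""
        return self.records[~self.records["merge_excluded"]]

    def summary(self) -> str:
        rec = self.analyzed
        g = self.global_rates
        lines = [
            "Growth model results",
            "=" * 56,
            f"eye_id                : {self.model.mask1.eye_id} ({self.model.laterality})",
            f"intervisit time       : {self.model.dt_years:.3f} yr",
            f"margin points modeled : {self.n_modeled}",
            f"  analyzed / excluded : {self.n_analyzed} / {self.n_excluded}"
            f" ({100.0 * self.n_excluded / max(self.n_modeled, 1):.1f}% excluded)",
            f"area growth rate      : {g.area_rate:+.4f} mm^2/yr",
            f"sqrt-area growth rate : {g.sqrt_area_rate:+.4f} mm/yr",
            f"eff. radius rate      : {g.eff_radius_rate:+.4f} mm/yr",
        ]
        if len(rec):
            lines += [
                f"local rate v (mm/yr)  : mean {rec.v_mm_per_yr.mean():.4f}, "
                f"median {rec.v_mm_per_yr.median():.4f}, "
                f"max {rec.v_mm_per_yr.max():.4f}",
                f"eccentricity r (mm)   : {rec.r_mm.min():.3f} .. {rec.r_mm.max():.3f}",
            ]
        return "\n".join(lines)

    def trajectories_frame(self) -> pd.DataFrame:
        """Long-format trajectory vertices for export or plotting."""
        rows = []
        for i, t in enumerate(self.trajectories):
            for j, (x, y) in enumerate(t.vertices):
                rows.append((self.model.mask1.eye_id, i, j, x, y))
        return pd.DataFrame(
            rows, columns=["eye_id", "point_index", "vertex_index", "x_mm", "y_mm"]
        )

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def plot_trajectories(self, ax=None, max_trajectories: int | None = None):
        """Overlay margins and growth trajectories, colored by arclength."""
        import matplotlib.pyplot as plt
        from matplotlib.collections import LineCollection

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        for m, color in ((self.model.mask1, "0.3"), (self.model.mask2, "0.7")):
            for c in extract_margins(m):
                v = np.vstack([c.vertices, c.vertices[:1]])
                ax.plot(v[:, 0], v[:, 1], color=color, lw=1.0)
        trajs = self.trajectories[:max_trajectories]
        segs = [t.vertices for t in trajs if len(t.vertices) > 1]
        lens = [t.arclength_mm for t in trajs if len(t.vertices) > 1]
        if segs:
            lc = LineCollection(segs, array=np.array(lens), cmap="viridis", lw=0.8)
            ax.add_collection(lc)
            plt.colorbar(lc, ax=ax, label="trajectory arclength (mm)")
        ax.set_aspect("equal")
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        return ax


def run_growth_model(
    mask1: LesionMask,
    mask2: LesionMask,
    fovea_mm,
    dt_years: float,
    laterality: str | None = None,
    params: GrowthParams | None = None,
) -> GrowthModelResults:
    """Functional wrapper: build a :class:`GrowthModel` and fit it."""
    return GrowthModel(mask1, mask2, fovea_mm, dt_years, laterality, params).fit()
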