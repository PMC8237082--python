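"""Cohort orchestration: eligibility, per-eye growth modeling, pooled statistics.

A study run takes a manifest of eyes (mask pair, fovea/FAZ trace, laterality,
visit dates or intervisit time), checks the data-level eligibility criteria,
fits the growth model per eye, pools the margin-point records across eyes
with equal point weighting, and computes the conditional-rate estimates,
fundus growth map, rate-distribution summary, support counts, global rates,
and a merge-bias report.  Per-eye failures are logged and skipped; they never
abort the cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import FoveaFrame
from .kinetics import (
    boxplot_stats,
    nw_mean_1d,
    nw_mean_2d,
    rate_distribution_summary,
    weighted_counts,
)
from .lesion import (
    LesionMask,
    classify_foveal_involvement,
    extract_margins,
    faz_centroid,
    lesion_area_mm2,
    load_lesion_mask,
)
from .model import GrowthModel, GrowthModelResults
from .params import GrowthParams
from .register import apply_warp, fit_polynomial_warp

__all__ = ["StudyConfig", "check_eligibility", "run_study", "StudyResults"]

# data-level eligibility thresholds
MIN_TOTAL_AREA_MM2 = 2.54  # one disc area
MIN_FOCUS_AREA_MM2 = 1.25  # largest focus, multifocal lesions


@dataclass
class EyeSpec:
    """One eye's inputs, already loaded into memory."""

    mask1: LesionMask
    mask2: LesionMask
    fovea_mm: np.ndarray
    dt_years: float
    eye_id: str
    laterality: str = "OD"


@dataclass
class StudyConfig:
    """Cohort configuration: eyes plus all model/statistics parameters."""

    eyes: list[EyeSpec]
    params: GrowthParams = field(default_factory=GrowthParams)
    sigma_ecc_um: float = 125.0
    sigma_angle_deg: float = 10.0
    sigma_map_um: float = 125.0
    map_min_points: int = 250
    map_support_radius_um: float = 250.0
    map_step_um: float = 25.0
    ecc_grid_max_mm: float = 3.5
    ecc_grid_step_um: float = 25.0
    angle_grid_step_deg: float = 1.0
    hist_bin_width: float = 0.005
    enforce_eligibility: bool = True
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_manifest(cls, path) -> "StudyConfig":
        """Build a config from a YAML/JSON manifest of file paths.

        Expected per-eye keys: mask1, mask2, pixel_pitch_um, laterality,
        eye_id, and either faz_csv (x_mm,y_mm vertices) or fovea_mm, plus
        either dt_years or visit dates (ISO, days / 365.25), and optional
        control_points_csv (src_x_mm, src_y_mm, dst_x_mm, dst_y_mm) warping
        visit-2 into the visit-1 frame.
        """
        path = Path(path)
        with open(path) as f:
            doc = yaml.safe_load(f)
        base = path.parent
        eyes = []
        for entry in doc["eyes"]:
            pitch = float(entry.get("pixel_pitch_um", 12.0))
            lat = entry.get("laterality", "OD")
            eid = entry.get("eye_id", Path(entry["mask1"]).stem)
            m1 = load_lesion_mask(base / entry["mask1"], pitch, lat, eid, "v1")
            m2 = load_lesion_mask(base / entry["mask2"], pitch, lat, eid, "v2")
            if "control_points_csv" in entry:
                cp = pd.read_csv(base / entry["control_points_csv"])
                fwd = fit_polynomial_warp(
                    cp[["src_x_mm", "src_y_mm"]].to_numpy(),
                    cp[["dst_x_mm", "dst_y_mm"]].to_numpy(),
                )
                inv = fit_polynomial_warp(
                    cp[["dst_x_mm", "dst_y_mm"]].to_numpy(),
                    cp[["src_x_mm", "src_y_mm"]].to_numpy(),
                )
                m2 = apply_warp(fwd, m2, inverse_warp=inv)
            if "faz_csv" in entry:
                faz = pd.read_csv(base / entry["faz_csv"])
                fovea = faz_centroid(faz[["x_mm", "y_mm"]].to_numpy())
            else:
                fovea = np.asarray(entry["fovea_mm"], dtype=float)
            if "dt_years" in entry:
                dt = float(entry["dt_years"])
            else:
                d1 = pd.Timestamp(entry["visit1_date"])
                d2 = pd.Timestamp(entry["visit2_date"])
                dt = (d2 - d1).days / 365.25
            eyes.append(EyeSpec(m1, m2, fovea, dt, eid, lat))
        opts = {k: v for k, v in doc.items() if k != "eyes"}
        params = GrowthParams(**opts.pop("params", {}))
        return cls(eyes=eyes, params=params, **opts)


def check_eligibility(
    mask1: LesionMask, mask2: LesionMask
) -> dict:
    """Apply the three data-level eligibility criteria.

    (1) total lesion area at baseline >= 2.54 mm^2 (one disc area);
    (2) for multifocal lesions, the largest focus exceeds 1.25 mm^2;
    (3) the lesion is fully contained in the field of view at both visits
    (no foreground pixel on the raster border).
    """
    reasons = []
    contours = extract_margins(mask1)
    total = lesion_area_mm2(contours)
    if total < MIN_TOTAL_AREA_MM2:
        reasons.append(
            f"total baseline area {total:.2f} mm^2 < {MIN_TOTAL_AREA_MM2} mm^2"
        )
    outer = [c for c in contours if not c.is_hole]
    if len(outer) > 1 and max(c.area_mm2 for c in outer) <= MIN_FOCUS_AREA_MM2:
        reasons.append(
            f"largest focus <= {MIN_FOCUS_AREA_MM2} mm^2 in a multifocal lesion"
        )
    if mask1.touches_border() or mask2.touches_border():
        reasons.append("lesion not fully contained in the field of view")
    return {"eligible": not reasons, "reasons": reasons}


@dataclass
class StudyResults:
    """Pooled cohort outputs."""

    records: pd.DataFrame  # all modeled points, all eyes
    per_eye: list[GrowthModelResults]
    global_rates: pd.DataFrame
    ecc_estimate: object
    margin_angle_estimate: object
    growth_angle_estimate: object
    fundus_map: object
    distribution: object
    merge_report: pd.DataFrame
    eligibility: pd.DataFrame
    failures: list[tuple[str, str]]
    config: StudyConfig

    @property
    def analyzed(self) -> pd.DataFrame:
        return self.records[~self.records["merge_excluded"]]

    @property
    def n_modeled(self) -> int:
        return len(self.records)

    @property
    def n_excluded(self) -> int:
        return int(self.records["merge_excluded"].sum())

    @property
    def n_analyzed(self) -> int:
        return self.n_modeled - self.n_excluded

    def summary(self) -> str:
        rec = self.analyzed
        lines = [
            "Study results",
            "=" * 56,
            f"eyes fitted            : {len(self.per_eye)}"
            + (f" ({len(self.failures)} failed)" if self.failures else ""),
            f"margin points modeled  : {self.n_modeled}",
            f"  analyzed / excluded  : {self.n_analyzed} / {self.n_excluded}"
            f" ({100.0 * self.n_excluded / max(self.n_modeled, 1):.1f}% excluded)",
        ]
        if len(rec):
            bs = boxplot_stats(rec["v_mm_per_yr"].to_numpy())
            lines += [
                f"local rate v (mm/yr)   : mean {rec.v_mm_per_yr.mean():.4f},"
                f" median {bs.median:.4f}, IQR [{bs.q1:.4f}, {bs.q3:.4f}]",
                f"exponential rate fit   : lambda = {self.distribution.exponential_rate:.3f} /(mm/yr)",
            ]
        return "\n".join(lines)

    def write(self, outdir) -> None:
        """Write all tables plus a machine-readable run log."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        self.global_rates.to_csv(out / "global_rates.csv", index=False)
        self.ecc_estimate.to_frame().to_csv(out / "rate_vs_eccentricity.csv", index=False)
        self.margin_angle_estimate.to_frame().to_csv(
            out / "rate_vs_margin_angle.csv", index=False
        )
        self.growth_angle_estimate.to_frame().to_csv(
            out / "rate_vs_growth_angle.csv", index=False
        )
        self.fundus_map.to_frame().to_csv(out / "fundus_growth_map.csv", index=False)
        self.merge_report.to_csv(out / "merge_report.csv", index=False)
        self.eligibility.to_csv(out / "eligibility.csv", index=False)
        pct = self.distribution.percentiles
        log = {
            "version": __version__,
            "seed": self.config.seed,
            "params": self.config.params.to_dict(),
            "n_eyes": len(self.per_eye),
            "n_failures": len(self.failures),
            "failures": self.failures,
            "n_modeled": self.n_modeled,
            "n_analyzed": self.n_analyzed,
            "n_excluded": self.n_excluded,
            "rate_percentiles_mm_per_yr": {str(k): v for k, v in pct.items()},
            "exponential_rate": self.distribution.exponential_rate,
        }
        with open(out / "run_log.json", "w") as f:
            json.dump(log, f, indent=2)


def _merge_bias_report(records: pd.DataFrame) -> pd.DataFrame:
    """Merge-excluded fraction stratified by eccentricity and growth-angle band."""
    rec = records.copy()
    rec["ecc_band"] = pd.cut(
        rec["r_mm"], bins=[0, 0.5, 1.0, 1.5, 2.0, 2.5, np.inf], right=False
    ).astype(str)
    rows = []
    for band, grp in rec.groupby("ecc_band", observed=True):
        rows.append(("eccentricity", band, len(grp), float(grp["merge_excluded"].mean())))
    ok = rec[np.isfinite(rec["psi_deg"])]
    ok = ok.copy()
    ok["psi_band"] = pd.cut(ok["psi_deg"], bins=[0, 45, 90, 135, 180.0001], right=False).astype(str)
    for band, grp in ok.groupby("psi_band", observed=True):
        rows.append(("growth_angle", band, len(grp), float(grp["merge_excluded"].mean())))
    return pd.DataFrame(
        rows, columns=["covariate", "band", "n_points", "excluded_fraction"]
    )


def run_study(config: StudyConfig) -> StudyResults:
    """Run the cohort end-to-end and pool statistics over all analyzed points.

    Deterministic given the config; margin points are pooled across eyes with
    equal weighting.  Raises only when no eligible eye can be fitted.
    """
    per_eye: list[GrowthModelResults] = []
    failures: list[tuple[str, str]] = []
    elig_rows = []
    grates = []
    for eye in config.eyes:
        elig = check_eligibility(eye.mask1, eye.mask2)
        inv = classify_foveal_involvement(eye.mask1, eye.fovea_mm)
        elig_rows.append(
            {
                "eye_id": eye.eye_id,
                "eligible": elig["eligible"],
                "reasons": "; ".join(elig["reasons"]),
                "center_involved": inv["center_involved"],
                "zone_involved": inv["zone_involved"],
            }
        )
        if config.enforce_eligibility and not elig["eligible"]:
            continue
        try:
            res = GrowthModel(
                eye.mask1,
                eye.mask2,
                eye.fovea_mm,
                eye.dt_years,
                eye.laterality,
                config.params,
            ).fit()
        except Exception as exc:  # logged and skipped, never aborts the cohort
            failures.append((eye.eye_id, repr(exc)))
            continue
        per_eye.append(res)
        g = res.global_rates
        grates.append(
            {
                "eye_id": eye.eye_id,
                "area_rate_mm2_per_yr": g.area_rate,
                "sqrt_area_rate_mm_per_yr": g.sqrt_area_rate,
                "eff_radius_rate_mm_per_yr": g.eff_radius_rate,
            }
        )
    if not per_eye:
        raise ValueError("no eligible eye could be fitted")
    records = pd.concat([r.records for r in per_eye], ignore_index=True)
    analyzed = records[~records["merge_excluded"]]
    ok_angles = analyzed[np.isfinite(analyzed["theta_deg"])]

    ecc_grid = np.arange(
        0.0, config.ecc_grid_max_mm + 1e-9, config.ecc_grid_step_um / 1000.0
    )
    ecc_est = nw_mean_1d(
        analyzed["r_mm"].to_numpy(),
        analyzed["v_mm_per_yr"].to_numpy(),
        ecc_grid,
        config.sigma_ecc_um / 1000.0,
        "linear",
    )
    ecc_est.weighted_point_count, ecc_est.weighted_eye_count = weighted_counts(
        analyzed["r_mm"].to_numpy(),
        analyzed["eye_id"].to_numpy(),
        ecc_grid,
        config.sigma_ecc_um / 1000.0,
        "linear",
    )
    th_grid = np.arange(0.0, 360.0, config.angle_grid_step_deg)
    th_est = nw_mean_1d(
        ok_angles["theta_deg"].to_numpy(),
        ok_angles["v_mm_per_yr"].to_numpy(),
        th_grid,
        config.sigma_angle_deg,
        "circular",
    )
    th_est.weighted_point_count, th_est.weighted_eye_count = weighted_counts(
        ok_angles["theta_deg"].to_numpy(),
        ok_angles["eye_id"].to_numpy(),
        th_grid,
        config.sigma_angle_deg,
        "circular",
    )
    psi_grid = np.arange(0.0, 180.0 + 1e-9, config.angle_grid_step_deg)
    ok_psi = analyzed[np.isfinite(analyzed["psi_deg"])]
    psi_est = nw_mean_1d(
        ok_psi["psi_deg"].to_numpy(),
        ok_psi["v_mm_per_yr"].to_numpy(),
        psi_grid,
        config.sigma_angle_deg,
        "linear",
    )
    psi_est.weighted_point_count, psi_est.weighted_eye_count = weighted_counts(
        ok_psi["psi_deg"].to_numpy(),
        ok_psi["eye_id"].to_numpy(),
        psi_grid,
        config.sigma_angle_deg,
        "linear",
    )

    # fundus map in the fovea-centred, laterality-normalized frame
    frames = {
        r.model.mask1.eye_id: FoveaFrame(r.model.fovea_mm, r.model.laterality)
        for r in per_eye
    }
    pts = []
    for r in per_eye:
        rec = r.analyzed
        frame = frames[r.model.mask1.eye_id]
        pts.append(frame.position_vectors(rec[["x_mm", "y_mm"]].to_numpy()))
    pts = np.vstack(pts) if pts else np.empty((0, 2))
    half = 3.0
    map_step = config.map_step_um / 1000.0
    map_grid = np.arange(-half, half + 1e-9, map_step)
    fmap = nw_mean_2d(
        pts,
        analyzed["v_mm_per_yr"].to_numpy(),
        map_grid,
        map_grid,
        sigma_um=config.sigma_map_um,
        min_points=config.map_min_points,
        support_radius_um=config.map_support_radius_um,
    )

    dist = rate_distribution_summary(
        analyzed["v_mm_per_yr"].to_numpy(), config.hist_bin_width
    )
    results = StudyResults(
        records=records,
        per_eye=per_eye,
        global_rates=pd.DataFrame(grates),
        ecc_estimate=ecc_est,
        margin_angle_estimate=th_est,
        growth_angle_estimate=psi_est,
        fundus_map=fmap,
        distribution=dist,
        merge_report=_merge_bias_report(records),
        eligibility=pd.DataFrame(elig_rows),
        failures=failures,
        config=config,
    )
    if config.output_dir:
        results.write(config.output_dir)
    return results
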