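"""Tunable parameters of the growth model, with units and defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = ["GrowthParams"]


@dataclass
class GrowthParams:
    """Parameters of the expanding-front growth model and trajectory tracing.

    spacing_um
        Arclength spacing of margin points along the visit-1 margin (um).
    beta_um
        Curvature weight of the front speed F = max(0, 1 - beta * kappa):
        concave margin segments (kappa < 0) advance faster than convex ones.
    grid_pitch_um
        Working grid pitch (um); native masks are supersampled to this pitch.
    epsilon_um
        Length of the surrogate growth vector at zero-growth margin points
        (only its direction is used downstream).
    delta_um
        Margin-hit tolerance for trajectory tracing; defaults to one working
        grid pitch when None.
    cfl
        CFL number of the explicit level-set update.
    reinit_interval, reinit_sweeps
        Signed-distance reinitialization cadence and per-event sweep count.
    max_steps
        Hard cap on level-set time steps.
    g_min
        Gradient-magnitude floor (per grid pitch) below which a streamline is
        declared stalled (arrival-time ridge / shock).
    stall_window
        Stop the front evolution if no new grid cell is covered for this many
        consecutive steps (unreachable pockets).
    """

    spacing_um: float = 6.0
    beta_um: float = 24.0
    grid_pitch_um: float = 6.0
    epsilon_um: float = 1.0
    delta_um: float | None = None
    cfl: float = 0.4
    reinit_interval: int = 20
    reinit_sweeps: int = 5
    max_steps: int = 4000
    g_min: float = 1e-6
    stall_window: int = 50

    @property
    def delta_mm(self) -> float:
        d = self.grid_pitch_um if self.delta_um is None else self.delta_um
        return d / 1000.0

    @property
    def grid_pitch_mm(self) -> float:
        return self.grid_pitch_um / 1000.0

    @property
    def beta_mm(self) -> float:
        return self.beta_um / 1000.0

    def to_dict(self) -> dict:
        return asdict(self)
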