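"""Axial velocity decay in a leaky sieve tube.

In a tube of constant diameter and impermeable walls the flow velocity is
constant; where the walls leak (i.e. where unloading occurs) the axial
velocity falls because fluid leaves laterally.  The default leak law is a
uniform volumetric leak per unit length, giving a piecewise-linear velocity
profile: a plateau ``u0`` basipetal of ``zone_start``, a linear decline
across the unloading zone, and zero beyond its apical end.  The tube
terminates at PSE zero (x = 0), so with a zone ending there all remaining
flow has unloaded by x = 0.

Positions are measured in micrometres basipetally from PSE zero (x = 0 at
the terminal sieve element, increasing shootward).

``fit_unloading_zone`` recovers the plateau velocity and the zone
boundaries from measured velocity-vs-position series by profiled least
squares over the two breakpoints, with bootstrap confidence intervals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "VelocityProfile",
    "LeakyTubeParams",
    "UnloadingZoneFit",
    "predict_velocity",
    "axial_flow_fraction",
    "fit_unloading_zone",
]


@dataclass(frozen=True)
class VelocityProfile:
    """Measured or synthetic velocity-vs-position series.

    ``positions_um`` must be strictly increasing; ``velocities_um_s``
    non-negative.  ``velocity_sd_um_s`` is an optional per-point SD.
    """

    positions_um: np.ndarray
    velocities_um_s: np.ndarray
    velocity_sd_um_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_um, dtype=float)
        vel = np.asarray(self.velocities_um_s, dtype=float)
        object.__setattr__(self, "positions_um", pos)
        object.__setattr__(self, "velocities_um_s", vel)
        if pos.ndim != 1 or pos.shape != vel.shape:
            raise ValueError("positions and velocities must be 1-D and equal length")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions_um must be strictly increasing")
        if np.any(vel < 0):
            raise ValueError("velocities_um_s must be non-negative")
        if self.velocity_sd_um_s is not None:
            sd = np.asarray(self.velocity_sd_um_s, dtype=float)
            object.__setattr__(self, "velocity_sd_um_s", sd)
            if sd.shape != pos.shape or np.any(sd < 0):
                raise ValueError("velocity_sd_um_s must match positions and be >= 0")

    def __len__(self) -> int:
        return self.positions_um.size

    def to_csv(self, path=None) -> str:
        frame = pd.DataFrame(
            {"position_um": self.positions_um, "velocity_um_s": self.velocities_um_s}
        )
        if self.velocity_sd_um_s is not None:
            frame["sd"] = self.velocity_sd_um_s
        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        text = buf.getvalue()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_csv(cls, path) -> "VelocityProfile":
        frame = pd.read_csv(path)
        sd = frame["sd"].to_numpy() if "sd" in frame else None
        return cls(
            positions_um=frame["position_um"].to_numpy(),
            velocities_um_s=frame["velocity_um_s"].to_numpy(),
            velocity_sd_um_s=sd,
        )


@dataclass(frozen=True)
class LeakyTubeParams:
    """Parameters of the leaky-tube velocity model.

    ``u0_um_s`` is the plateau velocity in the translocation zone,
    ``zone_start_um`` the position where deceleration begins and
    ``zone_length_um`` the axial extent of the leaky stretch.  The zone must
    end at or before PSE zero (``zone_start >= zone_length``); with equality
    the velocity reaches zero exactly at PSE zero.  ``zone_length == 0`` is
    the impermeable-wall limit (constant velocity everywhere).
    """

    u0_um_s: float = 22.6
    zone_start_um: float = 350.0
    zone_length_um: float = 350.0

    def __post_init__(self) -> None:
        if not self.u0_um_s > 0:
            raise ValueError("u0_um_s must be strictly positive")
        if self.zone_length_um < 0:
            raise ValueError("zone_length_um must be non-negative")
        if self.zone_start_um < self.zone_length_um:
            raise ValueError(
                "zone_start_um must be >= zone_length_um (zone ends at or "
                "before PSE zero)"
            )

    @property
    def zone_end_um(self) -> float:
        """Apical end of the leaky zone (0 = PSE zero)."""
        return self.zone_start_um - self.zone_length_um


def _model_velocity(
    positions: np.ndarray, params: LeakyTubeParams, leak_law: str
) -> np.ndarray:
    x = np.asarray(positions, dtype=float)
    u0 = params.u0_um_s
    if params.zone_length_um == 0:
        return np.full_like(x, u0)
    if leak_law == "uniform":
        frac = (x - params.zone_end_um) / params.zone_length_um
        return u0 * np.clip(frac, 0.0, 1.0)
    if leak_law == "exponential":
        # pressure-proportional leakage: exponential decay with e-folding
        # length zone_length_um apically of zone_start
        decay = np.exp(-(params.zone_start_um - x) / params.zone_length_um)
        return u0 * np.where(x >= params.zone_start_um, 1.0, decay)
    raise ValueError(f"unknown leak law {leak_law!r}")


def predict_velocity(
    params: LeakyTubeParams,
    positions_um,
    leak_law: Literal["uniform", "exponential"] = "uniform",
) -> VelocityProfile:
    """Model velocity profile at the given (strictly increasing) positions."""
    x = np.asarray(positions_um, dtype=float)
    return VelocityProfile(x, _model_velocity(x, params, leak_law))


def axial_flow_fraction(params: LeakyTubeParams, positions_um) -> np.ndarray:
    """Fraction ``u(x)/u0`` of the axial volumetric flow remaining at x.

    Because the tube has constant cross-section, the cumulative lateral
    efflux between two positions is ``A (u(x2) - u(x1))`` — mass
    conservation ties the velocity drop to the leak, exactly, for any leak
    law of this model family.
    """
    x = np.asarray(positions_um, dtype=float)
    return _model_velocity(x, params, "uniform") / params.u0_um_s


@dataclass(frozen=True)
class UnloadingZoneFit:
    """Result of fitting the leaky-tube model to a velocity profile."""

    params: LeakyTubeParams
    sse: float
    degenerate: bool = False
    ci: dict = field(default_factory=dict)
    n_boot: int = 0


def _profiled_sse(
    x: np.ndarray, y: np.ndarray, zone_end: float, zone_start: float
) -> tuple[float, float]:
    """SSE minimised over u0 for fixed breakpoints; returns (sse, u0)."""
    if zone_start <= zone_end:
        return (np.inf, np.nan)
    phi = np.clip((x - zone_end) / (zone_start - zone_end), 0.0, 1.0)
    denom = float(phi @ phi)
    if denom == 0.0:
        return (np.inf, np.nan)
    u0 = float(phi @ y) / denom
    resid = y - u0 * phi
    return (float(resid @ resid), u0)


def _fit_breakpoints(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Best (zone_end, zone_start, u0, sse) by grid search + local polish."""
    xmax = float(x.max())
    cand_start = np.unique(np.concatenate([x[x > 0], [xmax]]))
    cand_end = np.unique(np.concatenate([[0.0], x[x < xmax]]))
    best = (np.inf, np.nan, np.nan, np.nan)  # sse, end, start, u0
    # increasing zone_start order; strict improvement => ties break toward
    # the smaller zone_start
    for zs in np.sort(cand_start):
        for ze in cand_end[cand_end < zs]:
            sse, u0 = _profiled_sse(x, y, ze, zs)
            if best[0] - sse > 1e-12 * (1.0 + sse):
                best = (sse, ze, zs, u0)
    sse0, ze0, zs0, _ = best

    def objective(theta: np.ndarray) -> float:
        ze, zs = theta
        if ze < 0 or zs <= ze or zs > xmax * 2:
            return np.inf
        return _profiled_sse(x, y, ze, zs)[0]

    res = minimize(
        objective,
        np.array([ze0, zs0]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-18, "maxiter": 2000},
    )
    if np.isfinite(res.fun) and res.fun <= sse0:
        ze, zs = res.x
        sse, u0 = _profiled_sse(x, y, ze, zs)
    else:
        sse, ze, zs, u0 = sse0, ze0, zs0, best[3]
    return float(ze), float(zs), float(u0), float(sse)


def fit_unloading_zone(
    profile: VelocityProfile,
    n_boot: int = 200,
    seed: int = 0,
    ci_level: float = 0.95,
) -> UnloadingZoneFit:
    """Fit the piecewise-linear leaky-tube model by profiled least squares.

    Requires at least 5 points.  The two breakpoints (apical zone end and
    ``zone_start``) are profiled over a grid of the data positions and
    refined by a local simplex search; for fixed breakpoints the plateau
    ``u0`` has a closed-form least-squares solution.  Ties break toward the
    smaller ``zone_start``.  A profile with no detectable decline returns
    the mean velocity with ``zone_length = 0`` and ``degenerate=True``.

    Confidence intervals are percentile bootstrap over residual resampling
    (``n_boot`` replicates, seeded; 0 disables).
    """
    x = profile.positions_um
    y = profile.velocities_um_s
    if len(profile) < 5:
        raise ValueError("fit_unloading_zone requires at least 5 points")

    spread = float(np.ptp(y))
    if spread <= 1e-12 * max(1.0, float(np.max(np.abs(y)))):
        u0 = float(np.mean(y))
        params = LeakyTubeParams(u0_um_s=max(u0, np.finfo(float).tiny),
                                 zone_start_um=float(np.max(x)), zone_length_um=0.0)
        return UnloadingZoneFit(params=params, sse=float(np.sum((y - u0) ** 2)),
                                degenerate=True)

    ze, zs, u0, sse = _fit_breakpoints(x, y)
    # constant fit no better than piecewise => genuine decline; otherwise flag
    const_sse = float(np.sum((y - np.mean(y)) ** 2))
    degenerate = not (sse < const_sse)
    if degenerate:
        u0 = float(np.mean(y))
        params = LeakyTubeParams(u0_um_s=u0, zone_start_um=float(np.max(x)),
                                 zone_length_um=0.0)
        return UnloadingZoneFit(params=params, sse=const_sse, degenerate=True)

    params = LeakyTubeParams(
        u0_um_s=u0, zone_start_um=zs, zone_length_um=zs - max(ze, 0.0)
    )

    ci: dict = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        fitted = u0 * np.clip((x - ze) / (zs - ze), 0.0, 1.0)
        resid = y - fitted
        draws = {"u0_um_s": [], "zone_start_um": [], "zone_length_um": []}
        for _ in range(n_boot):
            yb = np.clip(fitted + rng.choice(resid, size=resid.size, replace=True), 0.0, None)
            zeb, zsb, u0b, _ = _fit_breakpoints(x, yb)
            draws["u0_um_s"].append(u0b)
            draws["zone_start_um"].append(zsb)
            draws["zone_length_um"].append(zsb - max(zeb, 0.0))
        alpha = (1.0 - ci_level) / 2.0
        for key, vals in draws.items():
            lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
            ci[key] = (float(lo), float(hi))

    return UnloadingZoneFit(params=params, sse=sse, degenerate=False, ci=ci,
                            n_boot=n_boot)
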