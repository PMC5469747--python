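"""Synthetic inputs with known ground truth.

Three generators cover every input the pipeline consumes:

* :func:`simulate_dcrws` — a switching first-difference CRW path on a
  regular grid with its true behavioural state sequence;
* :func:`observe_argos` — irregular Argos-like fixes of a true path:
  Poisson observation times, location classes drawn from a frequency table,
  heavy-tailed Student-t position errors per class;
* :func:`simulate_scene` — co-registered chlorophyll-a (with a sigmoidal
  front, optionally drifting by day), bathymetry, land-mask and
  lane-structured vessel-traffic layers on a lon/lat grid.

Every generator is a pure function of its arguments and a seed. Defaults
describe the study conditions the rest of the package is tested under:
12-h steps, two well-separated behavioural regimes, ~3 fixes/day with a
realistic preponderance of the poor Argos classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .argos import LC_ORDER, ArgosFix
from .grids import GridSpec
from .ssm import DCRWSParams, DEFAULT_ERROR_TABLE, rotation

#: Movement regime used as the reference study condition in tests:
#: persistent, straight transit vs. strongly turning, diffusive ARS,
#: with sticky transit (α₁ = 0.9) and a 0.3 chance of leaving ARS per step.
DEFAULT_TRUE_PARAMS = dict(
    gamma=(0.85, 0.15),
    theta=(0.0, math.pi),
    alpha=(0.9, 0.3),
    Sigma=np.diag([0.15**2, 0.15**2]),
)

#: Empirical flavour of marine Argos data: mostly low-quality classes.
DEFAULT_LC_FREQUENCIES = {"3": 0.05, "2": 0.08, "1": 0.12, "0": 0.15, "A": 0.25, "B": 0.35}


def default_params() -> DCRWSParams:
    p = dict(DEFAULT_TRUE_PARAMS)
    p["Sigma"] = np.array(p["Sigma"])
    return DCRWSParams(**p)


@dataclass
class SimTruth:
    """Ground truth for one simulated segment."""

    path: np.ndarray  # (n_steps, 2) lon/lat degrees at regular times
    states: np.ndarray  # (n_steps,) in {1, 2}
    params: DCRWSParams
    step_hours: float
    origin_time: pd.Timestamp
    seed: int

    @property
    def n_steps(self) -> int:
        return len(self.states)

    def times(self) -> pd.DatetimeIndex:
        return self.origin_time + pd.to_timedelta(
            np.arange(self.n_steps) * self.step_hours, unit="h"
        )


def simulate_dcrws(
    params: DCRWSParams | None = None,
    n_steps: int = 150,
    step_hours: float = 12.0,
    origin: tuple[float, float] = (8.0, 42.5),
    origin_time: str | pd.Timestamp = "2012-09-01",
    seed: int = 0,
    initial_step: tuple[float, float] | None = None,
) -> SimTruth:
    """Simulate a switching-CRW path with its true state sequence.

    The behavioural chain starts in state 1 and evolves with transition
    probabilities α; displacements follow the first-difference CRW with the
    state-dependent (γ, θ) and Gaussian noise Σ. ``initial_step`` fixes the
    first displacement; by default it is drawn from N(0, Σ / (1 − γ₁²)),
    a stationary-speed start.
    """
    params = params or default_params()
    params.validate()
    if n_steps < 3:
        raise ValueError("n_steps must be at least 3")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(params.Sigma + 1e-300 * np.eye(2))
    rot = [rotation(params.theta[0]), rotation(params.theta[1])]

    states = np.empty(n_steps, dtype=np.int64)
    states[0] = 1
    for t in range(1, n_steps):
        p1 = params.alpha[states[t - 1] - 1]
        states[t] = 1 if rng.random() < p1 else 2

    x = np.empty((n_steps, 2))
    x[0] = origin
    if initial_step is None:
        scale = 1.0 / math.sqrt(max(1e-12, 1.0 - params.gamma[0] ** 2))
        d = scale * (L @ rng.standard_normal(2))
    else:
        d = np.asarray(initial_step, float)
    x[1] = x[0] + d
    for t in range(2, n_steps):
        k = states[t] - 1
        d = params.gamma[k] * (rot[k] @ (x[t - 1] - x[t - 2])) + L @ rng.standard_normal(2)
        x[t] = x[t - 1] + d
    return SimTruth(
        path=x,
        states=states,
        params=params,
        step_hours=step_hours,
        origin_time=pd.Timestamp(origin_time),
        seed=seed,
    )


def observe_argos(
    truth: SimTruth,
    obs_rate_per_day: float = 3.0,
    lc_frequencies: dict[str, float] | None = None,
    error_table: dict | None = None,
    seed: int = 0,
    ptt: str = "SIM001",
) -> list[ArgosFix]:
    """Observe a true path through an Argos-like error process.

    Observation times form a Poisson process over the track's span; each
    fix linearly interpolates the true path and adds independent
    per-coordinate Student-t noise with the sampled class's (τ, ν). The
    first and last true instants are always observed so the fixes span the
    full segment.
    """
    if obs_rate_per_day <= 0:
        raise ValueError("obs_rate_per_day must be positive")
    lc_frequencies = lc_frequencies or DEFAULT_LC_FREQUENCIES
    freqs = np.array([lc_frequencies.get(lc, 0.0) for lc in LC_ORDER])
    if not math.isclose(freqs.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("lc_frequencies must sum to 1")
    error_table = error_table or DEFAULT_ERROR_TABLE
    rng = np.random.default_rng(seed)

    span_hours = (truth.n_steps - 1) * truth.step_hours
    span_days = span_hours / 24.0
    n = rng.poisson(obs_rate_per_day * span_days)
    t_hours = np.sort(rng.uniform(0.0, span_hours, size=n))
    t_hours = np.concatenate([[0.0], t_hours, [span_hours]])
    t_hours = np.round(t_hours * 3600.0) / 3600.0  # fixes are stamped to the second

    grid = np.arange(truth.n_steps) * truth.step_hours
    lon = np.interp(t_hours, grid, truth.path[:, 0])
    lat = np.interp(t_hours, grid, truth.path[:, 1])
    lcs = rng.choice(list(LC_ORDER), size=len(t_hours), p=freqs)

    fixes = []
    for th, lo_, la_, lc in zip(t_hours, lon, lat, lcs):
        tau = error_table["tau"][lc]
        tau_lon, tau_lat = (tau, tau) if np.isscalar(tau) else tau
        nu = error_table["nu"][lc]
        e_lon = tau_lon * rng.standard_t(nu)
        e_lat = tau_lat * rng.standard_t(nu)
        time = truth.origin_time + pd.to_timedelta(int(round(th * 3600.0)), unit="s")
        fixes.append(
            ArgosFix(
                ptt=ptt,
                time=time,
                lon=float(np.clip(lo_ + e_lon, -180.0, 180.0)),
                lat=float(np.clip(la_ + e_lat, -90.0, 90.0)),
                lc=str(lc),
            )
        )
    fixes.sort(key=lambda f: f.time)
    return fixes


# ---------------------------------------------------------------------------
# Environmental scene


@dataclass
class FrontSpec:
    """A sigmoidal chl-a transition in longitude, optionally drifting."""

    lon: float = 5.0  # front centre at day 0
    width_deg: float = 0.2
    chl_low: float = 0.08  # mg m^-3 plateau west of the front
    chl_high: float = 0.45  # plateau east of the front
    drift_deg_per_day: float = 0.0


@dataclass
class DepthSpec:
    """Bathymetry deepening away from a northern coast; metres positive down."""

    coast_lat: float | None = None  # default: northern grid edge
    max_depth_m: float = 2500.0
    land_band_deg: float = 0.0  # land strip against the coast


@dataclass
class LaneSpec:
    """A shipping lane: polyline in lon/lat with a width and cell value."""

    points: list[tuple[float, float]] = field(default_factory=list)
    width_deg: float = 0.1
    value: int = 300


@dataclass
class SimScene:
    grid: GridSpec
    chla: np.ndarray  # (n_days, ny, nx) mg m^-3
    depth: np.ndarray  # (ny, nx) metres, positive down
    land: np.ndarray  # (ny, nx) bool
    traffic: np.ndarray  # (ny, nx) int in [0, 409]


def _dist_to_polyline(px: np.ndarray, py: np.ndarray, pts: list[tuple[float, float]]) -> np.ndarray:
    """Point-to-polyline distance (in the grid's degree coordinates)."""
    best = np.full(px.shape, np.inf)
    for (x1, y1), (x2, y2) in zip(pts, pts[1:]):
        dx, dy = x2 - x1, y2 - y1
        denom = dx * dx + dy * dy
        if denom == 0:
            d2 = (px - x1) ** 2 + (py - y1) ** 2
        else:
            t = np.clip(((px - x1) * dx + (py - y1) * dy) / denom, 0.0, 1.0)
            d2 = (px - (x1 + t * dx)) ** 2 + (py - (y1 + t * dy)) ** 2
        best = np.minimum(best, np.sqrt(d2))
    return best


def simulate_scene(
    grid: GridSpec,
    front: FrontSpec | None = None,
    depth: DepthSpec | None = None,
    lanes: list[LaneSpec] | None = None,
    n_days: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SimScene:
    """Build chl-a / bathymetry / traffic layers on a shared lon/lat grid.

    The chl-a field transitions between two plateaus through a logistic band
    of the stated width centred on the front longitude (drifting by day);
    bathymetry deepens linearly southwards from the coast; traffic cells
    within half a lane-width of a lane polyline take that lane's value.
    Values are clipped to the [0, 409] range of the source traffic product.
    """
    front = front or FrontSpec()
    depth_spec = depth or DepthSpec()
    lanes = lanes if lanes is not None else []
    rng = np.random.default_rng(seed)
    LON, LAT = grid.center_mesh()

    coast_lat = depth_spec.coast_lat if depth_spec.coast_lat is not None else (
        grid.lat0 + grid.ny * grid.dlat
    )
    land = LAT > coast_lat - depth_spec.land_band_deg
    depth_arr = np.where(
        land, 0.0, depth_spec.max_depth_m * (coast_lat - depth_spec.land_band_deg - LAT)
        / max(1e-9, coast_lat - depth_spec.land_band_deg - grid.lat0)
    )
    depth_arr = np.clip(depth_arr, 0.0, depth_spec.max_depth_m)

    chla = np.empty((n_days, grid.ny, grid.nx))
    for day in range(n_days):
        centre = front.lon + day * front.drift_deg_per_day
        # logistic with "width" spanning the central 90% of the transition
        s = front.width_deg / (2 * math.log(19.0)) if front.width_deg > 0 else 1e-12
        z = 1.0 / (1.0 + np.exp(-(LON - centre) / s))
        f = front.chl_low + (front.chl_high - front.chl_low) * z
        if noise_sd > 0:
            f = f * np.exp(noise_sd * rng.standard_normal(f.shape))
        chla[day] = np.maximum(f, 1e-4)

    traffic = np.zeros(grid.shape, dtype=np.int64)
    for lane in lanes:
        if len(lane.points) < 2:
            raise ValueError("a lane needs at least two polyline points")
        d = _dist_to_polyline(LON, LAT, lane.points)
        traffic[d <= lane.width_deg / 2.0] = lane.value
    traffic = np.clip(traffic, 0, 409)

    return SimScene(grid=grid, chla=chla, depth=depth_arr, land=land, traffic=traffic)


def truth_to_frame(truth: SimTruth) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": truth.times(),
            "lon": truth.path[:, 0],
            "lat": truth.path[:, 1],
            "state": truth.states,
        }
    )
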