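"""Two-state switching first-difference correlated random walk (DCRWS).

The movement model: on a regular time grid with step Δ, the expected
displacement continues the previous displacement, damped and rotated
according to the current behavioural state b_t ∈ {1, 2}:

    x_{t+1} = x_t + γ_{b} T(θ_{b}) (x_t − x_{t−1}) + ε_t,   ε_t ~ N(0, Σ)

State 1 ("transit") has high move persistence γ₁ and near-zero mean turning
θ₁; state 2 ("area-restricted search", ARS) has low γ₂ and turning near π.
States follow a two-state Markov chain with α_k = Pr(b_t = 1 | b_{t−1} = k).
Argos fixes observe the linear interpolation of the two bracketing grid
locations with independent per-coordinate Student-t errors whose scale τ and
degrees of freedom ν depend on the Argos location class.

This module holds the model types, the time-grid regularisation of a track
segment, and the elementary densities; the MCMC machinery lives in
:mod:`finmove.sampler`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .argos import LC_ORDER, ArgosFix, TrackSegment

#: Observation-error table used throughout tests and synthetic runs:
#: per-class Student-t scale (degrees, same for lon and lat) and dof.
DEFAULT_ERROR_TABLE = {
    "tau": {"3": 0.01, "2": 0.02, "1": 0.04, "0": 0.08, "A": 0.12, "B": 0.25},
    "nu": {lc: 4.0 for lc in LC_ORDER},
}


@dataclass
class DCRWSParams:
    """Movement, switching and observation-error parameters.

    gamma : (γ₁, γ₂) move persistence per state, each in (0, 1), γ₁ > γ₂.
    theta : (θ₁, θ₂) mean turning angle per state, radians in (−π, π].
    alpha : (α₁, α₂) with α_k = Pr(b_t = 1 | b_{t−1} = k), each in (0, 1).
    Sigma : 2×2 symmetric positive-definite process covariance (degrees²).
    tau   : per-lc observation scale; scalar or (lon, lat) pair, degrees.
    nu    : per-lc Student-t degrees of freedom (> 1).
    """

    gamma: tuple[float, float]
    theta: tuple[float, float]
    alpha: tuple[float, float]
    Sigma: np.ndarray
    tau: dict[str, float | tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ERROR_TABLE["tau"])
    )
    nu: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ERROR_TABLE["nu"]))

    def __post_init__(self):
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.validate()

    def tau_pair(self, lc: str) -> tuple[float, float]:
        t = self.tau[lc]
        return (t, t) if np.isscalar(t) else (t[0], t[1])

    def validate(self) -> None:
        g1, g2 = self.gamma
        if not (0.0 <= g2 < 1.0 and 0.0 <= g1 <= 1.0 and g1 > g2):
            raise ValueError(f"gamma must satisfy 0 <= γ₂ < γ₁ <= 1, got {self.gamma}")
        for a in self.alpha:
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"alpha outside [0, 1]: {self.alpha}")
        if self.Sigma.shape != (2, 2) or not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be symmetric 2x2")
        if np.min(np.linalg.eigvalsh(self.Sigma)) < 0:
            raise ValueError("Sigma must be positive semi-definite")
        for lc, t in self.tau.items():
            pair = (t, t) if np.isscalar(t) else t
            if min(pair) <= 0:
                raise ValueError(f"tau[{lc}] must be positive")
        for lc, v in self.nu.items():
            if v <= 1:
                raise ValueError(f"nu[{lc}] must exceed 1")


def rotation(theta: float) -> np.ndarray:
    """Counter-clockwise rotation matrix T(θ)."""
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def process_mean(x_t: np.ndarray, x_prev: np.ndarray, state: int, params: DCRWSParams) -> np.ndarray:
    """E[x_{t+1}] = x_t + γ_k T(θ_k) (x_t − x_prev) for behavioural state k."""
    k = state - 1
    d = np.asarray(x_t, float) - np.asarray(x_prev, float)
    return np.asarray(x_t, float) + params.gamma[k] * rotation(params.theta[k]) @ d


def t_logpdf(r: np.ndarray, tau, nu) -> np.ndarray:
    """Log-density of a scaled Student-t at residual ``r`` (hand-coded).

    Matches ``scipy.stats.t.logpdf(r, df=nu, scale=tau)``; written out so the
    sampler's hot loop avoids per-call distribution objects.
    """
    r = np.asarray(r, dtype=float)
    tau = np.asarray(tau, dtype=float)
    nu = np.asarray(nu, dtype=float)
    c = (
        np.vectorize(math.lgamma)((nu + 1.0) / 2.0)
        - np.vectorize(math.lgamma)(nu / 2.0)
        - 0.5 * np.log(nu * np.pi)
        - np.log(tau)
    )
    return c - (nu + 1.0) / 2.0 * np.log1p((r / tau) ** 2 / nu)


def obs_loglik(fix: ArgosFix, location: np.ndarray, params: DCRWSParams) -> float:
    """Log-likelihood of one Argos fix at an interpolated model location.

    Per-coordinate independent Student-t errors with the class's (τ, ν);
    the two coordinate log-densities are summed.
    """
    if fix.lc not in params.tau or fix.lc not in params.nu:
        raise KeyError(f"location class {fix.lc!r} missing from error table")
    tau_lon, tau_lat = params.tau_pair(fix.lc)
    nu = params.nu[fix.lc]
    loc = np.asarray(location, dtype=float)
    ll = t_logpdf(fix.lon - loc[0], tau_lon, nu) + t_logpdf(fix.lat - loc[1], tau_lat, nu)
    return float(ll)


@dataclass
class RegularisedSegment:
    """A track segment mapped onto a regular state-time grid.

    ``state_times`` are equally spaced (spacing ``step_hours``) and cover the
    segment's fix times. Each fix i is indexed by the grid interval
    ``obs_interval[i]`` it falls in and its fractional position
    ``obs_frac[i] = (t_i − state_time[obs_interval[i]]) / Δ`` in [0, 1).
    """

    ptt: str
    segment_label: str
    step_hours: float
    origin: pd.Timestamp
    state_times: np.ndarray  # hours since origin, shape (T,)
    obs_lonlat: np.ndarray  # (n, 2)
    obs_interval: np.ndarray  # (n,) int
    obs_frac: np.ndarray  # (n,) float in [0, 1)
    obs_lc: np.ndarray  # (n,) str

    @property
    def n_states(self) -> int:
        return len(self.state_times)

    def timestamps(self) -> pd.DatetimeIndex:
        return self.origin + pd.to_timedelta(self.state_times, unit="h")


def regularise(segment: TrackSegment, step_hours: float = 12.0) -> RegularisedSegment:
    """Build the regular Δ-spaced state grid over a segment's time span.

    The grid starts at the first fix and extends in Δ steps until it covers
    the last fix. Raises for segments shorter than 2Δ.
    """
    if step_hours <= 0:
        raise ValueError("step_hours must be positive")
    fixes = segment.fixes
    if not fixes:
        raise ValueError(f"segment {segment.ptt}/{segment.segment_label}: no fixes")
    origin = fixes[0].time
    hours = np.array([(f.time - origin).total_seconds() / 3600.0 for f in fixes])
    span = hours[-1]
    if span < 2 * step_hours:
        raise ValueError(
            f"segment {segment.ptt}/{segment.segment_label} spans {span:.1f} h "
            f"< 2Δ = {2 * step_hours:.1f} h"
        )
    n_intervals = int(math.ceil(span / step_hours - 1e-9))
    state_times = np.arange(n_intervals + 1) * step_hours

    interval = np.minimum((hours // step_hours).astype(int), n_intervals)
    frac = (hours - state_times[interval]) / step_hours
    # a fix exactly on the final node indexes that node with frac 0
    on_final = interval == n_intervals
    frac[on_final] = 0.0
    if np.any(frac < 0) or np.any(frac >= 1):
        raise AssertionError("fractional positions outside [0, 1)")

    return RegularisedSegment(
        ptt=segment.ptt,
        segment_label=segment.segment_label,
        step_hours=step_hours,
        origin=origin,
        state_times=state_times,
        obs_lonlat=np.array([[f.lon, f.lat] for f in fixes]),
        obs_interval=interval,
        obs_frac=frac,
        obs_lc=np.array([f.lc for f in fixes]),
    )
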