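"""Metropolis-within-Gibbs sampler for the hierarchical switching CRW.

Movement parameters (γ, θ, α, Σ) are pooled across all track segments —
information from long tracks sharpens the estimates used to decode short
ones — while latent locations x_t and behavioural states b_t are sampled per
segment. Update blocks per iteration:

* b_t  — exact two-point full-conditional draws, alternating even/odd time
  indices (a checkerboard: b_t depends on b_{t−1}, b_{t+1} only).
* x_t  — random-walk Metropolis with per-node adaptive scales, in three
  interleaved colour classes (t mod 3): an innovation e_t touches
  x_{t−2..t}, so nodes three apart are conditionally independent and can be
  proposed simultaneously.
* γ, θ, Σ — adaptive scalar random-walk Metropolis, one block each.
* α — conjugate Beta draws from the pooled state-transition counts.

Everything is driven by per-chain ``numpy`` Generators spawned from a single
seed, so a fit is bit-reproducible for a fixed configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ssm import DCRWSParams, DEFAULT_ERROR_TABLE, RegularisedSegment

_TARGET_ACC = 0.44  # classic scalar random-walk target


@dataclass
class MCMCConfig:
    chains: int = 2
    iters: int = 10_000  # total iterations, including burn-in
    burn: int = 5_000
    thin: int = 10
    seed: int = 0
    store_locations: bool = True

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("at least 2 chains required for convergence diagnostics")
        if not 0 < self.burn < self.iters:
            raise ValueError("need 0 < burn < iters")


@dataclass
class Priors:
    """Default priors: uniforms on γ (order-truncated), θ and the process
    correlation; half-Normal on the process SDs; Beta(1,1) on α."""

    theta1_range: tuple[float, float] = (-math.pi / 4, math.pi / 4)
    #: upper bound on cos θ₂: the ARS turning angle is confined to the
    #: reversal half-circle by default (|θ₂| ≥ π/2). This anchors the state
    #: labels — without it, a track with no ARS at all admits a reflected
    #: mode in which every step is relabelled ARS with θ₂ ≈ 0. Set to 1.0
    #: to recover an unrestricted circular prior.
    theta2_cos_max: float = 0.0
    sigma_halfnormal_scale: float = 1.0  # degrees
    alpha_beta: tuple[float, float] = (1.0, 1.0)


@dataclass
class SegmentPosterior:
    ptt: str
    segment_label: str
    step_hours: float
    origin: pd.Timestamp
    state_times: np.ndarray
    b_samples: np.ndarray  # (chains, draws, T) int8
    x_samples: np.ndarray | None  # (chains, draws, T, 2) float32


@dataclass
class PosteriorFit:
    """Pooled parameter draws, per-segment latent draws and diagnostics."""

    params: dict[str, np.ndarray]  # name -> (chains, draws)
    segments: list[SegmentPosterior]
    diagnostics: dict
    config: dict

    def behaviour_means(self) -> list[np.ndarray]:
        """Per-segment posterior mean state b̂_t ∈ [1, 2] (avg over chains+draws)."""
        return [sp.b_samples.mean(axis=(0, 1)) for sp in self.segments]

    def location_means(self) -> list[np.ndarray]:
        if self.segments[0].x_samples is None:
            raise ValueError("locations were not stored")
        return [sp.x_samples.mean(axis=(0, 1)).astype(float) for sp in self.segments]

    def credible_interval(self, name: str, level: float = 0.9) -> tuple[float, float]:
        """Equal-tailed pooled-chain credible interval for a parameter."""
        lo = (1.0 - level) / 2.0
        draws = self.params[name].ravel()
        return (float(np.quantile(draws, lo)), float(np.quantile(draws, 1.0 - lo)))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.params.items():
            lo, hi = self.credible_interval(name)
            rows.append(
                {
                    "parameter": name,
                    "mean": float(arr.mean()),
                    "sd": float(arr.std(ddof=1)),
                    "q5": lo,
                    "q95": hi,
                    "rhat": self.diagnostics["rhat"].get(name, np.nan),
                    "ess": self.diagnostics["ess"].get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)


def behaviour_means(fit: PosteriorFit) -> list[np.ndarray]:
    return fit.behaviour_means()


class _SegmentData:
    """Precomputed observation arrays and colour maps for one segment."""

    def __init__(self, reg: RegularisedSegment, error_table: dict):
        self.reg = reg
        self.T = reg.n_states
        self.y = np.asarray(reg.obs_lonlat, float)
        self.t_idx = np.asarray(reg.obs_interval, int)
        self.j = np.asarray(reg.obs_frac, float)
        self.u_idx = np.minimum(self.t_idx + 1, self.T - 1)
        tau = error_table["tau"]
        nu = error_table["nu"]

        def pair(v):
            return (v, v) if np.isscalar(v) else tuple(v)

        self.tau = np.array([pair(tau[lc]) for lc in reg.obs_lc])  # (n, 2)
        self.nu = np.array([nu[lc] for lc in reg.obs_lc])[:, None]  # (n, 1)
        self.tconst = (
            np.vectorize(math.lgamma)((self.nu + 1) / 2)
            - np.vectorize(math.lgamma)(self.nu / 2)
            - 0.5 * np.log(self.nu * np.pi)
            - np.log(self.tau)
        )
        self.tcoef = (self.nu + 1.0) / 2.0
        # colour maps: which obs touch a node of colour c, and that node;
        # observation arrays are pre-sliced per colour to keep the hot loop
        # free of fancy indexing
        self.color_obs: list[np.ndarray] = []
        self.color_node: list[np.ndarray] = []
        self.color_slices: list[dict] = []
        for c in range(3):
            touch = (self.t_idx % 3 == c) | (self.u_idx % 3 == c)
            sel = np.where(touch)[0]
            node = np.where(self.t_idx[sel] % 3 == c, self.t_idx[sel], self.u_idx[sel])
            self.color_obs.append(sel)
            self.color_node.append(node)
            self.color_slices.append(
                {
                    "y": self.y[sel],
                    "t_idx": self.t_idx[sel],
                    "u_idx": self.u_idx[sel],
                    "j": self.j[sel, None],
                    "tau": self.tau[sel],
                    "nu": self.nu[sel],
                    "tconst": self.tconst[sel].sum(axis=1),
                    "tcoef": self.tcoef[sel],
                    "node": node,
                }
            )
        self.color_nodes = [np.arange(c, self.T, 3) for c in range(3)]

    def obs_loglik_color(self, X: np.ndarray, c: int) -> np.ndarray:
        """Per-observation log-likelihood for the colour-c observation slice."""
        s = self.color_slices[c]
        mu = (1.0 - s["j"]) * X[s["t_idx"]] + s["j"] * X[s["u_idx"]]
        r = s["y"] - mu
        return s["tconst"] - (
            s["tcoef"] * np.log1p((r / s["tau"]) ** 2 / s["nu"])
        ).sum(axis=1)

    def obs_loglik(self, X: np.ndarray, sel: np.ndarray | None = None) -> np.ndarray:
        """Per-observation log-likelihood (summed over lon/lat)."""
        if sel is None:
            sel = slice(None)
        mu = (1.0 - self.j[sel, None]) * X[self.t_idx[sel]] + self.j[sel, None] * X[self.u_idx[sel]]
        r = self.y[sel] - mu
        ll = self.tconst[sel] - self.tcoef[sel] * np.log1p((r / self.tau[sel]) ** 2 / self.nu[sel])
        return ll.sum(axis=1)

    def init_locations(self) -> np.ndarray:
        th = (self.t_idx + self.j) * self.reg.step_hours
        grid = self.reg.state_times
        return np.column_stack(
            [np.interp(grid, th, self.y[:, 0]), np.interp(grid, th, self.y[:, 1])]
        )


def _quad(e: np.ndarray, Sinv: np.ndarray) -> np.ndarray:
    return (
        Sinv[0, 0] * e[:, 0] ** 2
        + 2.0 * Sinv[0, 1] * e[:, 0] * e[:, 1]
        + Sinv[1, 1] * e[:, 1] ** 2
    )


def _innovations(X: np.ndarray, b: np.ndarray, gam, cth, sth) -> np.ndarray:
    """e_t = d_t − γ_{b_t} T(θ_{b_t}) d_{t−1} for t = 2..T−1."""
    D = X[1:] - X[:-1]
    k = b[2:] - 1
    g, c, s = gam[k], cth[k], sth[k]
    px = g * (c * D[:-1, 0] - s * D[:-1, 1])
    py = g * (s * D[:-1, 0] + c * D[:-1, 1])
    return np.column_stack([D[1:, 0] - px, D[1:, 1] - py])


class _ChainState:
    def __init__(self, data: list[_SegmentData], priors: Priors, rng: np.random.Generator):
        self.rng = rng
        self.data = data
        self.X = [sd.init_locations() for sd in data]
        self.b = [np.ones(sd.T, dtype=np.int64) for sd in data]
        self.gamma = np.array([0.7, 0.3])
        self.theta = np.array([0.0, math.pi])
        self.alpha = np.array([0.8, 0.3])
        s0 = max(
            1e-3,
            float(np.median([np.abs(np.diff(x, axis=0)).mean() for x in self.X])),
        )
        self.Sigma = np.diag([s0**2, s0**2])
        self._chol_update()
        # adaptive proposal scales
        self.x_scales = [np.full(sd.T, s0) for sd in data]
        self.p_scales = {
            "gamma1": 0.1,
            "gamma2": 0.1,
            "theta1": 0.2,
            "theta2": 0.4,
            "logs1": 0.2,
            "logs2": 0.2,
            "rho": 0.1,
        }
        self.priors = priors

    def _chol_update(self):
        self.Sinv = np.linalg.inv(self.Sigma)
        self.logdet = float(np.log(np.linalg.det(self.Sigma)))

    # -- behavioural states ------------------------------------------------
    def update_b(self):
        la = np.log(np.clip(self.alpha, 1e-300, 1.0))
        l1a = np.log(np.clip(1.0 - self.alpha, 1e-300, 1.0))
        # lp[k_prev, k_cur]: k = 0 (transit) / 1 (ARS)
        lp = np.array([[la[0], l1a[0]], [la[1], l1a[1]]])
        cth, sth = np.cos(self.theta), np.sin(self.theta)
        for sd, X, b in zip(self.data, self.X, self.b):
            T = sd.T
            ll = np.zeros((2, T))  # innovation loglik if b_t = k, at nodes 2..T-1
            D = X[1:] - X[:-1]
            for k in range(2):
                px = self.gamma[k] * (cth[k] * D[:-1, 0] - sth[k] * D[:-1, 1])
                py = self.gamma[k] * (sth[k] * D[:-1, 0] + cth[k] * D[:-1, 1])
                e = np.column_stack([D[1:, 0] - px, D[1:, 1] - py])
                ll[k, 2:] = -0.5 * _quad(e, self.Sinv)
            for parity in (0, 1):
                idx = np.arange(parity, T, 2)
                w = ll[:, idx].copy()
                prev = idx - 1
                has_prev = prev >= 0
                kprev = b[prev[has_prev]] - 1
                for k in range(2):
                    w[k, has_prev] += lp[kprev, k]
                nxt = idx + 1
                has_next = nxt <= T - 1
                knext = b[nxt[has_next]] - 1
                for k in range(2):
                    w[k, has_next] += lp[k, knext]
                p1 = 1.0 / (1.0 + np.exp(np.clip(w[1] - w[0], -500, 500)))
                b[idx] = np.where(self.rng.random(len(idx)) < p1, 1, 2)

    # -- latent locations --------------------------------------------------
    def update_x(self, adapt: float):
        cth, sth = np.cos(self.theta), np.sin(self.theta)
        for si, (sd, X, b) in enumerate(zip(self.data, self.X, self.b)):
            T = sd.T
            scales = self.x_scales[si]
            e_cur = _innovations(X, b, self.gamma, cth, sth)
            ll_cur = -0.5 * _quad(e_cur, self.Sinv)
            for c in range(3):
                nodes = sd.color_nodes[c]
                Xp = X.copy()
                Xp[nodes] += scales[nodes, None] * self.rng.standard_normal((len(nodes), 2))
                e_prop = _innovations(Xp, b, self.gamma, cth, sth)
                ll_prop = -0.5 * _quad(e_prop, self.Sinv)
                A = np.zeros(T + 2)
                A[2:T] = ll_prop - ll_cur
                d_nodes = A[nodes] + A[nodes + 1] + A[nodes + 2]
                onode = sd.color_node[c]
                if len(onode):
                    d_obs = sd.obs_loglik_color(Xp, c) - sd.obs_loglik_color(X, c)
                    acc_obs = np.zeros(T)
                    np.add.at(acc_obs, onode, d_obs)
                    d_nodes = d_nodes + acc_obs[nodes]
                accept = np.log(self.rng.random(len(nodes))) < d_nodes
                moved = nodes[accept]
                X[moved] = Xp[moved]
                if adapt > 0:
                    upd = scales[nodes] * np.exp(adapt * (accept.astype(float) - _TARGET_ACC))
                    scales[nodes] = np.clip(upd, 1e-6, 50.0)
                if accept.any():
                    # within a colour, an innovation index is touched by at
                    # most one node, so the proposed values can be spliced in
                    touched = np.concatenate([moved, moved + 1, moved + 2])
                    touched = touched[(touched >= 2) & (touched <= T - 1)] - 2
                    ll_cur[touched] = ll_prop[touched]

    # -- movement parameters ----------------------------------------------
    def _stack_displacements(self):
        """Concatenate per-segment displacement pairs for pooled-parameter MH."""
        dp, dc, kk = [], [], []
        for X, b in zip(self.X, self.b):
            D = X[1:] - X[:-1]
            dp.append(D[:-1])
            dc.append(D[1:])
            kk.append(b[2:] - 1)
        self._dp = np.concatenate(dp)
        self._dc = np.concatenate(dc)
        self._kk = np.concatenate(kk)

    def _innov_loglik(self, gamma, theta, Sinv, logdet) -> float:
        cth, sth = np.cos(theta), np.sin(theta)
        g, c, s = gamma[self._kk], cth[self._kk], sth[self._kk]
        ex = self._dc[:, 0] - g * (c * self._dp[:, 0] - s * self._dp[:, 1])
        ey = self._dc[:, 1] - g * (s * self._dp[:, 0] + c * self._dp[:, 1])
        q = Sinv[0, 0] * ex @ ex + 2.0 * Sinv[0, 1] * ex @ ey + Sinv[1, 1] * ey @ ey
        return -0.5 * float(q) - len(ex) * (math.log(2 * math.pi) + 0.5 * logdet)

    def update_params(self, adapt: float):
        self._stack_displacements()
        cur_ll = self._innov_loglik(self.gamma, self.theta, self.Sinv, self.logdet)

        def mh(name, apply_prop, log_prior_delta=0.0):
            nonlocal cur_ll
            step = self.p_scales[name] * self.rng.standard_normal()
            new = apply_prop(step)
            accepted = False
            if new is not None:
                gamma, theta, Sigma = new
                if Sigma is None:
                    Sinv, logdet = self.Sinv, self.logdet
                else:
                    Sinv = np.linalg.inv(Sigma)
                    logdet = float(np.log(np.linalg.det(Sigma)))
                ll = self._innov_loglik(gamma, theta, Sinv, logdet)
                lpd = (
                    log_prior_delta(gamma, theta, Sigma)
                    if callable(log_prior_delta)
                    else log_prior_delta
                )
                if math.log(self.rng.random()) < ll - cur_ll + lpd:
                    self.gamma, self.theta = np.asarray(gamma), np.asarray(theta)
                    if Sigma is not None:
                        self.Sigma = Sigma
                        self.Sinv, self.logdet = Sinv, logdet
                    cur_ll = ll
                    accepted = True
            if adapt > 0:
                self.p_scales[name] *= math.exp(adapt * (float(accepted) - _TARGET_ACC))
                self.p_scales[name] = min(max(self.p_scales[name], 1e-5), 10.0)

        pri = self.priors

        def prop_gamma(k):
            def f(step):
                g = self.gamma.copy()
                g[k] += step
                if not (0.0 < g[1] < g[0] < 1.0):
                    return None
                return g, self.theta, None

            return f

        mh("gamma1", prop_gamma(0))
        mh("gamma2", prop_gamma(1))

        def prop_theta1(step):
            th = self.theta.copy()
            th[0] += step
            if not (pri.theta1_range[0] < th[0] < pri.theta1_range[1]):
                return None
            return self.gamma, th, None

        def prop_theta2(step):
            th = self.theta.copy()
            th[1] = (th[1] + step + math.pi) % (2 * math.pi) - math.pi
            if math.cos(th[1]) > pri.theta2_cos_max:
                return None
            return self.gamma, th, None

        mh("theta1", prop_theta1)
        mh("theta2", prop_theta2)

        # process covariance: log-scale proposals with half-Normal prior on
        # the SDs (log-scale Jacobian included), uniform prior on correlation
        hs = pri.sigma_halfnormal_scale

        def sds(Sigma):
            a = math.sqrt(Sigma[0, 0])
            bb = math.sqrt(Sigma[1, 1])
            return a, bb, Sigma[0, 1] / (a * bb)

        def sigma_from(s1n, s2n, rhon):
            return np.array(
                [[s1n**2, rhon * s1n * s2n], [rhon * s1n * s2n, s2n**2]]
            )

        def prop_logs(which):
            def f(step):
                s1, s2, rho = sds(self.Sigma)
                a = s1 * math.exp(step) if which == 0 else s1
                bb = s2 * math.exp(step) if which == 1 else s2
                return self.gamma, self.theta, sigma_from(a, bb, rho)

            return f

        def logprior_logs(which):
            def f(gamma, theta, Sigma):
                sn = math.sqrt(Sigma[which, which])
                so = math.sqrt(self.Sigma[which, which])
                # half-Normal density on s, plus d s / d log s Jacobian
                return (-(sn**2) + so**2) / (2 * hs**2) + (math.log(sn) - math.log(so))

            return f

        mh("logs1", prop_logs(0), logprior_logs(0))
        mh("logs2", prop_logs(1), logprior_logs(1))

        def prop_rho(step):
            s1, s2, rho = sds(self.Sigma)
            rn = rho + step
            if not -0.99 < rn < 0.99:
                return None
            return self.gamma, self.theta, sigma_from(s1, s2, rn)

        mh("rho", prop_rho)

        # switching probabilities: conjugate Beta update from pooled counts
        a0, b0 = pri.alpha_beta
        n = np.zeros((2, 2))
        for b in self.b:
            prev = b[:-1] - 1
            cur = b[1:] - 1
            np.add.at(n, (prev, cur), 1)
        self.alpha[0] = self.rng.beta(a0 + n[0, 0], b0 + n[0, 1])
        self.alpha[1] = self.rng.beta(a0 + n[1, 0], b0 + n[1, 1])


PARAM_NAMES = ("gamma1", "gamma2", "theta1", "theta2", "alpha1", "alpha2",
               "sigma_lon", "sigma_lat", "rho")


def fit_hssm(
    segments: list[RegularisedSegment],
    error_table: dict | None = None,
    priors: Priors | None = None,
    mcmc: MCMCConfig | None = None,
) -> PosteriorFit:
    """Fit the pooled two-state switching CRW to regularised segments.

    Returns a :class:`PosteriorFit` with pooled parameter draws (γ, θ, α and
    the process covariance reported as per-axis SDs + correlation), thinned
    per-segment draws of states and locations, and R̂/ESS diagnostics.
    """
    if not segments:
        raise ValueError("no segments to fit")
    error_table = error_table or DEFAULT_ERROR_TABLE
    priors = priors or Priors()
    mcmc = mcmc or MCMCConfig()
    data = [_SegmentData(reg, error_table) for reg in segments]
    for sd in data:
        if sd.T < 5:
            raise ValueError(f"segment {sd.reg.ptt}/{sd.reg.segment_label}: too few state times")
        if not np.isfinite(sd.obs_loglik(sd.init_locations())).all():
            raise ValueError("non-finite observation likelihood at initial locations")

    n_keep = (mcmc.iters - mcmc.burn + mcmc.thin - 1) // mcmc.thin
    children = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)

    par_store = {name: np.empty((mcmc.chains, n_keep)) for name in PARAM_NAMES}
    b_store = [np.empty((mcmc.chains, n_keep, sd.T), dtype=np.int8) for sd in data]
    x_store = (
        [np.empty((mcmc.chains, n_keep, sd.T, 2), dtype=np.float32) for sd in data]
        if mcmc.store_locations
        else None
    )

    for ci in range(mcmc.chains):
        rng = np.random.default_rng(children[ci])
        st = _ChainState(data, priors, rng)
        k = 0
        for it in range(mcmc.iters):
            adapt = 0.05 if it < mcmc.burn else 0.0
            st.update_b()
            st.update_x(adapt)
            st.update_params(adapt)
            if it >= mcmc.burn and (it - mcmc.burn) % mcmc.thin == 0:
                s1 = math.sqrt(st.Sigma[0, 0])
                s2 = math.sqrt(st.Sigma[1, 1])
                vals = (
                    st.gamma[0], st.gamma[1], st.theta[0], st.theta[1],
                    st.alpha[0], st.alpha[1], s1, s2, st.Sigma[0, 1] / (s1 * s2),
                )
                for name, v in zip(PARAM_NAMES, vals):
                    par_store[name][ci, k] = v
                for si in range(len(data)):
                    b_store[si][ci, k] = st.b[si]
                    if x_store is not None:
                        x_store[si][ci, k] = st.X[si]
                k += 1

    diagnostics = _diagnostics(par_store)
    seg_posts = [
        SegmentPosterior(
            ptt=sd.reg.ptt,
            segment_label=sd.reg.segment_label,
            step_hours=sd.reg.step_hours,
            origin=sd.reg.origin,
            state_times=sd.reg.state_times,
            b_samples=b_store[si],
            x_samples=x_store[si] if x_store is not None else None,
        )
        for si, sd in enumerate(data)
    ]
    return PosteriorFit(
        params=par_store,
        segments=seg_posts,
        diagnostics=diagnostics,
        config={"mcmc": asdict(mcmc), "priors": asdict(priors)},
    )


def _diagnostics(par_store: dict[str, np.ndarray]) -> dict:
    import arviz as az

    rhat, ess = {}, {}
    for name, arr in par_store.items():
        rhat[name] = float(az.rhat(arr.copy()))
        ess[name] = float(az.ess(arr.copy()))
    return {"rhat": rhat, "ess": ess, "converged": all(v < 1.1 for v in rhat.values())}
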