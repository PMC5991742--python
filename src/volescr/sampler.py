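"""Bayesian inference for the SCR model by data augmentation.

The observed n capture histories are augmented to M potential individuals;
each has an inclusion flag z_i ~ Bernoulli(psi), a latent activity centre
s_i uniform on the state space, and a latent sex ~ Bernoulli(pi).
Population size is N = sum z, density D = N / area.  Updates are
Metropolis-within-Gibbs:

* detection coefficients and log-sigmas: random-walk Metropolis with
  proposal scales adapted to 25-45% acceptance during burn-in;
* activity centres: bivariate random-walk Metropolis constrained to the
  state space (uniform prior redraw for z=0 individuals), or exact Gibbs
  over an optional discrete centre grid;
* z, psi, pi, latent sexes: Gibbs from their full conditionals;
* Kuo-Mallick indicators (model-selection mode): Gibbs with
  Bernoulli(0.5) prior; a coefficient whose indicator is off is refreshed
  from its N(0, slab_variance) prior so the chain mixes over models.

Dead-in-trap individuals are excluded from the likelihood after their
removal occasion throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from volescr.data import (NOT_CAPTURED, EncounterData, StateSpace, TrapArray,
                          prior_capture_matrix)
from volescr.detection import (DetectionParams, IndicatorConfig,
                               standardized_occasions)

SELECT = "select"

#: default augmentation head-room rule: see ScrModelSpec.resolve_M
_M_DENSITY_CAP = 200.0  # individuals/ha, generous ceiling for vole densities


@dataclass
class ScrModelSpec:
    """MCMC configuration for one SCR fit."""

    M: int | None = None          # augmentation size; None = automatic
    cfg: IndicatorConfig | str = field(default_factory=IndicatorConfig)
    slab_variance: float = 10.0   # prior variance of detection coefficients
    sigma_prior_upper: float = 25.0  # metres; Uniform(0, upper) prior
    n_chains: int = 3
    n_iter: int = 150_000
    burn_in: int = 5_000
    thin: int = 1
    seed: int = 0
    centre_grid: np.ndarray | None = None   # optional discrete support
    update_detection: bool = True           # False freezes DetectionParams
    init_params: DetectionParams | None = None
    save_centres_every: int = 50            # thinning of centre draws
    select_sex_sigma: int = 1  # sigma structure held fixed in select mode
    link: str = "mlogit"

    def __post_init__(self) -> None:
        if self.slab_variance <= 0:
            raise ValueError("slab_variance must be positive")
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")

    @property
    def select_mode(self) -> bool:
        return isinstance(self.cfg, str) and self.cfg == SELECT

    def resolve_M(self, n: int, area_ha: float) -> int:
        if self.M is not None:
            if self.M < n:
                raise ValueError("augmentation size M must be >= observed n")
            return self.M
        return max(3 * n, int(np.ceil(1.5 * area_ha * _M_DENSITY_CAP)))


@dataclass
class PosteriorChains:
    """Retained MCMC draws plus bookkeeping.

    ``draws[name]`` has shape (n_chains, n_draws).  Scalar parameters:
    alpha0_f, alpha0_m, alpha_time, alpha_behav, sigma_f, sigma_m, psi,
    pi, N, D and (in selection mode) w_time, w_behav, w_sex.
    """

    draws: dict[str, np.ndarray]
    centres: np.ndarray      # (n_chains, n_saved, M, 2)
    z_saved: np.ndarray      # (n_chains, n_saved, M)
    area_ha: float
    M: int
    n_observed: int
    spec: ScrModelSpec
    accept_rates: dict[str, float]

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        cols = {"chain": np.repeat(np.arange(self.n_chains), self.n_draws)}
        for k, v in self.draws.items():
            cols[k] = v.reshape(-1)
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# core chain

class _ChainState:
    """Mutable sampler state for one chain (vectorised over individuals)."""

    def __init__(self, y, sex_known, alive, C, traps, space, spec,
                 rng, init: DetectionParams):
        self.rng = rng
        self.y = y
        self.M, self.K = y.shape
        self.J = traps.n_detectors
        self.trapxy = traps.coords
        self.space = space
        self.spec = spec
        self.alive = alive
        self.C = C
        self.caught = y != NOT_CAPTURED
        self.observed = self.caught.any(axis=1)
        self.tz = standardized_occasions(self.K)
        self.sex_known = sex_known

        cfg = spec.cfg if not spec.select_mode else \
            IndicatorConfig(1, 1, 1, spec.select_sex_sigma)
        self.sex_sigma = bool(cfg.sex_sigma)
        # active indicator state
        if spec.select_mode:
            self.w = {"t": 1, "b": 1, "s": 1}
            self.selecting = True
        else:
            self.w = {"t": cfg.w_time, "b": cfg.w_behav, "s": cfg.w_sex}
            self.selecting = False

        # parameters
        self.a0 = init.alpha0_f
        self.b_sex = init.alpha0_m - init.alpha0_f
        self.a_t = init.alpha_time
        self.a_b = init.alpha_behav
        self.lsig = np.log([init.sigma_f, init.sigma_m])  # [female, male]
        self.psi = 0.5
        self.pi = 0.5

        # latents
        self.sex = np.where(sex_known >= 0, sex_known,
                            rng.integers(0, 2, self.M))
        self.z = np.where(self.observed, 1,
                          rng.integers(0, 2, self.M))
        self.grid = spec.centre_grid
        if self.grid is not None:
            self.grid = np.asarray(self.grid, dtype=float)
            self.grid_d2 = ((self.grid[:, None, :] -
                             self.trapxy[None, :, :]) ** 2).sum(axis=2)
            self.s_idx = rng.integers(0, len(self.grid), self.M)
            # start observed individuals at the grid point nearest their
            # mean capture location
            for i in np.flatnonzero(self.observed):
                c = self.trapxy[y[i][self.caught[i]]].mean(axis=0)
                self.s_idx[i] = np.argmin(((self.grid - c) ** 2).sum(axis=1))
            self.s = self.grid[self.s_idx]
        else:
            self.s = np.column_stack([
                rng.uniform(space.xmin, space.xmax, self.M),
                rng.uniform(space.ymin, space.ymax, self.M)])
            for i in np.flatnonzero(self.observed):
                c = self.trapxy[y[i][self.caught[i]]].mean(axis=0)
                self.s[i] = c + rng.normal(0, 1.0, 2)
        self._llcache = None
        self._refresh_distance()
        self._refresh_sig2()
        self._refresh_G()

        # proposal scales (adapted during burn-in)
        self.step = {"a0": 0.2, "b_sex": 0.3, "a_t": 0.1, "a_b": 0.3,
                     "lsig_f": 0.1, "lsig_m": 0.1,
                     "s": max(1.0, float(np.exp(self.lsig).mean()))}
        self.acc = {k: 0 for k in self.step}
        self.tries = {k: 0 for k in self.step}

    # -- cached geometry ----------------------------------------------------
    def _d2_of(self, s: np.ndarray) -> np.ndarray:
        dx = s[:, 0][:, None] - self.trapxy[:, 0][None, :]
        dy = s[:, 1][:, None] - self.trapxy[:, 1][None, :]
        return dx * dx + dy * dy

    def _refresh_distance(self) -> None:
        self.d2 = self._d2_of(self.s)
        self.d2obs = np.zeros((self.M, self.K))
        ii, kk = np.nonzero(self.caught)
        self.d2obs[ii, kk] = self.d2[ii, self.y[ii, kk]]

    def _sig2_pair(self) -> tuple[float, float]:
        sf, sm = np.exp(self.lsig)
        if not self.sex_sigma:
            sm = sf
        return sf * sf, sm * sm

    def _refresh_sig2(self) -> None:
        """Per-individual sigma^2 under each individual's current sex."""
        s2f, s2m = self._sig2_pair()
        self.sig2 = np.where(self.sex == 1, s2m, s2f)

    def _refresh_G(self) -> None:
        """Kernel sum over traps per individual, at its current sex's
        sigma.  Cross-sex values are computed on demand in the sex
        update."""
        self.G = np.exp(-self.d2 / (2 * self.sig2[:, None])).sum(axis=1)

    # -- likelihood ---------------------------------------------------------
    def _ll_i(self, a0=None, b_sex=None, a_t=None, a_b=None, w=None,
              sex=None, G=None, sig2=None, d2obs=None) -> np.ndarray:
        if (a0 is None and b_sex is None and a_t is None and a_b is None
                and w is None and sex is None and G is None and sig2 is None
                and d2obs is None):
            if self._llcache is None:
                self._llcache = self._ll_i_raw()
            return self._llcache
        return self._ll_i_raw(a0, b_sex, a_t, a_b, w, sex, G, sig2, d2obs)

    def _ll_i_raw(self, a0=None, b_sex=None, a_t=None, a_b=None, w=None,
                  sex=None, G=None, sig2=None, d2obs=None) -> np.ndarray:
        """Per-individual log-likelihood of the capture history given
        inclusion (z=1); callers mask by z.  ``G`` and ``sig2`` must be
        consistent with ``sex``."""
        a0 = self.a0 if a0 is None else a0
        b_sex = self.b_sex if b_sex is None else b_sex
        a_t = self.a_t if a_t is None else a_t
        a_b = self.a_b if a_b is None else a_b
        w = self.w if w is None else w
        sex = self.sex if sex is None else sex
        G = self.G if G is None else G
        sig2 = self.sig2 if sig2 is None else sig2
        d2obs = self.d2obs if d2obs is None else d2obs
        lp = (a0 + w["s"] * b_sex * (sex == 1)[:, None]
              + w["t"] * a_t * self.tz[None, :]
              + w["b"] * a_b * self.C)
        ll = np.where(self.caught,
                      lp - d2obs / (2.0 * sig2[:, None]), 0.0) \
            - np.log1p(np.exp(lp) * G[:, None])
        return np.where(self.alive, ll, 0.0).sum(axis=1)

    def total_ll(self, **kw) -> float:
        return float((self._ll_i(**kw) * (self.z == 1)).sum())

    def _ll_rows(self, rows: np.ndarray, sex_rows: np.ndarray,
                 G_rows: np.ndarray, sig2_rows: np.ndarray) -> np.ndarray:
        """Row-restricted capture-history log-likelihood (for sex flips)."""
        lp = (self.a0 + self.w["s"] * self.b_sex * (sex_rows == 1)[:, None]
              + self.w["t"] * self.a_t * self.tz[None, :]
              + self.w["b"] * self.a_b * self.C[rows])
        ll = np.where(self.caught[rows],
                      lp - self.d2obs[rows] / (2.0 * sig2_rows[:, None]),
                      0.0) - np.log1p(np.exp(lp) * G_rows[:, None])
        return np.where(self.alive[rows], ll, 0.0).sum(axis=1)

    # -- Metropolis helpers -------------------------------------------------
    def _mh_coef(self, name: str, value: float, proposal_set,
                 prior_var: float) -> float:
        """Random-walk Metropolis on one scalar coefficient with a
        N(0, prior_var) prior."""
        self.tries[name] += 1
        prop = value + self.rng.normal(0, self.step[name])
        cur = self.total_ll()
        new = self.total_ll(**{proposal_set: prop})
        logr = new - cur - (prop * prop - value * value) / (2 * prior_var)
        if np.log(self.rng.uniform()) < logr:
            self.acc[name] += 1
            self._llcache = None
            return prop
        return value

    def update_coefficients(self) -> None:
        sv = self.spec.slab_variance
        self.a0 = self._mh_coef("a0", self.a0, "a0", sv)
        if self.w["s"]:
            self.b_sex = self._mh_coef("b_sex", self.b_sex, "b_sex", sv)
        elif self.selecting:
            self.b_sex = self.rng.normal(0, np.sqrt(sv))
            self._llcache = None
        if self.w["t"]:
            self.a_t = self._mh_coef("a_t", self.a_t, "a_t", sv)
        elif self.selecting:
            self.a_t = self.rng.normal(0, np.sqrt(sv))
            self._llcache = None
        if self.w["b"]:
            self.a_b = self._mh_coef("a_b", self.a_b, "a_b", sv)
        elif self.selecting:
            self.a_b = self.rng.normal(0, np.sqrt(sv))
            self._llcache = None

    def update_indicators(self) -> None:
        for key in ("t", "b", "s"):
            w0 = dict(self.w); w0[key] = 0
            w1 = dict(self.w); w1[key] = 1
            ll0 = self.total_ll(w=w0)
            ll1 = self.total_ll(w=w1)
            # Bernoulli(0.5) prior cancels
            p1 = float(expit(ll1 - ll0))
            new = int(self.rng.uniform() < p1)
            if new != self.w[key]:
                self.w[key] = new
                self._llcache = None

    def update_sigmas(self) -> None:
        upper = self.spec.sigma_prior_upper
        names = ("lsig_f", "lsig_m") if self.sex_sigma else ("lsig_f",)
        for idx, name in enumerate(names):
            self.tries[name] += 1
            prop = self.lsig.copy()
            prop[idx] += self.rng.normal(0, self.step[name])
            if not self.sex_sigma:
                prop[1] = prop[0]
            sig_new = np.exp(prop[idx])
            if sig_new <= 0 or sig_new >= upper:
                continue
            # only rows of this sex enter the likelihood ratio
            rows = np.flatnonzero(self.sex == idx) if self.sex_sigma \
                else np.arange(self.M)
            if rows.size == 0:
                self.lsig = prop
                continue
            G_rows = np.exp(-self.d2[rows] /
                            (2 * sig_new * sig_new)).sum(axis=1)
            s2_rows = np.full(rows.size, sig_new * sig_new)
            sex_rows = self.sex[rows]
            cur = self._ll_rows(rows, sex_rows, self.G[rows],
                                self.sig2[rows])
            new = self._ll_rows(rows, sex_rows, G_rows, s2_rows)
            zr = self.z[rows] == 1
            # Uniform(0, upper) prior on sigma; log-scale walk Jacobian
            logr = float(((new - cur) * zr).sum()) \
                + (prop[idx] - self.lsig[idx])
            if np.log(self.rng.uniform()) < logr:
                self.acc[name] += 1
                self.lsig = prop
                self.G[rows] = G_rows
                self.sig2[rows] = s2_rows
                self._llcache = None

    def update_centres(self) -> None:
        if self.grid is not None:
            self._update_centres_grid()
            return
        sp = self.space
        zmask = self.z == 1
        self.tries["s"] += int(zmask.sum())
        prop = self.s + self.rng.normal(0, self.step["s"], (self.M, 2))
        inside = sp.contains(prop)
        # z=0 individuals: Gibbs draw from the uniform prior
        free = ~zmask
        nfree = int(free.sum())
        if nfree:
            prop[free, 0] = self.rng.uniform(sp.xmin, sp.xmax, nfree)
            prop[free, 1] = self.rng.uniform(sp.ymin, sp.ymax, nfree)
        d2p = self._d2_of(prop)
        Gp = np.exp(-d2p / (2 * self.sig2[:, None])).sum(axis=1)
        d2obs_p = np.zeros((self.M, self.K))
        ii, kk = np.nonzero(self.caught)
        d2obs_p[ii, kk] = d2p[ii, self.y[ii, kk]]
        cur = self._ll_i()
        new = self._ll_i(G=Gp, d2obs=d2obs_p)
        accept = (np.log(self.rng.uniform(size=self.M)) < new - cur) \
            & inside & zmask
        accept |= free
        self.acc["s"] += int((accept & zmask).sum())
        rows = np.flatnonzero(accept)
        if rows.size:
            self.s[rows] = prop[rows]
            self.d2[rows] = d2p[rows]
            self.d2obs[rows] = d2obs_p[rows]
            self.G[rows] = Gp[rows]
            self._llcache = None

    def _update_centres_grid(self) -> None:
        """Exact Gibbs over the discrete centre grid."""
        s2f, s2m = self._sig2_pair()
        Gg_f = np.exp(-self.grid_d2 / (2 * s2f)).sum(axis=1)
        Gg_m = np.exp(-self.grid_d2 / (2 * s2m)).sum(axis=1) \
            if self.sex_sigma else Gg_f
        sex1 = self.sex == 1
        for i in range(self.M):
            if self.z[i] == 0:
                self.s_idx[i] = self.rng.integers(0, len(self.grid))
                continue
            sig2 = s2m if sex1[i] else s2f
            G = Gg_m if sex1[i] else Gg_f
            lp = (self.a0 + self.w["s"] * self.b_sex * sex1[i]
                  + self.w["t"] * self.a_t * self.tz
                  + self.w["b"] * self.a_b * self.C[i])      # (K,)
            alive = self.alive[i]
            lg = np.zeros((len(self.grid), self.K))
            kmask = self.caught[i]
            if kmask.any():
                lg[:, kmask] = -self.grid_d2[:, self.y[i, kmask]] / (2 * sig2)
            ll = np.where(kmask[None, :], lp[None, :] + lg, 0.0) \
                - np.log1p(np.exp(lp)[None, :] * G[:, None])
            lli = np.where(alive[None, :], ll, 0.0).sum(axis=1)
            p = np.exp(lli - lli.max())
            p /= p.sum()
            self.s_idx[i] = self.rng.choice(len(self.grid), p=p)
        self.s = self.grid[self.s_idx]
        self._refresh_distance()
        self._refresh_sig2()
        self._refresh_G()
        self._llcache = None

    def update_z_psi(self) -> None:
        # log-probability of an all-empty history for each individual
        ll0 = self._ll_empty()
        aug = ~self.observed
        num = self.psi * np.exp(ll0[aug])
        p = num / (num + 1.0 - self.psi)
        self.z[aug] = self.rng.uniform(size=int(aug.sum())) < p
        nz = int(self.z.sum())
        self.psi = self.rng.beta(1 + nz, 1 + self.M - nz)

    def _ll_empty(self) -> np.ndarray:
        """log P(no captures in any alive occasion | s, params)."""
        lp = (self.a0 + self.w["s"] * self.b_sex
              * (self.sex == 1)[:, None]
              + self.w["t"] * self.a_t * self.tz[None, :])
        # C = 0 for a never-captured history, so no behaviour term
        ll = -np.log1p(np.exp(lp) * self.G[:, None])
        return np.where(self.alive, ll, 0.0).sum(axis=1)

    def update_sexes_pi(self) -> None:
        unknown = self.sex_known < 0
        if unknown.any():
            s2f, s2m = self._sig2_pair()
            zmask = self.z == 1
            upd = np.flatnonzero(unknown & zmask)
            if upd.size:
                if self.sex_sigma:
                    G_f = np.exp(-self.d2[upd] / (2 * s2f)).sum(axis=1)
                    G_m = np.exp(-self.d2[upd] / (2 * s2m)).sum(axis=1)
                else:
                    G_f = G_m = self.G[upd]
                ll_f = self._ll_rows(upd, np.zeros(upd.size, dtype=int),
                                     G_f, np.full(upd.size, s2f))
                ll_m = self._ll_rows(upd, np.ones(upd.size, dtype=int),
                                     G_m, np.full(upd.size, s2m))
                top = np.maximum(ll_f, ll_m)
                num = self.pi * np.exp(ll_m - top)
                den = num + (1 - self.pi) * np.exp(ll_f - top)
                male = self.rng.uniform(size=upd.size) < num / den
                self.sex[upd] = male
                self.sig2[upd] = np.where(male, s2m, s2f)
                self.G[upd] = np.where(male, G_m, G_f)
                self._llcache = None
            prior = np.flatnonzero(unknown & ~zmask)
            if prior.size:
                old = self.sex[prior].copy()
                new = (self.rng.uniform(size=prior.size)
                       < self.pi).astype(int)
                self.sex[prior] = new
                if self.sex_sigma:
                    flip = prior[new != old]
                    if flip.size:
                        self.sig2[flip] = np.where(new[new != old] == 1,
                                                   s2m, s2f)
                        self.G[flip] = np.exp(
                            -self.d2[flip] /
                            (2 * self.sig2[flip][:, None])).sum(axis=1)
        nm = int(self.sex.sum())
        self.pi = self.rng.beta(1 + nm, 1 + self.M - nm)

    def adapt(self) -> None:
        for name in self.step:
            if self.tries[name] == 0:
                continue
            rate = self.acc[name] / self.tries[name]
            if rate > 0.45:
                self.step[name] *= 1.15
            elif rate < 0.25:
                self.step[name] /= 1.15
            self.acc[name] = 0
            self.tries[name] = 0

    def iterate(self, adapt: bool) -> None:
        if self.spec.update_detection:
            self.update_coefficients()
            if self.selecting:
                self.update_indicators()
            self.update_sigmas()
        self.update_centres()
        self.update_z_psi()
        self.update_sexes_pi()
        if adapt:
            self._adapt_counter = getattr(self, "_adapt_counter", 0) + 1
            if self._adapt_counter % 50 == 0:
                self.adapt()


def _augment(data: EncounterData, M: int):
    n, K = data.n, data.K
    y = np.full((M, K), NOT_CAPTURED, dtype=int)
    y[:n] = data.y
    sex_known = np.full(M, -1, dtype=int)
    sex_known[:n] = data.sex
    alive = np.ones((M, K), dtype=bool)
    for i in range(n):
        r = data.removal_occasion[i]
        if r >= 0:
            alive[i, r + 1:] = False
    C = prior_capture_matrix(y)
    return y, sex_known, alive, C


def run_mcmc(data: EncounterData, traps: TrapArray, space: StateSpace,
             spec: ScrModelSpec) -> PosteriorChains:
    """Run the data-augmentation sampler; returns retained draws."""
    M = spec.resolve_M(data.n, space.area_ha)
    y, sex_known, alive, C = _augment(data, M)
    n_store = (spec.n_iter - spec.burn_in) // spec.thin
    if n_store < 1:
        raise ValueError("no retained draws with these MCMC settings")
    names = ["alpha0_f", "alpha0_m", "alpha_time", "alpha_behav",
             "sigma_f", "sigma_m", "psi", "pi", "N", "D",
             "w_time", "w_behav", "w_sex"]
    draws = {k: np.empty((spec.n_chains, n_store)) for k in names}
    n_saved = max(1, n_store // max(1, spec.save_centres_every))
    centres = np.empty((spec.n_chains, n_saved, M, 2))
    z_saved = np.empty((spec.n_chains, n_saved, M), dtype=np.int8)
    accept: dict[str, float] = {}

    for c in range(spec.n_chains):
        rng = np.random.default_rng([int(spec.seed) % (2 ** 31), c])
        init = spec.init_params or DetectionParams(
            alpha0_f=-2.0 + rng.normal(0, 0.5),
            alpha0_m=-2.0 + rng.normal(0, 0.5),
            alpha_time=rng.normal(0, 0.2),
            alpha_behav=rng.normal(0, 0.2),
            sigma_f=float(np.clip(rng.uniform(3, 10), 0.1,
                                  spec.sigma_prior_upper * 0.9)),
            sigma_m=float(np.clip(rng.uniform(3, 10), 0.1,
                                  spec.sigma_prior_upper * 0.9)))
        st = _ChainState(y, sex_known, alive, C, traps, space, spec, rng,
                         init)
        ll0 = st.total_ll()
        if not np.isfinite(ll0):
            raise RuntimeError(
                f"non-finite log-likelihood at initialization (chain {c}): "
                f"check trap coordinates, state space and starting values")
        row = 0
        save_row = 0
        for it in range(spec.n_iter):
            st.iterate(adapt=it < spec.burn_in)
            if it < spec.burn_in or (it - spec.burn_in) % spec.thin:
                continue
            if row < n_store:
                sf, sm = np.exp(st.lsig)
                a0f = st.a0
                a0m = st.a0 + st.w["s"] * st.b_sex
                N = int(st.z.sum())
                draws["alpha0_f"][c, row] = a0f
                draws["alpha0_m"][c, row] = a0m
                draws["alpha_time"][c, row] = st.w["t"] * st.a_t
                draws["alpha_behav"][c, row] = st.w["b"] * st.a_b
                draws["sigma_f"][c, row] = sf
                draws["sigma_m"][c, row] = sm if st.sex_sigma else sf
                draws["psi"][c, row] = st.psi
                draws["pi"][c, row] = st.pi
                draws["N"][c, row] = N
                draws["D"][c, row] = N / space.area_ha
                draws["w_time"][c, row] = st.w["t"]
                draws["w_behav"][c, row] = st.w["b"]
                draws["w_sex"][c, row] = st.w["s"]
                if row % max(1, spec.save_centres_every) == 0 \
                        and save_row < n_saved:
                    centres[c, save_row] = st.s
                    z_saved[c, save_row] = st.z
                    save_row += 1
                row += 1
        while save_row < n_saved:   # pad if thinning did not fill
            centres[c, save_row] = st.s
            z_saved[c, save_row] = st.z
            save_row += 1
        for k in st.step:
            tr = st.tries[k]
            accept[f"chain{c}:{k}"] = st.acc[k] / tr if tr else np.nan

    chains = PosteriorChains(draws=draws, centres=centres, z_saved=z_saved,
                             area_ha=space.area_ha, M=M, n_observed=data.n,
                             spec=spec, accept_rates=accept)
    if chains.stacked("psi").mean() > 0.8:
        warnings.warn(
            "posterior psi > 0.8: augmentation size M may be too small; "
            "N estimates can be truncated", RuntimeWarning)
    return chains


# ---------------------------------------------------------------------------
# diagnostics and summaries

def gelman_rubin(chains, parameter: str | None = None) -> float:
    """Potential scale reduction factor (R-hat).

    Accepts either a (n_chains, n_draws) array or a PosteriorChains plus a
    parameter name.  Uses the classic between/within-chain variance
    formula: R-hat = sqrt(((n-1)/n * W + B/n) / W).
    """
    if isinstance(chains, PosteriorChains):
        if parameter is None:
            raise ValueError("parameter name required with PosteriorChains")
        x = chains.draws[parameter]
    else:
        x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains")
    m, n = x.shape
    if n < 10:
        raise ValueError("need >= 10 draws per chain")
    means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


_SUMMARY_PARAMS = ["D", "D.females", "D.males", "alpha0_f", "alpha0_m",
                   "alpha_time", "alpha_behav", "pi", "psi",
                   "sigma_f", "sigma_m", "N"]


def summarize(chains: PosteriorChains,
              parameters: list[str] | None = None) -> pd.DataFrame:
    """Posterior summary table: Mean, SD, 2.5/50/97.5% quantiles, R-hat.

    Adds the derived density rows D.females = D*(1-pi) and
    D.males = D*pi computed draw-wise.
    """
    if chains.n_draws == 0:
        raise ValueError("empty chains")
    parameters = parameters or _SUMMARY_PARAMS
    rows = []
    for name in parameters:
        if name == "D.females":
            x = chains.draws["D"] * (1 - chains.draws["pi"])
        elif name == "D.males":
            x = chains.draws["D"] * chains.draws["pi"]
        else:
            x = chains.draws[name]
        flat = x.reshape(-1)
        q = np.percentile(flat, [2.5, 50, 97.5])
        rhat = gelman_rubin(x) if (x.shape[0] >= 2 and x.shape[1] >= 10) \
            else np.nan
        rows.append({"parameter": name, "Mean": flat.mean(),
                     "SD": flat.std(ddof=1) if flat.size > 1 else 0.0,
                     "2.50%": q[0], "50%": q[1], "97.50%": q[2],
                     "Rhat": rhat})
    return pd.DataFrame(rows).set_index("parameter")


def model_weights(chains: PosteriorChains) -> pd.DataFrame:
    """Posterior model weights over the 2^3 detection-covariate models.

    Relative frequency of each (w_time, w_behav, w_sex) indicator state
    among retained draws; only defined for selection-mode runs.
    """
    if not chains.spec.select_mode:
        raise ValueError("model weights require a selection-mode run "
                         "(cfg='select')")
    wt = chains.stacked("w_time").astype(int)
    wb = chains.stacked("w_behav").astype(int)
    ws = chains.stacked("w_sex").astype(int)
    total = len(wt)
    rows = []
    for t in (0, 1):
        for b in (0, 1):
            for s in (0, 1):
                count = int(((wt == t) & (wb == b) & (ws == s)).sum())
                rows.append({"w_time": t, "w_behav": b, "w_sex": s,
                             "weight": count / total})
    return pd.DataFrame(rows).sort_values("weight",
                                          ascending=False,
                                          ignore_index=True)


def density_surface(chains: PosteriorChains,
                    space: StateSpace) -> pd.DataFrame:
    """Posterior mean density of activity centres per pixel.

    Returns a DataFrame with columns x, y (pixel centres) and density in
    individuals per 100 m^2.  The surface integrates (density * pixel
    area / 100 summed over pixels) to the posterior mean N of the saved
    draws.
    """
    nx, ny = space.nx, space.ny
    xedges = np.linspace(space.xmin, space.xmax, nx + 1)
    yedges = np.linspace(space.ymin, space.ymax, ny + 1)
    counts = np.zeros((nx, ny))
    n_draws = 0
    for c in range(chains.centres.shape[0]):
        for d in range(chains.centres.shape[1]):
            keep = chains.z_saved[c, d] == 1
            pts = chains.centres[c, d][keep]
            h, _, _ = np.histogram2d(pts[:, 0], pts[:, 1],
                                     bins=[xedges, yedges])
            counts += h
            n_draws += 1
    mean_count = counts / n_draws
    dens = mean_count / space.pixel_area * 100.0
    centres = space.pixel_centres()
    return pd.DataFrame({"x": centres[:, 0], "y": centres[:, 1],
                         "density": dens.ravel()})


def surface_total(surface: pd.DataFrame, space: StateSpace) -> float:
    """Integrate a density surface back to an abundance."""
    return float(surface["density"].sum() * space.pixel_area / 100.0)


def home_range_area(sigma: float, q: float = 5.99) -> float:
    """Circular home-range area pi * q * sigma^2 in m^2.

    The default q = 5.99 is the 95% quantile of a chi-square with 2
    degrees of freedom, so the circle of radius sigma * sqrt(q) (about
    2.45 sigma) contains 95% of a bivariate-normal utilisation
    distribution with scale sigma.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(np.pi * q * sigma * sigma)
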