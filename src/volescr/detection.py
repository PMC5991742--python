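"""Encounter model: half-normal detection, covariate structure, multinomial
cell probabilities and the full-data log-likelihood.

The encounter process is a multinomial over the J traps plus a
"not captured" cell.  Baseline detection is modelled on the logit scale,

    lp[i,k] = alpha0(sex_i) + w_t * alpha_time * z(k) + w_b * alpha_behav * C[i,k]

with z(k) the occasion index standardized to mean 0, variance 1, and
C[i,k] the prior-capture indicator.  The trap-specific hazard is
h_j = exp(lp) * exp(-d_j^2 / (2 sigma^2)); under the default
multinomial-logit (conditional-logit) link the probability of capture in
trap j is h_j / (1 + sum h) and of escaping capture 1 / (1 + sum h).
For a single trap at distance zero this reduces exactly to
p = logit^-1(lp), which is how lp is interpreted as logit(p0).  A
competing-hazard alternative ((h_j / sum h) * (1 - exp(-sum h))) is
available via ``link="hazard"``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from volescr.data import NOT_CAPTURED, TrapArray

MULTINOMIAL_LOGIT = "mlogit"
COMPETING_HAZARD = "hazard"


@dataclass
class DetectionParams:
    """Detection parameters on the logit / metre scale.

    When the sex effect on baseline detection is off, ``alpha0_f`` is used
    for both sexes; likewise ``sigma_f`` when sex-specific sigma is off.
    """

    alpha0_f: float = -2.0
    alpha0_m: float = -2.0
    alpha_time: float = 0.0
    alpha_behav: float = 0.0
    sigma_f: float = 5.0
    sigma_m: float = 5.0

    def __post_init__(self) -> None:
        if self.sigma_f <= 0 or self.sigma_m <= 0:
            raise ValueError("sigma must be positive")
        for a in (self.alpha0_f, self.alpha0_m, self.alpha_time,
                  self.alpha_behav):
            if not np.isfinite(a):
                raise ValueError("alpha coefficients must be finite")

    def sigma_of(self, sex: np.ndarray, sex_sigma: bool) -> np.ndarray:
        """Per-individual sigma; unknown sex (-1) falls back to female."""
        if not sex_sigma:
            return np.full(np.shape(sex), self.sigma_f)
        return np.where(np.asarray(sex) == 1, self.sigma_m, self.sigma_f)

    def to_dict(self) -> dict[str, float]:
        """Flat key-value form for config files."""
        return {f.name: getattr(self, f.name)
                for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class IndicatorConfig:
    """Binary switches for the detection covariates and sigma structure."""

    w_time: int = 0
    w_behav: int = 0
    w_sex: int = 0
    sex_sigma: int = 0

    def __post_init__(self) -> None:
        for w in (self.w_time, self.w_behav, self.w_sex, self.sex_sigma):
            if w not in (0, 1):
                raise ValueError("indicators must be 0 or 1")


def standardized_occasions(K: int) -> np.ndarray:
    """Occasion covariate z(k): indices 1..K standardized to mean 0,
    variance 1 (population variance) across occasions."""
    k = np.arange(1, K + 1, dtype=float)
    if K == 1:
        return np.zeros(1)
    return (k - k.mean()) / k.std()


def halfnormal_kernel(d, sigma):
    """Half-normal distance decay exp(-d^2 / (2 sigma^2))."""
    sigma = np.asarray(sigma, dtype=float)
    if (sigma <= 0).any() if sigma.ndim else sigma <= 0:
        raise ValueError("sigma must be positive")
    d = np.asarray(d, dtype=float)
    return np.exp(-(d ** 2) / (2.0 * sigma ** 2))


def baseline_logit(params: DetectionParams, cfg: IndicatorConfig,
                   k, C_ik, sex_i, K: int | None = None,
                   z_k=None) -> np.ndarray:
    """logit(p0) for occasion(s) k (1-based), prior-capture state C_ik and
    sex.  ``z_k`` may supply a precomputed standardized-occasion vector;
    otherwise K is required to standardize k."""
    if z_k is None:
        if K is None:
            raise ValueError("pass K or a precomputed z_k")
        z_k = standardized_occasions(K)[np.asarray(k, dtype=int) - 1]
    a0 = np.where(np.asarray(sex_i) == 1,
                  params.alpha0_m if cfg.w_sex else params.alpha0_f,
                  params.alpha0_f)
    return (a0
            + cfg.w_time * params.alpha_time * np.asarray(z_k, dtype=float)
            + cfg.w_behav * params.alpha_behav * np.asarray(C_ik, dtype=float))


def logit_p0_matrix(params: DetectionParams, cfg: IndicatorConfig,
                    K: int, C: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """(n, K) matrix of logit(p0[i,k])."""
    z = standardized_occasions(K)
    a0 = np.where(sex == 1,
                  params.alpha0_m if cfg.w_sex else params.alpha0_f,
                  params.alpha0_f)
    return (a0[:, None]
            + cfg.w_time * params.alpha_time * z[None, :]
            + cfg.w_behav * params.alpha_behav * C)


def encounter_cell_probs(s, traps: TrapArray, lp: float, sigma: float,
                         link: str = MULTINOMIAL_LOGIT) -> np.ndarray:
    """Multinomial cell probabilities of one individual-occasion.

    Returns a vector of length J + 1: trap cells 0..J-1 followed by the
    "not captured" cell.  Cells sum to 1.
    """
    s = np.asarray(s, dtype=float)
    d = np.hypot(traps.x - s[0], traps.y - s[1])
    h = np.exp(lp) * halfnormal_kernel(d, sigma)
    H = h.sum()
    out = np.empty(traps.n_detectors + 1)
    if link == MULTINOMIAL_LOGIT:
        out[:-1] = h / (1.0 + H)
        out[-1] = 1.0 / (1.0 + H)
    elif link == COMPETING_HAZARD:
        pcap = -np.expm1(-H)
        out[:-1] = (h / H) * pcap if H > 0 else 0.0
        out[-1] = np.exp(-H)
    else:
        raise ValueError(f"unknown link {link!r}")
    return out


def log_likelihood(y: np.ndarray, traps: TrapArray, params: DetectionParams,
                   cfg: IndicatorConfig, z: np.ndarray, s: np.ndarray,
                   sex: np.ndarray, removal_occasion: np.ndarray | None = None,
                   C: np.ndarray | None = None,
                   link: str = MULTINOMIAL_LOGIT) -> float:
    """Full-data log-likelihood of an augmented capture history.

    Parameters
    ----------
    y : (M, K) detector indices, -1 for not captured (augmented rows all -1)
    z : (M,) inclusion flags; observed individuals must have z=1
    s : (M, 2) activity centres
    sex : (M,) 0/1 (latent sexes already imputed)
    removal_occasion : (M,) 0-based occasion after which an individual is
        dead, -1 if never; occasions after removal contribute nothing.
    C : optional precomputed prior-capture matrix.

    Individuals with z=0 contribute 0 (their all-empty history is
    structural); occasions after removal contribute 0.
    """
    y = np.asarray(y, dtype=int)
    M, K = y.shape
    z = np.asarray(z, dtype=int)
    observed = (y != NOT_CAPTURED).any(axis=1)
    if (observed & (z == 0)).any():
        raise ValueError("observed individual has z=0")
    if removal_occasion is None:
        removal_occasion = np.full(M, -1, dtype=int)
    if C is None:
        from volescr.data import prior_capture_matrix
        C = prior_capture_matrix(y)
    sex01 = np.where(np.asarray(sex) == 1, 1, 0)
    lp = logit_p0_matrix(params, cfg, K, C, sex01)
    sig = params.sigma_of(sex01, bool(cfg.sex_sigma))
    d2 = ((np.asarray(s, float)[:, None, :] - traps.coords[None, :, :]) ** 2
          ).sum(axis=2)                      # (M, J)
    g = np.exp(-d2 / (2.0 * sig[:, None] ** 2))
    G = g.sum(axis=1)                        # (M,)
    alive = np.ones((M, K), dtype=bool)
    for i in range(M):
        r = removal_occasion[i]
        if r >= 0:
            alive[i, r + 1:] = False
    caught = y != NOT_CAPTURED
    # log kernel at the observed trap
    logg_obs = np.zeros((M, K))
    ii, kk = np.nonzero(caught)
    logg_obs[ii, kk] = -d2[ii, y[ii, kk]] / (2.0 * sig[ii] ** 2)
    H = np.exp(lp) * G[:, None]
    if link == MULTINOMIAL_LOGIT:
        ll_ik = np.where(caught, lp + logg_obs, 0.0) - np.log1p(H)
    elif link == COMPETING_HAZARD:
        with np.errstate(divide="ignore", invalid="ignore"):
            log_cell = (lp + logg_obs - np.log(H)
                        + np.log(-np.expm1(-H)))
        ll_ik = np.where(caught, log_cell, -H)
    else:
        raise ValueError(f"unknown link {link!r}")
    mask = alive & (z == 1)[:, None]
    return float(np.where(mask, ll_ik, 0.0).sum())
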