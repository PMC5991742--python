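"""Synthetic trap arrays and capture histories.

Reconstructs the study's two vole trapping-grid geometries and generates
capture histories with the structure the SCR analysis assumes: activity
centres uniform on the buffered state space, sex-specific half-normal
detection, baseline detection varying over occasions on the logit scale,
an optional prior-capture behavioural effect, single-catch trap
competition, and rare deaths in traps.

Grid geometry.  The May array is a 7 x 10 lattice of nodes (12 m spacing
along x over 72 m, 15 m along y over 135 m; 70 nodes) with two paired
detectors per node (140 detectors).  The June array keeps one detector
per node and adds one detector at each of the 54 interior cell centres
(6 x 9), giving 124 detectors with nearest-neighbour distances of
sqrt(6^2 + 7.5^2) = 9.6 m as well as 12 and 15 m.  This layout is a
reconstruction from the published counts, extents and spacings, which it
matches exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from volescr.data import (NOT_CAPTURED, EncounterData, StateSpace, TrapArray)
from volescr.detection import (DetectionParams, IndicatorConfig,
                               halfnormal_kernel, standardized_occasions)

#: lattice constants shared by both grids (metres)
_NX, _NY = 7, 10
_DX, _DY = 12.0, 15.0


@dataclass
class TruePopulation:
    """Ground truth for one simulated population."""

    centres: np.ndarray        # (N, 2)
    sexes: np.ndarray          # (N,) 0 = female, 1 = male
    params: DetectionParams
    cfg: IndicatorConfig

    @property
    def N(self) -> int:
        return len(self.centres)


@dataclass
class SimOptions:
    """Capture-simulation controls."""

    K: int = 8
    capture_mode: str = "single_catch"   # or "multinomial"
    death_prob: float = 0.03             # per-capture trap mortality
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.death_prob < 1:
            raise ValueError("death_prob must be in [0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.capture_mode not in ("single_catch", "multinomial"):
            raise ValueError(f"unknown capture_mode {self.capture_mode!r}")


def _nodes() -> np.ndarray:
    gx, gy = np.meshgrid(_DX * np.arange(_NX), _DY * np.arange(_NY),
                         indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def may_grid() -> TrapArray:
    """The paired-trap design: 70 nodes, 2 detectors per node, 140 traps."""
    nodes = _nodes()
    ids, xs, ys, node_ids = [], [], [], []
    for n, (x, y) in enumerate(nodes, start=1):
        for pair in ("a", "b"):
            ids.append(f"N{n:02d}{pair}")
            xs.append(x)
            ys.append(y)
            node_ids.append(f"N{n:02d}")
    return TrapArray(np.array(ids, dtype=object), np.array(xs),
                     np.array(ys), np.array(node_ids, dtype=object))


def june_grid() -> TrapArray:
    """The densified single-trap design: 70 nodes + 54 cell centres = 124
    detectors, minimum spacing 9.6 m."""
    nodes = _nodes()
    cx, cy = np.meshgrid(_DX * (np.arange(_NX - 1) + 0.5),
                         _DY * (np.arange(_NY - 1) + 0.5), indexing="ij")
    centres = np.column_stack([cx.ravel(), cy.ravel()])
    pts = np.vstack([nodes, centres])
    ids = np.array([f"T{j + 1:03d}" for j in range(len(pts))], dtype=object)
    return TrapArray(ids, pts[:, 0], pts[:, 1], ids.copy())


def simulate_population(space: StateSpace, density_per_ha: float,
                        pi_male: float, params: DetectionParams,
                        seed: int | np.random.Generator = 0,
                        cfg: IndicatorConfig | None = None,
                        fixed_n: int | None = None) -> TruePopulation:
    """Draw a population of activity centres on the state space.

    N ~ Poisson(density * area) unless ``fixed_n`` is given; centres are
    iid uniform; sexes iid Bernoulli(pi_male).
    """
    if density_per_ha <= 0 and fixed_n is None:
        raise ValueError("density must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    N = fixed_n if fixed_n is not None else \
        int(rng.poisson(density_per_ha * space.area_ha))
    centres = np.column_stack([rng.uniform(space.xmin, space.xmax, N),
                               rng.uniform(space.ymin, space.ymax, N)])
    sexes = (rng.uniform(size=N) < pi_male).astype(int)
    return TruePopulation(centres, sexes, params,
                          cfg or IndicatorConfig(w_time=1, w_sex=1,
                                                 sex_sigma=1))


def simulate_captures(pop: TruePopulation, traps: TrapArray,
                      opts: SimOptions,
                      return_truth: bool = False):
    """Simulate a capture history over ``opts.K`` occasions.

    multinomial mode: each alive individual's occasion outcome is an
    independent draw from the multinomial encounter cells.

    single_catch mode: within an occasion each individual-trap pair gets
    a latent exponential arrival time with rate h_ij on a unit horizon;
    an individual commits to its earliest-arriving trap, a trap takes
    only its earliest arrival, and losers are released uncaptured.

    Each realized capture kills the individual with probability
    ``opts.death_prob`` (died in trap), fixing its removal occasion.
    Never-captured individuals are dropped from the returned data; with
    ``return_truth=True`` the boolean captured flag per true individual
    is returned alongside.
    """
    rng = np.random.default_rng(opts.seed)
    N, K, J = pop.N, opts.K, traps.n_detectors
    cfg, par = pop.cfg, pop.params
    node_groups = _node_groups(traps)
    tz = standardized_occasions(K)
    sig = par.sigma_of(pop.sexes, bool(cfg.sex_sigma))
    d = np.hypot(pop.centres[:, 0][:, None] - traps.x[None, :],
                 pop.centres[:, 1][:, None] - traps.y[None, :])
    kernel = halfnormal_kernel(d, sig[:, None])          # (N, J)
    a0 = np.where(pop.sexes == 1,
                  par.alpha0_m if cfg.w_sex else par.alpha0_f,
                  par.alpha0_f)

    y = np.full((N, K), NOT_CAPTURED, dtype=int)
    removal = np.full(N, -1, dtype=int)
    prior_cap = np.zeros(N, dtype=bool)
    alive = np.ones(N, dtype=bool)
    for k in range(K):
        lp = (a0 + cfg.w_time * par.alpha_time * tz[k]
              + cfg.w_behav * par.alpha_behav * prior_cap)
        h = np.exp(lp)[:, None] * kernel                 # (N, J)
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        if opts.capture_mode == "multinomial":
            H = h[idx].sum(axis=1)
            u = rng.uniform(size=idx.size) * (1.0 + H)
            cum = np.cumsum(h[idx], axis=1)
            for r, i in enumerate(idx):
                if u[r] < H[r]:
                    y[i, k] = int(np.searchsorted(cum[r], u[r], side="right"))
        else:
            caps = _single_catch_occasion(rng, h[idx], node_groups)
            for r, j in caps:
                y[idx[r], k] = j
        caught_now = np.flatnonzero(y[:, k] != NOT_CAPTURED)
        prior_cap[caught_now] = True
        died = caught_now[rng.uniform(size=caught_now.size)
                          < opts.death_prob]
        removal[died] = k
        alive[died] = False

    captured = (y != NOT_CAPTURED).any(axis=1)
    obs_idx = np.flatnonzero(captured)
    # order by first capture occasion (first appearance)
    first = np.array([np.flatnonzero(y[i] != NOT_CAPTURED)[0]
                      for i in obs_idx])
    obs_idx = obs_idx[np.argsort(first, kind="stable")]
    data = EncounterData(
        y[obs_idx], pop.sexes[obs_idx],
        np.where(removal[obs_idx] >= 0, removal[obs_idx], -1),
        individual_id=np.array([f"sim{i + 1}" for i in obs_idx],
                               dtype=object))
    if return_truth:
        return data, captured
    return data


def _node_groups(traps: TrapArray) -> list[np.ndarray]:
    """Detector indices grouped by node, preserving detector order."""
    groups: dict[str, list[int]] = {}
    for j, node in enumerate(traps.node_id):
        groups.setdefault(str(node), []).append(j)
    return [np.asarray(g) for g in groups.values()]


def _single_catch_occasion(rng: np.random.Generator, h: np.ndarray,
                           groups: list[np.ndarray]
                           ) -> list[tuple[int, int]]:
    """One occasion of single-catch competition.

    h is the (n_alive, J) per-detector hazard matrix.  An animal
    encounters trapping *nodes*: co-located paired detectors share one
    encounter process (a second box at the same point adds capture
    capacity, not attractiveness), so a node's arrival rate is its first
    detector's hazard and its capacity is its detector count.  Latent
    arrival times are exponential on a unit horizon; each individual
    commits to its earliest node, a node captures its earliest arrivals
    up to capacity (filling detectors in order), and losers are released
    uncaptured.  For one-detector nodes this is plain earliest-arrival
    single-catch competition.  Returns (row, detector) capture pairs.
    """
    n = h.shape[0]
    hn = h[:, [g[0] for g in groups]]      # (n, n_nodes)
    t = np.full(hn.shape, np.inf)
    pos = hn > 0
    with np.errstate(over="ignore"):
        t[pos] = rng.exponential(1.0, size=int(pos.sum())) / hn[pos]
    gstar = t.argmin(axis=1)
    tstar = t[np.arange(n), gstar]
    arrived = tstar < 1.0
    caps: list[tuple[int, int]] = []
    for g in np.unique(gstar[arrived]):
        rows = np.flatnonzero(arrived & (gstar == g))
        rows = rows[np.argsort(tstar[rows], kind="stable")]
        for slot, row in enumerate(rows[:len(groups[g])]):
            caps.append((int(row), int(groups[g][slot])))
    return caps


def write_truth(pop: TruePopulation, captured: np.ndarray, path) -> None:
    """Truth table for recovery scoring: individual, x, y, sex, captured."""
    pd.DataFrame({
        "individual": [f"sim{i + 1}" for i in range(pop.N)],
        "x": pop.centres[:, 0],
        "y": pop.centres[:, 1],
        "sex": np.where(pop.sexes == 1, "M", "F"),
        "captured_flag": captured.astype(int),
    }).to_csv(path, index=False)
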