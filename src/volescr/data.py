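"""Trap arrays, capture histories, state space and descriptive statistics.

Conventions: coordinates are Cartesian metres with the origin at the
south-west corner of the trap grid; occasions are 1-based in files and
reports, 0-based in arrays. Sex is coded 0 = female, 1 = male,
-1 = unknown (files use F/M/U).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEX_FEMALE = 0
SEX_MALE = 1
SEX_UNKNOWN = -1
NOT_CAPTURED = -1

_SEX_CODES = {"F": SEX_FEMALE, "M": SEX_MALE, "U": SEX_UNKNOWN}
_SEX_LABELS = {v: k for k, v in _SEX_CODES.items()}


@dataclass
class TrapArray:
    """A set of detectors (traps) with planar coordinates.

    Several detectors may share one node (paired traps at a grid point);
    they are distinct detectors with identical coordinates.
    """

    detector_id: np.ndarray  # str, shape (J,)
    x: np.ndarray            # metres, shape (J,)
    y: np.ndarray            # metres, shape (J,)
    node_id: np.ndarray      # str, shape (J,)

    def __post_init__(self) -> None:
        self.detector_id = np.asarray(self.detector_id, dtype=object)
        self.node_id = np.asarray(self.node_id, dtype=object)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len({len(self.detector_id), len(self.x), len(self.y),
                len(self.node_id)}) != 1:
            raise ValueError("trap fields must have equal length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("trap coordinates must be finite")
        ids, counts = np.unique(self.detector_id.astype(str),
                                return_counts=True)
        if (counts > 1).any():
            dup = ids[counts > 1][0]
            raise ValueError(f"duplicate detector id: {dup!r}")

    @property
    def n_detectors(self) -> int:
        return len(self.detector_id)

    @property
    def n_nodes(self) -> int:
        return len(np.unique(self.node_id.astype(str)))

    @property
    def coords(self) -> np.ndarray:
        """(J, 2) array of detector coordinates."""
        return np.column_stack([self.x, self.y])

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the detector positions."""
        return (float(self.x.min()), float(self.x.max()),
                float(self.y.min()), float(self.y.max()))

    def index_of(self, detector_ids) -> np.ndarray:
        """Map detector id strings to 0-based detector indices."""
        lookup = {str(d): j for j, d in enumerate(self.detector_id)}
        out = np.empty(len(detector_ids), dtype=int)
        for r, d in enumerate(detector_ids):
            try:
                out[r] = lookup[str(d)]
            except KeyError:
                raise ValueError(f"unknown detector id {d!r}") from None
        return out


@dataclass
class EncounterData:
    """Per-individual, per-occasion capture records.

    ``y[i, k]`` is the 0-based detector index of the capture of individual
    ``i`` on occasion ``k``, or -1 if not captured.  ``removal_occasion[i]``
    is the 0-based occasion after which the individual is dead (died in
    trap), or -1 if it survived the session.
    """

    y: np.ndarray                 # int, (n, K)
    sex: np.ndarray               # int in {0, 1, -1}, (n,)
    removal_occasion: np.ndarray  # int, (n,); -1 = never removed
    individual_id: np.ndarray | None = None  # optional labels, (n,)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        self.sex = np.asarray(self.sex, dtype=int)
        self.removal_occasion = np.asarray(self.removal_occasion, dtype=int)
        if self.y.ndim != 2:
            raise ValueError("y must be 2-D (individuals x occasions)")
        n = self.y.shape[0]
        if self.sex.shape != (n,) or self.removal_occasion.shape != (n,):
            raise ValueError("sex / removal_occasion length mismatch")
        if n and (self.y == NOT_CAPTURED).all(axis=1).any():
            raise ValueError("observed individual with no captures")
        for i in range(n):
            r = self.removal_occasion[i]
            if r >= 0 and (self.y[i, r + 1:] != NOT_CAPTURED).any():
                raise ValueError(
                    f"individual {i} captured after removal occasion {r + 1}")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def K(self) -> int:
        return self.y.shape[1]

    @property
    def n_captures(self) -> int:
        return int((self.y != NOT_CAPTURED).sum())


@dataclass
class StateSpace:
    """Buffered rectangle of candidate activity centres, with a pixel grid.

    The rectangle is the trap bounding box expanded by ``buffer`` on every
    side.  The pixel grid tiles the rectangle exactly: the requested
    ``pixel_side`` is shrunk per axis to the nearest exact divisor so the
    pixel areas sum to the total area.
    """

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    buffer: float
    pixel_side: float
    nx: int = field(init=False)
    ny: int = field(init=False)

    def __post_init__(self) -> None:
        w, h = self.width, self.height
        if w <= 0 or h <= 0:
            raise ValueError("state-space rectangle must have positive extent")
        if self.pixel_side <= 0:
            raise ValueError("pixel_side must be positive")
        self.nx = max(1, int(np.ceil(w / self.pixel_side)))
        self.ny = max(1, int(np.ceil(h / self.pixel_side)))

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        """Total area in m^2."""
        return self.width * self.height

    @property
    def area_ha(self) -> float:
        return self.area / 1e4

    @property
    def pixel_area(self) -> float:
        return (self.width / self.nx) * (self.height / self.ny)

    def pixel_centres(self) -> np.ndarray:
        """(nx * ny, 2) pixel-centre coordinates, row-major over x then y."""
        dx = self.width / self.nx
        dy = self.height / self.ny
        cx = self.xmin + dx * (np.arange(self.nx) + 0.5)
        cy = self.ymin + dy * (np.arange(self.ny) + 0.5)
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return ((pts[:, 0] >= self.xmin) & (pts[:, 0] <= self.xmax)
                & (pts[:, 1] >= self.ymin) & (pts[:, 1] <= self.ymax))


@dataclass
class SaturationReport:
    """Trap-occupancy percentages: global per occasion, optionally local
    per detector x occasion within a neighbourhood radius."""

    global_pct: np.ndarray             # (K,)
    local_pct: np.ndarray | None = None  # (J, K), NaN where no neighbours
    radius: float | None = None


# ---------------------------------------------------------------------------
# file I/O

def read_traps(path) -> TrapArray:
    """Read a trap-array CSV with header ``detector_id,x,y[,node_id]``."""
    df = pd.read_csv(path, dtype={"detector_id": str, "node_id": str})
    required = {"detector_id", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"traps file missing columns: {sorted(missing)}")
    for col in ("x", "y"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric {col} coordinate at row {row + 2}")
    node = df["node_id"] if "node_id" in df.columns else df["detector_id"]
    node = node.fillna(df["detector_id"])
    return TrapArray(df["detector_id"].to_numpy(dtype=object),
                     df["x"].to_numpy(dtype=float),
                     df["y"].to_numpy(dtype=float),
                     node.to_numpy(dtype=object))


def write_traps(traps: TrapArray, path) -> None:
    pd.DataFrame({
        "detector_id": traps.detector_id,
        "x": traps.x,
        "y": traps.y,
        "node_id": traps.node_id,
    }).to_csv(path, index=False)


def read_captures(path, traps: TrapArray, K: int) -> EncounterData:
    """Read a capture-history CSV.

    Expected header: ``individual_id,occasion,detector_id,sex,died`` with
    1-based occasions, sex in {F, M, U}, died in {0, 1}.  Individuals are
    ordered by first appearance in the file.
    """
    try:
        df = pd.read_csv(path,
                         dtype={"individual_id": str, "detector_id": str})
    except pd.errors.EmptyDataError:
        raise ValueError("no captures in file") from None
    required = {"individual_id", "occasion", "detector_id", "sex", "died"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"captures file missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("no captures in file")
    occ = df["occasion"].to_numpy(dtype=int)
    if ((occ < 1) | (occ > K)).any():
        raise ValueError(f"occasion outside 1..{K}")
    det = traps.index_of(df["detector_id"].to_numpy())

    order: dict[str, int] = {}
    for ind in df["individual_id"]:
        order.setdefault(ind, len(order))
    n = len(order)
    y = np.full((n, K), NOT_CAPTURED, dtype=int)
    sex = np.full(n, SEX_UNKNOWN, dtype=int)
    removal = np.full(n, -1, dtype=int)
    for r in range(len(df)):
        i = order[df["individual_id"].iloc[r]]
        k = occ[r] - 1
        if y[i, k] != NOT_CAPTURED:
            raise ValueError(
                f"individual {df['individual_id'].iloc[r]!r} captured twice "
                f"on occasion {k + 1}")
        y[i, k] = det[r]
        s = str(df["sex"].iloc[r]).upper()
        if s not in _SEX_CODES:
            raise ValueError(f"unknown sex code {s!r} at row {r + 2}")
        if sex[i] != SEX_UNKNOWN and _SEX_CODES[s] != SEX_UNKNOWN \
                and _SEX_CODES[s] != sex[i]:
            raise ValueError(
                f"conflicting sex for {df['individual_id'].iloc[r]!r}")
        if _SEX_CODES[s] != SEX_UNKNOWN:
            sex[i] = _SEX_CODES[s]
        if int(df["died"].iloc[r]):
            removal[i] = k
    for ind, i in order.items():
        r = removal[i]
        if r >= 0 and (y[i, r + 1:] != NOT_CAPTURED).any():
            raise ValueError(
                f"individual {ind!r} captured after dying on occasion {r + 1}")
    ids = np.array(sorted(order, key=order.get), dtype=object)
    return EncounterData(y, sex, removal, individual_id=ids)


def write_captures(data: EncounterData, traps: TrapArray, path) -> None:
    rows = []
    ids = (data.individual_id if data.individual_id is not None
           else np.array([f"ind{i + 1}" for i in range(data.n)], dtype=object))
    for i in range(data.n):
        for k in range(data.K):
            j = data.y[i, k]
            if j == NOT_CAPTURED:
                continue
            rows.append({
                "individual_id": ids[i],
                "occasion": k + 1,
                "detector_id": traps.detector_id[j],
                "sex": _SEX_LABELS[int(data.sex[i])],
                "died": int(data.removal_occasion[i] == k),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# descriptive statistics

def prior_capture_matrix(data_or_y) -> np.ndarray:
    """Binary matrix C with C[i, k] = 1 iff individual i was captured on
    some occasion before k.  C[:, 0] is all zero and rows are monotone
    non-decreasing; never-captured (augmented) rows are all zero."""
    y = data_or_y.y if isinstance(data_or_y, EncounterData) else \
        np.asarray(data_or_y, dtype=int)
    caught = (y != NOT_CAPTURED).astype(int)
    C = np.zeros_like(caught)
    if y.shape[1] > 1:
        C[:, 1:] = np.minimum(1, np.cumsum(caught[:, :-1], axis=1))
    return C


def captures_per_individual(freq: dict[int, int]) -> float:
    """Mean captures per individual from a capture-frequency distribution
    mapping number-of-captures -> number-of-individuals."""
    if not freq:
        raise ValueError("empty capture-frequency distribution")
    if any(c <= 0 or f < 0 for c, f in freq.items()):
        raise ValueError("counts must be positive")
    total = sum(c * f for c, f in freq.items())
    inds = sum(freq.values())
    if inds == 0:
        raise ValueError("no individuals in distribution")
    return total / inds


def capture_frequency(data: EncounterData) -> dict[int, int]:
    """Distribution of per-individual capture counts."""
    counts = (data.y != NOT_CAPTURED).sum(axis=1)
    vals, f = np.unique(counts, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, f) if v > 0}


def count_spatial_recaptures(data: EncounterData,
                             traps: TrapArray | None = None,
                             per_event: bool = False) -> int:
    """Number of spatial recaptures: individuals captured at more than
    one place, counted once per individual (the conventional SCR usage).

    When ``traps`` is given, "place" means trap node, so the two paired
    detectors sharing a node (and coordinates) do not produce a spatial
    recapture — a capture in both carries no movement information.
    Without ``traps``, distinct detector indices are used (equivalent
    whenever each node holds one detector).  With ``per_event=True``
    counts (distinct places - 1) summed over individuals.
    """
    if traps is not None:
        place = [str(n) for n in traps.node_id]
    total = 0
    for i in range(data.n):
        dets = set(data.y[i][data.y[i] != NOT_CAPTURED].tolist())
        places = {place[j] for j in dets} if traps is not None else dets
        if len(places) >= 2:
            total += (len(places) - 1) if per_event else 1
    return total


def trap_saturation(data: EncounterData, traps: TrapArray) -> SaturationReport:
    """Percent of detectors holding >= 1 capture, per occasion."""
    J = traps.n_detectors
    occupied = _occupancy(data, J)  # (J, K) boolean
    return SaturationReport(global_pct=100.0 * occupied.mean(axis=0))


def local_saturation(data: EncounterData, traps: TrapArray,
                     radius: float) -> SaturationReport:
    """Per-detector percent of neighbouring detectors (strictly within
    ``radius``) occupied, per occasion.  Detectors with no neighbours get
    NaN rows.  The radius of interest is ~2.5 sigma, the effective limit
    of detection around an activity centre."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    J = traps.n_detectors
    occupied = _occupancy(data, J).astype(float)  # (J, K)
    pts = traps.coords
    d = np.hypot(pts[:, 0][:, None] - pts[:, 0][None, :],
                 pts[:, 1][:, None] - pts[:, 1][None, :])
    neigh = (d < radius) & ~np.eye(J, dtype=bool)
    local = np.full((J, data.K), np.nan)
    nn = neigh.sum(axis=1)
    has = nn > 0
    local[has] = 100.0 * (neigh[has].astype(float) @ occupied) / \
        nn[has][:, None]
    return SaturationReport(global_pct=100.0 * occupied.mean(axis=0),
                            local_pct=local, radius=radius)


def _occupancy(data: EncounterData, J: int) -> np.ndarray:
    occ = np.zeros((J, data.K), dtype=bool)
    ii, kk = np.nonzero(data.y != NOT_CAPTURED)
    occ[data.y[ii, kk], kk] = True
    return occ


def build_state_space(traps: TrapArray, buffer: float,
                      pixel_side: float = 1.2) -> StateSpace:
    """Buffered rectangle around the trap bounding box.

    The buffer should be at least ~2.5 times the movement scale sigma so
    that every individual exposed to capture has its activity centre
    inside the state space.
    """
    if buffer <= 0:
        raise ValueError("buffer must be positive")
    xmin, xmax, ymin, ymax = traps.bounding_box()
    if xmax - xmin <= 0 and ymax - ymin <= 0:
        raise ValueError("degenerate trap array: all detectors coincide")
    return StateSpace(xmin - buffer, xmax + buffer,
                      ymin - buffer, ymax + buffer,
                      buffer=buffer, pixel_side=pixel_side)
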