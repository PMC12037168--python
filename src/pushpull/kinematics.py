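"""Trajectory kinematics: tortuosity, Fréchet similarity, velocity, occupancy, circular spread.

Quantities computed per trial-level 2-D trajectory (mm, ms):

tortuosity
    Total path length divided by the Euclidean distance between the first
    and last points; 1 for a straight monotone path.  Undefined when the
    net displacement is (near) zero, in which case the trajectory is
    excluded rather than producing an unstable ratio.
discrete Fréchet distance
    Minimum over order-preserving couplings of the maximum paired point
    distance — the "dog-leash" similarity of two sampled curves, computed
    by dynamic programming.  Session similarity is the mean over all
    unordered trajectory pairs.
movement velocity
    Distance from the first point to the point of maximum displacement,
    divided by the elapsed time to reach it (mm/s).
explored area
    Number of visited 1 x 1 mm occupancy bins within a global workspace
    whose extent comes from the pooled coordinate minima/maxima.
angular deviation
    Circular spread sqrt(2 (1 - Rbar)) of movement-direction angles,
    ranging 0 (all parallel) to sqrt(2) (uniform); the session value pools
    inter-sample displacement directions by occupancy bin, computes the
    deviation per bin, and averages over bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .signal_io import PositionTrace

__all__ = [
    "Trajectory",
    "Workspace",
    "SessionKinematics",
    "DegenerateTrajectoryError",
    "preprocess",
    "tortuosity",
    "frechet_distance",
    "session_frechet_mean",
    "movement_velocity",
    "explored_area",
    "angular_deviation",
    "mean_angular_deviation",
    "workspace_from_trajectories",
    "summarize_session",
]


class DegenerateTrajectoryError(ValueError):
    """All points identical, or a ratio is undefined for this trajectory."""


@dataclass
class Trajectory:
    """Ordered 2-D points (mm) with timestamps (ms) and a push/pull label."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    label: str = "push"
    trial: int = -1

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")

    @classmethod
    def from_trace(cls, trace: PositionTrace, label: str = "push", trial: int = -1):
        return cls(t=trace.t, x=trace.x, y=trace.y, label=label, trial=trial)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class Workspace:
    """Global binning frame: pooled coordinate extrema, 1 mm bins."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    bin_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("workspace extents must satisfy max > min")
        if self.bin_mm <= 0:
            raise ValueError("bin size must be positive")

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Half-open bin edges [k, k+1) anchored at the workspace minimum."""
        nx = int(np.ceil((self.x_max - self.x_min) / self.bin_mm)) or 1
        ny = int(np.ceil((self.y_max - self.y_min) / self.bin_mm)) or 1
        return (
            self.x_min + self.bin_mm * np.arange(nx + 1),
            self.y_min + self.bin_mm * np.arange(ny + 1),
        )


def workspace_from_trajectories(
    trajs: Sequence[Trajectory], bin_mm: float = 1.0, pad: float = 1e-9
) -> Workspace:
    """Workspace spanning the pooled min/max coordinates of all trajectories."""
    xs = np.concatenate([tr.x for tr in trajs])
    ys = np.concatenate([tr.y for tr in trajs])
    return Workspace(
        x_min=float(xs.min()), x_max=float(xs.max()) + pad,
        y_min=float(ys.min()), y_max=float(ys.max()) + pad,
        bin_mm=bin_mm,
    )


def preprocess(traj: Trajectory) -> Trajectory:
    """Drop consecutive duplicate points and center on the coordinate medians."""
    if len(traj) < 2:
        raise ValueError("need at least 2 points")
    pts = traj.points
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    if keep.sum() < 2:
        raise DegenerateTrajectoryError("all points identical")
    x, y, t = traj.x[keep], traj.y[keep], traj.t[keep]
    return Trajectory(
        t=t, x=x - np.median(x), y=y - np.median(y),
        label=traj.label, trial=traj.trial,
    )


def _path_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def tortuosity(
    traj: Trajectory, epsilon_net: float = 0.5, segment: str = "full"
) -> float:
    """Path length over net first-to-last displacement (>= 1).

    ``segment='full'`` uses the whole trajectory; ``'outbound'`` truncates
    at the point of maximum displacement from the start, which keeps the
    ratio defined for out-and-back reaches whose endpoints nearly
    coincide.  Net displacements below ``epsilon_net`` mm leave the ratio
    undefined and raise :class:`DegenerateTrajectoryError`; callers
    exclude such trajectories with reason.
    """
    pts = traj.points
    if segment == "outbound":
        i = int(np.argmax(np.linalg.norm(pts - pts[0], axis=1)))
        pts = pts[: i + 1]
    elif segment != "full":
        raise ValueError("segment must be 'full' or 'outbound'")
    if len(pts) < 2:
        raise DegenerateTrajectoryError("outbound segment has a single point")
    net = float(np.linalg.norm(pts[-1] - pts[0]))
    if net < epsilon_net:
        raise DegenerateTrajectoryError(
            f"net displacement {net:.3g} mm below {epsilon_net} mm"
        )
    return _path_length(pts) / net


def _frechet_dp(dist: np.ndarray) -> float:
    # rolling-row dynamic program over the coupling lattice
    n, m = dist.shape
    row = np.empty(m)
    row[0] = dist[0, 0]
    for j in range(1, m):
        row[j] = max(row[j - 1], dist[0, j])
    prev = np.empty(m)
    for i in range(1, n):
        prev[:] = row
        row[0] = max(prev[0], dist[i, 0])
        for j in range(1, m):
            best = prev[j]
            if row[j - 1] < best:
                best = row[j - 1]
            if prev[j - 1] < best:
                best = prev[j - 1]
            row[j] = dist[i, j] if dist[i, j] > best else best
    return row[m - 1]


try:  # JIT the O(n*m) lattice sweep; falls back to pure Python
    from numba import njit as _njit

    _frechet_dp = _njit(cache=False)(_frechet_dp)
except ImportError:  # pragma: no cover
    pass


def frechet_distance(P: Trajectory | np.ndarray, Q: Trajectory | np.ndarray) -> float:
    """Discrete Fréchet distance between two point sequences (mm).

    Dynamic program over the coupling lattice:
    d[i,j] = max(|P_i - Q_j|, min(d[i-1,j], d[i,j-1], d[i-1,j-1])).
    """
    p = P.points if isinstance(P, Trajectory) else np.asarray(P, dtype=float)
    q = Q.points if isinstance(Q, Trajectory) else np.asarray(Q, dtype=float)
    if len(p) == 0 or len(q) == 0:
        raise ValueError("empty trajectory")
    diff = p[:, None, :] - q[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    return float(_frechet_dp(dist))


def session_frechet_mean(trajs: Sequence[Trajectory]) -> float:
    """Mean discrete Fréchet distance over all unordered trajectory pairs."""
    n = len(trajs)
    if n < 2:
        raise ValueError("need at least 2 trajectories for pairwise similarity")
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += frechet_distance(trajs[i], trajs[j])
    return total / (n * (n - 1) / 2)


def movement_velocity(traj: Trajectory) -> float:
    """Speed to the point of maximum displacement from the start (mm/s)."""
    pts = traj.points
    d = np.linalg.norm(pts - pts[0], axis=1)
    i = int(np.argmax(d))
    dt_ms = traj.t[i] - traj.t[0]
    if dt_ms <= 0:
        raise ValueError("max displacement at the first sample; zero interval")
    return float(d[i] / dt_ms * 1000.0)


def explored_area(
    trajs: Sequence[Trajectory] | Trajectory, ws: Workspace
) -> tuple[float, np.ndarray]:
    """Visited-bin count (mm^2 for 1 mm bins) and the visit-count grid.

    Bins are half-open [k, k+1) anchored at the workspace minimum; the
    grid doubles as an occupancy heatmap.  Points outside the workspace
    are an error — the workspace is defined from pooled extrema, so an
    outside point means the frame was built from different data.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    xe, ye = ws.edges()
    grid = np.zeros((len(xe) - 1, len(ye) - 1))
    for tr in trajs:
        bad = (
            (tr.x < ws.x_min) | (tr.x >= xe[-1]) | (tr.y < ws.y_min) | (tr.y >= ye[-1])
        )
        if bad.any():
            k = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"point ({tr.x[k]:.3g}, {tr.y[k]:.3g}) outside workspace"
            )
        ix = np.floor((tr.x - ws.x_min) / ws.bin_mm).astype(int)
        iy = np.floor((tr.y - ws.y_min) / ws.bin_mm).astype(int)
        np.add.at(grid, (ix, iy), 1)
    area = float((grid > 0).sum() * ws.bin_mm * ws.bin_mm)
    return area, grid


def angular_deviation(angles: Sequence[float]) -> float:
    """Circular spread s = sqrt(2 (1 - Rbar)) in [0, sqrt(2)]."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("no angles")
    rbar = float(np.hypot(np.cos(a).mean(), np.sin(a).mean()))
    rbar = min(rbar, 1.0)
    return float(np.sqrt(2.0 * (1.0 - rbar)))


def mean_angular_deviation(
    trajs: Sequence[Trajectory], ws: Workspace, min_angles: int = 2
) -> float:
    """Session-level mean angular deviation over occupancy bins.

    Inter-sample displacement directions are pooled by the occupancy bin
    of the segment's starting point; the angular deviation is computed per
    bin with at least ``min_angles`` entries, and averaged across bins.
    """
    xe, ye = ws.edges()
    nx, ny = len(xe) - 1, len(ye) - 1
    bins: dict[int, list[float]] = {}
    for tr in trajs:
        dx = np.diff(tr.x)
        dy = np.diff(tr.y)
        moved = (dx != 0) | (dy != 0)
        ang = np.arctan2(dy[moved], dx[moved])
        ix = np.floor((tr.x[:-1][moved] - ws.x_min) / ws.bin_mm).astype(int)
        iy = np.floor((tr.y[:-1][moved] - ws.y_min) / ws.bin_mm).astype(int)
        if ix.size and (
            ix.min() < 0 or ix.max() >= nx or iy.min() < 0 or iy.max() >= ny
        ):
            raise ValueError("segment start outside workspace")
        for b, a in zip(ix * ny + iy, ang):
            bins.setdefault(int(b), []).append(float(a))
    devs = [angular_deviation(v) for v in bins.values() if len(v) >= min_angles]
    if not devs:
        raise ValueError("no occupancy bin holds enough angles")
    return float(np.mean(devs))


@dataclass
class SessionKinematics:
    """Per-trajectory metrics plus session-level summaries."""

    tortuosity: list[float] = field(default_factory=list)
    velocity: list[float] = field(default_factory=list)
    excluded: list[tuple[int, str]] = field(default_factory=list)
    frechet_mean: float | None = None
    explored_area_mm2: dict = field(default_factory=dict)
    mean_angular_deviation: float | None = None
    visit_grid: np.ndarray | None = None


def summarize_session(
    trajs: Sequence[Trajectory],
    ws: Workspace | None = None,
    do_preprocess: bool = True,
    tortuosity_segment: str = "outbound",
) -> SessionKinematics:
    """Run the full kinematics suite on one session's trajectories.

    Tortuosity defaults to the outbound segment because trial reaches are
    out-and-back and the full-path ratio is undefined when the endpoints
    coincide; pass ``tortuosity_segment='full'`` for the whole path.
    """
    prepped: list[Trajectory] = []
    out = SessionKinematics()
    for tr in trajs:
        try:
            prepped.append(preprocess(tr) if do_preprocess else tr)
        except DegenerateTrajectoryError as exc:
            out.excluded.append((tr.trial, str(exc)))
    if not prepped:
        return out
    if ws is None:
        ws = workspace_from_trajectories(prepped)
    for tr in prepped:
        try:
            out.tortuosity.append(tortuosity(tr, segment=tortuosity_segment))
        except DegenerateTrajectoryError as exc:
            out.excluded.append((tr.trial, str(exc)))
        out.velocity.append(movement_velocity(tr))
    if len(prepped) >= 2:
        out.frechet_mean = session_frechet_mean(prepped)
    for label in ("push", "pull"):
        sub = [tr for tr in prepped if tr.label == label]
        if sub:
            area, _ = explored_area(sub, ws)
            out.explored_area_mm2[label] = area
    _, out.visit_grid = explored_area(prepped, ws)
    out.explored_area_mm2["all"] = float((out.visit_grid > 0).sum() * ws.bin_mm ** 2)
    try:
        out.mean_angular_deviation = mean_angular_deviation(prepped, ws)
    except ValueError:
        out.mean_angular_deviation = None
    return out
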