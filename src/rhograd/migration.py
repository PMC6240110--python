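"""Trajectory and morphodynamics analysis of migrating cells.

From threshold-segmented mask movies: centroid tracking, windowed
instantaneous speed, displacement angles relative to the stimulation
gradient, bootstrap angular precision (the mean resultant length
p = √((Σsinθ/n)² + (Σcosθ/n)²)), and morphodynamic edge-velocity maps over
contour coordinate × time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, special

from .errors import InvalidParameterError, SegmentationError

__all__ = [
    "Trajectory",
    "AngularStats",
    "MorphodynamicMap",
    "segment_cells",
    "track_centroid",
    "instantaneous_speed",
    "displacement_angle",
    "angular_precision",
    "morphodynamic_map",
    "kappa_from_resultant",
]


@dataclass
class Trajectory:
    """Centroid positions (µm) per frame at a fixed frame interval (min)."""

    positions: np.ndarray  # (T, 2) as (x, y) µm
    frame_interval: float
    condition: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise InvalidParameterError("positions must be (T, 2)")
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "t_min": self.times,
                "x_um": self.positions[:, 0],
                "y_um": self.positions[:, 1],
                "condition": self.condition,
            }
        )


def trajectories_from_csv(path) -> dict[str, Trajectory]:
    """Load per-cell trajectories from a CSV table with columns
    (frame, t_min, x_um, y_um, cell_id)."""
    import pandas as pd

    df = pd.read_csv(path)
    out: dict[str, Trajectory] = {}
    for cell_id, sub in df.groupby("cell_id"):
        sub = sub.sort_values("frame")
        t = sub["t_min"].to_numpy()
        dt = float(np.diff(t)[0]) if t.size > 1 else 1.0
        pos = sub[["x_um", "y_um"]].to_numpy()
        cond = str(sub["condition"].iloc[0]) if "condition" in sub else ""
        out[str(cell_id)] = Trajectory(pos, dt, cond)
    return out


@dataclass
class AngularStats:
    """Angular precision of a set of displacement angles.

    ``precision`` is the mean resultant length of the original sample;
    ``bootstrap`` holds the per-replicate precision of resampled angle
    sets and ``bootstrap_sd`` its dispersion.
    """

    angles: np.ndarray
    precision: float
    bootstrap: np.ndarray = field(repr=False)
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return self.angles.size

    @property
    def bootstrap_sd(self) -> float:
        return float(self.bootstrap.std(ddof=1)) if self.bootstrap.size > 1 else 0.0


@dataclass
class MorphodynamicMap:
    """Edge velocity (µm/min) over contour coordinate × time.

    Rows run over the contour coordinate from −π to π (radians of arc
    fraction), centered so coordinate 0 is the gradient direction; columns
    are frame transitions.  ``velocities`` may contain NaN where a frame
    was flagged (topology change)."""

    velocities: np.ndarray  # (n_contour_points, T-1)
    coords: np.ndarray  # contour coordinate, radians in (−π, π]
    times: np.ndarray  # min, one per transition
    flagged_frames: list[int] = field(default_factory=list)


def _mean_resultant_length(angles: np.ndarray) -> float:
    return float(np.hypot(np.sin(angles).mean(), np.cos(angles).mean()))


def segment_cells(frames: np.ndarray, dominance: float = 0.5) -> np.ndarray:
    """Otsu-threshold each frame, keep the largest component, fill holes.

    Raises :class:`SegmentationError` for empty masks or when a second
    component exceeds ``dominance`` × the largest one (no single dominant
    cell in the field).
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label

    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    masks = np.zeros(frames.shape, dtype=bool)
    for t, frame in enumerate(frames):
        frame = frame.astype(float)
        if frame.max() <= frame.min():
            raise SegmentationError(f"frame {t} is constant")
        thr = threshold_otsu(frame)
        binary = frame > thr
        lab = label(binary)
        if lab.max() == 0:
            raise SegmentationError(f"frame {t}: empty mask after thresholding")
        areas = np.bincount(lab.ravel())[1:]
        order = np.argsort(areas)[::-1]
        if len(areas) > 1 and areas[order[1]] > dominance * areas[order[0]]:
            raise SegmentationError(f"frame {t}: no single dominant cell")
        masks[t] = ndimage.binary_fill_holes(lab == order[0] + 1)
    return masks


def track_centroid(
    masks: np.ndarray, pixel_size: float, frame_interval: float, condition: str = ""
) -> Trajectory:
    """Area centroid of each mask, in µm, as a :class:`Trajectory`."""
    from skimage.measure import regionprops

    masks = np.asarray(masks, dtype=bool)
    if masks.ndim == 2:
        masks = masks[None]
    pos = np.empty((masks.shape[0], 2))
    for t, m in enumerate(masks):
        props = regionprops(m.astype(np.uint8))
        if not props:
            raise SegmentationError(f"frame {t}: empty mask")
        r, c = props[0].centroid
        pos[t] = (c * pixel_size, r * pixel_size)
    return Trajectory(pos, frame_interval, condition)


def instantaneous_speed(
    traj: Trajectory,
    smoothing_window: int = 5,
    averaging_interval: tuple[float, float] | None = None,
) -> float:
    """Mean instantaneous centroid speed (µm/min) over a time interval.

    Frame-to-frame displacements divided by the frame interval, boxcar-
    averaged over ``smoothing_window`` consecutive frames, then averaged
    over ``averaging_interval`` (min; whole track by default).
    """
    if traj.n_frames < 2:
        raise InvalidParameterError("trajectory too short")
    steps = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    speeds = steps / traj.frame_interval
    if smoothing_window > 1:
        speeds = ndimage.uniform_filter1d(
            speeds, size=min(smoothing_window, speeds.size), mode="nearest"
        )
    t_mid = traj.times[:-1] + traj.frame_interval / 2.0
    if averaging_interval is not None:
        t0, t1 = averaging_interval
        if t0 < traj.times[0] or t1 > traj.times[-1]:
            raise InvalidParameterError("averaging interval outside the trajectory")
        sel = (t_mid >= t0) & (t_mid <= t1)
        if not sel.any():
            raise InvalidParameterError("averaging interval contains no frames")
        speeds = speeds[sel]
    return float(speeds.mean())


def displacement_angle(
    traj: Trajectory, gradient_axis: float = 0.0, n_end_frames: int = 3
) -> float | None:
    """Angle between the net displacement and the stimulation axis.

    The displacement vector runs from the centroid averaged over the first
    ``n_end_frames`` frames to the centroid averaged over the last
    ``n_end_frames``; the result is in (−π, π] with 0 toward the gradient
    maximum.  Returns ``None`` for zero net displacement (excluded from
    precision statistics by the caller).
    """
    if traj.n_frames < 2 * n_end_frames:
        raise InvalidParameterError(f"need at least {2 * n_end_frames} frames")
    start = traj.positions[:n_end_frames].mean(axis=0)
    end = traj.positions[-n_end_frames:].mean(axis=0)
    v = end - start
    if np.hypot(*v) < 1e-12:
        return None
    ang = math.atan2(v[1], v[0]) - gradient_axis
    return float((ang + math.pi) % (2 * math.pi) - math.pi)


def angular_precision(
    angles,
    n_boot: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> AngularStats:
    """Mean resultant length of displacement angles, with bootstrap.

    ``None`` entries (undefined angles) are excluded and counted.  The
    point estimate is computed on the original sample; ``n_boot`` seeded
    resamples (with replacement, same n) give the sampling dispersion.
    """
    clean = np.array([a for a in angles if a is not None], dtype=float)
    n_excluded = len(list(angles)) - clean.size
    if clean.size < 3:
        raise InvalidParameterError("need at least three defined angles")
    p = _mean_resultant_length(clean)
    rng = rng if rng is not None else np.random.default_rng(seed)
    idx = rng.integers(0, clean.size, size=(n_boot, clean.size))
    resampled = clean[idx]
    boot = np.hypot(
        np.sin(resampled).mean(axis=1), np.cos(resampled).mean(axis=1)
    )
    return AngularStats(clean, p, boot, n_excluded)


def kappa_from_resultant(p: float) -> float:
    """Invert the von Mises mean resultant length p = I₁(κ)/I₀(κ).

    Used to recover the concentration parameter of a heading distribution
    from its measured angular precision.
    """
    if not 0 <= p < 1:
        raise InvalidParameterError("resultant length must be in [0, 1)")
    if p < 1e-9:
        return 0.0

    def f(kappa: float) -> float:
        return special.i1(kappa) / special.i0(kappa) - p

    hi = 2.0
    while f(hi) < 0 and hi < 1e6:
        hi *= 2.0
    return float(optimize.brentq(f, 1e-9, hi))


def _largest_contour(mask: np.ndarray):
    from skimage.measure import find_contours

    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise SegmentationError("mask has no contour")
    return max(contours, key=len)


def _densify_contour(contour: np.ndarray, max_spacing: float = 0.1) -> np.ndarray:
    """Linearly interpolate a contour so vertices are <= max_spacing apart,
    making nearest-vertex queries approximate nearest-point-on-polyline."""
    closed = contour
    if not np.allclose(closed[0], closed[-1]):
        closed = np.vstack([closed, closed[:1]])
    seg = np.diff(closed, axis=0)
    ds = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(ds)])
    n = max(int(np.ceil(s[-1] / max_spacing)), closed.shape[0])
    targets = np.linspace(0.0, s[-1], n, endpoint=False)
    return np.stack(
        [np.interp(targets, s, closed[:, 0]), np.interp(targets, s, closed[:, 1])],
        axis=1,
    )


def _resample_contour(
    contour: np.ndarray, n_points: int, centroid_rc: np.ndarray, start_angle: float
) -> np.ndarray:
    """Resample a closed contour to n points by arc length, starting at the
    point whose direction from the centroid matches ``start_angle`` (image
    coordinates: angle 0 = +col, positive toward +row), oriented
    counterclockwise in (row, col) space."""
    closed = contour
    if not np.allclose(closed[0], closed[-1]):
        closed = np.vstack([closed, closed[:1]])
    seg = np.diff(closed, axis=0)
    ds = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(ds)])
    total = s[-1]
    # angle of each vertex about the centroid
    ang = np.arctan2(closed[:-1, 0] - centroid_rc[0], closed[:-1, 1] - centroid_rc[1])
    dang = (ang - start_angle + math.pi) % (2 * math.pi) - math.pi
    i0 = int(np.argmin(np.abs(dang)))
    s_start = s[i0]
    targets = (s_start + np.arange(n_points) / n_points * total) % total
    rows = np.interp(targets, s, closed[:, 0])
    cols = np.interp(targets, s, closed[:, 1])
    return np.stack([rows, cols], axis=1)


def morphodynamic_map(
    masks: np.ndarray,
    gradient_axis: float = 0.0,
    n_contour_points: int = 360,
    pixel_size: float = 0.5,
    frame_interval: float = 2.0,
) -> MorphodynamicMap:
    """Edge-velocity map from a mask movie.

    For each frame transition the current contour is resampled to
    ``n_contour_points`` by arc length starting from the gradient
    direction, and the edge velocity at each contour point is the signed
    Euclidean distance to the next frame's boundary (nearest point on the
    sub-pixel contour; sign positive where the cell advanced outward)
    divided by the frame interval.  Frames whose mask splits into several
    components are flagged and filled with NaN.
    """
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim != 3 or masks.shape[0] < 2:
        raise InvalidParameterError("need a (T, H, W) movie with >= 2 frames")
    from skimage.measure import label

    n_t = masks.shape[0] - 1
    vel = np.full((n_contour_points, n_t), np.nan)
    flagged: list[int] = []
    half = n_contour_points // 2
    for t in range(n_t):
        cur, nxt = masks[t], masks[t + 1]
        if label(cur).max() != 1 or label(nxt).max() != 1:
            flagged.append(t)
            continue
        com = np.array(ndimage.center_of_mass(cur))
        contour = _largest_contour(cur)
        pts = _resample_contour(contour, n_contour_points, com, gradient_axis)
        from scipy.spatial import cKDTree

        next_contour = _densify_contour(_largest_contour(nxt), max_spacing=0.1)
        dist, _ = cKDTree(next_contour).query(pts)
        inside = ndimage.map_coordinates(
            nxt.astype(float), pts.T, order=1, mode="nearest"
        )
        sd = np.where(inside >= 0.5, dist, -dist)
        # reorder rows so index `half` is the gradient direction (coord 0)
        vel[:, t] = np.roll(sd * pixel_size / frame_interval, half)
    coords = (np.arange(n_contour_points) - half) / n_contour_points * 2 * math.pi
    times = (np.arange(n_t) + 0.5) * frame_interval
    return MorphodynamicMap(vel, coords, times, flagged)
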