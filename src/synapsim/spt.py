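"""Single-particle-tracking statistics for surface-receptor trajectories.

Implements the analysis applied to uPAINT recordings of GluA2-containing
AMPARs: time-averaged mean squared displacement (MSD), a diffusion
coefficient from a linear fit of the first four MSD points (D = slope/4
in 2D), the mobile fraction above a 0.02 µm²/s threshold, a sliding-window
instantaneous diffusion coefficient, and the three-way classing of
trajectories (always mobile / always immobile / alternating) with the
per-track percentage of time spent immobile.

Positions are in µm, times in seconds; the default acquisition rate is
50 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

MOBILITY_THRESHOLD = 0.02   # µm²/s, D above which a track counts as mobile
D_FIT_POINTS = 4            # MSD lags used for the linear fit


class TrajectoryError(ValueError):
    pass


@dataclass
class Trajectory:
    """A single 2D track: strictly increasing frames, positions in µm."""

    track_id: int
    frames: np.ndarray
    times: np.ndarray
    positions: np.ndarray
    synaptic: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise TrajectoryError("frames must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise TrajectoryError("positions must be finite")
        if self.positions.shape != (len(self.frames), 2):
            raise TrajectoryError("positions must be (n_frames, 2)")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times))) if len(self) > 1 else np.nan

    def is_synaptic(self, min_fraction: float = 0.5) -> bool:
        if self.synaptic is None:
            return False
        return float(np.mean(self.synaptic)) >= min_fraction


@dataclass
class TrajectorySet:
    tracks: list[Trajectory]

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.tracks)

    def __getitem__(self, i: int) -> Trajectory:
        return self.tracks[i]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: track_id, frame, t_s, x_um, y_um, synaptic."""
        rows = []
        for tr in self.tracks:
            syn = tr.synaptic if tr.synaptic is not None else np.zeros(len(tr), int)
            rows.append(pd.DataFrame({
                "track_id": tr.track_id, "frame": tr.frames, "t_s": tr.times,
                "x_um": tr.positions[:, 0], "y_um": tr.positions[:, 1],
                "synaptic": np.asarray(syn, dtype=int),
            }))
        if not rows:
            return pd.DataFrame(columns=["track_id", "frame", "t_s",
                                         "x_um", "y_um", "synaptic"])
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrajectorySet":
        tracks = []
        for tid, sub in df.groupby("track_id", sort=True):
            sub = sub.sort_values("frame")
            tracks.append(Trajectory(
                track_id=int(tid),
                frames=sub["frame"].to_numpy(),
                times=sub["t_s"].to_numpy(),
                positions=sub[["x_um", "y_um"]].to_numpy(),
                synaptic=sub["synaptic"].to_numpy()
                if "synaptic" in sub else None,
            ))
        return cls(tracks)


def compute_msd(traj: Trajectory, max_lag: int) -> np.ndarray:
    """Time-averaged MSD over all frame pairs separated by each lag.

    Returns shape (max_lag, 2): columns (lag in frames, MSD in µm²).
    Tracks are assumed gap-free (uPAINT linking upstream); lags index
    positions directly.
    """
    n = len(traj)
    if n < 2:
        raise TrajectoryError("need at least 2 points for an MSD")
    if max_lag >= n:
        raise TrajectoryError("max_lag must be < track length")
    out = np.empty((max_lag, 2))
    pos = traj.positions
    for lag in range(1, max_lag + 1):
        d = pos[lag:] - pos[:-lag]
        out[lag - 1] = (lag, np.mean(np.sum(d * d, axis=1)))
    return out


def estimate_D(msd: np.ndarray, dt: float, n_points: int = D_FIT_POINTS) -> float:
    """Diffusion coefficient from an ordinary least-squares line (free
    intercept) through the first *n_points* MSD lags: D = slope/4.

    Negative fitted values are returned as-is; downstream they fall into
    the lowest log-histogram bin rather than being clipped, which would
    bias the mobile fraction.
    """
    msd = np.asarray(msd, dtype=float)
    if msd.shape[0] < n_points:
        raise TrajectoryError(f"need at least {n_points} MSD lags")
    t = msd[:n_points, 0] * dt
    y = msd[:n_points, 1]
    slope = np.polyfit(t, y, 1)[0]
    return float(slope / 4.0)


def track_diffusion_coefficient(traj: Trajectory,
                                n_points: int = D_FIT_POINTS) -> float:
    """Whole-track D from the first-four-points MSD fit."""
    max_lag = min(n_points, len(traj) - 1)
    if max_lag < 2:
        raise TrajectoryError("track too short for a D estimate")
    msd = compute_msd(traj, max_lag)
    return estimate_D(msd, traj.dt, n_points=max_lag)


def mobile_fraction(d_values: Sequence[float],
                    threshold: float = MOBILITY_THRESHOLD) -> float:
    """Percentage of D values strictly above *threshold*."""
    d = np.asarray(list(d_values), dtype=float)
    if d.size == 0:
        raise TrajectoryError("no D values")
    return float(100.0 * np.mean(d > threshold))


def log_d_histogram(d_values: Sequence[float], bins: np.ndarray | int = 40,
                    lo: float = -5.0, hi: float = 1.0):
    """Histogram of log10(D); non-positive D goes to the lowest bin."""
    d = np.asarray(list(d_values), dtype=float)
    if isinstance(bins, int):
        bins = np.linspace(lo, hi, bins + 1)
    logd = np.where(d > 0, np.log10(np.maximum(d, 1e-300)), -np.inf)
    logd = np.clip(logd, bins[0], bins[-1])
    counts, edges = np.histogram(logd, bins=bins)
    return counts, edges


def instantaneous_diffusion(traj: Trajectory, window: int = 9) -> np.ndarray:
    """Per-point D series from an MSD fit inside a sliding window.

    The window is centred on each point; at the edges it is truncated but
    never below 5 points.  Tracks shorter than 5 points get a constant
    series equal to the whole-track D.
    """
    if window < 5 or window % 2 == 0:
        raise TrajectoryError("window must be odd and >= 5")
    n = len(traj)
    if n < 5:
        return np.full(n, track_diffusion_coefficient(traj))
    window = min(window, n if n % 2 == 1 else n - 1)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        if hi - lo < 5:                      # widen truncated edge windows
            if lo == 0:
                hi = min(n, lo + 5)
            else:
                lo = max(0, hi - 5)
        sub = Trajectory(track_id=-1, frames=traj.frames[lo:hi] - traj.frames[lo],
                         times=traj.times[lo:hi], positions=traj.positions[lo:hi])
        out[i] = track_diffusion_coefficient(sub)
    return out


def classify_trajectory(inst_d: Sequence[float],
                        threshold: float = MOBILITY_THRESHOLD
                        ) -> tuple[str, float]:
    """Class I (always mobile), II (always immobile) or III (alternating),
    plus the percentage of points at or below the immobility threshold."""
    d = np.asarray(list(inst_d), dtype=float)
    if d.size == 0:
        raise TrajectoryError("empty instantaneous-D series")
    below = d <= threshold
    pct_immobile = float(100.0 * np.mean(below))
    if not below.any():
        return "I", pct_immobile
    if below.all():
        return "II", pct_immobile
    return "III", pct_immobile


@dataclass
class MobilityReport:
    """Per-track mobility statistics and their summary."""

    table: pd.DataFrame           # track_id, D, class, pct_immobile, synaptic
    mobile_fraction: float        # %
    class_percentages: dict[str, float]
    threshold: float = MOBILITY_THRESHOLD

    def summary(self) -> dict:
        return {
            "n_tracks": int(len(self.table)),
            "mobile_fraction_pct": self.mobile_fraction,
            "class_percentages": self.class_percentages,
            "median_D": float(self.table["D"].median()),
            "threshold": self.threshold,
        }


def analyze_tracks(tracks: Iterable[Trajectory],
                   threshold: float = MOBILITY_THRESHOLD,
                   window: int = 9,
                   min_length: int = 5,
                   classify: bool = True) -> MobilityReport:
    """Full per-track pipeline: whole-track D, instantaneous-D classing,
    percent immobile; tracks shorter than *min_length* are skipped.
    ``classify=False`` skips the sliding-window classification when only
    whole-track mobility is needed."""
    rows = []
    for tr in tracks:
        if len(tr) < max(min_length, D_FIT_POINTS + 1):
            continue
        d = track_diffusion_coefficient(tr)
        if classify:
            inst = instantaneous_diffusion(tr, window=window)
            cls, pct = classify_trajectory(inst, threshold=threshold)
        else:
            cls = "I" if d > threshold else "II"
            pct = 0.0 if d > threshold else 100.0
        rows.append((tr.track_id, d, cls, pct, tr.is_synaptic()))
    if not rows:
        raise TrajectoryError("no analysable tracks")
    table = pd.DataFrame(rows, columns=["track_id", "D", "class",
                                        "pct_immobile", "synaptic"])
    mf = mobile_fraction(table["D"], threshold)
    counts = table["class"].value_counts(normalize=True) * 100.0
    cls_pct = {c: float(counts.get(c, 0.0)) for c in ("I", "II", "III")}
    return MobilityReport(table=table, mobile_fraction=mf,
                          class_percentages=cls_pct, threshold=threshold)
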