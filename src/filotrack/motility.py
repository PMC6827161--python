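"""Migration track statistics and transwell migration efficiency.

Per-track statistics follow the conventions of chemotaxis tracking tools:
accumulated distance is the sum of consecutive step lengths, Euclidean
distance the start-to-end displacement, straightness their ratio (1 for a
perfectly straight path, 0 for a closed loop), and velocity the accumulated
distance divided by the track duration (mean path speed).  The mean
instantaneous speed — average of step length over step Δt — is reported
alongside since frame gaps make the two differ.

Transwell efficiency is the percentage of loaded cells recovered in the
lower chamber, with viability from trypan-blue counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class TrackError(ValueError):
    """A track violates the input contract (too short, duplicate times)."""


@dataclass
class Track:
    """Time-ordered planar positions of one cell.

    ``positions`` is an (n, 3) array of (t_min, x_um, y_um); an optional
    z_um fourth column is used in the distance computations if present.
    """

    track_id: int | str
    positions: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[0] < 2 or pos.shape[1] < 3:
            raise TrackError(
                f"track {self.track_id}: need >= 2 positions of (t, x, y[, z])"
            )
        dt = np.diff(pos[:, 0])
        if np.any(dt <= 0):
            raise TrackError(
                f"track {self.track_id}: timestamps must be strictly increasing"
            )
        self.positions = pos


@dataclass
class TrackStats:
    track_id: int | str
    accumulated_distance: float
    euclidean_distance: float
    duration: float
    velocity: float
    straightness: float
    mean_instantaneous_speed: float
    condition: str = ""


def track_stats(track: Track) -> TrackStats:
    """Accumulated/Euclidean distance, straightness and velocity of a track.

    Straightness = Euclidean / accumulated distance (0 when the cell never
    moved); velocity = accumulated distance / duration.  Gaps in frames are
    tolerated: each step uses its actual Δt.
    """
    pos = track.positions
    t = pos[:, 0]
    xy = pos[:, 1:]
    steps = np.sqrt((np.diff(xy, axis=0) ** 2).sum(axis=1))
    accumulated = float(steps.sum())
    euclid = float(np.linalg.norm(xy[-1] - xy[0]))
    duration = float(t[-1] - t[0])
    straightness = euclid / accumulated if accumulated > 0 else 0.0
    dts = np.diff(t)
    return TrackStats(
        track_id=track.track_id,
        accumulated_distance=accumulated,
        euclidean_distance=euclid,
        duration=duration,
        velocity=accumulated / duration,
        straightness=straightness,
        mean_instantaneous_speed=float(np.mean(steps / dts)),
        condition=track.condition,
    )


def tracks_from_table(
    table: pd.DataFrame, condition: str = "", pixel_size: float = 1.0
) -> list[Track]:
    """Build tracks from a tidy table (track_id, t_min, x_um, y_um[, z_um]).

    ``pixel_size`` converts pixel-unit exports from manual-tracking tools
    into µm; leave at 1.0 for tables already in µm.
    """
    required = {"track_id", "t_min", "x_um", "y_um"}
    missing = required - set(table.columns)
    if missing:
        raise TrackError(f"tracking table is missing columns: {sorted(missing)}")
    tracks = []
    cols = ["t_min", "x_um", "y_um"] + (["z_um"] if "z_um" in table.columns else [])
    for tid, grp in table.groupby("track_id", sort=True):
        grp = grp.sort_values("t_min")
        pos = grp[cols].to_numpy(dtype=float)
        pos[:, 1:] *= pixel_size
        tracks.append(Track(track_id=tid, positions=pos, condition=condition))
    return tracks


def read_track_table(path: str | Path, pixel_size: float = 1.0, condition: str = "") -> list[Track]:
    """Read a CSV or tab-separated tracking export."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt", ".xls"} else ","
    table = pd.read_csv(path, sep=sep, comment="#")
    return tracks_from_table(table, condition=condition, pixel_size=pixel_size)


def stats_to_frame(stats: Sequence[TrackStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "track_id": s.track_id,
                "condition": s.condition,
                "accumulated_um": s.accumulated_distance,
                "euclidean_um": s.euclidean_distance,
                "duration_min": s.duration,
                "velocity_um_per_min": s.velocity,
                "mean_instantaneous_speed_um_per_min": s.mean_instantaneous_speed,
                "straightness": s.straightness,
            }
            for s in stats
        ]
    )


def summarize_condition(tracks_by_condition: dict[str, Sequence[Track]]) -> pd.DataFrame:
    """Per-condition mean/median velocity and straightness with n and sem.

    Empty conditions are excluded with a warning rather than raising, so a
    partially parsed experiment still summarizes.
    """
    import warnings

    rows = []
    for cond, tracks in tracks_by_condition.items():
        if len(tracks) == 0:
            warnings.warn(f"condition {cond!r} has no tracks; excluded", stacklevel=2)
            continue
        stats = [track_stats(t) for t in tracks]
        v = np.array([s.velocity for s in stats])
        st = np.array([s.straightness for s in stats])
        n = len(stats)
        sem = lambda a: float(a.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append(
            {
                "condition": cond,
                "n_tracks": n,
                "mean_velocity_um_per_min": float(v.mean()),
                "median_velocity_um_per_min": float(np.median(v)),
                "sem_velocity": sem(v),
                "sd_velocity": float(v.std(ddof=1)) if n > 1 else 0.0,
                "mean_straightness": float(st.mean()),
                "median_straightness": float(np.median(st)),
                "sem_straightness": sem(st),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# transwell assay
# --------------------------------------------------------------------------

@dataclass
class TranswellResult:
    input_cells: int
    migrated_cells: float
    viable_fraction: float
    efficiency: float  # percent
    efficiency_sem: float = float("nan")
    n_replicates: int = 1


def transwell_efficiency(
    input_cells: int,
    migrated_counts: int | Sequence[int],
    viable_counts: Sequence[tuple[int, int]] | None = None,
) -> TranswellResult:
    """Migration efficiency (%) across one or more replicate counts.

    ``migrated_counts`` is a single lower-chamber count or a sequence of
    replicates; efficiency = 100 * migrated / input per replicate, reported
    as the replicate mean with its standard error.  ``viable_counts`` are
    optional trypan-blue (viable, dead) pairs pooled into a viable fraction.
    """
    if input_cells <= 0:
        raise ValueError(f"input_cells must be > 0, got {input_cells}")
    counts = np.atleast_1d(np.asarray(migrated_counts, dtype=float))
    if np.any(counts < 0):
        raise ValueError("migrated counts must be >= 0")
    if np.any(counts > input_cells):
        raise ValueError(
            f"migrated count exceeds input ({counts.max():.0f} > {input_cells}); "
            "likely a miscount"
        )
    eff = 100.0 * counts / input_cells
    n = counts.size
    sem = float(eff.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    if viable_counts is not None:
        viable = sum(v for v, _ in viable_counts)
        total = sum(v + d for v, d in viable_counts)
        viable_fraction = viable / total if total > 0 else float("nan")
    else:
        viable_fraction = float("nan")
    return TranswellResult(
        input_cells=int(input_cells),
        migrated_cells=float(counts.mean()),
        viable_fraction=float(viable_fraction),
        efficiency=float(eff.mean()),
        efficiency_sem=sem,
        n_replicates=int(n),
    )


# --------------------------------------------------------------------------
# optional figures
# --------------------------------------------------------------------------

def plot_tracks(tracks: Sequence[Track], ax=None, origin_centered: bool = True):
    """Rose-style overlay of tracks, each translated to start at the origin."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for t in tracks:
        xy = t.positions[:, 1:3]
        if origin_centered:
            xy = xy - xy[0]
        ax.plot(xy[:, 0], xy[:, 1], lw=0.8)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    return ax
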