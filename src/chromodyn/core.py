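"""Shared containers for single-particle tracking data.

Coordinate conventions used throughout the package: frames are 0-based,
positions are in pixels with a pixel-center origin (x = column, y = row),
and positions in micrometres are ``px * pixel_size_nm / 1000``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = ["AcquisitionParams", "Track", "TrackSet"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera/optics context needed to interpret a track table.

    Parameters
    ----------
    pixel_size_nm : float
        Lateral pixel size in nanometres (110 nm on the reference setup).
    frame_interval_s : float
        Time between consecutive frames in seconds. Slow acquisition for
        dwell-time analysis uses 0.2 s; fast acquisition for jump-length
        analysis uses 0.015 s.
    exposure_s : float
        Exposure time per frame in seconds (informational).
    n_frames : int
        Number of frames in the movie.
    axial_range_nm : float
        Depth of the axial detection slab. Fluorophores diffusing outside
        ``+/- axial_range_nm / 2`` of the focal plane are lost from tracks.
        Set to 0 to disable axial modelling.
    localization_error_um : float
        Gaussian localization error (standard deviation per coordinate)
        in micrometres.
    """

    pixel_size_nm: float = 110.0
    frame_interval_s: float = 0.2
    exposure_s: float = 0.05
    n_frames: int = 200
    axial_range_nm: float = 294.0
    localization_error_um: float = 0.035

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.axial_range_nm < 0:
            raise ValueError("axial_range_nm must be non-negative")
        if self.localization_error_um < 0:
            raise ValueError("localization_error_um must be non-negative")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionParams":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class Track:
    """One linked particle trajectory.

    ``frames`` are strictly increasing but need not be contiguous: missing
    frames are photoblinking gaps that were closed during linking.
    Positions are stored in pixels; ``true_state`` (optional) carries the
    simulator's per-observation ground truth (``"bound_s"``, ``"bound_ns"``
    or ``"free"``).
    """

    track_id: int
    frames: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    intensity: np.ndarray | None = None
    true_state: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        if not (len(self.frames) == len(self.x_px) == len(self.y_px)):
            raise ValueError("frames, x_px, y_px must have equal length")
        if len(self.frames) >= 2 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def gap_frames(self) -> set[int]:
        """Frames inside the track's span with no observation."""
        full = set(range(int(self.frames[0]), int(self.frames[-1]) + 1))
        return full - set(int(f) for f in self.frames)

    def positions_um(self, acq: AcquisitionParams) -> np.ndarray:
        """(n, 2) array of (x, y) in micrometres."""
        return np.column_stack([self.x_px, self.y_px]) * acq.pixel_size_um


@dataclass
class TrackSet:
    """A collection of tracks sharing one acquisition context."""

    tracks: list[Track]
    acq: AcquisitionParams
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        scale = self.acq.pixel_size_um
        for t in self.tracks:
            n = len(t)
            inten = t.intensity if t.intensity is not None else np.full(n, np.nan)
            state = t.true_state if t.true_state is not None else np.full(n, "", dtype=object)
            rows.append(
                pd.DataFrame(
                    {
                        "track_id": t.track_id,
                        "frame": t.frames,
                        "x_px": t.x_px,
                        "y_px": t.y_px,
                        "x_um": t.x_px * scale,
                        "y_um": t.y_px * scale,
                        "intensity": inten,
                        "true_state": state,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(
                columns=["track_id", "frame", "x_px", "y_px", "x_um", "y_um", "intensity", "true_state"]
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: str | Path, write_sidecar: bool = True) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if write_sidecar:
            self.acq.to_json(path.with_suffix(".acq.json"))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, acq: AcquisitionParams, provenance: str = "") -> "TrackSet":
        tracks = []
        for tid, grp in df.groupby("track_id", sort=True):
            grp = grp.sort_values("frame")
            intensity = grp["intensity"].to_numpy() if "intensity" in grp else None
            state = grp["true_state"].to_numpy() if "true_state" in grp else None
            tracks.append(
                Track(
                    track_id=int(tid),
                    frames=grp["frame"].to_numpy(),
                    x_px=grp["x_px"].to_numpy(),
                    y_px=grp["y_px"].to_numpy(),
                    intensity=intensity,
                    true_state=state,
                )
            )
        return cls(tracks=tracks, acq=acq, provenance=provenance)

    @classmethod
    def from_csv(cls, path: str | Path, acq: AcquisitionParams | None = None) -> "TrackSet":
        path = Path(path)
        if acq is None:
            sidecar = path.with_suffix(".acq.json")
            if not sidecar.exists():
                raise ValueError("no AcquisitionParams given and no .acq.json sidecar found")
            acq = AcquisitionParams.from_json(sidecar)
        return cls.from_dataframe(pd.read_csv(path), acq, provenance=str(path))
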