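"""Particle detection and nearest-neighbor track linking.

Detection finds local intensity maxima above the frame background, refines
each candidate with a 2D Gaussian fit for sub-pixel position, and filters
candidates by fitted amplitude ("remove dim": amplitude must lie inside an
instrument-dependent band) and by a normalized sharpness score ("remove
blur": out-of-focus blobs fit with large widths score low).

Linking is frame-to-frame nearest neighbor with a maximum jump radius,
gap closing for short photoblinking dropouts, and a minimum track length.
Candidate links are processed globally per frame in ascending distance
order, which makes tie-breaking deterministic and input-order independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from skimage.feature import peak_local_max

from .core import AcquisitionParams, Track, TrackSet
from .synth import ImageStack

logger = logging.getLogger(__name__)

__all__ = ["Detection", "detect_spots", "link_tracks"]


@dataclass(frozen=True)
class Detection:
    """One sub-pixel localization (pixel-center convention, x = column)."""

    frame: int
    x: float
    y: float
    intensity: float  # fitted Gaussian amplitude
    quality: float  # normalized sharpness (amplitude / width^2, relative to frame max)


def _fit_gaussian_2d(window: np.ndarray, x0: float, y0: float) -> tuple[float, float, float, float, float]:
    """Fit A*exp(-((x-xc)^2+(y-yc)^2)/(2 s^2)) + b on a small window.

    Returns (A, xc, yc, s, b) in window coordinates.
    """
    h, w = window.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    b0 = float(np.percentile(window, 20))
    a0 = max(float(window.max()) - b0, 1e-6)

    def resid(p):
        a, xc, yc, s, b = p
        return (a * np.exp(-((xx - xc) ** 2 + (yy - yc) ** 2) / (2 * s**2)) + b - window).ravel()

    sol = least_squares(
        resid,
        x0=[a0, x0, y0, 1.3, b0],
        bounds=([0, -1, -1, 0.3, -np.inf], [np.inf, w, h, max(h, w), np.inf]),
        max_nfev=200,
    )
    return tuple(sol.x)  # type: ignore[return-value]


def detect_spots(
    stack: ImageStack | np.ndarray,
    blur_threshold: float = 0.02,
    intensity_band: tuple[float, float] = (50.0, 250.0),
    detection_nsigma: float = 4.0,
    min_distance: int = 3,
    fit_halfwidth: int = 3,
) -> list[Detection]:
    """Detect sub-pixel particle positions in every frame of a stack.

    Candidates are local maxima more than ``detection_nsigma`` robust
    standard deviations above the frame median; each is refined by a local
    2D Gaussian fit. Candidates whose fitted amplitude falls outside
    ``intensity_band`` or whose sharpness score falls below
    ``blur_threshold`` are discarded.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack, dtype=float)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError("expected a single-channel (frames, h, w) stack")
    if data.size == 0:
        raise ValueError("empty stack")

    detections: list[Detection] = []
    lo, hi = intensity_band
    for f in range(data.shape[0]):
        frame = data[f]
        if np.all(frame == frame.flat[0]):
            continue  # constant frame: nothing to detect
        bg = float(np.median(frame))
        noise = 1.4826 * float(np.median(np.abs(frame - bg)))
        frame_max = float(frame.max())
        if frame_max >= np.iinfo(np.uint16).max:
            logger.warning("frame %d contains saturated pixels", f)
        thr = bg + detection_nsigma * noise
        peaks = peak_local_max(frame, min_distance=min_distance, threshold_abs=thr, exclude_border=False)
        for r, c in peaks:
            r0, r1 = max(0, r - fit_halfwidth), min(frame.shape[0], r + fit_halfwidth + 1)
            c0, c1 = max(0, c - fit_halfwidth), min(frame.shape[1], c + fit_halfwidth + 1)
            window = frame[r0:r1, c0:c1]
            try:
                a, xc, yc, s, _b = _fit_gaussian_2d(window, float(c - c0), float(r - r0))
            except Exception:  # fit blow-up on pathological windows
                continue
            x, y = c0 + xc, r0 + yc
            if not (0 <= x < frame.shape[1] and 0 <= y < frame.shape[0]):
                continue
            quality = (a / s**2) / frame_max if frame_max > 0 else 0.0
            if a < lo or a > hi:
                continue
            if quality < blur_threshold:
                continue
            detections.append(Detection(frame=f, x=float(x), y=float(y), intensity=float(a), quality=float(quality)))
    return detections


def link_tracks(
    detections: list[Detection],
    acq: AcquisitionParams | None = None,
    max_jump: float = 6.0,
    max_gap: int = 4,
    min_length: int = 4,
) -> TrackSet:
    """Link detections into trajectories by nearest-neighbor assignment.

    Within each frame, candidate (open track end, detection) pairs within
    the allowed radius are sorted by distance and assigned greedily; each
    detection joins at most one track. A track end left unmatched stays
    open for up to ``max_gap`` missing frames and may reconnect to a
    detection within ``max_jump * sqrt(gap + 1)`` (diffusive scaling of the
    search radius across a gap of ``gap`` frames). Tracks with fewer than
    ``min_length`` observed detections are discarded.
    """
    if acq is None:
        acq = AcquisitionParams()

    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)

    open_tracks: list[dict] = []  # {"dets": [Detection], "id": int}
    closed: list[dict] = []
    next_id = 0
    for f in sorted(by_frame):
        dets = by_frame[f]
        # retire tracks whose gap can no longer be closed
        still_open = []
        for tr in open_tracks:
            if f - tr["dets"][-1].frame - 1 > max_gap:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        # candidate links, globally sorted by distance (deterministic ties)
        cands = []
        for ti, tr in enumerate(open_tracks):
            last = tr["dets"][-1]
            span = f - last.frame  # 1 for adjacent frames
            radius = max_jump * np.sqrt(span)
            for di, d in enumerate(dets):
                dist = float(np.hypot(d.x - last.x, d.y - last.y))
                if dist <= radius:
                    cands.append((dist, tr["id"], di, ti))
        cands.sort()
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, _tid, di, ti in cands:
            if ti in used_tracks or di in used_dets:
                continue
            open_tracks[ti]["dets"].append(dets[di])
            used_tracks.add(ti)
            used_dets.add(di)
        for di, d in enumerate(dets):
            if di not in used_dets:
                open_tracks.append({"dets": [d], "id": next_id})
                next_id += 1
    closed.extend(open_tracks)

    tracks = []
    for tr in closed:
        if len(tr["dets"]) < min_length:
            continue
        ds = tr["dets"]
        tracks.append(
            Track(
                track_id=tr["id"],
                frames=np.array([d.frame for d in ds]),
                x_px=np.array([d.x for d in ds]),
                y_px=np.array([d.y for d in ds]),
                intensity=np.array([d.intensity for d in ds]),
            )
        )
    # renumber consecutively for a tidy output table
    for i, t in enumerate(tracks):
        t.track_id = i
    return TrackSet(tracks=tracks, acq=acq, provenance="link_tracks")
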