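"""Detection, tracking and selection of mitochondrial foci in 3D+t stacks.

A light-weight stand-in for a commercial "spots" workflow: stacks are
background-subtracted and Gaussian-smoothed, bright 3D local maxima are
detected per frame, detections are linked frame-to-frame by greedy
nearest-neighbour assignment, the per-frame maximum fluorescence of each
focus is extracted from every channel, and tracks are filtered with the
selection criteria used for computational analysis — longevity, a captured
recruitment event, and spatial isolation from other foci.

Coordinates are 0-based voxel indices in (z, y, x) order; frames are indexed
from 0 and reported in minutes as frame_index * sampling_interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, maximum_filter

from .synthetic import TRACE_COLUMNS

__all__ = [
    "FocusTrack",
    "TrackSelectionCriteria",
    "preprocess",
    "detect_spots",
    "link_tracks",
    "extract_intensities",
    "select_tracks",
    "tracks_to_traces",
]


@dataclass
class FocusTrack:
    """A 3D+t trajectory of one focus with extracted per-channel intensities."""

    focus_id: str
    frames: list[tuple[int, int, int, int]]  # (t_index, z, y, x)
    max_intensity_per_channel: dict[str, np.ndarray] = field(default_factory=dict)
    isolated: bool = True
    spans_recruitment: bool = True

    @property
    def track_length(self) -> int:
        return len(self.frames)

    @property
    def t_indices(self) -> np.ndarray:
        return np.array([f[0] for f in self.frames], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        return np.array([f[1:] for f in self.frames], dtype=float)


def preprocess(
    stack: np.ndarray,
    background: float | str = "median",
    sigma_vox: float = 1.0,
) -> np.ndarray:
    """Constant-background subtraction (clipped at zero) + 3D Gaussian smoothing.

    ``stack`` is (T, Z, Y, X) or a single (Z, Y, X) frame, nonnegative.
    ``background`` is a constant estimate, or ``"median"`` for the per-frame
    median.  Deterministic.  An all-zero frame triggers a warning but is
    retained.
    """
    arr = np.asarray(stack, dtype=float)
    if np.any(arr < 0):
        raise ValueError("stack intensities must be nonnegative")
    single = arr.ndim == 3
    frames = arr[None] if single else arr
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        if not frame.any():
            warnings.warn(f"frame {i} is all zero; retained", stacklevel=2)
        bg = float(np.median(frame)) if background == "median" else float(background)
        sub = np.clip(frame - bg, 0.0, None)
        out[i] = gaussian_filter(sub, sigma=sigma_vox)
    return out[0] if single else out


def detect_spots(
    frame_3d: np.ndarray,
    threshold: float,
    min_separation_vox: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """3D local maxima above ``threshold``, greedily pruned by separation.

    Returns (centroids (n, 3) int voxel coords in (z, y, x), peak
    intensities (n,)).  No two returned spots are closer than
    ``min_separation_vox`` (Euclidean); the brighter wins, ties broken by
    lexicographic voxel order.  An empty result is legal.
    """
    frame = np.asarray(frame_3d, dtype=float)
    if frame.ndim != 3:
        raise ValueError("detect_spots expects a single 3D frame")
    is_max = frame == maximum_filter(frame, size=3, mode="nearest")
    cand = np.argwhere(is_max & (frame > threshold))
    if len(cand) == 0:
        return np.empty((0, 3), dtype=int), np.empty(0)
    values = frame[tuple(cand.T)]
    # sort brighter-first, ties by lexicographic voxel order
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -values))
    cand, values = cand[order], values[order]
    kept: list[int] = []
    for i in range(len(cand)):
        if all(np.linalg.norm(cand[i] - cand[j]) >= min_separation_vox for j in kept):
            kept.append(i)
    return cand[kept].astype(int), values[kept]


def link_tracks(
    detections_per_frame: Sequence[tuple[np.ndarray, np.ndarray]],
    max_displacement_vox: float = 5.0,
) -> list[FocusTrack]:
    """Greedy nearest-neighbour linking of per-frame detections into tracks.

    ``detections_per_frame`` holds (centroids, peaks) per frame, as returned
    by :func:`detect_spots`.  Pairings are made in order of increasing
    distance up to ``max_displacement_vox``; unassigned detections start new
    tracks; a track unmatched for more than one frame is terminated (a
    single missed frame is tolerated).
    """
    if len(detections_per_frame) < 2:
        raise ValueError("need at least 2 frames to link")
    next_id = 0
    active: list[dict] = []
    finished: list[FocusTrack] = []

    def _new_track(t: int, pos: np.ndarray) -> dict:
        nonlocal next_id
        track = {"id": next_id, "frames": [(t, *map(int, pos))], "last_pos": pos,
                 "missed": 0}
        next_id += 1
        return track

    for t, (cents, _peaks) in enumerate(detections_per_frame):
        cents = np.asarray(cents, dtype=float).reshape(-1, 3)
        if t == 0:
            active = [_new_track(0, c) for c in cents]
            continue
        pairs = []
        for ai, tr in enumerate(active):
            d = np.linalg.norm(cents - tr["last_pos"], axis=1) if len(cents) else []
            for di, dist in enumerate(d):
                if dist <= max_displacement_vox:
                    pairs.append((dist, ai, di))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_a: set[int] = set()
        used_d: set[int] = set()
        for dist, ai, di in pairs:
            if ai in used_a or di in used_d:
                continue
            used_a.add(ai)
            used_d.add(di)
            tr = active[ai]
            tr["frames"].append((t, *map(int, cents[di])))
            tr["last_pos"] = cents[di]
            tr["missed"] = 0
        still_active = []
        for ai, tr in enumerate(active):
            if ai in used_a:
                still_active.append(tr)
            else:
                tr["missed"] += 1
                if tr["missed"] > 1:
                    finished.append(_finalize(tr))
                else:
                    still_active.append(tr)
        for di in range(len(cents)):
            if di not in used_d:
                still_active.append(_new_track(t, cents[di]))
        active = still_active
    finished.extend(_finalize(tr) for tr in active)
    finished.sort(key=lambda tr: int(tr.focus_id.split("track")[1]))
    return finished


def _finalize(tr: dict) -> FocusTrack:
    return FocusTrack(focus_id=f"track{tr['id']:03d}", frames=tr["frames"])


def extract_intensities(
    tracks: Sequence[FocusTrack],
    stacks: Mapping[str, np.ndarray],
    background: float | str = "median",
    radius_vox: int = 1,
) -> None:
    """Extract per-frame maximum fluorescence for each track, in place.

    The maximum is taken over a (2r+1)^3 neighbourhood of the tracked voxel
    in the background-subtracted (but unsmoothed) stack of every channel —
    smoothing is for detection only, so extracted peaks stay on the
    acquisition intensity scale.
    """
    subtracted = {}
    for ch, stack in stacks.items():
        arr = np.asarray(stack, dtype=float)
        out = np.empty_like(arr)
        for i, frame in enumerate(arr):
            bg = float(np.median(frame)) if background == "median" else float(background)
            out[i] = np.clip(frame - bg, 0.0, None)
        subtracted[ch] = out
    for tr in tracks:
        for ch, stack in subtracted.items():
            vals = np.empty(tr.track_length)
            shape = stack.shape[1:]
            for j, (t, z, y, x) in enumerate(tr.frames):
                sl = tuple(
                    slice(max(0, c - radius_vox), min(s, c + radius_vox + 1))
                    for c, s in zip((z, y, x), shape)
                )
                vals[j] = float(stack[t][sl].max())
            tr.max_intensity_per_channel[ch] = vals


@dataclass
class TrackSelectionCriteria:
    """Selection filters applied before computational analysis.

    ``min_length_fraction``: minimum track length as a fraction of the movie
    (longevity).  ``min_fold_change``: minimum dynamic range (max/min) of the
    BAX channel — the proxy for "the track encompassed the recruitment
    event".  ``min_separation_vox``: minimum distance to any other track at
    every co-occurring frame (spatial isolation).  ``intensity_floor`` guards
    the fold-change denominator against background-subtracted values near 0.
    """

    min_length_fraction: float = 0.8
    min_fold_change: float = 1.5
    min_separation_vox: float = 5.0
    intensity_floor: float = 1e-6
    bax_channel: str = "bax"


def select_tracks(
    tracks: Sequence[FocusTrack],
    n_frames: int,
    criteria: TrackSelectionCriteria | None = None,
    cell_mask: np.ndarray | None = None,
) -> tuple[list[FocusTrack], pd.DataFrame]:
    """Apply the track-selection filters; return (kept tracks, per-track report).

    Filters: (i) longevity, (ii) BAX dynamic range (recruitment event
    captured), (iii) spatial isolation from every other track at every
    frame, (iv) positions inside ``cell_mask`` (z, y, x boolean) if given.
    An empty result is legal.  Isolation is evaluated against *all* tracks,
    including ones that fail other filters.
    """
    crit = criteria or TrackSelectionCriteria()
    by_frame: dict[int, list[tuple[int, np.ndarray]]] = {}
    for idx, tr in enumerate(tracks):
        for t, z, y, x in tr.frames:
            by_frame.setdefault(t, []).append((idx, np.array([z, y, x], dtype=float)))

    rows = []
    kept: list[FocusTrack] = []
    for idx, tr in enumerate(tracks):
        long_enough = tr.track_length >= crit.min_length_fraction * n_frames
        bax = tr.max_intensity_per_channel.get(crit.bax_channel)
        if bax is None or len(bax) == 0:
            recruiting = False
            fold = float("nan")
        else:
            fold = float(np.max(bax) / max(np.min(bax), crit.intensity_floor))
            recruiting = fold >= crit.min_fold_change
        min_gap = math.inf
        for t, z, y, x in tr.frames:
            me = np.array([z, y, x], dtype=float)
            for other_idx, pos in by_frame[t]:
                if other_idx != idx:
                    min_gap = min(min_gap, float(np.linalg.norm(me - pos)))
        isolated = min_gap >= crit.min_separation_vox
        in_mask = True
        if cell_mask is not None:
            in_mask = all(bool(cell_mask[z, y, x]) for _t, z, y, x in tr.frames)
        keep = long_enough and recruiting and isolated and in_mask
        tr.isolated = isolated
        tr.spans_recruitment = recruiting
        rows.append({
            "focus_id": tr.focus_id, "track_length": tr.track_length,
            "long_enough": long_enough, "fold_change": fold,
            "spans_recruitment": recruiting, "min_gap_vox": min_gap,
            "isolated": isolated, "in_mask": in_mask, "selected": keep,
        })
        if keep:
            kept.append(tr)
    report = pd.DataFrame(rows)
    if len(kept) == 0:
        warnings.warn("no tracks passed the selection criteria", stacklevel=2)
    return kept, report


def tracks_to_traces(
    tracks: Sequence[FocusTrack],
    sampling_interval_min: float = 1.0,
    cell_id: str = "cell000",
) -> pd.DataFrame:
    """Convert tracks to the long trace-table schema (times in minutes)."""
    frames = []
    for tr in tracks:
        t_min = tr.t_indices * sampling_interval_min
        for ch, vals in tr.max_intensity_per_channel.items():
            frames.append(pd.DataFrame({
                "cell_id": cell_id, "focus_id": tr.focus_id, "time_min": t_min,
                "channel": ch, "intensity": vals,
            }))
    if not frames:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    return pd.concat(frames, ignore_index=True)[TRACE_COLUMNS]
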