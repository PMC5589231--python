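"""Spot detection, greedy linking and track selection."""

import numpy as np
import pandas as pd
import pytest

from baxkin import synthetic, tracking
from baxkin.synthetic import StackSimParams
from baxkin.tracking import (
    TrackSelectionCriteria,
    detect_spots,
    link_tracks,
    preprocess,
    select_tracks,
)


def _gaussian_frame(shape=(10, 32, 32), centers=((5, 16, 16),), amps=(200.0,),
                    sigma=1.5, background=0.0):
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    frame = np.full(shape, float(background))
    for c, a in zip(centers, amps):
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        frame += a * np.exp(-d2 / (2 * sigma**2))
    return frame


# ---------------------------------------------------------------------------
# preprocess


def test_constant_image_with_matching_background_becomes_zero():
    frame = np.full((4, 8, 8), 37.0)
    out = preprocess(frame, background=37.0, sigma_vox=1.0)
    np.testing.assert_allclose(out, 0.0)


def test_negative_going_noise_is_clipped_to_zero(rng):
    frame = rng.normal(10.0, 5.0, (4, 16, 16))
    frame = np.clip(frame, 0, None)
    out = preprocess(frame, background=10.0)
    assert np.all(out >= 0.0)


def test_smoothing_preserves_peak_location():
    frame = _gaussian_frame(background=5.0)
    out = preprocess(frame, background=5.0, sigma_vox=1.0)  # sigma <= spot sigma
    assert np.unravel_index(np.argmax(out), out.shape) == (5, 16, 16)


def test_all_zero_frame_warns_but_is_retained():
    stack = np.zeros((2, 4, 8, 8))
    stack[1] += 1.0
    with pytest.warns(UserWarning, match="all zero"):
        out = preprocess(stack, background=0.0)
    assert out.shape == stack.shape


def test_negative_intensities_rejected():
    with pytest.raises(ValueError, match="nonnegative"):
        preprocess(np.full((2, 4, 4), -1.0))


# ---------------------------------------------------------------------------
# detect_spots


def test_single_spot_detected_within_one_voxel():
    frame = _gaussian_frame(centers=((5, 16.4, 15.7),))
    cents, peaks = detect_spots(frame, threshold=20.0)
    assert len(cents) == 1
    assert np.linalg.norm(cents[0] - np.array([5, 16.4, 15.7])) <= 1.0
    assert peaks[0] > 100.0


def test_empty_frame_gives_empty_list():
    cents, peaks = detect_spots(np.zeros((6, 16, 16)), threshold=5.0)
    assert len(cents) == 0 and len(peaks) == 0


def test_close_pair_is_pruned_to_the_brighter():
    frame = _gaussian_frame(centers=((5, 16, 16), (5, 16, 18)), amps=(100.0, 200.0))
    cents, peaks = detect_spots(frame, threshold=20.0, min_separation_vox=5.0)
    assert len(cents) == 1
    assert tuple(cents[0]) == (5, 16, 18)  # the brighter one wins


# ---------------------------------------------------------------------------
# link_tracks


def _detections_from_paths(paths, n_frames, drop=None):
    """paths: list of (n_frames, 3) arrays; drop: {spot_index: frames to skip}."""
    dets = []
    for t in range(n_frames):
        cents, peaks = [], []
        for i, p in enumerate(paths):
            if drop and i in drop and t in drop[i]:
                continue
            cents.append(np.round(p[t]).astype(int))
            peaks.append(100.0)
        dets.append((np.array(cents).reshape(-1, 3), np.array(peaks)))
    return dets


def test_static_spots_give_full_length_zero_displacement_tracks():
    paths = [np.tile([5, 10, 10], (20, 1)), np.tile([5, 30, 30], (20, 1))]
    tracks = link_tracks(_detections_from_paths(paths, 20))
    assert len(tracks) == 2
    for tr in tracks:
        assert tr.track_length == 20
        assert np.ptp(tr.positions, axis=0).max() == 0.0


def test_drifting_spots_recover_ground_truth_assignments(rng):
    """Greedy linking matches >= 95% of true frame-to-frame assignments."""
    n_frames, n_spots = 60, 4
    starts = np.array([[6, 10, 10], [6, 10, 40], [6, 40, 10], [6, 40, 40]], float)
    steps = rng.normal(0.0, 0.5 / np.sqrt(3), (n_spots, n_frames - 1, 3))
    paths = [np.cumsum(np.vstack([starts[i][None], steps[i]]), axis=0)
             for i in range(n_spots)]
    tracks = link_tracks(_detections_from_paths(paths, n_frames), max_displacement_vox=5.0)
    assert len(tracks) == n_spots
    # brute-force oracle: per tracked frame, the nearest true path's identity
    correct = total = 0
    for tr in tracks:
        ids = []
        for (t, z, y, x) in tr.frames:
            d = [np.linalg.norm(np.array([z, y, x]) - p[t]) for p in paths]
            ids.append(int(np.argmin(d)))
        ids = np.asarray(ids)
        total += len(ids) - 1
        correct += int(np.sum(ids[1:] == ids[:-1]))
    assert correct / total >= 0.95


def test_disappearing_spot_terminates_after_gap_tolerance():
    paths = [np.tile([5, 10, 10], (20, 1))]
    drop = {0: set(range(8, 20))}  # vanishes from frame 8 on
    tracks = link_tracks(_detections_from_paths(paths, 20, drop))
    assert len(tracks) == 1
    assert tracks[0].frames[-1][0] == 7  # last detection frame


# ---------------------------------------------------------------------------
# select_tracks


def _make_track(focus_id, n_frames, pos, bax):
    return tracking.FocusTrack(
        focus_id=focus_id,
        frames=[(t, *pos) for t in range(n_frames)],
        max_intensity_per_channel={"bax": np.asarray(bax, dtype=float)},
    )


def test_selection_filters_short_flat_and_crowded_tracks():
    n = 40
    rising = np.linspace(100.0, 400.0, n)
    good = _make_track("track000", n, (5, 10, 10), rising)
    short = _make_track("track001", 10, (5, 30, 30), np.linspace(100, 400, 10))
    flat = _make_track("track002", n, (5, 10, 40), np.full(n, 300.0))
    pair_a = _make_track("track003", n, (5, 40, 10), rising)
    pair_b = _make_track("track004", n, (5, 40, 13), rising)
    kept, report = select_tracks([good, short, flat, pair_a, pair_b], n_frames=n)
    assert [tr.focus_id for tr in kept] == ["track000"]
    rep = report.set_index("focus_id")
    assert not rep.loc["track001", "long_enough"]
    assert not rep.loc["track002", "spans_recruitment"]
    assert not rep.loc["track003", "isolated"]
    assert not rep.loc["track004", "isolated"]


def test_cell_mask_filters_outside_tracks():
    n = 20
    inside = _make_track("track000", n, (5, 10, 10), np.linspace(100, 400, n))
    outside = _make_track("track001", n, (5, 30, 30), np.linspace(100, 400, n))
    mask = np.zeros((10, 48, 48), dtype=bool)
    mask[:, :20, :20] = True
    kept, report = select_tracks([inside, outside], n_frames=n, cell_mask=mask)
    assert [tr.focus_id for tr in kept] == ["track000"]
    assert not report.set_index("focus_id").loc["track001", "in_mask"]


def test_generator_scenario_selection_is_exact():
    """On rendered stacks, selection keeps exactly the well-behaved spots."""
    n_frames = 40
    t = np.arange(n_frames, dtype=float)
    rows = []

    def add_trace(focus, intensity):
        rows.append(pd.DataFrame({
            "cell_id": "cell000", "focus_id": focus, "time_min": t,
            "channel": "bax", "intensity": intensity,
        }))

    sig = lambda onset, k=0.8, amp=2.0: 1.0 + amp / (1 + np.exp(-k * (t - onset)))
    add_trace("focus000", sig(12.0))
    add_trace("focus001", sig(20.0))
    add_trace("focus002", np.full(n_frames, 1.0))          # never recruits
    fade = sig(10.0)
    fade[15:] = 0.0                                        # disappears mid-movie
    add_trace("focus003", fade)
    traces = pd.concat(rows, ignore_index=True)
    pos = np.stack([
        np.tile([6.0, 12.0, 12.0], (n_frames, 1)),
        np.tile([6.0, 12.0, 36.0], (n_frames, 1)),
        np.tile([6.0, 36.0, 12.0], (n_frames, 1)),
        np.tile([6.0, 36.0, 36.0], (n_frames, 1)),
    ])
    params = StackSimParams(image_shape=(12, 48, 48), n_frames=n_frames,
                            drift_per_frame_vox=0.0, seed=11)
    stacks, gt = synthetic.simulate_stack(params, traces, pos)
    pre = tracking.preprocess(stacks["bax"], sigma_vox=1.0)
    dets = [tracking.detect_spots(f, 5 * params.background_noise_sd) for f in pre]
    tracks = tracking.link_tracks(dets)
    tracking.extract_intensities(tracks, stacks)
    kept, report = select_tracks(tracks, n_frames=n_frames)
    kept_positions = {tuple(tr.frames[0][1:]) for tr in kept}
    assert kept_positions == {(6, 12, 12), (6, 12, 36)}
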