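"""Detector, linker and track filters against rendered ground truth."""

import numpy as np
import pytest

from nm2motility.filament_simulator import Trajectory
from nm2motility.synthetic_imaging import (
    ActinLayout,
    OpticsModel,
    place_trajectories,
    render_background_stack,
    render_movie,
)
from nm2motility.tracking import (
    Spot,
    detect_movie,
    detect_spots,
    filter_and_annotate,
    link_tracks,
    match_tracks_to_ground_truth,
    measure_roi_intensity,
    subtract_background,
    track_statistics,
    trackmate_compat,
)


def _static_traj(duration=1e4):
    return Trajectory(
        event_times=np.array([0.0, duration]), positions=np.zeros(2),
        bound_counts=np.ones((2, 1), int), species_names=("NM2B",),
        segments=np.array([[0.0, duration, 0.0]]), termination="timeout",
        run_length=0.0, duration=duration, mean_velocity=0.0, censored=True,
        bound_time_integral=duration)


def _render_spots(positions_nm, optics, seed=1, n_molecules=30):
    """One frame with spots at given positions, background-subtracted."""
    segs = [[x, y, x + 2000.0, y] for x, y in positions_nm]
    lay = ActinLayout(segments=segs)
    pls = place_trajectories([_static_traj() for _ in segs], lay,
                             [{"488": n_molecules}] * len(segs))
    movie = render_movie(pls, lay, optics, seed=seed, render_actin=False)
    bg = render_background_stack(optics, 20, seed=seed + 1)
    return subtract_background(movie, bg)


def test_trackmate_compat_config_is_verbatim():
    """The printed detection/linking/filter parameter set, frozen."""
    assert trackmate_compat["detector"] == "LoG"
    assert trackmate_compat["estimated_blob_diameter_um"] == 1.0
    assert trackmate_compat["quality_threshold_min"] == 50.0
    assert trackmate_compat["quality_threshold_max"] == 200.0
    assert trackmate_compat["tracker"] == "Simple LAP"
    assert trackmate_compat["linking_max_distance_um"] == 1.0
    assert trackmate_compat["gap_closing_max_distance_um"] == 0.5
    assert trackmate_compat["gap_closing_max_frame_gap"] == 2
    assert trackmate_compat["track_displacement_min_nm"] == 150.0


def test_subtract_background_identities():
    opt = OpticsModel(frame_count=4, image_shape=(16, 16))
    from nm2motility.synthetic_imaging import MovieStack
    const = MovieStack(channels={"488": np.full((4, 16, 16), 7, np.uint16)},
                       optics=opt)
    zero = subtract_background(const, const)
    assert np.all(zero.channels["488"] == 0)
    shifted = MovieStack(channels={"488": np.full((4, 16, 16), 12, np.uint16)},
                         optics=opt)
    bg = MovieStack(channels={"488": np.full((2, 16, 16), 5, np.uint16)}, optics=opt)
    rec = subtract_background(shifted, bg)
    assert np.all(rec.channels["488"] == 7)
    with pytest.raises(ValueError):
        subtract_background(const, MovieStack(channels={"561": np.zeros((1, 16, 16))},
                                              optics=opt))


def test_blank_frame_yields_no_detections():
    opt = OpticsModel(frame_count=5, image_shape=(128, 128))
    movie = render_background_stack(opt, 5, seed=21)
    bg = render_background_stack(opt, 20, seed=22)
    clean = subtract_background(movie, bg)
    for f in range(5):
        assert detect_spots(clean.channels["488"][f]) == []


def test_single_spot_detection_and_localization():
    opt = OpticsModel(frame_count=3, image_shape=(64, 64))
    clean = _render_spots([(4030.0, 3120.0)], opt)
    spots = detect_spots(clean.channels["488"][0])
    assert len(spots) == 1
    s = spots[0]
    assert abs(s.x - 4030.0) < opt.pixel_size
    assert abs(s.y - 3120.0) < opt.pixel_size
    # integrated intensity close to the emitted photons
    assert s.total_intensity == pytest.approx(
        30 * opt.photons_per_fluorophore_per_frame, rel=0.2)


def test_two_spot_resolution_at_blob_scale():
    opt = OpticsModel(frame_count=2, image_shape=(96, 96))
    far = _render_spots([(3000.0, 6000.0), (6000.0, 6000.0)], opt)  # 3 um apart
    assert len(detect_spots(far.channels["488"][0])) == 2
    near = _render_spots([(5000.0, 6000.0), (5200.0, 6000.0)], opt)  # 200 nm
    assert len(detect_spots(near.channels["488"][0])) == 1


def test_link_single_persistent_spot():
    spots = [[Spot(f, 1000.0, 1000.0, 10.0, 1.0, 500.0, 150.0)]
             for f in range(10)]
    tracks = link_tracks(spots)
    assert len(tracks) == 1
    assert len(tracks[0].spots) == 10


def test_gap_closing_within_caps():
    def spot(f, x):
        return Spot(f, x, 2000.0, 10.0, 1.0, 500.0, 150.0)
    spots = [[spot(0, 1000.0)], [], [spot(2, 1300.0)], [spot(3, 1400.0)]]
    tracks = link_tracks(spots)
    assert len(tracks) == 1
    assert [s.frame_index for s in tracks[0].spots] == [0, 2, 3]
    # beyond the gap-closing distance cap: two tracks
    spots = [[spot(0, 1000.0)], [], [spot(2, 1900.0)]]
    assert len(link_tracks(spots)) == 2


def test_linking_permutation_invariance():
    rng = np.random.default_rng(31)
    frames = []
    xs = np.array([1000.0, 4000.0, 8000.0])
    for f in range(6):
        sp = [Spot(f, x + 50 * f, 3000.0, 10.0, 1.0, 500.0, 150.0) for x in xs]
        rng.shuffle(sp)
        frames.append(sp)
    tracks = link_tracks(frames)
    assert len(tracks) == 3
    for t in tracks:
        assert len(t.spots) == 6
        assert np.all(np.diff([s.frame_index for s in t.spots]) == 1)


def test_track_statistics_constructed_kinematics():
    spots = [Spot(f, 1000.0 + 43.0 * f, 500.0, 10.0, 1.0, 500.0, 150.0)
             for f in range(11)]
    from nm2motility.tracking import Track
    t = track_statistics(Track(spots=spots), frame_interval=1.0)
    assert t.mean_velocity == pytest.approx(43.0)
    assert t.run_length == pytest.approx(0.43)
    static = Track(spots=[Spot(0, 1000.0, 500.0, 1, 1, 500.0, 1),
                          Spot(5, 1000.0, 500.0, 1, 1, 500.0, 1)])
    assert track_statistics(static, 1.0).mean_velocity == 0.0


def test_displacement_filter_drops_stationary_tracks():
    from nm2motility.tracking import Track
    static = Track(spots=[Spot(f, 1000.0, 500.0, 1, 1, 500.0, 1)
                          for f in range(8)])
    moving = Track(spots=[Spot(f, 1000.0 + 100.0 * f, 500.0, 1, 1, 500.0, 1)
                          for f in range(8)])
    kept = filter_and_annotate([static, moving], frame_interval=1.0)
    assert len(kept) == 1
    assert kept[0].displacement > 150.0


def test_end_of_actin_censoring_flag():
    from nm2motility.tracking import Track
    lay = ActinLayout(segments=[[1000.0, 500.0, 5000.0, 500.0]])
    at_end = Track(spots=[Spot(f, 4000.0 + 130.0 * f, 500.0, 1, 1, 500.0, 1)
                          for f in range(8)])  # ends at 4910 ~ 5000
    mid = Track(spots=[Spot(f, 1000.0 + 130.0 * f, 500.0, 1, 1, 500.0, 1)
                       for f in range(8)])
    kept = filter_and_annotate([at_end, mid], 1.0, actin=lay,
                               last_frame_index=100)
    assert kept[0].censored_at_end is True
    assert kept[1].censored_at_end is False
    assert not kept[0].censored_at_movie_end


def test_full_movie_tracking_recovers_ground_truth(rendered_movie_pack):
    """Moving rendered filaments are recovered with sub-pixel accuracy."""
    pack = rendered_movie_pack
    clean = subtract_background(pack["movie"], pack["background"])
    spots = detect_movie(clean, "488")
    tracks = link_tracks(spots)
    tracks = filter_and_annotate(
        tracks, clean.optics.frame_interval, actin=pack["layout"],
        last_frame_index=clean.optics.frame_count - 1)
    match = match_tracks_to_ground_truth(tracks, pack["movie"].ground_truth)
    assert match["recovered"].mean() >= 0.9
    err_px = match.loc[match["recovered"], "mean_error_nm"] / clean.optics.pixel_size
    assert err_px.mean() < 0.5


def test_roi_intensity_measures_second_channel():
    opt = OpticsModel(frame_count=40, image_shape=(64, 64))
    lay = ActinLayout(segments=[[3000.0, 3000.0, 7000.0, 3000.0]])
    pls = place_trajectories([_static_traj()], lay, [{"488": 30, "561": 10}])
    movie = render_movie(pls, lay, opt, seed=41, render_actin=False)
    bg = render_background_stack(opt, 20, seed=42, channels=("488", "561"))
    clean = subtract_background(movie, bg)
    spots = detect_movie(clean, "488")
    tracks = link_tracks(spots)
    assert len(tracks) == 1
    roi = measure_roi_intensity(clean, tracks[0], "561")
    expected = 10 * opt.photons_per_fluorophore_per_frame
    assert np.mean(roi) == pytest.approx(expected, rel=0.25)
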