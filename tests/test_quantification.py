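"""Stoichiometry, run-length, velocity and regression estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nm2motility.quantification import (
    IntensityCalibration,
    build_kymograph,
    calibrate_reference,
    estimate_fraction_2A,
    estimate_motor_number,
    fit_run_length,
    fit_velocity,
    regress_runlength_vs_motors,
    save_kymograph_figure,
    save_regression_figure,
    save_run_length_figure,
)


# --- intensity calibration and stoichiometry -------------------------------

def test_calibrate_reference_mean_and_per_track_weighting():
    cal = calibrate_reference(np.full(12, 1000.0))
    assert cal.I_2B_ref == 1000.0
    assert cal.I_2B_ref_se == 0.0
    # tracks are weighted equally regardless of their durations
    cal = calibrate_reference(np.array([1000.0] * 6 + [2000.0] * 6))
    assert cal.I_2B_ref == 1500.0
    with pytest.raises(ValueError):
        calibrate_reference(np.array([1.0]))


def test_motor_number_identities_and_linearity():
    cal = IntensityCalibration(I_2B_ref=500.0)
    assert estimate_motor_number(500.0, cal).n_motors == pytest.approx(60)
    assert estimate_motor_number(250.0, cal).n_motors == pytest.approx(30)
    # linear in I_cof
    n1 = estimate_motor_number(100.0, cal).n_motors
    n3 = estimate_motor_number(300.0, cal).n_motors
    assert n3 == pytest.approx(3 * n1)
    with pytest.raises(ValueError):
        estimate_motor_number(-1.0, cal)


def test_fraction_2A_algebra_and_boundaries():
    cal = IntensityCalibration(I_2B_ref=100.0, I_2A_ref=100.0)
    assert estimate_fraction_2A(30.0, 70.0, cal).F_2A == pytest.approx(0.30)
    assert estimate_fraction_2A(50.0, 50.0, cal).F_2A == pytest.approx(0.5)
    assert estimate_fraction_2A(0.0, 10.0, cal).F_2A == 0.0
    assert estimate_fraction_2A(10.0, 0.0, cal).F_2A == 1.0
    with pytest.raises(ValueError):
        estimate_fraction_2A(0.0, 0.0, cal)


@given(st.floats(0.1, 1e4), st.floats(0.1, 1e4), st.floats(0.01, 100))
@settings(max_examples=100, derandomize=True)
def test_fraction_2A_scale_invariance_and_complement(a, b, scale):
    cal = IntensityCalibration(I_2B_ref=120.0, I_2A_ref=80.0)
    f = estimate_fraction_2A(a, b, cal).F_2A
    f_scaled = estimate_fraction_2A(a * scale, b * scale, cal).F_2A
    assert f_scaled == pytest.approx(f, rel=1e-9)
    swapped_cal = IntensityCalibration(I_2B_ref=80.0, I_2A_ref=120.0)
    f_swap = estimate_fraction_2A(b, a, swapped_cal).F_2A
    assert f + f_swap == pytest.approx(1.0, abs=1e-9)


# --- run-length fitting -----------------------------------------------------

def test_mle_equals_shifted_sample_mean():
    x = np.full(40, 2.5)
    fit = fit_run_length(x, method="mle", detection_minimum=0.0)
    assert fit.characteristic_length == pytest.approx(2.5)
    assert fit.standard_error == pytest.approx(2.5 / np.sqrt(40))


def test_mle_recovers_truncated_exponential_scale():
    """1463 draws from Exp(1.95 um) truncated at the 150 nm filter."""
    rng = np.random.default_rng(7)
    lam_true = 1.95
    x = rng.exponential(lam_true, size=20_000)
    x = x[x >= 0.15][:1463]
    fit = fit_run_length(x, method="mle", detection_minimum=0.15)
    assert fit.n_tracks == 1463
    assert fit.characteristic_length == pytest.approx(
        lam_true, abs=3 * fit.standard_error)


def test_histogram_fit_agrees_with_mle():
    rng = np.random.default_rng(8)
    x = rng.exponential(1.2, size=10_000) + 0.15
    mle = fit_run_length(x, method="mle")
    hist = fit_run_length(x, method="histogram_lsq")
    assert hist.characteristic_length == pytest.approx(
        mle.characteristic_length, rel=0.05)
    assert hist.goodness > 0.95


def test_run_length_censoring_exclusion_is_minimum_estimate():
    """Excluding end-censored runs yields a conservative (minimum) scale.

    Censoring can only truncate a run, so both treatments underestimate
    the true scale, the exclusion rule most strongly:
    lam_excl <= lam_incl <= lam_true (up to sampling noise).
    """
    rng = np.random.default_rng(9)
    lam_true = 1.0
    x = rng.exponential(lam_true, size=6000) + 0.15
    ends = rng.uniform(0.3, 3.0, size=6000)  # remaining actin per run
    censored = x > ends
    obs = np.where(censored, ends, x)
    fit_excl = fit_run_length(obs, censored=censored, method="mle")
    fit_incl = fit_run_length(obs, method="mle")
    noise = 3 * fit_excl.standard_error
    assert fit_excl.characteristic_length <= fit_incl.characteristic_length + noise
    assert fit_incl.characteristic_length <= lam_true + noise
    assert fit_excl.characteristic_length < lam_true  # minimum estimate


def test_run_length_input_validation():
    with pytest.raises(ValueError):
        fit_run_length(np.full(5, 1.0))  # too few
    with pytest.raises(ValueError):
        fit_run_length(np.full(50, 1.0), method="nope")


# --- velocity fitting -------------------------------------------------------

def test_velocity_degenerate_sample():
    fit = fit_velocity(np.full(35, 43.0))
    assert fit.mu == 43.0 and fit.sigma == 0.0 and fit.arithmetic_mean == 43.0


def test_velocity_gaussian_recovery():
    rng = np.random.default_rng(10)
    v = rng.normal(43.0, 21.0, size=1463)
    fit = fit_velocity(v)
    assert fit.gaussian_ok
    assert fit.mu == pytest.approx(43.0, abs=3 * max(fit.mu_se, 21 / np.sqrt(1463)))
    assert fit.sigma == pytest.approx(21.0, rel=0.15)


def test_velocity_bimodal_mixture_flagged_non_gaussian():
    """Two-paralog mixtures: arithmetic mean is the reportable statistic."""
    rng = np.random.default_rng(11)
    v = np.concatenate([rng.normal(43, 10, 700), rng.normal(133, 10, 700)])
    fit = fit_velocity(v)
    assert not fit.gaussian_ok
    assert fit.arithmetic_mean == pytest.approx(88.0, abs=2.0)


# --- motor-number regression ------------------------------------------------

def test_regression_line_through_origin():
    reg = regress_runlength_vs_motors([(5, 0.5), (10, 1.0)])
    assert reg.x_intercept == pytest.approx(0.0, abs=1e-9)


def test_regression_two_point_algebra():
    reg = regress_runlength_vs_motors([(9, 0.45), (18, 0.98)])
    assert reg.slope == pytest.approx(0.0589, abs=1e-4)
    assert reg.x_intercept == pytest.approx(1.36, abs=0.02)


def test_regression_recovery_over_replicates():
    """x-intercept recovered within 2 SE on noisy three-point data."""
    rng = np.random.default_rng(12)
    slope, x0 = 0.06, 4.0
    ns = np.array([9.0, 14.0, 18.0])
    se = 0.04
    hits = 0
    for _ in range(500):
        lams = slope * (ns - x0) + rng.normal(0, se, size=3)
        reg = regress_runlength_vs_motors(
            [(n, lam, se) for n, lam in zip(ns, lams)])
        if abs(reg.x_intercept - x0) <= 2 * reg.x_intercept_se:
            hits += 1
    assert hits / 500 >= 0.9


def test_regression_errors():
    with pytest.raises(ValueError):
        regress_runlength_vs_motors([(9, 0.5), (9, 0.6)])


# --- kymograph --------------------------------------------------------------

def test_kymograph_streak_slope_matches_velocity():
    from nm2motility.filament_simulator import Trajectory
    from nm2motility.synthetic_imaging import (
        ActinLayout, OpticsModel, place_trajectories, render_movie)

    v_um_s = 0.05
    opt = OpticsModel(frame_count=80, image_shape=(96, 96))
    lay = ActinLayout(segments=[[1000.0, 6000.0, 10000.0, 6000.0]])
    tr = Trajectory(
        event_times=np.array([0.0, 160.0]), positions=np.array([0.0, 8.0]),
        bound_counts=np.ones((2, 1), int), species_names=("NM2B",),
        segments=np.array([[0.0, 160.0, v_um_s]]), termination="timeout",
        run_length=8.0, duration=160.0, mean_velocity=50.0, censored=True,
        bound_time_integral=1.0)
    pl = place_trajectories([tr], lay, [{"488": 30}])
    movie = render_movie(pl, lay, opt, seed=13, render_actin=False)
    kymo = build_kymograph(movie, lay, 0, channel="488")
    assert kymo.shape[0] == opt.frame_count
    # line-fit oracle on the per-frame argmax positions
    sample_step_nm = lay.lengths[0] / (kymo.shape[1] - 1)
    peak_pos_nm = kymo.argmax(axis=1) * sample_step_nm
    t = np.arange(opt.frame_count) * opt.frame_interval
    slope_nm_s = np.polyfit(t, peak_pos_nm, 1)[0]
    assert slope_nm_s == pytest.approx(v_um_s * 1000, rel=0.05)


def test_figure_outputs_written(tmp_path):
    rng = np.random.default_rng(20)
    x = rng.exponential(1.5, 500) + 0.15
    fit = fit_run_length(x, method="mle")
    save_run_length_figure(x, fit, tmp_path / "rl.png")
    pts = [(9, 0.45, 0.04), (14, 0.7, 0.05), (18, 0.98, 0.03)]
    reg = regress_runlength_vs_motors(pts)
    save_regression_figure(pts, reg, tmp_path / "reg.png")
    save_kymograph_figure(np.random.default_rng(0).poisson(200, (30, 80)),
                          tmp_path / "kymo.png", frame_interval=2.0)
    for name in ("rl.png", "reg.png", "kymo.png"):
        assert (tmp_path / name).stat().st_size > 1000


def test_kymograph_static_spot_is_vertical_line():
    from nm2motility.filament_simulator import Trajectory
    from nm2motility.synthetic_imaging import (
        ActinLayout, OpticsModel, place_trajectories, render_movie)

    opt = OpticsModel(frame_count=30, image_shape=(64, 64))
    lay = ActinLayout(segments=[[1000.0, 4000.0, 7000.0, 4000.0]])
    tr = Trajectory(
        event_times=np.array([0.0, 100.0]), positions=np.zeros(2),
        bound_counts=np.ones((2, 1), int), species_names=("NM2B",),
        segments=np.array([[0.0, 100.0, 0.0]]), termination="timeout",
        run_length=0.0, duration=100.0, mean_velocity=0.0, censored=True,
        bound_time_integral=1.0)
    pl = place_trajectories([tr], lay, [{"488": 30}])
    movie = render_movie(pl, lay, opt, seed=14, render_actin=False)
    kymo = build_kymograph(movie, lay, 0, channel="488")
    peaks = kymo.argmax(axis=1)
    assert np.ptp(peaks) <= 2  # constant position across time

    # empty movie: flat background, no systematic peak structure
    from nm2motility.synthetic_imaging import render_background_stack
    blank = render_background_stack(opt, 30, seed=15)
    kymo_b = build_kymograph(blank, lay, 0, channel="488")
    assert kymo_b.std() < 3 * np.sqrt(opt.background_mean)
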