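"""Estimators for filament motility and stoichiometry.

Covers the statistics extracted from single-filament motility assays:

* intensity calibration against 100%-labeled reference filaments and the
  ratio estimators built on it — the motor-bearing fraction
  ``R = I_cof / I_ref``, the motor count ``n = R * n_c`` (with
  ``n_c = 60`` motor domains per filament from electron microscopy), and
  the two-color paralog fraction
  ``F_2A = (I_2A/I_2A_ref) / (I_2A/I_2A_ref + I_2B/I_2B_ref)``;
* censored single-exponential run-length fitting (histogram least
  squares or maximum likelihood on the detection-truncated exponential);
* Gaussian velocity fitting with the arithmetic mean as the primary
  statistic for visibly non-Gaussian (mixture) distributions;
* weighted linear regression of characteristic run length on motor
  number, whose x-intercept estimates the minimum motor number needed
  for processive movement;
* kymograph construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .synthetic_imaging import ActinLayout, MovieStack

__all__ = [
    "IntensityCalibration",
    "CompositionEstimate",
    "RunLengthFit",
    "VelocityFit",
    "MotorRegression",
    "N_C_MOTORS_PER_FILAMENT",
    "calibrate_reference",
    "estimate_motor_number",
    "estimate_fraction_2A",
    "fit_run_length",
    "fit_velocity",
    "regress_runlength_vs_motors",
    "build_kymograph",
    "save_run_length_figure",
    "save_regression_figure",
    "save_kymograph_figure",
]

#: Average number of motor domains per 100% full-length filament
#: (30 molecules x 2 heads), from electron-microscopy counts.
N_C_MOTORS_PER_FILAMENT = 60


@dataclass(frozen=True)
class IntensityCalibration:
    """Reference intensities of 100%-labeled filaments per channel.

    ``I_2B_ref`` is the mean per-track total intensity of pure NM2-B
    filaments in the 488 channel; ``I_2A_ref`` the pure NM2-A value in
    the 561 channel.  Standard errors are over tracks.
    """

    I_2B_ref: float
    I_2A_ref: float = math.nan
    I_2B_ref_se: float = 0.0
    I_2A_ref_se: float = 0.0
    channel_map: dict = field(default_factory=lambda: {"NM2B": "488", "NM2A": "561"})

    def __post_init__(self) -> None:
        if not self.I_2B_ref > 0:
            raise ValueError("I_2B_ref must be > 0")
        if not math.isnan(self.I_2A_ref) and not self.I_2A_ref > 0:
            raise ValueError("I_2A_ref must be > 0 when given")


@dataclass(frozen=True)
class CompositionEstimate:
    """Stoichiometry of a (set of) co-filament(s) from intensities."""

    R: float = math.nan  # fraction of motor-bearing molecules vs pure filaments
    n_motors: float = math.nan  # R * n_c, motor domains per filament
    F_2A: float = math.nan  # NM2-A fraction in paralog co-filaments
    I_cof: float = math.nan
    I_2A_mix: float = math.nan
    I_2B_mix: float = math.nan
    R_se: float = math.nan
    n_motors_se: float = math.nan
    F_2A_se: float = math.nan


@dataclass(frozen=True)
class RunLengthFit:
    """Single-exponential fit of a run-length distribution."""

    characteristic_length: float  # um
    standard_error: float  # um
    n_tracks: int
    goodness: float  # R^2 for histogram fits, log-likelihood for MLE
    method: str = "histogram_lsq"

    def __post_init__(self) -> None:
        if not self.characteristic_length > 0:
            raise ValueError("characteristic_length must be > 0")


@dataclass(frozen=True)
class VelocityFit:
    """Gaussian fit plus arithmetic mean of a velocity distribution."""

    mu: float  # nm/s, Gaussian centre
    sigma: float  # nm/s
    arithmetic_mean: float  # nm/s
    n_tracks: int
    mu_se: float = math.nan
    r_squared: float = math.nan
    gaussian_ok: bool = True  # False when the single-Gaussian fit is poor


@dataclass(frozen=True)
class MotorRegression:
    """Weighted line fit of characteristic run length vs motor number."""

    slope: float  # um per motor
    intercept: float  # um
    x_intercept: float  # motors per half filament
    x_intercept_se: float
    slope_se: float = math.nan
    intercept_se: float = math.nan


def calibrate_reference(
    track_intensities_2B: np.ndarray,
    track_intensities_2A: np.ndarray | None = None,
    min_tracks: int = 10,
) -> IntensityCalibration:
    """Mean per-track total intensity of 100%-labeled reference filaments.

    Each track contributes its time-averaged total intensity once
    (tracks are weighted equally, not by duration).
    """
    i2b = np.asarray(track_intensities_2B, dtype=float)
    if i2b.size < min_tracks:
        raise ValueError(f"need >= {min_tracks} reference tracks, got {i2b.size}")
    kw = dict(
        I_2B_ref=float(i2b.mean()),
        I_2B_ref_se=float(i2b.std(ddof=1) / math.sqrt(i2b.size)) if i2b.size > 1 else 0.0,
    )
    if track_intensities_2A is not None:
        i2a = np.asarray(track_intensities_2A, dtype=float)
        if i2a.size < min_tracks:
            raise ValueError(f"need >= {min_tracks} reference tracks, got {i2a.size}")
        kw["I_2A_ref"] = float(i2a.mean())
        kw["I_2A_ref_se"] = float(i2a.std(ddof=1) / math.sqrt(i2a.size))
    return IntensityCalibration(**kw)


def estimate_motor_number(
    I_cof: float,
    calibration: IntensityCalibration,
    n_c: int = N_C_MOTORS_PER_FILAMENT,
    I_cof_se: float = 0.0,
) -> CompositionEstimate:
    """Motor content of a co-filament from its 488-channel intensity.

    ``R = I_cof / I_2B_ref`` is the motor-bearing molecule fraction
    relative to 100% full-length filaments; ``n = R * n_c`` is the
    average number of motor domains per co-filament.  Standard errors
    propagate from the intensity SE and the calibration SE.
    """
    if I_cof < 0:
        raise ValueError("I_cof must be >= 0")
    R = I_cof / calibration.I_2B_ref
    rel_var = 0.0
    if I_cof > 0:
        rel_var = ((I_cof_se / I_cof) ** 2
                   + (calibration.I_2B_ref_se / calibration.I_2B_ref) ** 2)
    R_se = R * math.sqrt(rel_var)
    return CompositionEstimate(R=R, n_motors=R * n_c, I_cof=I_cof,
                               R_se=R_se, n_motors_se=R_se * n_c)


def estimate_fraction_2A(
    I_2A_mix: float,
    I_2B_mix: float,
    calibration: IntensityCalibration,
) -> CompositionEstimate:
    """NM2-A fraction of a paralog co-filament from two-color intensities.

    Intensities are normalized by the corresponding pure-filament
    references so the two channels become molecule counts on a common
    scale; the fraction is scale-invariant in the raw intensities.
    """
    if I_2A_mix < 0 or I_2B_mix < 0:
        raise ValueError("intensities must be >= 0")
    if math.isnan(calibration.I_2A_ref):
        raise ValueError("calibration lacks the NM2-A reference intensity")
    a = I_2A_mix / calibration.I_2A_ref
    b = I_2B_mix / calibration.I_2B_ref
    if a + b == 0:
        raise ValueError("composition undefined: both normalized intensities are zero")
    f = a / (a + b)
    return CompositionEstimate(F_2A=f, I_2A_mix=I_2A_mix, I_2B_mix=I_2B_mix)


def _freedman_diaconis_edges(x: np.ndarray, x0: float) -> np.ndarray:
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    width = 2 * iqr / x.size ** (1 / 3)
    if width <= 0:
        width = max((x.max() - x0) / 10.0, 1e-6)
    n_bins = max(int(np.ceil((x.max() - x0) / width)), 3)
    return x0 + width * np.arange(n_bins + 1)


def fit_run_length(
    run_lengths: np.ndarray,
    censored: np.ndarray | None = None,
    method: str = "histogram_lsq",
    detection_minimum: float = 0.15,
    min_n: int = 30,
) -> RunLengthFit:
    """Fit a single-exponential decay to a run-length sample (um).

    Censored runs (terminated by reaching the actin end or the end of
    observation rather than by dissociation) are excluded, making the
    result a minimum estimate of the run length.  ``histogram_lsq``
    least-squares fits ``A * exp(-x / lam)`` to a Freedman-Diaconis
    histogram whose first edge sits at ``detection_minimum`` (the track
    displacement filter); ``mle`` uses the shifted-exponential maximum
    likelihood ``lam = mean(x - detection_minimum)``, exact for the
    truncated exponential by memorylessness.
    """
    x = np.asarray(run_lengths, dtype=float)
    if censored is not None:
        x = x[~np.asarray(censored, dtype=bool)]
    x = x[x >= detection_minimum]
    if np.any(x < 0):
        raise ValueError("run lengths must be nonnegative")
    if x.size < min_n:
        raise ValueError(f"need >= {min_n} uncensored run lengths, got {x.size}")

    if method == "mle":
        lam = float(np.mean(x - detection_minimum))
        if lam <= 0:
            raise ValueError("degenerate sample: all values at the detection minimum")
        se = lam / math.sqrt(x.size)
        loglik = float(-x.size * (math.log(lam) + 1.0))
        return RunLengthFit(characteristic_length=lam, standard_error=se,
                            n_tracks=int(x.size), goodness=loglik, method="mle")
    if method != "histogram_lsq":
        raise ValueError(f"unknown method {method!r}")

    edges = _freedman_diaconis_edges(x, detection_minimum)
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    lam0 = max(float(np.mean(x - detection_minimum)), 1e-3)

    def model(xv, amp, lam):
        return amp * np.exp(-xv / lam)

    popt, pcov = curve_fit(model, centers, counts,
                           p0=[counts.max() if counts.max() > 0 else 1.0, lam0],
                           maxfev=10000)
    lam = float(popt[1])
    if lam <= 0:
        raise ValueError("exponential fit failed to converge to a positive scale")
    se = float(np.sqrt(pcov[1, 1]))
    resid = counts - model(centers, *popt)
    ss_tot = float(((counts - counts.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return RunLengthFit(characteristic_length=lam, standard_error=se,
                        n_tracks=int(x.size), goodness=r2, method="histogram_lsq")


def fit_velocity(velocities: np.ndarray, min_n: int = 30,
                 r2_threshold: float = 0.8) -> VelocityFit:
    """Gaussian fit of a velocity histogram plus the arithmetic mean.

    When the single-Gaussian fit is poor (R^2 below ``r2_threshold``,
    as for paralog mixtures whose velocity distribution is bimodal),
    ``gaussian_ok`` is False and the arithmetic mean is the statistic to
    report.
    """
    v = np.asarray(velocities, dtype=float)
    if v.size < min_n:
        raise ValueError(f"need >= {min_n} velocities, got {v.size}")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0:
        return VelocityFit(mu=mean, sigma=0.0, arithmetic_mean=mean,
                           n_tracks=int(v.size), mu_se=0.0, r_squared=1.0)

    counts, edges = np.histogram(v, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])

    def model(x, amp, mu, sigma):
        return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    try:
        popt, pcov = curve_fit(model, centers, counts,
                               p0=[counts.max(), mean, sd], maxfev=10000)
        mu, sigma = float(popt[1]), abs(float(popt[2]))
        mu_se = float(np.sqrt(pcov[1, 1]))
        resid = counts - model(centers, *popt)
        ss_tot = float(((counts - counts.mean()) ** 2).sum())
        r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    except RuntimeError:
        mu, sigma, mu_se, r2 = math.nan, math.nan, math.nan, -math.inf
    return VelocityFit(mu=mu, sigma=sigma, arithmetic_mean=mean,
                       n_tracks=int(v.size), mu_se=mu_se, r_squared=r2,
                       gaussian_ok=bool(r2 >= r2_threshold))


def regress_runlength_vs_motors(
    points: list[tuple[float, float] | tuple[float, float, float]],
    n_bootstrap: int = 0,
    seed: int = 0,
) -> MotorRegression:
    """Weighted linear fit of characteristic run length on motor number.

    ``points`` are ``(n_motors_half, lam)`` or
    ``(n_motors_half, lam, lam_se)``; weights are ``1/se^2`` when SEs
    are given.  The x-intercept ``-intercept/slope`` estimates the
    minimum motor number sustaining processive movement.  Its SE comes
    from first-order propagation with the parameter covariance, or from
    a parametric bootstrap when ``n_bootstrap > 0``.
    """
    pts = [tuple(p) for p in points]
    ns = np.array([p[0] for p in pts], dtype=float)
    lams = np.array([p[1] for p in pts], dtype=float)
    ses = np.array([p[2] if len(p) > 2 else np.nan for p in pts], dtype=float)
    if np.unique(ns).size < 2:
        raise ValueError("need >= 2 points with distinct motor numbers")
    use_w = np.isfinite(ses).all() and np.all(ses > 0)
    w = 1.0 / ses ** 2 if use_w else np.ones_like(ns)

    W = np.diag(w)
    X = np.column_stack([ns, np.ones_like(ns)])
    xtw = X.T @ W
    cov = np.linalg.inv(xtw @ X)
    beta = cov @ xtw @ lams
    slope, intercept = float(beta[0]), float(beta[1])
    if slope == 0:
        raise ValueError("slope is zero: x-intercept undefined")
    if ns.size > 2 and not use_w:
        resid = lams - X @ beta
        s2 = float(resid @ resid) / (ns.size - 2)
        cov = cov * s2
    x_int = -intercept / slope

    if n_bootstrap > 0 and use_w:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_bootstrap):
            lam_b = rng.normal(lams, ses)
            beta_b = cov @ 0  # placeholder shape
            beta_b = np.linalg.solve(xtw @ X, xtw @ lam_b)
            if beta_b[0] != 0:
                draws.append(-beta_b[1] / beta_b[0])
        x_int_se = float(np.std(draws, ddof=1))
    else:
        # d(x_int)/d(slope) = intercept/slope^2 ; d/d(intercept) = -1/slope
        g = np.array([intercept / slope ** 2, -1.0 / slope])
        x_int_se = float(math.sqrt(g @ cov @ g))

    return MotorRegression(
        slope=slope, intercept=intercept, x_intercept=float(x_int),
        x_intercept_se=x_int_se,
        slope_se=float(math.sqrt(cov[0, 0])),
        intercept_se=float(math.sqrt(cov[1, 1])))


def build_kymograph(
    movie: MovieStack,
    actin: ActinLayout,
    segment_index: int = 0,
    channel: str | None = None,
    line_width: int = 3,
    reduce: str = "max",
) -> np.ndarray:
    """Position-vs-time intensity image along one actin segment.

    For every frame, the movie is sampled along the segment at half-
    pixel steps; at each sample the maximum (or mean) intensity across
    ``line_width`` pixels perpendicular to the segment is taken.  Rows
    of the output are frames (time), columns position along the actin;
    diagonal streaks indicate processive movement.
    """
    if channel is None:
        channel = sorted(movie.channels)[0]
    arr = np.asarray(movie.channels[channel], dtype=float)
    ps = movie.optics.pixel_size
    h, w = arr.shape[1:]
    seg = actin.segments[segment_index]
    u = actin.directions[segment_index]
    length = actin.lengths[segment_index]
    normal = np.array([-u[1], u[0]])

    n_samples = max(int(length / (ps / 2.0)), 2)
    s_vals = np.linspace(0.0, length, n_samples)
    offsets = (np.arange(line_width) - (line_width - 1) / 2.0) * ps

    # sample coordinates (px indices), clipped to the field
    pts = (seg[0:2][None, None, :] + s_vals[:, None, None] * u[None, None, :]
           + offsets[None, :, None] * normal[None, None, :])
    cols = np.clip((pts[..., 0] / ps).astype(int), 0, w - 1)
    rows = np.clip((pts[..., 1] / ps).astype(int), 0, h - 1)
    if np.any((pts[..., 0] < -ps) | (pts[..., 0] > (w + 1) * ps)):
        raise ValueError("actin segment lies outside the field")

    samples = arr[:, rows, cols]  # (frames, n_samples, line_width)
    if reduce == "max":
        return samples.max(axis=2)
    if reduce == "mean":
        return samples.mean(axis=2)
    raise ValueError(f"unknown reduce {reduce!r}")


# --- figure outputs ---------------------------------------------------------

def save_run_length_figure(run_lengths, fit: RunLengthFit, path,
                           detection_minimum: float = 0.15) -> None:
    """Frequency histogram with the fitted exponential overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(run_lengths, float)
    x = x[x >= detection_minimum]
    fig, ax = plt.subplots(figsize=(4, 3))
    counts, edges, _ = ax.hist(x, bins="fd", color="0.8", edgecolor="0.4")
    xs = np.linspace(detection_minimum, x.max(), 200)
    lam = fit.characteristic_length
    width = edges[1] - edges[0]
    amp = x.size * width / lam * math.exp(detection_minimum / lam)
    ax.plot(xs, amp * np.exp(-xs / lam), "k-")
    ax.set_xlabel("run length (um)")
    ax.set_ylabel("frequency")
    ax.set_title(f"lambda = {lam:.2f} +/- {fit.standard_error:.2f} um "
                 f"(n = {fit.n_tracks})", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_regression_figure(points, reg: MotorRegression, path) -> None:
    """Run length vs motor number with the weighted line fit."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = [tuple(p) for p in points]
    ns = np.array([p[0] for p in pts], float)
    lams = np.array([p[1] for p in pts], float)
    ses = np.array([p[2] if len(p) > 2 else 0.0 for p in pts], float)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.errorbar(ns, lams, yerr=ses, fmt="o", color="k", capsize=3)
    xs = np.linspace(min(reg.x_intercept, ns.min()) - 1, ns.max() + 1, 50)
    ax.plot(xs, reg.slope * xs + reg.intercept, "k-")
    ax.axhline(0, color="0.7", lw=0.8)
    ax.set_xlabel("motors per half filament")
    ax.set_ylabel("characteristic run length (um)")
    ax.set_title(f"x-intercept = {reg.x_intercept:.1f} +/- "
                 f"{reg.x_intercept_se:.1f} motors", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_kymograph_figure(kymograph: np.ndarray, path,
                          frame_interval: float = 1.0,
                          pixel_step_um: float = 0.065) -> None:
    """Kymograph image (position along actin x time)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    extent = (0, kymograph.shape[1] * pixel_step_um,
              kymograph.shape[0] * frame_interval, 0)
    ax.imshow(kymograph, cmap="gray", aspect="auto", extent=extent)
    ax.set_xlabel("position along actin (um)")
    ax.set_ylabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
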