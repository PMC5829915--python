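"""Rendering of simulated filament runs into synthetic TIRF movie stacks.

Each myosin filament is drawn as a diffraction-limited 2-D Gaussian spot
(the filaments are barely longer than the resolution limit) whose
integrated photon count is proportional to the number of fluorescently
labeled molecules it contains.  Actin filaments are static line profiles
in their own channel.  Images carry Poisson shot noise on signal plus
background and Gaussian read noise, quantized to unsigned 16-bit counts.
Ground-truth positions and molecule counts are emitted alongside every
rendered stack, so downstream tracking and stoichiometry estimators can
be validated without any real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .filament_simulator import Trajectory

__all__ = [
    "OpticsModel",
    "ActinLayout",
    "MovieStack",
    "FilamentPlacement",
    "layout_actin",
    "place_trajectories",
    "render_movie",
    "render_background_stack",
    "save_movie",
]


@dataclass(frozen=True)
class OpticsModel:
    """Camera and illumination parameters of the synthetic microscope.

    Defaults emulate a 100x TIRF objective on a 13 um-pixel EMCCD
    (130 nm/px).  ``photons_per_fluorophore_per_frame`` sets the signal
    scale; EM gain and offset are folded into this count scale.
    """

    pixel_size: float = 130.0  # nm per pixel
    psf_sigma: float = 140.0  # nm
    frame_interval: float = 2.0  # s
    photons_per_fluorophore_per_frame: float = 30.0
    background_mean: float = 200.0  # counts
    read_noise_sd: float = 3.0  # counts
    frame_count: int = 150
    image_shape: tuple[int, int] = (256, 256)  # (rows, cols) px

    def __post_init__(self) -> None:
        for name in ("pixel_size", "psf_sigma", "frame_interval",
                     "background_mean", "read_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.photons_per_fluorophore_per_frame < 0:
            raise ValueError("photons_per_fluorophore_per_frame must be >= 0")
        if self.frame_count < 1 or min(self.image_shape) < 8:
            raise ValueError("frame_count >= 1 and image_shape >= 8 px required")
        if self.psf_sigma < self.pixel_size / 3:
            raise ValueError("psf_sigma must be >= pixel_size/3 (undersampled PSF)")

    @property
    def field_size_nm(self) -> tuple[float, float]:
        return (self.image_shape[0] * self.pixel_size,
                self.image_shape[1] * self.pixel_size)

    def peak_snr(self, n_fluorophores: int) -> float:
        """Peak-pixel signal over background noise sd for one spot."""
        sigma_px = self.psf_sigma / self.pixel_size
        amp = (n_fluorophores * self.photons_per_fluorophore_per_frame
               / (2 * np.pi * sigma_px ** 2))
        noise_sd = np.sqrt(self.background_mean + self.read_noise_sd ** 2)
        return amp / noise_sd


@dataclass
class ActinLayout:
    """Surface-immobilized actin filaments as oriented line segments.

    ``segments`` has one row per filament: (x0, y0, x1, y1) in nm, with
    motion running from (x0, y0) toward (x1, y1) (polarity).
    """

    segments: np.ndarray
    channel: str = "640"

    def __post_init__(self) -> None:
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=float))
        if np.any(self.lengths <= 0):
            raise ValueError("actin segments must have positive length")

    @property
    def lengths(self) -> np.ndarray:
        d = self.segments[:, 2:4] - self.segments[:, 0:2]
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def directions(self) -> np.ndarray:
        d = self.segments[:, 2:4] - self.segments[:, 0:2]
        return d / self.lengths[:, None]


@dataclass
class MovieStack:
    """Multi-channel synthetic movie with ground truth.

    ``channels`` maps channel label -> uint16 array (frames, rows, cols)
    or float array after background subtraction.  ``ground_truth`` (when
    rendered) is a table of true per-frame spot positions and molecule
    counts per channel.
    """

    channels: dict[str, np.ndarray]
    optics: OpticsModel
    ground_truth: pd.DataFrame | None = None
    layout: ActinLayout | None = None
    seed: int | None = None
    #: signed (unclipped) background-subtracted frames, filled in by
    #: background subtraction and used for unbiased photometry
    signed_channels: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must have identical shapes")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]


@dataclass(frozen=True)
class FilamentPlacement:
    """Assignment of one simulated run to an actin segment.

    ``offset`` is the distance (um) from the segment start at which the
    run begins; ``t_start`` shifts the run in time (s);
    ``fluorophores`` maps channel label -> number of labeled molecules.
    """

    trajectory: Trajectory
    segment_index: int
    fluorophores: dict[str, int]
    offset: float = 0.0
    t_start: float = 0.0


def layout_actin(
    n_filaments: int,
    mean_length_um: float,
    field: tuple[int, int],
    seed: int,
    sd_length_um: float = 0.0,
    pixel_size: float = 130.0,
    orientation: str | float = "random",
    min_start_separation_um: float = 2.0,
    margin_um: float = 0.5,
    max_tries: int = 20000,
) -> ActinLayout:
    """Place random actin line segments in the field.

    Lengths are drawn from a normal distribution truncated at one pixel;
    start points are rejected until pairwise separated by
    ``min_start_separation_um``; segments must fit inside the field.
    ``orientation`` is ``"random"``, ``"rows"`` (horizontal segments on
    distinct rows, for unambiguous tracking benchmarks) or a fixed angle
    in radians.
    """
    if n_filaments < 1:
        raise ValueError("n_filaments must be >= 1")
    rng = np.random.default_rng(seed)
    h_nm = field[0] * pixel_size
    w_nm = field[1] * pixel_size
    margin = margin_um * 1000.0
    min_sep = min_start_separation_um * 1000.0

    segments: list[tuple[float, float, float, float]] = []
    if orientation == "rows":
        usable = h_nm - 2 * margin
        if n_filaments > 1 and usable / (n_filaments - 1) < min_sep:
            raise ValueError("field too small to place filaments on separated rows")
        ys = margin + np.arange(n_filaments) * (usable / max(n_filaments - 1, 1))
        for i in range(n_filaments):
            length = max(rng.normal(mean_length_um, sd_length_um),
                         pixel_size / 1000.0) * 1000.0
            length = min(length, w_nm - 2 * margin)
            x0 = rng.uniform(margin, max(w_nm - margin - length, margin + 1e-9))
            segments.append((x0, ys[i], x0 + length, ys[i]))
        return ActinLayout(segments=np.asarray(segments))

    starts: list[tuple[float, float]] = []
    tries = 0
    while len(segments) < n_filaments:
        tries += 1
        if tries > max_tries:
            raise ValueError("field too small to place the requested filaments")
        length = max(rng.normal(mean_length_um, sd_length_um),
                     pixel_size / 1000.0) * 1000.0
        theta = rng.uniform(0, 2 * np.pi) if orientation == "random" else float(orientation)
        x0 = rng.uniform(margin, w_nm - margin)
        y0 = rng.uniform(margin, h_nm - margin)
        x1 = x0 + length * np.cos(theta)
        y1 = y0 + length * np.sin(theta)
        if not (margin <= x1 <= w_nm - margin and margin <= y1 <= h_nm - margin):
            continue
        if any((x0 - sx) ** 2 + (y0 - sy) ** 2 < min_sep ** 2 for sx, sy in starts):
            continue
        starts.append((x0, y0))
        segments.append((x0, y0, x1, y1))
    return ActinLayout(segments=np.asarray(segments))


def place_trajectories(
    trajectories: list[Trajectory],
    layout: ActinLayout,
    fluorophores: list[dict[str, int]],
    t_starts: list[float] | None = None,
    offsets: list[float] | None = None,
) -> list[FilamentPlacement]:
    """Map simulated runs one-to-one onto actin segments (run i -> segment i)."""
    if len(trajectories) > layout.segments.shape[0]:
        raise ValueError("more trajectories than actin segments")
    if len(fluorophores) != len(trajectories):
        raise ValueError("need one fluorophore map per trajectory")
    t_starts = t_starts or [0.0] * len(trajectories)
    offsets = offsets or [0.0] * len(trajectories)
    return [
        FilamentPlacement(trajectory=tr, segment_index=i, fluorophores=fl,
                          offset=off, t_start=ts)
        for i, (tr, fl, ts, off) in enumerate(
            zip(trajectories, fluorophores, t_starts, offsets))
    ]


def _pixel_integrated_gaussian(x_nm: float, y_nm: float, photons: float,
                               optics: OpticsModel, out: np.ndarray) -> None:
    """Add a pixel-integrated 2-D Gaussian spot to ``out`` (photon units).

    Pixel (0,0) centre sits at (pixel_size/2, pixel_size/2) nm, so pixel
    i covers [i*ps, (i+1)*ps) nm.  Integration over each pixel uses erf
    differences, conserving total photons up to field clipping.
    """
    from scipy.special import erf

    ps = optics.pixel_size
    s = optics.psf_sigma
    h, w = out.shape
    half = max(int(np.ceil(5 * s / ps)), 2)
    ix0 = max(int(np.floor(x_nm / ps)) - half, 0)
    ix1 = min(int(np.floor(x_nm / ps)) + half + 1, w)
    iy0 = max(int(np.floor(y_nm / ps)) - half, 0)
    iy1 = min(int(np.floor(y_nm / ps)) + half + 1, h)
    if ix0 >= ix1 or iy0 >= iy1:
        return
    xs = np.arange(ix0, ix1 + 1) * ps
    ys = np.arange(iy0, iy1 + 1) * ps
    fx = 0.5 * (1 + erf((xs - x_nm) / (np.sqrt(2) * s)))
    fy = 0.5 * (1 + erf((ys - y_nm) / (np.sqrt(2) * s)))
    out[iy0:iy1, ix0:ix1] += photons * np.outer(np.diff(fy), np.diff(fx))


def _render_actin_channel(layout: ActinLayout, optics: OpticsModel,
                          photons_per_um: float = 2000.0) -> np.ndarray:
    """Static line profile of the actin segments, photon units."""
    img = np.zeros(optics.image_shape, dtype=float)
    step = optics.pixel_size / 2.0
    for x0, y0, x1, y1 in layout.segments:
        length = float(np.hypot(x1 - x0, y1 - y0))
        n_pts = max(int(length / step), 2)
        per_pt = photons_per_um * (length / 1000.0) / n_pts
        for t in np.linspace(0.0, 1.0, n_pts):
            _pixel_integrated_gaussian(x0 + t * (x1 - x0), y0 + t * (y1 - y0),
                                       per_pt, optics, img)
    return img


def _apply_camera(signal: np.ndarray, optics: OpticsModel,
                  rng: np.random.Generator) -> np.ndarray:
    """Poisson(signal + background) + Gaussian read noise, as uint16.

    The Poisson draw is split into a constant-background part and a
    sparse signal part (signal is zero on most pixels), which is
    distributionally identical since Poisson variables add.
    """
    counts = rng.poisson(optics.background_mean, size=signal.shape).astype(np.float32)
    nz = signal > 0
    if nz.any():
        counts[nz] += rng.poisson(signal[nz])
    noise = rng.standard_normal(signal.shape, dtype=np.float32)
    noise *= optics.read_noise_sd
    counts += noise
    np.rint(counts, out=counts)
    np.clip(counts, 0, 65535, out=counts)
    return counts.astype(np.uint16)


def render_movie(
    placements: list[FilamentPlacement],
    layout: ActinLayout,
    optics: OpticsModel,
    seed: int,
    render_actin: bool = True,
    bleach_rate: float = 0.0,
) -> MovieStack:
    """Render placed runs into a multi-channel movie stack.

    Spots are visible from ``t_start`` to ``t_start + duration`` of
    their run; intensity per channel is (labeled molecules) x
    (photons per fluorophore per frame), optionally decaying at
    ``bleach_rate`` (per second) to emulate photobleaching.  Returns the
    stack together with ground-truth per-frame positions.
    """
    rng = np.random.default_rng(seed)
    channel_labels = sorted({ch for p in placements for ch in p.fluorophores})
    n_frames = optics.frame_count
    h, w = optics.image_shape
    dirs = layout.directions
    starts = layout.segments[:, 0:2]
    lengths_nm = layout.lengths

    signal = {ch: np.zeros((n_frames, h, w), dtype=float) for ch in channel_labels}
    gt_records = []
    frame_times = np.arange(n_frames) * optics.frame_interval

    for fid, p in enumerate(placements):
        seg = p.segment_index
        tr = p.trajectory
        t_local_all = frame_times - p.t_start
        visible = (t_local_all >= 0) & (t_local_all <= tr.duration)
        if not visible.any():
            continue
        s_um_all = np.full(n_frames, np.nan)
        s_um_all[visible] = p.offset + tr.position_at(t_local_all[visible])
        for f in np.nonzero(visible)[0]:
            t_local = t_local_all[f]
            s_nm = min(s_um_all[f] * 1000.0, lengths_nm[seg])
            x = starts[seg, 0] + dirs[seg, 0] * s_nm
            y = starts[seg, 1] + dirs[seg, 1] * s_nm
            clipped = not (0 <= x <= w * optics.pixel_size
                           and 0 <= y <= h * optics.pixel_size)
            fade = float(np.exp(-bleach_rate * t_local)) if bleach_rate > 0 else 1.0
            rec = {"frame": int(f), "filament_id": fid, "x_nm": x, "y_nm": y,
                   "segment_index": seg, "clipped": clipped,
                   "position_um": s_um_all[f], "termination": tr.termination}
            for ch in channel_labels:
                n_fluor = p.fluorophores.get(ch, 0)
                rec[f"n_molecules_{ch}"] = n_fluor
                if n_fluor > 0 and not clipped:
                    _pixel_integrated_gaussian(
                        x, y,
                        n_fluor * optics.photons_per_fluorophore_per_frame * fade,
                        optics, signal[ch][f])
            gt_records.append(rec)

    channels = {ch: _apply_camera(signal[ch], optics, rng) for ch in channel_labels}
    if render_actin:
        actin_signal = _render_actin_channel(layout, optics)
        channels[layout.channel] = _apply_camera(
            np.broadcast_to(actin_signal, (n_frames, h, w)).copy(), optics, rng)

    gt = pd.DataFrame.from_records(gt_records) if gt_records else None
    return MovieStack(channels=channels, optics=optics, ground_truth=gt,
                      layout=layout, seed=seed)


def render_background_stack(optics: OpticsModel, n_frames: int = 20,
                            seed: int = 0,
                            channels: tuple[str, ...] = ("488",)) -> MovieStack:
    """Signal-free calibration stack with the same noise model.

    Emulates capturing a set of field-of-view images at identical laser
    power and exposure before the experiment.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = optics.image_shape
    zeros = np.zeros((n_frames, h, w), dtype=float)
    return MovieStack(
        channels={ch: _apply_camera(zeros, optics, rng) for ch in channels},
        optics=optics, seed=seed)


def save_movie(stack: MovieStack, outdir, prefix: str = "movie") -> dict[str, str]:
    """Write one multi-page TIFF per channel plus a JSON sidecar.

    Returns the mapping of channel label to written TIFF path.  Ground
    truth, when present, is written as ``<prefix>_ground_truth.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for ch, arr in stack.channels.items():
        p = outdir / f"{prefix}_ch{ch}.tif"
        tifffile.imwrite(p, np.asarray(arr))
        paths[ch] = str(p)
    sidecar = {
        "seed": stack.seed,
        "channels": sorted(stack.channels),
        "optics": {
            "pixel_size_nm": stack.optics.pixel_size,
            "psf_sigma_nm": stack.optics.psf_sigma,
            "frame_interval_s": stack.optics.frame_interval,
            "photons_per_fluorophore_per_frame":
                stack.optics.photons_per_fluorophore_per_frame,
            "background_mean_counts": stack.optics.background_mean,
            "read_noise_sd_counts": stack.optics.read_noise_sd,
            "frame_count": stack.optics.frame_count,
            "image_shape_px": list(stack.optics.image_shape),
        },
    }
    (outdir / f"{prefix}_meta.json").write_text(json.dumps(sidecar, indent=2))
    if stack.ground_truth is not None:
        stack.ground_truth.to_csv(outdir / f"{prefix}_ground_truth.csv", index=False)
    return paths
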