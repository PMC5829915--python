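"""Stochastic simulation of single bipolar myosin filaments moving on actin.

A bipolar filament engages one actin filament with the motors of one of
its two halves.  Each motor domain is an independent two-state unit
attaching at rate ``k_att = 1/((1-r) t_cycle)`` and detaching at rate
``k_det = 1/(r t_cycle)``, so its stationary bound probability equals
the duty ratio ``r``.  While at least one motor is bound the filament
glides at the unloaded speed of the slowest species currently bound;
mixture velocity is therefore dominated by the slower paralog.  When the
last motor detaches, a rescue window of length
``rescue_window_at_unit_viscosity * viscosity`` opens during which a new
attachment continues the run (high viscosity slows diffusive escape);
otherwise the run terminates.  Runs are censored when the filament
reaches the end of its actin track or outlives ``max_time``.

The simulation is exact (event-driven, Gillespie); position is
integrated analytically between events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .motor_model import DEFAULT_SPECIES, MotorSpecies

__all__ = [
    "FilamentComposition",
    "SimulationConditions",
    "Trajectory",
    "CompositionDesign",
    "sample_composition",
    "simulate_run",
    "simulate_ensemble",
    "run_table_to_csv",
    "run_table_from_csv",
]

MOLECULES_PER_FILAMENT_DEFAULT = 30  # 60 motor domains per filament (EM count)


def _child_seed(master_seed: int, index: int) -> int:
    """Deterministic per-run seed below 2**31 derived from a master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class FilamentComposition:
    """Molecule counts in the actin-engaged half of a bipolar filament.

    ``n_motor_molecules_A/B`` are full-length (motor-bearing) molecules;
    ``n_tail_molecules`` are headless tail fragments that co-polymerize
    but contribute no motor domains.  Motor domains available to the
    actin track: ``heads_per_molecule * (n_A + n_B)``.
    """

    n_motor_molecules_A: int = 0
    n_motor_molecules_B: int = 0
    n_tail_molecules: int = 0
    heads_per_molecule: int = 2

    def __post_init__(self) -> None:
        for name in ("n_motor_molecules_A", "n_motor_molecules_B", "n_tail_molecules"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.heads_per_molecule < 1:
            raise ValueError("heads_per_molecule must be >= 1")

    @property
    def n_motors_A(self) -> int:
        return self.heads_per_molecule * self.n_motor_molecules_A

    @property
    def n_motors_B(self) -> int:
        return self.heads_per_molecule * self.n_motor_molecules_B

    @property
    def n_motors(self) -> int:
        """Motor domains per half filament (tails contribute none)."""
        return self.n_motors_A + self.n_motors_B


@dataclass(frozen=True)
class SimulationConditions:
    """Assay conditions for a simulated run.

    viscosity is in mPa*s (1.0 for aqueous buffer, ~25.0 for 0.5%
    methylcellulose); actin_length in micrometres; max_time in seconds.
    ``rescue_window_at_unit_viscosity`` (tau0, seconds) is the time a
    fully detached filament lingers near actin at viscosity 1 before
    diffusing away; the effective window scales linearly with viscosity.
    """

    viscosity: float = 1.0
    actin_length: float = 15.0
    max_time: float = 600.0
    rescue_window_at_unit_viscosity: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError("viscosity must be > 0")
        if self.actin_length <= 0:
            raise ValueError("actin_length must be > 0")
        if self.max_time <= 0:
            raise ValueError("max_time must be > 0")
        if self.rescue_window_at_unit_viscosity < 0:
            raise ValueError("rescue window must be >= 0")

    @property
    def rescue_window(self) -> float:
        """Effective rescue window tau0 * viscosity, seconds."""
        return self.rescue_window_at_unit_viscosity * self.viscosity


@dataclass
class Trajectory:
    """One simulated processive run.

    ``event_times`` / ``positions`` / ``bound_counts`` record the full
    Gillespie event sequence (bound_counts has one column per species in
    ``species_names``).  ``segments`` is the compact motion profile:
    rows ``(t_start, t_end, velocity_um_s)`` covering [0, duration].
    """

    event_times: np.ndarray
    positions: np.ndarray
    bound_counts: np.ndarray
    species_names: tuple[str, ...]
    segments: np.ndarray
    termination: str  # all_detached | reached_end | timeout
    run_length: float  # micrometres
    duration: float  # seconds, up to final detachment / censoring event
    mean_velocity: float  # nm/s
    censored: bool
    bound_time_integral: float  # integral of total bound count over time, motor*s
    composition: FilamentComposition | None = None
    seed: int | None = None

    def position_at(self, times: np.ndarray) -> np.ndarray:
        """Position (um) at arbitrary times; clamped to [0, duration]."""
        times = np.asarray(times, dtype=float)
        seg = self.segments
        pos = np.empty_like(times)
        t = np.clip(times, 0.0, self.duration)
        # cumulative position at segment starts
        seg_start = seg[:, 0]
        seg_v = seg[:, 2]
        seg_pos0 = np.concatenate([[0.0], np.cumsum((seg[:, 1] - seg[:, 0]) * seg_v)])[:-1]
        idx = np.clip(np.searchsorted(seg_start, t, side="right") - 1, 0, len(seg) - 1)
        pos = seg_pos0[idx] + (t - seg_start[idx]) * seg_v[idx]
        return pos


@dataclass(frozen=True)
class CompositionDesign:
    """Random co-polymerization design for an ensemble of filaments.

    ``mix_kind`` selects which pair of species the ratio refers to:
    ``"fulllength_tail"`` mixes full-length NM2-B with headless tails,
    ``"A_B"`` mixes the NM2-A and NM2-B paralogs.  Each molecule of each
    half filament is assigned independently with probability
    proportional to the ratio parts (binomial composition).
    """

    mix_ratio: tuple[float, float] = (1.0, 0.0)
    mix_kind: str = "fulllength_tail"
    molecules_per_filament: int = MOLECULES_PER_FILAMENT_DEFAULT
    heads_per_molecule: int = 2

    def __post_init__(self) -> None:
        if self.mix_kind not in ("fulllength_tail", "A_B"):
            raise ValueError(f"unknown mix_kind {self.mix_kind!r}")
        a, b = self.mix_ratio
        if a < 0 or b < 0 or (a + b) == 0:
            raise ValueError("mixing-ratio parts must be nonnegative, not all zero")
        if self.molecules_per_filament <= 0 or self.molecules_per_filament % 2:
            raise ValueError("molecules_per_filament must be even and > 0")


def sample_composition(design: CompositionDesign, seed: int) -> FilamentComposition:
    """Draw the engaged-half composition of one filament.

    Each of the ``molecules_per_filament / 2`` molecules of the half is
    assigned a species by an independent draw with probability
    proportional to the mixing-ratio parts.
    """
    rng = np.random.default_rng(seed)
    half = design.molecules_per_filament // 2
    a, b = design.mix_ratio
    p_first = a / (a + b)
    n_first = int(rng.binomial(half, p_first))
    if design.mix_kind == "fulllength_tail":
        return FilamentComposition(
            n_motor_molecules_A=0,
            n_motor_molecules_B=n_first,
            n_tail_molecules=half - n_first,
            heads_per_molecule=design.heads_per_molecule,
        )
    return FilamentComposition(
        n_motor_molecules_A=n_first,
        n_motor_molecules_B=half - n_first,
        n_tail_molecules=0,
        heads_per_molecule=design.heads_per_molecule,
    )


def _active_species(
    composition: FilamentComposition, species: dict[str, MotorSpecies]
) -> tuple[list[str], list[int], list[float], list[float], list[float]]:
    """Species with at least one motor domain: names, counts and rates."""
    names: list[str] = []
    counts: list[int] = []
    katt: list[float] = []
    kdet: list[float] = []
    v0: list[float] = []
    for key, n in (("NM2A", composition.n_motors_A), ("NM2B", composition.n_motors_B)):
        if n <= 0:
            continue
        sp = species[key]
        if not 0.0 < sp.duty_ratio < 1.0:
            raise ValueError(
                f"species {key} has degenerate duty ratio {sp.duty_ratio}")
        names.append(key)
        counts.append(n)
        katt.append(sp.k_att)
        kdet.append(sp.k_det)
        v0.append(sp.unloaded_speed / 1000.0)  # um/s
    return names, counts, katt, kdet, v0


def simulate_run(
    composition: FilamentComposition,
    conditions: SimulationConditions,
    species: dict[str, MotorSpecies] | None = None,
    seed: int = 0,
    record_events: bool = True,
) -> Trajectory:
    """Simulate one processive run by exact event-driven kinetics.

    The run starts at the first attachment event (time 0, position 0).
    Termination causes: ``all_detached`` (rescue window expired with no
    motor bound), ``reached_end`` (position reached the end of the actin
    track; censored) or ``timeout`` (``max_time`` elapsed; censored).
    ``duration`` excludes the final, unsuccessful rescue window.
    """
    if species is None:
        species = DEFAULT_SPECIES
    names, counts, katt, kdet, v0 = _active_species(composition, species)
    n_sp = len(names)

    if n_sp == 0:
        empty = np.zeros((1, max(n_sp, 1)))
        return Trajectory(
            event_times=np.zeros(1), positions=np.zeros(1), bound_counts=empty,
            species_names=tuple(names) or ("none",),
            segments=np.array([[0.0, 0.0, 0.0]]),
            termination="all_detached", run_length=0.0, duration=0.0,
            mean_velocity=0.0, censored=False, bound_time_integral=0.0,
            composition=composition, seed=seed)

    rng = np.random.default_rng(seed)
    tau = conditions.rescue_window
    L = conditions.actin_length
    t_max = conditions.max_time

    # block-sampled uniforms for speed; refilled on exhaustion
    block = rng.random(4096)
    bi = 0

    def _u() -> float:
        nonlocal block, bi
        if bi >= block.size:
            block = rng.random(4096)
            bi = 0
        u = block[bi]
        bi += 1
        return u

    bound = [0] * n_sp
    t = 0.0
    pos = 0.0
    bti = 0.0  # integral of total bound count dt

    times = [0.0] if record_events else None
    positions = [0.0] if record_events else None
    bound_hist = [tuple(bound)] if record_events else None
    segments: list[list[float]] = []  # [t_start, t_end, v]
    seg_t0 = 0.0
    seg_v = 0.0

    def _close_segment(t_end: float, new_v: float) -> None:
        nonlocal seg_t0, seg_v
        if t_end > seg_t0 or not segments:
            segments.append([seg_t0, t_end, seg_v])
            seg_t0 = t_end
        seg_v = new_v

    def _velocity() -> float:
        v = math.inf
        for i in range(n_sp):
            if bound[i] > 0 and v0[i] < v:
                v = v0[i]
        return 0.0 if v is math.inf else v

    # first attachment at t = 0 (run begins with binding)
    att0 = [counts[i] * katt[i] for i in range(n_sp)]
    tot0 = sum(att0)
    u = _u() * tot0
    acc = 0.0
    first = 0
    for i in range(n_sp):
        acc += att0[i]
        if u <= acc:
            first = i
            break
    bound[first] = 1
    seg_v = _velocity()
    if record_events:
        times.append(0.0)
        positions.append(0.0)
        bound_hist.append(tuple(bound))

    termination = None
    while True:
        rates = []
        total = 0.0
        nb = 0
        for i in range(n_sp):
            ra = (counts[i] - bound[i]) * katt[i]
            rd = bound[i] * kdet[i]
            rates.append((ra, rd))
            total += ra + rd
            nb += bound[i]

        if nb == 0:
            # rescue window: only attachments compete with escape
            if total <= 0.0:
                termination = "all_detached"
                break
            wait = -math.log(max(_u(), 1e-300)) / total
            if wait > tau:
                termination = "all_detached"
                break
            if t + wait >= t_max:
                _close_segment(t_max, 0.0)
                t = t_max
                termination = "timeout"
                break
            t += wait
            # choose attaching species
            u = _u() * total
            acc = 0.0
            for i in range(n_sp):
                acc += rates[i][0]
                if u <= acc:
                    bound[i] = 1
                    break
            _close_segment(t, _velocity())
            if record_events:
                times.append(t)
                positions.append(pos)
                bound_hist.append(tuple(bound))
            continue

        v = _velocity()
        wait = -math.log(max(_u(), 1e-300)) / total

        # censoring checks within the inter-event interval
        t_end_candidates = t + wait
        if v > 0.0 and pos + v * wait >= L:
            dt_to_end = (L - pos) / v
            if t + dt_to_end <= t_max:
                t += dt_to_end
                pos = L
                bti += nb * dt_to_end
                _close_segment(t, 0.0)
                termination = "reached_end"
                break
        if t_end_candidates >= t_max:
            dt = t_max - t
            pos += v * dt
            bti += nb * dt
            t = t_max
            _close_segment(t, 0.0)
            termination = "timeout"
            break

        t += wait
        pos += v * wait
        bti += nb * wait

        # pick event
        u = _u() * total
        acc = 0.0
        for i in range(n_sp):
            ra, rd = rates[i]
            acc += ra
            if u <= acc:
                bound[i] += 1
                break
            acc += rd
            if u <= acc:
                bound[i] -= 1
                break
        new_v = _velocity()
        if new_v != seg_v:
            _close_segment(t, new_v)
        if record_events:
            times.append(t)
            positions.append(pos)
            bound_hist.append(tuple(bound))

    if not segments or segments[-1][1] < t:
        _close_segment(t, 0.0)
    seg_arr = np.asarray(segments, dtype=float)
    if seg_arr.size == 0:
        seg_arr = np.array([[0.0, 0.0, 0.0]])

    duration = t
    run_length = pos
    mean_velocity = (run_length * 1000.0 / duration) if duration > 0 else 0.0
    censored = termination != "all_detached"

    if record_events:
        ev = np.asarray(times)
        pv = np.asarray(positions)
        bc = np.asarray(bound_hist, dtype=int)
    else:
        ev = np.array([0.0, duration])
        pv = np.array([0.0, run_length])
        bc = np.zeros((2, n_sp), dtype=int)

    return Trajectory(
        event_times=ev, positions=pv, bound_counts=bc,
        species_names=tuple(names), segments=seg_arr,
        termination=termination, run_length=run_length, duration=duration,
        mean_velocity=mean_velocity, censored=censored,
        bound_time_integral=bti, composition=composition, seed=seed)


def simulate_ensemble(
    design: CompositionDesign | FilamentComposition,
    conditions: SimulationConditions,
    n_runs: int,
    seed: int,
    species: dict[str, MotorSpecies] | None = None,
    return_trajectories: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[Trajectory]]:
    """Simulate ``n_runs`` independent runs and tabulate them.

    Per-run seeds are derived deterministically from the master seed, so
    any row can be replayed bit-for-bit with ``simulate_run`` and the
    recorded seed.  The distal (non-engaged) half of each filament is
    sampled from the same design so that whole-filament molecule counts
    (the quantities fluorescence reports) are available for rendering.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if species is None:
        species = DEFAULT_SPECIES

    records = []
    trajectories: list[Trajectory] = []
    for i in range(n_runs):
        run_seed = _child_seed(seed, 3 * i)
        if isinstance(design, CompositionDesign):
            comp = sample_composition(design, _child_seed(seed, 3 * i + 1))
            distal = sample_composition(design, _child_seed(seed, 3 * i + 2))
        else:
            comp = design
            distal = design
        traj = simulate_run(comp, conditions, species=species, seed=run_seed,
                            record_events=return_trajectories)
        n_motors = comp.n_motors
        records.append({
            "run_id": i,
            "seed": run_seed,
            "n_molecules_A_half": comp.n_motor_molecules_A,
            "n_molecules_B_half": comp.n_motor_molecules_B,
            "n_tail_half": comp.n_tail_molecules,
            "n_motors_half": n_motors,
            "n_molecules_A_total": comp.n_motor_molecules_A + distal.n_motor_molecules_A,
            "n_molecules_B_total": comp.n_motor_molecules_B + distal.n_motor_molecules_B,
            "n_tail_total": comp.n_tail_molecules + distal.n_tail_molecules,
            "run_length_um": traj.run_length,
            "duration_s": traj.duration,
            "mean_velocity_nm_s": traj.mean_velocity,
            "termination": traj.termination,
            "censored": traj.censored,
            "bound_time_integral": traj.bound_time_integral,
            "viscosity_mPas": conditions.viscosity,
        })
        if return_trajectories:
            trajectories.append(traj)
    table = pd.DataFrame.from_records(records)
    if return_trajectories:
        return table, trajectories
    return table


def run_table_to_csv(table: pd.DataFrame, path, master_seed: int | None = None) -> None:
    """Write a run table as CSV with a provenance header comment."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# nm2motility run table; run lengths um, velocities nm/s\n")
        if master_seed is not None:
            fh.write(f"# master_seed = {master_seed}\n")
        table.to_csv(fh, index=False)


def run_table_from_csv(path) -> pd.DataFrame:
    """Read a run table written by :func:`run_table_to_csv`."""
    return pd.read_csv(path, comment="#")
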