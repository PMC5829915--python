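"""Ensemble duty-ratio mathematics for bipolar myosin filaments.

A single myosin motor spends a fraction ``r`` (the duty ratio) of its
ATPase cycle strongly bound to actin.  A filament presenting ``n``
independent motors to an actin track is attached whenever at least one
motor is bound, so its apparent (ensemble) duty ratio is

    r_f = 1 - (1 - r)**n

This module holds the closed-form predictions built on that relation:
the minimum motor number needed for processive movement, the expected
composition of co-polymerized filaments, and the two-state
attachment/detachment rates implied by a duty ratio and cycle time.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MotorSpecies",
    "EnsembleDutyRatio",
    "filament_duty_ratio",
    "min_motors_for_processivity",
    "expected_fulllength_fraction",
    "species_rates",
    "DEFAULT_SPECIES",
    "PROCESSIVITY_TARGET_RF",
]

#: Ensemble duty ratio assumed necessary for processive movement.
PROCESSIVITY_TARGET_RF = 0.9


@dataclass(frozen=True)
class MotorSpecies:
    """Kinetic and mechanical parameters of one myosin species.

    Parameters
    ----------
    name
        Species label (e.g. ``"NM2B"``).
    duty_ratio
        Fraction of the ATPase cycle spent strongly bound to actin,
        in ``[0, 1]``.
    cycle_time
        Duration of one ATPase cycle, seconds.
    step_size
        Working stroke, nanometres.
    unloaded_speed
        Gliding speed of a saturating ensemble, nm/s.
    """

    name: str
    duty_ratio: float
    cycle_time: float
    step_size: float = 8.0
    unloaded_speed: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.duty_ratio <= 1.0:
            raise ValueError(f"duty_ratio must be in [0, 1], got {self.duty_ratio}")
        if self.cycle_time <= 0:
            raise ValueError(f"cycle_time must be > 0, got {self.cycle_time}")
        if self.step_size <= 0:
            raise ValueError(f"step_size must be > 0, got {self.step_size}")
        if self.unloaded_speed < 0:
            raise ValueError(f"unloaded_speed must be >= 0, got {self.unloaded_speed}")

    @property
    def k_att(self) -> float:
        """Attachment rate 1/((1-r)*t_cycle), per second (requires r < 1)."""
        if self.duty_ratio >= 1.0:
            raise ValueError("attachment rate undefined for duty_ratio = 1")
        return 1.0 / ((1.0 - self.duty_ratio) * self.cycle_time)

    @property
    def k_det(self) -> float:
        """Detachment rate 1/(r*t_cycle), per second (requires r > 0)."""
        if self.duty_ratio <= 0.0:
            raise ValueError("detachment rate undefined for duty_ratio = 0")
        return 1.0 / (self.duty_ratio * self.cycle_time)


@dataclass(frozen=True)
class EnsembleDutyRatio:
    """Ensemble duty ratio r_f of a half filament with ``n_motors`` motors."""

    n_motors: int
    rf: float

    def __post_init__(self) -> None:
        if self.n_motors < 0:
            raise ValueError("n_motors must be >= 0")
        if not 0.0 <= self.rf <= 1.0:
            raise ValueError("rf must be in [0, 1]")


def filament_duty_ratio(r: float, n: int) -> float:
    """Ensemble duty ratio ``1 - (1 - r)**n`` of ``n`` independent motors.

    Parameters
    ----------
    r
        Single-motor duty ratio, in ``[0, 1]``.
    n
        Number of motor domains available to bind the actin filament
        (non-negative integer).

    Returns
    -------
    float
        Probability that at least one of the ``n`` motors is strongly
        bound at any instant.  Monotone nondecreasing in both ``r`` and
        ``n``; ``0.0`` for ``n = 0``.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"duty ratio r must be in [0, 1], got {r}")
    if isinstance(n, bool) or (not isinstance(n, (int,)) and n != int(n)):
        raise ValueError(f"n must be an integer, got {n!r}")
    n = int(n)
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return 1.0 - (1.0 - r) ** n


def min_motors_for_processivity(r: float, target_rf: float = PROCESSIVITY_TARGET_RF) -> int:
    """Smallest motor number whose ensemble duty ratio reaches ``target_rf``.

    Parameters
    ----------
    r
        Single-motor duty ratio, in ``(0, 1]``.
    target_rf
        Required ensemble duty ratio, in ``(0, 1)``.  Defaults to 0.9,
        the conventional threshold for calling a filament processive.

    Returns
    -------
    int
        Smallest ``n`` with ``filament_duty_ratio(r, n) >= target_rf``.
    """
    if not 0.0 < target_rf < 1.0:
        raise ValueError(f"target_rf must be in (0, 1), got {target_rf}")
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"duty ratio r must be in [0, 1], got {r}")
    if r == 0.0:
        raise ValueError("target ensemble duty ratio unreachable with r = 0")
    if r == 1.0:
        return 1
    # 1 - (1-r)^n >= target  <=>  n >= log(1-target)/log(1-r)
    import math

    n = math.ceil(math.log(1.0 - target_rf) / math.log(1.0 - r))
    n = max(n, 1)
    # guard against floating-point boundary slip
    while filament_duty_ratio(r, n) < target_rf:
        n += 1
    while n > 1 and filament_duty_ratio(r, n - 1) >= target_rf:
        n -= 1
    return n


def expected_fulllength_fraction(parts_fulllength: float, parts_tail: float) -> float:
    """Expected motor-bearing fraction under unbiased co-polymerization.

    A full-length:tail mixing ratio of ``a:b`` yields an expected
    fraction ``a / (a + b)`` of full-length (motor-bearing) molecules
    per filament when the two species polymerize randomly.
    """
    if parts_fulllength < 0 or parts_tail < 0:
        raise ValueError("mixing-ratio parts must be nonnegative")
    if parts_fulllength <= 0:
        raise ValueError("parts_fulllength must be > 0")
    return parts_fulllength / (parts_fulllength + parts_tail)


def species_rates(species: MotorSpecies) -> tuple[float, float]:
    """Two-state attachment/detachment rates implied by a duty ratio.

    The motor is modeled as a telegraph process alternating between a
    detached state (mean dwell ``1/k_att``) and an actin-bound state
    (mean dwell ``1/k_det``); the stationary bound probability
    ``(1/k_det) / (1/k_det + 1/k_att)`` equals the duty ratio.

    Returns
    -------
    (k_att, k_det)
        Attachment and detachment rates, per second.
    """
    r = species.duty_ratio
    if r <= 0.0 or r >= 1.0:
        raise ValueError(f"degenerate kinetics for duty_ratio = {r}; need 0 < r < 1")
    return species.k_att, species.k_det


def _nm2_species(name: str, duty_ratio: float, unloaded_speed: float,
                 step_size: float = 8.0) -> MotorSpecies:
    # cycle time chosen so that unloaded_speed = step_size / (r * cycle_time)
    if duty_ratio > 0 and unloaded_speed > 0:
        cycle_time = step_size / (duty_ratio * unloaded_speed)
    else:
        cycle_time = 1.0
    return MotorSpecies(name=name, duty_ratio=duty_ratio, cycle_time=cycle_time,
                        step_size=step_size, unloaded_speed=unloaded_speed)


#: Shipped defaults.  Duty ratios: 0.23 (NM2-B, lower bound from solution
#: kinetics) and 0.05 (NM2-A).  Unloaded speeds are the measured single
#: filament gliding speeds (43 and 133 nm/s); cycle times are derived so
#: that unloaded_speed = step_size / (r * cycle_time) with an 8 nm step.
#: The headless tail fragment co-polymerizes but contributes no motors.
DEFAULT_SPECIES: dict[str, MotorSpecies] = {
    "NM2A": _nm2_species("NM2A", duty_ratio=0.05, unloaded_speed=133.0),
    "NM2B": _nm2_species("NM2B", duty_ratio=0.23, unloaded_speed=43.0),
    "NM2B_tail": MotorSpecies(name="NM2B_tail", duty_ratio=0.0, cycle_time=1.0,
                              step_size=8.0, unloaded_speed=0.0),
}
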