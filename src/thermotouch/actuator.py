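"""Simulated thermal-display hardware loop: PWM vibration and Peltier control.

Two actuators are modelled:

* vibrotactile tactors, driven open-loop by a PWM duty cycle mapped
  monotonically from an ordinal surface-roughness level;
* a Peltier element under the fingertip, driven closed-loop to track the
  setpoint temperature from the touch timeline.  The plant is first order
  (relaxation toward ambient with time constant ``tau``, plus a drive term
  ``gain * duty`` degrees per second, signed by the drive direction), the
  sensor optionally adds Gaussian noise, and the controller is
  proportional with hysteresis and a hard safety clamp.

Controller law: with error ``e = setpoint - sensed``, an idle controller
starts driving only once ``|e|`` exceeds the deadband; an active direction
then persists until ``e`` crosses zero, with duty ``min(1, |e|/error_span)``.
The persistence (hysteresis) lets the loop settle at the stable
proportional equilibrium *inside* the deadband instead of chattering at
its edge.  Heating is forced off whenever the plant is within ``margin``
of ``max_temperature``, and the plant state itself is saturated at
``max_temperature`` (a hardware-style thermal cutoff independent of the
possibly noisy sensor), so the safety bound holds for any setpoint
sequence, step size and noise seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import TouchTimeline

__all__ = [
    "Direction",
    "PwmCommand",
    "PeltierPlant",
    "ControlTrace",
    "vibration_duty",
    "step_controller",
    "simulate_loop",
    "constant_setpoint_timeline",
]


class Direction(str, enum.Enum):
    HEAT = "heat"
    COOL = "cool"
    OFF = "off"


@dataclass(frozen=True)
class PwmCommand:
    """A PWM drive command: duty fraction in [0, 1] at a fixed frequency."""

    duty_cycle: float
    direction: Direction = Direction.OFF
    frequency: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))
        duty = float(self.duty_cycle)
        if not 0.0 <= duty <= 1.0:
            raise ValueError(f"duty_cycle must be in [0, 1], got {duty}")
        if self.direction is Direction.OFF and duty != 0.0:
            raise ValueError("direction 'off' requires duty_cycle 0")
        object.__setattr__(self, "duty_cycle", duty)
        if not self.frequency > 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")


OFF_COMMAND = PwmCommand(duty_cycle=0.0, direction=Direction.OFF)


@dataclass(frozen=True)
class PeltierPlant:
    """First-order Peltier plant plus controller constants.

    time_constant [s]: relaxation time toward ambient.
    gain [C/s]: full-duty temperature slew rate (default 60: smallest
        round value keeping the proportional equilibrium error
        ``error_span*(setpoint-ambient)/(gain*time_constant)`` inside the
        deadband for every reachable setpoint below the safety clamp).
    ambient [C]: unpowered equilibrium (skin/room mix at the fingertip).
    max_temperature [C]: hard safety bound, below sustained-contact burn
        thresholds; margin [C]: clamp engages this far below the bound.
    deadband [C]: tracking tolerance; error_span [C]: error mapped to
        full duty.  sensor_noise_sd [C]: optional Gaussian sensor noise.
    """

    time_constant: float = 5.0
    gain: float = 60.0
    ambient: float = 33.0
    max_temperature: float = 43.0
    margin: float = 0.5
    deadband: float = 0.25
    error_span: float = 7.0
    sensor_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.time_constant > 0:
            raise ValueError(f"time_constant must be positive, got {self.time_constant}")
        if not self.max_temperature > self.ambient:
            raise ValueError("max_temperature must exceed ambient")
        for name in ("gain", "error_span"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("margin", "deadband", "sensor_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def vibration_duty(level: int, max_level: int = 8) -> float:
    """Monotone mapping from ordinal roughness level to PWM duty fraction.

    Level 0 (smooth) is off; the maximum level saturates at full duty;
    intermediate levels are linear.  Longer ON pulses spin the tactors
    faster, rendering rougher surfaces.
    """
    level = int(level)
    max_level = int(max_level)
    if max_level < 1:
        raise ValueError(f"max_level must be >= 1, got {max_level}")
    if not 0 <= level <= max_level:
        raise ValueError(f"roughness level must be in [0, {max_level}], got {level}")
    return level / max_level


def step_controller(
    setpoint: float,
    plant_temperature: float,
    plant: PeltierPlant,
    previous: Optional[PwmCommand] = None,
) -> tuple[PwmCommand, bool]:
    """One controller evaluation: (command, clamped flag).

    ``previous`` carries the hysteresis state (the last issued command);
    pass ``None`` for an idle controller.  The clamped flag is set when
    the safety clamp vetoed (or would veto) heating.
    """
    setpoint = float(setpoint)
    plant_temperature = float(plant_temperature)
    if not (np.isfinite(setpoint) and np.isfinite(plant_temperature)):
        raise ValueError("setpoint and plant_temperature must be finite")

    error = setpoint - plant_temperature
    clamped = plant_temperature >= plant.max_temperature - plant.margin

    prev_dir = previous.direction if previous is not None else Direction.OFF
    if prev_dir is Direction.HEAT and error > 0:
        direction = Direction.HEAT
    elif prev_dir is Direction.COOL and error < 0:
        direction = Direction.COOL
    elif abs(error) > plant.deadband:
        direction = Direction.HEAT if error > 0 else Direction.COOL
    else:
        direction = Direction.OFF

    if clamped and direction is Direction.HEAT:
        direction = Direction.OFF

    if direction is Direction.OFF:
        return OFF_COMMAND, clamped
    duty = min(1.0, abs(error) / plant.error_span)
    return PwmCommand(duty_cycle=duty, direction=direction), clamped


@dataclass(frozen=True)
class ControlTrace:
    """Per-tick closed-loop record.

    The hard safety invariant ``plant_temperatures <= max_temperature``
    is validated at construction.
    """

    times: np.ndarray
    setpoints: np.ndarray
    plant_temperatures: np.ndarray
    commands: tuple
    clamped: np.ndarray
    max_temperature: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "setpoints", np.asarray(self.setpoints, dtype=float))
        object.__setattr__(
            self, "plant_temperatures", np.asarray(self.plant_temperatures, dtype=float)
        )
        object.__setattr__(self, "clamped", np.asarray(self.clamped, dtype=bool))
        object.__setattr__(self, "commands", tuple(self.commands))
        n = self.times.size
        if not (
            self.setpoints.shape == (n,)
            and self.plant_temperatures.shape == (n,)
            and self.clamped.shape == (n,)
            and len(self.commands) == n
        ):
            raise ValueError("control trace arrays must share the tick axis")
        if np.any(self.plant_temperatures > self.max_temperature):
            raise ValueError("safety invariant violated: plant exceeded max_temperature")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_seconds": self.times,
                "setpoint_c": self.setpoints,
                "plant_c": self.plant_temperatures,
                "direction": [c.direction.value for c in self.commands],
                "duty": [c.duty_cycle for c in self.commands],
                "clamped": self.clamped.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


def constant_setpoint_timeline(
    setpoint: float, duration: float, dt: float = 0.005, baseline: float | None = None
) -> TouchTimeline:
    """Convenience timeline holding one constant setpoint (test/tuning aid)."""
    n = int(np.floor(duration / dt)) + 1
    times = dt * np.arange(n)
    return TouchTimeline(
        times=times,
        positions=np.zeros((n, 3)),
        in_contact=np.ones(n, dtype=bool),
        setpoints=np.full(n, float(setpoint)),
        surface_labels=tuple(["constant"] * n),
    )


def simulate_loop(
    timeline: TouchTimeline,
    plant: PeltierPlant | None = None,
    dt: float = 0.005,
    seed: int = 0,
) -> ControlTrace:
    """Closed-loop simulation of the Peltier display tracking a timeline.

    The setpoint is zero-order held from the timeline ticks onto a uniform
    grid of step ``dt`` spanning the timeline.  Per step: the sensor reads
    the plant (plus seeded Gaussian noise), the controller issues a PWM
    command, and the plant integrates one explicit Euler step

        T <- T + dt/tau * (ambient - T) +- gain * duty * dt

    followed by the hardware thermal cutoff at ``max_temperature``.
    Deterministic for a fixed seed.
    """
    if plant is None:
        plant = PeltierPlant()
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    rng = np.random.default_rng(seed)

    t0, t1 = timeline.times[0], timeline.times[-1]
    n = int(np.floor((t1 - t0) / dt)) + 1
    times = t0 + dt * np.arange(n)
    # zero-order hold of the timeline setpoints
    hold = np.clip(np.searchsorted(timeline.times, times, side="right") - 1, 0, None)
    setpoints = timeline.setpoints[hold]

    temp = plant.ambient
    command: Optional[PwmCommand] = None
    temps = np.empty(n)
    clamped_flags = np.empty(n, dtype=bool)
    commands: List[PwmCommand] = []
    for i in range(n):
        sensed = temp
        if plant.sensor_noise_sd > 0:
            sensed = temp + plant.sensor_noise_sd * rng.standard_normal()
        command, clamped = step_controller(setpoints[i], sensed, plant, command)
        drive = {Direction.HEAT: 1.0, Direction.COOL: -1.0, Direction.OFF: 0.0}[
            command.direction
        ]
        temp = (
            temp
            + dt / plant.time_constant * (plant.ambient - temp)
            + plant.gain * command.duty_cycle * dt * drive
        )
        if temp > plant.max_temperature:  # hardware thermal cutoff
            temp = plant.max_temperature
            clamped = True
        temps[i] = temp
        clamped_flags[i] = clamped
        commands.append(command)
    return ControlTrace(
        times=times,
        setpoints=setpoints,
        plant_temperatures=temps,
        commands=tuple(commands),
        clamped=clamped_flags,
        max_temperature=plant.max_temperature,
    )
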