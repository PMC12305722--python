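"""Gantry kinematics: the 3-DOF pose space and its motor emulation.

The scanner is a probe carried along a single linear rail (NEMA-17 stepper
driving a TR8x2 trapezoidal screw, 200 steps/rev, 2 mm lead) with a two-servo
gimbal providing pitch and roll about a pivot above the phantom surface.

A :class:`ProbePose` is ``(x, pitch, roll)``: rail position in mm plus gimbal
angles in degrees.  ``y`` exists on the pose for completeness but is frozen at
0 — the hardware has one actuated linear axis.  ``pose_to_plane`` maps a pose
to the oriented imaging plane; ``pose_to_motor_commands`` emulates the command
stream the controller would issue to move between poses.

Rotation composition is pitch about the lateral (y) axis through the gimbal
pivot, then roll about the travel (x) axis; this order is a documented,
fixed convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import ValidationError

__all__ = [
    "ProbePose",
    "GantryGeometry",
    "ImagingPlane",
    "MotorCommand",
    "MotorState",
    "pose_to_plane",
    "pose_to_motor_commands",
    "apply_motor_commands",
    "enumerate_stations",
    "format_command_log",
]


@dataclass(frozen=True)
class ProbePose:
    """Rail position (mm) and gimbal pitch/roll (degrees)."""

    x: float
    pitch: float = 0.0
    roll: float = 0.0
    y: float = 0.0  # not actuated; kept at 0

    def astuple(self) -> tuple[float, float, float]:
        return (self.x, self.pitch, self.roll)


@dataclass(frozen=True)
class GantryGeometry:
    """Physical constants of the gantry and of the synthesized image plane.

    ``steps_per_rev`` and ``screw_lead`` default to the NEMA-17 / TR8x2
    combination (1.8 deg step angle, 2 mm lead), giving a linear resolution
    of 0.01 mm per step.  ``pivot_height`` is the gimbal pivot's height above
    the phantom surface; the imaging rectangle starts ``pivot_height`` along
    the beam from the pivot (i.e. at the surface for an untilted probe) and
    extends ``image_depth`` downward.
    """

    rail_length: float = 160.0
    pivot_height: float = 20.0
    image_width: float = 60.0
    image_depth: float = 60.0
    slice_thickness: float = 2.0
    steps_per_rev: int = 200
    screw_lead: float = 2.0
    servo_resolution: float = 1.0
    lateral_center: float = 60.0  # y of the scan line, mm

    def __post_init__(self):
        for name in ("rail_length", "pivot_height", "image_width",
                     "image_depth", "slice_thickness", "screw_lead",
                     "servo_resolution"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"geometry.{name} must be positive")
        if self.steps_per_rev < 1:
            raise ValidationError("geometry.steps_per_rev must be >= 1")

    @property
    def mm_per_step(self) -> float:
        return self.screw_lead / self.steps_per_rev


@dataclass(frozen=True)
class ImagingPlane:
    """Oriented image rectangle: ``origin`` is the top-center of the
    rectangle (on the phantom surface at zero tilt); ``u`` spans the lateral
    image axis, ``v`` the beam/depth axis, ``n = u x v`` the plane normal."""

    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    n: np.ndarray


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def pose_to_plane(pose: ProbePose, geometry: GantryGeometry) -> ImagingPlane:
    """Imaging plane for a pose.

    At pitch = roll = 0 the plane is the lateral-depth (y-z) plane at
    ``x = pose.x`` with normal along the rail (+x).  Pitch tilts the beam
    along the rail; roll swings it laterally.  Both rotate about the gimbal
    pivot at ``(pose.x, lateral_center, -pivot_height)``.
    """
    R = _rot_x(pose.roll) @ _rot_y(pose.pitch)
    u = R @ np.array([0.0, 1.0, 0.0])
    v = R @ np.array([0.0, 0.0, 1.0])
    n = R @ np.array([1.0, 0.0, 0.0])
    pivot = np.array([pose.x, geometry.lateral_center + pose.y, -geometry.pivot_height])
    origin = pivot + geometry.pivot_height * v
    return ImagingPlane(origin=origin, u=u, v=v, n=n)


@dataclass(frozen=True)
class MotorCommand:
    """One emulated actuator command: a signed stepper move (integer steps)
    or an absolute servo target (degrees)."""

    kind: str  # "stepper" | "servo1" | "servo2"
    magnitude: float
    direction: int = 0

    def __post_init__(self):
        if self.kind not in ("stepper", "servo1", "servo2"):
            raise ValidationError(f"unknown motor kind {self.kind!r}")
        if self.kind == "stepper":
            if self.magnitude < 0 or self.magnitude != int(self.magnitude):
                raise ValidationError("stepper magnitude must be a non-negative integer")
            if self.direction not in (-1, 1):
                raise ValidationError("stepper direction must be +1 or -1")


def pose_to_motor_commands(
    frm: ProbePose, to: ProbePose, geometry: GantryGeometry
) -> list[MotorCommand]:
    """Command stream moving the gantry from one pose to another.

    The stepper count is the nearest whole number of steps for the linear
    move (open-loop quantization); each changed gimbal angle yields one
    absolute servo command.  Equal poses yield an empty list.
    """
    commands: list[MotorCommand] = []
    dx = to.x - frm.x
    steps = int(round(abs(dx) / geometry.screw_lead * geometry.steps_per_rev))
    if steps > 0:
        commands.append(MotorCommand("stepper", steps, 1 if dx > 0 else -1))
    if to.pitch != frm.pitch:
        commands.append(MotorCommand("servo1", float(to.pitch)))
    if to.roll != frm.roll:
        commands.append(MotorCommand("servo2", float(to.roll)))
    return commands


@dataclass
class MotorState:
    """Emulated open-loop actuator state (what the hardware would hold)."""

    x: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0


def apply_motor_commands(
    state: MotorState, commands: list[MotorCommand], geometry: GantryGeometry
) -> MotorState:
    """Apply a command stream to an emulated motor state.

    Stepper moves are exact multiples of the per-step travel; servo targets
    are quantized to the servo resolution.
    """
    x, pitch, roll = state.x, state.pitch, state.roll
    res = geometry.servo_resolution
    for cmd in commands:
        if cmd.kind == "stepper":
            x += cmd.direction * cmd.magnitude * geometry.mm_per_step
        elif cmd.kind == "servo1":
            pitch = round(cmd.magnitude / res) * res
        else:
            roll = round(cmd.magnitude / res) * res
    return MotorState(x=x, pitch=pitch, roll=roll)


def enumerate_stations(
    x_start: float, slin: float, nstep: int, geometry: GantryGeometry
) -> list[float]:
    """Rail positions ``x_start + k*slin`` for ``k = 0..nstep-1``.

    Raises if any station falls off the rail: the scan schedule must be
    physically executable before any image is acquired.
    """
    if slin <= 0:
        raise ValidationError("linear step slin must be positive")
    if nstep < 1:
        raise ValidationError("nstep must be >= 1")
    stations = [x_start + k * slin for k in range(int(nstep))]
    for x in stations:
        if x < -1e-9 or x > geometry.rail_length + 1e-9:
            raise ValidationError(
                f"station x = {x} mm falls outside the rail "
                f"[0, {geometry.rail_length}] mm"
            )
    return stations


def format_command_log(commands: list[MotorCommand]) -> str:
    """Plain-text command log, one command per line, diffable:
    ``STEP <n> <dir>`` / ``SERVO1 <deg>`` / ``SERVO2 <deg>``."""
    lines = []
    for cmd in commands:
        if cmd.kind == "stepper":
            lines.append(f"STEP {int(cmd.magnitude)} {cmd.direction:+d}")
        else:
            lines.append(f"{cmd.kind.upper()} {cmd.magnitude:g}")
    return "\n".join(lines) + ("\n" if lines else "")
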