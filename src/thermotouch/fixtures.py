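"""Programmatic fixtures with analytically known answers.

Every generated geometry is simple enough that downstream results can be
checked in closed form: an icosphere of known radius/center (watertight by
construction) and a radial approach-hold-retract fingertip trajectory whose
epsilon-shell crossing time is a line-sphere intersection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .bioheat import SlabProblem, default_problem
from .geometry import FingertipTrajectory, TumorSurface

__all__ = [
    "make_sphere_surface",
    "make_approach_trajectory",
    "approach_crossing_time",
    "make_fixtures",
]


def make_sphere_surface(
    radius: float = 0.01,
    center=(0.0, 0.0, 0.0),
    subdivisions: int = 3,
    label: str = "tumor",
    slab: SlabProblem | None = None,
) -> TumorSurface:
    """Watertight icosphere tumor surface (radius in meters).

    Subdivision level 3 gives 1280 triangles; the chord error of the
    tessellation is below 1e-3 * radius.
    """
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    mesh.apply_translation(np.asarray(center, dtype=float))
    return TumorSurface(
        label=label, mesh=mesh, slab=slab if slab is not None else default_problem()
    )


def approach_crossing_time(
    start_distance: float, radius: float, epsilon: float, speed: float
) -> float:
    """Time at which a radial approach first enters the epsilon contact shell.

    The fingertip starts ``start_distance`` from the sphere center and
    moves radially inward at ``speed``; contact begins when the
    center distance reaches ``radius + epsilon``.
    """
    if start_distance <= radius + epsilon:
        return 0.0
    return (start_distance - radius - epsilon) / speed


@dataclass(frozen=True)
class ApproachSpec:
    """Parameters of the generated approach-hold-retract trajectory."""

    start_distance: float = 0.030
    hold_distance: float = 0.0105
    speed: float = 0.005
    hold_duration: float = 5.0
    sample_dt: float = 0.05
    wobble_sd: float = 1e-4


def make_approach_trajectory(
    center=(0.0, 0.0, 0.0),
    spec: ApproachSpec = ApproachSpec(),
    seed: int = 0,
) -> FingertipTrajectory:
    """Radial approach along +x toward ``center``, hold, then retract.

    A seeded lateral wobble (default sd 0.1 mm, in the plane perpendicular
    to the approach axis) emulates hand tremor; at the fixture distances
    it perturbs the center distance by under a micrometer, so the analytic
    crossing time of :func:`approach_crossing_time` still holds to well
    below the sampling step.
    """
    rng = np.random.default_rng(seed)
    center = np.asarray(center, dtype=float)
    travel = spec.start_distance - spec.hold_distance
    t_in = travel / spec.speed
    t_hold_end = t_in + spec.hold_duration
    t_end = t_hold_end + travel / spec.speed
    n = int(np.floor(t_end / spec.sample_dt)) + 1
    times = spec.sample_dt * np.arange(n)

    dist = np.empty(n)
    approach = times <= t_in
    hold = (times > t_in) & (times <= t_hold_end)
    dist[approach] = spec.start_distance - spec.speed * times[approach]
    dist[hold] = spec.hold_distance
    dist[~approach & ~hold] = spec.hold_distance + spec.speed * (
        times[~approach & ~hold] - t_hold_end
    )

    wobble = spec.wobble_sd * rng.standard_normal((n, 2))
    positions = np.column_stack([center[0] + dist, center[1] + wobble[:, 0], center[2] + wobble[:, 1]])
    return FingertipTrajectory(times=times, positions=positions)


def make_fixtures(seed: int = 0, out_dir="fixtures") -> dict:
    """Write the standard fixture set (sphere OBJ + STL, trajectory CSV).

    Deterministic for a fixed seed.  Returns a dict of written paths plus
    the analytic epsilon-crossing time for the default 2 mm contact
    tolerance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    surface = make_sphere_surface()
    spec = ApproachSpec()
    trajectory = make_approach_trajectory(seed=seed, spec=spec)

    paths = {
        "sphere_obj": out / "sphere.obj",
        "sphere_stl": out / "sphere.stl",
        "trajectory_csv": out / "trajectory.csv",
    }
    obj_text = trimesh.exchange.export.export_mesh(surface.mesh, file_obj=None, file_type="obj")
    paths["sphere_obj"].write_text(obj_text if isinstance(obj_text, str) else obj_text.decode())
    stl_text = trimesh.exchange.export.export_mesh(
        surface.mesh, file_obj=None, file_type="stl_ascii"
    )
    paths["sphere_stl"].write_text(stl_text if isinstance(stl_text, str) else stl_text.decode())
    trajectory.to_csv(paths["trajectory_csv"])

    crossing = approach_crossing_time(
        spec.start_distance, radius=0.01, epsilon=0.002, speed=spec.speed
    )
    return {**{k: str(v) for k, v in paths.items()}, "epsilon_crossing_s": crossing}
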