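"""Tumor surfaces, fingertip contact detection and setpoint rendering.

A virtual touch interaction is resolved in three steps:

1. proximity query — exact minimum Euclidean distance from the fingertip
   point to the triangle soup of each tumor surface (vectorised
   point-to-triangle projection over every triangle; exact, no spatial
   acceleration);
2. contact detection — a trajectory tick is "in contact" with the nearest
   surface whose distance is at most ``epsilon`` (the tolerance absorbs
   the finger-pad radius; the fingertip itself is modelled as a point);
3. setpoint rendering — during a contact episode the displayed temperature
   follows the slab-model transient ``T(x=0, tau)`` of the touched
   surface's associated :class:`~thermotouch.bioheat.SlabProblem`, where
   ``tau`` is the elapsed time since contact onset; outside contact the
   setpoint is the baseline (bare-skin) display temperature.

The contact clock resets at every new contact event, so re-touching a
tumor restarts the thermal transient from the tumor's initial temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import trimesh

from .bioheat import SlabProblem, default_problem, temperature
from .stehfest import StehfestScheme

__all__ = [
    "TumorSurface",
    "FingertipTrajectory",
    "ContactEvent",
    "TouchTimeline",
    "load_mesh",
    "surface_distance",
    "detect_contact",
    "render_timeline",
    "DEFAULT_EPSILON",
    "DEFAULT_BASELINE",
]

#: Default contact tolerance [m]; absorbs the un-modelled finger-pad radius.
DEFAULT_EPSILON = 0.002

#: Default no-contact display temperature [C] (typical fingertip skin).
DEFAULT_BASELINE = 33.0


@dataclass(frozen=True)
class TumorSurface:
    """A labelled closed triangle mesh with its thermal slab problem.

    Vertices are in meters.  ``slab`` carries the tissue/source parameters
    used to render the touch transient of this tumor.
    """

    label: str
    mesh: trimesh.Trimesh = field(repr=False)
    slab: SlabProblem = field(default_factory=default_problem)

    def __post_init__(self) -> None:
        if len(self.mesh.faces) == 0:
            raise ValueError(f"surface {self.label!r} has zero triangles")
        if np.max(self.mesh.faces) >= len(self.mesh.vertices):
            raise ValueError(f"surface {self.label!r} has out-of-range vertex indices")
        diag = np.linalg.norm(self.mesh.bounds[1] - self.mesh.bounds[0])
        if not diag > 0:
            raise ValueError(f"surface {self.label!r} has a degenerate bounding box")

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.mesh.vertices)

    @property
    def triangles(self) -> np.ndarray:
        return np.asarray(self.mesh.faces)


@dataclass(frozen=True)
class FingertipTrajectory:
    """Sampled fingertip path: strictly increasing times [s], 3D points [m]."""

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("trajectory needs at least two time samples")
        if np.any(np.diff(times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if positions.shape != (times.size, 3):
            raise ValueError(
                f"positions must have shape ({times.size}, 3), got {positions.shape}"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)

    def resample(self, dt: float) -> "FingertipTrajectory":
        """Uniform resampling at step ``dt`` by linear interpolation."""
        if not dt > 0:
            raise ValueError(f"dt must be positive, got {dt}")
        t0, t1 = self.times[0], self.times[-1]
        n = int(np.floor((t1 - t0) / dt)) + 1
        times = t0 + dt * np.arange(n)
        cols = [np.interp(times, self.times, self.positions[:, k]) for k in range(3)]
        return FingertipTrajectory(times=times, positions=np.column_stack(cols))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "t_seconds": self.times,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
            }
        ).to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "FingertipTrajectory":
        df = pd.read_csv(path)
        missing = {"t_seconds", "x", "y", "z"} - set(df.columns)
        if missing:
            raise ValueError(f"trajectory CSV {path} is missing columns {sorted(missing)}")
        return cls(times=df["t_seconds"].to_numpy(), positions=df[["x", "y", "z"]].to_numpy())


@dataclass(frozen=True)
class ContactEvent:
    """A maximal run of in-contact ticks on one surface.

    ``end_time`` is the time of the first tick after the run (half-open
    interval) or ``None`` while the contact is still open at the end of
    the trajectory.  ``contact_point`` is the closest surface point at the
    onset tick.
    """

    start_time: float
    end_time: Optional[float]
    surface_label: str
    contact_point: np.ndarray

    def __post_init__(self) -> None:
        if self.end_time is not None and not self.end_time > self.start_time:
            raise ValueError("end_time must exceed start_time for a closed event")


def load_mesh(
    path,
    fmt: Optional[str] = None,
    unit_scale: float = 1.0,
    label: Optional[str] = None,
    slab: Optional[SlabProblem] = None,
) -> TumorSurface:
    """Load a tumor surface from a Wavefront OBJ or an STL file.

    Parameters
    ----------
    path:
        Mesh file path.
    fmt:
        ``"obj"`` or ``"stl"``; inferred from the suffix when omitted.
    unit_scale:
        Factor converting the file's length unit to meters (e.g. 0.001
        for millimeter meshes).
    label, slab:
        Surface identity and associated thermal problem; the label
        defaults to the file stem, the slab to the repository default.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in ("obj", "stl"):
        raise ValueError(f"unsupported mesh format {fmt!r}; expected 'obj' or 'stl'")
    try:
        mesh = trimesh.load(str(path), file_type=fmt, force="mesh", process=False)
    except Exception as exc:  # normalise loader-specific failures
        raise ValueError(f"failed to parse {fmt.upper()} mesh {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise ValueError(f"mesh {path} contains no triangles")
    if unit_scale != 1.0:
        mesh = mesh.copy()
        mesh.apply_scale(float(unit_scale))
    return TumorSurface(
        label=label if label is not None else path.stem,
        mesh=mesh,
        slab=slab if slab is not None else default_problem(),
    )


def _closest_on_triangles(points: np.ndarray, triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact closest point on a triangle soup for each query point.

    Region-based point-to-triangle projection (barycentric clamping over
    the seven Voronoi regions of each triangle), fully vectorised over the
    (points x triangles) grid.  Returns ``(closest, distance)`` with
    shapes (n, 3) and (n,).  This tests every triangle — no spatial
    acceleration — which is exact and fast enough for the mesh sizes this
    package handles (thousands of triangles).
    """
    p = points[:, None, :]  # (n, m, 3) broadcast
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    ab, ac, bc = b - a, c - a, c - b

    ap = p - a
    d1 = np.einsum("mk,nmk->nm", ab, ap)
    d2 = np.einsum("mk,nmk->nm", ac, ap)
    bp = p - b
    d3 = np.einsum("mk,nmk->nm", ab, bp)
    d4 = np.einsum("mk,nmk->nm", ac, bp)
    cp = p - c
    d5 = np.einsum("mk,nmk->nm", ab, cp)
    d6 = np.einsum("mk,nmk->nm", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = va + vb + vc
        v_face = np.where(denom != 0, vb / np.where(denom != 0, denom, 1.0), 0.0)
        w_face = np.where(denom != 0, vc / np.where(denom != 0, denom, 1.0), 0.0)
        q = a + v_face[..., None] * ab + w_face[..., None] * ac

        def edge_point(origin, direction, num, den):
            t = np.where(den != 0, num / np.where(den != 0, den, 1.0), 0.0)
            t = np.clip(t, 0.0, 1.0)
            return origin + t[..., None] * direction

        # override in reverse priority order so earlier regions win
        on_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
        q = np.where(on_bc[..., None], edge_point(b, bc, d4 - d3, (d4 - d3) + (d5 - d6)), q)
        on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        q = np.where(on_ac[..., None], edge_point(a, ac, d2, d2 - d6), q)
        at_c = (d6 >= 0) & (d5 <= d6)
        q = np.where(at_c[..., None], np.broadcast_to(c, q.shape), q)
        on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        q = np.where(on_ab[..., None], edge_point(a, ab, d1, d1 - d3), q)
        at_b = (d3 >= 0) & (d4 <= d3)
        q = np.where(at_b[..., None], np.broadcast_to(b, q.shape), q)
        at_a = (d1 <= 0) & (d2 <= 0)
        q = np.where(at_a[..., None], np.broadcast_to(a, q.shape), q)

    dist = np.linalg.norm(p - q, axis=-1)
    best = np.argmin(dist, axis=1)
    rows = np.arange(points.shape[0])
    return q[rows, best], dist[rows, best]


def _closest_points(points: np.ndarray, surface: TumorSurface, chunk: int = 128):
    """Chunked exact closest-point query against all surface triangles."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    triangles = surface.vertices[surface.triangles]
    closest = np.empty_like(points)
    dist = np.empty(points.shape[0])
    for start in range(0, points.shape[0], chunk):
        sl = slice(start, start + chunk)
        closest[sl], dist[sl] = _closest_on_triangles(points[sl], triangles)
    return closest, dist


def surface_distance(point, surface: TumorSurface) -> float:
    """Exact minimum distance [m] from a 3D point to the surface triangles."""
    return float(surface_distances(np.asarray(point, dtype=float)[None, :], surface)[0])


def surface_distances(points: np.ndarray, surface: TumorSurface) -> np.ndarray:
    """Vectorised exact point-to-mesh distances for an (n, 3) array."""
    return _closest_points(points, surface)[1]


def _nearest_surfaces(
    points: np.ndarray, surfaces: Sequence[TumorSurface]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point distance to, and index of, the nearest surface.

    Ties are broken by smaller distance first, then lexicographic label;
    surface order in the input list does not matter.
    """
    order = np.argsort([s.label for s in surfaces], kind="stable")
    dists = np.full(len(points), np.inf)
    idx = np.full(len(points), -1)
    for k in order:
        d = surface_distances(points, surfaces[k])
        better = d < dists  # strict: first (lexicographically smaller) label wins ties
        dists[better] = d[better]
        idx[better] = k
    return dists, idx


def detect_contact(
    trajectory: FingertipTrajectory,
    surfaces: Sequence[TumorSurface],
    epsilon: float = DEFAULT_EPSILON,
) -> List[ContactEvent]:
    """Contact events of a fingertip trajectory against a set of surfaces.

    A tick is in contact when its distance to the nearest surface is at
    most ``epsilon``; events are maximal runs of in-contact ticks on one
    surface (a run is split when the nearest surface changes).
    """
    if not epsilon > 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    if len(surfaces) == 0:
        return []
    dists, idx = _nearest_surfaces(trajectory.positions, surfaces)
    in_contact = dists <= epsilon
    events: List[ContactEvent] = []
    i = 0
    n = trajectory.times.size
    while i < n:
        if not in_contact[i]:
            i += 1
            continue
        k = idx[i]
        j = i
        while j + 1 < n and in_contact[j + 1] and idx[j + 1] == k:
            j += 1
        surface = surfaces[k]
        onset = trajectory.positions[i][None, :]
        closest, _ = _closest_points(onset, surface)
        events.append(
            ContactEvent(
                start_time=float(trajectory.times[i]),
                end_time=float(trajectory.times[j + 1]) if j + 1 < n else None,
                surface_label=surface.label,
                contact_point=np.asarray(closest[0], dtype=float),
            )
        )
        i = j + 1
    return events


@dataclass(frozen=True)
class TouchTimeline:
    """Per-tick record of a touch interaction.

    Arrays share the tick axis; ``surface_labels`` holds ``None`` for
    out-of-contact ticks.  ``setpoints`` equals the baseline temperature
    whenever ``in_contact`` is false.
    """

    times: np.ndarray
    positions: np.ndarray
    in_contact: np.ndarray
    setpoints: np.ndarray
    surface_labels: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "in_contact", np.asarray(self.in_contact, dtype=bool))
        object.__setattr__(self, "setpoints", np.asarray(self.setpoints, dtype=float))
        object.__setattr__(self, "surface_labels", tuple(self.surface_labels))
        n = self.times.size
        if not (
            self.positions.shape == (n, 3)
            and self.in_contact.shape == (n,)
            and self.setpoints.shape == (n,)
            and len(self.surface_labels) == n
        ):
            raise ValueError("timeline arrays must share the tick axis")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_seconds": self.times,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "in_contact": self.in_contact.astype(int),
                "surface": ["" if s is None else s for s in self.surface_labels],
                "setpoint_celsius": self.setpoints,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "TouchTimeline":
        df = pd.read_csv(path, keep_default_na=False)
        return cls(
            times=df["t_seconds"].to_numpy(float),
            positions=df[["x", "y", "z"]].to_numpy(float),
            in_contact=df["in_contact"].to_numpy(int).astype(bool),
            setpoints=df["setpoint_celsius"].to_numpy(float),
            surface_labels=tuple(s if s != "" else None for s in df["surface"]),
        )


def render_timeline(
    trajectory: FingertipTrajectory,
    surfaces: Sequence[TumorSurface],
    epsilon: float = DEFAULT_EPSILON,
    scheme: StehfestScheme | None = None,
    baseline: float = DEFAULT_BASELINE,
    dt: float = 0.01,
) -> TouchTimeline:
    """Model-predicted setpoint temperature timeline for a trajectory.

    The trajectory is resampled at step ``dt``; each in-contact tick gets
    the slab transient ``T(0, tau)`` of its surface, with ``tau`` elapsed
    since the enclosing event's onset (so the setpoint at contact onset is
    exactly the tumor's initial temperature).  Out-of-contact ticks get
    the baseline temperature.
    """
    resampled = trajectory.resample(dt)
    events = detect_contact(resampled, surfaces, epsilon)
    by_label = {s.label: s for s in surfaces}

    n = resampled.times.size
    setpoints = np.full(n, float(baseline))
    in_contact = np.zeros(n, dtype=bool)
    labels: list = [None] * n
    for ev in events:
        start = int(np.searchsorted(resampled.times, ev.start_time))
        stop = (
            int(np.searchsorted(resampled.times, ev.end_time))
            if ev.end_time is not None
            else n
        )
        slab = by_label[ev.surface_label].slab
        for i in range(start, stop):
            tau = resampled.times[i] - ev.start_time
            try:
                setpoints[i] = temperature(slab, 0.0, tau, scheme)
            except ValueError as exc:
                raise ValueError(
                    f"setpoint evaluation failed at tick t={resampled.times[i]:g} s "
                    f"(surface {ev.surface_label!r}): {exc}"
                ) from exc
            in_contact[i] = True
            labels[i] = ev.surface_label
    return TouchTimeline(
        times=resampled.times,
        positions=resampled.positions,
        in_contact=in_contact,
        setpoints=setpoints,
        surface_labels=tuple(labels),
    )
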