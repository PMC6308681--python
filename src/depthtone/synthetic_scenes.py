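"""Synthetic depth scenes standing in for the physical structured-light sensor.

A parametric 3-D scene (axis-aligned boxes and planes, metric coordinates)
is ray-cast through a pinhole camera with the sensor's field of view (57 x
43 degrees, 640 x 480 pixels) to a per-pixel depth map.  Depth follows the
structured-light convention: the distance from the plane perpendicular to
the optical axis (the z coordinate of the hit point), not the length of the
ray, so a fronto-parallel wall reads the same depth at every pixel.

Metric depths are converted to 11-bit raw codes with the classical tangent
disparity approximation ``z = a * tan(raw / b + c)``, whose default
constants (a = 0.1236, b = 2842.5, c = 1.1863) reproduce the sensor's
published calibration point — raw 488 at 0.57 m — within 5 mm.  Depths
outside the readable range, pixels with no surface, and randomly dropped
pixels (emulating IR washout) get the invalid code 2047.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .depth_transform import RAW_MAX, RawDepthFrame


@dataclass(frozen=True)
class SensorModel:
    """Geometry and raw<->metric calibration of the depth sensor."""

    width: int = 640
    height: int = 480
    hfov_deg: float = 57.0
    vfov_deg: float = 43.0
    min_range_m: float = 0.57
    max_range_m: float = 9.0
    cal_a: float = 0.1236
    cal_b: float = 2842.5
    cal_c: float = 1.1863

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("resolution must be positive")
        if not 0 < self.hfov_deg < 180 or not 0 < self.vfov_deg < 180:
            raise ValueError("fields of view must lie in (0, 180) degrees")
        if not 0 < self.min_range_m < self.max_range_m:
            raise ValueError("need 0 < min range < max range")

    def raw_to_metric(self, raw) -> np.ndarray:
        """Metric depth in metres for raw codes (monotone on [488, ~1054])."""
        raw = np.asarray(raw, dtype=np.float64)
        return self.cal_a * np.tan(raw / self.cal_b + self.cal_c)

    def metric_to_raw(self, z) -> np.ndarray:
        """Raw codes for metric depths; out-of-range depths map to 2047.

        Accepts scalars or arrays (including +inf for "no surface").
        """
        z = np.asarray(z, dtype=np.float64)
        out = np.full(z.shape, RAW_MAX, dtype=np.int64)
        ok = np.isfinite(z) & (z >= self.min_range_m) & (z <= self.max_range_m)
        if ok.any():
            raw = (np.arctan(z[ok] / self.cal_a) - self.cal_c) * self.cal_b
            out[ok] = np.round(raw).astype(np.int64)
        return out

    def pixel_directions(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel ray slopes (dx/dz, dy/dz) for the pinhole camera.

        x is right, y is up, z is forward along the optical axis; pixel
        row 0 is the top of the image.
        """
        fx = (self.width / 2.0) / math.tan(math.radians(self.hfov_deg) / 2.0)
        fy = (self.height / 2.0) / math.tan(math.radians(self.vfov_deg) / 2.0)
        cols = np.arange(self.width) + 0.5
        rows = np.arange(self.height) + 0.5
        dx = (cols - self.width / 2.0) / fx
        dy = (self.height / 2.0 - rows) / fy  # row 0 = top = +y
        return np.meshgrid(dx, dy)

    def azimuth_to_column(self, azimuth_deg: float) -> float:
        """Fractional pixel column at which a given azimuth projects."""
        fx = (self.width / 2.0) / math.tan(math.radians(self.hfov_deg) / 2.0)
        return self.width / 2.0 + fx * math.tan(math.radians(azimuth_deg))


@dataclass(frozen=True)
class Box:
    """Axis-aligned box with metric centre and edge lengths."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if min(self.size) <= 0:
            raise ValueError("box extents must be positive")


@dataclass(frozen=True)
class Wall:
    """Fronto-parallel plane at depth z, optionally limited laterally.

    ``x_range``/``y_range`` bound the wall in metres; ``None`` means
    unbounded (an infinite wall filling the field of view).
    """

    z: float
    x_range: tuple[float, float] | None = None
    y_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("wall depth must be positive (in front of the camera)")


@dataclass(frozen=True)
class ObliquePlane:
    """Infinite plane through ``point`` with unit ``normal`` (metric)."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if np.linalg.norm(n) == 0:
            raise ValueError("plane normal must be non-zero")


SceneObject = Union[Box, Wall, ObliquePlane]


@dataclass(frozen=True)
class Scene:
    """A list of metric scene objects plus sensor-noise settings.

    ``dropout`` is the i.i.d. probability that a pixel is replaced by the
    invalid code, emulating IR pattern washout; ``seed`` makes the dropout
    pattern reproducible.
    """

    objects: tuple[SceneObject, ...] = ()
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must lie in [0, 1]")
        object.__setattr__(self, "objects", tuple(self.objects))


def _intersect_box(box: Box, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Per-pixel z of the nearest intersection with the box (inf if none).

    Rays start at the origin with direction (dx, dy, 1); the slab method is
    applied in z-parametrised form, so the parameter t equals the depth z.
    """
    cx, cy, cz = box.center
    hx, hy, hz = (s / 2.0 for s in box.size)
    t_near = np.full(dx.shape, -np.inf)
    t_far = np.full(dx.shape, np.inf)
    for d, lo, hi in ((dx, cx - hx, cx + hx), (dy, cy - hy, cy + hy)):
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(d != 0, lo / np.where(d == 0, 1, d), -np.inf)
            t2 = np.where(d != 0, hi / np.where(d == 0, 1, d), np.inf)
        # pixels with d == 0 hit the slab only if the origin ray stays inside
        inside = (lo <= 0) & (0 <= hi)
        t1z = np.where(d == 0, np.where(inside, -np.inf, np.inf), np.minimum(t1, t2))
        t2z = np.where(d == 0, np.where(inside, np.inf, -np.inf), np.maximum(t1, t2))
        t_near = np.maximum(t_near, t1z)
        t_far = np.minimum(t_far, t2z)
    # z slab: direction component is 1
    t_near = np.maximum(t_near, cz - hz)
    t_far = np.minimum(t_far, cz + hz)
    hit = (t_near <= t_far) & (t_far > 0)
    t = np.where(t_near > 0, t_near, t_far)  # camera inside box: front face behind
    return np.where(hit, t, np.inf)


def _intersect_wall(wall: Wall, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    z = np.full(dx.shape, wall.z)
    hit = np.ones(dx.shape, dtype=bool)
    if wall.x_range is not None:
        x = dx * wall.z
        hit &= (wall.x_range[0] <= x) & (x <= wall.x_range[1])
    if wall.y_range is not None:
        y = dy * wall.z
        hit &= (wall.y_range[0] <= y) & (y <= wall.y_range[1])
    return np.where(hit, z, np.inf)


def _intersect_plane(plane: ObliquePlane, dx: np.ndarray,
                     dy: np.ndarray) -> np.ndarray:
    p = np.asarray(plane.point, dtype=float)
    n = np.asarray(plane.normal, dtype=float)
    denom = n[0] * dx + n[1] * dy + n[2]
    num = float(np.dot(n, p))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
    return np.where((denom != 0) & (t > 0), t, np.inf)


def ray_cast(scene: Scene, sensor: SensorModel = SensorModel()) -> np.ndarray:
    """Per-pixel metric depth map of the scene (z convention, +inf = no hit)."""
    dx, dy = sensor.pixel_directions()
    depth = np.full((sensor.height, sensor.width), np.inf)
    for obj in scene.objects:
        if isinstance(obj, Box):
            z = _intersect_box(obj, dx, dy)
        elif isinstance(obj, Wall):
            z = _intersect_wall(obj, dx, dy)
        elif isinstance(obj, ObliquePlane):
            z = _intersect_plane(obj, dx, dy)
        else:
            raise TypeError(f"unknown scene object {obj!r}")
        depth = np.minimum(depth, z)
    return depth


def generate_frame(scene: Scene,
                   sensor: SensorModel = SensorModel()) -> RawDepthFrame:
    """Ray-cast the scene and quantize to a raw depth frame.

    Out-of-range depths and missed rays become the invalid code; a seeded
    RNG then replaces a ``scene.dropout`` fraction of pixels with the
    invalid code.  Deterministic for a fixed seed.
    """
    depth = ray_cast(scene, sensor)
    raw = sensor.metric_to_raw(depth)
    if scene.dropout > 0:
        rng = np.random.default_rng(scene.seed)
        drop = rng.random(raw.shape) < scene.dropout
        raw = np.where(drop, RAW_MAX, raw)
    return RawDepthFrame(values=raw)


# ---------------------------------------------------------------------------
# JSON scene descriptions


def scene_from_dict(data: dict) -> Scene:
    """Build a Scene from its JSON-style dict description."""
    objects: list[SceneObject] = []
    for obj in data.get("objects", []):
        kind = obj.get("type")
        if kind == "box":
            objects.append(Box(center=tuple(obj["center"]), size=tuple(obj["size"])))
        elif kind == "wall":
            objects.append(Wall(z=obj["z"],
                                x_range=tuple(obj["x_range"]) if "x_range" in obj else None,
                                y_range=tuple(obj["y_range"]) if "y_range" in obj else None))
        elif kind == "plane":
            objects.append(ObliquePlane(point=tuple(obj["point"]),
                                        normal=tuple(obj["normal"])))
        else:
            raise ValueError(f"unknown scene object type {kind!r}")
    return Scene(objects=tuple(objects),
                 dropout=float(data.get("dropout", 0.0)),
                 seed=int(data.get("seed", 0)))


def load_scene(path: Union[str, Path]) -> Scene:
    """Load a Scene from a JSON file."""
    with open(path) as fh:
        return scene_from_dict(json.load(fh))
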