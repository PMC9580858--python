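"""Perspective camera, volume/world transforms, sampling plane, picking.

Conventions (documented defaults; the rendering model does not depend on
them being any particular value):

* World space equals view space: the camera sits at ``(0, 0,
  camera_distance)`` looking down the -z axis at the volume centre, which
  is the origin.  ``world_rotation`` is the orientation of the *volume*: a
  volume-frame point ``p`` appears at world position ``R @ p``.
* The volume's physical extents are uniformly scaled so the largest equals
  one world unit (anisotropy preserved).
* Zoom scales the ray grid in view space (dolly-free), so picking math is
  unchanged by zoom.  Pan rigidly translates the ray origin in the view
  plane, so ray/plane intersections shift by exactly the pan vector.
* The sampling plane is perpendicular to the view axis at world depth
  ``z = plane_depth`` (signed from the volume centre, positive toward the
  camera).
* Voxel cells are half-open with centres at index + 0.5; picking floors
  the continuous coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError
from .volume import VolumeMetadata

__all__ = [
    "CameraModel",
    "ViewParams",
    "CLIP_MODES",
    "volume_world_box",
    "generate_ray",
    "project_point",
    "pick_voxel",
    "compose_rotation",
    "reset_view",
    "rotation_about_axis",
    "orthonormalize",
    "rotated_box_aabb",
]

CLIP_MODES = ("off", "front", "plane")


@dataclass(frozen=True)
class CameraModel:
    fov_y: float = 30.0
    viewport: tuple[int, int] = (512, 512)
    camera_distance: float = 2.5
    near: float = 0.01
    far: float = 10.0

    def __post_init__(self):
        if not 0.0 < self.fov_y < 180.0:
            raise InvalidParameterError(f"fov_y must be in (0, 180), got {self.fov_y}")
        w, h = self.viewport
        if w < 1 or h < 1:
            raise InvalidParameterError(f"viewport must be at least 1x1, got {self.viewport}")
        if not 0.0 < self.near < self.far:
            raise InvalidParameterError("require 0 < near < far")


def orthonormalize(rot: np.ndarray) -> np.ndarray:
    """Nearest rotation matrix by polar decomposition (via SVD).

    Matrices already orthonormal to 1e-9 are returned bit-unchanged, so the
    operation is idempotent and serialized documents round-trip exactly.
    """
    rot = np.asarray(rot, dtype=np.float64)
    if np.max(np.abs(rot @ rot.T - np.eye(3))) <= 1e-9:
        return rot
    u, _, vt = np.linalg.svd(rot)
    r = u @ vt
    if np.linalg.det(r) < 0:  # reflection guard; cannot occur for near-rotations
        u[:, -1] = -u[:, -1]
        r = u @ vt
    return r


@dataclass
class ViewParams:
    """Serializable view state (volume orientation, zoom, pan, plane, clip)."""

    world_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    zoom: float = 1.0
    pan: tuple[float, float] = (0.0, 0.0)
    plane_depth: float = 0.0
    clip_mode: str = "off"

    def __post_init__(self):
        self.world_rotation = np.asarray(self.world_rotation, dtype=np.float64)
        if self.world_rotation.shape != (3, 3):
            raise InvalidParameterError("world_rotation must be 3x3")
        if abs(np.linalg.det(self.world_rotation) - 1.0) > 1e-3:
            raise InvalidParameterError("world_rotation is not a rotation matrix (det != 1)")
        self.world_rotation = orthonormalize(self.world_rotation)
        if not self.zoom > 0:
            raise InvalidParameterError(f"zoom must be > 0, got {self.zoom}")
        if self.clip_mode not in CLIP_MODES:
            raise InvalidParameterError(
                f"clip_mode must be one of {CLIP_MODES}, got {self.clip_mode!r}"
            )
        self.pan = (float(self.pan[0]), float(self.pan[1]))
        self.zoom = float(self.zoom)
        self.plane_depth = float(self.plane_depth)

    def to_doc(self) -> dict:
        return {
            "rotation": [float(v) for v in self.world_rotation.ravel()],
            "zoom": self.zoom,
            "pan": [self.pan[0], self.pan[1]],
            "plane_depth": self.plane_depth,
            "clip_mode": self.clip_mode,
        }

    @classmethod
    def from_doc(cls, doc: dict, base: "ViewParams | None" = None) -> "ViewParams":
        base = base or cls()
        known = {"rotation", "zoom", "pan", "plane_depth", "clip_mode"}
        unknown = set(doc) - known
        if unknown:
            raise InvalidParameterError(f"unknown view field {sorted(unknown)[0]!r}")
        rot = doc.get("rotation")
        rotation = (
            np.asarray(rot, dtype=np.float64).reshape(3, 3)
            if rot is not None
            else base.world_rotation
        )
        return cls(
            world_rotation=rotation,
            zoom=doc.get("zoom", base.zoom),
            pan=tuple(doc.get("pan", base.pan)),
            plane_depth=doc.get("plane_depth", base.plane_depth),
            clip_mode=doc.get("clip_mode", base.clip_mode),
        )


def volume_world_box(meta: VolumeMetadata) -> np.ndarray:
    """Full world-space extents (x, y, z) of the volume box.

    Physical extent per axis is dims * physical_voxel_size, uniformly
    rescaled so the largest extent is 1 world unit; box centred at origin.
    """
    ext = np.array(
        [d * s for d, s in zip(meta.dims, meta.physical_voxel_size)], dtype=np.float64
    )
    return ext / ext.max()


def rotated_box_aabb(meta: VolumeMetadata, view: ViewParams) -> tuple[np.ndarray, np.ndarray]:
    """World-space axis-aligned bounds of the rotated volume box."""
    half = volume_world_box(meta) / 2.0
    corners = np.array(
        [[sx * half[0], sy * half[1], sz * half[2]] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    world = corners @ view.world_rotation.T
    return world.min(axis=0), world.max(axis=0)


def _ray_grid_view(cam: CameraModel, view: ViewParams, px, py):
    """Unnormalized view-space ray directions for (possibly float) pixel
    coordinates; pixel centres sit at index + 0.5."""
    w, h = cam.viewport
    tanf = math.tan(math.radians(cam.fov_y) / 2.0)
    aspect = w / h
    u = ((np.asarray(px, dtype=np.float64) + 0.5) / w * 2.0 - 1.0) * tanf * aspect
    v = (1.0 - (np.asarray(py, dtype=np.float64) + 0.5) / h * 2.0) * tanf
    dirs = np.stack(
        [u / view.zoom, v / view.zoom, -np.ones_like(u)], axis=-1
    )
    origin = np.array([view.pan[0], view.pan[1], cam.camera_distance])
    return origin, dirs


def generate_ray(
    cam: CameraModel, view: ViewParams, pixel: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Volume-frame (origin, unit direction) of the ray through a pixel."""
    origin_v, d = _ray_grid_view(cam, view, pixel[0], pixel[1])
    d = d / np.linalg.norm(d)
    rt = view.world_rotation.T
    return rt @ origin_v, rt @ d


def project_point(
    cam: CameraModel, view: ViewParams, p_volume: np.ndarray
) -> tuple[float, float, float]:
    """Project a volume-frame point to (pixel_x, pixel_y, view_depth).

    Inverse of :func:`generate_ray` in the sense that the returned pixel's
    ray passes through the point; view_depth is the world z of the point
    (the plane_depth at which picking recovers it).
    """
    w, h = cam.viewport
    tanf = math.tan(math.radians(cam.fov_y) / 2.0)
    aspect = w / h
    pw = view.world_rotation @ np.asarray(p_volume, dtype=np.float64)
    dz = cam.camera_distance - pw[2]
    if dz <= 0:
        raise InvalidParameterError("point is at or behind the camera")
    sx = (pw[0] - view.pan[0]) * view.zoom / dz
    sy = (pw[1] - view.pan[1]) * view.zoom / dz
    px = (sx / (tanf * aspect) + 1.0) / 2.0 * w - 0.5
    py = (1.0 - sy / tanf) / 2.0 * h - 0.5
    return float(px), float(py), float(pw[2])


def pick_voxel(
    cam: CameraModel,
    view: ViewParams,
    meta: VolumeMetadata,
    pixel: tuple[float, float],
) -> tuple[int, int, int] | None:
    """Voxel index (ix, iy, iz) under a pixel at the sampling plane, or
    ``None`` when the plane point falls outside the volume."""
    origin_v, d = _ray_grid_view(cam, view, pixel[0], pixel[1])
    if d[2] >= 0:
        raise InvalidParameterError("degenerate ray parallel to sampling plane")
    t = (view.plane_depth - origin_v[2]) / d[2]
    if t <= 0:
        return None
    hit_world = origin_v + t * d
    p_vol = view.world_rotation.T @ hit_world
    ext = volume_world_box(meta)
    cont = (p_vol + ext / 2.0) / ext * np.asarray(meta.dims, dtype=np.float64)
    idx = np.floor(cont).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(meta.dims)):
        return None
    return int(idx[0]), int(idx[1]), int(idx[2])


def compose_rotation(view: ViewParams, delta: np.ndarray) -> ViewParams:
    """Left-compose a delta rotation onto the view's world rotation,
    re-orthonormalizing to prevent drift over long scripted movies."""
    delta = np.asarray(delta, dtype=np.float64)
    if delta.shape != (3, 3) or abs(np.linalg.det(delta) - 1.0) > 1e-3:
        raise InvalidParameterError("delta is not a rotation matrix")
    new_rot = orthonormalize(delta @ view.world_rotation)
    return replace(view, world_rotation=new_rot)


def reset_view(meta: VolumeMetadata) -> ViewParams:
    """Default view: identity rotation, zoom 1, no pan, sampling plane at
    the camera-side edge of the volume box, clipping off."""
    ext = volume_world_box(meta)
    return ViewParams(plane_depth=float(ext[2]) / 2.0)


def rotation_about_axis(axis: str, degrees: float) -> np.ndarray:
    """Rotation matrix about a principal axis ('x', 'y' or 'z')."""
    th = math.radians(degrees)
    c, s = math.cos(th), math.sin(th)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=np.float64)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=np.float64)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=np.float64)
    raise InvalidParameterError(f"axis must be 'x', 'y' or 'z', got {axis!r}")
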