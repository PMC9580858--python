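"""Front-to-back multichannel alpha-compositing raycaster.

Rendering model (emission/absorption only, no lighting):

* One perspective ray per pixel, clipped to the volume box by the slab
  method; the marched segment is ``[t0, t1]`` with ``t0`` clamped to 0.
* Uniform sampling at ray midpoints: ``t_k = t0 + (k + 0.5) * step`` for
  ``k = 0 .. n-1`` with ``n = floor((t1 - t0)/step + 0.5)`` and
  ``step = step_scale * (smallest world-space voxel extent)``.
* At each sample the per-channel transfers produce emissive intensities;
  channels combine by union opacity ``1 - prod(1 - a_c)`` with an
  opacity-weighted colour average; samples accumulate with the
  front-to-back over-operator on premultiplied colour.
* Clip modes: ``off`` marches the full segment, ``front`` keeps only the
  sub-segment at or behind the sampling plane, ``plane`` takes a single
  sample exactly at the plane intersection.
* The accumulated colour is composited over the background; overlays
  (plane grid, coordinate readout) are drawn last and only when a clip
  mode engages the sampling plane.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .camera import CameraModel, ViewParams, _ray_grid_view, rotated_box_aabb, volume_world_box
from .errors import InvalidParameterError
from .transfer import ChannelTransfer, solve_coefficients
from .volume import Volume

__all__ = [
    "OverlaySettings",
    "RenderSettings",
    "FrameImage",
    "sample_channels",
    "composite_step",
    "channel_blend",
    "render_frame",
    "render_slice",
    "frame_to_png_bytes",
    "png_bytes_to_array",
]


@dataclass
class OverlaySettings:
    plane_grid: bool = True
    coordinate_readout: bool = True

    def to_doc(self) -> dict:
        return {"plane_grid": self.plane_grid, "coordinate_readout": self.coordinate_readout}


@dataclass
class RenderSettings:
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)
    step_scale: float = 1.0
    early_termination_alpha: float = 0.995
    overlays: OverlaySettings = field(default_factory=OverlaySettings)

    def __post_init__(self):
        if not self.step_scale > 0:
            raise InvalidParameterError(f"step_scale must be > 0, got {self.step_scale}")
        if not 0.0 < self.early_termination_alpha <= 1.0:
            raise InvalidParameterError("early_termination_alpha must be in (0, 1]")
        bg = tuple(float(v) for v in self.background)
        if len(bg) != 3 or any(not 0.0 <= v <= 1.0 for v in bg):
            raise InvalidParameterError(f"background must be an RGB triple in [0, 1]")
        self.background = bg

    def to_doc(self) -> dict:
        return {
            "background": list(self.background),
            "step_scale": self.step_scale,
            "early_termination_alpha": self.early_termination_alpha,
        }


@dataclass
class FrameImage:
    """Rendered frame: RGB raster plus the pre-background accumulated
    opacity plane (kept for compositing tests)."""

    rgb: np.ndarray  # (H, W, 3) float in [0, 1]
    alpha: np.ndarray  # (H, W) float in [0, 1]


# ---------------------------------------------------------------------------
# Sampling and compositing primitives
# ---------------------------------------------------------------------------


def _padded_normalized(vol: Volume) -> np.ndarray:
    """Channel stack in [0,1] zero-padded by one voxel per side, so
    trilinear gathers never index out of bounds for in-box points."""
    c, z, y, x = vol.codes.shape
    pad = np.zeros((c, z + 2, y + 2, x + 2), dtype=np.float64)
    pad[:, 1:-1, 1:-1, 1:-1] = vol.normalized()
    return pad


def _trilinear(pad: np.ndarray, dims: tuple[int, int, int], pts: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at continuous voxel coordinates.

    ``pts`` is (M, 3) in (x, y, z) voxel units (centres at index + 0.5);
    returns (C, M).  Points outside the volume return 0 (zero padding).
    """
    dims = np.asarray(dims, dtype=np.float64)
    g = pts - 0.5
    inside = np.all((g >= -1.0) & (g <= dims), axis=-1)
    i0 = np.floor(g).astype(np.int64)
    f = g - i0
    i0 = np.clip(i0, -1, np.asarray(dims, dtype=np.int64) - 1) + 1  # into padded indexing
    ix0, iy0, iz0 = i0[:, 0], i0[:, 1], i0[:, 2]
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    out = np.zeros((pad.shape[0], pts.shape[0]), dtype=np.float64)
    for dz in (0, 1):
        wz = fz if dz else 1.0 - fz
        for dy in (0, 1):
            wy = fy if dy else 1.0 - fy
            for dx in (0, 1):
                wx = fx if dx else 1.0 - fx
                w = wx * wy * wz
                out += w * pad[:, iz0 + dz, iy0 + dy, ix0 + dx]
    out *= inside
    return out


def sample_channels(vol: Volume, p) -> np.ndarray:
    """Per-channel normalized values at one continuous voxel coordinate
    (x, y, z); zero outside the volume."""
    pad = _padded_normalized(vol)
    pts = np.asarray(p, dtype=np.float64).reshape(1, 3)
    return _trilinear(pad, vol.meta.dims, pts)[:, 0]


def composite_step(acc, sample):
    """One front-to-back over-operator step on premultiplied colour.

    ``acc`` is (C_rgb, alpha); ``sample`` is (c_rgb, alpha_s).
    """
    c_acc, a_acc = acc
    c_s, a_s = sample
    c_acc = np.asarray(c_acc, dtype=np.float64)
    c_new = c_acc + (1.0 - a_acc) * a_s * np.asarray(c_s, dtype=np.float64)
    a_new = a_acc + (1.0 - a_acc) * a_s
    return c_new, a_new


def channel_blend(values, transfers: list[ChannelTransfer]):
    """Blend per-channel sample values into one (colour, opacity) sample.

    Per channel, emission e_c = transfer(value_c) and contribution
    a_c = e_c * alpha_c; the sample opacity is the union
    1 - prod(1 - a_c) and the colour the a_c-weighted average of channel
    colours (zero vector when nothing contributes).  Invisible channels are
    skipped.
    """
    from .transfer import apply_transfer

    values = np.asarray(values, dtype=np.float64)
    rgb = np.zeros(3)
    one_minus = 1.0
    total = 0.0
    for v, t in zip(values, transfers):
        if not t.visible:
            continue
        a_c = apply_transfer(t, float(v)) * t.alpha
        one_minus *= 1.0 - a_c
        total += a_c
        rgb = rgb + a_c * np.asarray(t.color)
    if total > 0:
        rgb = rgb / total
    return rgb, 1.0 - one_minus


# ---------------------------------------------------------------------------
# Frame rendering
# ---------------------------------------------------------------------------


def _slab_intersect(origin: np.ndarray, dirs: np.ndarray, half: np.ndarray):
    """Ray/box intersection for a shared origin and (..., 3) unit dirs."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dirs
    t_lo = (-half - origin) * inv
    t_hi = (half - origin) * inv
    near = np.minimum(t_lo, t_hi)
    far = np.maximum(t_lo, t_hi)
    # Degenerate axis (dir component 0): inside the slab -> unbounded, else miss.
    zero = np.abs(dirs) < 1e-300
    inside = np.abs(origin) <= half
    near = np.where(zero, np.where(inside, -np.inf, np.inf), near)
    far = np.where(zero, np.where(inside, np.inf, -np.inf), far)
    t0 = near.max(axis=-1)
    t1 = far.min(axis=-1)
    return t0, t1


def _transfer_tables(transfers: list[ChannelTransfer]):
    vis = [t for t in transfers if t.visible]
    if not vis:
        return None
    coefs = [solve_coefficients(t) for t in vis]
    return {
        "dark": np.array([t.i_dark for t in vis])[:, None],
        "bright": np.array([t.i_bright for t in vis])[:, None],
        "a": np.array([c.a for c in coefs])[:, None],
        "b": np.array([c.b for c in coefs])[:, None],
        "c": np.array([c.c for c in coefs])[:, None],
        "alpha": np.array([t.alpha for t in vis])[:, None],
        "color": np.array([t.color for t in vis]),  # (C, 3)
        "index": [i for i, t in enumerate(transfers) if t.visible],
    }


def _blend_many(values: np.ndarray, tab) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized channel_blend over (C, M) sample values."""
    e = np.clip(tab["a"] * values * values + tab["b"] * values + tab["c"], 0.0, 1.0)
    e = np.where(values <= tab["dark"], 0.0, e)
    e = np.where(values >= tab["bright"], 1.0, e)
    a_c = e * tab["alpha"]  # (C, M)
    alpha_s = 1.0 - np.prod(1.0 - a_c, axis=0)
    total = a_c.sum(axis=0)
    safe = np.where(total > 0, total, 1.0)
    rgb = np.einsum("cm,ck->mk", a_c, tab["color"]) / safe[:, None]
    rgb[total == 0] = 0.0
    return rgb, alpha_s


def render_frame(
    vol: Volume,
    transfers: list[ChannelTransfer],
    view: ViewParams,
    cam: CameraModel,
    settings: RenderSettings | None = None,
) -> FrameImage:
    """Render one frame by front-to-back raycasting (see module docstring)."""
    settings = settings or RenderSettings()
    w, h = cam.viewport
    px, py = np.meshgrid(np.arange(w), np.arange(h))
    origin_v, dirs_v = _ray_grid_view(cam, view, px, py)
    dirs_v = dirs_v / np.linalg.norm(dirs_v, axis=-1, keepdims=True)

    rot = view.world_rotation
    o_vol = rot.T @ origin_v
    d_vol = dirs_v @ rot  # == (rot.T @ d) per ray

    ext = volume_world_box(vol.meta)
    half = ext / 2.0
    dims = np.asarray(vol.meta.dims, dtype=np.float64)

    t0, t1 = _slab_intersect(o_vol, d_vol, half)
    t0 = np.maximum(t0, 0.0)
    hit = t1 > t0

    # Sampling-plane intersection parameter (plane is z_view = plane_depth;
    # every forward ray has a strictly negative view-space z component).
    t_plane = (view.plane_depth - origin_v[2]) / dirs_v[..., 2]

    acc_rgb = np.zeros((h, w, 3), dtype=np.float64)
    acc_a = np.zeros((h, w), dtype=np.float64)
    tab = _transfer_tables(transfers)

    if tab is not None and vol.codes.any():
        pad = _padded_normalized(vol)
        pad = pad[tab["index"]]
        step = settings.step_scale * float((ext / dims).min())

        if view.clip_mode == "plane":
            sel = hit & (t_plane >= t0) & (t_plane <= t1)
            if sel.any():
                pts_w = o_vol + t_plane[sel, None] * d_vol[sel]
                pts = (pts_w + half) / ext * dims
                rgb_s, a_s = _blend_many(_trilinear(pad, vol.meta.dims, pts), tab)
                acc_rgb[sel] = a_s[:, None] * rgb_s
                acc_a[sel] = a_s
        else:
            if view.clip_mode == "front":
                t0 = np.maximum(t0, t_plane)
                hit = t1 > t0
            seg = np.where(hit, t1 - t0, 0.0)
            n_steps = np.floor(seg / step + 0.5).astype(np.int64)
            max_k = int(n_steps.max()) if hit.any() else 0
            flat_rgb = acc_rgb.reshape(-1, 3)
            flat_a = acc_a.reshape(-1)
            f_t0 = t0.reshape(-1)
            f_n = n_steps.reshape(-1)
            f_o = o_vol
            f_d = d_vol.reshape(-1, 3)
            for k in range(max_k):
                active = (f_n > k) & (flat_a < settings.early_termination_alpha)
                if not active.any():
                    break
                idx = np.nonzero(active)[0]
                t = f_t0[idx] + (k + 0.5) * step
                pts_w = f_o + t[:, None] * f_d[idx]
                pts = (pts_w + half) / ext * dims
                rgb_s, a_s = _blend_many(_trilinear(pad, vol.meta.dims, pts), tab)
                trans = 1.0 - flat_a[idx]
                flat_rgb[idx] += (trans * a_s)[:, None] * rgb_s
                flat_a[idx] += trans * a_s
            acc_rgb = flat_rgb.reshape(h, w, 3)
            acc_a = flat_a.reshape(h, w)

    bg = np.asarray(settings.background, dtype=np.float64)
    rgb = np.clip(acc_rgb + (1.0 - acc_a)[..., None] * bg, 0.0, 1.0)
    frame = FrameImage(rgb=rgb, alpha=np.clip(acc_a, 0.0, 1.0))
    if view.clip_mode != "off":
        _draw_overlays(frame, vol, view, cam, settings, t_plane, origin_v, dirs_v)
    return frame


def render_slice(
    vol: Volume,
    transfers: list[ChannelTransfer],
    view: ViewParams,
    cam: CameraModel,
    settings: RenderSettings | None = None,
) -> FrameImage:
    """Single-sample slice at the sampling plane (clip_mode must be 'plane')."""
    if view.clip_mode != "plane":
        raise InvalidParameterError("render_slice requires clip_mode 'plane'")
    return render_frame(vol, transfers, view, cam, settings)


def _draw_overlays(frame, vol, view, cam, settings, t_plane, origin_v, dirs_v):
    """Plane grid (yellow lines at 1/8 spacing of the box footprint) and a
    bottom-left depth-readout strip.  Appearance is a documented
    approximation, drawn after compositing."""
    lo, hi = rotated_box_aabb(vol.meta, view)
    if not (lo[2] <= view.plane_depth <= hi[2]):
        return
    h, w = frame.rgb.shape[:2]
    if settings.overlays.plane_grid:
        hit = origin_v[None, None, :2] + t_plane[..., None] * dirs_v[..., :2]
        span = np.maximum(hi[:2] - lo[:2], 1e-12)
        gx = (hit[..., 0] - lo[0]) / span[0] * 8.0
        gy = (hit[..., 1] - lo[1]) / span[1] * 8.0
        in_foot = (
            (t_plane > 0)
            & (hit[..., 0] >= lo[0]) & (hit[..., 0] <= hi[0])
            & (hit[..., 1] >= lo[1]) & (hit[..., 1] <= hi[1])
        )
        line = (np.abs(gx - np.round(gx)) < 0.05) | (np.abs(gy - np.round(gy)) < 0.05)
        mask = in_foot & line
        frame.rgb[mask] = (1.0, 1.0, 0.0)
    if settings.overlays.coordinate_readout:
        frac = float(np.clip((view.plane_depth - lo[2]) / max(hi[2] - lo[2], 1e-12), 0.0, 1.0))
        bar = max(1, int(round(frac * (w // 4))))
        frame.rgb[h - 3 : h, 0 : bar] = 1.0


# ---------------------------------------------------------------------------
# PNG export (lossless, deterministic)
# ---------------------------------------------------------------------------


def frame_to_png_bytes(frame: FrameImage) -> bytes:
    from PIL import Image

    arr = np.floor(frame.rgb * 255.0 + 0.5).astype(np.uint8)
    buf = io.BytesIO()
    Image.fromarray(arr, mode="RGB").save(buf, format="PNG")
    return buf.getvalue()


def png_bytes_to_array(data: bytes) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(io.BytesIO(data)).convert("RGB"))
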