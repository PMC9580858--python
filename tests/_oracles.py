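"""Independent straight-line reference integrator used by the renderer
equivalence tests.

Everything here is written from the documented rendering rules alone —
scalar per-pixel loops, brute-force box clipping, an 8-corner trilinear
sum, a linear-system transfer solve — sharing no code with the package's
vectorized implementation.
"""

import math

import numpy as np


def oracle_transfer(dark, bright, mid, x):
    m = (dark + bright) / 2.0
    mid = min(max(mid, 0.25), 0.75)
    A = np.array([[dark**2, dark, 1.0], [bright**2, bright, 1.0], [m**2, m, 1.0]])
    a, b, c = np.linalg.solve(A, np.array([0.0, 1.0, mid]))
    if x <= dark:
        return 0.0
    if x >= bright:
        return 1.0
    return float(min(max(a * x * x + b * x + c, 0.0), 1.0))


def oracle_trilinear(norm, dims, p):
    """8-corner weighted sum at continuous (x, y, z) voxel coordinates;
    ``norm`` is (C, z, y, x) in [0, 1]; zero outside the volume."""
    nx, ny, nz = dims
    gx, gy, gz = p[0] - 0.5, p[1] - 0.5, p[2] - 0.5
    i, j, k = math.floor(gx), math.floor(gy), math.floor(gz)
    fx, fy, fz = gx - i, gy - j, gz - k
    out = np.zeros(norm.shape[0])
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                ii, jj, kk = i + dx, j + dy, k + dz
                if 0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz:
                    w = (fx if dx else 1 - fx) * (fy if dy else 1 - fy) * (fz if dz else 1 - fz)
                    out += w * norm[:, kk, jj, ii]
    return out


def oracle_clip_box(origin, direction, half):
    """Brute-force slab clipping; returns (t0, t1) or None on a miss."""
    t0, t1 = -math.inf, math.inf
    for ax in range(3):
        d, o, h = direction[ax], origin[ax], half[ax]
        if abs(d) < 1e-300:
            if abs(o) > h:
                return None
            continue
        ta, tb = (-h - o) / d, (h - o) / d
        t0 = max(t0, min(ta, tb))
        t1 = min(t1, max(ta, tb))
    if t1 <= t0:
        return None
    return t0, t1


def oracle_render(vol, transfers, view, cam, settings):
    """Scalar per-pixel reference renderer (off/front/plane clip modes)."""
    w, h = cam.viewport
    tanf = math.tan(math.radians(cam.fov_y) / 2.0)
    aspect = w / h
    rot = view.world_rotation
    norm = vol.codes.astype(np.float64) / 255.0
    norm = norm[[i for i, t in enumerate(transfers) if t.visible]]
    dims = vol.meta.dims
    ext = np.array([d * s for d, s in zip(dims, vol.meta.physical_voxel_size)], float)
    ext = ext / ext.max()
    half = ext / 2.0
    step = settings.step_scale * min(e / d for e, d in zip(ext, dims))
    vis = [t for t in transfers if t.visible]
    bg = np.array(settings.background)
    img = np.zeros((h, w, 3))
    alpha_img = np.zeros((h, w))

    for py in range(h):
        for px in range(w):
            u = ((px + 0.5) / w * 2 - 1) * tanf * aspect
            v = (1 - (py + 0.5) / h * 2) * tanf
            d_view = np.array([u / view.zoom, v / view.zoom, -1.0])
            d_view = d_view / np.linalg.norm(d_view)
            o_view = np.array([view.pan[0], view.pan[1], cam.camera_distance])
            o = rot.T @ o_view
            d = rot.T @ d_view
            clip = oracle_clip_box(o, d, half)
            acc_c = np.zeros(3)
            acc_a = 0.0
            if clip is not None:
                t0, t1 = clip
                t0 = max(t0, 0.0)
                t_plane = (view.plane_depth - o_view[2]) / d_view[2]
                if view.clip_mode == "plane":
                    ts = [t_plane] if t0 <= t_plane <= t1 and t1 > t0 else []
                else:
                    if view.clip_mode == "front":
                        t0 = max(t0, t_plane)
                    n = int(math.floor((t1 - t0) / step + 0.5)) if t1 > t0 else 0
                    ts = [t0 + (k + 0.5) * step for k in range(n)]
                for t in ts:
                    if acc_a >= settings.early_termination_alpha:
                        break
                    p = o + t * d
                    cont = (p + half) / ext * np.array(dims, float)
                    values = oracle_trilinear(norm, dims, cont)
                    rgb = np.zeros(3)
                    one_minus = 1.0
                    total = 0.0
                    for val, tr in zip(values, vis):
                        a_c = oracle_transfer(tr.i_dark, tr.i_bright, tr.i_mid, val) * tr.alpha
                        one_minus *= 1.0 - a_c
                        total += a_c
                        rgb += a_c * np.array(tr.color)
                    a_s = 1.0 - one_minus
                    if total > 0:
                        rgb /= total
                    acc_c = acc_c + (1 - acc_a) * a_s * rgb
                    acc_a = acc_a + (1 - acc_a) * a_s
            img[py, px] = np.clip(acc_c + (1 - acc_a) * bg, 0, 1)
            alpha_img[py, px] = acc_a
    return img, alpha_img
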