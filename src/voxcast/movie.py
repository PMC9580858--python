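"""Keyframed, reproducible movie generation.

A movie is an ordered list of stages; each stage interpolates one view
parameter linearly over ``round(duration_s * fps)`` frames and captures a
frame at every step.  Rotation stages compose a constant per-frame delta
rotation (total_angle / frame_count about the stated axis) onto the world
rotation, so the stage endpoint matches the closed-form single rotation to
numerical precision.  Output is a zero-padded PNG sequence (bit-exact
surface); MP4 muxing is best-effort and never required.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .camera import compose_rotation, reset_view, rotated_box_aabb, rotation_about_axis
from .errors import InvalidParameterError, VoxcastError
from .render import FrameImage, frame_to_png_bytes
from .server import Session

__all__ = [
    "MovieStage",
    "MovieRecipe",
    "MovieResult",
    "run_stage",
    "run_recipe",
    "sample_movie_recipe",
    "sample_movie",
    "write_movie",
]

STAGE_KINDS = ("zoom", "rotate", "plane_move", "mode_switch")


@dataclass
class MovieStage:
    """One interpolation stage.

    ``params`` per kind:
      zoom        — start, end (zoom factors; start defaults to current)
      rotate      — axis ('x'|'y'|'z'), degrees (total angle)
      plane_move  — start, end (plane depths; start defaults to current)
      mode_switch — clip_mode ('off'|'front'|'plane')
    """

    kind: str
    duration_s: float = 1.0
    fps: float = 10.0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in STAGE_KINDS:
            raise InvalidParameterError(f"unknown stage kind {self.kind!r}")
        if self.duration_s <= 0 or self.fps <= 0:
            raise InvalidParameterError("duration_s and fps must be positive")

    @property
    def frame_count(self) -> int:
        return max(1, int(round(self.duration_s * self.fps)))

    def to_doc(self) -> dict:
        return {"kind": self.kind, "duration_s": self.duration_s, "fps": self.fps,
                "params": dict(self.params)}

    @classmethod
    def from_doc(cls, doc: dict) -> "MovieStage":
        return cls(kind=doc["kind"], duration_s=doc.get("duration_s", 1.0),
                   fps=doc.get("fps", 10.0), params=dict(doc.get("params", {})))


@dataclass
class MovieRecipe:
    stages: list[MovieStage]
    render_params: dict = field(default_factory=dict)
    view_params: dict = field(default_factory=dict)
    ui_params: dict = field(default_factory=dict)
    reset_first: bool = True

    def __post_init__(self):
        if not self.stages:
            raise InvalidParameterError("recipe must contain at least one stage")

    def to_doc(self) -> dict:
        return {
            "stages": [s.to_doc() for s in self.stages],
            "render_params": self.render_params,
            "view_params": self.view_params,
            "ui_params": self.ui_params,
            "reset_first": self.reset_first,
        }

    @classmethod
    def from_doc(cls, doc: dict) -> "MovieRecipe":
        return cls(
            stages=[MovieStage.from_doc(s) for s in doc.get("stages", [])],
            render_params=dict(doc.get("render_params", {})),
            view_params=dict(doc.get("view_params", {})),
            ui_params=dict(doc.get("ui_params", {})),
            reset_first=bool(doc.get("reset_first", True)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MovieRecipe":
        return cls.from_doc(json.loads(Path(path).read_text()))


@dataclass
class MovieResult:
    frames: list[FrameImage]
    stage_frame_counts: list[int]
    out_dir: Path | None = None


def run_stage(session: Session, stage: MovieStage) -> list[FrameImage]:
    """Execute one stage: set parameters at t = k / frame_count for
    k = 1..frame_count, capturing after each set."""
    if session.volume is None or session.view is None:
        raise InvalidParameterError("no volume loaded; cannot run a movie stage")
    n = stage.frame_count
    frames: list[FrameImage] = []
    view = session.view
    p = stage.params

    if stage.kind == "zoom":
        start = float(p.get("start", view.zoom))
        end = float(p.get("end", view.zoom))
        for k in range(1, n + 1):
            t = k / n
            session.view = view = _with(view, zoom=start + t * (end - start))
            frames.append(session.render())
    elif stage.kind == "rotate":
        axis = p.get("axis", "y")
        total = float(p.get("degrees", 0.0))
        delta = rotation_about_axis(axis, total / n)
        for _ in range(n):
            session.view = view = compose_rotation(view, delta)
            frames.append(session.render())
    elif stage.kind == "plane_move":
        if "clip_mode" in p:
            view = _with(view, clip_mode=p["clip_mode"])
        start = float(p.get("start", view.plane_depth))
        end = float(p.get("end", view.plane_depth))
        for k in range(1, n + 1):
            t = k / n
            session.view = view = _with(view, plane_depth=start + t * (end - start))
            frames.append(session.render())
    else:  # mode_switch
        session.view = view = _with(view, clip_mode=p["clip_mode"])
        for _ in range(n):
            frames.append(session.render())
    return frames


def _with(view, **kw):
    from dataclasses import replace

    return replace(view, **kw)


def run_recipe(session: Session, recipe: MovieRecipe,
               out_dir: str | Path | None = None) -> MovieResult:
    """Run all stages in order; on failure any partial output directory is
    removed so reruns start clean."""
    if session.volume is None:
        raise InvalidParameterError("no volume loaded")
    if recipe.render_params:
        session.put_render_params(recipe.render_params)
    if recipe.ui_params:
        session.put_ui_params(recipe.ui_params)
    if recipe.reset_first:
        session.view = reset_view(session.volume.meta)
    if recipe.view_params:
        session.put_view_params(recipe.view_params)

    frames: list[FrameImage] = []
    counts: list[int] = []
    out_path = Path(out_dir) if out_dir is not None else None
    try:
        for stage in recipe.stages:
            stage_frames = run_stage(session, stage)
            counts.append(len(stage_frames))
            frames.extend(stage_frames)
        if out_path is not None:
            write_movie(frames, out_path, fps=recipe.stages[0].fps)
    except VoxcastError:
        if out_path is not None and out_path.exists():
            shutil.rmtree(out_path)
        raise
    return MovieResult(frames=frames, stage_frame_counts=counts, out_dir=out_path)


# ---------------------------------------------------------------------------
# The packaged sample movie: zoom in, a 180-degree y-rotation, a front-clip
# plane sweep to just behind the volume centre, a second 180-degree
# y-rotation back to the start, then a slice fly-out toward the camera.
# Stage lengths: 1 s zoom, 5 s rotation, 2 s plane sweep at 10 fps; the
# final rotation and fly-out reuse 5 s and 2 s for symmetry.
# ---------------------------------------------------------------------------


def sample_movie_recipe(session: Session, fps: float = 10.0) -> MovieRecipe:
    """Build the packaged sample recipe against the loaded volume's
    geometry (plane depths depend on the box extent)."""
    if session.volume is None:
        raise InvalidParameterError("no volume loaded")
    meta = session.volume.meta
    view0 = reset_view(meta)
    lo, hi = rotated_box_aabb(meta, view0)
    extent = float(hi[2] - lo[2])
    edge = float(hi[2])
    near_center = -0.10 * extent  # "a little back from the volume centre"
    render_params = {
        "channels": {
            str(i): {"dark": 0.05, "mid": 0.6, "bright": 0.9, "alpha": 1.0}
            for i in range(meta.num_channels)
        }
    }
    stages = [
        MovieStage("zoom", duration_s=1.0, fps=fps, params={"start": 1.0, "end": 1.8}),
        MovieStage("rotate", duration_s=5.0, fps=fps, params={"axis": "y", "degrees": 180.0}),
        MovieStage(
            "plane_move", duration_s=2.0, fps=fps,
            params={"clip_mode": "front", "start": edge, "end": near_center},
        ),
        MovieStage("rotate", duration_s=5.0, fps=fps, params={"axis": "y", "degrees": 180.0}),
        MovieStage(
            "plane_move", duration_s=2.0, fps=fps,
            params={"clip_mode": "plane", "start": near_center, "end": edge + 0.1 * extent},
        ),
    ]
    return MovieRecipe(
        stages=stages,
        render_params=render_params,
        ui_params={"plane_grid": False, "coordinate_readout": False},
    )


def sample_movie(session: Session, out_dir: str | Path | None = None,
                 fps: float = 10.0) -> MovieResult:
    """Run the packaged sample movie on the session's volume."""
    return run_recipe(session, sample_movie_recipe(session, fps=fps), out_dir=out_dir)


def write_movie(frames: Iterable[FrameImage], path: str | Path, fps: float = 10.0,
                mp4: bool = False) -> list[Path]:
    """Write frames as frame_000001.png ... under ``path``.

    All frames must share one size; nothing is written otherwise.  MP4
    muxing (requires imageio + an ffmpeg backend) is opt-in best-effort.
    """
    frames = list(frames)
    if not frames:
        raise InvalidParameterError("no frames to write")
    shapes = {f.rgb.shape for f in frames}
    if len(shapes) != 1:
        raise InvalidParameterError(f"frame dimensions differ: {sorted(shapes)}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for i, frame in enumerate(frames, start=1):
        p = path / f"frame_{i:06d}.png"
        p.write_bytes(frame_to_png_bytes(frame))
        written.append(p)
    if mp4:
        try:  # pragma: no cover - optional encoder
            import imageio.v3 as iio

            arrs = [np.floor(f.rgb * 255.0 + 0.5).astype(np.uint8) for f in frames]
            iio.imwrite(path / "movie.mp4", arrs, fps=fps)
        except Exception:
            pass
    return written
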