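"""Local HTTP control service and the headless session it drives.

Endpoints (localhost, default port 8307):

* ``POST /loadImage`` — JSON metadata in the ``X-Volume-Meta`` header,
  raw little-endian channel-major bytes in the body.  Non-8-bit payloads
  are quantized on arrival.
* ``GET/PUT /renderParams`` — per-channel transfer documents plus render
  settings; partial PUTs merge.
* ``GET/PUT /viewParams`` — rotation/zoom/pan/plane/clip document.
* ``GET /captureImage?width=&height=`` — deterministic PNG of the current
  state.
* ``PUT /uiParams`` — overlay toggles.

The API is piecemeal: a client that only implements /loadImage and
/captureImage gets a valid rendering with all defaults.
"""

from __future__ import annotations

import json
import logging
import threading
import time
from dataclasses import replace
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from urllib.parse import parse_qs, urlparse

import numpy as np

from .camera import CameraModel, ViewParams, reset_view
from .errors import ApiError, InvalidParameterError, VoxcastError
from .render import OverlaySettings, RenderSettings, frame_to_png_bytes, render_frame
from .transfer import ChannelTransfer, default_transfers
from .volume import Volume, VolumeMetadata, quantize_volume

__all__ = ["Session", "VoxcastServer", "start_server", "serve_forever", "DEFAULT_PORT"]

DEFAULT_PORT = 8307

log = logging.getLogger(__name__)

_DTYPES = {"uint8": np.uint8, "uint16": np.uint16, "float32": np.float32, "float64": np.float64}


def canonical_json(doc) -> str:
    """Stable serialization so set -> get -> set -> get is byte-identical."""
    return json.dumps(doc, sort_keys=True, separators=(",", ":"))


class Session:
    """Single-viewer state machine behind the HTTP endpoints.

    All mutating calls validate first and only then commit, so an invalid
    request never leaves the session half-updated.
    """

    def __init__(self, settings: RenderSettings | None = None, camera: CameraModel | None = None):
        self.volume: Volume | None = None
        self.transfers: list[ChannelTransfer] = []
        self.view: ViewParams | None = None
        self.settings = settings or RenderSettings()
        self.camera = camera or CameraModel()
        self._lock = threading.RLock()

    # -- image send -----------------------------------------------------

    def load_image(self, meta_doc: dict, body: bytes) -> dict:
        dtype_name = meta_doc.get("dtype", "uint8")
        if dtype_name not in _DTYPES:
            raise ApiError(400, f"unsupported dtype '{dtype_name}'")
        try:
            meta = VolumeMetadata.from_dict(meta_doc)
        except VoxcastError as e:
            raise ApiError(400, str(e))
        dtype = np.dtype(_DTYPES[dtype_name]).newbyteorder("<")
        expected = int(np.prod(meta.shape_czyx)) * dtype.itemsize
        if len(body) != expected:
            raise ApiError(
                400,
                f"body length {len(body)} does not match metadata "
                f"(expected {expected} bytes for dtype {dtype_name})",
            )
        arr = np.frombuffer(body, dtype=dtype).reshape(meta.shape_czyx)
        if dtype == np.uint8:
            vol = Volume(meta=meta, codes=arr.copy())
        else:
            try:
                vol = quantize_volume(arr.astype(np.float64), meta)
            except VoxcastError as e:
                raise ApiError(400, str(e))
        with self._lock:
            self.volume = vol
            self.transfers = default_transfers(meta.num_channels)
            self.view = reset_view(meta)
        return {"channels": meta.num_channels, "dims": list(meta.dims)}

    def set_volume(self, vol: Volume) -> None:
        with self._lock:
            self.volume = vol
            self.transfers = default_transfers(vol.meta.num_channels)
            self.view = reset_view(vol.meta)

    # -- render params --------------------------------------------------

    def get_render_params(self) -> dict:
        if self.volume is None:
            raise ApiError(409, "no volume loaded")
        return {
            "channels": [t.to_doc() for t in self.transfers],
            "settings": self.settings.to_doc(),
        }

    def put_render_params(self, doc: dict) -> dict:
        if self.volume is None:
            raise ApiError(409, "no volume loaded")
        if not isinstance(doc, dict):
            raise ApiError(400, "render params document must be a JSON object")
        unknown = set(doc) - {"channels", "settings"}
        if unknown:
            raise ApiError(400, f"unknown render field '{sorted(unknown)[0]}'")
        new_transfers = list(self.transfers)
        channels = doc.get("channels", {})
        if isinstance(channels, list):
            items = list(enumerate(channels))
        else:
            try:
                items = [(int(k), v) for k, v in channels.items()]
            except ValueError:
                raise ApiError(400, "channel keys must be integers")
        try:
            for idx, ch_doc in items:
                if not 0 <= idx < len(new_transfers):
                    raise ApiError(400, f"channel index {idx} out of range")
                new_transfers[idx] = ChannelTransfer.from_doc(ch_doc, base=new_transfers[idx])
            s = doc.get("settings", {})
            unknown = set(s) - {"background", "step_scale", "early_termination_alpha"}
            if unknown:
                raise ApiError(400, f"unknown settings field '{sorted(unknown)[0]}'")
            new_settings = RenderSettings(
                background=tuple(s.get("background", self.settings.background)),
                step_scale=s.get("step_scale", self.settings.step_scale),
                early_termination_alpha=s.get(
                    "early_termination_alpha", self.settings.early_termination_alpha
                ),
                overlays=self.settings.overlays,
            )
        except InvalidParameterError as e:
            raise ApiError(400, str(e))
        with self._lock:
            self.transfers = new_transfers
            self.settings = new_settings
        return self.get_render_params()

    # -- view params ----------------------------------------------------

    def get_view_params(self) -> dict:
        if self.view is None:
            raise ApiError(409, "no volume loaded")
        return self.view.to_doc()

    def put_view_params(self, doc: dict) -> dict:
        if self.view is None:
            raise ApiError(409, "no volume loaded")
        try:
            new_view = ViewParams.from_doc(doc, base=self.view)
        except InvalidParameterError as e:
            raise ApiError(400, str(e))
        with self._lock:
            self.view = new_view
        return self.get_view_params()

    # -- UI overlays ----------------------------------------------------

    def put_ui_params(self, doc: dict) -> dict:
        unknown = set(doc) - {"plane_grid", "coordinate_readout"}
        if unknown:
            raise ApiError(400, f"unknown ui field '{sorted(unknown)[0]}'")
        ov = self.settings.overlays
        with self._lock:
            self.settings.overlays = OverlaySettings(
                plane_grid=bool(doc.get("plane_grid", ov.plane_grid)),
                coordinate_readout=bool(doc.get("coordinate_readout", ov.coordinate_readout)),
            )
        return self.settings.overlays.to_doc()

    # -- capture ---------------------------------------------------------

    def render(self, width: int | None = None, height: int | None = None):
        if self.volume is None or self.view is None:
            raise ApiError(409, "no volume loaded")
        cam = self.camera
        if width is not None or height is not None:
            w = cam.viewport[0] if width is None else int(width)
            h = cam.viewport[1] if height is None else int(height)
            if not (1 <= w <= 4096 and 1 <= h <= 4096):
                raise ApiError(400, "width/height must be in [1, 4096]")
            cam = replace(cam, viewport=(w, h))
        with self._lock:
            return render_frame(self.volume, self.transfers, self.view, cam, self.settings)

    def capture(self, width: int | None = None, height: int | None = None) -> bytes:
        return frame_to_png_bytes(self.render(width, height))


# ---------------------------------------------------------------------------
# HTTP layer (stdlib http.server; localhost-only by default)
# ---------------------------------------------------------------------------


class _Handler(BaseHTTPRequestHandler):
    protocol_version = "HTTP/1.1"

    @property
    def session(self) -> Session:
        return self.server.session  # type: ignore[attr-defined]

    def log_message(self, fmt, *args):  # route through logging, not stderr
        log.debug(fmt, *args)

    def _reply(self, status: int, payload: bytes, content_type: str):
        self.send_response(status)
        self.send_header("Content-Type", content_type)
        self.send_header("Content-Length", str(len(payload)))
        self.end_headers()
        self.wfile.write(payload)

    def _reply_json(self, status: int, doc):
        self._reply(status, canonical_json(doc).encode() + b"\n", "application/json")

    def _read_body(self) -> bytes:
        length = int(self.headers.get("Content-Length", 0))
        return self.rfile.read(length) if length else b""

    def _dispatch(self, method: str):
        start = time.monotonic()
        parsed = urlparse(self.path)
        route = (method, parsed.path)
        status = 200
        try:
            if route == ("POST", "/loadImage"):
                meta_header = self.headers.get("X-Volume-Meta")
                if meta_header:
                    meta_doc = json.loads(meta_header)
                    body = self._read_body()
                else:
                    raise ApiError(400, "missing X-Volume-Meta header with JSON metadata")
                self._reply_json(200, self.session.load_image(meta_doc, body))
            elif route == ("GET", "/renderParams"):
                self._reply_json(200, self.session.get_render_params())
            elif route == ("PUT", "/renderParams"):
                doc = json.loads(self._read_body() or b"{}")
                self._reply_json(200, self.session.put_render_params(doc))
            elif route == ("GET", "/viewParams"):
                self._reply_json(200, self.session.get_view_params())
            elif route == ("PUT", "/viewParams"):
                doc = json.loads(self._read_body() or b"{}")
                self._reply_json(200, self.session.put_view_params(doc))
            elif route == ("PUT", "/uiParams"):
                doc = json.loads(self._read_body() or b"{}")
                self._reply_json(200, self.session.put_ui_params(doc))
            elif route == ("GET", "/captureImage"):
                q = parse_qs(parsed.query)
                width = int(q["width"][0]) if "width" in q else None
                height = int(q["height"][0]) if "height" in q else None
                self._reply(200, self.session.capture(width, height), "image/png")
            elif route == ("GET", "/health"):
                self._reply_json(200, {"status": "ok"})
            else:
                status = 404
                self._reply_json(404, {"error": f"no route {method} {parsed.path}"})
        except ApiError as e:
            status = e.status
            self._reply_json(e.status, {"error": e.message})
        except (json.JSONDecodeError, ValueError) as e:
            status = 400
            self._reply_json(400, {"error": f"malformed request: {e}"})
        finally:
            log.info(
                "%s %s -> %d (%.1f ms)", method, parsed.path, status,
                (time.monotonic() - start) * 1e3,
            )

    def do_GET(self):
        self._dispatch("GET")

    def do_POST(self):
        self._dispatch("POST")

    def do_PUT(self):
        self._dispatch("PUT")


class VoxcastServer(ThreadingHTTPServer):
    daemon_threads = True

    def __init__(self, port: int = DEFAULT_PORT, host: str = "127.0.0.1",
                 session: Session | None = None):
        self.session = session or Session()
        super().__init__((host, port), _Handler)

    @property
    def port(self) -> int:
        return self.server_address[1]


def start_server(
    port: int = DEFAULT_PORT, host: str = "127.0.0.1", session: Session | None = None
) -> VoxcastServer:
    """Start a server on a background daemon thread; returns the server
    (use ``server.port`` when binding port 0)."""
    server = VoxcastServer(port=port, host=host, session=session)
    thread = threading.Thread(target=server.serve_forever, daemon=True, name="voxcast-http")
    thread.start()
    server._thread = thread  # type: ignore[attr-defined]
    return server


def serve_forever(port: int = DEFAULT_PORT, host: str = "127.0.0.1",
                  session: Session | None = None) -> None:
    server = VoxcastServer(port=port, host=host, session=session)
    log.info("voxcast server listening on %s:%d", host, server.port)
    try:
        server.serve_forever()
    finally:
        server.server_close()
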