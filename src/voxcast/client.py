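"""Thin HTTP scripting client mirroring the server endpoints.

No rendering logic lives here: every method is a pass-through with payload
encoding, so any environment that can issue HTTP POST/GET requests can
reimplement it.  By default the client auto-starts an in-process server
when nothing is listening on the configured port.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.request

import numpy as np

from .errors import ApiError
from .server import DEFAULT_PORT, canonical_json, start_server

__all__ = ["Client"]


class Client:
    def __init__(self, port: int = DEFAULT_PORT, host: str = "127.0.0.1",
                 auto_start: bool = True, timeout: float = 30.0):
        self.host = host
        self.port = port
        self.timeout = timeout
        self._auto_start = auto_start
        self._server = None
        if auto_start and port == 0:  # ephemeral port implies a fresh local server
            self._server = start_server(port=0, host=host)
            self.port = self._server.port
            self._auto_start = False

    @property
    def base_url(self) -> str:
        return f"http://{self.host}:{self.port}"

    def _request(self, method: str, path: str, body: bytes | None = None,
                 headers: dict | None = None) -> tuple[int, bytes]:
        req = urllib.request.Request(
            self.base_url + path, data=body, method=method, headers=headers or {}
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                return resp.status, resp.read()
        except urllib.error.HTTPError as e:
            payload = e.read()
            try:
                message = json.loads(payload).get("error", payload.decode())
            except Exception:
                message = payload.decode(errors="replace")
            raise ApiError(e.code, message)
        except urllib.error.URLError as e:
            if self._auto_start and self._server is None:
                self._server = start_server(port=self.port, host=self.host)
                self.port = self._server.port
                self._auto_start = False
                return self._request(method, path, body, headers)
            raise ConnectionError(
                f"no voxcast server reachable at {self.base_url}; "
                f"start one with 'voxcast serve --port {self.port}' ({e.reason})"
            )

    def _json(self, method: str, path: str, doc=None) -> dict:
        body = canonical_json(doc).encode() if doc is not None else None
        _, payload = self._request(
            method, path, body, {"Content-Type": "application/json"} if body else {}
        )
        return json.loads(payload)

    # -- endpoint mirrors -----------------------------------------------

    def show(self, array: np.ndarray, meta: dict | None = None) -> dict:
        """Send an image stack to the viewer (the one required call).

        ``array`` is (channel, z, y, x) or (z, y, x); float data is
        quantized server-side.  ``meta`` may supply physical_voxel_size
        and channel_names.
        """
        arr = np.asarray(array)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.ndim != 4:
            raise ValueError(f"expected a 3-D or 4-D array, got shape {arr.shape}")
        c, z, y, x = arr.shape
        if arr.dtype not in (np.uint8, np.uint16, np.float32, np.float64):
            arr = arr.astype(np.float64)
        doc = {
            "dims": [x, y, z],
            "num_channels": c,
            "physical_voxel_size": [1.0, 1.0, 1.0],
            "dtype": arr.dtype.name,
        }
        if meta:
            doc.update(meta)
        body = np.ascontiguousarray(arr.astype(arr.dtype.newbyteorder("<"))).tobytes()
        _, payload = self._request(
            "POST", "/loadImage", body,
            {"X-Volume-Meta": canonical_json(doc), "Content-Type": "application/octet-stream"},
        )
        return json.loads(payload)

    def get_render_params(self) -> dict:
        return self._json("GET", "/renderParams")

    def set_render_params(self, doc: dict) -> dict:
        return self._json("PUT", "/renderParams", doc)

    def get_view_params(self) -> dict:
        return self._json("GET", "/viewParams")

    def set_view_params(self, doc: dict) -> dict:
        return self._json("PUT", "/viewParams", doc)

    def set_ui_params(self, doc: dict) -> dict:
        return self._json("PUT", "/uiParams", doc)

    def capture(self, width: int | None = None, height: int | None = None) -> bytes:
        """Capture the current rendering as PNG bytes."""
        query = "&".join(
            f"{k}={v}" for k, v in (("width", width), ("height", height)) if v is not None
        )
        _, payload = self._request("GET", "/captureImage" + (f"?{query}" if query else ""))
        return payload

    def capture_array(self, width: int | None = None, height: int | None = None) -> np.ndarray:
        from .render import png_bytes_to_array

        return png_bytes_to_array(self.capture(width, height))

    def close(self):
        if self._server is not None:
            self._server.shutdown()
            self._server.server_close()
            self._server = None
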