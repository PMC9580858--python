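"""Volume representation: 8-bit quantization, file I/O, synthetic fixtures.

Volumes are stored as 8-bit codes per channel with a per-channel linear
normalization record, so any floating-point stack can round-trip to within
half a code of its original values.  Axis order is fixed as
``(channel, z, y, x)``; voxel indices are 0-based; physical sizes are
ordered ``(x, y, z)`` in micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, InvalidInputError, InvalidParameterError

__all__ = [
    "VolumeMetadata",
    "Volume",
    "quantize_volume",
    "dequantize",
    "load_volume",
    "save_volume",
    "save_tiff",
    "make_synthetic_volume",
]


@dataclass(frozen=True)
class VolumeMetadata:
    """Geometry and channel bookkeeping for a multichannel stack.

    ``dims`` counts voxels along (x, y, z); ``physical_voxel_size`` is the
    physical extent of one voxel along (x, y, z) in micrometres.  Channel
    names are auto-filled ``ch0, ch1, ...`` when not supplied.
    """

    dims: tuple[int, int, int]
    num_channels: int = 1
    physical_voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel_names: tuple[str, ...] = ()

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise InvalidParameterError(f"dims must be three positive integers, got {self.dims!r}")
        pvs = tuple(float(s) for s in self.physical_voxel_size)
        if len(pvs) != 3 or any(not np.isfinite(s) or s <= 0 for s in pvs):
            raise InvalidParameterError(
                f"physical_voxel_size must be three positive reals, got {self.physical_voxel_size!r}"
            )
        if self.num_channels < 1:
            raise InvalidParameterError(f"num_channels must be >= 1, got {self.num_channels}")
        names = tuple(self.channel_names)
        if not names:
            names = tuple(f"ch{i}" for i in range(self.num_channels))
        elif len(names) != self.num_channels:
            raise InvalidParameterError(
                f"channel_names has {len(names)} entries for {self.num_channels} channels"
            )
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "physical_voxel_size", pvs)
        object.__setattr__(self, "num_channels", int(self.num_channels))
        object.__setattr__(self, "channel_names", names)

    @property
    def shape_czyx(self) -> tuple[int, int, int, int]:
        x, y, z = self.dims
        return (self.num_channels, z, y, x)

    def to_dict(self) -> dict:
        return {
            "dims": list(self.dims),
            "num_channels": self.num_channels,
            "physical_voxel_size": list(self.physical_voxel_size),
            "channel_names": list(self.channel_names),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "VolumeMetadata":
        for key in ("dims", "num_channels", "physical_voxel_size"):
            if key not in doc:
                raise FormatError(f"metadata missing required field '{key}'")
        return cls(
            dims=tuple(doc["dims"]),
            num_channels=int(doc["num_channels"]),
            physical_voxel_size=tuple(doc["physical_voxel_size"]),
            channel_names=tuple(doc.get("channel_names") or ()),
        )


@dataclass
class Volume:
    """Quantized multichannel volume.

    ``codes`` has shape ``(num_channels, z, y, x)`` and dtype uint8;
    ``norm_records`` maps each channel's codes back to input units via
    ``value = offset + scale * code``.
    """

    meta: VolumeMetadata
    codes: np.ndarray
    norm_records: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        if self.codes.shape != self.meta.shape_czyx:
            raise InvalidInputError(
                f"codes shape {self.codes.shape} does not match metadata shape {self.meta.shape_czyx}"
            )
        if self.codes.dtype != np.uint8:
            if self.codes.min() < 0 or self.codes.max() > 255:
                raise InvalidInputError("codes must lie in [0, 255]")
            self.codes = self.codes.astype(np.uint8)
        if not self.norm_records:
            self.norm_records = [(0.0, 1.0 / 255.0)] * self.meta.num_channels
        if len(self.norm_records) != self.meta.num_channels:
            raise InvalidInputError("norm_records length must equal num_channels")
        for off, scale in self.norm_records:
            if scale < 0:
                raise InvalidInputError("norm_records scale must be >= 0")

    def normalized(self) -> np.ndarray:
        """Codes mapped to [0, 1] as float64 (renderer-facing view)."""
        return self.codes.astype(np.float64) / 255.0


def quantize_volume(raw: np.ndarray, meta: VolumeMetadata) -> Volume:
    """Quantize a floating-point stack to 8 bits per channel.

    Per channel, ``code = round(255 * (v - min) / (max - min))`` with
    round-half-up; a constant channel maps wholly to code 0 with scale 0.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.shape != meta.shape_czyx:
        raise InvalidInputError(
            f"raw shape {raw.shape} does not match metadata shape {meta.shape_czyx}"
        )
    if not np.all(np.isfinite(raw)):
        raise InvalidInputError("raw volume contains non-finite values")
    codes = np.empty(raw.shape, dtype=np.uint8)
    records: list[tuple[float, float]] = []
    for c in range(meta.num_channels):
        ch = raw[c]
        lo = float(ch.min())
        hi = float(ch.max())
        if hi == lo:
            codes[c] = 0
            records.append((lo, 0.0))
            continue
        scaled = 255.0 * (ch - lo) / (hi - lo)
        codes[c] = np.floor(scaled + 0.5).astype(np.uint8)  # round half up
        records.append((lo, (hi - lo) / 255.0))
    return Volume(meta=meta, codes=codes, norm_records=records)


def dequantize(vol: Volume, channel: int) -> np.ndarray:
    """Map one channel's codes back to input units (inverse of quantize
    up to half-code error)."""
    if not 0 <= channel < vol.meta.num_channels:
        raise InvalidInputError(
            f"channel {channel} out of range for {vol.meta.num_channels}-channel volume"
        )
    offset, scale = vol.norm_records[channel]
    return offset + scale * vol.codes[channel].astype(np.float64)


# ---------------------------------------------------------------------------
# I/O: raw+JSON is the bit-exact reference dialect; TIFF is best-effort
# z-major channel-interleaved pages (page index = z * num_channels + c).
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def save_volume(vol: Volume, path: str | Path) -> Path:
    """Write the raw+JSON dialect: little-endian uint8 codes plus a JSON
    sidecar ``<path>.json``.  Byte-identical across runs."""
    path = Path(path)
    doc = vol.meta.to_dict()
    doc["dtype"] = "uint8"
    doc["norm_records"] = [[off, scale] for off, scale in vol.norm_records]
    path.write_bytes(np.ascontiguousarray(vol.codes).tobytes())
    _sidecar_path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")
    return path


def save_tiff(vol: Volume, path: str | Path) -> Path:
    import tifffile

    path = Path(path)
    c, z, y, x = vol.codes.shape
    pages = vol.codes.transpose(1, 0, 2, 3).reshape(z * c, y, x)
    tifffile.imwrite(path, pages, metadata=None)
    return path


def load_volume(path: str | Path, meta_path: str | Path | None = None) -> Volume:
    """Load a multi-page TIFF or raw+JSON volume.

    Float and 16-bit payloads are quantized via :func:`quantize_volume`;
    8-bit payloads are taken as codes with identity normalization.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _load_tiff(path, meta_path)
    return _load_raw(path, meta_path)


def _load_raw(path: Path, meta_path: str | Path | None) -> Volume:
    side = Path(meta_path) if meta_path else _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"metadata sidecar not found: field 'meta_path' ({side})")
    doc = json.loads(side.read_text())
    meta = VolumeMetadata.from_dict(doc)
    dtype = np.dtype(doc.get("dtype", "uint8")).newbyteorder("<")
    data = np.frombuffer(path.read_bytes(), dtype=dtype)
    expected = int(np.prod(meta.shape_czyx))
    if data.size != expected:
        raise FormatError(
            f"raw payload has {data.size} samples but field 'dims'/'num_channels' imply {expected}"
        )
    arr = data.reshape(meta.shape_czyx)
    if dtype == np.uint8:
        records = [tuple(r) for r in doc.get("norm_records", [])] or None
        return Volume(meta=meta, codes=arr.copy(), norm_records=list(records) if records else [])
    return quantize_volume(arr.astype(np.float64), meta)


def _load_tiff(path: Path, meta_path: str | Path | None) -> Volume:
    import tifffile

    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError(f"TIFF field 'pages': expected 2-D grayscale pages, got shape {pages.shape}")
    n_pages, y, x = pages.shape
    if meta_path is not None:
        doc = json.loads(Path(meta_path).read_text())
        meta = VolumeMetadata.from_dict(doc)
    else:
        meta = VolumeMetadata(dims=(x, y, n_pages), num_channels=1)
    if n_pages % meta.num_channels:
        raise FormatError(
            f"TIFF page count {n_pages} not divisible by field 'num_channels'={meta.num_channels}"
        )
    z = n_pages // meta.num_channels
    if meta.dims != (x, y, z):
        raise FormatError(
            f"TIFF geometry ({x},{y},{z}) contradicts field 'dims'={meta.dims}"
        )
    arr = pages.reshape(z, meta.num_channels, y, x).transpose(1, 0, 2, 3)
    if arr.dtype == np.uint8:
        return Volume(meta=meta, codes=arr.copy())
    return quantize_volume(arr.astype(np.float64), meta)


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

_KINDS = ("blobs", "single_voxel", "gradient")


def make_synthetic_volume(
    kind: str,
    dims: tuple[int, int, int] = (32, 32, 32),
    num_channels: int = 1,
    seed: int = 0,
    physical_voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    num_blobs: int = 5,
    probe_index: tuple[int, int, int] | None = None,
) -> Volume:
    """Deterministic synthetic volumes for tests and demos.

    ``blobs``: per channel, a sum of ``num_blobs`` isotropic Gaussian spots
    at seeded random centres (a nuclei-like stand-in).  ``single_voxel``:
    one voxel (default centre, or ``probe_index`` as (x, y, z)) set to code
    255 on every channel.  ``gradient``: codes increase linearly along x.
    """
    if kind not in _KINDS:
        raise InvalidParameterError(f"unknown synthetic kind {kind!r}; expected one of {_KINDS}")
    meta = VolumeMetadata(
        dims=dims, num_channels=num_channels, physical_voxel_size=physical_voxel_size
    )
    x, y, z = meta.dims
    if kind == "single_voxel":
        codes = np.zeros(meta.shape_czyx, dtype=np.uint8)
        ix, iy, iz = probe_index if probe_index is not None else (x // 2, y // 2, z // 2)
        codes[:, iz, iy, ix] = 255
        return Volume(meta=meta, codes=codes)
    if kind == "gradient":
        ramp = (
            np.zeros(x) if x == 1 else np.floor(255.0 * np.arange(x) / (x - 1) + 0.5)
        ).astype(np.uint8)
        codes = np.broadcast_to(ramp, (num_channels, z, y, x)).copy()
        return Volume(meta=meta, codes=codes)
    # blobs
    if min(meta.dims) < 4:
        raise InvalidParameterError("blobs fixture requires dims >= 4 on every axis")
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.meshgrid(np.arange(z), np.arange(y), np.arange(x), indexing="ij")
    raw = np.zeros(meta.shape_czyx, dtype=np.float64)
    sigma = max(min(meta.dims) / 12.0, 1.0)
    for c in range(num_channels):
        for _ in range(num_blobs):
            cx = rng.uniform(0.15 * x, 0.85 * x)
            cy = rng.uniform(0.15 * y, 0.85 * y)
            cz = rng.uniform(0.15 * z, 0.85 * z)
            amp = rng.uniform(0.5, 1.0)
            r2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
            raw[c] += amp * np.exp(-r2 / (2.0 * sigma**2))
    return quantize_volume(raw, meta)
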