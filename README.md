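# voxcast

Headless, scriptable multichannel 3-D volume visualization for fluorescence
microscopy stacks. voxcast renders anisotropic image volumes by perspective
raycasting with front-to-back alpha compositing, per-channel dark/mid/bright
quadratic transfer functions, a view-aligned sampling plane for clipping,
oblique slicing and quantitative voxel picking, an HTTP control API for any
scripting environment, and reproducible keyframed movie generation. No GPU,
no window system — every rendering lands in a file or an HTTP response.

## Library quickstart

```python
import numpy as np
import voxcast as vc

vol = vc.make_synthetic_volume("blobs", dims=(64, 64, 64), num_channels=2, seed=0)

session = vc.Session()
session.set_volume(vol)
frame = session.render(512, 512)          # FrameImage (rgb + alpha planes)
png = session.capture(512, 512)           # deterministic PNG bytes

# quantitative picking: which voxel is under a pixel at the sampling plane?
idx = vc.pick_voxel(session.camera, session.view, vol.meta, (256, 256))

# the packaged sample movie (zoom, 180° rotation, clip sweep, rotation
# back, slice fly-out) as a PNG sequence
vc.sample_movie(session, out_dir="movie_out")
```

Volumes are quantized to 8 bits per channel with per-channel linear
normalization (`quantize_volume` / `dequantize`); `load_volume`/`save_volume`
speak a bit-exact raw+JSON dialect and multi-page TIFF.

## HTTP API

```bash
voxcast serve --port 8307
```

Endpoints: `POST /loadImage` (JSON metadata in the `X-Volume-Meta` header,
raw channel-major bytes in the body), `GET/PUT /renderParams`,
`GET/PUT /viewParams`, `GET /captureImage?width=&height=`,
`PUT /uiParams`. A client that only implements `loadImage` + `captureImage`
gets a valid rendering with all defaults. From Python:

```python
client = vc.Client(port=8307)       # auto-starts a local server if absent
client.show(np.random.rand(2, 32, 64, 64))   # float data quantized server-side
params = client.get_render_params()
client.set_view_params({"clip_mode": "plane", "plane_depth": 0.0})
png = client.capture(800, 600)
```

## CLI

```bash
voxcast render --volume vol.raw --out frame.png --width 512 --height 512
voxcast movie  --volume vol.raw --recipe sample --out movie_dir
voxcast demo   --out demo_dir --seed 0
voxcast serve  --port 8307 --config config.json
```

`--recipe sample` runs the packaged sample movie; otherwise pass a JSON
recipe (`{"stages": [{"kind": "zoom", "duration_s": 1, "fps": 10,
"params": {"end": 1.8}}, ...]}`). All commands are deterministic given
their inputs; `--seed` is the only entropy source.

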