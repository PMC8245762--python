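"""Dilated 3D residual regression network, in pure NumPy.

The architecture follows the high-resolution compact 3D design used for
volumetric parcellation: an input 3x3x3 convolution, three stages of
pre-activation residual blocks (two 3x3x3 convolutions each) with dilation
factors 1, 2 and 4 widening the receptive field without pooling, and a
linear 1x1x1 regression head. With the default three blocks per stage this
totals 20 convolutional layers. All convolutions are zero-padded so spatial
shape is preserved end to end, which is what lets the model regress a
heatmap voxel-for-voxel against its input window.

Forward and backward passes are written directly against NumPy (tap-wise
accumulation, float32); there is no framework dependency. The second
convolution of every residual branch is zero-initialized so each block
starts as the identity, which stabilizes training without normalization
layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .volumes_io import Volume

__all__ = [
    "NetConfig",
    "ModelHandle",
    "build_network",
    "forward",
    "backward",
    "infer_heatmap",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetConfig:
    """Topology of the dilated residual regression network.

    base_channels 16 is the full-scale preset; the desk preset halves the
    channels (8) but keeps the structure, so topology-dependent properties
    (layer count, receptive field) are unchanged.
    """

    n_blocks_per_stage: int = 3
    dilations: tuple[int, ...] = (1, 2, 4)
    base_channels: int = 16
    kernel: int = 3
    norm_kind: str = "none"
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd so padding can preserve shape")
        if self.norm_kind != "none":
            raise ValueError(f"unsupported norm_kind {self.norm_kind!r}")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")
        if self.n_blocks_per_stage < 1 or self.base_channels < 1:
            raise ValueError("n_blocks_per_stage and base_channels must be >= 1")
        if any(d < 1 for d in self.dilations):
            raise ValueError("dilations must be >= 1")

    @classmethod
    def desk(cls) -> "NetConfig":
        return cls(base_channels=8)

    @property
    def total_conv_layers(self) -> int:
        """Input conv + 2 per residual block + regression head."""
        return 2 + 2 * self.n_blocks_per_stage * len(self.dilations)

    def receptive_field(self) -> int:
        """Theoretical receptive field extent (voxels, per axis) by the
        layer-wise recurrence rf += (k - 1) * dilation."""
        rf = 1
        rf += (self.kernel - 1) * 1  # input conv
        for d in self.dilations:
            rf += 2 * self.n_blocks_per_stage * (self.kernel - 1) * d
        return rf


@dataclass
class ModelHandle:
    """Parameter container + config; the unit that training and inference share."""

    params: dict
    config: NetConfig
    training_seed: int
    input_norm: str = "volume_zscore"

    def n_parameters(self) -> int:
        return sum(int(a.size) for a in _iter_arrays(self.params))


def _iter_arrays(params: dict):
    yield params["conv_in"]["w"]
    yield params["conv_in"]["b"]
    for blk in params["blocks"]:
        for key in ("w1", "b1", "w2", "b2"):
            yield blk[key]
    yield params["conv_out"]["w"]
    yield params["conv_out"]["b"]


def build_network(c: NetConfig, seed: int) -> ModelHandle:
    """Seeded He-normal initialization; residual second convs start at zero."""
    rng = np.random.default_rng(seed)
    k, ch = c.kernel, c.base_channels

    def he(cout, cin, kk):
        fan_in = cin * kk**3
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, kk, kk, kk)).astype(
            np.float32
        )

    params: dict = {
        "conv_in": {"w": he(ch, 1, k), "b": np.zeros(ch, dtype=np.float32)},
        "blocks": [],
        "conv_out": {
            "w": rng.normal(0.0, 0.01, size=(1, ch, 1, 1, 1)).astype(np.float32),
            "b": np.zeros(1, dtype=np.float32),
        },
    }
    for d in c.dilations:
        for _ in range(c.n_blocks_per_stage):
            params["blocks"].append(
                {
                    "dilation": int(d),
                    "w1": he(ch, ch, k),
                    "b1": np.zeros(ch, dtype=np.float32),
                    "w2": np.zeros((ch, ch, k, k, k), dtype=np.float32),
                    "b2": np.zeros(ch, dtype=np.float32),
                }
            )
    return ModelHandle(params=params, config=c, training_seed=int(seed))


# ---------------------------------------------------------------------------
# convolution primitives (stride 1, zero padding preserving shape)

def _valid_taps(extent: int, k: int, dilation: int) -> list[int]:
    """Kernel taps whose shifted slice overlaps real (non-padding) data.

    For quasi-2D inputs (extent 1 along an axis) only the center tap
    survives, which cuts the 27-tap loop to 9.
    """
    pad = dilation * (k // 2)
    return [t for t in range(k) if t * dilation < pad + extent and t * dilation + extent > pad]


def _conv3d(x: np.ndarray, w: np.ndarray, b: np.ndarray, dilation: int) -> np.ndarray:
    """x: (N, Cin, X, Y, Z); w: (Cout, Cin, k, k, k) -> (N, Cout, X, Y, Z)."""
    n, cin, X, Y, Z = x.shape
    cout, _, k, _, _ = w.shape
    if k == 1:
        out = np.tensordot(w[:, :, 0, 0, 0], x, axes=([1], [1]))  # (Cout, N, X, Y, Z)
        out = np.moveaxis(out, 0, 1).copy()
    else:
        pad = dilation * (k // 2)
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
        acc = np.zeros((n, X, Y, Z, cout), dtype=np.float32)
        for kx in _valid_taps(X, k, dilation):
            ox = kx * dilation
            for ky in _valid_taps(Y, k, dilation):
                oy = ky * dilation
                for kz in _valid_taps(Z, k, dilation):
                    oz = kz * dilation
                    sl = xp[:, :, ox : ox + X, oy : oy + Y, oz : oz + Z]
                    # (N, X, Y, Z, Cout) += (N,Cin,X,Y,Z) x (Cout,Cin)
                    acc += np.tensordot(sl, w[:, :, kx, ky, kz], axes=([1], [1]))
        out = np.moveaxis(acc, -1, 1)
    return out + b.reshape(1, -1, 1, 1, 1)


def _conv3d_backward(
    x: np.ndarray, w: np.ndarray, dout: np.ndarray, dilation: int, need_dx: bool = True
):
    """Gradients of _conv3d w.r.t. weights, bias and (optionally) input."""
    n, cin, X, Y, Z = x.shape
    cout, _, k, _, _ = w.shape
    db = dout.sum(axis=(0, 2, 3, 4)).astype(np.float32)
    if k == 1:
        dw = np.tensordot(dout, x, axes=([0, 2, 3, 4], [0, 2, 3, 4]))[
            :, :, None, None, None
        ].astype(np.float32)
        dx = None
        if need_dx:
            dx = np.moveaxis(
                np.tensordot(w[:, :, 0, 0, 0], dout, axes=([0], [1])), 0, 1
            ).astype(np.float32, copy=False)
        return dw, db, dx

    pad = dilation * (k // 2)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    dw = np.zeros_like(w)
    dxp = (
        np.zeros((n, cin, X + 2 * pad, Y + 2 * pad, Z + 2 * pad), dtype=np.float32)
        if need_dx
        else None
    )
    for kx in _valid_taps(X, k, dilation):
        ox = kx * dilation
        for ky in _valid_taps(Y, k, dilation):
            oy = ky * dilation
            for kz in _valid_taps(Z, k, dilation):
                oz = kz * dilation
                sl = xp[:, :, ox : ox + X, oy : oy + Y, oz : oz + Z]
                dw[:, :, kx, ky, kz] = np.tensordot(
                    dout, sl, axes=([0, 2, 3, 4], [0, 2, 3, 4])
                )
                if need_dx:
                    # (N, X, Y, Z, Cin) from (N,Cout,...) x (Cout,Cin)
                    contrib = np.tensordot(dout, w[:, :, kx, ky, kz], axes=([1], [0]))
                    dxp[:, :, ox : ox + X, oy : oy + Y, oz : oz + Z] += np.moveaxis(
                        contrib, -1, 1
                    )
    dx = None
    if need_dx:
        dx = dxp[:, :, pad : pad + X, pad : pad + Y, pad : pad + Z]
        if pad:
            dx = np.ascontiguousarray(dx)
    return dw, db, dx


def forward(m: ModelHandle, x: np.ndarray, want_cache: bool = False):
    """Run the network on a batch (N, 1, X, Y, Z) -> (N, 1, X, Y, Z).

    With ``want_cache`` the intermediate activations needed by
    :func:`backward` are returned as well.
    """
    x = np.ascontiguousarray(x, dtype=np.float32)
    if x.ndim != 5 or x.shape[1] != 1:
        raise ValueError(f"expected batch shaped (N, 1, X, Y, Z), got {x.shape}")
    cache: dict = {"x_in": x, "blocks": []}
    h = _conv3d(x, m.params["conv_in"]["w"], m.params["conv_in"]["b"], 1)
    for blk in m.params["blocks"]:
        d = blk["dilation"]
        r1 = np.maximum(h, 0.0)
        c1 = _conv3d(r1, blk["w1"], blk["b1"], d)
        r2 = np.maximum(c1, 0.0)
        c2 = _conv3d(r2, blk["w2"], blk["b2"], d)
        if want_cache:
            cache["blocks"].append({"h": h, "r1": r1, "c1": c1, "r2": r2})
        h = h + c2
    if want_cache:
        cache["h_out"] = h
    out = _conv3d(h, m.params["conv_out"]["w"], m.params["conv_out"]["b"], 1)
    return (out, cache) if want_cache else out


def backward(m: ModelHandle, cache: dict, dout: np.ndarray) -> dict:
    """Backpropagate dLoss/dOutput through the cached forward pass.

    Returns a gradient tree shaped like ``m.params``.
    """
    grads: dict = {"blocks": []}
    dw, db, dh = _conv3d_backward(cache["h_out"], m.params["conv_out"]["w"], dout, 1)
    grads["conv_out"] = {"w": dw, "b": db}

    for blk, bc in zip(reversed(m.params["blocks"]), reversed(cache["blocks"])):
        d = blk["dilation"]
        # h_next = h + c2 : gradient flows to both branches
        dc2 = dh
        dw2, db2, dr2 = _conv3d_backward(bc["r2"], blk["w2"], dc2, d)
        dc1 = dr2 * (bc["c1"] > 0)
        dw1, db1, dr1 = _conv3d_backward(bc["r1"], blk["w1"], dc1, d)
        dh = dh + dr1 * (bc["h"] > 0)
        grads["blocks"].append({"w1": dw1, "b1": db1, "w2": dw2, "b2": db2})
    grads["blocks"].reverse()

    dw, db, _ = _conv3d_backward(
        cache["x_in"], m.params["conv_in"]["w"], dh, 1, need_dx=False
    )
    grads["conv_in"] = {"w": dw, "b": db}
    return grads


def standardize(data: np.ndarray) -> np.ndarray:
    """Volume-level z-scoring applied before the network sees any intensity."""
    data = np.asarray(data, dtype=np.float32)
    sd = float(data.std())
    return (data - float(data.mean())) / (sd if sd > 0 else 1.0)


def _tile_starts(extent: int, win: int, step: int) -> list[int]:
    starts = list(range(0, extent - win + 1, max(1, step)))
    if starts[-1] != extent - win:
        starts.append(extent - win)
    return starts


def infer_heatmap(
    m: ModelHandle,
    v: Volume,
    window: tuple[int, int, int] | None = None,
    overlap_fraction: float = 0.5,
) -> Volume:
    """Full-volume prediction by sliding-window tiling.

    The volume is standardized (per ``m.input_norm``), tiled with
    overlapping windows, each window is run through the network, and
    overlapping predictions are aggregated by voxelwise averaging. Output
    shape and affine equal the input's.
    """
    shape = v.shape
    if window is None:
        window = (min(shape[0], 64), min(shape[1], 64), 1)
    window = tuple(int(w) for w in window)
    if any(w > s for w, s in zip(window, shape)):
        raise ValueError(f"window {window} larger than volume {shape}")
    if m.input_norm == "volume_zscore":
        data = standardize(v.data)
    elif m.input_norm == "none":
        data = np.asarray(v.data, dtype=np.float32)
    else:
        raise ValueError(f"unknown input_norm {m.input_norm!r}")

    steps = [max(1, int(round(w * (1.0 - overlap_fraction)))) for w in window]
    starts = [_tile_starts(s, w, st) for s, w, st in zip(shape, window, steps)]
    acc = np.zeros(shape, dtype=np.float64)
    wt = np.zeros(shape, dtype=np.float64)
    batch: list[tuple[tuple[int, int, int], np.ndarray]] = []

    def flush() -> None:
        if not batch:
            return
        x = np.stack([b[1] for b in batch])[:, None]
        pred = forward(m, x)
        for (ox, oy, oz), p in zip((b[0] for b in batch), pred[:, 0]):
            sl = (
                slice(ox, ox + window[0]),
                slice(oy, oy + window[1]),
                slice(oz, oz + window[2]),
            )
            acc[sl] += p
            wt[sl] += 1.0
        batch.clear()

    for ox in starts[0]:
        for oy in starts[1]:
            for oz in starts[2]:
                batch.append(
                    (
                        (ox, oy, oz),
                        data[ox : ox + window[0], oy : oy + window[1], oz : oz + window[2]],
                    )
                )
                if len(batch) >= 16:
                    flush()
    flush()
    return Volume(data=(acc / wt).astype(np.float32), affine=v.affine)


# ---------------------------------------------------------------------------
# checkpoints: single parameter archive + JSON sidecar with config and seed

def save_checkpoint(m: ModelHandle, path) -> None:
    path = Path(path)
    flat = {"conv_in.w": m.params["conv_in"]["w"], "conv_in.b": m.params["conv_in"]["b"],
            "conv_out.w": m.params["conv_out"]["w"], "conv_out.b": m.params["conv_out"]["b"]}
    for i, blk in enumerate(m.params["blocks"]):
        for key in ("w1", "b1", "w2", "b2"):
            flat[f"block{i}.{key}"] = blk[key]
    np.savez(path.with_suffix(".npz"), **flat)
    sidecar = {
        "config": {
            "n_blocks_per_stage": m.config.n_blocks_per_stage,
            "dilations": list(m.config.dilations),
            "base_channels": m.config.base_channels,
            "kernel": m.config.kernel,
            "norm_kind": m.config.norm_kind,
            "activation": m.config.activation,
        },
        "training_seed": m.training_seed,
        "input_norm": m.input_norm,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> ModelHandle:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfgd = sidecar["config"]
    cfgd["dilations"] = tuple(cfgd["dilations"])
    cfg = NetConfig(**cfgd)
    m = build_network(cfg, sidecar["training_seed"])
    m.input_norm = sidecar.get("input_norm", "volume_zscore")
    with np.load(path.with_suffix(".npz")) as arc:
        m.params["conv_in"]["w"] = arc["conv_in.w"]
        m.params["conv_in"]["b"] = arc["conv_in.b"]
        m.params["conv_out"]["w"] = arc["conv_out.w"]
        m.params["conv_out"]["b"] = arc["conv_out.b"]
        for i, blk in enumerate(m.params["blocks"]):
            for key in ("w1", "b1", "w2", "b2"):
                blk[key] = arc[f"block{i}.{key}"]
    return m
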