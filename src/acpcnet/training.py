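"""Training: dataset splitting, prior-weighted window sampling, augmentation,
losses/regularizers, Adam/RMSprop, and the seeded training loop.

Training is patch-based: quasi-2D windows (default 72x72x1) are drawn with
their centers distributed according to the Gaussian-sphere sampling prior
built from the template AC/PC locations, so most windows contain landmark
signal. Windows are augmented by orthogonal-view assignment, in-plane flips
and +/-10% isotropic rescaling. The loss is RMSE or Huber on the heatmap
regression, plus an L1 or L2 penalty on the convolution weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform

from .heatmap_targets import HeatmapSpec, make_sampling_prior, make_target_heatmap
from .network import ModelHandle, NetConfig, backward, build_network, forward, standardize
from .synthetic_phantom import default_template
from .volumes_io import FiducialSet, Volume

__all__ = [
    "TrainConfig",
    "LearningCurve",
    "TrainingDivergedError",
    "split_dataset",
    "sample_windows",
    "augment_window",
    "compute_loss",
    "train_model",
]


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    """One cell of the loss/regularizer/optimizer grid plus sampling knobs.

    The eight studied variants are the product
    {rmse, huber} x {L1, L2} x {adam, rmsprop}; variant 1 (rmse + L1 +
    rmsprop) is the reference configuration. learning_rate and weight_decay
    default to 0.005 and 1e-5; the weight-decay value doubles as the L1/L2
    regularizer coefficient.
    """

    loss: str = "rmse"
    huber_delta: float = 1.0
    regularizer: str = "L1"
    reg_weight: float | None = None
    optimizer: str = "rmsprop"
    learning_rate: float = 0.005
    weight_decay: float = 1e-5
    iterations: int = 2500
    batch_windows: int = 64
    window: tuple[int, int, int] = (72, 72, 1)
    scale_aug_pct: float = 10.0
    split_ratios: tuple[float, float, float] = (80, 10, 10)
    val_every: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.loss = self.loss.lower()
        self.optimizer = self.optimizer.lower()
        self.regularizer = self.regularizer.upper()
        if self.loss not in ("rmse", "huber"):
            raise ValueError(f"loss must be rmse or huber, got {self.loss!r}")
        if self.regularizer not in ("L1", "L2"):
            raise ValueError(f"regularizer must be L1 or L2, got {self.regularizer!r}")
        if self.optimizer not in ("adam", "rmsprop"):
            raise ValueError(f"optimizer must be adam or rmsprop, got {self.optimizer!r}")
        if abs(sum(self.split_ratios) - 100) > 1e-9:
            raise ValueError(f"split ratios must sum to 100, got {self.split_ratios}")
        if self.learning_rate <= 0 or self.weight_decay < 0 or self.iterations < 1:
            raise ValueError("rates must be positive and iterations >= 1")

    @property
    def effective_reg_weight(self) -> float:
        return self.weight_decay if self.reg_weight is None else self.reg_weight

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        """Scaled-down preset for CPU-sized experiments on 64-voxel phantoms."""
        kw = dict(iterations=500, batch_windows=16, window=(48, 48, 1))
        kw.update(overrides)
        return cls(**kw)


@dataclass
class LearningCurve:
    train_loss: list[float] = field(default_factory=list)
    val_iterations: list[int] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


def split_dataset(n: int, ratios=(80, 10, 10), seed: int = 0):
    """Seeded disjoint exhaustive train/val/test split.

    Validation and test sizes are the nearest integer of n*ratio; the
    remainder goes to training (908 at 80:10:10 gives 726/91/91).
    """
    if n < 3:
        raise ValueError("need n >= 3 to populate three subsets")
    if abs(sum(ratios) - 100) > 1e-9:
        raise ValueError(f"ratios must sum to 100, got {ratios}")
    n_val = int(round(n * ratios[1] / 100.0))
    n_test = int(round(n * ratios[2] / 100.0))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("ratios leave a negative subset size")
    perm = np.random.default_rng(seed).permutation(n)
    return (
        np.sort(perm[:n_train]),
        np.sort(perm[n_train : n_train + n_val]),
        np.sort(perm[n_train + n_val :]),
    )


def _draw_centers(prior_flat: np.ndarray, shape, n: int, rng) -> np.ndarray:
    cdf = np.cumsum(prior_flat)
    cdf /= cdf[-1]
    flat_idx = np.searchsorted(cdf, rng.random(n), side="right")
    return np.stack(np.unravel_index(flat_idx, shape), axis=-1)


def sample_windows(
    v: Volume,
    target: Volume,
    prior: Volume,
    window: tuple[int, int, int],
    n: int,
    seed: int,
    orient: bool = True,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw co-located (input, target) windows with prior-weighted centers.

    Center voxels are sampled from the prior density, then clipped so every
    window lies fully inside the volume. For quasi-2D windows
    (w, w, 1) with ``orient`` enabled, the singleton axis is assigned
    uniformly among the three axes — the mechanism that yields the three
    orthogonal 2D views — and the slab is returned in canonical
    (w, w, 1) axis order.
    """
    window = tuple(int(w) for w in window)
    shape = v.shape
    if any(w > s for w, s in zip(window, shape)):
        raise ValueError(f"window {window} does not fit in volume {shape}")
    p = np.asarray(prior.data, dtype=np.float64).ravel()
    total = p.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("degenerate sampling prior")
    rng = np.random.default_rng(seed)
    centers = _draw_centers(p, shape, n, rng)

    quasi2d = orient and window[2] == 1 and window[0] == window[1]
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for c in centers:
        if quasi2d:
            ax = int(rng.integers(3))
            ext = [window[0]] * 3
            ext[ax] = 1
            if any(e > s for e, s in zip(ext, shape)):
                ax, ext = 2, list(window)  # volume too thin for this view
        else:
            ax, ext = 2, list(window)
        start = [int(np.clip(c[i] - ext[i] // 2, 0, shape[i] - ext[i])) for i in range(3)]
        sl = tuple(slice(s, s + e) for s, e in zip(start, ext))
        wi = np.asarray(v.data[sl], dtype=np.float32)
        wt = np.asarray(target.data[sl], dtype=np.float32)
        if quasi2d and ax != 2:
            wi = np.moveaxis(wi, ax, 2)
            wt = np.moveaxis(wt, ax, 2)
        out.append((np.ascontiguousarray(wi), np.ascontiguousarray(wt)))
    return out


def augment_window(
    pair: tuple[np.ndarray, np.ndarray], seed: int, scale_aug_pct: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Random flips (+ in-plane transpose) and +/-scale_aug_pct% rescaling.

    Input and target receive identical geometry. Rescaling uses trilinear
    interpolation about the window center on the non-singleton axes; the
    target is renormalized afterwards so its maximum stays <= 1.
    """
    rng = np.random.default_rng(seed)
    wi, wt = pair
    if wi.shape[0] == wi.shape[1] and rng.random() < 0.5:
        wi, wt = np.swapaxes(wi, 0, 1), np.swapaxes(wt, 0, 1)
    for ax in range(3):
        if wi.shape[ax] > 1 and rng.random() < 0.5:
            wi, wt = np.flip(wi, ax), np.flip(wt, ax)
    f = float(rng.uniform(1.0 - scale_aug_pct / 100.0, 1.0 + scale_aug_pct / 100.0))
    if abs(f - 1.0) > 1e-12:
        diag = np.array([1.0 / f if s > 1 else 1.0 for s in wi.shape])
        center = (np.asarray(wi.shape, dtype=float) - 1.0) / 2.0
        offset = center - diag * center
        wi = affine_transform(
            np.ascontiguousarray(wi), diag, offset=offset, order=1, mode="nearest"
        ).astype(np.float32)
        wt = affine_transform(
            np.ascontiguousarray(wt), diag, offset=offset, order=1, mode="constant"
        ).astype(np.float32)
        peak = float(wt.max())
        if peak > 1.0:
            wt = wt / peak
    return np.ascontiguousarray(wi, dtype=np.float32), np.ascontiguousarray(wt, dtype=np.float32)


# ---------------------------------------------------------------------------
# losses and regularizers

def _weight_arrays(params: dict):
    yield params["conv_in"]["w"]
    for blk in params["blocks"]:
        yield blk["w1"]
        yield blk["w2"]
    yield params["conv_out"]["w"]


def _data_loss_and_grad(pred: np.ndarray, target: np.ndarray, cfg: TrainConfig):
    r = pred.astype(np.float64) - target.astype(np.float64)
    count = r.size
    if cfg.loss == "rmse":
        mse = float(np.mean(r * r))
        rmse = math.sqrt(mse)
        grad = r / (count * max(rmse, 1e-12))
        return rmse, grad.astype(np.float32)
    delta = cfg.huber_delta
    absr = np.abs(r)
    quad = absr <= delta
    loss = float(np.mean(np.where(quad, 0.5 * r * r, delta * (absr - 0.5 * delta))))
    grad = np.clip(r, -delta, delta) / count
    return loss, grad.astype(np.float32)


def _reg_loss(params: dict, cfg: TrainConfig) -> float:
    rw = cfg.effective_reg_weight
    if rw == 0:
        return 0.0
    if cfg.regularizer == "L1":
        return rw * float(sum(np.abs(w).sum() for w in _weight_arrays(params)))
    return rw * float(sum((w.astype(np.float64) ** 2).sum() for w in _weight_arrays(params)))


def _add_reg_grads(params: dict, grads: dict, cfg: TrainConfig) -> None:
    rw = cfg.effective_reg_weight
    if rw == 0:
        return
    pairs = zip(_weight_arrays(params), _weight_arrays(grads))
    for w, g in pairs:
        if cfg.regularizer == "L1":
            g += (rw * np.sign(w)).astype(g.dtype)
        else:
            g += (2.0 * rw * w).astype(g.dtype)


def compute_loss(
    pred: np.ndarray, target: np.ndarray, cfg: TrainConfig, model: ModelHandle | None = None
) -> float:
    """Total loss: RMSE/Huber data term plus the configured weight penalty."""
    data_loss, _ = _data_loss_and_grad(np.asarray(pred), np.asarray(target), cfg)
    reg = _reg_loss(model.params, cfg) if model is not None else 0.0
    return data_loss + reg


# ---------------------------------------------------------------------------
# optimizers

class _Optimizer:
    def __init__(self, cfg: TrainConfig):
        self.lr = cfg.learning_rate
        self.kind = cfg.optimizer
        self.t = 0
        self.state: list[dict] | None = None

    def step(self, arrays: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.state is None:
            self.state = [
                {"m": np.zeros_like(a), "v": np.zeros_like(a)} for a in arrays
            ]
        self.t += 1
        eps = 1e-8
        for a, g, s in zip(arrays, grads, self.state):
            g = g.astype(a.dtype, copy=False)
            if self.kind == "rmsprop":
                s["v"] *= 0.9
                s["v"] += 0.1 * g * g
                a -= self.lr * g / (np.sqrt(s["v"]) + eps)
            else:  # adam
                b1, b2 = 0.9, 0.999
                s["m"] = b1 * s["m"] + (1 - b1) * g
                s["v"] = b2 * s["v"] + (1 - b2) * g * g
                mhat = s["m"] / (1 - b1**self.t)
                vhat = s["v"] / (1 - b2**self.t)
                a -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _param_grad_lists(params: dict, grads: dict):
    arrays = [params["conv_in"]["w"], params["conv_in"]["b"]]
    glist = [grads["conv_in"]["w"], grads["conv_in"]["b"]]
    for pb, gb in zip(params["blocks"], grads["blocks"]):
        for key in ("w1", "b1", "w2", "b2"):
            arrays.append(pb[key])
            glist.append(gb[key])
    arrays += [params["conv_out"]["w"], params["conv_out"]["b"]]
    glist += [grads["conv_out"]["w"], grads["conv_out"]["b"]]
    return arrays, glist


# ---------------------------------------------------------------------------
# training loop

def _resolve_cohort(cohort) -> list[tuple[Volume, FiducialSet]]:
    from .cli import read_manifest  # manifest CSV support; avoids a cycle at import

    if isinstance(cohort, (str,)) or hasattr(cohort, "__fspath__"):
        return read_manifest(cohort)
    return list(cohort)


def train_model(
    cohort,
    cfg: TrainConfig,
    net: NetConfig | None = None,
    template: FiducialSet | None = None,
    heatmap_spec: HeatmapSpec | None = None,
    model: ModelHandle | None = None,
) -> tuple[ModelHandle, LearningCurve]:
    """Train the heatmap-regression network on a cohort.

    ``cohort`` is a sequence of (Volume, FiducialSet) pairs or a manifest
    CSV path. The cohort is split train/val/test by ``cfg.split_ratios``
    (the test share is left untouched); windows are drawn from the template
    sampling prior, augmented, and optimized for ``cfg.iterations`` steps.
    Validation loss is computed every ``cfg.val_every`` iterations on a
    fixed window set. Fully seeded; raises :class:`TrainingDivergedError`
    if the loss goes non-finite.
    """
    pairs = _resolve_cohort(cohort)
    if len(pairs) < 2:
        raise ValueError("need at least 2 volumes to train")
    net = net or NetConfig()
    template = template or default_template()
    spec = heatmap_spec or HeatmapSpec()

    shape = pairs[0][0].shape
    affine = pairs[0][0].affine
    for v, _ in pairs:
        if v.shape != shape:
            raise ValueError("all cohort volumes must share one shape")

    train_ids, val_ids, _ = split_dataset(len(pairs), cfg.split_ratios, cfg.seed)
    if len(train_ids) < 2:
        train_ids = np.arange(len(pairs))
    vols = [
        Volume(data=standardize(pairs[i][0].data), affine=pairs[i][0].affine)
        for i in range(len(pairs))
    ]
    targets = [
        make_target_heatmap(shape, pairs[i][1], pairs[i][0].affine, spec)
        for i in range(len(pairs))
    ]
    prior = make_sampling_prior(template, shape, affine, spec)

    rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = build_network(net, seed=int(rng.integers(2**31)))
    model.training_seed = cfg.seed

    # Fixed validation window set (no augmentation).
    val_source = val_ids if len(val_ids) > 0 else train_ids
    val_pairs: list[tuple[np.ndarray, np.ndarray]] = []
    per = max(1, (2 * cfg.batch_windows) // max(1, len(val_source)))
    for j, i in enumerate(val_source):
        val_pairs += sample_windows(
            vols[i], targets[i], prior, cfg.window, per, seed=int(rng.integers(2**31))
        )
    val_x = np.stack([p[0] for p in val_pairs])[:, None]
    val_t = np.stack([p[1] for p in val_pairs])[:, None]

    opt = _Optimizer(cfg)
    curve = LearningCurve()
    for it in range(1, cfg.iterations + 1):
        vol_choice = rng.integers(0, len(train_ids), size=cfg.batch_windows)
        batch: list[tuple[np.ndarray, np.ndarray]] = []
        for vi in np.unique(vol_choice):
            k = int(np.sum(vol_choice == vi))
            i = int(train_ids[vi])
            wins = sample_windows(
                vols[i], targets[i], prior, cfg.window, k, seed=int(rng.integers(2**31))
            )
            batch += [
                augment_window(w, seed=int(rng.integers(2**31)), scale_aug_pct=cfg.scale_aug_pct)
                for w in wins
            ]
        x = np.stack([b[0] for b in batch])[:, None]
        t = np.stack([b[1] for b in batch])[:, None]

        pred, cache = forward(model, x, want_cache=True)
        data_loss, dpred = _data_loss_and_grad(pred, t, cfg)
        total = data_loss + _reg_loss(model.params, cfg)
        if not np.isfinite(total):
            raise TrainingDivergedError(f"loss became non-finite at iteration {it}")
        grads = backward(model, cache, dpred)
        _add_reg_grads(model.params, grads, cfg)
        arrays, glist = _param_grad_lists(model.params, grads)
        opt.step(arrays, glist)
        curve.train_loss.append(float(total))

        if it % cfg.val_every == 0 or it == cfg.iterations:
            vloss = 0.0
            nchunks = 0
            for s in range(0, len(val_x), 16):
                pv = forward(model, val_x[s : s + 16])
                dl, _ = _data_loss_and_grad(pv, val_t[s : s + 16], cfg)
                vloss += dl
                nchunks += 1
            curve.val_iterations.append(it)
            curve.val_loss.append(vloss / max(1, nchunks))
    return model, curve
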