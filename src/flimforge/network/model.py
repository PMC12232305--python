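"""Encoder-decoder lifetime-regression network and its training loop.

The network maps a (T, H, W) photon-count stack — time encoded into the
channel dimension — to an (H, W) map of average fluorescence lifetimes.
The backbone downsamples with CBL stages and C3 cross-stage blocks and
ends in an SPPF module; the neck upsamples with U-Net-like skip
concatenations; the head is a single 1x1 convolution with ReLU so every
predicted lifetime is nonnegative.

Model-fitting follows the statsmodels convention: build a
:class:`LifetimeRegressionModel` from data, call :meth:`fit`, and work
with the returned :class:`LifetimeRegressionResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ..simulate import FLIMStack, LifetimeMap
from . import layers as L


class TrainingError(RuntimeError):
    pass


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``stage_channels`` lists the nominal channel widths of the stem plus
    each downsampling stage; ``width_multiplier`` scales them (YOLO-style
    compound scaling), ``depth_multiplier`` scales the number of
    bottlenecks inside each C3 block.
    """

    in_time_bins: int = 256
    width_multiplier: float = 1.0
    depth_multiplier: float = 1.0
    stage_channels: tuple = (32, 64, 128)
    use_sppf: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_multiplier <= 0 or self.depth_multiplier <= 0:
            raise ValueError("multipliers must be positive")
        if self.in_time_bins < 1:
            raise ValueError("in_time_bins must be >= 1")

    @property
    def channels(self) -> list[int]:
        return [max(4, int(round(c * self.width_multiplier))) for c in self.stage_channels]

    @property
    def downsample_factor(self) -> int:
        return 2 ** (len(self.stage_channels) - 1)

    @property
    def n_bottlenecks(self) -> int:
        return max(1, int(round(self.depth_multiplier)))


@dataclass
class TrainingConfig:
    """Optimization protocol: AdamW at lr 0.01 with weight decay 1e-8,
    batches of 10, MSE loss, 80/20 train/validation split, early stopping
    after 20 epochs without validation improvement."""

    batch_size: int = 10
    learning_rate: float = 0.01
    weight_decay: float = 1e-8
    max_epochs: int = 150
    patience: int = 20
    val_fraction: float = 0.2
    seed: int = 0
    background_in_loss: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


class FLIMNet:
    """The assembled encoder-decoder graph with explicit backprop."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.channels
        n = config.n_bottlenecks
        self.stem = L.cbl(config.in_time_bins, ch[0], k=3, rng=rng)
        self.downs = []
        self.c3s = []
        for i in range(1, len(ch)):
            self.downs.append(L.cbl(ch[i - 1], ch[i], k=3, stride=2, rng=rng))
            self.c3s.append(L.C3(ch[i], ch[i], n=n, rng=rng))
        self.sppf = L.SPPF(ch[-1], ch[-1], rng=rng) if config.use_sppf else None
        self.ups = [L.Upsample2x() for _ in range(len(ch) - 1)]
        self.neck = []
        for i in range(len(ch) - 1, 0, -1):
            self.neck.append(L.cbl(ch[i] + ch[i - 1], ch[i - 1], k=3, rng=rng))
        self.head = L.Conv2d(ch[0], 1, k=1, bias=True, rng=rng)
        self.out_act = L.ReLU()

    # -- parameter plumbing -------------------------------------------------
    def _modules(self) -> list:
        mods = [self.stem, *self.downs, *self.c3s]
        if self.sppf is not None:
            mods.append(self.sppf)
        mods += [*self.neck, self.head]
        return mods

    def parameters(self) -> list[L.Parameter]:
        return [p for m in self._modules() for p in m.parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def _batchnorms(self) -> list[L.BatchNorm2d]:
        out = []

        def walk(m):
            if isinstance(m, L.BatchNorm2d):
                out.append(m)
            for attr in ("mods", "body", "cv1", "cv2", "cv3", "blocks"):
                sub = getattr(m, attr, None)
                if sub is None:
                    continue
                if isinstance(sub, list):
                    for s in sub:
                        walk(s)
                else:
                    walk(sub)

        for m in self._modules():
            walk(m)
        return out

    # -- forward / backward -------------------------------------------------
    def _check_spatial(self, h: int, w: int) -> None:
        f = self.config.downsample_factor
        if h % f or w % f:
            raise ValueError(
                f"spatial dims ({h}, {w}) not divisible by the network's "
                f"downsampling factor {f}; pad the input (see pad_crop_square)"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(N, T, H, W) -> (N, H, W) nonnegative lifetimes."""
        self._check_spatial(x.shape[2], x.shape[3])
        feats = [self.stem.forward(x, train)]
        for down, c3 in zip(self.downs, self.c3s):
            feats.append(c3.forward(down.forward(feats[-1], train), train))
        g = self.sppf.forward(feats[-1], train) if self.sppf is not None else feats[-1]
        self._skip_channels = []
        for j, neck in enumerate(self.neck):
            skip = feats[len(feats) - 2 - j]
            g = self.ups[j].forward(g, train)
            self._skip_channels.append((g.shape[1], skip.shape[1]))
            g = neck.forward(np.concatenate([g, skip], axis=1), train)
        out = self.out_act.forward(self.head.forward(g, train), train)
        self._depth = len(feats)
        return out[:, 0]

    def backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(self.out_act.backward(grad[:, None]))
        skip_grads = [None] * self._depth
        for j in range(len(self.neck) - 1, -1, -1):
            gc = self.neck[j].backward(g)
            c_up, _ = self._skip_channels[j]
            g_up, g_skip = gc[:, :c_up], gc[:, c_up:]
            idx = self._depth - 2 - j
            skip_grads[idx] = g_skip if skip_grads[idx] is None else skip_grads[idx] + g_skip
            g = self.ups[j].backward(g_up)
        if self.sppf is not None:
            g = self.sppf.backward(g)
        for i in range(len(self.downs) - 1, -1, -1):
            if skip_grads[i + 1] is not None:
                g = g + skip_grads[i + 1]
            g = self.downs[i].backward(self.c3s[i].backward(g))
        if skip_grads[0] is not None:
            g = g + skip_grads[0]
        self.stem.backward(g)

    # -- checkpointing ------------------------------------------------------
    def state_arrays(self) -> dict:
        state = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._batchnorms()):
            state[f"bn_mean_{i}"] = bn.running_mean
            state[f"bn_var_{i}"] = bn.running_var
        return state

    def load_state_arrays(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.array(state[f"param_{i}"])
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = np.array(state[f"bn_mean_{i}"])
            bn.running_var = np.array(state[f"bn_var_{i}"])


def build_network(config: NetworkConfig) -> FLIMNet:
    """Construct the encoder-decoder network for a given configuration."""
    return FLIMNet(config)


def normalize_stack(counts: np.ndarray) -> np.ndarray:
    """Per-pixel max normalization of a (T, H, W) stack; all-zero
    (background) pixels stay all-zero."""
    counts = np.asarray(counts, dtype=float)
    peak = counts.max(axis=0)
    return counts / np.where(peak > 0, peak, 1.0)


def make_training_pairs(stacks, maps, config: TrainingConfig):
    """Normalize and split image pairs into train and validation sets.

    Returns two triples ``(X, Y, M)``: inputs (N, T, H, W), targets
    (N, H, W) and non-background masks (N, H, W).
    """
    if len(stacks) != len(maps):
        raise ValueError("stacks and maps must have equal length")
    if not stacks:
        raise ValueError("empty dataset")
    X = np.stack([normalize_stack(s.counts) for s in stacks])
    Y = np.stack([m.tau for m in maps])
    M = np.stack([~m.background_mask for m in maps])
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(stacks))
    n_val = int(round(len(stacks) * config.val_fraction))
    n_val = min(max(n_val, 1), len(stacks) - 1)
    val_idx, train_idx = order[:n_val], order[n_val:]
    return (X[train_idx], Y[train_idx], M[train_idx]), (X[val_idx], Y[val_idx], M[val_idx])


def _masked_mse(pred: np.ndarray, y: np.ndarray, m: np.ndarray | None) -> float:
    if m is None:
        return float(np.mean((pred - y) ** 2))
    return float(np.sum(((pred - y) ** 2) * m) / np.sum(m))


def train_model(net: FLIMNet, data, tconfig: TrainingConfig):
    """Minimize MSE with AdamW and early stopping.

    ``data`` is the ``(train, val)`` pair from :func:`make_training_pairs`.
    Returns ``(net, history)`` with the best-validation weights restored;
    ``history`` is a list of per-epoch dicts.
    """
    (Xt, Yt, Mt), (Xv, Yv, Mv) = data
    if len(Xt) == 0 or len(Xv) == 0:
        raise ValueError("train and validation sets must be nonempty")
    use_mask = not tconfig.background_in_loss
    opt = L.AdamW(net.parameters(), lr=tconfig.learning_rate,
                  weight_decay=tconfig.weight_decay)
    rng = np.random.default_rng(tconfig.seed)
    best_val = np.inf
    best_state = net.state_arrays()
    best_state = {k: v.copy() for k, v in best_state.items()}
    since_best = 0
    history = []
    for epoch in range(tconfig.max_epochs):
        order = rng.permutation(len(Xt))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), tconfig.batch_size):
            idx = order[start : start + tconfig.batch_size]
            xb, yb = Xt[idx], Yt[idx]
            mb = Mt[idx] if use_mask else None
            pred = net.forward(xb, train=True)
            loss = _masked_mse(pred, yb, mb)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            if mb is None:
                grad = 2.0 * (pred - yb) / pred.size
            else:
                grad = 2.0 * (pred - yb) * mb / max(mb.sum(), 1)
            opt.zero_grad()
            net.backward(grad)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        val_pred = predict_batch(net, Xv)
        val_mse = _masked_mse(val_pred, Yv, Mv if use_mask else None)
        history.append({
            "epoch": epoch,
            "train_loss": epoch_loss / max(n_batches, 1),
            "val_mse": val_mse,
        })
        if val_mse < best_val:
            best_val = val_mse
            best_state = {k: v.copy() for k, v in net.state_arrays().items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= tconfig.patience:
                break
    net.load_state_arrays(best_state)
    return net, history


def predict_batch(net: FLIMNet, X: np.ndarray, batch: int = 8) -> np.ndarray:
    out = [net.forward(X[i : i + batch], train=False) for i in range(0, len(X), batch)]
    return np.concatenate(out)


def predict_map(net: FLIMNet, stack: FLIMStack) -> LifetimeMap:
    """Run inference on one FLIM stack, masking zero-count pixels."""
    if stack.axis.n_bins != net.config.in_time_bins:
        raise ValueError(
            f"stack has {stack.axis.n_bins} time bins but the network expects "
            f"{net.config.in_time_bins}; use resample_time_axis first"
        )
    x = normalize_stack(stack.counts)[None]
    pred = net.forward(x, train=False)[0]
    background = stack.total_counts() == 0
    return LifetimeMap(tau=np.where(background, 0.0, pred), background_mask=background)


# ---------------------------------------------------------------------------
# statsmodels-style fitting interface


class LifetimeRegressionModel:
    """Lifetime-regression model bound to a training dataset.

    Parameters
    ----------
    stacks, maps : lists of FLIMStack / LifetimeMap
        Paired photon-count stacks and ground-truth lifetime maps.
    network_config, training_config : optional
        Architecture and optimization settings; ``in_time_bins`` is
        inferred from the data when not supplied.
    """

    def __init__(self, stacks, maps, network_config: NetworkConfig | None = None,
                 training_config: TrainingConfig | None = None):
        if len(stacks) != len(maps) or not stacks:
            raise ValueError("stacks and maps must be nonempty and paired")
        self.stacks = list(stacks)
        self.maps = list(maps)
        if network_config is None:
            network_config = NetworkConfig(in_time_bins=stacks[0].axis.n_bins)
        if network_config.in_time_bins != stacks[0].axis.n_bins:
            raise ValueError("network in_time_bins does not match the data")
        self.network_config = network_config
        self.training_config = training_config or TrainingConfig()
        self.bin_width = stacks[0].axis.bin_width

    def fit(self) -> "LifetimeRegressionResults":
        net = build_network(self.network_config)
        data = make_training_pairs(self.stacks, self.maps, self.training_config)
        net, history = train_model(net, data, self.training_config)
        return LifetimeRegressionResults(self, net, history)


class LifetimeRegressionResults:
    """Fitted network plus its training history and diagnostics."""

    def __init__(self, model: LifetimeRegressionModel, net: FLIMNet, history: list):
        self.model = model
        self.net = net
        self.history = history

    @property
    def best_val_mse(self) -> float:
        return min(h["val_mse"] for h in self.history)

    @property
    def n_epochs(self) -> int:
        return len(self.history)

    def predict(self, stack: FLIMStack) -> LifetimeMap:
        return predict_map(self.net, stack)

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)

    def summary(self) -> str:
        cfg = self.model.network_config
        tc = self.model.training_config
        lines = [
            "Lifetime Regression Results",
            "=" * 45,
            f"{'Images (train+val)':30s} {len(self.model.stacks):>13d}",
            f"{'Time bins (channels)':30s} {cfg.in_time_bins:>13d}",
            f"{'Stage channels':30s} {str(cfg.channels):>13s}",
            f"{'Trainable parameters':30s} {self.net.n_parameters():>13d}",
            f"{'Optimizer':30s} {'AdamW':>13s}",
            f"{'Learning rate':30s} {tc.learning_rate:>13g}",
            f"{'Weight decay':30s} {tc.weight_decay:>13g}",
            f"{'Epochs run':30s} {self.n_epochs:>13d}",
            f"{'Best validation MSE (ns^2)':30s} {self.best_val_mse:>13.5f}",
            "=" * 45,
        ]
        return "\n".join(lines)

    # -- checkpoints --------------------------------------------------------
    def save(self, path) -> None:
        """Serialize weights + config + bin width to a .npz checkpoint."""
        meta = {
            "network_config": asdict(self.model.network_config),
            "training_config": asdict(self.model.training_config),
            "bin_width": self.model.bin_width,
            "history": self.history,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.net.state_arrays())


def load_checkpoint(path) -> tuple[FLIMNet, dict]:
    """Load a checkpoint saved by :meth:`LifetimeRegressionResults.save`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = meta["network_config"]
        cfg["stage_channels"] = tuple(cfg["stage_channels"])
        net = build_network(NetworkConfig(**cfg))
        net.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    return net, meta
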