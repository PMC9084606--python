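"""PoseNet-style plane regressors: baseline, single-head and multihead MTL.

The trunk is five convolutional blocks (3D conv -> ReLU -> batch norm ->
max pool) with channel progression 1->8->16->32->64->128; the final block
pools adaptively to 4x5x4 so the flattened feature vector has 10,240
entries, feeding a fully connected head 10240 -> 1300 -> 50 -> n_outputs,
where n_outputs = 3 planes x (3 translation + rotation-code) values.

Three usage modes share this layout:

* ``baseline`` — one network per body region (region-agnostic architecture);
* ``single_head`` — one network trained on all regions with a single head;
* ``multi_head`` — a shared trunk with one fully connected head per region.
  During training only the head of each sample's region receives gradient
  (the batch is processed per region subgroup, which realizes the masked
  backward pass exactly); the trunk accumulates gradients from all samples.

A reduced configuration (32^3 input, channels 4->8->16->32, head 256->64->n)
is provided for CPU-scale experiments on synthetic phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .geometry import PlaneTriplet, VolumeGeometry
from .preprocessing import (
    AugmentationConfig,
    IntensityWindowConfig,
    intensity_normalize,
    resample_volume,
    sample_augmentation,
    transform_labels,
)
from .postprocess import postprocess as _postprocess_triplet
from .rotations import (
    RotationCodec,
    build_parameter_vector,
    get_codec,
    parameter_vector_length,
    parse_parameter_vector,
)

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "PlaneRegressionNetwork",
    "build_model",
    "reduced_model_spec",
    "mse_loss",
    "train_step",
    "make_sampler",
    "oversample_weights",
    "train",
    "predict",
    "parameter_count",
    "save_model",
    "load_model",
]

mse_loss = nn.mse_loss

MODES = ("baseline", "single_head", "multi_head")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description; defaults follow the full-size layout."""

    mode: str = "baseline"
    codec: str = "six_d_xy"
    regions: tuple = ("ankle",)
    input_shape: tuple = (72, 72, 72)
    conv_channels: tuple = (8, 16, 32, 64, 128)
    head_widths: tuple = (1300, 50)
    adaptive_pool: tuple | None = (4, 5, 4)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        get_codec(self.codec)
        if self.mode == "multi_head" and len(self.regions) < 1:
            raise ValueError("multi_head requires at least one region")

    @property
    def n_outputs(self) -> int:
        return parameter_vector_length(get_codec(self.codec))


def reduced_model_spec(**overrides) -> ModelSpec:
    """CPU-scale configuration: 32^3 input, channels 4-32, head 256->64->n."""
    base = dict(
        input_shape=(32, 32, 32),
        conv_channels=(4, 8, 16, 32),
        head_widths=(64,),
        adaptive_pool=None,
    )
    base.update(overrides)
    return ModelSpec(**base)


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol; defaults are the full-scale reference settings."""

    epochs: int = 400
    learning_rate: float = 0.00164
    lr_decay: float = 0.27291
    lr_decay_step: int = 75
    momentum: float = 0.957437
    batch_size: int = 9
    seed: int = 0
    oversample: bool = False
    augment: AugmentationConfig | None = None
    intensity: IntensityWindowConfig = IntensityWindowConfig()


class PlaneRegressionNetwork(nn.Module):
    """Shared convolutional trunk + one or more fully connected heads."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        layers = []
        c_prev = 1
        n_blocks = len(spec.conv_channels)
        for i, c in enumerate(spec.conv_channels):
            layers += [nn.Conv3d(c_prev, c, 3, rng), nn.ReLU(), nn.BatchNorm3d(c)]
            last = i == n_blocks - 1
            if last and spec.adaptive_pool is not None:
                layers.append(nn.AdaptiveMaxPool3d(spec.adaptive_pool))
            else:
                layers.append(nn.MaxPool3d())
            c_prev = c
        layers.append(nn.Flatten())
        self.trunk = nn.Sequential(*layers)
        self.n_features = self._probe_features(spec)

        def make_head():
            widths = [self.n_features, *spec.head_widths, spec.n_outputs]
            head_layers = []
            for a, b in zip(widths[:-1], widths[1:]):
                head_layers += [nn.Linear(a, b, rng), nn.ReLU()]
            head_layers.pop()  # no activation on the output layer
            # small output-layer init: targets are bounded in [-1, 1], so the
            # regression head starts near zero instead of swamping the trunk
            # with huge error gradients in the first steps
            head_layers[-1].weight.data *= 0.01
            return nn.Sequential(*head_layers)

        if spec.mode == "multi_head":
            self.heads = {r: make_head() for r in spec.regions}
        else:
            self.heads = {"shared": make_head()}

    def _probe_features(self, spec: ModelSpec) -> int:
        was_training = self.training
        self.train(False)
        x = np.zeros((1, 1, *spec.input_shape), dtype=np.float32)
        n = self.trunk(x).shape[1]
        self.train(was_training)
        return int(n)

    def head_for(self, region: str | None) -> nn.Sequential:
        if self.spec.mode != "multi_head":
            return self.heads["shared"]
        if region not in self.heads:
            raise ValueError(f"no head for region {region!r}")
        return self.heads[region]

    def forward(self, x, region: str | None = None):
        return self.head_for(region)(self.trunk(x))

    def backward_from(self, dout, region: str | None = None):
        self.trunk.backward(self.head_for(region).backward(dout))


def build_model(spec: ModelSpec) -> PlaneRegressionNetwork:
    return PlaneRegressionNetwork(spec)


def parameter_count(model: PlaneRegressionNetwork) -> int:
    return int(sum(p.data.size for p in model.parameters()))


def oversample_weights(regions: Sequence[str]) -> np.ndarray:
    """Per-sample draw weight proportional to 1 / (count of its region)."""
    regions = list(regions)
    if not regions:
        raise ValueError("empty dataset")
    counts = {}
    for r in regions:
        counts[r] = counts.get(r, 0) + 1
    w = np.array([1.0 / counts[r] for r in regions])
    return w / w.sum()


def make_sampler(regions: Sequence[str], rng: np.random.Generator):
    """Infinite index stream balancing the expected per-region frequency."""
    w = oversample_weights(regions)
    n = len(w)
    while True:
        yield int(rng.choice(n, p=w))


def train_step(model, optimizer, batch, targets, regions=None):
    """One minibatch step; multihead batches are grouped by region.

    ``batch``: (B, 1, D, H, W) float array; ``targets``: (B, n_outputs).
    Returns the batch loss (mean squared error over every output node).
    """
    optimizer.zero_grad()
    B = batch.shape[0]
    if model.spec.mode != "multi_head":
        pred = model.forward(batch)
        loss, grad = nn.mse_loss(pred, targets.astype(np.float32))
        model.backward_from(grad)
        optimizer.step()
        return loss
    if regions is None:
        raise ValueError("multi_head training requires per-sample region labels")
    regions = np.asarray(regions)
    total_elems = B * targets.shape[1]
    total_loss = 0.0
    for region in dict.fromkeys(regions.tolist()):
        sel = np.flatnonzero(regions == region)
        pred = model.forward(batch[sel], region)
        loss, grad = nn.mse_loss(pred, targets[sel].astype(np.float32))
        frac = pred.size / total_elems
        total_loss += loss * frac
        model.backward_from(grad * frac, region)
    optimizer.step()
    return total_loss


def _prepare_sample(sample, input_shape, cfg: TrainConfig, rng=None):
    """Augment (optionally), resample to network resolution, normalize."""
    vol, geom, triplet = sample.volume, sample.geometry, sample.triplet
    factor = 1.0
    if cfg.augment is not None and rng is not None:
        aug = sample_augmentation(cfg.augment, rng)
        vol, geom = resample_volume(vol, geom, aug, input_shape)
        triplet = transform_labels(triplet, aug)
        factor = aug.intensity_factor
    elif tuple(geom.shape) != tuple(input_shape):
        vol, geom = resample_volume(vol, geom, np.eye(4), input_shape)
    x = intensity_normalize(vol, factor=factor, cfg=cfg.intensity).astype(np.float32)
    return x, geom, triplet


def train(model: PlaneRegressionNetwork, samples, cfg: TrainConfig):
    """Run the training loop; returns a per-epoch log of the mean batch loss.

    ``samples`` is a sequence with attributes ``volume`` (HU array),
    ``geometry``, ``triplet`` and ``region`` (e.g. phantom dataset entries).
    The learning rate is multiplied by the decay factor every
    ``lr_decay_step`` epochs.  A NaN loss aborts with a diagnostic.
    """
    codec = get_codec(model.spec.codec)
    rng = np.random.default_rng(cfg.seed)
    optimizer = nn.SGD(model.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum)
    model.train(True)
    n = len(samples)
    input_shape = model.spec.input_shape

    cache = None
    if cfg.augment is None:
        cache = [
            _prepare_sample(s, input_shape, cfg) for s in samples
        ]

    log = []
    for epoch in range(cfg.epochs):
        if epoch > 0 and cfg.lr_decay_step > 0 and epoch % cfg.lr_decay_step == 0:
            optimizer.lr *= cfg.lr_decay
        if cfg.oversample:
            sampler = make_sampler([s.region for s in samples], rng)
            order = [next(sampler) for _ in range(n)]
        else:
            order = rng.permutation(n).tolist()
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xs, ys, regs = [], [], []
            for i in idx:
                if cache is not None:
                    x, geom, triplet = cache[i]
                else:
                    x, geom, triplet = _prepare_sample(
                        samples[i], input_shape, cfg, rng
                    )
                xs.append(x[None])
                ys.append(build_parameter_vector(triplet, codec, geom))
                regs.append(samples[i].region)
            batch = np.stack(xs).astype(np.float32)
            targets = np.stack(ys)
            loss = train_step(model, optimizer, batch, targets, regs)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}"
                )
            losses.append(loss)
        log.append({"epoch": epoch, "loss": float(np.mean(losses)), "lr": optimizer.lr})
    model.train(False)
    return log


def _batchnorm_layers(model: PlaneRegressionNetwork):
    seqs = [model.trunk] + [model.heads[k] for k in sorted(model.heads)]
    for seq in seqs:
        for layer in seq.layers:
            if isinstance(layer, nn.BatchNorm3d):
                yield layer


def save_model(model: PlaneRegressionNetwork, path) -> None:
    """Serialize spec + parameters + batch-norm statistics to an .npz file."""
    import json

    spec = model.spec
    meta = dict(
        mode=spec.mode,
        codec=spec.codec,
        regions=list(spec.regions),
        input_shape=list(spec.input_shape),
        conv_channels=list(spec.conv_channels),
        head_widths=list(spec.head_widths),
        adaptive_pool=list(spec.adaptive_pool) if spec.adaptive_pool else None,
        seed=spec.seed,
    )
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    for i, bn in enumerate(_batchnorm_layers(model)):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_model(path) -> PlaneRegressionNetwork:
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        spec = ModelSpec(
            mode=meta["mode"],
            codec=meta["codec"],
            regions=tuple(meta["regions"]),
            input_shape=tuple(meta["input_shape"]),
            conv_channels=tuple(meta["conv_channels"]),
            head_widths=tuple(meta["head_widths"]),
            adaptive_pool=tuple(meta["adaptive_pool"])
            if meta["adaptive_pool"]
            else None,
            seed=meta["seed"],
        )
        model = PlaneRegressionNetwork(spec)
        for i, p in enumerate(model.parameters()):
            arr = data[f"param_{i}"]
            if arr.shape != p.data.shape:
                raise ValueError("stored parameters do not match the model spec")
            p.data = arr.astype(p.data.dtype)
        for i, bn in enumerate(_batchnorm_layers(model)):
            bn.running_mean = data[f"bn_mean_{i}"]
            bn.running_var = data[f"bn_var_{i}"]
    model.train(False)
    return model


def predict(
    model: PlaneRegressionNetwork,
    volume: np.ndarray,
    geom: VolumeGeometry,
    region: str,
    apply_postprocess: bool = True,
    intensity: IntensityWindowConfig = IntensityWindowConfig(),
) -> PlaneTriplet:
    """Forward pass on one volume -> decoded (and optionally corrected) planes."""
    codec = get_codec(model.spec.codec)
    input_shape = model.spec.input_shape
    if tuple(geom.shape) != tuple(input_shape):
        volume, geom = resample_volume(volume, geom, np.eye(4), input_shape)
    model.train(False)
    x = intensity_normalize(volume, cfg=intensity).astype(np.float32)
    out = model.forward(x[None, None], region)[0]
    triplet = parse_parameter_vector(np.asarray(out, dtype=float), region, codec, geom)
    if apply_postprocess:
        triplet = _postprocess_triplet(triplet)
    return triplet
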