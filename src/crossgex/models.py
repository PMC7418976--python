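"""The five trajectory-translation predictors behind one fit/predict contract.

Three neural models (naive bottleneck encoder, modified autoencoder with
grafted pre-trained halves, gene-axis CNN) are trained with Adam on the
mean-absolute-error loss; k-nearest-neighbours and a random regression forest
serve as classical baselines. All models map a flat (or genes x time) encoded
source instance to a flat encoded target instance with entries in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.neighbors import KNeighborsRegressor

from .encoding import EncodedInstance, from_flat
from .nnet import AdamState, ConvGenes, Dense, Flatten, MaxPoolGenes, Network
from .pairing import LearningExample

__all__ = [
    "TrainingConfig",
    "ModelSpec",
    "TrainedModel",
    "build_naive_encoder",
    "build_modified_autoencoder",
    "build_cnn",
    "build_knn",
    "build_rrf",
    "fit",
    "predict",
    "pretrain_and_graft",
    "design_matrices",
    "NAIVE_ENCODER_WIDTHS",
    "AUTOENCODER_WIDTHS",
]

NAIVE_ENCODER_WIDTHS = (256, 160, 32, 96, 256)
AUTOENCODER_WIDTHS = (70, 70, 60, 70, 70)
CNN_FILTERS = (16, 8, 4)
CNN_KERNELS = (10, 10, 2)
CNN_DENSE = (20, 30)


@dataclass(frozen=True)
class TrainingConfig:
    """Adam + regularization settings (defaults chosen for ~700 examples)."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 200
    batch_size: int = 32
    l1_strength: float = 1e-5
    seed: int = 0
    pretrain_epochs: int | None = None  # modified autoencoder only

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.l1_strength < 0:
            raise ValueError("l1_strength must be nonnegative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description; ``kind`` selects the backend."""

    kind: str
    input_dim: int | None = None  # flat models
    input_shape: tuple[int, int] | None = None  # cnn: (G, T)
    output_dim: int = 0
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        kinds = ("naive_encoder", "modified_autoencoder", "cnn", "knn", "rrf")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.output_dim < 1:
            raise ValueError("output_dim must be positive")


def build_naive_encoder(input_dim: int, output_dim: int) -> ModelSpec:
    """Dense bottleneck net 256-160-32-96-256, ReLU hidden / sigmoid output,
    L1 activity regularization on all five hidden layers."""
    if input_dim < 1 or output_dim < 1:
        raise ValueError("dims must be >= 1")
    return ModelSpec(
        kind="naive_encoder",
        input_dim=input_dim,
        output_dim=output_dim,
        hyperparams={"hidden": NAIVE_ENCODER_WIDTHS},
    )


def build_modified_autoencoder(input_dim: int, output_dim: int) -> ModelSpec:
    """Five hidden layers 70-70-60-70-70; initial weights come from grafting
    a source-domain autoencoder's encoder onto a target-domain autoencoder's
    decoder, then fine-tuning on paired examples. L1 activity regularization
    sits on the three middle hidden layers."""
    if input_dim < 1 or output_dim < 1:
        raise ValueError("dims must be >= 1")
    return ModelSpec(
        kind="modified_autoencoder",
        input_dim=input_dim,
        output_dim=output_dim,
        hyperparams={"hidden": AUTOENCODER_WIDTHS},
    )


def build_cnn(g_source: int, t_source: int, output_dim: int) -> ModelSpec:
    """Gene-axis CNN: conv(16, 10x1) / pool 2x1 / conv(8, 10x1) / pool /
    conv(4, 2x1) / pool / flatten / dense 20 (L1) / dense 30 / output.

    Convolutions use same-padding and pooling floor-divides the gene axis, so
    gene sets as small as 18 remain valid.
    """
    if g_source < 2:
        raise ValueError("need at least two genes for the gene-axis CNN")
    return ModelSpec(
        kind="cnn",
        input_shape=(g_source, t_source),
        output_dim=output_dim,
        hyperparams={
            "filters": CNN_FILTERS,
            "kernels": CNN_KERNELS,
            "dense": CNN_DENSE,
        },
    )


def build_knn(k: int = 5, output_dim: int = 1, input_dim: int | None = None) -> ModelSpec:
    if k < 1:
        raise ValueError("k must be >= 1")
    return ModelSpec(kind="knn", input_dim=input_dim, output_dim=output_dim,
                     hyperparams={"k": k})


def build_rrf(n_trees: int = 100, output_dim: int = 1, input_dim: int | None = None) -> ModelSpec:
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    return ModelSpec(kind="rrf", input_dim=input_dim, output_dim=output_dim,
                     hyperparams={"n_trees": n_trees})


# ----------------------------------------------------------------- assembly

def _dense_stack(
    input_dim: int,
    hidden: Sequence[int],
    output_dim: int,
    l1_mask: Sequence[bool],
    l1: float,
    rng: np.random.Generator,
) -> Network:
    layers = []
    prev = input_dim
    for width, reg in zip(hidden, l1_mask):
        layers.append(Dense(prev, width, "relu", activity_l1=l1 if reg else 0.0, rng=rng))
        prev = width
    layers.append(Dense(prev, output_dim, "sigmoid", rng=rng))
    return Network(layers)


def _cnn_stack(spec: ModelSpec, l1: float, rng: np.random.Generator) -> Network:
    g, t = spec.input_shape
    filters, kernels = spec.hyperparams["filters"], spec.hyperparams["kernels"]
    d1, d2 = spec.hyperparams["dense"]
    layers: list = []
    channels = 1
    g_len = g
    for f, k in zip(filters, kernels):
        layers.append(ConvGenes(k, channels, f, "relu", rng=rng))
        layers.append(MaxPoolGenes(2))
        channels = f
        g_len = g_len // 2
    layers.append(Flatten())
    flat = g_len * t * channels
    layers.append(Dense(flat, d1, "relu", activity_l1=l1, rng=rng))
    layers.append(Dense(d1, d2, "relu", rng=rng))
    layers.append(Dense(d2, spec.output_dim, "sigmoid", rng=rng))
    return Network(layers)


def cnn_flat_dim(g: int, t: int) -> int:
    """Flattened length after the three conv/pool blocks (same-padding convs,
    floor-division pooling)."""
    return (g // 2 // 2 // 2) * t * CNN_FILTERS[-1]


def _build_network(spec: ModelSpec, cfg: TrainingConfig, rng: np.random.Generator) -> Network:
    if spec.kind == "naive_encoder":
        return _dense_stack(
            spec.input_dim, spec.hyperparams["hidden"], spec.output_dim,
            l1_mask=(True,) * 5, l1=cfg.l1_strength, rng=rng,
        )
    if spec.kind == "modified_autoencoder":
        return _dense_stack(
            spec.input_dim, spec.hyperparams["hidden"], spec.output_dim,
            l1_mask=(False, True, True, True, False), l1=cfg.l1_strength, rng=rng,
        )
    if spec.kind == "cnn":
        return _cnn_stack(spec, cfg.l1_strength, rng)
    raise ValueError(f"{spec.kind} is not a network model")


# ------------------------------------------------------------------- training

def design_matrices(
    examples: Sequence[LearningExample], kind: str
) -> tuple[np.ndarray, np.ndarray]:
    """Stack examples into (X, Y) arrays for the given model kind: flat
    vectors for dense/KNN/RRF models, genes x time blocks for the CNN."""
    if not examples:
        raise ValueError("empty training set")
    y = np.stack([ex.target.flat for ex in examples])
    if kind == "cnn":
        x = np.stack([ex.source.matrix for ex in examples])
    else:
        x = np.stack([ex.source.flat for ex in examples])
    return x, y


@dataclass
class TrainedModel:
    """A fitted predictor: maps encoded source instances to encoded target
    vectors. Network predictions are sigmoid outputs, hence in [0, 1];
    KNN/RRF predictions are means of observed targets, also in [0, 1]."""

    spec: ModelSpec
    backend: object
    target_time_points: int | None = None
    history: list = field(default_factory=list)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.spec.kind == "cnn":
            if x.ndim == 2:  # single instance (G, T)
                x = x[None, ...]
            pred = self.backend.predict(x[..., None])
        else:
            if x.ndim == 1:
                x = x[None, :]
            pred = self.backend.predict(x)
        pred = np.asarray(pred, dtype=float)
        if pred.ndim == 1:
            pred = pred[None, :]
        if not np.all(np.isfinite(pred)):
            raise FloatingPointError("non-finite prediction")
        if self.spec.kind in ("naive_encoder", "modified_autoencoder", "cnn"):
            assert pred.min() >= 0.0 and pred.max() <= 1.0, "sigmoid output left [0,1]"
        return pred

    def predict_instances(
        self, instances: Sequence[EncodedInstance]
    ) -> list[EncodedInstance]:
        t = self.target_time_points
        if t is None:
            raise ValueError("target_time_points unknown; predict on arrays instead")
        if self.spec.kind == "cnn":
            x = np.stack([inst.matrix for inst in instances])
        else:
            x = np.stack([inst.flat for inst in instances])
        preds = self.predict(x)
        return [
            from_flat(p, t, compound=inst.compound, dose=inst.dose,
                      replicate=inst.replicate, layout=inst.layout)
            for p, inst in zip(preds, instances)
        ]

    # ------------------------------------------------------------------ I/O

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "kind": self.spec.kind,
            "input_dim": self.spec.input_dim,
            "input_shape": self.spec.input_shape,
            "output_dim": self.spec.output_dim,
            "hyperparams": {k: list(v) if isinstance(v, tuple) else v
                            for k, v in self.spec.hyperparams.items()},
            "target_time_points": self.target_time_points,
        }
        (directory / "spec.json").write_text(json.dumps(meta, indent=2))
        if isinstance(self.backend, Network):
            weights = self.backend.get_weights()
            np.savez(directory / "weights.npz",
                     **{f"w{i}": w for i, w in enumerate(weights)})
        else:
            import joblib

            joblib.dump(self.backend, directory / "backend.joblib")
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "spec.json").read_text())
        spec = ModelSpec(
            kind=meta["kind"],
            input_dim=meta["input_dim"],
            input_shape=tuple(meta["input_shape"]) if meta["input_shape"] else None,
            output_dim=meta["output_dim"],
            hyperparams={k: tuple(v) if isinstance(v, list) else v
                         for k, v in meta["hyperparams"].items()},
        )
        if spec.kind in ("naive_encoder", "modified_autoencoder", "cnn"):
            net = _build_network(spec, TrainingConfig(), np.random.default_rng(0))
            data = np.load(directory / "weights.npz")
            net.set_weights([data[f"w{i}"] for i in range(len(data.files))])
            backend = net
        else:
            import joblib

            backend = joblib.load(directory / "backend.joblib")
        return cls(spec=spec, backend=backend,
                   target_time_points=meta.get("target_time_points"))


def _autoencoder_spec(dim: int) -> ModelSpec:
    return build_modified_autoencoder(dim, dim)


def pretrain_and_graft(
    source_inputs: np.ndarray,
    target_outputs: np.ndarray,
    cfg: TrainingConfig,
    output_dim: int | None = None,
) -> tuple[Network, Network, Network]:
    """Pre-train one autoencoder per domain, then assemble the prediction net.

    Returns ``(grafted, source_ae, target_ae)``. The grafted network's first
    three hidden layers carry the source autoencoder's encoder weights and the
    last two hidden layers plus the output layer carry the target
    autoencoder's decoder weights, bit for bit. No fine-tuning is applied
    here.
    """
    in_dim = source_inputs.shape[1]
    out_dim = output_dim or target_outputs.shape[1]
    ss = np.random.SeedSequence(cfg.seed)
    rng_src, rng_tgt, rng_graft, rng_fit_src, rng_fit_tgt = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    epochs = cfg.pretrain_epochs if cfg.pretrain_epochs is not None else cfg.epochs
    src_ae = _dense_stack(in_dim, AUTOENCODER_WIDTHS, in_dim,
                          (False, True, True, True, False), cfg.l1_strength, rng_src)
    tgt_ae = _dense_stack(out_dim, AUTOENCODER_WIDTHS, out_dim,
                          (False, True, True, True, False), cfg.l1_strength, rng_tgt)
    if epochs:
        src_ae.fit(source_inputs, source_inputs, epochs, cfg.batch_size,
                   AdamState(cfg.learning_rate, cfg.beta1, cfg.beta2), rng_fit_src)
        tgt_ae.fit(target_outputs, target_outputs, epochs, cfg.batch_size,
                   AdamState(cfg.learning_rate, cfg.beta1, cfg.beta2), rng_fit_tgt)
    grafted = _dense_stack(in_dim, AUTOENCODER_WIDTHS, out_dim,
                           (False, True, True, True, False), cfg.l1_strength, rng_graft)
    # layers 0-2 (encoder) from the source AE; layers 3-4 + output from target
    src_w, tgt_w = src_ae.get_weights(), tgt_ae.get_weights()
    graft_w = grafted.get_weights()
    for i in range(0, 6):  # W,b for dense layers 0..2
        graft_w[i] = src_w[i]
    for i in range(6, 12):  # W,b for dense layers 3..4 and output
        graft_w[i] = tgt_w[i]
    grafted.set_weights(graft_w)
    return grafted, src_ae, tgt_ae


def fit(
    spec: ModelSpec,
    examples: Sequence[LearningExample],
    cfg: TrainingConfig,
) -> TrainedModel:
    """Train a fresh model of the given spec on the examples."""
    if not examples:
        raise ValueError("empty training set")
    x, y = design_matrices(examples, spec.kind)
    t_target = examples[0].target.n_time_points
    if spec.kind == "knn":
        k = spec.hyperparams["k"]
        if k > len(examples):
            raise ValueError(f"k={k} exceeds training-set size {len(examples)}")
        backend = KNeighborsRegressor(n_neighbors=k, weights="uniform",
                                      algorithm="brute", metric="euclidean")
        backend.fit(x, y)
        return TrainedModel(spec=spec, backend=backend, target_time_points=t_target)
    if spec.kind == "rrf":
        backend = RandomForestRegressor(
            n_estimators=spec.hyperparams["n_trees"], random_state=cfg.seed, n_jobs=1
        )
        backend.fit(x, y)
        return TrainedModel(spec=spec, backend=backend, target_time_points=t_target)
    if spec.kind == "modified_autoencoder":
        net, _, _ = pretrain_and_graft(x, y, cfg, output_dim=spec.output_dim)
        rng_fit = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(6)[5])
        history = []
        if cfg.epochs:
            history = net.fit(x, y, cfg.epochs, cfg.batch_size,
                              AdamState(cfg.learning_rate, cfg.beta1, cfg.beta2), rng_fit)
        return TrainedModel(spec=spec, backend=net, target_time_points=t_target,
                            history=history)
    # naive encoder / CNN
    ss = np.random.SeedSequence(cfg.seed)
    rng_init, rng_fit = (np.random.default_rng(s) for s in ss.spawn(2))
    net = _build_network(spec, cfg, rng_init)
    x_net = x[..., None] if spec.kind == "cnn" else x
    history = []
    if cfg.epochs:
        history = net.fit(x_net, y, cfg.epochs, cfg.batch_size,
                          AdamState(cfg.learning_rate, cfg.beta1, cfg.beta2), rng_fit)
    return TrainedModel(spec=spec, backend=net, target_time_points=t_target,
                        history=history)


def predict(model: TrainedModel, instances: Sequence[EncodedInstance]) -> list[EncodedInstance]:
    """Module-level alias for :meth:`TrainedModel.predict_instances`."""
    return model.predict_instances(instances)
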