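"""Supervised CNN baseline: error-free vs any-error classification of DD maps.

Three convolution blocks (3x3 conv, batch norm, ReLU, 2x2 max pool; 16/32/64
filters) followed by dense layers 256 -> 32 -> 2 with dropout 0.2 and 0.5,
softmax output.  Unlike the unsupervised detector, this model trains on
labelled error maps of all nine simulated error kinds; the error-free class
is balanced by a 9-fold flip/rescale expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .ddmap import (BeamCase, CLIP_LIMIT, MAP_SIZE, DDMap, augment_flips,
                    beam_case_maps)
from .simulate import ERROR_KINDS, Dataset

__all__ = [
    "SCNNConfig", "CaseProbability", "TrainedSCNN",
    "build_scnn", "assemble_scnn_datasets", "train_scnn",
    "predict_error_probability", "score_case_scnn", "score_cases_scnn",
    "classify_probability",
]


@dataclass
class SCNNConfig:
    conv_filters: tuple[int, int, int] = (16, 32, 64)
    dense_nodes: tuple[int, int, int] = (256, 32, 2)
    dropout_rates: tuple[float, float] = (0.2, 0.5)
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if self.dense_nodes[-1] != 2:
            raise ValueError("output layer must have exactly 2 nodes")
        if any(n < 1 for n in self.conv_filters + self.dense_nodes):
            raise ValueError("layer sizes must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class CaseProbability:
    beam_id: int
    error: str
    p_error_plane1: float
    p_error_plane2: float

    @property
    def p_error_mean(self) -> float:
        return 0.5 * (self.p_error_plane1 + self.p_error_plane2)


@dataclass
class TrainedSCNN:
    net: nn.Sequential
    config: SCNNConfig
    history: dict[str, list[float]] = field(default_factory=dict)


def build_scnn(config: SCNNConfig | None = None) -> TrainedSCNN:
    config = config or SCNNConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    f1, f2, f3 = config.conv_filters
    d1, d2, d3 = config.dense_nodes
    # 27 -> 13 -> 6 -> 3 through the three pooling stages
    feat = f3 * 3 * 3
    net = nn.Sequential([
        nn.Conv2d(1, f1, 3, 1, 1, rng), nn.BatchNorm(f1), nn.ReLU(), nn.MaxPool2d(),
        nn.Conv2d(f1, f2, 3, 1, 1, rng), nn.BatchNorm(f2), nn.ReLU(), nn.MaxPool2d(),
        nn.Conv2d(f2, f3, 3, 1, 1, rng), nn.BatchNorm(f3), nn.ReLU(), nn.MaxPool2d(),
        nn.Flatten(),
        nn.Dense(feat, d1, rng), nn.ReLU(), nn.Dropout(config.dropout_rates[0]),
        nn.Dense(d1, d2, rng), nn.ReLU(), nn.Dropout(config.dropout_rates[1]),
        nn.Dense(d2, d3, rng),
    ])
    return TrainedSCNN(net, config, {})


def expand_ninefold(ddmap: DDMap, factors: tuple[float, float] = (0.95, 1.05)) -> list[DDMap]:
    """9 augmentation variants: 4 flips, the 4 flips rescaled alternately by
    the two factors, and the rescaled identity."""
    flips = augment_flips(ddmap)
    out = list(flips)
    for i, m in enumerate(flips):
        f = factors[i % 2]
        out.append(DDMap(np.clip(m.values * f, -CLIP_LIMIT, CLIP_LIMIT),
                         m.plane_id, m.beam_id, m.error))
    m = flips[0]
    out.append(DDMap(np.clip(m.values * factors[1], -CLIP_LIMIT, CLIP_LIMIT),
                     m.plane_id, m.beam_id, m.error))
    return out


def assemble_scnn_datasets(dataset: Dataset):
    """Labelled map arrays for supervised training.

    Returns dict with train/validation (maps, labels) and the test beam
    cases.  With the default 100/25/36 split: 1800 expanded error-free +
    1800 error training maps, 50 + 450 validation maps, 360 test cases.
    Labels: 0 = error-free, 1 = any-error.
    """
    error_kinds = tuple(k for k in ERROR_KINDS if k != "none")

    def split_maps(split: str, expand: bool):
        free_cases = beam_case_maps(dataset, splits=(split,), conditions=("none",))
        err_cases = beam_case_maps(dataset, splits=(split,), conditions=error_kinds)
        maps, labels = [], []
        for case in free_cases:
            for m in case.maps:
                variants = expand_ninefold(m) if expand else [m]
                maps.extend(v.values for v in variants)
                labels.extend([0] * len(variants))
        for case in err_cases:
            for m in case.maps:
                maps.append(m.values)
                labels.append(1)
        return np.stack(maps), np.array(labels, dtype=np.intp)

    train = split_maps("train", expand=True)
    validation = split_maps("validation", expand=False)
    test_cases = beam_case_maps(dataset, splits=("test",))
    return {"train": train, "validation": validation, "test": test_cases}


def _as_batch(maps: np.ndarray) -> np.ndarray:
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 2:
        maps = maps[None]
    return maps.reshape(-1, 1, MAP_SIZE, MAP_SIZE)


def _accuracy(net: nn.Sequential, x: np.ndarray, labels: np.ndarray,
              batch: int = 256) -> float:
    hits = 0
    for s in range(0, len(x), batch):
        logits = net.forward(x[s:s + batch], train=False)
        hits += int(np.sum(logits.argmax(axis=1) == labels[s:s + batch]))
    return hits / len(x)


def train_scnn(datasets: dict, config: SCNNConfig | None = None) -> TrainedSCNN:
    """Cross-entropy training with Adam; keeps the best-validation-accuracy
    checkpoint.  History records per-epoch loss and train/validation accuracy."""
    model = build_scnn(config)
    config = model.config
    x, y = datasets["train"]
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    x = _as_batch(x)
    xv, yv = datasets["validation"]
    xv = _as_batch(xv)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    model.net.set_dropout_rng(rng)
    opt = nn.Adam(model.net.params(), lr=config.learning_rate)
    hist: dict[str, list[float]] = {"loss": [], "train_acc": [], "val_acc": []}
    best_val, best_state = -1.0, None

    for _ in range(config.epochs):
        order = rng.permutation(len(x))
        ep_loss = 0.0
        ep_hits = 0
        for s in range(0, len(x), config.batch_size):
            idx = order[s:s + config.batch_size]
            opt.zero_grad()
            logits = model.net.forward(x[idx], train=True)
            loss, grad = nn.softmax_cross_entropy(logits, y[idx])
            model.net.backward(grad)
            opt.step()
            ep_loss += loss * len(idx)
            ep_hits += int(np.sum(logits.argmax(axis=1) == y[idx]))
        hist["loss"].append(ep_loss / len(x))
        hist["train_acc"].append(ep_hits / len(x))
        val_acc = _accuracy(model.net, xv, yv) if len(xv) else np.nan
        hist["val_acc"].append(val_acc)
        if len(xv) and val_acc >= best_val:
            best_val = val_acc
            best_state = nn.state_dict(model.net)

    if best_state is not None:
        nn.load_state_dict(model.net, best_state)
    model.history = hist
    return model


def predict_error_probability(model: TrainedSCNN, maps: np.ndarray) -> np.ndarray:
    """P(any-error) per map; deterministic (dropout disabled at inference)."""
    logits = model.net.forward(_as_batch(maps), train=False)
    return nn.softmax(logits)[:, 1]


def score_case_scnn(model: TrainedSCNN, case: BeamCase) -> CaseProbability:
    p = predict_error_probability(model, np.stack([m.values for m in case.maps]))
    return CaseProbability(case.beam_id, case.error, float(p[0]), float(p[1]))


def score_cases_scnn(model: TrainedSCNN, cases: list[BeamCase]) -> list[CaseProbability]:
    maps = np.stack([m.values for c in cases for m in c.maps])
    p = predict_error_probability(model, maps)
    return [CaseProbability(c.beam_id, c.error, float(p[2 * i]), float(p[2 * i + 1]))
            for i, c in enumerate(cases)]


def classify_probability(p_error_mean: float, threshold: float) -> str:
    """'any-error' if the probability reaches the threshold, else 'error-free'."""
    return "any-error" if p_error_mean >= threshold else "error-free"
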