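"""Mitotic-stage classification of Raman maps.

Cells are classified into interphase or one of the five mitotic stages
from their 1600-channel spectral maps.  Training sees 15x15 crops shifted
by two pixels (cheap augmentation that also caps memory); evaluation
aggregates crop predictions over the whole cell, so every reported
accuracy is per cell.  Splitting is by cell, never by crop, so crops of
one cell can never leak across the train/validation/test boundary.

Because the six stages are temporally ordered, a prediction that lands on
a neighboring stage is a near miss; the one-miss accuracy (the tridiagonal
mass of the 6x6 confusion matrix over its total) credits those.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import (
    ConfigError,
    DivergenceError,
    ParameterError,
    SizeError,
    StratificationError,
)
from . import nn
from .spectral_io import RamanMap, StageLabel

__all__ = [
    "CropSpec",
    "ModelConfig",
    "SplitSpec",
    "Split",
    "ConfusionMatrix",
    "LabelledCell",
    "StageClassifier",
    "enumerate_crops",
    "split_cells",
    "build_model",
    "train_classifier",
    "predict_cell",
    "confusion",
    "standard_accuracy",
    "one_miss_accuracy",
]


@dataclass(frozen=True)
class CropSpec:
    """Spatial crop geometry: size x size windows shifted by stride pixels."""

    size: int = 15
    stride: int = 2

    def __post_init__(self) -> None:
        if self.size < 1 or self.stride < 1:
            raise ParameterError("crop size and stride must be >= 1")


@dataclass(frozen=True)
class LabelledCell:
    """One cell's spectral map with its annotated stage."""

    map: RamanMap
    stage: StageLabel

    @property
    def cell_id(self) -> str | None:
        return self.map.cell_id


def enumerate_crops(height: int, width: int, spec: CropSpec = CropSpec()) -> list[tuple[int, int]]:
    """All (top, left) crop offsets on the stride grid that fit in the map."""
    if height < spec.size or width < spec.size:
        raise SizeError(
            f"map {height}x{width} is smaller than the crop size {spec.size}"
        )
    tops = range(0, height - spec.size + 1, spec.stride)
    lefts = range(0, width - spec.size + 1, spec.stride)
    return [(t, l) for t in tops for l in lefts]


# ---------------------------------------------------------------------------
# cell-level splitting


@dataclass(frozen=True)
class SplitSpec:
    """Cell-level train/validation/test split specification."""

    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    stratify_by_stage: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ConfigError(f"split ratios {self.ratios} must sum to 1")
        if any(r < 0 for r in self.ratios):
            raise ConfigError("split ratios must be nonnegative")


class Split(NamedTuple):
    train: list
    val: list
    test: list


def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    """Apportion n items to the ratios; ties go to the earlier partition."""
    raw = [n * r for r in ratios]
    counts = [int(np.floor(x)) for x in raw]
    leftover = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:leftover]:
        counts[i] += 1
    return counts


def _stage_of(cell) -> StageLabel:
    if isinstance(cell, LabelledCell):
        return cell.stage
    if isinstance(cell, tuple):
        return StageLabel(cell[1])
    if hasattr(cell, "stage"):
        return StageLabel(cell.stage)
    raise ParameterError(f"cannot extract a stage label from {type(cell).__name__}")


def split_cells(cells: Sequence, spec: SplitSpec = SplitSpec()) -> Split:
    """Disjoint, exhaustive cell-level partition; deterministic per seed.

    With stratification each stage is apportioned separately by the
    largest-remainder rule, keeping per-stage proportions within one cell
    of the requested ratios.
    """
    rng = np.random.default_rng(spec.seed)
    parts: tuple[list, list, list] = ([], [], [])
    if spec.stratify_by_stage:
        stages = [_stage_of(c) for c in cells]
        for stage in StageLabel:
            idx = [i for i, s in enumerate(stages) if s == stage]
            if not idx:
                raise StratificationError(f"no cells with stage {stage.display}")
            order = rng.permutation(len(idx))
            shuffled = [idx[j] for j in order]
            counts = _largest_remainder(len(idx), spec.ratios)
            pos = 0
            for p, k in enumerate(counts):
                parts[p].extend(cells[i] for i in shuffled[pos : pos + k])
                pos += k
    else:
        order = rng.permutation(len(cells))
        counts = _largest_remainder(len(cells), spec.ratios)
        pos = 0
        for p, k in enumerate(counts):
            parts[p].extend(cells[int(i)] for i in order[pos : pos + k])
            pos += k
    return Split(*parts)


# ---------------------------------------------------------------------------
# model


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the stage classifier.

    The channel section reduces the 1600 spectral channels through grouped
    1x1 convolutions (widths ``in_channels -> channel_reduction[...]``, one
    group count per stage); the spatial section applies plain 3x3
    convolutions; global average pooling feeds exactly two fully connected
    layers, the last of which emits the six class scores.
    """

    in_channels: int = 1600
    n_classes: int = 6
    channel_reduction: tuple[int, ...] = (400, 100, 32)
    groups: tuple[int, ...] = (8, 4, 4)
    spatial_convs: tuple[int, ...] = (64, 64)
    fc_widths: tuple[int, int] = (128, 6)
    activation: str = "relu"
    input_norm: str = "snv"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) != len(self.channel_reduction):
            raise ConfigError("need one group count per channel-reduction stage")
        widths = (self.in_channels, *self.channel_reduction)
        for g, cin, cout in zip(self.groups, widths[:-1], widths[1:]):
            if cin % g or cout % g:
                raise ConfigError(
                    f"group count {g} must divide stage widths {cin} -> {cout}"
                )
        if len(self.fc_widths) != 2:
            raise ConfigError("exactly two fully connected layers are required")
        if self.fc_widths[-1] != self.n_classes:
            raise ConfigError("last FC width must equal n_classes")
        if self.activation != "relu":
            raise ConfigError("only relu activation is implemented")
        if self.input_norm not in ("snv", "none"):
            raise ConfigError("input_norm must be 'snv' or 'none'")


class StageClassifier:
    """Grouped-convolution network over spectral crops."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers: list[nn.Layer] = []
        cin = config.in_channels
        for cout, g in zip(config.channel_reduction, config.groups):
            layers += [nn.GroupedConv1x1(cin, cout, g, rng), nn.ReLU()]
            cin = cout
        for cout in config.spatial_convs:
            layers += [nn.Conv3x3(cin, cout, rng), nn.ReLU()]
            cin = cout
        layers.append(nn.GlobalAvgPool())
        layers += [nn.Dense(cin, config.fc_widths[0], rng), nn.ReLU()]
        layers.append(nn.Dense(config.fc_widths[0], config.fc_widths[1], rng))
        self.net = nn.Sequential(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x.astype(np.float32, copy=False))

    def predict_logits(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = [self.net.forward(x[i : i + batch_size].astype(np.float32, copy=False))
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    def param_count(self) -> int:
        return self.net.param_count()

    def param_checksum(self) -> float:
        return self.net.param_checksum()


def build_model(config: ModelConfig = ModelConfig()) -> StageClassifier:
    """Deterministically initialized classifier for the given architecture."""
    return StageClassifier(config)


# ---------------------------------------------------------------------------
# features and training


def map_features(raman_map: RamanMap, norm: str = "snv") -> np.ndarray:
    """Float32 (H, W, m) feature cube; 'snv' standardizes each pixel spectrum."""
    cube = raman_map.cube.astype(np.float32)
    if norm == "snv":
        mean = cube.mean(axis=2, keepdims=True)
        sd = cube.std(axis=2, ddof=1, keepdims=True)
        cube = (cube - mean) / np.maximum(sd, 1e-12)
    return cube


def _gather_crops(features: list[np.ndarray], index: np.ndarray, size: int) -> np.ndarray:
    out = np.empty((len(index), size, size, features[0].shape[2]), dtype=np.float32)
    for k, (ci, top, left) in enumerate(index):
        out[k] = features[ci][top : top + size, left : left + size]
    return out


def train_classifier(
    train_cells: Sequence[LabelledCell],
    val_cells: Sequence[LabelledCell],
    config: ModelConfig = ModelConfig(),
    epochs: int = 20,
    lr: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
    crop_spec: CropSpec = CropSpec(),
    crops_per_cell: int | None = None,
) -> tuple[StageClassifier, dict]:
    """Train with cross-entropy on stride-grid crops of the training cells.

    Per epoch, each training cell contributes ``crops_per_cell`` crops
    sampled without replacement from its stride grid (all of them when
    None).  Validation cells are evaluated intact, per cell, through
    :func:`predict_cell` aggregation.  Fully deterministic for a fixed
    seed and thread count.
    """
    if not train_cells:
        raise ParameterError("empty training set")
    model = build_model(config)
    optimizer = nn.Adam(model.net.params, lr=lr)
    rng = np.random.default_rng(seed)

    feats = [map_features(c.map, config.input_norm) for c in train_cells]
    labels = np.array([int(c.stage) for c in train_cells])
    offsets_per_cell = [
        enumerate_crops(c.map.height, c.map.width, crop_spec) for c in train_cells
    ]

    history: dict = {"train_loss": [], "val_accuracy": []}
    for epoch in range(epochs):
        index: list[tuple[int, int, int]] = []
        for ci, offs in enumerate(offsets_per_cell):
            if crops_per_cell is not None and crops_per_cell < len(offs):
                chosen = rng.choice(len(offs), size=crops_per_cell, replace=False)
                index.extend((ci, *offs[int(j)]) for j in sorted(chosen))
            else:
                index.extend((ci, *o) for o in offs)
        idx_arr = np.array(index)
        rng.shuffle(idx_arr, axis=0)

        losses = []
        for start in range(0, len(idx_arr), batch_size):
            batch = idx_arr[start : start + batch_size]
            x = _gather_crops(feats, batch, crop_spec.size)
            y = labels[batch[:, 0]]
            logits = model.forward(x)
            loss, dlogits = nn.cross_entropy_loss_and_grad(logits, y)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            model.net.backward(dlogits)
            optimizer.step(model.net.grads)
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))

        if val_cells:
            correct = sum(
                predict_cell(model, c.map, crop_spec)[0] == c.stage for c in val_cells
            )
            history["val_accuracy"].append(correct / len(val_cells))
        else:
            history["val_accuracy"].append(float("nan"))
    return model, history


def predict_cell(
    model: StageClassifier,
    raman_map: RamanMap,
    spec: CropSpec = CropSpec(),
    aggregation: str = "mean_logits",
) -> tuple[StageLabel, np.ndarray]:
    """Aggregate crop predictions over the whole cell map.

    ``mean_logits`` (default) averages crop logits; ``majority`` votes per
    crop with ties broken by the mean logits.  Returns the stage and the
    per-class aggregated scores.
    """
    if aggregation not in ("mean_logits", "majority"):
        raise ParameterError(f"unknown aggregation {aggregation!r}")
    offs = enumerate_crops(raman_map.height, raman_map.width, spec)
    features = map_features(raman_map, model.config.input_norm)
    index = np.array([(0, t, l) for t, l in offs])
    crops = _gather_crops([features], index, spec.size)
    logits = model.predict_logits(crops)
    mean_logits = logits.mean(axis=0)
    if aggregation == "mean_logits":
        return StageLabel(int(np.argmax(mean_logits))), mean_logits
    votes = np.bincount(np.argmax(logits, axis=1), minlength=model.config.n_classes)
    top = np.flatnonzero(votes == votes.max())
    if len(top) == 1:
        return StageLabel(int(top[0])), mean_logits
    winner = top[np.argmax(mean_logits[top])]
    return StageLabel(int(winner)), mean_logits


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[i, j] = cells of true stage i predicted as stage j."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros((6, 6), dtype=int))

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ParameterError("confusion matrix must be square")
        if np.any(c < 0):
            raise ParameterError("confusion matrix counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(y_true: Sequence, y_pred: Sequence, n_classes: int = 6) -> ConfusionMatrix:
    if len(y_true) != len(y_pred):
        raise ParameterError("y_true and y_pred must have equal lengths")
    if len(y_true) == 0:
        raise ParameterError("need at least one prediction")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[int(t), int(p)] += 1
    return ConfusionMatrix(counts)


def standard_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of exact hits: trace over total."""
    if cm.total == 0:
        raise DegenerateMatrix()
    return float(np.trace(cm.counts)) / cm.total


def one_miss_accuracy(cm: ConfusionMatrix) -> float:
    """Tridiagonal mass over total: exact hits plus hits on an adjacent stage."""
    if cm.total == 0:
        raise DegenerateMatrix()
    i, j = np.indices(cm.counts.shape)
    return float(cm.counts[np.abs(i - j) <= 1].sum()) / cm.total


class DegenerateMatrix(ParameterError):
    def __init__(self) -> None:
        super().__init__("empty confusion matrix")


# ---------------------------------------------------------------------------
# model serialization (npz: config JSON + weight arrays)


def save_model(model: StageClassifier, path) -> None:
    import dataclasses
    import json

    cfg = json.dumps(dataclasses.asdict(model.config))
    arrays = {f"p{i}": p for i, p in enumerate(model.net.params)}
    np.savez(path, config=np.array(cfg), **arrays)


def load_model(path) -> StageClassifier:
    import json

    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(str(data["config"]))
        for key in ("channel_reduction", "groups", "spatial_convs", "fc_widths"):
            cfg[key] = tuple(cfg[key])
        model = StageClassifier(ModelConfig(**cfg))
        for i, p in enumerate(model.net.params):
            p[...] = data[f"p{i}"]
    return model
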