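"""InceptionTime six-command classifier for 2.5-s decode windows.

The network follows the InceptionTime time-series architecture: each
Inception module applies a kernel-1 bottleneck followed by three parallel
convolutions with kernels {5, 11, 23} (32 filters each) plus a
max-pool(3) -> kernel-1 convolution branch; the four branches are
concatenated (128 feature maps), batch-normalized and rectified.  Six blocks
of three modules are used, with a residual shortcut per block, no
ensembling.  The final feature maps are max-pooled over time and a fully
connected layer yields the six class scores; a softmax turns them into
probabilities so the 0.55 registration threshold acts on a bounded scale.

Training uses Adam with cross-entropy loss and selects the model by accuracy
on a held-out day, mirroring the leave-one-day-out validation of the
original system.  Gradient saliency (L1 norm over time of the loss gradient
with respect to the input) exposes per-electrode contributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .detection import DecodeWindow
from .recordings import COMMANDS


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters (defaults follow the reference design)."""

    n_channels: int = 60
    n_frames: int = 250
    n_blocks: int = 6
    modules_per_block: int = 3
    n_filters: int = 32
    kernel_sizes: tuple[int, ...] = (5, 11, 23)
    bottleneck_filters: int = 32
    pool_kernel: int = 3
    n_classes: int = 6
    head_pool: str = "max"  # "max" per the stated head; "avg" switchable
    use_residual: bool = True
    use_batchnorm: bool = True
    classes: tuple[str, ...] = COMMANDS

    def __post_init__(self) -> None:
        if self.head_pool not in ("max", "avg"):
            raise ValueError("head_pool must be 'max' or 'avg'")
        if len(self.classes) != self.n_classes:
            raise ValueError("classes must match n_classes")

    @property
    def module_out_channels(self) -> int:
        return self.n_filters * (len(self.kernel_sizes) + 1)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for decoder training."""

    holdout_day: str
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0


@dataclass(frozen=True)
class DecodeResult:
    """One classification of a decode window."""

    label: str
    score: float
    registered: bool
    peak_time_s: float
    registered_time_s: float


#: Raw-score registration threshold ("at or above 0.55").
REGISTRATION_THRESHOLD = 0.55


class InceptionModule:
    """Bottleneck -> three parallel convs + pool branch -> concat -> BN -> ReLU."""

    def __init__(self, c_in: int, spec: ModelSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        self.bottleneck = nn.Conv1d(c_in, spec.bottleneck_filters, 1, rng, bias=False)
        self.branch_convs = [
            nn.Conv1d(spec.bottleneck_filters, spec.n_filters, k, rng, bias=False)
            for k in spec.kernel_sizes
        ]
        self.pool = nn.MaxPool1d(spec.pool_kernel)
        self.pool_conv = nn.Conv1d(c_in, spec.n_filters, 1, rng, bias=False)
        self.bn = nn.BatchNorm1d(spec.module_out_channels) if spec.use_batchnorm else None
        self.relu = nn.ReLU()
        self.c_out = spec.module_out_channels

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b = self.bottleneck.forward(x, train)
        outs = [conv.forward(b, train) for conv in self.branch_convs]
        outs.append(self.pool_conv.forward(self.pool.forward(x, train), train))
        y = np.concatenate(outs, axis=1)
        if self.bn is not None:
            y = self.bn.forward(y, train)
        return self.relu.forward(y, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.relu.backward(dy)
        if self.bn is not None:
            dy = self.bn.backward(dy)
        nf = self.spec.n_filters
        chunks = [dy[:, i * nf:(i + 1) * nf] for i in range(len(self.branch_convs) + 1)]
        db = sum(
            conv.backward(chunk)
            for conv, chunk in zip(self.branch_convs, chunks[:-1])
        )
        dx = self.bottleneck.backward(db)
        dx += self.pool.backward(self.pool_conv.backward(chunks[-1]))
        return dx

    def layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = [self.bottleneck, *self.branch_convs, self.pool_conv]
        if self.bn is not None:
            out.append(self.bn)
        return out


class InceptionBlock:
    """A run of Inception modules with an optional residual shortcut."""

    def __init__(self, c_in: int, spec: ModelSpec, rng: np.random.Generator) -> None:
        self.modules: list[InceptionModule] = []
        c = c_in
        for _ in range(spec.modules_per_block):
            m = InceptionModule(c, spec, rng)
            self.modules.append(m)
            c = m.c_out
        self.c_out = c
        self.use_residual = spec.use_residual
        if self.use_residual:
            self.short_conv = nn.Conv1d(c_in, c, 1, rng, bias=False)
            self.short_bn = (
                nn.BatchNorm1d(c) if spec.use_batchnorm else None
            )
            self.out_relu = nn.ReLU()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x
        for m in self.modules:
            h = m.forward(h, train)
        if not self.use_residual:
            return h
        s = self.short_conv.forward(x, train)
        if self.short_bn is not None:
            s = self.short_bn.forward(s, train)
        return self.out_relu.forward(h + s, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.use_residual:
            dy = self.out_relu.backward(dy)
            ds = dy
            if self.short_bn is not None:
                ds = self.short_bn.backward(ds)
            dx_short = self.short_conv.backward(ds)
        dh = dy
        for m in reversed(self.modules):
            dh = m.backward(dh)
        if self.use_residual:
            dh = dh + dx_short
        return dh

    def layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for m in self.modules:
            out.extend(m.layers())
        if self.use_residual:
            out.append(self.short_conv)
            if self.short_bn is not None:
                out.append(self.short_bn)
        return out


class InceptionTimeNet:
    """The assembled classifier: blocks -> global pool over time -> linear."""

    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
        self.blocks: list[InceptionBlock] = []
        c = spec.n_channels
        for _ in range(spec.n_blocks):
            b = InceptionBlock(c, spec, rng)
            self.blocks.append(b)
            c = b.c_out
        self.head_pool = nn.GlobalMaxPool() if spec.head_pool == "max" \
            else nn.GlobalAvgPool()
        self.head = nn.Linear(c, spec.n_classes, rng)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[1:] != (self.spec.n_channels, self.spec.n_frames):
            raise ValueError(
                f"input must be (N, {self.spec.n_channels}, {self.spec.n_frames})"
            )
        for b in self.blocks:
            x = b.forward(x, train)
        pooled = self.head_pool.forward(x, train)
        return self.head.forward(pooled, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.head.backward(dlogits)
        d = self.head_pool.backward(d)
        for b in reversed(self.blocks):
            d = b.backward(d)
        return d

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x, train=False))

    # -- parameter plumbing -------------------------------------------------
    def layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for b in self.blocks:
            out.extend(b.layers())
        out.append(self.head)
        return out

    def parameters(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for lyr in self.layers():
            out.extend(lyr.params())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            state[f"p{i}"] = p.value.copy()
        j = 0
        for lyr in self.layers():
            if isinstance(lyr, nn.BatchNorm1d):
                state[f"rm{j}"] = lyr.running_mean.copy()
                state[f"rv{j}"] = lyr.running_var.copy()
                j += 1
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.value[...] = state[f"p{i}"]
        j = 0
        for lyr in self.layers():
            if isinstance(lyr, nn.BatchNorm1d):
                lyr.running_mean[...] = state[f"rm{j}"]
                lyr.running_var[...] = state[f"rv{j}"]
                j += 1

    def save(self, path: str | Path, train_meta: dict | None = None) -> None:
        spec_doc = asdict(self.spec)
        spec_doc["kernel_sizes"] = list(self.spec.kernel_sizes)
        spec_doc["classes"] = list(self.spec.classes)
        np.savez(
            path,
            __spec__=json.dumps(spec_doc),
            __meta__=json.dumps(train_meta or {}),
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path: str | Path) -> "InceptionTimeNet":
        with np.load(path, allow_pickle=False) as f:
            spec_doc = json.loads(str(f["__spec__"]))
            spec_doc["kernel_sizes"] = tuple(spec_doc["kernel_sizes"])
            spec_doc["classes"] = tuple(spec_doc["classes"])
            model = cls(ModelSpec(**spec_doc))
            model.load_state_dict({k: f[k] for k in f.files
                                   if not k.startswith("__")})
        return model


def build_model(spec: ModelSpec | None = None, seed: int = 0) -> InceptionTimeNet:
    """Construct the classifier; deterministic given the seed."""
    return InceptionTimeNet(spec or ModelSpec(), seed=seed)


@dataclass
class TrainReport:
    """Holdout-day validation report for a trained decoder."""

    holdout_day: str
    best_epoch: int
    n_epochs_run: int
    holdout_accuracy: float
    train_accuracy: float
    per_class_accuracy: dict[str, float]
    confusion: np.ndarray  # (n_classes, n_classes), rows = truth
    history: list[float] = field(default_factory=list)  # holdout acc per epoch


def _accuracy(model: InceptionTimeNet, x: np.ndarray, y: np.ndarray,
              batch: int = 64) -> tuple[float, np.ndarray]:
    preds = np.empty(y.shape[0], dtype=int)
    for i in range(0, x.shape[0], batch):
        logits = model.forward(x[i:i + batch], train=False)
        preds[i:i + batch] = logits.argmax(axis=1)
    n_cls = model.spec.n_classes
    conf = np.zeros((n_cls, n_cls), dtype=int)
    np.add.at(conf, (y, preds), 1)
    return float((preds == y).mean()), conf


def train(
    model: InceptionTimeNet,
    trials: Sequence[tuple[DecodeWindow, str, str]],
    cfg: TrainConfig,
) -> TrainReport:
    """Train the decoder, selecting the epoch with best holdout-day accuracy.

    ``trials`` are (window, label, day_id) triples; the whole day named by
    ``cfg.holdout_day`` is withheld as the validation set.  The model is
    left holding the best-epoch parameters.
    """
    classes = model.spec.classes
    cls_index = {c: i for i, c in enumerate(classes)}
    days = {d for _, _, d in trials}
    if len(days) < 2:
        raise ValueError("need at least 2 distinct day_ids")
    if cfg.holdout_day not in days:
        raise ValueError(f"holdout day {cfg.holdout_day!r} absent from trials")
    x = np.stack([w.values for w, _, _ in trials])
    y = np.array([cls_index[lab] for _, lab, _ in trials])
    is_holdout = np.array([d == cfg.holdout_day for _, _, d in trials])
    x_tr, y_tr = x[~is_holdout], y[~is_holdout]
    x_ho, y_ho = x[is_holdout], y[is_holdout]
    missing = set(range(len(classes))) - set(y_tr.tolist())
    if missing:
        names = [classes[i] for i in sorted(missing)]
        raise ValueError(f"classes absent from training split: {names}")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    best_acc, best_epoch, best_state = -1.0, -1, model.state_dict()
    history: list[float] = []
    n = x_tr.shape[0]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            opt.zero_grad()
            logits = model.forward(x_tr[idx], train=True)
            _, dlogits, _ = nn.cross_entropy(logits, y_tr[idx])
            model.backward(dlogits)
            opt.step()
        acc, _ = _accuracy(model, x_ho, y_ho)
        history.append(acc)
        if acc > best_acc:
            best_acc, best_epoch = acc, epoch
            best_state = model.state_dict()
        if epoch - best_epoch >= cfg.patience:
            break
    model.load_state_dict(best_state)
    ho_acc, conf = _accuracy(model, x_ho, y_ho)
    tr_acc, _ = _accuracy(model, x_tr, y_tr)
    row_tot = conf.sum(axis=1)
    per_class = {
        classes[i]: (conf[i, i] / row_tot[i] if row_tot[i] else np.nan)
        for i in range(len(classes))
    }
    return TrainReport(
        holdout_day=cfg.holdout_day,
        best_epoch=best_epoch,
        n_epochs_run=len(history),
        holdout_accuracy=ho_acc,
        train_accuracy=tr_acc,
        per_class_accuracy=per_class,
        confusion=conf,
        history=history,
    )


def classify(
    model: InceptionTimeNet,
    window: DecodeWindow,
    threshold: float = REGISTRATION_THRESHOLD,
    registered_time_s: float | None = None,
) -> DecodeResult:
    """Classify one decode window; registration is inclusive at the threshold.

    Argmax ties break toward the lowest class index.  ``registered_time_s``
    defaults to the moment the window is complete (peak + 0.5 s).
    """
    probs = model.predict_proba(window.values[None])[0]
    idx = int(probs.argmax())
    score = float(probs[idx])
    if registered_time_s is None:
        registered_time_s = window.peak_time_s + 0.5
    return DecodeResult(
        label=model.spec.classes[idx],
        score=score,
        registered=score >= threshold,
        peak_time_s=window.peak_time_s,
        registered_time_s=registered_time_s,
    )


def saliency(
    model: InceptionTimeNet, window: DecodeWindow, target_label: str,
) -> np.ndarray:
    """Per-channel contribution: L1 norm over time of d(loss)/d(input).

    The loss is the cross-entropy of the window against ``target_label``,
    evaluated with the trained (inference-mode) network.
    """
    if target_label not in model.spec.classes:
        raise ValueError(f"unknown label {target_label!r}")
    y = np.array([model.spec.classes.index(target_label)])
    logits = model.forward(window.values[None], train=False)
    _, dlogits, _ = nn.cross_entropy(logits, y)
    dx = model.backward(dlogits)[0]  # (n_channels, n_frames)
    return np.abs(dx).sum(axis=1)
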