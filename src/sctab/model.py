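"""Feature-attention classifier for scRNA-seq profiles, baselines, ensembles.

The network is a single-decision-step TabNet-style architecture adapted to
normalized expression input. The forward pipeline is:

    input batch norm
    -> feature transformer (shared + step-specific GLU blocks)
    -> attention embedding (n_a) -> linear + ghost BN to gene space
    -> row-wise 1.5-entmax  => sparse feature mask on the simplex
    -> mask (*) normalized input
    -> feature transformer (shared blocks reused + second step-specific stack)
    -> decision embedding (n_d) -> ReLU -> linear head -> class logits

Training minimizes class-weighted cross-entropy plus a small entropy penalty
on the mask (lambda_sparse), with AdamW and per-epoch step LR decay, optional
donor-difference augmentation, and early stopping on validation macro F1.
Deep ensembles (members differing only by seed) average member softmax
outputs; 1 - max mean probability is the prediction uncertainty.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import f1_score

from . import autodiff as ag
from .autodiff import Tensor
from .augmentation import AugmentationBank, augment_batch
from .corpus import SplitAssignment
from .io import ExpressionDataset, LabelSpace, NormalizedMatrix, ShardStore, normalize

__all__ = [
    "ScTabConfig", "TrainConfig", "ClassWeights", "TrainedEnsemble",
    "ScTabNetwork", "LinearNetwork", "MLPNetwork", "FittedModel",
    "class_weights", "train", "train_baseline", "train_ensemble",
    "predict_ensemble",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ScTabConfig:
    """Architecture hyperparameters (published defaults)."""

    n_genes: int
    n_classes: int
    n_d: int = 128
    n_a: int = 64
    n_shared: int = 3
    n_independent: int = 5
    n_steps: int = 1
    lambda_sparse: float = 1e-5
    virtual_batch_size: int = 256
    mask_type: str = "entmax"

    def __post_init__(self) -> None:
        if min(self.n_d, self.n_a, self.n_shared, self.n_independent, self.n_steps) < 1:
            raise ValueError("architecture widths/depths must be >= 1")
        if self.mask_type != "entmax":
            raise ValueError("only the entmax mask is supported")


@dataclass
class TrainConfig:
    batch_size: int = 2048
    learning_rate: float = 0.005
    lr_gamma: float = 0.9
    weight_decay: float = 0.05
    optimizer: str = "adamw"
    augment: bool = True
    max_epochs: int = 20
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 < self.lr_gamma <= 1:
            raise ValueError("lr_gamma must be in (0, 1]")


@dataclass
class ClassWeights:
    weights: dict[str, float]

    def as_array(self, label_space: LabelSpace) -> np.ndarray:
        return np.array([self.weights[c] for c in label_space.classes])


def class_weights(labels: list[str], label_space: LabelSpace) -> ClassWeights:
    """Inverse-frequency weights: w_c = n_samples / (n_classes * count_c)."""
    n = len(labels)
    k = label_space.n_classes
    counts = {c: 0 for c in label_space.classes}
    for l in labels:
        counts[l] += 1
    missing = [c for c, v in counts.items() if v == 0]
    if missing:
        raise ValueError(f"classes never observed in labels: {missing}")
    return ClassWeights({c: n / (k * v) for c, v in counts.items()})


# ---------------------------------------------------------------------------
# Network building blocks
# ---------------------------------------------------------------------------

def _init_linear(rng: np.random.Generator, d_in: int, d_out: int) -> tuple[Tensor, Tensor]:
    lim = np.sqrt(6.0 / (d_in + d_out))
    w = Tensor(rng.uniform(-lim, lim, size=(d_in, d_out)), requires_grad=True)
    b = Tensor(np.zeros(d_out), requires_grad=True)
    return w, b


class _GLUBlock:
    """FC to 2*width -> ghost BN -> gated linear unit.

    The FC weights may be shared with another block (TabNet shares the FC
    layers of the "shared" blocks across transformer instances), but every
    block owns its BN: the two uses see different input distributions, so
    shared normalization statistics would be wrong for both.
    """

    def __init__(self, rng, d_in: int, width: int, vbs: int,
                 shared_fc: tuple[Tensor, Tensor] | None = None):
        self.w, self.b = shared_fc if shared_fc is not None else _init_linear(rng, d_in, 2 * width)
        self.owns_fc = shared_fc is None
        self.bn = ag.BatchNorm(2 * width, virtual_batch_size=vbs)

    def parameters(self, include_shared: bool = True):
        fc = [self.w, self.b] if (self.owns_fc or include_shared) else []
        return fc + self.bn.parameters()

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return ag.glu(self.bn(ag.add_bias(ag.matmul(x, self.w), self.b), training))


class _FeatureTransformer:
    """Shared-weight GLU blocks followed by step-specific ones, residual-connected.

    Residual sums after the first block are scaled by sqrt(0.5) to keep
    variance stable through the stack.
    """

    SQRT_HALF = float(np.sqrt(0.5))

    def __init__(self, rng, width: int, shared_fc: list[tuple[Tensor, Tensor]],
                 n_independent: int, vbs: int):
        self.blocks = [
            _GLUBlock(rng, 0, width, vbs, shared_fc=fc) for fc in shared_fc
        ] + [_GLUBlock(rng, width, width, vbs) for _ in range(n_independent)]

    def parameters(self):
        out = []
        for blk in self.blocks:
            out += blk.parameters(include_shared=False)
        return out

    def bn_layers(self):
        return [blk.bn for blk in self.blocks]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        h = None
        for blk in self.blocks:
            if h is None:
                h = blk(x, training)
            else:
                h = ag.scale(ag.add(blk(h, training), h), self.SQRT_HALF)
        return h


class ScTabNetwork:
    """Single-decision-step feature-attention classifier."""

    def __init__(self, cfg: ScTabConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        width = cfg.n_d + cfg.n_a
        vbs = cfg.virtual_batch_size
        self.bn_in = ag.BatchNorm(cfg.n_genes)  # plain BN on the input
        # shared FC weights: first maps genes -> 2*width, rest width -> 2*width
        self.shared_fc = [_init_linear(rng, cfg.n_genes, 2 * width)]
        self.shared_fc += [_init_linear(rng, width, 2 * width) for _ in range(cfg.n_shared - 1)]
        self.ft_attention = _FeatureTransformer(rng, width, self.shared_fc, cfg.n_independent, vbs)
        self.ft_decision = _FeatureTransformer(rng, width, self.shared_fc, cfg.n_independent, vbs)
        self.att_w, self.att_b = _init_linear(rng, cfg.n_a, cfg.n_genes)
        self.att_bn = ag.BatchNorm(cfg.n_genes, virtual_batch_size=vbs)
        self.head_w, self.head_b = _init_linear(rng, cfg.n_d, cfg.n_classes)

    def parameters(self) -> list[Tensor]:
        params = self.bn_in.parameters()
        for w, b in self.shared_fc:
            params += [w, b]
        params += self.ft_attention.parameters() + self.ft_decision.parameters()
        params += [self.att_w, self.att_b] + self.att_bn.parameters()
        params += [self.head_w, self.head_b]
        return params

    def bn_layers(self) -> list[ag.BatchNorm]:
        """All BN layers in forward order (attention pass, then decision pass)."""
        return (
            [self.bn_in]
            + self.ft_attention.bn_layers()
            + [self.att_bn]
            + self.ft_decision.bn_layers()
        )

    def forward(self, x: np.ndarray, training: bool = False) -> tuple[Tensor, Tensor]:
        """Returns (logits, feature mask); mask rows lie on the simplex."""
        if x.shape[1] != self.cfg.n_genes:
            raise ValueError(f"expected {self.cfg.n_genes} genes, got {x.shape[1]}")
        xin = self.bn_in(Tensor(x), training)
        h = self.ft_attention(xin, training)
        a = ag.narrow(h, self.cfg.n_d, self.cfg.n_d + self.cfg.n_a)
        att = self.att_bn(ag.add_bias(ag.matmul(a, self.att_w), self.att_b), training)
        mask = ag.entmax_rows(att)
        masked = ag.mul(mask, xin)
        h2 = self.ft_decision(masked, training)
        d = ag.relu(ag.narrow(h2, 0, self.cfg.n_d))
        logits = ag.add_bias(ag.matmul(d, self.head_w), self.head_b)
        return logits, mask

    def loss(self, x, y, weights) -> tuple[Tensor, Tensor]:
        logits, mask = self.forward(x, training=True)
        ce = ag.weighted_softmax_ce(logits, y, weights)
        sparse = ag.mask_entropy(mask)
        return ag.add(ce, ag.scale(sparse, self.cfg.lambda_sparse)), mask


class LinearNetwork:
    """Multinomial logistic regression: a single weight matrix and bias."""

    def __init__(self, n_genes: int, n_classes: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.w, self.b = _init_linear(rng, n_genes, n_classes)
        self.n_genes, self.n_classes = n_genes, n_classes

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> tuple[Tensor, None]:
        return ag.add_bias(ag.matmul(Tensor(x), self.w), self.b), None

    def loss(self, x, y, weights):
        logits, _ = self.forward(x, training=True)
        return ag.weighted_softmax_ce(logits, y, weights), None

    @property
    def n_parameters(self) -> int:
        return self.w.data.size + self.b.data.size


class MLPNetwork:
    """MLP baseline: n_hidden ReLU layers of hidden_size with dropout."""

    def __init__(self, n_genes: int, n_classes: int, n_hidden: int = 8,
                 hidden_size: int = 128, p_dropout: float = 0.1, seed: int = 0):
        rng = np.random.default_rng(seed)
        dims = [n_genes] + [hidden_size] * n_hidden
        self.layers = [_init_linear(rng, dims[i], dims[i + 1]) for i in range(n_hidden)]
        self.head = _init_linear(rng, hidden_size, n_classes)
        self.p_dropout = p_dropout
        self._rng = np.random.default_rng(seed + 1)
        self.n_genes, self.n_classes = n_genes, n_classes

    def parameters(self):
        out = []
        for w, b in self.layers + [self.head]:
            out += [w, b]
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> tuple[Tensor, None]:
        h = Tensor(x)
        for w, b in self.layers:
            h = ag.relu(ag.add_bias(ag.matmul(h, w), b))
            h = ag.dropout(h, self.p_dropout, self._rng, training)
        return ag.add_bias(ag.matmul(h, self.head[0]), self.head[1]), None

    def loss(self, x, y, weights):
        logits, _ = self.forward(x, training=True)
        return ag.weighted_softmax_ce(logits, y, weights), None


# ---------------------------------------------------------------------------
# Fitted models and training
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    network: object
    label_space: LabelSpace
    gene_ids: list[str]
    target_sum: float
    history: dict = field(default_factory=dict)

    def predict_proba(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        """Softmax probabilities on normalized expression rows."""
        out = []
        for lo in range(0, x.shape[0], batch_size):
            logits, _ = self.network.forward(x[lo:lo + batch_size], training=False)
            out.append(ag.softmax(logits.data))
        return np.vstack(out)

    def predict(self, x: np.ndarray) -> list[str]:
        return self.label_space.decode(self.predict_proba(x).argmax(axis=1))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "FittedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


@dataclass
class TrainedEnsemble:
    members: list[FittedModel]
    label_space: LabelSpace
    config: ScTabConfig | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        for m in self.members:
            if m.label_space != self.label_space:
                raise ValueError("ensemble members disagree on label space")
            if m.gene_ids != self.members[0].gene_ids:
                raise ValueError("ensemble members disagree on gene order")


def _resolve_data(data, split: SplitAssignment | None):
    """Load (normalized values, labels, donor ids) for train and val splits."""
    if isinstance(data, ShardStore):
        data = data.read_all()
    if not isinstance(data, ExpressionDataset):
        raise TypeError(f"cannot train on {type(data)!r}")
    norm = normalize(data)
    labels = data.cell_meta["cell_type"].tolist()
    if split is None:
        tr = np.ones(data.n_cells, dtype=bool)
        va = np.zeros(data.n_cells, dtype=bool)
    else:
        tr = split.cell_mask(data.cell_meta, "train")
        va = split.cell_mask(data.cell_meta, "val")
    return data, norm, labels, tr, va


def recalibrate_bn(
    network,
    x: np.ndarray,
    batch_size: int,
    bank: AugmentationBank | None = None,
    seed: int = 0,
) -> None:
    """Recompute batch-norm running statistics over ``x``.

    Running statistics updated with small exponential momentum are far from
    converged after a short fit on a modest corpus, which would skew every
    eval-mode prediction; a single cumulative-averaging pass over the training
    data fixes them to the statistics the trained weights actually see. When
    the model was trained with augmentation the calibration pass applies the
    same augmentation, so the statistics match the distribution the weights
    were optimized on (the entmax mask is sensitive to input scale).
    """
    layers = network.bn_layers() if hasattr(network, "bn_layers") else []
    if not layers:
        return
    rng = np.random.default_rng(seed)
    # shuffle so chunk statistics match the shuffled batches seen in training:
    # in on-disk order chunks are donor-blocked, which would fold donor
    # structure into the means and hide the between-batch variance
    order = rng.permutation(x.shape[0])
    for bn in layers:
        bn.begin_calibration()
    for lo in range(0, x.shape[0], batch_size):
        xb = x[order[lo:lo + batch_size]]
        if bank is not None:
            xb = augment_batch(xb, bank, rng)
        network.forward(xb, training=True)
    for bn in layers:
        bn.end_calibration()


def _fit(
    network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None,
    y_val: np.ndarray | None,
    weights: np.ndarray,
    tcfg: TrainConfig,
    bank: AugmentationBank | None,
) -> dict:
    """Generic minibatch training loop shared by all architectures."""
    if x_train.shape[0] == 0:
        raise ValueError("training split is empty")
    opt = ag.AdamW(network.parameters(), lr=tcfg.learning_rate, weight_decay=tcfg.weight_decay)
    # separate streams so the batch order is identical with and without
    # augmentation (paired comparisons isolate the augmentation effect)
    order_ss, aug_ss = np.random.SeedSequence(tcfg.seed).spawn(2)
    rng = np.random.default_rng(order_ss)
    rng_aug = np.random.default_rng(aug_ss)
    history = {"train_loss": [], "val_macro_f1": [], "lr": []}
    best_f1, best_state, patience = -np.inf, None, 0
    lr = tcfg.learning_rate

    for epoch in range(tcfg.max_epochs):
        opt.lr = lr
        order = rng.permutation(x_train.shape[0])
        losses = []
        for lo in range(0, len(order), tcfg.batch_size):
            idx = order[lo:lo + tcfg.batch_size]
            xb = x_train[idx]
            if bank is not None and tcfg.augment:
                xb = augment_batch(xb, bank, rng_aug)
            loss, _ = network.loss(xb, y_train[idx], weights)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.data!r}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        history["lr"].append(lr)
        lr *= tcfg.lr_gamma

        if x_val is not None and x_val.shape[0]:
            recalibrate_bn(network, x_train, tcfg.batch_size,
                           bank if tcfg.augment else None, seed=tcfg.seed)
            preds = []
            for vlo in range(0, x_val.shape[0], 4096):
                logits, _ = network.forward(x_val[vlo:vlo + 4096], training=False)
                preds.append(logits.data.argmax(axis=1))
            f1 = f1_score(y_val, np.concatenate(preds), average="macro")
            history["val_macro_f1"].append(float(f1))
            if f1 > best_f1 + 1e-12:
                best_f1, patience = f1, 0
                best_state = [p.data.copy() for p in network.parameters()]
            else:
                patience += 1
                if patience >= tcfg.early_stop_patience:
                    break
    if best_state is not None:
        for p, s in zip(network.parameters(), best_state):
            p.data = s
    recalibrate_bn(network, x_train, tcfg.batch_size,
                   bank if tcfg.augment else None, seed=tcfg.seed)
    return history


def train(
    data: ExpressionDataset | ShardStore,
    split: SplitAssignment | None,
    cfg: ScTabConfig | None = None,
    tcfg: TrainConfig | None = None,
    bank: AugmentationBank | None = None,
) -> FittedModel:
    """Train the feature-attention classifier; see module docstring."""
    tcfg = tcfg or TrainConfig()
    dataset, norm, labels, tr, va = _resolve_data(data, split)
    label_space = LabelSpace.from_labels([l for l, m in zip(labels, tr) if m] or labels)
    y = label_space.encode(labels)
    if cfg is None:
        cfg = ScTabConfig(n_genes=dataset.n_genes, n_classes=label_space.n_classes)
    w = class_weights([labels[i] for i in np.flatnonzero(tr)], label_space).as_array(label_space)
    network = ScTabNetwork(cfg, seed=tcfg.seed)
    history = _fit(network, norm.values[tr], y[tr], norm.values[va], y[va], w, tcfg, bank)
    return FittedModel(network, label_space, list(dataset.gene_ids), norm.target_sum, history)


def train_baseline(
    kind: str,
    data: ExpressionDataset | ShardStore,
    split: SplitAssignment | None,
    tcfg: TrainConfig | None = None,
    bank: AugmentationBank | None = None,
) -> FittedModel:
    """Train the linear or MLP reference model with its published defaults."""
    if kind not in ("linear", "mlp"):
        raise ValueError(f"unknown baseline {kind!r}")
    if tcfg is None:
        tcfg = (
            TrainConfig(learning_rate=0.0005, weight_decay=0.01, augment=False)
            if kind == "linear"
            else TrainConfig(learning_rate=0.002, weight_decay=0.05)
        )
    dataset, norm, labels, tr, va = _resolve_data(data, split)
    label_space = LabelSpace.from_labels([l for l, m in zip(labels, tr) if m] or labels)
    y = label_space.encode(labels)
    w = class_weights([labels[i] for i in np.flatnonzero(tr)], label_space).as_array(label_space)
    if kind == "linear":
        network = LinearNetwork(dataset.n_genes, label_space.n_classes, seed=tcfg.seed)
    else:
        network = MLPNetwork(dataset.n_genes, label_space.n_classes, seed=tcfg.seed)
    history = _fit(network, norm.values[tr], y[tr], norm.values[va], y[va], w, tcfg, bank)
    return FittedModel(network, label_space, list(dataset.gene_ids), norm.target_sum, history)


def train_ensemble(
    data,
    split,
    cfg: ScTabConfig | None = None,
    tcfg: TrainConfig | None = None,
    bank: AugmentationBank | None = None,
    n_members: int = 5,
) -> TrainedEnsemble:
    """Deep ensemble: members identical except for the random seed."""
    tcfg = tcfg or TrainConfig()
    members = []
    for k in range(n_members):
        member_cfg = TrainConfig(**{**asdict(tcfg), "seed": tcfg.seed + k})
        members.append(train(data, split, cfg=cfg, tcfg=member_cfg, bank=bank))
    return TrainedEnsemble(members=members, label_space=members[0].label_space,
                           config=cfg)


def predict_ensemble(
    ensemble: TrainedEnsemble, x: NormalizedMatrix | np.ndarray
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Average member probabilities; uncertainty = 1 - max mean probability."""
    xv = x.values if isinstance(x, NormalizedMatrix) else np.asarray(x)
    probs = np.mean([m.predict_proba(xv) for m in ensemble.members], axis=0)
    labels = ensemble.label_space.decode(probs.argmax(axis=1))
    uncertainty = 1.0 - probs.max(axis=1)
    return labels, probs, uncertainty
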