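"""Losses and the iterative four-step adversarial training procedure.

Per mini-batch the trainer runs:

A. update the generator G (extractor + both attentions) and both heads
   C1/C2 to minimize the source cross-entropy;
B. with G fixed, update the domain discriminator D on the binary
   source(1)/target(0) task, then update G to fool the (now fixed) D via
   flipped-label cross-entropy;
C. with G fixed, update C1/C2 to minimize source cross-entropy MINUS the
   target discrepancy — the heads maximize their disagreement on target
   samples while staying accurate on the source;
D. with the heads and D fixed, update G to minimize the target
   discrepancy, repeated ``n_gen_steps`` times.

The discrepancy between the two heads is the mean L1 distance of their
softmax rows, d(p1, p2) = (1/K) Σ_k |p1k - p2k|, bounded by 2/K. Steps C/D
implement the maximum-classifier-discrepancy game: the heads sweep their
decision boundaries apart over ambiguous target features and the generator
pulls those features back inside the source support.

Target labels never enter any loss: the trainer strips them on entry and
every loss signature is label-free for the target domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import nn
from .io_preprocess import EpochedRecording
from .metrics import evaluate
from .model import ModelConfig, TDSANModel, classify, discriminate, generate, predict
from .nn import Adam, Tensor

EPS = 1e-7  # probability clamp for log terms

__all__ = [
    "TrainConfig",
    "LossRecord",
    "discrepancy",
    "source_classification_loss",
    "domain_loss",
    "adv_discrepancy_loss",
    "generator_confusion_loss",
    "train_minibatch",
    "fit",
    "fit_source_only",
    "split_train_test",
    "adaptation_experiment",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Hyperparameters; defaults are the published settings where stated."""

    batch_size: int = 128
    lr: float = 1e-3
    optimizer: str = "adam"
    max_epochs: int = 10
    n_gen_steps: int = 4  # the trade-off parameter n; repeats of step D
    k: int = 5
    seed: int = 0
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)  # five-run protocol
    device: str = "cpu"
    train_frac: float = 0.8
    pretrain_each_batch: bool = True  # run step A inside every mini-batch
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if self.n_gen_steps < 1:
            raise ValueError("n_gen_steps must be >= 1")
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is supported")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["seeds"] = list(self.seeds)
        return yaml.safe_dump(d)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        d = yaml.safe_load(text) or {}
        if "model" in d and isinstance(d["model"], dict):
            m = d["model"]
            for key in ("conv_channels", "conv_kernels", "pool_sizes", "fc_sizes"):
                if key in m:
                    m[key] = tuple(m[key])
            d["model"] = ModelConfig(**m)
        if "seeds" in d:
            d["seeds"] = tuple(d["seeds"])
        return cls(**d)


@dataclass
class LossRecord:
    """Per-mini-batch training telemetry."""

    cls_loss: list[float] = field(default_factory=list)
    domain_loss: list[float] = field(default_factory=list)
    discrepancy: list[float] = field(default_factory=list)
    gen_adv: list[float] = field(default_factory=list)
    epoch: list[int] = field(default_factory=list)

    def append(self, epoch: int, cls: float, dom: float, disc: float, gen: float):
        for name, v in (("cls_loss", cls), ("domain_loss", dom),
                        ("discrepancy", disc), ("gen_adv", gen)):
            if not np.isfinite(v):
                raise FloatingPointError(f"non-finite {name} at epoch {epoch}")
        self.epoch.append(epoch)
        self.cls_loss.append(cls)
        self.domain_loss.append(dom)
        self.discrepancy.append(disc)
        self.gen_adv.append(gen)

    def __len__(self) -> int:
        return len(self.epoch)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _rows_on_simplex(p: np.ndarray, tol: float = 1e-4) -> None:
    sums = p.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > tol) or np.any(p < -tol):
        raise ValueError("probability rows must lie on the simplex")


def discrepancy(p1, p2) -> Tensor:
    """Mean over rows of (1/K) Σ_k |p1k - p2k|; differentiable."""
    t1 = p1 if isinstance(p1, Tensor) else Tensor(np.atleast_2d(p1))
    t2 = p2 if isinstance(p2, Tensor) else Tensor(np.atleast_2d(p2))
    _rows_on_simplex(t1.data)
    _rows_on_simplex(t2.data)
    k = t1.data.shape[-1]
    return (t1 - t2).abs().sum(axis=-1).mean() * (1.0 / k)


def _cross_entropy(probs: Tensor, y: np.ndarray) -> Tensor:
    """Cross-entropy from probability rows (clamped log)."""
    onehot = np.eye(probs.data.shape[1], dtype=np.float32)[y]
    logp = nn.log(nn.clip(probs, EPS, 1.0))
    return -(Tensor(onehot) * logp).sum(axis=1).mean()


def _cross_entropy_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Same value via log-softmax; gradients survive softmax saturation."""
    onehot = np.eye(logits.data.shape[1], dtype=np.float32)[y]
    return -(Tensor(onehot) * nn.log_softmax(logits, axis=1)).sum(axis=1).mean()


def source_classification_loss(x_s, y_s, model: TDSANModel,
                               feat: Tensor | None = None) -> Tensor:
    """Cross-entropy of both heads against the source labels, averaged."""
    y = np.asarray(y_s, dtype=np.int64)
    if y.min() < 0 or y.max() >= model.cfg.n_classes:
        raise ValueError(f"labels must lie in 0..{model.cfg.n_classes - 1}")
    if feat is None:
        feat = generate(x_s, "source", model)
    l1 = _cross_entropy_logits(model.C1.logits(feat), y)
    l2 = _cross_entropy_logits(model.C2.logits(feat), y)
    return (l1 + l2) * 0.5


def _binary_ce(p_source: Tensor, y: np.ndarray) -> Tensor:
    p = nn.clip(p_source, EPS, 1.0 - EPS)
    yt = Tensor(y.astype(np.float32))
    return -(yt * nn.log(p) + (1.0 - yt) * nn.log(1.0 - p)).mean()


def _source_prob(feat: Tensor, model: TDSANModel) -> Tensor:
    # column 1 of the discriminator softmax = probability of "source"
    return (discriminate(feat, model) * Tensor(np.array([0.0, 1.0], np.float32))).sum(axis=1)


def _domain_ce(feat: Tensor, model: TDSANModel, domain_label: int) -> Tensor:
    """BCE of D's source-probability against a constant domain label.

    Computed from the discriminator logits (two-class log-softmax), which
    equals -[y log ŷ + (1-y) log(1-ŷ)] with ŷ the softmax source column.
    """
    n = feat.data.shape[0]
    y = np.full(n, domain_label, dtype=np.int64)
    return _cross_entropy_logits(model.D.logits(feat), y)


def domain_loss(feat_s: Tensor, feat_t: Tensor, model: TDSANModel) -> Tensor:
    """Binary cross-entropy of D: source rows labeled 1, target rows 0."""
    ns, nt = feat_s.data.shape[0], feat_t.data.shape[0]
    if ns == 0 or nt == 0:
        raise ValueError("both domains must contribute a non-empty batch")
    loss_s = _domain_ce(feat_s, model, 1)
    loss_t = _domain_ce(feat_t, model, 0)
    return (loss_s * ns + loss_t * nt) * (1.0 / (ns + nt))


def adv_discrepancy_loss(x_t, model: TDSANModel, feat: Tensor | None = None) -> Tensor:
    """Mean discrepancy of the two heads on (unlabeled) target samples."""
    if feat is None:
        feat = generate(x_t, "target", model)
    return discrepancy(classify(feat, "C1", model), classify(feat, "C2", model))


def generator_confusion_loss(feat_s: Tensor, feat_t: Tensor, model: TDSANModel) -> Tensor:
    """Domain BCE with flipped labels (source->0, target->1); fools a fixed D."""
    ns, nt = feat_s.data.shape[0], feat_t.data.shape[0]
    loss_s = _domain_ce(feat_s, model, 0)
    loss_t = _domain_ce(feat_t, model, 1)
    return (loss_s * ns + loss_t * nt) * (1.0 / (ns + nt))


# ---------------------------------------------------------------------------
# Training steps
# ---------------------------------------------------------------------------

class _Optimizers:
    def __init__(self, model: TDSANModel, cfg: TrainConfig):
        self.g = Adam(model.generator_params(), lr=cfg.lr)
        self.c = Adam(model.classifier_params(), lr=cfg.lr)
        self.d = Adam(model.discriminator_params(), lr=cfg.lr)

    def zero_all(self):
        self.g.zero_grad()
        self.c.zero_grad()
        self.d.zero_grad()


def _step(loss: Tensor, opts: _Optimizers, update: list[Adam], step_name: str) -> float:
    if not np.isfinite(loss.data):
        raise FloatingPointError(f"non-finite loss in step {step_name}")
    opts.zero_all()
    loss.backward()
    for opt in update:
        opt.step()
    return loss.item()


def train_minibatch(batch_s, y_s, batch_t, model: TDSANModel, cfg: TrainConfig,
                    opts: _Optimizers | None = None) -> dict[str, float]:
    """One pass of the four adversarial steps on a paired mini-batch."""
    opts = opts or _Optimizers(model, cfg)
    model.set_training(True)

    # A: pretrain generator + heads on labeled source
    cls = 0.0
    if cfg.pretrain_each_batch:
        cls = _step(source_classification_loss(batch_s, y_s, model),
                    opts, [opts.g, opts.c], "A")

    # B1: discriminator on fixed G (detached features)
    fs = generate(batch_s, "source", model).detach()
    ft = generate(batch_t, "target", model).detach()
    dom = _step(domain_loss(fs, ft, model), opts, [opts.d], "B1")
    # B2: generator fools the fixed discriminator (fresh graph through G)
    fs2 = generate(batch_s, "source", model)
    ft2 = generate(batch_t, "target", model)
    gen_adv = _step(generator_confusion_loss(fs2, ft2, model), opts, [opts.g], "B2")

    # C: heads maximize target discrepancy subject to source accuracy (G fixed)
    fs3 = generate(batch_s, "source", model).detach()
    ft3 = generate(batch_t, "target", model).detach()
    loss_c = source_classification_loss(batch_s, y_s, model, feat=fs3) \
        - adv_discrepancy_loss(batch_t, model, feat=ft3)
    _step(loss_c, opts, [opts.c], "C")

    # D: generator minimizes the discrepancy, n times (heads and D fixed)
    disc = 0.0
    for _ in range(cfg.n_gen_steps):
        disc = _step(adv_discrepancy_loss(batch_t, model), opts, [opts.g], "D")

    return {"cls_loss": cls, "domain_loss": dom, "discrepancy": disc,
            "gen_adv": gen_adv}


def split_train_test(rec: EpochedRecording, train_frac: float = 0.8
                     ) -> tuple[EpochedRecording, EpochedRecording]:
    """Ordered 80/20 split — epoch order is never shuffled."""
    n = len(rec)
    cut = int(round(n * train_frac))
    return (
        EpochedRecording(rec.epochs[:cut], rec.labels[:cut], rec.rate),
        EpochedRecording(rec.epochs[cut:], rec.labels[cut:], rec.rate),
    )


def _batches(rng: np.random.Generator, n_s: int, n_t: int, batch: int):
    """Paired mini-batch index streams, cycled to equal length per epoch."""
    perm_s = rng.permutation(n_s)
    perm_t = rng.permutation(n_t)
    nb = max(int(np.ceil(n_s / batch)), int(np.ceil(n_t / batch)), 1)
    for b in range(nb):
        idx_s = np.take(perm_s, np.arange(b * batch, (b + 1) * batch), mode="wrap")
        idx_t = np.take(perm_t, np.arange(b * batch, (b + 1) * batch), mode="wrap")
        yield idx_s[: min(batch, n_s)], idx_t[: min(batch, n_t)]


def fit(source: EpochedRecording, target: EpochedRecording, cfg: TrainConfig,
        ) -> tuple[TDSANModel, LossRecord]:
    """Train TDSAN on a labeled source and an *unlabeled* target domain.

    Target labels, if present on `target`, are discarded on entry and can
    never reach a loss (the target-side loss signatures take no labels).
    Both domains are split 80/20 in recording order; only the training
    splits are used here.
    """
    x_t_all = target.epochs  # labels stripped: only the signal is kept
    n_t = x_t_all.shape[0]
    cut_t = int(round(n_t * cfg.train_frac))
    x_t = x_t_all[:cut_t]

    src_train, _ = split_train_test(source, cfg.train_frac)
    rng = np.random.default_rng(cfg.seed)
    model = TDSANModel(cfg.model, seed=int(rng.integers(2**31)))
    opts = _Optimizers(model, cfg)
    record = LossRecord()

    for epoch in range(cfg.max_epochs):
        for idx_s, idx_t in _batches(rng, len(src_train), x_t.shape[0], cfg.batch_size):
            losses = train_minibatch(
                src_train.epochs[idx_s], src_train.labels[idx_s],
                x_t[idx_t], model, cfg, opts,
            )
            record.append(epoch, losses["cls_loss"], losses["domain_loss"],
                          losses["discrepancy"], losses["gen_adv"])
    model.set_training(False)
    return model, record


def fit_source_only(source: EpochedRecording, cfg: TrainConfig
                    ) -> tuple[TDSANModel, LossRecord]:
    """Direct-transfer baseline: source cross-entropy only, no adaptation."""
    src_train, _ = split_train_test(source, cfg.train_frac)
    rng = np.random.default_rng(cfg.seed)
    model = TDSANModel(cfg.model, seed=int(rng.integers(2**31)))
    opts = _Optimizers(model, cfg)
    record = LossRecord()
    model.set_training(True)
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(src_train))
        for b in range(int(np.ceil(len(src_train) / cfg.batch_size))):
            idx = perm[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            cls = _step(
                source_classification_loss(src_train.epochs[idx],
                                           src_train.labels[idx], model),
                opts, [opts.g, opts.c], "A",
            )
            record.append(epoch, cls, 0.0, 0.0, 0.0)
    model.set_training(False)
    return model, record


def adaptation_experiment(source: EpochedRecording, target: EpochedRecording,
                          cfg: TrainConfig) -> dict:
    """Fit TDSAN and the direct-transfer baseline; score the target test split.

    Target labels are used *only* to compute the evaluation reports.
    """
    y_target_test = split_train_test(target, cfg.train_frac)[1].labels
    x_target_test = split_train_test(target, cfg.train_frac)[1].epochs

    model, record = fit(source, target, cfg)
    pred_da = predict(x_target_test, "target", model)
    rep_da = evaluate(y_target_test, pred_da, k=cfg.k)

    base, _ = fit_source_only(source, cfg)
    pred_dt = predict(x_target_test, "source", base)
    rep_dt = evaluate(y_target_test, pred_dt, k=cfg.k)

    return {
        "tdsan": rep_da,
        "direct_transfer": rep_dt,
        "gain": rep_da.acc - rep_dt.acc,
        "record": record,
        "model": model,
    }


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: TDSANModel, cfg: TrainConfig) -> None:
    """Single-archive checkpoint: all five parameter groups + the config."""
    arrays = model.state_arrays()
    np.savez(path, __config__=np.frombuffer(cfg.to_yaml().encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple[TDSANModel, TrainConfig]:
    with np.load(path) as z:
        cfg = TrainConfig.from_yaml(bytes(z["__config__"]).decode())
        model = TDSANModel(cfg.model, seed=0)
        model.load_state_arrays({k: z[k] for k in z.files if k != "__config__"})
    model.set_training(False)
    return model, cfg
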