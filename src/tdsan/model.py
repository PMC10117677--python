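"""TDSAN network: shared CNN feature extractor, per-domain (unshared)
convolutional self-attention, dual stage classifiers and a domain
discriminator.

Architecture (default widths)::

    input (B, 1, 3000)                       one 30-s epoch at 100 Hz
      Conv1d k=25 -> 32  + BN + leakyReLU + MaxPool 2   -> (B, 32, 1500)
      Conv1d k=8  -> 64  + BN + leakyReLU + MaxPool 3   -> (B, 64, 500)
      Conv1d k=8  -> 128 + BN + leakyReLU + MaxPool 3   -> (B, 128, 166)
    attention (per domain, kernel-1 query/key convs, residual gate gamma)
    flatten -> 21248
    classifier C1/C2: FC 1024 -> FC 512 -> FC 5 (softmax)
    discriminator D:  FC 1024 -> FC 512 -> FC 2 (softmax, index 1 = source)

Convolutions are stride-1 with zero "same" padding, so max pooling is the
only down-sampler and the temporal length is 3000 // 2 // 3 // 3 = 166.
C1 and C2 share the architecture but are initialized from independent random
streams so their decision boundaries differ; the source and target attention
modules are likewise independent instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

N_CLASSES = 5  #: W, N1, N2, N3, REM

__all__ = [
    "ModelConfig",
    "TDSANModel",
    "FeatureExtractor",
    "DomainAttention",
    "MLPHead",
    "feature_extract",
    "attention_forward",
    "generate",
    "classify",
    "discriminate",
    "predict",
]


@dataclass
class ModelConfig:
    """Widths and shapes of the network.

    Defaults follow the published architecture; narrower settings are used
    for fast CPU-scale experiments (see :func:`ModelConfig.reduced`).
    """

    input_len: int = 3000
    conv_channels: tuple[int, int, int] = (32, 64, 128)
    conv_kernels: tuple[int, int, int] = (25, 8, 8)
    pool_sizes: tuple[int, int, int] = (2, 3, 3)
    fc_sizes: tuple[int, int] = (1024, 512)
    n_classes: int = N_CLASSES
    leaky_slope: float = 0.1
    attn_ratio: int = 8  # query/key channels = conv_channels[-1] // attn_ratio

    @property
    def feature_len(self) -> int:
        l = self.input_len
        for p in self.pool_sizes:
            l //= p
        return l

    @property
    def flat_dim(self) -> int:
        return self.conv_channels[-1] * self.feature_len

    @classmethod
    def reduced(cls) -> "ModelConfig":
        """A narrow variant for CPU-scale training experiments."""
        return cls(conv_channels=(4, 8, 16), fc_sizes=(64, 32))


class FeatureExtractor(nn.Module):
    """Three Conv1d -> BatchNorm -> leaky-ReLU -> MaxPool blocks."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        chans = (1,) + cfg.conv_channels
        self.convs = [
            nn.Conv1d(chans[i], chans[i + 1], cfg.conv_kernels[i], rng)
            for i in range(3)
        ]
        self.bns = [nn.BatchNorm1d(c) for c in cfg.conv_channels]
        self.pools = [nn.MaxPool1d(p) for p in cfg.pool_sizes]
        self.act = nn.LeakyReLU(cfg.leaky_slope)

    def __call__(self, x: Tensor) -> Tensor:
        for conv, bn, pool in zip(self.convs, self.bns, self.pools):
            x = pool(self.act(bn(conv(x))))
        return x


class DomainAttention(nn.Module):
    """Convolutional self-attention over temporal positions of a feature map.

    Two kernel-1 convolutions M1, M2 project each position's feature vector
    to query/key space; the attention weight of output position y on input
    position x is softmax over x of M1(p_x)·M2(p_y) (un-scaled dot product).
    The context vectors are folded back through a learnable residual gate
    initialized at zero, so a fresh module is the identity map.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.conv_channels[-1]
        dq = max(1, d // cfg.attn_ratio)
        self.m1 = nn.Conv1d(d, dq, 1, rng)
        self.m2 = nn.Conv1d(d, dq, 1, rng)
        self.gamma = nn.Parameter(np.zeros(1, dtype=np.float32))

    def __call__(self, fm: Tensor) -> Tensor:
        q1 = self.m1(fm)  # (B, dq, L) keys, indexed by x
        q2 = self.m2(fm)  # (B, dq, L) queries, indexed by y
        # scores[b, y, x] = q1[b,:,x] . q2[b,:,y]
        scores = q2.transpose(0, 2, 1) @ q1
        w = nn.softmax(scores, axis=2)  # rows over x sum to 1
        o = fm @ w.transpose(0, 2, 1)  # o[b,:,y] = sum_x w[y,x] fm[b,:,x]
        return fm + self.gamma * o

    def weights(self, fm: Tensor) -> np.ndarray:
        """Attention matrix (B, L, L), rows (axis 2) normalized over x."""
        q1 = self.m1(fm)
        q2 = self.m2(fm)
        return nn.softmax(q2.transpose(0, 2, 1) @ q1, axis=2).data


class MLPHead(nn.Module):
    """FC stack fc_sizes -> n_out with leaky-ReLU hidden activations."""

    def __init__(self, cfg: ModelConfig, n_out: int, rng: np.random.Generator):
        dims = (cfg.flat_dim,) + cfg.fc_sizes + (n_out,)
        self.fcs = [nn.Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        self.act = nn.LeakyReLU(cfg.leaky_slope)

    def logits(self, x: Tensor) -> Tensor:
        for fc in self.fcs[:-1]:
            x = self.act(fc(x))
        return self.fcs[-1](x)

    def __call__(self, x: Tensor) -> Tensor:
        return nn.softmax(self.logits(x), axis=1)


class TDSANModel(nn.Module):
    """Parameter container for the five network components.

    ``F`` (shared extractor), ``A_s``/``A_t`` (unshared domain attentions),
    ``C1``/``C2`` (dual classifiers), ``D`` (domain discriminator).
    """

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        self.cfg = cfg or ModelConfig()
        root = np.random.default_rng(seed)
        # independent init streams: C1 and C2 must differ, A_s and A_t too
        seeds = root.integers(0, 2**31 - 1, size=6)
        self.F = FeatureExtractor(self.cfg, np.random.default_rng(seeds[0]))
        self.A_s = DomainAttention(self.cfg, np.random.default_rng(seeds[1]))
        self.A_t = DomainAttention(self.cfg, np.random.default_rng(seeds[2]))
        self.C1 = MLPHead(self.cfg, self.cfg.n_classes, np.random.default_rng(seeds[3]))
        self.C2 = MLPHead(self.cfg, self.cfg.n_classes, np.random.default_rng(seeds[4]))
        self.D = MLPHead(self.cfg, 2, np.random.default_rng(seeds[5]))
        # flatten-dimension consistency between generate() and the FC heads
        assert self.C1.fcs[0].weight.shape[0] == self.cfg.flat_dim

    # parameter groups for the optimizers
    def generator_params(self):
        return self.F.parameters() + self.A_s.parameters() + self.A_t.parameters()

    def classifier_params(self):
        return self.C1.parameters() + self.C2.parameters()

    def discriminator_params(self):
        return self.D.parameters()

    def attention(self, domain: str) -> DomainAttention:
        if domain == "source":
            return self.A_s
        if domain == "target":
            return self.A_t
        raise ValueError(f"unknown domain {domain!r}; expected 'source' or 'target'")


def _check_batch(x: np.ndarray | Tensor, input_len: int) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
    if t.data.ndim != 3 or t.data.shape[1] != 1 or t.data.shape[2] != input_len:
        raise ValueError(
            f"expected epoch batch of shape (batch, 1, {input_len}), got {t.data.shape}"
        )
    return t


def feature_extract(x, model: TDSANModel) -> Tensor:
    """Run the shared CNN extractor; (B, 1, T) -> (B, C, L)."""
    return model.F(_check_batch(x, model.cfg.input_len))


def attention_forward(fm: Tensor, params: DomainAttention) -> Tensor:
    """Apply one domain's self-attention; shape-preserving."""
    return params(fm)


def generate(x, domain: str, model: TDSANModel) -> Tensor:
    """Full generator G = A_domain(F(x)), flattened to (B, C*L)."""
    attn = model.attention(domain)
    fm = attention_forward(feature_extract(x, model), attn)
    b = fm.data.shape[0]
    return fm.reshape(b, model.cfg.flat_dim)


def classify(feat: Tensor, head: str, model: TDSANModel) -> Tensor:
    """Class probabilities from one of the dual heads ('C1' or 'C2')."""
    if head not in ("C1", "C2"):
        raise ValueError(f"unknown head {head!r}; expected 'C1' or 'C2'")
    return getattr(model, head)(feat)


def discriminate(feat: Tensor, model: TDSANModel) -> Tensor:
    """Domain probabilities (B, 2); column 1 is the source domain."""
    return model.D(feat)


def predict(x, domain: str, model: TDSANModel) -> np.ndarray:
    """Predicted stage labels: argmax of the mean of the two heads' rows.

    Ties break to the lower class index (numpy argmax convention).
    """
    model.set_training(False)
    feat = generate(np.asarray(x, dtype=np.float32), domain, model)
    p = 0.5 * (classify(feat, "C1", model).data + classify(feat, "C2", model).data)
    return p.argmax(axis=1)
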