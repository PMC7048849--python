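"""The image modality translation core: a conditional adversarial
image-to-image network with an L1 reconstruction term.

Generator G is a U-Net (8 convolutional encoder layers, 8 deconvolutional
decoder layers, mirrored skip connections, tanh head); discriminator D is a
patch classifier (four 4x4 convolution stages plus a stride-1 sigmoid head,
70x70 receptive field) scoring (condition, candidate) pairs.  Training
alternates one D step and one G step per sample with Adam (lr 2e-4,
beta1 0.5), batch size 1 — the batch-normalization layers then behave as
instance normalization.  The loss is

    L = L_cGAN(G, D) + lambda * L_L1(G),        lambda = 100 by default,

with variants selecting the adversarial term alone ("cGAN"), the L1 term
alone ("L1", an ordinary least-absolute-deviation CNN), or both.  The noise
input z is realized as dropout in the first decoder stages, active at both
training and inference time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .nn import Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Module, Tensor
from .nn import autograd as ag
from .synthio import ImageSlice, LabelMap, LandmarkSet

__all__ = [
    "PairedSample",
    "GeneratorSpec",
    "DiscriminatorSpec",
    "TrainConfig",
    "TrainedTranslator",
    "UNetGenerator",
    "PatchDiscriminator",
    "build_generator",
    "build_discriminator",
    "receptive_field",
    "receptive_field_probe",
    "loss_cgan",
    "loss_l1",
    "total_objective",
    "train",
    "translate",
]

LOSS_MODES = ("cGAN", "L1", "cGAN+L1")


@dataclass
class PairedSample:
    """An aligned (given-modality, target-modality) slice pair."""

    given: ImageSlice
    target: ImageSlice
    label: LabelMap | None = None
    landmarks: LandmarkSet | None = None

    def __post_init__(self):
        if self.given.pixels.shape != self.target.pixels.shape:
            raise ValueError("paired slices must share shape")


@dataclass
class GeneratorSpec:
    """U-Net layer widths; the defaults are the full-size architecture.

    ``decoder_filters`` records the input width of each deconvolution stage
    (the values the skip concatenations produce); it is derived from
    ``encoder_filters`` and validated, not free."""

    encoder_filters: tuple[int, ...] = (64, 128, 256, 512, 512, 512, 512, 512)
    decoder_filters: tuple[int, ...] = (512, 1024, 1024, 1024, 1024, 512, 256, 128)
    leaky_slope: float = 0.2
    dropout_layers: tuple[int, ...] = (0, 1, 2)
    dropout_rate: float = 0.5
    skip_connections: bool = True

    def __post_init__(self):
        derived = self.derived_decoder_filters()
        if tuple(self.decoder_filters) != derived:
            raise ValueError(
                f"decoder_filters {self.decoder_filters} inconsistent with "
                f"encoder mirror {derived}")

    @property
    def depth(self) -> int:
        return len(self.encoder_filters)

    @property
    def min_side(self) -> int:
        return 2 ** self.depth

    def derived_decoder_filters(self) -> tuple[int, ...]:
        """Input channel widths of the deconv stages for a mirrored U-Net
        with skip concatenation."""
        e = self.encoder_filters
        d = len(e)
        widths = [e[-1]]
        out = list(e[-2::-1])  # deconv output widths for stages 0..d-2
        for i in range(1, d):
            if self.skip_connections:
                widths.append(out[i - 1] + e[d - 1 - i])
            else:
                widths.append(out[i - 1])
        return tuple(widths)

    @classmethod
    def scaled(cls, depth: int = 4, divide: int = 8) -> "GeneratorSpec":
        """Reduced test-size network: first ``depth`` encoder widths of the
        full architecture divided by ``divide``."""
        full = (64, 128, 256, 512, 512, 512, 512, 512)
        enc = tuple(f // divide for f in full[:depth])
        spec = cls.__new__(cls)
        object.__setattr__(spec, "encoder_filters", enc)
        object.__setattr__(spec, "leaky_slope", 0.2)
        # dropout stages scale with depth (the full net noises 3 of 8)
        n_drop = max(1, (3 * depth) // 8)
        object.__setattr__(spec, "dropout_layers", tuple(range(n_drop)))
        object.__setattr__(spec, "dropout_rate", 0.5)
        object.__setattr__(spec, "skip_connections", True)
        object.__setattr__(spec, "decoder_filters", spec.derived_decoder_filters())
        return spec


@dataclass
class DiscriminatorSpec:
    """Patch discriminator: four conv-BatchNorm-ReLU stages (kernel 4) plus
    a stride-1 sigmoid head; default strides give a 70-pixel receptive
    field."""

    filters: tuple[int, ...] = (64, 128, 256, 512)
    kernel: int = 4
    strides: tuple[int, ...] = (2, 2, 2, 1)

    def __post_init__(self):
        if len(self.filters) != len(self.strides):
            raise ValueError("one stride per stage required")

    def layers(self) -> list[tuple[int, int]]:
        """(kernel, stride) per conv layer, head included."""
        return [(self.kernel, s) for s in self.strides] + [(self.kernel, 1)]

    @classmethod
    def scaled(cls, divide: int = 8) -> "DiscriminatorSpec":
        """Reduced test-size discriminator; kernels and strides (hence the
        70-pixel receptive field) are unchanged."""
        return cls(filters=tuple(f // divide for f in (64, 128, 256, 512)))


@dataclass
class TrainConfig:
    lambda_l1: float = 100.0
    lr: float = 2e-4
    beta1: float = 0.5
    batch_size: int = 1
    epochs: int = 1
    seed: int = 0
    loss_mode: str = "cGAN+L1"
    image_side: int = 256

    def __post_init__(self):
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"loss_mode must be one of {LOSS_MODES}")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class UNetGenerator(Module):
    """Encoder-decoder with mirrored skip connections and a tanh head."""

    def __init__(self, spec: GeneratorSpec, side: int, seed: int = 0):
        if side % (2 ** spec.depth) != 0 or side < spec.min_side:
            raise ValueError(
                f"side {side} incompatible with depth {spec.depth}; "
                f"minimum (and granularity) is {spec.min_side}")
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.side = side
        e = spec.encoder_filters
        d = spec.depth
        self.enc_convs, self.enc_bns = [], []
        cin = 1
        for f in e:
            self.enc_convs.append(Conv2d(cin, f, 4, 2, 1, rng))
            self.enc_bns.append(BatchNorm2d(f, rng))
            cin = f
        self.dec_convs, self.dec_bns = [], []
        widths = spec.derived_decoder_filters()
        outs = list(e[-2::-1]) + [1]
        for i in range(d):
            self.dec_convs.append(ConvTranspose2d(widths[i], outs[i], 4, 2, 1, rng))
            if i < d - 1:
                self.dec_bns.append(BatchNorm2d(outs[i], rng))

    def forward(self, x: Tensor, train: bool, rng: np.random.Generator,
                dropout_active: bool = True) -> Tensor:
        spec = self.spec
        skips = []
        h = x
        for conv, bn in zip(self.enc_convs, self.enc_bns):
            h = ag.leaky_relu(bn(conv(h), train), spec.leaky_slope)
            skips.append(h)
        d = spec.depth
        for i, conv in enumerate(self.dec_convs):
            h = conv(h)
            if i == d - 1:
                return ag.tanh(h)
            h = ag.relu(self.dec_bns[i](h, train))
            if i in spec.dropout_layers:
                h = ag.dropout(h, spec.dropout_rate, rng, dropout_active)
            if spec.skip_connections:
                h = ag.concat(h, skips[d - 2 - i])
        raise AssertionError("unreachable")

    def translate_array(self, pixels: np.ndarray, seed: int = 0,
                        dropout_active: bool = True) -> np.ndarray:
        x = Tensor(pixels[None, None])
        rng = np.random.default_rng(seed)
        return self.forward(x, train=True, rng=rng,
                            dropout_active=dropout_active).data[0, 0]


class PatchDiscriminator(Module):
    """Scores overlapping patches of a (condition, candidate) pair; outputs
    a grid of confidence probabilities in (0, 1)."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.convs, self.bns = [], []
        cin = 2
        for f, s in zip(spec.filters, spec.strides):
            self.convs.append(Conv2d(cin, f, spec.kernel, s, 1, rng))
            self.bns.append(BatchNorm2d(f, rng))
            cin = f
        self.head = Conv2d(cin, 1, spec.kernel, 1, 1, rng)

    def forward(self, x: Tensor, y: Tensor, train: bool,
                presigmoid: bool = False) -> Tensor:
        if x.shape != y.shape:
            raise ValueError("condition/candidate shape mismatch")
        h = ag.concat(x, y)
        for conv, bn in zip(self.convs, self.bns):
            h = ag.relu(bn(conv(h), train))
        h = self.head(h)
        return h if presigmoid else ag.sigmoid(h)


def build_generator(spec: GeneratorSpec | None = None, side: int = 256,
                    seed: int = 0) -> UNetGenerator:
    return UNetGenerator(spec or GeneratorSpec(), side, seed)


def build_discriminator(spec: DiscriminatorSpec | None = None,
                        seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(spec or DiscriminatorSpec(), seed)


def receptive_field(spec: DiscriminatorSpec | None = None) -> int:
    """Receptive field (input pixels) of one output unit, by the standard
    recurrence r <- (r - 1) * stride + kernel applied output-to-input."""
    spec = spec or DiscriminatorSpec()
    r = 1
    for k, s in reversed(spec.layers()):
        r = (r - 1) * s + k
    return r


def receptive_field_probe(spec: DiscriminatorSpec | None = None,
                          side: int = 128, seed: int = 0) -> int:
    """Empirical receptive field via gradient support.

    Builds the discriminator with strictly positive weights and runs it in
    eval mode (per-channel normalization only, so no spatial mixing outside
    the convolution kernels), then measures the input support of one central
    output unit's gradient.  Returns the support width in pixels.
    """
    disc = PatchDiscriminator(spec or DiscriminatorSpec(), seed=seed)
    for p in disc.parameters():
        p.data = np.abs(p.data) + 1e-3
    x = Tensor(np.ones((1, 1, side, side)))
    y = Tensor(np.ones((1, 1, side, side)))
    x.requires_grad = True
    # probe the pre-sigmoid patch response: the sigmoid is pointwise, so the
    # support is identical, but its gradient cannot underflow
    out = disc.forward(x, y, train=False, presigmoid=True)
    h, w = out.shape[2], out.shape[3]
    seed_grad = np.zeros_like(out.data)
    seed_grad[0, 0, h // 2, w // 2] = 1.0
    out.backward(seed_grad)
    support = np.abs(x.grad[0, 0]) > 0
    rows = np.nonzero(support.any(axis=1))[0]
    cols = np.nonzero(support.any(axis=0))[0]
    width = int(rows[-1] - rows[0] + 1)
    height = int(cols[-1] - cols[0] + 1)
    return max(width, height)


# ---------------------------------------------------------------------------
# Losses (array-level; training uses the autograd equivalents)
# ---------------------------------------------------------------------------

def _scores(a) -> np.ndarray:
    return a.data if isinstance(a, Tensor) else np.asarray(a, dtype=np.float64)


def loss_cgan(d_real, d_fake, eps: float = 1e-7,
              saturating: bool = False) -> tuple[float, float]:
    """Adversarial losses from the discriminator's real/fake score maps.

    d_loss = -mean log D(x,y) - mean log(1 - D(x,G(x,z))); the generator
    term is the non-saturating -mean log D(x,G(x,z)) by default, or the
    original +mean log(1 - D) when ``saturating``.  Scores are clamped to
    [eps, 1-eps].
    """
    r = np.clip(_scores(d_real), eps, 1.0 - eps)
    f = np.clip(_scores(d_fake), eps, 1.0 - eps)
    d_loss = float(-np.log(r).mean() - np.log(1.0 - f).mean())
    if saturating:
        g_adv = float(np.log(1.0 - f).mean())
    else:
        g_adv = float(-np.log(f).mean())
    return d_loss, g_adv


def loss_l1(y, y_hat) -> float:
    """Mean absolute difference between target and translated images."""
    ya = y.pixels if isinstance(y, ImageSlice) else np.asarray(y)
    yb = y_hat.pixels if isinstance(y_hat, ImageSlice) else np.asarray(y_hat)
    if ya.shape != yb.shape:
        raise ValueError("shape mismatch")
    return float(np.abs(ya - yb).mean())


def total_objective(adv: float, l1: float, cfg: TrainConfig) -> float:
    """Combine the adversarial and L1 terms per the configured variant."""
    if cfg.loss_mode == "cGAN+L1":
        return adv + cfg.lambda_l1 * l1
    if cfg.loss_mode == "L1":
        return l1
    return adv


# ---------------------------------------------------------------------------
# Training / inference
# ---------------------------------------------------------------------------

class TrainedTranslator:
    """A trained generator with its spec snapshot and training history."""

    def __init__(self, generator: UNetGenerator, gen_spec: GeneratorSpec,
                 cfg: TrainConfig, history: dict[str, list[float]],
                 discriminator: PatchDiscriminator | None = None):
        self.generator = generator
        self.gen_spec = gen_spec
        self.cfg = cfg
        self.history = history
        self.discriminator = discriminator

    def translate(self, x: ImageSlice, seed: int = 0,
                  dropout_active: bool | None = None) -> ImageSlice:
        return translate(self, x, seed=seed, dropout_active=dropout_active)

    def save(self, path) -> None:
        meta = {
            "gen_spec": asdict(self.gen_spec),
            "cfg": asdict(self.cfg),
            "history": self.history,
            "side": self.generator.side,
        }
        state = {f"g.{k}": v for k, v in self.generator.state_dict().items()}
        if self.discriminator is not None:
            state.update({f"d.{k}": v for k, v in self.discriminator.state_dict().items()})
            meta["disc_spec"] = asdict(self.discriminator.spec)
        np.savez(str(path), __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path) -> "TrainedTranslator":
        with np.load(str(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        gmeta = dict(meta["gen_spec"])
        for key in ("encoder_filters", "decoder_filters", "dropout_layers"):
            gmeta[key] = tuple(gmeta[key])
        spec = GeneratorSpec(**gmeta)
        gen = UNetGenerator(spec, meta["side"])
        gen.load_state_dict({k[2:]: v for k, v in state.items() if k.startswith("g.")})
        disc = None
        if "disc_spec" in meta:
            dmeta = dict(meta["disc_spec"])
            dmeta["filters"] = tuple(dmeta["filters"])
            dmeta["strides"] = tuple(dmeta["strides"])
            disc = PatchDiscriminator(DiscriminatorSpec(**dmeta))
            disc.load_state_dict({k[2:]: v for k, v in state.items() if k.startswith("d.")})
        return cls(gen, spec, TrainConfig(**meta["cfg"]), meta["history"], disc)


def train(pairs: list[PairedSample], cfg: TrainConfig,
          gen_spec: GeneratorSpec | None = None,
          disc_spec: DiscriminatorSpec | None = None,
          saturating: bool = False) -> TrainedTranslator:
    """Alternating adversarial training: per sample, one D step then one G
    step, Adam(lr, beta1) for both, batch size 1.  Seeded and reproducible.
    """
    if not pairs:
        raise ValueError("training set is empty")
    side = pairs[0].given.pixels.shape[0]
    for p in pairs:
        if p.given.pixels.shape != (side, side):
            raise ValueError("all pairs must share one square shape")
        if not (p.given.normalized and p.target.normalized):
            raise ValueError("pairs must be normalized to [-1, 1]")
    gen_spec = gen_spec or GeneratorSpec()
    disc_spec = disc_spec or DiscriminatorSpec()
    cfg = replace(cfg, image_side=side)

    gen = UNetGenerator(gen_spec, side, seed=cfg.seed)
    use_adv = cfg.loss_mode in ("cGAN", "cGAN+L1")
    disc = PatchDiscriminator(disc_spec, seed=cfg.seed + 1) if use_adv else None
    opt_g = Adam(gen.parameters(), lr=cfg.lr, beta1=cfg.beta1)
    opt_d = Adam(disc.parameters(), lr=cfg.lr, beta1=cfg.beta1) if use_adv else None
    order_rng = np.random.default_rng(cfg.seed + 2)
    drop_rng = np.random.default_rng(cfg.seed + 3)

    history: dict[str, list[float]] = {"g_loss": [], "d_loss": [], "l1": []}
    for _epoch in range(cfg.epochs):
        idx = order_rng.permutation(len(pairs))
        g_sum = d_sum = l1_sum = 0.0
        for i in idx:
            x = Tensor(pairs[i].given.pixels[None, None])
            y = Tensor(pairs[i].target.pixels[None, None])

            d_loss_val = 0.0
            if use_adv:
                yhat = gen.forward(x, train=True, rng=drop_rng).detach()
                d_real = disc.forward(x, y, train=True)
                d_fake = disc.forward(x, yhat, train=True)
                d_loss = ag.affine_sum(
                    [ag.bce_loss(d_real, 1.0), ag.bce_loss(d_fake, 0.0)], [1.0, 1.0])
                disc.zero_grad()
                d_loss.backward()
                opt_d.step()
                d_loss_val = float(d_loss.data)

            yhat = gen.forward(x, train=True, rng=drop_rng)
            l1_t = ag.l1_loss(yhat, y)
            terms, coeffs = [], []
            if use_adv:
                d_fake2 = disc.forward(x, yhat, train=True)
                if saturating:
                    terms.append(ag.bce_loss(d_fake2, 0.0))
                    coeffs.append(-1.0)
                else:
                    terms.append(ag.bce_loss(d_fake2, 1.0))
                    coeffs.append(1.0)
            if cfg.loss_mode in ("L1", "cGAN+L1"):
                terms.append(l1_t)
                coeffs.append(cfg.lambda_l1 if cfg.loss_mode == "cGAN+L1" else 1.0)
            g_loss = ag.affine_sum(terms, coeffs)
            if not np.isfinite(g_loss.data) or not np.isfinite(d_loss_val):
                raise RuntimeError(
                    f"non-finite loss at epoch {_epoch}: g={float(g_loss.data)}, "
                    f"d={d_loss_val}")
            gen.zero_grad()
            if disc is not None:
                disc.zero_grad()
            g_loss.backward()
            opt_g.step()

            g_sum += float(g_loss.data)
            d_sum += d_loss_val
            l1_sum += float(l1_t.data)
        n = len(pairs)
        history["g_loss"].append(g_sum / n)
        history["d_loss"].append(d_sum / n)
        history["l1"].append(l1_sum / n)

    return TrainedTranslator(gen, gen_spec, cfg, history, disc)


def translate(t: TrainedTranslator, x: ImageSlice, seed: int = 0,
              dropout_active: bool | None = None) -> ImageSlice:
    """Synthesize the translated-modality image for a given-modality slice.

    Deterministic for a fixed dropout ``seed``.  Batch-normalization uses
    per-instance statistics, the same regime as batch-size-1 training.
    """
    if not x.normalized:
        raise ValueError("input slice must be normalized to [-1, 1]")
    if x.pixels.shape != (t.generator.side, t.generator.side):
        raise ValueError(
            f"input shape {x.pixels.shape} does not match the trained side "
            f"{t.generator.side}")
    active = dropout_active if dropout_active is not None else True
    out = t.generator.translate_array(x.pixels, seed=seed, dropout_active=active)
    return ImageSlice(pixels=np.clip(out, -1.0, 1.0),
                      modality=f"{x.modality}->translated", normalized=True)
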