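"""Conditional-GAN restoration engine: U-Net generator, PatchGAN critic.

The restoration problem is posed as conditional image-to-image translation
in the pix2pix style: a generator G(z, y) maps a degraded frame y (plus
stochasticity z, realised as training-time dropout) to an enhanced frame,
while a patch-wise discriminator D(·, y) scores local patches of a
(candidate, condition) pair as real or fake.  Training minimises over G and
maximises over D the cGAN objective

    E_{x,y}[log D(x, y)] + E_{y,z}[log(1 - D(G(z, y), y))]

combined with an L1 data-fidelity term weighted by ``l1_weight``; the
generator update uses the non-saturating form by default (the minimax form
is selectable).  Images travel through the networks in a symmetric unit
range: 8-bit [0, 255] <-> [-1, 1].
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn

__all__ = [
    "GanConfig",
    "TrainingPair",
    "ModelBundle",
    "TrainHistory",
    "UNetGenerator",
    "PatchDiscriminator",
    "build_generator",
    "build_discriminator",
    "gan_objective",
    "train",
    "infer",
    "transplant_parameters",
    "save_bundle",
    "load_bundle",
    "to_unit",
    "from_unit",
]

_LOG_EPS = 1e-7


@dataclass(frozen=True)
class GanConfig:
    """Hyperparameters of one restoration network.

    Defaults follow the pix2pix lineage (l1_weight 100, 70-px patches,
    Adam with beta1 = 0.5), except the learning rate (1e-3), raised for the
    few-hundred-step training runs this package targets; depth/width are
    sized for desk-scale frames and scale up by config for full 512x512
    parity runs.
    """

    image_size: int = 128
    gen_depth: int = 3
    base_channels: int = 16
    patch_scale: int = 70
    l1_weight: float = 100.0
    lr: float = 1e-3
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    epochs: int = 50
    batch_size: int = 4
    seed: int = 0
    gen_loss_mode: str = "non_saturating"  # or "minimax"
    dropout_p: float = 0.0
    val_fraction: float = 0.15
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.image_size % (2**self.gen_depth) != 0:
            raise ValueError(
                f"image_size {self.image_size} must be a multiple of "
                f"2^gen_depth = {2**self.gen_depth}"
            )
        if self.l1_weight < 0:
            raise ValueError("l1_weight must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.patch_scale > self.image_size:
            raise ValueError("patch_scale cannot exceed image_size")
        if self.gen_loss_mode not in ("non_saturating", "minimax"):
            raise ValueError("gen_loss_mode must be non_saturating or minimax")

    @property
    def np_dtype(self) -> np.dtype:
        return np.dtype(self.dtype)


@dataclass(frozen=True)
class TrainingPair:
    """One aligned (ground truth x, conditional input y) frame pair.

    Frames are stored in 8-bit units; ``meta`` carries provenance (source
    stack, frame index, augmentation seed z) sufficient to regenerate the
    pair.
    """

    x: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.asarray(self.x).shape != np.asarray(self.y).shape:
            raise ValueError("x and y must share geometry")


def to_unit(img: np.ndarray, dtype: np.dtype = np.float64) -> np.ndarray:
    """8-bit intensities -> symmetric unit range [-1, 1]."""
    return (np.asarray(img, dtype=dtype) / 127.5) - 1.0


def from_unit(u: np.ndarray) -> np.ndarray:
    """Symmetric unit range -> float intensities clipped to [0, 255]."""
    return np.clip((np.asarray(u, dtype=np.float64) + 1.0) * 127.5, 0.0, 255.0)


def _channel_schedule(base: int, depth: int, cap_mult: int = 8) -> list[int]:
    return [min(base * 2**i, base * cap_mult) for i in range(depth)]


class UNetGenerator(nn.Layer):
    """Encoder-decoder with skip connections mapping 1-channel frames.

    A full-resolution stem feeds both the encoder and a direct skip into the
    output stage, so fine detail never has to survive a strided bottleneck;
    below the stem, ``gen_depth`` stride-2 encoder levels mirror upsampling
    decoder levels with concatenated skips, ending in a Tanh that bounds the
    output to the canonical unit range.
    """

    def __init__(self, cfg: GanConfig, rng: np.random.Generator) -> None:
        d = cfg.gen_depth
        base = cfg.base_channels
        ch = _channel_schedule(base, d)
        dt = cfg.np_dtype
        self.depth = d
        self.channels = ch
        self.base = base
        self.dropout_rng = np.random.default_rng(int(rng.integers(2**31)))
        self.stem = nn.Sequential(
            nn.Conv2d(1, base, 3, stride=1, pad=1, rng=rng, dtype=dt),
            nn.LeakyReLU(0.2),
        )
        self.enc: list[nn.Sequential] = []
        prev = base
        for i in range(d):
            block: list[nn.Layer] = [
                nn.Conv2d(prev, ch[i], 4, stride=2, pad=1, rng=rng, dtype=dt)
            ]
            if i > 0:
                block.append(nn.InstanceNorm(ch[i], dtype=dt))
            block.append(nn.LeakyReLU(0.2))
            self.enc.append(nn.Sequential(*block))
            prev = ch[i]
        self.dec: list[nn.Sequential] = []
        cur = ch[d - 1]
        for i in range(d - 1, 0, -1):
            block = [
                nn.Upsample2x(),
                nn.Conv2d(cur, ch[i - 1], 3, stride=1, pad=1, rng=rng, dtype=dt),
                nn.InstanceNorm(ch[i - 1], dtype=dt),
                nn.ReLU(),
            ]
            if i >= d - 1 and cfg.dropout_p > 0:
                block.append(nn.Dropout(cfg.dropout_p, self.dropout_rng))
            self.dec.append(nn.Sequential(*block))
            cur = 2 * ch[i - 1]  # after concat with the skip
        self.up_final = nn.Sequential(
            nn.Upsample2x(),
            nn.Conv2d(cur, base, 3, stride=1, pad=1, rng=rng, dtype=dt),
            nn.ReLU(),
        )
        self.out_conv = nn.Sequential(
            nn.Conv2d(2 * base, 1, 3, stride=1, pad=1, rng=rng, dtype=dt),
            nn.Tanh(),
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        f0 = self.stem.forward(x, train=train)
        feats = []
        h = f0
        for enc in self.enc:
            h = enc.forward(h, train=train)
            feats.append(h)
        for idx, dec in enumerate(self.dec):
            h = dec.forward(h, train=train)
            skip = feats[self.depth - 2 - idx]
            h = np.concatenate([h, skip], axis=1)
        h = self.up_final.forward(h, train=train)
        h = np.concatenate([h, f0], axis=1)
        return self.out_conv.forward(h, train=train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        d = self.depth
        g = self.out_conv.backward(grad)
        g_up, g_f0_direct = g[:, : self.base], g[:, self.base :]
        g = self.up_final.backward(g_up)
        skip_grads: list[np.ndarray | None] = [None] * d
        for idx in range(len(self.dec) - 1, -1, -1):
            ch = self.channels[d - 2 - idx]
            g_dec, g_skip = g[:, :ch], g[:, ch:]
            skip_grads[d - 2 - idx] = g_skip
            g = self.dec[idx].backward(g_dec)
        # g is now the gradient w.r.t. the bottleneck feature
        for i in range(d - 1, -1, -1):
            g = self.enc[i].backward(g)
            if i - 1 >= 0 and skip_grads[i - 1] is not None:
                g = g + skip_grads[i - 1]
        return self.stem.backward(g + g_f0_direct)

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for b in [self.stem] + self.enc + self.dec + [self.up_final, self.out_conv]:
            out.extend(b.params())
        return out


def _disc_n_stride2(patch_scale: int) -> int:
    """Smallest number of stride-2 layers whose receptive field covers
    ``patch_scale`` (k=4 layers followed by two stride-1 k=4 layers)."""
    for n in range(1, 6):
        rf = 1
        for _, s in [(4, 1), (4, 1)] + [(4, 2)] * n:
            rf = rf * s + (4 - s)
        if rf >= patch_scale:
            return n
    return 5


def _receptive_field(n_stride2: int) -> int:
    rf = 1
    for _, s in [(4, 1), (4, 1)] + [(4, 2)] * n_stride2:
        rf = rf * s + (4 - s)
    return rf


class PatchDiscriminator(nn.Layer):
    """Patch-wise classifier over (candidate, condition) pairs.

    Emits a spatial field of probabilities in (0, 1); each output unit sees a
    receptive field of roughly ``patch_scale`` input pixels.
    """

    def __init__(self, cfg: GanConfig, rng: np.random.Generator) -> None:
        dt = cfg.np_dtype
        n2 = _disc_n_stride2(cfg.patch_scale)
        max_n2 = max(int(np.log2(cfg.image_size)) - 2, 1)
        n2 = min(n2, max_n2)
        self.n_stride2 = n2
        self.receptive_field = _receptive_field(n2)
        layers: list[nn.Layer] = []
        prev = 2
        ch = cfg.base_channels
        for i in range(n2):
            layers.append(nn.Conv2d(prev, ch, 4, stride=2, pad=1, rng=rng, dtype=dt))
            if i > 0:
                layers.append(nn.InstanceNorm(ch, dtype=dt))
            layers.append(nn.LeakyReLU(0.2))
            prev = ch
            ch = min(ch * 2, cfg.base_channels * 8)
        layers.append(nn.Conv2d(prev, ch, 4, stride=1, pad=1, rng=rng, dtype=dt))
        layers.append(nn.InstanceNorm(ch, dtype=dt))
        layers.append(nn.LeakyReLU(0.2))
        layers.append(nn.Conv2d(ch, 1, 4, stride=1, pad=1, rng=rng, dtype=dt))
        layers.append(nn.Sigmoid())
        self.net = nn.Sequential(*layers)

    def forward(self, candidate: np.ndarray, condition: np.ndarray | None = None,
                train: bool = True) -> np.ndarray:
        if condition is not None:
            x = np.concatenate([candidate, condition], axis=1)
        else:
            x = candidate
        return self.net.forward(x, train=train)

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        """Returns the gradient w.r.t. the *candidate* channel only."""
        g = self.net.backward(grad)
        return g[:, :1]

    def params(self) -> list[nn.Param]:
        return self.net.params()


def build_generator(cfg: GanConfig) -> UNetGenerator:
    """Deterministically initialised U-Net generator for ``cfg``."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    return UNetGenerator(cfg, rng)


def build_discriminator(cfg: GanConfig) -> PatchDiscriminator:
    """Deterministically initialised PatchGAN discriminator for ``cfg``."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    return PatchDiscriminator(cfg, rng)


def _safe_log(p: np.ndarray) -> np.ndarray:
    return np.log(np.clip(p, _LOG_EPS, 1.0 - _LOG_EPS))


def gan_objective(
    G_out: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    D,
    l1_weight: float,
    gen_loss_mode: str = "non_saturating",
) -> dict[str, float]:
    """Evaluate the cGAN losses for one batch (forward only, unit range).

    Returns the discriminator loss -(E[log D(x,y)] + E[log(1 - D(G,y))]),
    the generator adversarial term (non-saturating -E[log D(G,y)] or minimax
    +E[log(1 - D(G,y))]), the L1 term E|G - x|, and the combined generator
    loss adversarial + l1_weight * L1.
    """
    for a in (x, y):
        if np.asarray(a).shape != np.asarray(G_out).shape:
            raise ValueError("G_out, x and y must share geometry")
    d_real = D(x, y, train=False)
    d_fake = D(G_out, y, train=False)
    d_loss = -(float(_safe_log(d_real).mean()) + float(_safe_log(1.0 - d_fake).mean()))
    if gen_loss_mode == "non_saturating":
        g_adv = -float(_safe_log(d_fake).mean())
    else:
        g_adv = float(_safe_log(1.0 - d_fake).mean())
    l1 = float(np.abs(G_out - x).mean())
    return {
        "d_loss": d_loss,
        "g_adv": g_adv,
        "l1": l1,
        "g_loss": g_adv + l1_weight * l1,
    }


@dataclass
class TrainHistory:
    """Per-epoch loss bookkeeping of one training run."""

    records: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(dict(kwargs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ModelBundle:
    """A trained generator/discriminator pair with its provenance."""

    G: UNetGenerator
    D: PatchDiscriminator
    config: GanConfig
    provenance: dict = field(default_factory=dict)

    def param_checksum(self) -> str:
        h = hashlib.sha256()
        for p in self.G.params() + self.D.params():
            h.update(np.ascontiguousarray(p.data, dtype=np.float64).tobytes())
        return h.hexdigest()


def _dataset_fingerprint(pairs: Sequence[TrainingPair]) -> str:
    h = hashlib.sha256()
    for p in pairs:
        h.update(np.ascontiguousarray(p.x, dtype=np.float32).tobytes())
        h.update(np.ascontiguousarray(p.y, dtype=np.float32).tobytes())
    return h.hexdigest()[:16]


def _batch_arrays(
    pairs: Sequence[TrainingPair], idx: np.ndarray, dtype: np.dtype
) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([to_unit(pairs[i].x, dtype) for i in idx])[:, None]
    ys = np.stack([to_unit(pairs[i].y, dtype) for i in idx])[:, None]
    return xs, ys


def _validation_l1(
    G: UNetGenerator, pairs: Sequence[TrainingPair], dtype: np.dtype
) -> float:
    if not pairs:
        return float("nan")
    tot = 0.0
    for p in pairs:
        y = to_unit(p.y, dtype)[None, None]
        out = G.forward(y, train=False)
        tot += float(np.abs(out[0, 0] - to_unit(p.x, dtype)).mean())
    return tot / len(pairs)


def train(
    pairs: Sequence[TrainingPair],
    cfg: GanConfig,
    val_pairs: Sequence[TrainingPair] | None = None,
    init: ModelBundle | None = None,
    progress: bool = False,
) -> tuple[ModelBundle, TrainHistory]:
    """Alternating D/G Adam optimisation of the cGAN objective.

    All randomness (initialisation, shuffling, dropout) derives from
    ``cfg.seed``.  ``init`` transplants pre-trained parameters into the fresh
    networks before the first update (the learning-transfer "Pretrain"
    scheme).  A held-out validation split (``cfg.val_fraction`` of the pairs,
    or ``val_pairs`` if given) is scored by deterministic-mode L1 per epoch.
    """
    if len(pairs) == 0:
        raise ValueError("training requires at least one pair")
    for p in pairs:
        if p.x.shape != (cfg.image_size, cfg.image_size):
            raise ValueError(
                f"pair geometry {p.x.shape} does not match config image_size "
                f"{cfg.image_size}"
            )
    dt = cfg.np_dtype
    G = build_generator(cfg)
    D = build_discriminator(cfg)
    if init is not None:
        transplant_parameters(init.G.params(), G.params())
        transplant_parameters(init.D.params(), D.params())
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))

    pairs = list(pairs)
    if val_pairs is None and cfg.val_fraction > 0 and len(pairs) >= 4:
        n_val = max(1, int(round(cfg.val_fraction * len(pairs))))
        order = shuffle_rng.permutation(len(pairs))
        val_pairs = [pairs[i] for i in order[:n_val]]
        pairs = [pairs[i] for i in order[n_val:]]
    val_pairs = list(val_pairs) if val_pairs else []

    opt_g = nn.Adam(G.params(), lr=cfg.lr, beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    opt_d = nn.Adam(D.params(), lr=cfg.lr, beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    history = TrainHistory()
    n = len(pairs)
    bs = min(cfg.batch_size, n)

    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        ep = {"d_loss": 0.0, "g_adv": 0.0, "l1": 0.0, "g_loss": 0.0}
        n_batches = 0
        for b0 in range(0, n, bs):
            idx = order[b0 : b0 + bs]
            xb, yb = _batch_arrays(pairs, idx, dt)
            fake = G.forward(yb, train=True)

            # --- discriminator step ---
            opt_d.zero_grad()
            d_real = D(xb, yb, train=True)
            m_r = d_real.size
            D.backward((-1.0 / (np.clip(d_real, _LOG_EPS, 1 - _LOG_EPS) * m_r)).astype(dt))
            d_fake = D(fake, yb, train=True)
            m_f = d_fake.size
            D.backward((1.0 / (np.clip(1.0 - d_fake, _LOG_EPS, 1 - _LOG_EPS) * m_f)).astype(dt))
            d_loss = -(
                float(_safe_log(d_real).mean()) + float(_safe_log(1.0 - d_fake).mean())
            )
            opt_d.step()

            # --- generator step ---
            opt_g.zero_grad()
            for p in D.params():
                p.zero_grad()  # D is only a conduit here
            d_fake_g = D(fake, yb, train=True)
            if cfg.gen_loss_mode == "non_saturating":
                g_adv = -float(_safe_log(d_fake_g).mean())
                dprob = (-1.0 / (np.clip(d_fake_g, _LOG_EPS, 1 - _LOG_EPS) * d_fake_g.size))
            else:
                g_adv = float(_safe_log(1.0 - d_fake_g).mean())
                dprob = (-1.0 / (np.clip(1.0 - d_fake_g, _LOG_EPS, 1 - _LOG_EPS) * d_fake_g.size))
            grad_fake = D.backward(dprob.astype(dt))
            l1 = float(np.abs(fake - xb).mean())
            grad_l1 = (cfg.l1_weight * np.sign(fake - xb) / fake.size).astype(dt)
            G.backward(grad_fake + grad_l1)
            opt_g.step()

            ep["d_loss"] += d_loss
            ep["g_adv"] += g_adv
            ep["l1"] += l1
            ep["g_loss"] += g_adv + cfg.l1_weight * l1
            n_batches += 1
            if not np.isfinite(d_loss) or not np.isfinite(g_adv):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {b0 // bs}"
                )
        rec = {k: v / n_batches for k, v in ep.items()}
        rec["epoch"] = epoch
        rec["val_l1"] = _validation_l1(G, val_pairs, dt)
        history.append(**rec)
        if progress:
            print(
                f"epoch {epoch:3d}  d={rec['d_loss']:.3f}  g_adv={rec['g_adv']:.3f}"
                f"  l1={rec['l1']:.4f}  val_l1={rec['val_l1']:.4f}"
            )
    bundle = ModelBundle(
        G=G,
        D=D,
        config=cfg,
        provenance={
            "seed": cfg.seed,
            "n_pairs": n,
            "n_val": len(val_pairs),
            "dataset_fingerprint": _dataset_fingerprint(pairs),
            "init": "pretrain" if init is not None else "scratch",
        },
    )
    return bundle, history


def transplant_parameters(src: list[nn.Param], dst: list[nn.Param]) -> None:
    """Copy parameters position-wise between identically shaped networks."""
    if len(src) != len(dst):
        raise ValueError("parameter lists differ in length; incompatible configs")
    for s, d in zip(src, dst):
        if s.data.shape != d.data.shape:
            raise ValueError(
                f"parameter shape mismatch {s.data.shape} vs {d.data.shape}"
            )
        d.data[...] = s.data


def infer(bundle: ModelBundle, frame: np.ndarray) -> np.ndarray:
    """Deterministic single-frame enhancement, de-normalised to 8-bit range.

    Output dtype follows the input: integer inputs come back as uint8,
    float inputs as float64 clipped to [0, 255].
    """
    frame = np.asarray(frame)
    size = bundle.config.image_size
    if frame.shape != (size, size):
        raise ValueError(
            f"frame shape {frame.shape} does not match model image_size {size}"
        )
    u = to_unit(frame, bundle.config.np_dtype)[None, None]
    out = bundle.G.forward(u, train=False)[0, 0]
    out8 = from_unit(out)
    if np.issubdtype(frame.dtype, np.integer):
        return np.rint(out8).astype(np.uint8)
    return out8


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Persist a bundle as ``.npz`` parameters plus embedded JSON metadata."""
    path = Path(path)
    arrays = {}
    for i, p in enumerate(bundle.G.params()):
        arrays[f"g_{i}"] = p.data
    for i, p in enumerate(bundle.D.params()):
        arrays[f"d_{i}"] = p.data
    meta = json.dumps(
        {"config": asdict(bundle.config), "provenance": bundle.provenance}
    )
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_bundle(path: str | Path) -> ModelBundle:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing model checkpoint: {path}")
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        cfg = GanConfig(**meta["config"])
        G = build_generator(cfg)
        D = build_discriminator(cfg)
        for i, p in enumerate(G.params()):
            p.data[...] = data[f"g_{i}"]
        for i, p in enumerate(D.params()):
            p.data[...] = data[f"d_{i}"]
    return ModelBundle(G=G, D=D, config=cfg, provenance=meta["provenance"])
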