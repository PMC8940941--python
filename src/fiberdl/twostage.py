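"""Two-stage learning-transfer protocol for high-speed restoration.

Ideal ground truth (slow-scan, frame-averaged, full-density frames) exists
only for motion-free recordings.  The protocol therefore proceeds in two
stages:

1. **DNN-1 (denoiser)** is trained on motion-free stacks: each field of view
   contributes a randomly chosen single frame (with extra acquisition noise
   drawn over a range of scanning speeds) as input, paired with the
   k-frame-averaged stack (default k=10) as ground truth.
2. **DNN-2 (denoiser + inpainter)** targets a *different* dataset for which
   no averaging is possible.  The trained DNN-1 is applied frame-by-frame to
   produce an intermediate ground truth; each raw frame is also radially
   down-sampled by the factor M (emulating a low scanning density), and the
   (down-sampled, DNN-1 output) pairs train one DNN-2 per M — a given DNN-2
   corresponds to one scanning density.  DNN-2 can start from random weights
   ("Scratch") or from DNN-1's parameters ("Pretrain").
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .gan import GanConfig, ModelBundle, TrainHistory, TrainingPair, infer, train
from .phantom import NoiseModel, apply_noise, frame_average
from .scanmodel import RingMap, radial_downsample

__all__ = [
    "StageDataset",
    "TwoStagePlan",
    "make_dnn1_dataset",
    "make_dnn2_dataset",
    "run_two_stage",
    "enhance_stack",
]


@dataclass(frozen=True)
class StageDataset:
    """Training pairs plus the provenance needed to regenerate them."""

    pairs: list[TrainingPair]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class TwoStagePlan:
    """Configuration of a full two-stage training run."""

    dnn1_config: GanConfig
    dnn2_configs: dict[int, GanConfig]
    averaging_k: int = 10
    M_list: tuple[int, ...] = (2, 4, 8, 16, 32)
    init_scheme: str = "Scratch"  # or "Pretrain"
    fill: str = "nearest_ring"

    def __post_init__(self) -> None:
        if self.averaging_k < 2:
            raise ValueError("averaging_k must be >= 2")
        if self.init_scheme not in ("Scratch", "Pretrain"):
            raise ValueError("init_scheme must be 'Scratch' or 'Pretrain'")
        for M in self.M_list:
            if M not in self.dnn2_configs:
                raise ValueError(f"M_list entry {M} has no dnn2_config")


def make_dnn1_dataset(
    stacks: list[np.ndarray],
    k: int,
    augment: NoiseModel | None,
    seed: int,
    speed_range: tuple[float, float] = (1650.0, 3360.0),
    pairs_per_stack: int = 1,
    strict: bool = False,
) -> StageDataset:
    """Stage-1 dataset: (noisy single frame, k-frame average) per FOV.

    Ground truth x is the k-frame average of the stack; the input y is one
    uniformly chosen frame with augmentation noise applied at a scanning
    speed drawn from ``speed_range`` (mimicking varied imaging conditions).
    ``pairs_per_stack`` > 1 resamples extra frames per FOV to enlarge small
    synthetic datasets.  Stacks shorter than k are skipped (or rejected under
    ``strict``).
    """
    rng = np.random.default_rng(seed)
    pairs: list[TrainingPair] = []
    skipped = []
    for s_idx, stack in enumerate(stacks):
        stack = np.asarray(stack)
        if stack.shape[0] < k:
            if strict:
                raise ValueError(
                    f"stack {s_idx} has {stack.shape[0]} frames, fewer than k={k}"
                )
            skipped.append(s_idx)
            continue
        x = frame_average(stack, k)
        for p in range(pairs_per_stack):
            t = int(rng.integers(stack.shape[0]))
            z = int(rng.integers(2**31))
            speed = float(rng.uniform(*speed_range))
            y = stack[t].astype(np.float64)
            if augment is not None:
                y = apply_noise(y, augment, speed, rng=np.random.default_rng(z))
            pairs.append(
                TrainingPair(
                    x=x,
                    y=y,
                    meta={
                        "stack": s_idx,
                        "frame": t,
                        "z_seed": z,
                        "speed": speed,
                        "stage": 1,
                    },
                )
            )
    return StageDataset(
        pairs=pairs,
        provenance={
            "stage": 1,
            "k": k,
            "seed": seed,
            "speed_range": list(speed_range),
            "pairs_per_stack": pairs_per_stack,
            "n_stacks": len(stacks),
            "skipped": skipped,
            "augment": None if augment is None else dataclasses.asdict(augment),
        },
    )


def make_dnn2_dataset(
    stacks: list[np.ndarray],
    dnn1: ModelBundle,
    M: int,
    rings: RingMap,
    fill: str = "nearest_ring",
) -> StageDataset:
    """Stage-2 dataset: (radially down-sampled frame, DNN-1 output) per frame.

    The intermediate ground truth x is never a raw frame — it is always the
    DNN-1 enhancement of the frame; y is the same frame decimated to every
    M-th ring under the chosen fill policy.
    """
    size = dnn1.config.image_size
    pairs: list[TrainingPair] = []
    for s_idx, stack in enumerate(stacks):
        stack = np.asarray(stack)
        if stack.shape[1:] != (size, size):
            raise ValueError(
                f"stack {s_idx} geometry {stack.shape[1:]} does not match "
                f"DNN-1 image_size {size}"
            )
        for t in range(stack.shape[0]):
            frame = stack[t].astype(np.float64)
            x = infer(dnn1, frame)
            y = radial_downsample(frame, rings, M, fill=fill)
            pairs.append(
                TrainingPair(
                    x=np.asarray(x, dtype=np.float64),
                    y=y,
                    meta={
                        "stack": s_idx,
                        "frame": t,
                        "M": M,
                        "fill": fill,
                        "stage": 2,
                        "x_provenance": "dnn1_output",
                    },
                )
            )
    return StageDataset(
        pairs=pairs,
        provenance={
            "stage": 2,
            "M": M,
            "fill": fill,
            "dnn1_seed": dnn1.provenance.get("seed"),
            "dnn1_checksum": dnn1.param_checksum(),
            "n_stacks": len(stacks),
        },
    )


def run_two_stage(
    plan: TwoStagePlan,
    trainA: list[np.ndarray],
    trainB: list[np.ndarray],
    rings: RingMap,
    augment: NoiseModel | None = None,
    seed: int = 0,
    pairs_per_stack: int = 1,
    progress: bool = False,
) -> tuple[ModelBundle, dict[int, ModelBundle], dict[str, TrainHistory]]:
    """Execute the full learning-transfer protocol.

    ``trainA`` (motion-free, averaging-friendly stacks) feeds stage 1;
    ``trainB`` (the deployment-like dataset) feeds stage 2.  One DNN-2 is
    trained per M in ``plan.M_list``; under "Pretrain" its generator and
    discriminator start from DNN-1's parameters.
    """
    ds1 = make_dnn1_dataset(
        trainA, plan.averaging_k, augment, seed=seed, pairs_per_stack=pairs_per_stack
    )
    if len(ds1) == 0:
        raise ValueError("stage 1: no usable training stacks")
    dnn1, hist1 = train(ds1.pairs, plan.dnn1_config, progress=progress)
    dnn1.provenance["stage"] = 1

    dnn2: dict[int, ModelBundle] = {}
    histories: dict[str, TrainHistory] = {"dnn1": hist1}
    for M in plan.M_list:
        ds2 = make_dnn2_dataset(trainB, dnn1, M, rings, fill=plan.fill)
        init = dnn1 if plan.init_scheme == "Pretrain" else None
        bundle, hist = train(
            ds2.pairs, plan.dnn2_configs[M], init=init, progress=progress
        )
        bundle.provenance.update(
            {"stage": 2, "M": M, "fill": plan.fill, "init_scheme": plan.init_scheme}
        )
        dnn2[M] = bundle
        histories[f"dnn2_M{M}"] = hist
    return dnn1, dnn2, histories


def enhance_stack(bundle: ModelBundle, stack: np.ndarray) -> np.ndarray:
    """Frame-wise deterministic enhancement of a whole stack."""
    stack = np.asarray(stack)
    size = bundle.config.image_size
    if stack.ndim != 3 or stack.shape[1:] != (size, size):
        raise ValueError(
            f"stack geometry {stack.shape} does not match model image_size {size}"
        )
    return np.stack([infer(bundle, f) for f in stack])
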