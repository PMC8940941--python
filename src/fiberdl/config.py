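"""Run configuration: YAML parsing and deterministic seed fan-out.

A run is described by one YAML file with sections ``phantom``, ``scan``,
``stage1``, ``stage2``, ``metrics``, ``paths`` and a single global ``seed``.
Sub-seeds for each module are derived from the global seed with
``numpy.random.SeedSequence`` spawning, so one number reproduces the whole
run while modules never share a stream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .gan import GanConfig
from .phantom import ActivityModel, NoiseModel, PhantomSpec
from .scanmodel import ScanConfig

__all__ = ["RunConfig", "derive_seed", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "phantom": {
        "image_size": 128,
        "n_somas": 4,
        "n_stacks": 8,
        "n_frames": 30,
        "spike_rate": 0.03,
        "decay_tau": 8.0,
    },
    "scan": {
        "scanning_speed": 3360.0,
        "scanning_density": 512,
        "duty_ratio": 0.5,
        "M": 8,
    },
    "noise": {
        "photons_per_unit_at_ref_speed": 4.0,
        "ref_speed": 1650.0,
        "read_noise_sigma": 3.0,
    },
    "stage1": {"epochs": 50, "base_channels": 16, "gen_depth": 3},
    "stage2": {
        "epochs": 50,
        "base_channels": 16,
        "gen_depth": 3,
        "M_list": [8],
        "init_scheme": "Scratch",
        "fill": "nearest_ring",
    },
    "metrics": {"baseline_percentile": 10.0, "n_scales": 3},
    "paths": {"run_dir": "runs/default"},
}


def derive_seed(global_seed: int, stream: int) -> int:
    """Deterministic sub-seed (< 2**31) for module ``stream``."""
    ss = np.random.SeedSequence([int(global_seed), int(stream)])
    return int(ss.generate_state(1)[0] % (2**31))


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """Fully materialised configuration of one pipeline run."""

    raw: dict = field(default_factory=lambda: dict(DEFAULT_CONFIG))

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    def sub_seed(self, stream: int) -> int:
        return derive_seed(self.seed, stream)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()[:16]

    # --- section constructors -------------------------------------------
    def phantom_spec(self, stack_index: int = 0) -> PhantomSpec:
        p = self.raw["phantom"]
        return PhantomSpec(
            image_size=p.get("image_size", 128),
            n_somas=p.get("n_somas", 4),
            seed=derive_seed(self.seed, 100 + stack_index),
        )

    def activity_model(self, stack_index: int = 0) -> ActivityModel:
        p = self.raw["phantom"]
        return ActivityModel(
            spike_rate=p.get("spike_rate", 0.03),
            decay_tau=p.get("decay_tau", 8.0),
            n_frames=p.get("n_frames", 30),
            seed=derive_seed(self.seed, 200 + stack_index),
        )

    def noise_model(self, stream: int = 0) -> NoiseModel:
        n = self.raw["noise"]
        return NoiseModel(
            photons_per_unit_at_ref_speed=n.get("photons_per_unit_at_ref_speed", 4.0),
            ref_speed=n.get("ref_speed", 1650.0),
            read_noise_sigma=n.get("read_noise_sigma", 3.0),
            seed=derive_seed(self.seed, 300 + stream),
        )

    def scan_config(self) -> ScanConfig:
        s = self.raw["scan"]
        return ScanConfig(
            scanning_speed=s.get("scanning_speed", 3360.0),
            scanning_density=s.get("scanning_density", 512),
            duty_ratio=s.get("duty_ratio", 0.5),
            M=s.get("M", 1),
        )

    def gan_config(self, stage: int, M: int | None = None) -> GanConfig:
        sec = self.raw["stage1" if stage == 1 else "stage2"]
        p = self.raw["phantom"]
        stream = 400 + stage * 10 + (M or 0)
        return GanConfig(
            image_size=p.get("image_size", 128),
            gen_depth=sec.get("gen_depth", 3),
            base_channels=sec.get("base_channels", 16),
            patch_scale=sec.get("patch_scale", 70),
            l1_weight=sec.get("l1_weight", 100.0),
            lr=sec.get("lr", 1e-3),
            epochs=sec.get("epochs", 50),
            batch_size=sec.get("batch_size", 4),
            seed=derive_seed(self.seed, stream),
        )


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load YAML on top of the defaults (missing file -> pure defaults)."""
    raw = dict(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        raw = _merge(raw, loaded)
    if overrides:
        raw = _merge(raw, overrides)
    return RunConfig(raw=raw)
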