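"""Packaged acquisition-protocol presets (field strength, TEs, R, matrix, FA)."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .fat_model import EchoTrain

__all__ = ["ProtocolPreset", "load_presets", "get_preset", "PRESET_NAMES"]

PRESET_NAMES = (
    "protocol1_055T",
    "protocol2_055T",
    "protocol1_15T",
    "protocol2_15T",
)


@dataclass(frozen=True)
class ProtocolPreset:
    name: str
    field_strength_t: float
    te_ms: tuple
    tr_ms: float
    acceleration: int
    acquired_matrix: tuple
    flip_angle_deg: float

    def echo_train(self) -> EchoTrain:
        return EchoTrain.from_ms(
            list(self.te_ms), self.field_strength_t, repetition_time_ms=self.tr_ms
        )


def load_presets() -> dict:
    ref = resources.files("llrpdff.data").joinpath("protocols.yaml")
    raw = yaml.safe_load(ref.read_text())
    return {
        name: ProtocolPreset(
            name=name,
            field_strength_t=float(d["field_strength_t"]),
            te_ms=tuple(d["te_ms"]),
            tr_ms=float(d["tr_ms"]),
            acceleration=int(d["acceleration"]),
            acquired_matrix=tuple(d["acquired_matrix"]),
            flip_angle_deg=float(d["flip_angle_deg"]),
        )
        for name, d in raw.items()
    }


def get_preset(name: str) -> ProtocolPreset:
    presets = load_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return presets[name]
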