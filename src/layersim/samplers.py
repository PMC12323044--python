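"""Integer samplers for statewidths and spreading offsets.

Binding-factor geometry parameters can be drawn per application from a
distribution instead of being fixed — the mechanism the spreading models
use to generate, e.g., normally distributed spreading distances with
mean 147 bp and SD 30 bp (roughly one nucleosome plus linker).

A sampler returns integers.  ``signed`` declares whether its draws carry
their own sign; unsigned (magnitude) samplers get a uniformly random
sign applied by the placement step, giving bidirectional spreading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class SamplerError(ValueError):
    pass


@dataclass(frozen=True)
class ConstantSampler:
    value: int
    signed: bool = True

    def draw(self, rng: np.random.Generator) -> int:
        return int(self.value)

    def to_dict(self) -> dict:
        return {"dist": "constant", "value": int(self.value)}


@dataclass(frozen=True)
class UniformSampler:
    """Uniform integer draw from [lo, hi] inclusive."""

    lo: int
    hi: int
    signed: bool = False

    def __post_init__(self):
        if self.hi < self.lo:
            raise SamplerError(f"uniform sampler needs lo <= hi, got [{self.lo}, {self.hi}]")

    def draw(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.lo, self.hi + 1))

    def to_dict(self) -> dict:
        return {"dist": "uniform", "lo": int(self.lo), "hi": int(self.hi),
                "signed": self.signed}


@dataclass(frozen=True)
class NormalSampler:
    """Rounded normal draw; unsigned samplers return the magnitude."""

    mean: float
    sd: float
    signed: bool = False

    def __post_init__(self):
        if self.sd < 0:
            raise SamplerError("sd must be >= 0")

    def draw(self, rng: np.random.Generator) -> int:
        x = rng.normal(self.mean, self.sd)
        return int(round(x if self.signed else abs(x)))

    def to_dict(self) -> dict:
        return {"dist": "normal", "mean": float(self.mean), "sd": float(self.sd),
                "signed": self.signed}


def sampler_from_dict(d: dict):
    kind = d.get("dist")
    if kind == "constant":
        return ConstantSampler(int(d["value"]))
    if kind == "uniform":
        return UniformSampler(int(d["lo"]), int(d["hi"]), bool(d.get("signed", False)))
    if kind == "normal":
        return NormalSampler(float(d["mean"]), float(d["sd"]),
                             bool(d.get("signed", False)))
    raise SamplerError(f"unknown sampler spec {d!r}")
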