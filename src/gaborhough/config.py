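"""Pipeline configuration: nested dataclasses with flat-dotted YAML I/O.

Every parameter has a default; an empty config runs the pipeline end-to-end
on a phantom.  The on-disk form is a flat mapping of dotted keys
(``gabor.wavelengths: [8, 16]``) so single values are easy to override from
the command line.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

__all__ = ["PipelineConfig"]

CONFIG_VERSION = "1"


@dataclass
class GaborConfig:
    orientations: list[float] = field(
        default_factory=lambda: [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]
    )
    wavelengths: list[float] = field(default_factory=lambda: [8.0, 16.0])
    gamma: float = 0.5
    bandwidth: float = 1.0


@dataclass
class RoiConfig:
    margin: int = 8
    closing_radius: int = 2


@dataclass
class GhtConfig:
    n_bins: int = 36
    edge_percentile: float = 75.0
    sx: list[float] = field(default_factory=lambda: [0.85, 1.15, 0.05])
    sy: list[float] | None = None  # None: same as sx
    theta: list[float] = field(
        default_factory=lambda: [-np.pi / 6, np.pi / 6, np.pi / 36]
    )
    k: int = 10
    suppression_radius: float = 5.0


@dataclass
class BandConfig:
    beta: float = 0.1
    lateral_halfwidth: float = 6.0


@dataclass
class PipelineConfig:
    gabor: GaborConfig = field(default_factory=GaborConfig)
    roi: RoiConfig = field(default_factory=RoiConfig)
    ght: GhtConfig = field(default_factory=GhtConfig)
    band: BandConfig = field(default_factory=BandConfig)
    template_path: str | None = None
    confidence_model_path: str | None = None
    seed: int = 0
    version: str = CONFIG_VERSION

    # -- flat-dotted serialization ----------------------------------------
    def to_flat_dict(self) -> dict:
        flat: dict = {}

        def walk(prefix: str, obj) -> None:
            for f in fields(obj):
                v = getattr(obj, f.name)
                key = f"{prefix}{f.name}"
                if hasattr(v, "__dataclass_fields__"):
                    walk(key + ".", v)
                else:
                    flat[key] = v
        walk("", self)
        return dict(sorted(flat.items()))

    @classmethod
    def from_flat_dict(cls, flat: dict) -> "PipelineConfig":
        cfg = cls()
        for key, value in flat.items():
            obj = cfg
            *parts, last = key.split(".")
            for p in parts:
                obj = getattr(obj, p)
            if not hasattr(obj, last):
                raise KeyError(f"unknown config key: {key}")
            setattr(obj, last, value)
        return cfg

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_flat_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        return cls.from_flat_dict(data)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())
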