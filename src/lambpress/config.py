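"""Run configuration: the fit settings plus processing and seeding knobs.

A ``RunConfig`` serializes losslessly to JSON and back; every pipeline
output embeds the effective configuration so runs are reproducible from
their result files alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .inversion import FitConfig
from .wavefield import KSpaceConfig


@dataclass(frozen=True)
class RunConfig:
    fit: FitConfig = field(default_factory=FitConfig)
    kspace: KSpaceConfig = field(default_factory=KSpaceConfig)
    seed: int = 0
    pressure_unit: str = "mmHg"  # boundary unit; SI internally

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            return cls(fit=FitConfig(**d.get("fit", {})),
                       kspace=KSpaceConfig(**d.get("kspace", {})),
                       seed=int(d.get("seed", 0)),
                       pressure_unit=str(d.get("pressure_unit", "mmHg")))
        except TypeError as exc:
            raise ValueError(f"invalid run configuration: {exc}") from exc

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
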