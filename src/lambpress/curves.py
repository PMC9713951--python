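"""Dispersion-curve containers shared by the processing and fitting stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DispersionCurve", "AcquisitionSet"]


@dataclass
class DispersionCurve:
    """Frequency-resolved phase velocity samples (f [Hz], c [m/s]).

    Frequencies are strictly increasing and positive; velocities positive.
    Optional labels identify the acquisition replicate and fill volume the
    curve came from.
    """

    f: np.ndarray
    c: np.ndarray
    fill_volume_ml: float | None = None
    acquisition: int | None = None

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.f.shape != self.c.shape or self.f.ndim != 1:
            raise ValueError("f and c must be 1-D arrays of equal length")
        if self.f.size:
            if np.any(self.f <= 0):
                raise ValueError("frequencies must be positive")
            if np.any(np.diff(self.f) <= 0):
                raise ValueError("frequencies must be strictly increasing")
            if np.any(self.c <= 0):
                raise ValueError("phase velocities must be positive")

    def __len__(self) -> int:
        return self.f.size

    def restrict(self, f_min: float, f_max: float) -> "DispersionCurve":
        """Samples with f_min <= f <= f_max (closed interval)."""
        m = (self.f >= f_min) & (self.f <= f_max)
        return DispersionCurve(self.f[m], self.c[m],
                               fill_volume_ml=self.fill_volume_ml,
                               acquisition=self.acquisition)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fill_volume_ml": self.fill_volume_ml,
            "acquisition": self.acquisition,
            "frequency_hz": self.f,
            "phase_velocity_m_s": self.c,
        })


@dataclass
class AcquisitionSet:
    """Replicate dispersion curves, possibly across several fill volumes."""

    curves: list[DispersionCurve] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.curves)

    def for_fill(self, fill_volume_ml: float) -> "AcquisitionSet":
        return AcquisitionSet([c for c in self.curves
                               if c.fill_volume_ml == fill_volume_ml])

    @property
    def fill_volumes(self) -> list[float]:
        seen: list[float] = []
        for c in self.curves:
            if c.fill_volume_ml is not None and c.fill_volume_ml not in seen:
                seen.append(c.fill_volume_ml)
        return seen

    def to_frame(self) -> pd.DataFrame:
        if not self.curves:
            return pd.DataFrame(columns=["fill_volume_ml", "acquisition",
                                         "frequency_hz", "phase_velocity_m_s"])
        return pd.concat([c.to_frame() for c in self.curves], ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AcquisitionSet":
        curves = []
        for (fill, acq), g in df.groupby(["fill_volume_ml", "acquisition"],
                                         dropna=False, sort=True):
            g = g.sort_values("frequency_hz")
            curves.append(DispersionCurve(
                g["frequency_hz"].to_numpy(), g["phase_velocity_m_s"].to_numpy(),
                fill_volume_ml=None if pd.isna(fill) else float(fill),
                acquisition=None if pd.isna(acq) else int(acq)))
        return cls(curves)
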