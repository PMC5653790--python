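"""The pipeline's central 1-D object: intensity along the radial axis."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RadialProfile"]

MIN_PROFILE_LENGTH = 32


@dataclass
class RadialProfile:
    """Band intensity as a function of radial position.

    ``positions`` are 0-based pixel centers, strictly increasing away
    from the colony seed.  ``time_axis`` is filled once a pixel→hour
    calibration is available.  ``provenance`` is an append-only log of
    the processing stages the profile has been through.
    """

    positions: np.ndarray
    intensities: np.ndarray
    time_axis: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must have equal length")
        if self.positions.size < MIN_PROFILE_LENGTH:
            raise ValueError(f"profile needs >= {MIN_PROFILE_LENGTH} samples")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.time_axis is not None:
            self.time_axis = np.asarray(self.time_axis, dtype=float)

    def __len__(self) -> int:
        return self.positions.size

    def with_intensities(self, intensities: np.ndarray, note: str) -> "RadialProfile":
        """New profile with replaced intensities and an extra log entry."""
        return replace(
            self,
            intensities=np.asarray(intensities, dtype=float),
            provenance=[*self.provenance, note],
        )

    def processed_by(self, stage: str) -> bool:
        return any(stage in entry for entry in self.provenance)

    # -- I/O -----------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        cols = {"position_px": self.positions, "intensity": self.intensities}
        if self.time_axis is not None:
            cols["time_h"] = self.time_axis
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RadialProfile":
        df = pd.read_csv(path)
        if not {"position_px", "intensity"} <= set(df.columns):
            raise ValueError("profile CSV needs position_px and intensity columns")
        time_axis = df["time_h"].to_numpy() if "time_h" in df.columns else None
        return cls(
            positions=df["position_px"].to_numpy(),
            intensities=df["intensity"].to_numpy(),
            time_axis=time_axis,
            provenance=[f"loaded from {Path(path).name}"],
        )
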