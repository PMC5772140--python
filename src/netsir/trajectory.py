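"""Shared container for mean-field solver output."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MeanFieldTrajectory"]


@dataclass(frozen=True)
class MeanFieldTrajectory:
    """S/I/R fractions and the edge message on a uniform time grid.

    ``message`` is the probability that a random neighbour of a cavity-state
    test node has not attempted transmission to it by time t (H1 in the
    message-passing formulation, Theta in the edge-based one).
    """

    t: np.ndarray
    message: np.ndarray
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    z: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("t", "message", "S", "I", "R"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.shape
        for name in ("message", "S", "I", "R"):
            if getattr(self, name).shape != n:
                raise ValueError(f"{name} series does not match the time grid")

    @property
    def h(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "S": self.S, "I": self.I, "R": self.R, "message": self.message}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    def peak(self) -> tuple[float, float]:
        """(time, height) of the prevalence peak."""
        i = int(np.argmax(self.I))
        return float(self.t[i]), float(self.I[i])
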