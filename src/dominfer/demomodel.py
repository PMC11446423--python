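"""Demographic model containers shared by the diffusion and fitting code.

Sizes are relative to the ancestral population (multiples of N_anc); times
are in units of 2*N_anc generations, ordered past -> present.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

__all__ = ["Epoch", "DemographicModel", "three_epoch_model"]


@dataclass(frozen=True)
class Epoch:
    relative_size_start: float
    relative_size_end: float
    duration: float
    growth: str = "constant"  # "constant" | "exponential"

    def __post_init__(self) -> None:
        if self.relative_size_start <= 0 or self.relative_size_end <= 0:
            raise ValueError("relative sizes must be positive")
        if self.duration <= 0:
            raise ValueError("epoch duration must be positive")
        if self.growth not in ("constant", "exponential"):
            raise ValueError(f"unknown growth mode {self.growth!r}")
        if self.growth == "constant" and self.relative_size_start != self.relative_size_end:
            raise ValueError("constant epochs must have equal start and end sizes")

    def size_at(self, t: float) -> float:
        """Relative size a fraction ``t/duration`` of the way through the epoch."""
        if self.growth == "constant":
            return self.relative_size_start
        frac = min(max(t / self.duration, 0.0), 1.0)
        return self.relative_size_start * (self.relative_size_end / self.relative_size_start) ** frac


@dataclass(frozen=True)
class DemographicModel:
    """An ordered (past -> present) list of epochs after ancestral equilibrium."""

    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", tuple(self.epochs))
        if not self.epochs:
            raise ValueError("a demographic model needs at least one epoch")

    @property
    def model_id(self) -> str:
        """Stable hash of the epoch parameters, used to key grid caches."""
        desc = ";".join(
            f"{e.relative_size_start:.12g},{e.relative_size_end:.12g},"
            f"{e.duration:.12g},{e.growth}"
            for e in self.epochs
        )
        return hashlib.sha1(desc.encode()).hexdigest()[:16]


def three_epoch_model(
    N1: float, T1: float, N2: float, T2: float, NC: float, TC: float
) -> DemographicModel:
    """Bottleneck (N1, T1) -> recovery (N2, T2) -> exponential growth N2 -> NC over TC.

    The growth epoch starts from the recovery size N2, the conventional
    reading of a bottleneck / recovery / recent-growth history.
    """
    return DemographicModel(
        (
            Epoch(N1, N1, T1, "constant"),
            Epoch(N2, N2, T2, "constant"),
            Epoch(N2, NC, TC, "exponential"),
        )
    )
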