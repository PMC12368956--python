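"""Stimulation protocol and single trials.

The protocol captures the long-train stimulation parameters (500 ms trains
of 0.4 ms biphasic pulses at 300 Hz) and the current staircase used for
threshold hunting: 10 uA steps for thresholds below 150 uA, 50 uA steps at
or above, with a 300 uA ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping


@dataclass(frozen=True)
class StimTrial:
    """One stimulation train at a given current and whether a movement was seen."""

    current_ua: float
    observed: bool

    def __post_init__(self) -> None:
        if not self.current_ua > 0:
            raise ValueError(f"trial current must be positive, got {self.current_ua}")


@dataclass(frozen=True)
class StimProtocol:
    """Stimulation-train and staircase parameters (currents in uA)."""

    train_ms: float = 500.0
    pulse_ms: float = 0.4
    rate_hz: float = 300.0
    max_current_ua: float = 300.0
    step_low_ua: float = 10.0
    step_high_ua: float = 50.0
    step_breakpoint_ua: float = 150.0

    def __post_init__(self) -> None:
        vals = (
            self.train_ms,
            self.pulse_ms,
            self.rate_hz,
            self.max_current_ua,
            self.step_low_ua,
            self.step_high_ua,
            self.step_breakpoint_ua,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all protocol parameters must be positive")
        if self.step_low_ua > self.step_high_ua:
            raise ValueError("step_low_ua must not exceed step_high_ua")
        if self.max_current_ua < self.step_breakpoint_ua:
            raise ValueError("max_current_ua must be >= step_breakpoint_ua")

    def step_at(self, threshold_ua: float) -> float:
        """Staircase step applicable to a threshold value."""
        if threshold_ua < self.step_breakpoint_ua:
            return self.step_low_ua
        return self.step_high_ua

    def grid(self) -> tuple[float, ...]:
        """Test currents of the staircase: fine steps up to the breakpoint,
        coarse steps from the breakpoint to the ceiling."""
        fine = [
            self.step_low_ua * k
            for k in range(1, int(round(self.step_breakpoint_ua / self.step_low_ua)) + 1)
        ]
        coarse: list[float] = []
        c = self.step_breakpoint_ua + self.step_high_ua
        while c <= self.max_current_ua + 1e-9:
            coarse.append(c)
            c += self.step_high_ua
        return tuple(fine + coarse)

    def on_grid(self, current_ua: float, tol: float = 1e-9) -> bool:
        return any(abs(current_ua - g) <= tol for g in self.grid())


def protocol_from_dict(cfg: Mapping) -> StimProtocol:
    """Build a protocol from a configuration mapping (e.g. parsed YAML)."""
    return StimProtocol(**dict(cfg))
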