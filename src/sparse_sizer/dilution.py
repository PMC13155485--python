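"""Volume-weighted dilution arithmetic for saline-spiked specimens."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DilutionSpec", "final_concentration"]


@dataclass(frozen=True)
class DilutionSpec:
    """A base fluid spiked with a concentrated solution.

    Volumes in ml; concentrations in % w/v (the mixing rule is linear in
    concentration for dilute solutes, so the unit cancels).
    """

    base_volume: float
    base_concentration: float
    spike_volume: float
    spike_concentration: float

    def __post_init__(self) -> None:
        if self.base_volume <= 0 or self.spike_volume <= 0:
            raise ValueError("volumes must be positive")


def final_concentration(spec: DilutionSpec) -> float:
    """Volume-weighted mean concentration after spiking."""
    return (
        spec.base_volume * spec.base_concentration
        + spec.spike_volume * spec.spike_concentration
    ) / (spec.base_volume + spec.spike_volume)
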