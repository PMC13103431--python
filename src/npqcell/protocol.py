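"""Illumination protocols and the saturating-pulse sampling grid.

A pulse-amplitude-modulated (PAM) experiment alternates actinic light
phases (high light, low light, dark) while brief saturating pulses (SPs)
probe the maximal fluorescence yield F_m′ at regular intervals.  The SP
schedule therefore defines the sampling grid of every F_m′ trace: one
sample per pulse.

The reference protocol used throughout this package is 15 min of high
light (400 µmol photons m⁻² s⁻¹, 470 nm) followed by 15 min of darkness,
with one 200 ms saturating pulse (1400 µmol photons m⁻² s⁻¹, 405 nm)
every 20 s starting at t = 0, which yields 91 samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "PhaseLabel",
    "LightPhase",
    "PulseSchedule",
    "Protocol",
    "build_reference_protocol",
    "pulse_times",
    "phase_at",
]


class PhaseLabel(str, Enum):
    """Actinic illumination state of a protocol phase."""

    HL = "HL"
    LOW = "LOW"
    DARK = "DARK"


@dataclass(frozen=True)
class LightPhase:
    """A contiguous actinic light phase.

    Parameters
    ----------
    label:
        Illumination state (HL, LOW or DARK).
    start:
        Phase start time in seconds (>= 0).
    duration:
        Phase duration in seconds (> 0).
    intensity:
        Actinic photon flux in µmol photons m⁻² s⁻¹ (0 for DARK).
    wavelength:
        Actinic LED centre wavelength in nm, or None for DARK.
    """

    label: PhaseLabel
    start: float
    duration: float
    intensity: float
    wavelength: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("phase start must be >= 0")
        if self.duration <= 0:
            raise ValueError("phase duration must be > 0")
        if self.intensity < 0:
            raise ValueError("phase intensity must be >= 0")
        if self.label is PhaseLabel.DARK and self.intensity != 0:
            raise ValueError("DARK phase must have zero intensity")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def is_light(self) -> bool:
        return self.label is not PhaseLabel.DARK


@dataclass(frozen=True)
class PulseSchedule:
    """Periodic saturating-pulse schedule.

    ``period`` is the pulse spacing in seconds, ``pulse_duration`` the SP
    length in seconds (must be shorter than the period); intensity and
    wavelength describe the SP LED.
    """

    period: float = 20.0
    pulse_duration: float = 0.2
    intensity: float = 1400.0
    wavelength: float = 405.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("pulse period must be > 0")
        if not self.pulse_duration < self.period:
            raise ValueError("pulse_duration must be smaller than the period")


@dataclass(frozen=True)
class Protocol:
    """Ordered actinic phases plus the saturating-pulse schedule."""

    phases: tuple[LightPhase, ...]
    pulses: PulseSchedule = field(default_factory=PulseSchedule)

    def __post_init__(self) -> None:
        phases = tuple(self.phases)
        object.__setattr__(self, "phases", phases)
        if not phases:
            raise ValueError("protocol needs at least one phase")
        t = phases[0].start
        if t != 0:
            raise ValueError("first phase must start at t = 0")
        for ph in phases:
            if not math.isclose(ph.start, t, rel_tol=0, abs_tol=1e-9):
                raise ValueError("phases must be contiguous and non-overlapping")
            t = ph.end

    @property
    def total_duration(self) -> float:
        return self.phases[-1].end

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "units": {"time": "s", "intensity": "umol_photons_m-2_s-1",
                      "wavelength": "nm"},
            "phases": [
                {
                    "label": ph.label.value,
                    "duration": ph.duration,
                    "intensity": ph.intensity,
                    "wavelength": ph.wavelength,
                }
                for ph in self.phases
            ],
            "pulses": {
                "period": self.pulses.period,
                "pulse_duration": self.pulses.pulse_duration,
                "intensity": self.pulses.intensity,
                "wavelength": self.pulses.wavelength,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        phases = []
        t = 0.0
        for entry in d["phases"]:
            phases.append(
                LightPhase(
                    label=PhaseLabel(entry["label"]),
                    start=t,
                    duration=float(entry["duration"]),
                    intensity=float(entry["intensity"]),
                    wavelength=entry.get("wavelength"),
                )
            )
            t += float(entry["duration"])
        p = d["pulses"]
        return cls(
            phases=tuple(phases),
            pulses=PulseSchedule(
                period=float(p["period"]),
                pulse_duration=float(p["pulse_duration"]),
                intensity=float(p["intensity"]),
                wavelength=float(p["wavelength"]),
            ),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "Protocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_reference_protocol() -> Protocol:
    """Reference high-light/dark protocol: 15 min HL then 15 min dark.

    High light is 400 µmol photons m⁻² s⁻¹ at 470 nm; saturating pulses of
    200 ms at 1400 µmol photons m⁻² s⁻¹ (405 nm) every 20 s, the first one
    at t = 0.  The resulting F_m′ sampling grid has 91 points.
    """
    return Protocol(
        phases=(
            LightPhase(PhaseLabel.HL, start=0.0, duration=900.0,
                       intensity=400.0, wavelength=470.0),
            LightPhase(PhaseLabel.DARK, start=900.0, duration=900.0,
                       intensity=0.0, wavelength=None),
        ),
        pulses=PulseSchedule(period=20.0, pulse_duration=0.2,
                             intensity=1400.0, wavelength=405.0),
    )


def pulse_times(p: Protocol) -> np.ndarray:
    """Saturating-pulse times t_k = k·period within [0, total duration].

    Returns ``floor(total/period) + 1`` strictly increasing times; the
    first pulse fires at t = 0 (the dark-adapted F_m sample).
    """
    n = int(math.floor(p.total_duration / p.pulses.period + 1e-9)) + 1
    return np.arange(n, dtype=float) * p.pulses.period


def phase_at(p: Protocol, t: float) -> LightPhase:
    """Phase containing time ``t``.

    Phases are half-open ``[start, start + duration)`` so a pulse at a
    light→dark boundary samples the new phase; the protocol's final
    instant maps to the last phase.
    """
    if t < 0 or t > p.total_duration:
        raise ValueError(
            f"t={t} outside protocol [0, {p.total_duration}]")
    for ph in p.phases:
        if ph.start <= t < ph.end:
            return ph
    return p.phases[-1]


def light_state(p: Protocol, times: Sequence[float]) -> np.ndarray:
    """Boolean array: True where the actinic light is on at each time."""
    return np.array([phase_at(p, float(t)).is_light for t in times])
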