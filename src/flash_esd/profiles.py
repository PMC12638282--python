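"""Piecewise-constant temporal dose-delivery profiles.

A delivery profile is the time course of the instantaneous dose rate
``Ddot(t)`` at the dosimetric reference point, represented as an ordered
list of constant-rate segments.  All delivery archetypes handled here —
continuous constant-rate beams, rectangular-pulsed beams, pencil-beam spot
sequences and split schedules with pauses — are exactly piecewise constant,
so no further discretization is introduced downstream.

Conventions
-----------
* Exposure time runs from first beam-on to last beam-off; leading or
  trailing zero-rate segments are disallowed, interior pauses are kept.
* The time-averaged dose rate (TADR) is total dose over exposure time,
  pauses included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence


@dataclass(frozen=True)
class ProfileSegment:
    """One constant-rate stretch of a delivery: ``duration`` s at ``dose_rate`` Gy/s."""

    duration: float
    dose_rate: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.duration) and self.duration > 0):
            raise ValueError(f"segment duration must be positive and finite, got {self.duration}")
        if not (math.isfinite(self.dose_rate) and self.dose_rate >= 0):
            raise ValueError(f"segment dose rate must be finite and >= 0, got {self.dose_rate}")

    @property
    def dose(self) -> float:
        return self.duration * self.dose_rate


@dataclass(frozen=True)
class DeliveryProfile:
    """Ordered piecewise-constant dose-rate time course Ddot(t).

    The profile is the sole carrier of temporal delivery structure: every
    downstream quantity (latent-state trajectory, RRS-weighted dose, FMF)
    is a functional of it.
    """

    segments: tuple[ProfileSegment, ...]
    label: str = ""

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        if not segs:
            raise ValueError("a delivery profile needs at least one segment")
        if segs[0].dose_rate == 0 or segs[-1].dose_rate == 0:
            raise ValueError(
                "leading/trailing zero-rate segments are not part of the exposure; trim them"
            )
        object.__setattr__(self, "segments", segs)

    @property
    def total_dose(self) -> float:
        return sum(s.dose for s in self.segments)

    @property
    def exposure_time(self) -> float:
        """First beam-on to last beam-off, interior pauses included."""
        return sum(s.duration for s in self.segments)

    @property
    def tadr(self) -> float:
        """Time-averaged dose rate (Gy/s), pauses included."""
        return self.total_dose / self.exposure_time

    @property
    def max_dose_rate(self) -> float:
        return max(s.dose_rate for s in self.segments)

    def __len__(self) -> int:
        return len(self.segments)


def make_constant(dose: float, dose_rate: float, label: str = "") -> DeliveryProfile:
    """Continuous constant-rate delivery of ``dose`` Gy at ``dose_rate`` Gy/s."""
    if not dose > 0:
        raise ValueError(f"dose must be positive, got {dose}")
    if not dose_rate > 0:
        raise ValueError(f"dose rate must be positive, got {dose_rate}")
    return DeliveryProfile(
        (ProfileSegment(dose / dose_rate, dose_rate),), label=label or f"const-{dose_rate:g}Gy_s"
    )


def make_pulsed(
    total_dose: float,
    n_pulses: int,
    pulse_width: float,
    repetition_frequency: float,
    label: str = "",
) -> DeliveryProfile:
    """Rectangular-pulsed delivery: equal-dose pulses at a fixed repetition rate.

    The in-pulse dose rate is ``total_dose / (n_pulses * pulse_width)``;
    pulses are separated by zero-rate gaps of ``1/f - pulse_width`` so the
    exposure time is ``(n_pulses - 1)/f + pulse_width``.
    """
    if not total_dose > 0:
        raise ValueError(f"total dose must be positive, got {total_dose}")
    if n_pulses < 1:
        raise ValueError(f"need at least one pulse, got {n_pulses}")
    if not pulse_width > 0:
        raise ValueError(f"pulse width must be positive, got {pulse_width}")
    in_pulse_rate = total_dose / (n_pulses * pulse_width)
    if n_pulses == 1:
        return DeliveryProfile(
            (ProfileSegment(pulse_width, in_pulse_rate),), label=label or "pulsed-1"
        )
    if not repetition_frequency > 0:
        raise ValueError("repetition frequency must be positive for multi-pulse deliveries")
    duty = pulse_width * repetition_frequency
    if duty >= 1:
        raise ValueError(
            f"duty cycle {duty:g} >= 1: pulses overlap at width {pulse_width} s, "
            f"frequency {repetition_frequency} Hz"
        )
    gap = 1.0 / repetition_frequency - pulse_width
    segs: list[ProfileSegment] = []
    for i in range(n_pulses):
        segs.append(ProfileSegment(pulse_width, in_pulse_rate))
        if i < n_pulses - 1:
            segs.append(ProfileSegment(gap, 0.0))
    return DeliveryProfile(tuple(segs), label=label or f"pulsed-{n_pulses}")


def make_split(
    sub_profile: DeliveryProfile, n_parts: int, pause: float, label: str = ""
) -> DeliveryProfile:
    """Split the delivery into ``n_parts`` equal-dose copies separated by pauses.

    Each part is ``sub_profile`` with all segment durations divided by
    ``n_parts`` (dose rates unchanged), so the total dose is preserved
    exactly.  A zero-rate pause of ``pause`` seconds separates consecutive
    parts; ``n_parts == 1`` returns an identical profile.
    """
    if n_parts < 1:
        raise ValueError(f"need at least one part, got {n_parts}")
    if pause < 0:
        raise ValueError(f"pause must be >= 0, got {pause}")
    if n_parts == 1:
        return DeliveryProfile(sub_profile.segments, label=label or sub_profile.label)
    part = tuple(ProfileSegment(s.duration / n_parts, s.dose_rate) for s in sub_profile.segments)
    segs: list[ProfileSegment] = []
    for i in range(n_parts):
        segs.extend(part)
        if i < n_parts - 1 and pause > 0:
            segs.append(ProfileSegment(pause, 0.0))
    return DeliveryProfile(tuple(segs), label=label or f"{sub_profile.label}-split{n_parts}")


def make_spot_scan(
    spot_doses: Sequence[float],
    spot_durations: Sequence[float],
    dead_times: Sequence[float],
    label: str = "",
) -> DeliveryProfile:
    """Pencil-beam spot sequence at the reference point.

    Spatial structure is abstracted away: each spot contributes its dose at
    the reference point over its delivery duration, separated by beam-off
    dead times (``len(dead_times) == len(spot_doses) - 1``).
    """
    if len(spot_doses) != len(spot_durations):
        raise ValueError(
            f"spot_doses ({len(spot_doses)}) and spot_durations ({len(spot_durations)}) differ"
        )
    if len(dead_times) != len(spot_doses) - 1:
        raise ValueError(
            f"need exactly {len(spot_doses) - 1} dead times for {len(spot_doses)} spots, "
            f"got {len(dead_times)}"
        )
    segs: list[ProfileSegment] = []
    for i, (d, tau) in enumerate(zip(spot_doses, spot_durations)):
        if not d > 0:
            raise ValueError(f"spot dose must be positive, got {d} at index {i}")
        segs.append(ProfileSegment(tau, d / tau))
        if i < len(dead_times) and dead_times[i] > 0:
            segs.append(ProfileSegment(dead_times[i], 0.0))
        elif i < len(dead_times) and dead_times[i] < 0:
            raise ValueError(f"dead time must be >= 0, got {dead_times[i]}")
    return DeliveryProfile(tuple(segs), label=label or f"spots-{len(spot_doses)}")


def profile_summary(profile: DeliveryProfile) -> tuple[float, float, float]:
    """Return ``(total_dose_gy, exposure_time_s, tadr_gy_s)``."""
    return profile.total_dose, profile.exposure_time, profile.tadr
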