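"""Synthetic delivery suites, FMF datasets and animal cohorts.

The generator emulates the statistical structure of a murine acute-skin
FLASH study: delivery profiles spanning 18-53 Gy and time-averaged dose
rates of 0.11-111 Gy/s across four archetypes (continuous constant-rate
beams, rectangular-pulsed beams, pencil-beam spot sequences, and split
schedules with 2-minute pauses), including dose-rate scans at a fixed
dose.  Cohorts draw binary toxicity outcomes from a logistic NTCP curve
evaluated at the RRS-weighted dose, so the full pipeline — cohort ->
reference fit -> FMF derivation -> model fit — can be exercised and its
parameter recovery quantified without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from flash_esd.core import ESDParameters, ModelVariant, fmf_pred, rrs
from flash_esd.fitting import FMFDataset, FMFEntry
from flash_esd.ntcp import LogisticNTCP, SubjectRecord
from flash_esd.profiles import (
    DeliveryProfile,
    make_constant,
    make_pulsed,
    make_split,
    make_spot_scan,
)

#: reference dose-response curves used as cohort fixtures; values are chosen
#: so the suite's doses land on the informative part of the curve
DEFAULT_ELECTRON_REFERENCE = LogisticNTCP(d50=26.0, slope_scale=1.5)
DEFAULT_PROTON_REFERENCE = LogisticNTCP(d50=30.0, slope_scale=1.5)

#: constant reference dose rates (Gy/s) for electron-like and proton-like data
ELECTRON_REF_RATE = 0.11
PROTON_REF_RATE = 0.37

_PULSE_WIDTH = 1.8e-6  # s, linac macro-pulse width
_PULSE_FREQUENCY = 100.0  # Hz


@dataclass(frozen=True)
class SuiteSpec:
    """Specification of a synthetic delivery-profile suite.

    Fractions select the archetype mix and must sum to 1; half of the
    constant-rate budget is spent on a dose-rate scan at a fixed dose
    (the classic rate-scan design) and the rest on random (dose, rate)
    pairs covering the requested ranges.
    """

    n_profiles: int = 52
    dose_range: tuple[float, float] = (18.0, 53.0)
    tadr_range: tuple[float, float] = (0.11, 111.0)
    f_constant: float = 0.35
    f_pulsed: float = 0.15
    f_spot_scan: float = 0.25
    f_split: float = 0.25
    pause: float = 120.0
    scan_dose: float = 39.3
    split_sub_rate: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_profiles < 0:
            raise ValueError("n_profiles must be >= 0")
        if not 0 < self.dose_range[0] < self.dose_range[1]:
            raise ValueError(f"bad dose range {self.dose_range}")
        if not 0 < self.tadr_range[0] < self.tadr_range[1]:
            raise ValueError(f"bad TADR range {self.tadr_range}")
        total = self.f_constant + self.f_pulsed + self.f_spot_scan + self.f_split
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype fractions must sum to 1, got {total}")
        if self.pause < 0:
            raise ValueError("pause must be >= 0")


def _apportion(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n slots among fractions."""
    raw = [f * n for f in fractions]
    counts = [int(math.floor(x)) for x in raw]
    rest = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rest]:
        counts[i] += 1
    return counts


def generate_profile_suite(spec: SuiteSpec) -> list[DeliveryProfile]:
    """Seeded, reproducible suite of delivery profiles covering the spec's ranges."""
    if spec.n_profiles == 0:
        return []
    rng = np.random.default_rng(spec.seed)
    d_lo, d_hi = spec.dose_range
    t_lo, t_hi = spec.tadr_range
    n_const, n_pulsed, n_spot, n_split = _apportion(
        spec.n_profiles, [spec.f_constant, spec.f_pulsed, spec.f_spot_scan, spec.f_split]
    )
    profiles: list[DeliveryProfile] = []

    # constant-rate: a dose-rate scan at fixed dose plus random (dose, rate) pairs
    n_scan = n_const // 2
    scan_dose = min(max(spec.scan_dose, d_lo), d_hi)
    if n_scan == 1:
        rates = [math.sqrt(t_lo * t_hi)]
    else:
        rates = list(np.geomspace(t_lo, t_hi, n_scan))
    for i, rate in enumerate(rates):
        profiles.append(make_constant(scan_dose, rate, label=f"scan-{i:02d}"))
    for i in range(n_const - n_scan):
        dose = rng.uniform(d_lo, d_hi)
        rate = math.exp(rng.uniform(math.log(t_lo), math.log(t_hi)))
        profiles.append(make_constant(dose, rate, label=f"const-{i:02d}"))

    # rectangular-pulsed: linac-style micro-pulses, TADR set by the pulse count
    for i in range(n_pulsed):
        dose = rng.uniform(d_lo, d_hi)
        tadr_target = math.exp(
            rng.uniform(math.log(max(t_lo, 40.0)), math.log(0.97 * t_hi))
        )
        n_pulses = max(1, round((dose / tadr_target - _PULSE_WIDTH) * _PULSE_FREQUENCY + 1))
        prof = make_pulsed(dose, n_pulses, _PULSE_WIDTH, _PULSE_FREQUENCY,
                           label=f"pulsed-{i:02d}")
        while prof.tadr > t_hi:
            n_pulses += 1
            prof = make_pulsed(dose, n_pulses, _PULSE_WIDTH, _PULSE_FREQUENCY,
                               label=f"pulsed-{i:02d}")
        profiles.append(prof)

    # spot scans: equal-dose spots with dead times; duty set by a beam-on fraction
    for i in range(n_spot):
        dose = rng.uniform(d_lo, d_hi)
        tadr_target = math.exp(
            rng.uniform(math.log(max(t_lo, 20.0)), math.log(min(t_hi, 100.0)))
        )
        total_time = dose / tadr_target
        n_spots = int(rng.integers(5, 13))
        beam_frac = rng.uniform(0.75, 0.95)
        weights = rng.uniform(0.5, 1.5, n_spots)
        durations = beam_frac * total_time * weights / weights.sum()
        dead = [(1.0 - beam_frac) * total_time / (n_spots - 1)] * (n_spots - 1)
        profiles.append(
            make_spot_scan([dose / n_spots] * n_spots, list(durations), dead,
                           label=f"spot-{i:02d}")
        )

    # split schedules: equal sub-deliveries at a fixed sub-rate with long pauses
    split_dose = min(max(spec.scan_dose, d_lo), d_hi)
    sub_rate = min(spec.split_sub_rate, t_hi)
    if spec.pause > 0:
        k_max = int((split_dose / t_lo - split_dose / sub_rate) / spec.pause) + 1
        k_max = max(1, min(6, k_max))
    else:
        k_max = 6
    for i in range(n_split):
        parts = 1 + i % k_max
        sub = make_constant(split_dose, sub_rate)
        profiles.append(make_split(sub, parts, spec.pause, label=f"split-{i:02d}-{parts}x"))

    return profiles


def default_ref_rate(profile: DeliveryProfile) -> float:
    """Reference rate by archetype: electron-like deliveries vs proton-like ones."""
    if profile.label.startswith(("pulsed", "const")):
        return ELECTRON_REF_RATE
    return PROTON_REF_RATE


def generate_fmf_dataset(
    variant: ModelVariant,
    params: ESDParameters,
    profiles: Sequence[DeliveryProfile],
    ref_dose_rate: float | Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FMFDataset:
    """FMF observations from a planted model: fmf_exp = fmf_pred + N(0, noise_sd).

    Gaussian noise is truncated to keep every observation positive (by
    redrawing).  ``ref_dose_rate`` may be a scalar, one value per profile,
    or None for the archetype default.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if ref_dose_rate is None:
        rates = [default_ref_rate(p) for p in profiles]
    elif np.isscalar(ref_dose_rate):
        rates = [float(ref_dose_rate)] * len(profiles)
    else:
        rates = [float(x) for x in ref_dose_rate]
        if len(rates) != len(profiles):
            raise ValueError("one reference rate per profile required")
    rng = np.random.default_rng(seed)
    entries = []
    for prof, rate in zip(profiles, rates):
        fmf = fmf_pred(prof, rate, variant, params)
        value = fmf + rng.normal(0.0, noise_sd) if noise_sd > 0 else fmf
        while value <= 0:  # truncate: FMF is a dose ratio and must stay positive
            value = fmf + rng.normal(0.0, noise_sd)
        entries.append(FMFEntry(profile=prof, fmf_exp=value, ref_dose_rate=rate))
    return FMFDataset(tuple(entries))


def generate_cohort(
    reference: LogisticNTCP,
    variant: ModelVariant,
    params: ESDParameters,
    profiles: Sequence[DeliveryProfile],
    group_size: int = 10,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Binary-toxicity cohort: one group per profile, purely binomial noise.

    Outcomes are Bernoulli with probability ``reference.ntcp(D_RRS)`` —
    the complication probability a conventional delivery of the
    RRS-weighted dose would produce, which is what the isoeffect
    construction assumes.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    for prof in profiles:
        dose = prof.total_dose
        drrs = rrs(prof, variant, params) * dose
        p = float(reference.ntcp(drrs))
        outcomes = rng.binomial(1, p, size=group_size)
        for j, y in enumerate(outcomes):
            records.append(
                SubjectRecord(
                    subject_id=f"{prof.label}-m{j:03d}",
                    group_id=prof.label,
                    dose=dose,
                    outcome=int(y),
                    grade="ulcer",
                    profile_id=prof.label,
                    modality="synthetic",
                )
            )
    return records
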