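"""Independent numerical oracles for cross-checking the analytic ESD solver.

Everything here deliberately avoids the package's piecewise-analytic code
path: the state equation is integrated by brute force (fixed-step RK4 on
the projected field with clamping to [0, Q0]) and isoeffective doses are
found by grid scan + bisection.  Numba keeps the fine-step integration
affordable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from flash_esd.core import ESDParameters, ModelVariant
from flash_esd.profiles import DeliveryProfile, ProfileSegment

_ESD_ID = {"ESD1": 1, "ESD2": 2, "ESD3": 3}
_RRS_ID = {"RRS1": 1, "RRS2": 2, "RRS3": 3}


@njit(cache=True)
def _srel_num(q, q0, smin, rrs_id, shape):
    if rrs_id == 1:
        return smin + (1.0 - smin) * (1.0 if q > 0.0 else 0.0)
    u = q / q0
    if rrs_id == 2:
        return smin + (1.0 - smin) * u**shape
    m = (1.0 + shape) / smin - shape
    return (1.0 + shape) * (m * u + shape) / ((m + shape) * (u + shape))


@njit(cache=True)
def _field(q, d, g, r, q0, esd_id):
    """ODE right-hand side with projected (sliding) dynamics at the boundaries."""
    if esd_id == 1:
        s = r - g * d
        if q <= 0.0:
            return max(0.0, s)
        if q >= q0:
            return min(0.0, s)
        return s
    if esd_id == 2:
        return -g * d * q + r * (q0 - q)
    s = -g * d + r * (q0 - q)
    if q <= 0.0:
        return max(0.0, -g * d + r * q0)
    if q >= q0:
        return min(0.0, s)
    return s


@njit(cache=True)
def _integrate(durations, rates, g, r, q0, smin, shape, esd_id, rrs_id, steps):
    """Clamped fixed-step RK4 per segment; trapezoidal D_RRS accumulation.

    Returns (Q at each segment end, total RRS-weighted dose).
    """
    q = q0
    drrs = 0.0
    q_ends = np.empty(len(durations))
    for i in range(len(durations)):
        d = rates[i]
        dt = durations[i] / steps
        w_prev = _srel_num(q, q0, smin, rrs_id, shape)
        for _ in range(steps):
            k1 = _field(q, d, g, r, q0, esd_id)
            q2 = min(max(q + 0.5 * dt * k1, 0.0), q0)
            k2 = _field(q2, d, g, r, q0, esd_id)
            q3 = min(max(q + 0.5 * dt * k2, 0.0), q0)
            k3 = _field(q3, d, g, r, q0, esd_id)
            q4 = min(max(q + dt * k3, 0.0), q0)
            k4 = _field(q4, d, g, r, q0, esd_id)
            qn = q + dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
            if qn < 0.0:
                qn = 0.0
            elif qn > q0:
                qn = q0
            w = _srel_num(qn, q0, smin, rrs_id, shape)
            drrs += 0.5 * (w_prev + w) * d * dt
            w_prev = w
            q = qn
        q_ends[i] = q
    return q_ends, drrs


def integrate_reference(
    profile: DeliveryProfile,
    variant: ModelVariant,
    params: ESDParameters,
    steps_per_segment: int = 60_000,
) -> tuple[np.ndarray, float]:
    """Brute-force (Q at segment ends, D_RRS) for comparison with solve_state."""
    durations = np.array([s.duration for s in profile.segments])
    rates = np.array([s.dose_rate for s in profile.segments])
    shape = params.shape if params.shape is not None else 1.0
    return _integrate(
        durations,
        rates,
        params.g,
        params.r,
        params.q0,
        params.smin,
        shape,
        _ESD_ID[variant.esd_form],
        _RRS_ID[variant.rrs_form],
        steps_per_segment,
    )


def fmf_grid_oracle(
    drrs_test: float,
    d_test: float,
    ref_dose_rate: float,
    variant: ModelVariant,
    params: ESDParameters,
    tol: float = 1e-6,
) -> float:
    """FMF by scanning the reference dose: coarse grid + bisection.

    Uses the package's forward D_RRS evaluation (the quantity under test
    is the *inversion*), but no root-finding library.
    """
    from flash_esd.core import _drrs
    from flash_esd.profiles import make_constant

    def forward(d_ref: float) -> float:
        return _drrs(make_constant(d_ref, ref_dose_rate), variant, params)

    lo, hi = drrs_test * 0.999, drrs_test / params.smin * 1.001
    grid = np.linspace(lo, hi, 200)
    vals = np.array([forward(d) for d in grid]) - drrs_test
    idx = int(np.searchsorted(vals > 0, True))
    if idx == 0:
        return grid[0] / d_test
    a, b = grid[idx - 1], grid[idx]
    while b - a > tol * drrs_test:
        mid = 0.5 * (a + b)
        if forward(mid) - drrs_test > 0:
            b = mid
        else:
            a = mid
    return 0.5 * (a + b) / d_test


def random_profile(rng: np.random.Generator, max_segments: int = 10) -> DeliveryProfile:
    """Random piecewise-constant profile with interior pauses allowed."""
    n = int(rng.integers(1, max_segments + 1))
    segs = []
    for i in range(n):
        duration = float(np.exp(rng.uniform(np.log(1e-3), np.log(8.0))))
        if 0 < i < n - 1 and rng.random() < 0.25:
            rate = 0.0
        else:
            rate = float(np.exp(rng.uniform(np.log(0.01), np.log(150.0))))
        segs.append(ProfileSegment(duration, rate))
    return DeliveryProfile(tuple(segs), label="random")


def random_params(rng: np.random.Generator, variant: ModelVariant) -> ESDParameters:
    g = float(rng.uniform(0.05, 0.5))
    r = 0.0 if rng.random() < 0.2 else float(rng.uniform(0.02, 2.0))
    smin = float(rng.uniform(0.3, 0.9))
    shape = None
    if variant.rrs_form == "RRS2":
        shape = float(rng.uniform(0.5, 3.0))
    elif variant.rrs_form == "RRS3":
        shape = float(rng.uniform(0.1, 5.0))
    return ESDParameters(g=g, r=r, smin=smin, shape=shape)
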