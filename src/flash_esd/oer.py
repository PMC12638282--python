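"""Oxygen-depletion (OER-weighted dose) model, written in its own terms.

This is the classical radiolytic-oxygen-depletion description of FLASH
sparing: oxygen tension O(t) is consumed in proportion to the dose rate
and replenished toward the environmental level,

    dO/dt = -g * O * Ddot(t) + lam * (O_env - O),

and dose increments are weighted by the relative oxygen enhancement
ratio OER(O) / OER(O_env) with the saturable enhancement curve

    OER(O) = (m*O + K') / (O + K'),   m > 1.

It is kept deliberately separate from the ESD solver: the module solves
its own (linear, per-segment exponential) kinetics and integrates its own
weight function, so it can serve as an independent formulation against
which the ESD2_RRS3 parameter renaming is verified.
"""

from __future__ import annotations

import math

from scipy.integrate import quad
from scipy.optimize import brentq

from flash_esd.core import OERParameters
from flash_esd.profiles import DeliveryProfile, make_constant


def relative_oer(o: float, oer: OERParameters) -> float:
    """OER(O) / OER(O_env): the dose weight at oxygen tension ``o``."""
    enh = (oer.m * o + oer.k_prime) / (o + oer.k_prime)
    enh_env = (oer.m * oer.o_env + oer.k_prime) / (oer.o_env + oer.k_prime)
    return enh / enh_env


def oer_weighted_dose(profile: DeliveryProfile, oer: OERParameters) -> float:
    """Integral of OER(O(t))/OER(O_env) * Ddot(t) dt from O(0) = O_env.

    Per constant-rate segment the kinetics are linear with rate constant
    g*Ddot + lam, so O(t) relaxes exponentially toward
    lam*O_env / (g*Ddot + lam); the weight integral is evaluated by
    adaptive quadrature on that closed form.
    """
    o = oer.o_env
    total = 0.0
    for seg in profile.segments:
        d, tau = seg.dose_rate, seg.duration
        k = oer.g * d + oer.lam
        if k == 0.0:
            o_end = o
            if d > 0.0:
                total += relative_oer(o, oer) * d * tau
        else:
            o_eq = oer.lam * oer.o_env / k
            o_start = o

            def o_of(t: float) -> float:
                return o_eq + (o_start - o_eq) * math.exp(-k * t)

            o_end = o_of(tau)
            if d > 0.0:
                val, _ = quad(
                    lambda t: relative_oer(o_of(t), oer), 0.0, tau,
                    epsabs=1e-13, epsrel=1e-11, limit=200,
                )
                total += d * val
        o = o_end
    return total


def oer_fmf(profile: DeliveryProfile, ref_dose_rate: float, oer: OERParameters) -> float:
    """Isoeffective dose ratio under the OER-weighted dose model.

    Same isoeffect construction as for ESD models: find the constant-rate
    reference dose whose weighted dose equals the test profile's, and
    return D_ref / D_test.
    """
    d_test = profile.total_dose
    target = oer_weighted_dose(profile, oer)
    w_floor = relative_oer(0.0, oer)

    def f(d_ref: float) -> float:
        return oer_weighted_dose(make_constant(d_ref, ref_dose_rate), oer) - target

    lo, hi = target, target / w_floor
    if abs(f(lo)) <= 1e-13 * target:
        return lo / d_test
    if abs(f(hi)) <= 1e-13 * target:
        return hi / d_test
    return brentq(f, lo, hi, rtol=1e-13, maxiter=200) / d_test
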