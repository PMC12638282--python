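"""Equilibrium-state dynamics: latent-state ODE, RRS-weighted dose, FMF prediction.

The latent resource pool ``Q(t)`` starts at its equilibrium ``Q0`` and obeys

    dQ/dt = Delta(Q) * Ddot(t) + Rdot(Q),      Q0 >= Q(t) >= 0,

with three depletion/recovery combinations (Theta is the Heaviside step
with ``Theta(x > 0) = 1`` and ``Theta(x <= 0) = 0``):

    ESD1:  dQ/dt = -g*Theta(Q)*Ddot + r*Theta(Q0 - Q)
    ESD2:  dQ/dt = -g*Q*Ddot       + r*(Q0 - Q)
    ESD3:  dQ/dt = -g*Theta(Q)*Ddot + r*(Q0 - Q)

While perturbed, Q scales the instantaneous relative radiosensitivity
``Srel(Q)`` between 1 (at equilibrium) and a floor ``Smin`` (at full
depletion) through one of three response shapes (step, power,
Michaelis-Menten).  The RRS-weighted dose

    D_RRS = integral Srel(Q(t)) * Ddot(t) dt

measures effective damage; the predicted FLASH-modifying factor of a test
delivery against a constant-rate reference is the isoeffective dose ratio
``FMF = D_ref / D_test`` with ``D_ref`` solving
``D_RRS,ref(D_ref) = D_RRS,test``.

Because every profile is piecewise constant in dose rate, the state
equation is solved exactly per segment (linear for ESD1, single
exponential for ESD2/ESD3) with analytic boundary-event times; boundaries
use projected (Filippov) dynamics, i.e. the state slides at Q = 0 or
Q = Q0 while the interior field points outward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from flash_esd.profiles import DeliveryProfile, make_constant

_ESD_FORMS = ("ESD1", "ESD2", "ESD3")
_RRS_FORMS = ("RRS1", "RRS2", "RRS3")

# snap tolerance for Q against its boundaries, relative to Q0
_SNAP = 1e-13


@dataclass(frozen=True)
class ESDParameters:
    """Parameters of an ESD model variant.

    g : depletion coefficient (1/Gy), > 0
    r : recovery rate (1/s), >= 0
    q0 : equilibrium level (dimensionless), fixed to 1 in all fits
    smin : radiosensitivity floor, 0 < smin <= 1
    shape : response-shape parameter — exponent ``n`` for RRS2 or
        Michaelis constant ``K`` for RRS3; ``None`` for RRS1
    """

    g: float
    r: float
    smin: float
    q0: float = 1.0
    shape: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.g) and self.g > 0):
            raise ValueError(f"g must be positive and finite, got {self.g}")
        if not (math.isfinite(self.r) and self.r >= 0):
            raise ValueError(f"r must be >= 0 and finite, got {self.r}")
        if not (math.isfinite(self.q0) and self.q0 > 0):
            raise ValueError(f"q0 must be positive, got {self.q0}")
        if not (0 < self.smin <= 1):
            raise ValueError(f"smin must be in (0, 1], got {self.smin}")
        if self.shape is not None and not (math.isfinite(self.shape) and self.shape > 0):
            raise ValueError(f"shape must be positive when given, got {self.shape}")


@dataclass(frozen=True)
class ModelVariant:
    """An (ESD form, RRS form) pair, e.g. ``ModelVariant("ESD1", "RRS1")``.

    ESD2 combined with the step response RRS1 is rejected: ESD2 cannot
    reach Q = 0, so Srel would stay at 1 and every FMF prediction would be
    exactly 1.  ``allow_degenerate=True`` bypasses the rejection solely so
    that this degeneracy can be asserted.
    """

    esd_form: str
    rrs_form: str
    allow_degenerate: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.esd_form not in _ESD_FORMS:
            raise ValueError(f"unknown ESD form {self.esd_form!r}; expected one of {_ESD_FORMS}")
        if self.rrs_form not in _RRS_FORMS:
            raise ValueError(f"unknown RRS form {self.rrs_form!r}; expected one of {_RRS_FORMS}")
        if self.esd_form == "ESD2" and self.rrs_form == "RRS1" and not self.allow_degenerate:
            raise ValueError(
                "ESD2_RRS1 is degenerate (Q never reaches 0, so FMF = 1 on every "
                "profile); pass allow_degenerate=True only to assert that property"
            )

    @property
    def needs_shape(self) -> bool:
        return self.rrs_form in ("RRS2", "RRS3")

    @property
    def n_free_params(self) -> int:
        """Free parameters with q0 fixed: (g, r, smin) plus shape for RRS2/RRS3."""
        return 4 if self.needs_shape else 3

    @classmethod
    def from_string(cls, name: str, allow_degenerate: bool = False) -> "ModelVariant":
        try:
            esd, rrs = name.split("_")
        except ValueError:
            raise ValueError(f"variant name must look like 'ESD1_RRS1', got {name!r}") from None
        return cls(esd, rrs, allow_degenerate)

    def __str__(self) -> str:
        return f"{self.esd_form}_{self.rrs_form}"


ALL_VARIANTS: tuple[ModelVariant, ...] = tuple(
    ModelVariant(e, s)
    for e in _ESD_FORMS
    for s in _RRS_FORMS
    if not (e == "ESD2" and s == "RRS1")
)


@dataclass(frozen=True)
class StateTrajectory:
    """Solved Q(t) over a profile, sampled at the analytic breakpoints.

    Breakpoints are segment boundaries plus boundary-event times (Q
    reaching 0 or Q0).  ``cumulative_drrs`` holds the RRS-weighted dose
    accumulated up to each breakpoint; between breakpoints Q follows a
    known closed form, so the arrays fully determine the trajectory.
    """

    times: np.ndarray
    q: np.ndarray
    srel: np.ndarray
    cumulative_drrs: np.ndarray
    total_dose: float


def _check_shape(variant: ModelVariant, params: ESDParameters) -> None:
    if variant.needs_shape and params.shape is None:
        raise ValueError(f"variant {variant} needs a shape parameter (n or K)")


def srel(q: float, variant: ModelVariant, params: ESDParameters) -> float:
    """Instantaneous relative radiosensitivity Srel(Q) for the variant's RRS form.

    RRS1 is a step (1 for Q > 0, Smin at Q = 0, Heaviside convention
    Theta(x <= 0) = 0); RRS2 a power law ``Smin + (1-Smin)*(Q/Q0)**n``;
    RRS3 a Michaelis-Menten-type saturable response.  All forms satisfy
    Srel(Q0) = 1 and Srel(0) = Smin.
    """
    _check_shape(variant, params)
    q0, smin = params.q0, params.smin
    if q < -_SNAP * q0 or q > q0 * (1 + _SNAP):
        raise ValueError(f"Q={q} outside [0, {q0}]")
    q = min(max(q, 0.0), q0)
    if variant.rrs_form == "RRS1":
        return smin + (1.0 - smin) * (1.0 if q > 0 else 0.0)
    u = q / q0
    if variant.rrs_form == "RRS2":
        return smin + (1.0 - smin) * u ** params.shape
    k = params.shape
    m = (1.0 + k) / smin - k
    return (1.0 + k) * (m * u + k) / ((m + k) * (u + k))


# ---------------------------------------------------------------------------
# piecewise-analytic state propagation
#
# Each (dose-rate, duration) segment is split at boundary events into
# "pieces" over which Q follows a single closed form:
#   kind "const": Q constant (sliding at a boundary, or equilibrium)
#   kind "lin":   Q = qa + s*tau                       (ESD1; ESD3 with r=0)
#   kind "exp":   Q = qeq + (qa - qeq)*exp(-k*tau)     (ESD2; ESD3 with r>0)
# ---------------------------------------------------------------------------


def _snap_boundary(q: float, q0: float) -> float:
    if abs(q) < _SNAP * q0:
        return 0.0
    if abs(q - q0) < _SNAP * q0:
        return q0
    return min(max(q, 0.0), q0)


def _pieces_linear(
    q: float, tau: float, d: float, s: float, q0: float
) -> Iterator[tuple[str, float, float, float, float]]:
    """Pieces (kind, h, qa, qb, aux) for linear interior dynamics with slope s.

    Used by ESD1 (s = r - g*d) and ESD3 with r = 0 (s = -g*d).  Sliding at
    Q=0 while s <= 0 and at Q=Q0 while s >= 0, per the projected-dynamics
    convention.
    """
    while tau > 0:
        if q <= 0.0 and s <= 0.0:
            yield ("const", tau, 0.0, 0.0, 0.0)
            return
        if q >= q0 and s >= 0.0:
            yield ("const", tau, q0, q0, 0.0)
            return
        if s == 0.0:
            yield ("const", tau, q, q, 0.0)
            return
        te = q / (-s) if s < 0 else (q0 - q) / s
        if te < tau:
            target = 0.0 if s < 0 else q0
            yield ("lin", te, q, target, s)
            q = target
            tau -= te
        else:
            qb = q + s * tau
            qb = min(max(qb, 0.0), q0)
            yield ("lin", tau, q, qb, s)
            return


def _pieces_segment(
    esd_form: str, q: float, tau: float, d: float, params: ESDParameters
) -> Iterator[tuple[str, float, float, float, float]]:
    g, r, q0 = params.g, params.r, params.q0
    if esd_form == "ESD1":
        yield from _pieces_linear(q, tau, d, r - g * d, q0)
        return
    if esd_form == "ESD3" and r == 0.0:
        yield from _pieces_linear(q, tau, d, -g * d, q0)
        return
    if esd_form == "ESD2":
        k = g * d + r
        if k == 0.0:
            yield ("const", tau, q, q, 0.0)
            return
        qeq = r * q0 / k
        qb = qeq + (q - qeq) * math.exp(-k * tau)
        yield ("exp", tau, q, qb, k) if q != qeq else ("const", tau, q, q, 0.0)
        return
    # ESD3 with r > 0: exponential toward qeq = q0 - g*d/r, event at Q = 0
    qeq = q0 - g * d / r
    while tau > 0:
        if q <= 0.0 and qeq <= 0.0:
            yield ("const", tau, 0.0, 0.0, 0.0)
            return
        if qeq < 0.0 and q > 0.0:
            te = math.log((q - qeq) / (-qeq)) / r
            if te < tau:
                yield ("exp", te, q, 0.0, r)
                q = 0.0
                tau -= te
                continue
        qb = qeq + (q - qeq) * math.exp(-r * tau)
        qb = min(max(qb, 0.0), q0)
        if q == qeq:
            yield ("const", tau, q, q, 0.0)
        else:
            yield ("exp", tau, q, qb, r)
        return


def _q_at(kind: str, qa: float, qb: float, aux: float, h: float, tau: float) -> float:
    if kind == "const":
        return qa
    if kind == "lin":
        return qa + aux * tau
    # exp: reconstruct qeq from endpoints
    e = math.exp(-aux * h)
    qeq = (qb - qa * e) / (1.0 - e)
    return qeq + (qa - qeq) * math.exp(-aux * tau)


def _piece_srel_integral(
    kind: str,
    h: float,
    qa: float,
    qb: float,
    aux: float,
    variant: ModelVariant,
    params: ESDParameters,
) -> float:
    """integral of Srel(Q(tau)) dtau over one piece (closed form where possible)."""
    q0, smin = params.q0, params.smin
    form = variant.rrs_form
    if kind == "const":
        return srel(qa, variant, params) * h
    if form == "RRS1":
        # pieces never cross Q=0 in their interior; qa>0 or qb>0 means Q>0 a.e.
        return h if (qa > 0.0 or qb > 0.0) else smin * h
    if kind == "lin":
        ua, ub, s_u = qa / q0, qb / q0, aux / q0
        if form == "RRS2":
            n = params.shape
            return smin * h + (1.0 - smin) * (ub ** (n + 1) - ua ** (n + 1)) / (s_u * (n + 1))
        k = params.shape
        m = (1.0 + k) / smin - k
        prim = m * (ub - ua) + k * (1.0 - m) * math.log((ub + k) / (ua + k))
        return (1.0 + k) / (m + k) * prim / s_u
    val, _ = quad(
        lambda tau: srel(_q_at(kind, qa, qb, aux, h, tau), variant, params),
        0.0,
        h,
        epsabs=1e-13,
        epsrel=1e-11,
        limit=200,
    )
    return val


def solve_state(
    profile: DeliveryProfile, variant: ModelVariant, params: ESDParameters
) -> StateTrajectory:
    """Solve the latent-state ODE over a profile from equilibrium Q(0) = Q0.

    Exact per-segment propagation with analytic boundary-event times;
    Srel and the cumulative RRS-weighted dose are evaluated along the way
    and reported at every breakpoint.
    """
    _check_shape(variant, params)
    q0 = params.q0
    t, q, cum = 0.0, q0, 0.0
    times, qs, srels, cums = [0.0], [q0], [srel(q0, variant, params)], [0.0]
    for seg in profile.segments:
        for kind, h, qa, qb, aux in _pieces_segment(
            variant.esd_form, q, seg.duration, seg.dose_rate, params
        ):
            if seg.dose_rate > 0.0:
                cum += seg.dose_rate * _piece_srel_integral(
                    kind, h, qa, qb, aux, variant, params
                )
            t += h
            q = _snap_boundary(qb, q0)
            times.append(t)
            qs.append(q)
            srels.append(srel(q, variant, params))
            cums.append(cum)
    return StateTrajectory(
        times=np.asarray(times),
        q=np.asarray(qs),
        srel=np.asarray(srels),
        cumulative_drrs=np.asarray(cums),
        total_dose=profile.total_dose,
    )


def rrs_weighted_dose(trajectory: StateTrajectory) -> float:
    """D_RRS (Gy): the dose integral weighted by Srel(Q(t))."""
    return float(trajectory.cumulative_drrs[-1])


def _drrs_esd1_rrs1(
    segments: tuple, g: float, r: float, q0: float, smin: float
) -> float:
    """Fast D_RRS for ESD1 with the step response, pure scalar arithmetic.

    Q is piecewise linear with slope r - g*d and slides at the boundaries,
    so Srel is 1 wherever Q > 0 and Smin on the slide at Q = 0.  This is
    the hot path of model fitting.
    """
    q = q0
    acc = 0.0
    for seg in segments:
        d = seg.dose_rate
        tau = seg.duration
        s = r - g * d
        while tau > 0.0:
            if q <= 0.0 and s <= 0.0:
                acc += smin * d * tau
                break
            if q >= q0 and s >= 0.0:
                acc += d * tau
                break
            if s == 0.0:
                acc += d * tau
                break
            te = q / (-s) if s < 0.0 else (q0 - q) / s
            if te < tau:
                acc += d * te
                tau -= te
                q = 0.0 if s < 0.0 else q0
            else:
                acc += d * tau
                q += s * tau
                break
    return acc


def _drrs(profile: DeliveryProfile, variant: ModelVariant, params: ESDParameters) -> float:
    if variant.esd_form == "ESD1" and variant.rrs_form == "RRS1":
        return _drrs_esd1_rrs1(profile.segments, params.g, params.r, params.q0, params.smin)
    return rrs_weighted_dose(solve_state(profile, variant, params))


def rrs(profile: DeliveryProfile, variant: ModelVariant, params: ESDParameters) -> float:
    """Relative radiosensitivity of a whole delivery: RRS = D_RRS / D, in (0, 1]."""
    d = profile.total_dose
    if d <= 0:
        raise ValueError("profile delivers zero dose")
    return _drrs(profile, variant, params) / d


def _invert_reference_dose(
    drrs_target: float, ref_dose_rate: float, variant: ModelVariant, params: ESDParameters
) -> float:
    """Solve D_ref * RRS_ref(D_ref) = drrs_target for a constant-rate reference.

    F(D) = D_RRS of a constant delivery of dose D is strictly increasing
    and bounded by Smin*D <= F(D) <= D, so the root lies in
    [drrs_target, drrs_target / Smin] and is unique.
    """
    smin = params.smin
    if variant.esd_form == "ESD1" and variant.rrs_form == "RRS1":
        s = params.g * ref_dose_rate - params.r
        if s <= 0.0:
            return drrs_target  # reference never depletes: RRS_ref = 1
        d_thr = ref_dose_rate * params.q0 / s
        if drrs_target <= d_thr:
            return drrs_target
        return d_thr + (drrs_target - d_thr) / smin

    def f(d_ref: float) -> float:
        return _drrs(make_constant(d_ref, ref_dose_rate), variant, params) - drrs_target

    lo = drrs_target
    hi = drrs_target / smin
    f_lo = f(lo)
    if abs(f_lo) <= 1e-13 * drrs_target:
        return lo
    if lo == hi:
        return lo
    f_hi = f(hi)
    if abs(f_hi) <= 1e-13 * drrs_target:
        return hi
    if f_lo * f_hi > 0:  # pragma: no cover - cannot occur for valid parameters
        raise RuntimeError(
            f"isoeffect bracket failed: F({lo})-target={f_lo}, F({hi})-target={f_hi}, "
            f"target={drrs_target}, ref rate={ref_dose_rate}, variant={variant}"
        )
    return brentq(f, lo, hi, rtol=1e-13, maxiter=200)


def fmf_pred(
    test_profile: DeliveryProfile,
    ref_dose_rate: float,
    variant: ModelVariant,
    params: ESDParameters,
) -> float:
    """Predicted FLASH-modifying factor FMF = D_ref / D_test at isoeffect.

    The reference is a constant-rate delivery at ``ref_dose_rate`` whose
    dose D_ref is solved from the isoeffect condition
    ``D_ref * RRS_ref(D_ref) = D_test * RRS_test``; equivalently
    FMF = RRS_test / RRS_ref at the isoeffective doses.
    """
    if not ref_dose_rate > 0:
        raise ValueError(f"reference dose rate must be positive, got {ref_dose_rate}")
    _check_shape(variant, params)
    d_test = test_profile.total_dose
    drrs_test = _drrs(test_profile, variant, params)
    d_ref = _invert_reference_dose(drrs_test, ref_dose_rate, variant, params)
    return d_ref / d_test


def rrs_closed_form_constant_rate(
    dose: float,
    dose_rate: float,
    params: ESDParameters,
    variant: ModelVariant = ModelVariant("ESD1", "RRS1"),
) -> float:
    """Closed-form RRS for ESD1 with step response at a constant dose rate.

    With depletion slope g*Ddot_c > r the pool empties at
    T0 = Q0 / (g*Ddot_c - r); irradiations shorter than T0 see RRS = 1,
    longer ones

        RRS = (1 - Smin) * Ddot_c * Q0 / (D * (g*Ddot_c - r)) + Smin.

    With r = 0 this reduces to the dose-only form with threshold Q0/g.
    """
    if variant != ModelVariant("ESD1", "RRS1"):
        raise ValueError(f"closed form holds for ESD1_RRS1 only, got {variant}")
    if not (dose > 0 and dose_rate > 0):
        raise ValueError("dose and dose rate must be positive")
    s = params.g * dose_rate - params.r
    if s <= 0.0:
        return 1.0
    if dose / dose_rate < params.q0 / s:
        return 1.0
    return (1.0 - params.smin) * dose_rate * params.q0 / (dose * s) + params.smin


def set_parameters_map(
    params: ESDParameters, dose_rate: float | None = None
) -> tuple[float, float]:
    """Map ESD1_RRS1 parameters onto the SET function (FMF_min, D_T).

    The SET (sudden-effect-transition) description of single-fraction
    FLASH sparing is a piecewise-linear FMF-weighted dose vs. dose with a
    sparing floor FMF_min and a transition dose D_T.  Assuming the
    reference is undepleted (RRS_ref = 1), FMF_min = Smin and
    D_T = Ddot_c * Q0 / (g*Ddot_c - r); with negligible recovery
    (``dose_rate=None``) this reduces to D_T = Q0 / g.
    """
    if dose_rate is None:
        return params.smin, params.q0 / params.g
    s = params.g * dose_rate - params.r
    if s <= 0:
        raise ValueError(
            f"no depletion regime: g*Ddot_c = {params.g * dose_rate} <= r = {params.r}"
        )
    return params.smin, dose_rate * params.q0 / s


# ---------------------------------------------------------------------------
# correspondence with the oxygen-depletion (OER-weighted dose) model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OERParameters:
    """Parameters of the radiolytic oxygen-depletion weighted-dose model.

    Oxygen tension O(t) obeys dO/dt = -g*O*Ddot + lam*(O_env - O) and
    weights dose by OER(O)/OER(O_env) with the standard saturable
    enhancement OER(O) = (m*O + K') / (O + K'), m > 1.
    """

    g: float
    lam: float
    o_env: float
    k_prime: float
    m: float

    def __post_init__(self) -> None:
        if not self.g > 0:
            raise ValueError(f"g must be positive, got {self.g}")
        if not self.lam >= 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if not self.o_env > 0:
            raise ValueError(f"o_env must be positive, got {self.o_env}")
        if not self.k_prime > 0:
            raise ValueError(f"k_prime must be positive, got {self.k_prime}")
        if not self.m > 1:
            raise ValueError(f"m must exceed 1 (no sensitization otherwise), got {self.m}")


def oer_to_esd(oer: OERParameters) -> tuple[ModelVariant, ESDParameters]:
    """Rename oxygen-depletion parameters into the equivalent ESD2_RRS3 model.

    O(t) plays the role of Q(t) with Q0 = O_env, r = lam,
    K = K'/O_env and Smin = (1 + K) / (m + K); the weighted doses of the
    two formulations then agree identically on every profile.
    """
    k = oer.k_prime / oer.o_env
    smin = (1.0 + k) / (oer.m + k)
    return ModelVariant("ESD2", "RRS3"), ESDParameters(
        g=oer.g, r=oer.lam, smin=smin, q0=oer.o_env, shape=k
    )


def esd_to_oer(params: ESDParameters) -> OERParameters:
    """Inverse renaming: ESD2_RRS3 parameters back to the oxygen-depletion model."""
    if params.shape is None:
        raise ValueError("ESD2_RRS3 parameters need the Michaelis constant K as shape")
    if not params.smin < 1:
        raise ValueError("smin must be < 1 to map onto m > 1")
    k = params.shape
    m = (1.0 + k) / params.smin - k
    return OERParameters(
        g=params.g, lam=params.r, o_env=params.q0, k_prime=k * params.q0, m=m
    )


# spec-facing alias: the operation is a parameter renaming in either direction
oer_parameter_map = oer_to_esd
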