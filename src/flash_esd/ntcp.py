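"""Logistic NTCP dose-response fitting and experimental FMF derivation.

Normal-tissue complication probability (NTCP) is the fraction of animals
in a group that reach the toxicity endpoint (e.g. skin ulceration) at a
given dose.  A two-parameter logistic curve

    NTCP(D) = 1 / (1 + exp(-(D - d50) / slope_scale))

is fitted per reference cohort and toxicity grade by maximum likelihood on
the individual binary outcomes.  Experimental FLASH-modifying factors are
then derived per test group by isoeffect inversion: the observed responder
fraction is mapped back through the reference curve to the reference dose
producing the same NTCP, and FMF = D_ref / D_test.  Groups with complete
absence or saturation of effect have no defined isoeffect; only responder
fractions strictly between 1% and 99% are used.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: slope scale (Gy) assigned when the data are completely separated and the
#: likelihood has no finite maximizer
SEPARATION_SLOPE_CAP = 0.1

NTCP_BAND = (0.01, 0.99)


@dataclass(frozen=True)
class SubjectRecord:
    """One animal: delivered dose, binary toxicity outcome, and grouping labels."""

    subject_id: str
    group_id: str
    dose: float
    outcome: int
    grade: str = ""
    profile_id: str = ""
    modality: str = ""

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise ValueError(f"dose must be positive, got {self.dose} for {self.subject_id}")
        if self.outcome not in (0, 1):
            raise ValueError(f"outcome must be 0 or 1, got {self.outcome}")


@dataclass(frozen=True)
class LogisticNTCP:
    """Logistic dose-response curve with midpoint ``d50`` (Gy) and width ``slope_scale`` (Gy)."""

    d50: float
    slope_scale: float
    converged: bool = True
    warning: str = ""

    def __post_init__(self) -> None:
        if not self.slope_scale > 0:
            raise ValueError(f"slope_scale must be positive, got {self.slope_scale}")

    def ntcp(self, dose: float | np.ndarray) -> float | np.ndarray:
        z = (np.asarray(dose, dtype=float) - self.d50) / self.slope_scale
        out = 1.0 / (1.0 + np.exp(-z))
        return float(out) if np.isscalar(dose) or out.ndim == 0 else out


@dataclass(frozen=True)
class FMFRecord:
    """One experimental isoeffective dose ratio for a (group, grade) pair."""

    group_id: str
    grade: str
    d_test: float
    observed_ntcp: float
    d_ref: float
    fmf: float
    profile_id: str = ""


def fit_ntcp(records: Sequence[SubjectRecord]) -> LogisticNTCP:
    """Maximum-likelihood logistic fit to individual binary outcomes.

    Needs at least two distinct dose levels and both outcome classes.
    Completely separated data (every responder dosed above every
    non-responder) have no finite ML slope; the fit is then flagged, the
    slope capped at ``SEPARATION_SLOPE_CAP`` and d50 placed mid-gap.
    """
    if not records:
        raise ValueError("no records to fit")
    doses = np.array([rec.dose for rec in records], dtype=float)
    y = np.array([rec.outcome for rec in records], dtype=float)
    if len(np.unique(doses)) < 2:
        raise ValueError("need >= 2 distinct dose levels to identify a dose-response curve")
    if y.min() == y.max():
        raise ValueError("need both responders and non-responders to fit a curve")
    hi_neg = doses[y == 0].max()
    lo_pos = doses[y == 1].min()
    if hi_neg < lo_pos:
        msg = (
            f"complete separation: all responders above {lo_pos} Gy, all "
            f"non-responders below {hi_neg} Gy; slope capped at {SEPARATION_SLOPE_CAP} Gy"
        )
        warnings.warn(msg, stacklevel=2)
        return LogisticNTCP(
            d50=0.5 * (hi_neg + lo_pos),
            slope_scale=SEPARATION_SLOPE_CAP,
            converged=False,
            warning=msg,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, sm.add_constant(doses)).fit(disp=0, maxiter=200)
    b0, b1 = res.params
    if b1 <= 0:
        raise ValueError(f"fitted dose-response is non-increasing (slope {b1:g} per Gy)")
    model = LogisticNTCP(d50=-b0 / b1, slope_scale=1.0 / b1, converged=bool(res.mle_retvals.get("converged", True)))
    if not model.converged:
        model = replace(model, warning="logistic MLE did not converge")
    return model


def invert_ntcp(model: LogisticNTCP, p: float) -> float:
    """Dose at which the curve reaches probability ``p``: d50 + slope_scale*logit(p)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability must be strictly inside (0, 1), got {p}")
    return model.d50 + model.slope_scale * math.log(p / (1.0 - p))


def derive_fmf_exp(
    test_records: Iterable[SubjectRecord], reference: LogisticNTCP
) -> list[FMFRecord]:
    """Experimental FMF per (group, grade) by isoeffect inversion.

    Each test group contributes its raw responder fraction as the observed
    NTCP at its (single) test dose; the isoeffective reference dose comes
    from inverting the fitted reference curve.  Fractions outside the open
    1-99% band are skipped (isoeffect undefined) and logged.
    """
    groups: dict[tuple[str, str], list[SubjectRecord]] = {}
    for rec in test_records:
        groups.setdefault((rec.group_id, rec.grade), []).append(rec)
    out: list[FMFRecord] = []
    for (group_id, grade), recs in groups.items():
        doses = {rec.dose for rec in recs}
        if len(doses) != 1:
            raise ValueError(
                f"group {group_id!r} grade {grade!r} mixes doses {sorted(doses)}; "
                "expected one test dose per group"
            )
        d_test = doses.pop()
        observed = float(np.mean([rec.outcome for rec in recs]))
        if not NTCP_BAND[0] < observed < NTCP_BAND[1]:
            logger.info(
                "skipping group %s grade %s: observed NTCP %.3f outside (1%%, 99%%)",
                group_id, grade, observed,
            )
            continue
        d_ref = invert_ntcp(reference, observed)
        out.append(
            FMFRecord(
                group_id=group_id,
                grade=grade,
                d_test=d_test,
                observed_ntcp=observed,
                d_ref=d_ref,
                fmf=d_ref / d_test,
                profile_id=recs[0].profile_id,
            )
        )
    if not out:
        warnings.warn("all test groups fell outside the 1-99% NTCP band; no FMF derived",
                      stacklevel=2)
    return out


def average_fmf_by_group(records: Sequence[FMFRecord]) -> list[FMFRecord]:
    """Average FMF over toxicity grades within each group (unweighted mean).

    Returns one record per group, tagged grade ``"mean"``; d_ref is set to
    mean(FMF) * d_test so the record stays internally consistent.
    Idempotent on already-averaged input.
    """
    by_group: dict[str, list[FMFRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.group_id not in by_group:
            order.append(rec.group_id)
        by_group.setdefault(rec.group_id, []).append(rec)
    out = []
    for gid in order:
        recs = by_group[gid]
        d_test = float(np.mean([r.d_test for r in recs]))
        fmf = float(np.mean([r.fmf for r in recs]))
        out.append(
            FMFRecord(
                group_id=gid,
                grade="mean",
                d_test=d_test,
                observed_ntcp=float(np.mean([r.observed_ntcp for r in recs])),
                d_ref=fmf * d_test,
                fmf=fmf,
                profile_id=recs[0].profile_id,
            )
        )
    return out
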