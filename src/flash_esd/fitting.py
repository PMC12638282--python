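"""Fitting ESD model variants to FMF data and ranking them.

The objective is the mean squared error between experimental and
predicted FMF values,

    chi2 = sum_i (FMF_exp,i - FMF_pred,i)^2 / n,

minimized with the Nelder-Mead simplex over (g, r, Smin[, shape]) with Q0
fixed to 1.  Box constraints are enforced by optimizing log(g), log(r),
logit(Smin) and log(shape); multiple seeded Latin-hypercube restarts guard
against local minima and make the fit deterministic given a seed.  Models
are ranked by the Gaussian-residual Bayesian Information Criterion
``BIC = n*ln(chi2) + k*ln(n)``; differences from the best model are read
on the conventional bands [0, 2) / [2, 6) / [6, 10) / >= 10 as weak /
positive / strong / very strong support for rejecting the weaker model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.stats import qmc

from flash_esd.core import ESDParameters, ModelVariant, fmf_pred
from flash_esd.profiles import DeliveryProfile

# natural-scale start boxes for the Latin-hypercube restarts (log/logit-uniform)
_START_BOUNDS = {
    "g": (0.02, 2.0),       # 1/Gy
    "r": (0.01, 10.0),      # 1/s
    "smin": (0.2, 0.95),
    "shape": (0.2, 8.0),
}

_DELTA_BIC_BANDS = ((2.0, "weak"), (6.0, "positive"), (10.0, "strong"))


@dataclass(frozen=True)
class FMFEntry:
    """One FMF observation: a delivery profile and its isoeffective dose ratio."""

    profile: DeliveryProfile
    fmf_exp: float
    ref_dose_rate: float
    d_test: float = 0.0

    def __post_init__(self) -> None:
        if not self.fmf_exp > 0:
            raise ValueError(f"fmf_exp must be positive, got {self.fmf_exp}")
        if not self.ref_dose_rate > 0:
            raise ValueError(f"ref_dose_rate must be positive, got {self.ref_dose_rate}")
        if self.d_test == 0.0:
            object.__setattr__(self, "d_test", self.profile.total_dose)


@dataclass(frozen=True)
class FMFDataset:
    entries: tuple[FMFEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def fmf_exp(self) -> np.ndarray:
        return np.array([e.fmf_exp for e in self.entries])


@dataclass(frozen=True)
class FitResult:
    """Fitted variant with parameters, objective value and goodness of fit."""

    variant: ModelVariant
    params: ESDParameters
    chi2: float
    n: int
    k: int
    r2: float
    mae: float
    mape: float
    rmse: float
    bic: float
    residuals: tuple[float, ...]
    converged: bool
    n_starts: int
    seed: int


def predict_dataset(
    dataset: FMFDataset, variant: ModelVariant, params: ESDParameters
) -> np.ndarray:
    return np.array(
        [fmf_pred(e.profile, e.ref_dose_rate, variant, params) for e in dataset.entries]
    )


def chi2_objective(
    params: ESDParameters, variant: ModelVariant, dataset: FMFDataset
) -> float:
    """Mean squared error between experimental and predicted FMF values."""
    if len(dataset) == 0:
        raise ValueError("empty FMF dataset")
    resid = dataset.fmf_exp - predict_dataset(dataset, variant, params)
    return float(np.mean(resid**2))


def _to_params(x: np.ndarray, variant: ModelVariant) -> ESDParameters:
    g = math.exp(x[0])
    r = math.exp(x[1])
    smin = 1.0 / (1.0 + math.exp(-x[2]))
    shape = math.exp(x[3]) if variant.needs_shape else None
    return ESDParameters(g=g, r=r, smin=smin, shape=shape)


def _from_natural(g: float, r: float, smin: float, shape: float | None) -> np.ndarray:
    x = [math.log(g), math.log(r), math.log(smin / (1.0 - smin))]
    if shape is not None:
        x.append(math.log(shape))
    return np.array(x)


def _lhs_starts(variant: ModelVariant, n_starts: int, seed: int) -> list[np.ndarray]:
    names = ["g", "r", "smin"] + (["shape"] if variant.needs_shape else [])
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    u = sampler.random(n_starts)
    starts = []
    for row in u:
        vals = {}
        for j, name in enumerate(names):
            lo, hi = _START_BOUNDS[name]
            vals[name] = lo * (hi / lo) ** row[j]  # log-uniform
        starts.append(
            _from_natural(vals["g"], vals["r"], vals["smin"], vals.get("shape"))
        )
    return starts


def fit_model(
    dataset: FMFDataset,
    variant: ModelVariant,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Fit one model variant by Nelder-Mead with seeded multistart.

    The best of ``n_starts`` Latin-hypercube restarts is polished with a
    second, tighter simplex run.  Deterministic for a given seed.
    """
    if len(dataset) == 0:
        raise ValueError("empty FMF dataset")
    if n_starts < 1:
        raise ValueError("need at least one start")

    def objective(x: np.ndarray) -> float:
        try:
            return chi2_objective(_to_params(x, variant), variant, dataset)
        except (OverflowError, ValueError):
            return 1e6

    best = None
    diagnostics = []
    for x0 in _lhs_starts(variant, n_starts, seed):
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-14, "maxfev": 3000, "adaptive": True},
        )
        diagnostics.append((res.fun, res.success, res.message))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):  # pragma: no cover
        raise RuntimeError(f"all {n_starts} starts failed: {diagnostics}")
    polish = minimize(
        objective,
        best.x,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-18, "maxfev": 5000},
    )
    if polish.fun <= best.fun:
        best = polish

    params = _to_params(best.x, variant)
    predicted = predict_dataset(dataset, variant, params)
    observed = dataset.fmf_exp
    residuals = observed - predicted
    chi2 = float(np.mean(residuals**2))
    n = len(dataset)
    k = variant.n_free_params
    r2, mae, mape, rmse = gof_metrics(observed, predicted)
    return FitResult(
        variant=variant,
        params=params,
        chi2=chi2,
        n=n,
        k=k,
        r2=r2,
        mae=mae,
        mape=mape,
        rmse=rmse,
        bic=_bic(chi2, n, k),
        residuals=tuple(float(x) for x in residuals),
        converged=bool(best.success),
        n_starts=n_starts,
        seed=seed,
    )


def gof_metrics(
    observed: Sequence[float], predicted: Sequence[float]
) -> tuple[float, float, float, float]:
    """Goodness-of-fit summary: (R^2, MAE, MAPE in percent, RMSE)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} observed vs {pred.shape} predicted")
    if obs.size < 2:
        raise ValueError("need at least two points for goodness-of-fit metrics")
    if np.any(obs == 0):
        raise ValueError("MAPE undefined: observed values contain zero")
    err = obs - pred
    rss = float(np.sum(err**2))
    tss = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    mae = float(np.mean(np.abs(err)))
    mape = 100.0 * float(np.mean(np.abs(err) / np.abs(obs)))
    rmse = math.sqrt(rss / obs.size)
    return r2, mae, mape, rmse


def _bic(chi2: float, n: int, k: int) -> float:
    return n * math.log(max(chi2, 1e-300)) + k * math.log(n)


def delta_bic_label(delta: float) -> str:
    """Conventional evidence bands for a BIC difference against the best model."""
    if delta < 0:
        raise ValueError("delta BIC is measured against the best model and must be >= 0")
    for upper, label in _DELTA_BIC_BANDS:
        if delta < upper:
            return label
    return "very strong"


def bic_and_rank(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fitted variants by BIC with ΔBIC and support labels.

    All fits must come from the same dataset (equal n); rows are sorted by
    BIC ascending (best first).
    """
    if not fits:
        raise ValueError("no fits to rank")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits mix dataset sizes {sorted(ns)}; ranking is per-dataset")
    rows = sorted(fits, key=lambda f: f.bic)
    best = rows[0].bic
    return pd.DataFrame(
        {
            "variant": [str(f.variant) for f in rows],
            "r2": [f.r2 for f in rows],
            "mae": [f.mae for f in rows],
            "mape_pct": [f.mape for f in rows],
            "rmse": [f.rmse for f in rows],
            "bic": [f.bic for f in rows],
            "delta_bic": [f.bic - best for f in rows],
            "support_label": [delta_bic_label(f.bic - best) for f in rows],
            "k": [f.k for f in rows],
        }
    )


class NormalityResult(NamedTuple):
    statistic: float
    p_value: float
    normal: bool


def residual_normality(residuals: Sequence[float], alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk test of residual normality (3 <= n <= 5000)."""
    resid = np.asarray(residuals, dtype=float)
    if not 3 <= resid.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={resid.size}")
    if np.ptp(resid) == 0:
        raise ValueError("residuals are constant; normality test undefined")
    stat, p = stats.shapiro(resid)
    return NormalityResult(float(stat), float(p), bool(p > alpha))
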