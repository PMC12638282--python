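"""Parsing and serialization: profile specs, model specs, subject/FMF tables.

Formats are deliberately plain: JSON for nested specifications (profiles,
model parameters, fit results) and comma-separated UTF-8 CSV with a
mandatory header for tabular data.  Serialization is deterministic
(sorted keys, repr floats) so identical inputs reproduce byte-identical
files.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import pandas as pd

from flash_esd import __version__ as _pkg_version
from flash_esd.core import ESDParameters, ModelVariant
from flash_esd.fitting import FitResult
from flash_esd.ntcp import FMFRecord, SubjectRecord
from flash_esd.profiles import (
    DeliveryProfile,
    ProfileSegment,
    make_constant,
    make_pulsed,
    make_split,
    make_spot_scan,
)

_PROFILE_TYPES = ("constant", "pulsed", "split", "spot_scan", "segments")

SUBJECT_COLUMNS = ["subject_id", "group_id", "dose_gy", "outcome", "grade",
                   "profile_id", "modality"]
FMF_COLUMNS = ["group_id", "grade", "d_test_gy", "observed_ntcp", "d_ref_gy",
               "fmf", "profile_id"]


# -- profiles ---------------------------------------------------------------


def profile_from_spec(spec: dict[str, Any]) -> DeliveryProfile:
    """Build a profile from a JSON-style spec dict keyed by ``type``."""
    kind = spec.get("type")
    if kind not in _PROFILE_TYPES:
        raise ValueError(f"unknown profile type {kind!r}; allowed: {_PROFILE_TYPES}")
    label = spec.get("label", "")
    if kind == "constant":
        return make_constant(spec["dose_gy"], spec["dose_rate_gy_s"], label=label)
    if kind == "pulsed":
        return make_pulsed(
            spec["total_dose_gy"],
            spec["n_pulses"],
            spec["pulse_width_s"],
            spec.get("repetition_frequency_hz", 0.0),
            label=label,
        )
    if kind == "split":
        sub = profile_from_spec(spec["sub_profile"])
        return make_split(sub, spec["n_parts"], spec["pause_s"], label=label)
    if kind == "spot_scan":
        return make_spot_scan(
            spec["spot_doses_gy"], spec["spot_durations_s"], spec["dead_times_s"],
            label=label,
        )
    segments = tuple(
        ProfileSegment(s["duration_s"], s["dose_rate_gy_s"]) for s in spec["segments"]
    )
    return DeliveryProfile(segments, label=label)


def profile_to_spec(profile: DeliveryProfile) -> dict[str, Any]:
    """Dump a profile as an explicit segment-list spec (round-trips exactly)."""
    return {
        "type": "segments",
        "label": profile.label,
        "segments": [
            {"duration_s": s.duration, "dose_rate_gy_s": s.dose_rate}
            for s in profile.segments
        ],
    }


def load_profile_json(path: str | Path) -> DeliveryProfile:
    with open(path, encoding="utf-8") as fh:
        return profile_from_spec(json.load(fh))


def dump_profile_json(profile: DeliveryProfile, path: str | Path) -> None:
    _write_json(profile_to_spec(profile), path)


def segments_to_csv(profile: DeliveryProfile, path: str | Path) -> None:
    t = 0.0
    rows = []
    for s in profile.segments:
        rows.append({"t_start_s": t, "duration_s": s.duration,
                     "dose_rate_gy_s": s.dose_rate})
        t += s.duration
    pd.DataFrame(rows).to_csv(path, index=False)


def segments_from_csv(path: str | Path, label: str = "") -> DeliveryProfile:
    df = pd.read_csv(path)
    _require_columns(df, ["duration_s", "dose_rate_gy_s"], path)
    segs = tuple(
        ProfileSegment(row.duration_s, row.dose_rate_gy_s) for row in df.itertuples()
    )
    return DeliveryProfile(segs, label=label)


# -- model specs ------------------------------------------------------------


def model_from_spec(spec: dict[str, Any]) -> tuple[ModelVariant, ESDParameters]:
    variant = ModelVariant.from_string(spec["variant"])
    params = ESDParameters(
        g=spec["g"],
        r=spec["r"],
        smin=spec["smin"],
        q0=spec.get("q0", 1.0),
        shape=spec.get("shape"),
    )
    if variant.needs_shape and params.shape is None:
        raise ValueError(f"variant {variant} requires a 'shape' entry")
    return variant, params


def model_to_spec(variant: ModelVariant, params: ESDParameters) -> dict[str, Any]:
    spec: dict[str, Any] = {
        "variant": str(variant),
        "g": params.g,
        "r": params.r,
        "q0": params.q0,
        "smin": params.smin,
    }
    if params.shape is not None:
        spec["shape"] = params.shape
    return spec


def load_model_json(path: str | Path) -> tuple[ModelVariant, ESDParameters]:
    with open(path, encoding="utf-8") as fh:
        return model_from_spec(json.load(fh))


# -- tabular data -----------------------------------------------------------


def _require_columns(df: pd.DataFrame, columns: list[str], path: Any) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; found {list(df.columns)}")


def read_subjects_csv(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    _require_columns(df, SUBJECT_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(), start=2):  # header is line 1
        try:
            records.append(
                SubjectRecord(
                    subject_id=str(row.subject_id),
                    group_id=str(row.group_id),
                    dose=float(row.dose_gy),
                    outcome=int(row.outcome),
                    grade=str(row.grade),
                    profile_id=str(row.profile_id),
                    modality=str(row.modality),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
    return records


def write_subjects_csv(records: list[SubjectRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group_id": r.group_id,
                "dose_gy": r.dose,
                "outcome": r.outcome,
                "grade": r.grade,
                "profile_id": r.profile_id,
                "modality": r.modality,
            }
            for r in records
        ],
        columns=SUBJECT_COLUMNS,
    ).to_csv(path, index=False)


def read_fmf_csv(path: str | Path) -> list[FMFRecord]:
    df = pd.read_csv(path)
    _require_columns(df, FMF_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(), start=2):
        try:
            records.append(
                FMFRecord(
                    group_id=str(row.group_id),
                    grade=str(row.grade),
                    d_test=float(row.d_test_gy),
                    observed_ntcp=float(row.observed_ntcp),
                    d_ref=float(row.d_ref_gy),
                    fmf=float(row.fmf),
                    profile_id=str(row.profile_id),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
    return records


def write_fmf_csv(records: list[FMFRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "group_id": r.group_id,
                "grade": r.grade,
                "d_test_gy": r.d_test,
                "observed_ntcp": r.observed_ntcp,
                "d_ref_gy": r.d_ref,
                "fmf": r.fmf,
                "profile_id": r.profile_id,
            }
            for r in records
        ],
        columns=FMF_COLUMNS,
    ).to_csv(path, index=False)


# -- results ----------------------------------------------------------------


def _write_json(payload: dict[str, Any], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def fit_result_to_dict(result: FitResult) -> dict[str, Any]:
    return {
        "variant": str(result.variant),
        "params": model_to_spec(result.variant, result.params),
        "chi2": result.chi2,
        "n": result.n,
        "k": result.k,
        "r2": result.r2,
        "mae": result.mae,
        "mape_pct": result.mape,
        "rmse": result.rmse,
        "bic": result.bic,
        "residuals": list(result.residuals),
        "converged": result.converged,
        "n_starts": result.n_starts,
        "seed": result.seed,
        "package_version": _pkg_version,
    }


def emit_fit_json(result: FitResult, path: str | Path) -> None:
    """Deterministic fit-result dump: same result twice gives identical bytes."""
    _write_json(fit_result_to_dict(result), path)


def write_ranking_csv(ranking: pd.DataFrame, path: str | Path) -> None:
    ranking.to_csv(path, index=False)


def trajectory_to_csv(trajectory, path: str | Path) -> None:
    pd.DataFrame(
        {
            "t_s": trajectory.times,
            "Q": trajectory.q,
            "srel": trajectory.srel,
            "drrs_cum_gy": trajectory.cumulative_drrs,
        }
    ).to_csv(path, index=False)
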