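"""Internal-standard semi-quantification and method-validation statistics.

Semi-quantification assumes equal response of every class member and its
internal standard:

    conc [ug/g] = area(compound) / area(IS of class) * IS amount [ug]
                  / sample weight [g]

The validation battery mirrors bioanalytical practice: spiked recovery at
three levels, calibration linearity with back-calculated accuracy, LOD at
a signal-to-noise of 3.3, repeatability / intra-day / inter-day CV%, and
a compound filter combining repeatability with the Kendrick grid check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kendrick import PASS

__all__ = [
    "semi_quantify",
    "to_matrix",
    "impute_missing",
    "cv_percent",
    "recovery",
    "CalibrationResult",
    "linearity_lod",
    "validation_filter",
]

DEFAULT_SPIKE_LEVELS = (0.1, 0.5, 1.0)  # mg/L


def _class_of(transition_id: str) -> str:
    return transition_id.split(" ", 1)[0]


def semi_quantify(
    areas: pd.DataFrame,
    samples: pd.DataFrame,
    is_map: dict[str, tuple[str, float]],
) -> pd.DataFrame:
    """Convert peak areas to ug/g fresh weight via per-class IS ratio.

    Parameters
    ----------
    areas
        Long table with columns ``sample``, ``transition_id``, ``area``
        and optionally ``lipid_class`` (else derived from the transition
        id prefix).  Internal-standard rows are located by the ids in
        ``is_map``.
    samples
        One row per sample with columns ``sample`` and ``weight_mg``.
    is_map
        lipid class -> (IS transition id, IS amount spiked per sample, ug).

    Missing (NaN) analyte areas stay missing in the output.
    """
    areas = areas.copy()
    if "lipid_class" not in areas.columns:
        areas["lipid_class"] = areas["transition_id"].map(_class_of)
    if areas.duplicated(["sample", "transition_id"]).any():
        raise ValueError("duplicate (sample, transition) records")
    weights = samples.set_index("sample")["weight_mg"]
    if (weights <= 0).any():
        bad = weights.index[weights <= 0].tolist()
        raise ValueError(f"non-positive sample weight for {bad}")

    is_ids = {cls: tid for cls, (tid, _) in is_map.items()}
    is_amounts = {cls: amt for cls, (_, amt) in is_map.items()}
    is_rows = areas[areas["transition_id"].isin(set(is_ids.values()))]
    # area of the IS transition per (sample, IS id)
    is_area = is_rows.set_index(["sample", "transition_id"])["area"]

    analytes = areas[~areas["transition_id"].isin(set(is_ids.values()))].copy()
    unknown = set(analytes["lipid_class"]) - set(is_ids)
    if unknown:
        raise KeyError(f"no internal standard assigned for classes {sorted(unknown)}")

    def _conc(row):
        cls = row["lipid_class"]
        key = (row["sample"], is_ids[cls])
        try:
            ref = is_area.loc[key]
        except KeyError:
            raise ValueError(
                f"missing IS area for class {cls!r} in sample {row['sample']!r}"
            ) from None
        if not np.isfinite(ref) or ref <= 0:
            raise ValueError(
                f"missing IS area for class {cls!r} in sample {row['sample']!r}"
            )
        grams = weights.loc[row["sample"]] / 1000.0
        return row["area"] / ref * is_amounts[cls] / grams

    analytes["conc_ug_g"] = analytes.apply(_conc, axis=1)
    return analytes[["sample", "transition_id", "lipid_class", "conc_ug_g"]]


def to_matrix(conc: pd.DataFrame, value: str = "conc_ug_g") -> pd.DataFrame:
    """Pivot a long concentration table to samples x compounds."""
    return conc.pivot(index="sample", columns="transition_id", values=value)


def impute_missing(
    matrix: pd.DataFrame, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Replace NaNs by uniform draws on (0, min_observed/2) per compound."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = matrix.copy()
    for col in out.columns:
        vals = out[col]
        mask = vals.isna()
        if not mask.any():
            continue
        if mask.all():
            raise ValueError(f"compound {col!r} has no observed values")
        half_min = vals.min(skipna=True) / 2.0
        out.loc[mask, col] = rng.uniform(0.0, half_min, size=int(mask.sum()))
    return out


def cv_percent(values) -> float:
    """Coefficient of variation: 100 * sample sd / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * arr.std(ddof=1) / mean


def recovery(
    spiked: pd.DataFrame,
    levels: tuple[float, ...] = DEFAULT_SPIKE_LEVELS,
) -> pd.Series:
    """Per-class recovery %: mean over replicates per level, then levels.

    ``spiked`` needs columns ``lipid_class``, ``level``, ``measured``,
    ``expected``.
    """
    out = {}
    for cls, sub in spiked.groupby("lipid_class"):
        found = sorted(sub["level"].unique())
        missing = [lv for lv in levels if lv not in found]
        if missing:
            raise ValueError(
                f"class {cls!r}: missing spike levels {missing}; found {found}"
            )
        per_level = [
            (sub.loc[sub["level"] == lv, "measured"]
             / sub.loc[sub["level"] == lv, "expected"]).mean() * 100.0
            for lv in levels
        ]
        out[cls] = float(np.mean(per_level))
    return pd.Series(out, name="recovery_pct").sort_index()


@dataclass(frozen=True)
class CalibrationResult:
    slope: float
    intercept: float
    r2: float
    linear_range: tuple[float, float] | None
    loq: float | None
    lod: float | None
    flags: tuple[str, ...] = field(default_factory=tuple)


def _fit(conc: np.ndarray, resp: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(conc, resp, 1)
    pred = slope * conc + intercept
    ss_res = float(((resp - pred) ** 2).sum())
    ss_tot = float(((resp - resp.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def linearity_lod(
    concentrations,
    responses,
    noise_sd: float,
    *,
    min_points: int = 5,
    accuracy_tol: float = 0.20,
    r2_min: float = 0.99,
) -> CalibrationResult:
    """Linear range, LOQ and LOD of a calibration series.

    The linear range is the longest contiguous run of calibration points
    (lowest start wins ties) whose least-squares fit has R^2 >= ``r2_min``
    and back-calculated concentrations within ``accuracy_tol`` of nominal.
    LOQ is the lowest point of that run; LOD is the concentration at
    which the predicted signal-to-noise reaches 3.3 (3.3 * noise / slope).
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.size < min_points:
        raise ValueError(f"need at least {min_points} calibration points")
    if not np.all(np.diff(conc) > 0):
        raise ValueError("concentrations must be strictly increasing")

    best: tuple[int, int] | None = None
    for length in range(conc.size, min_points - 1, -1):
        for start in range(conc.size - length + 1):
            idx = slice(start, start + length)
            slope, intercept, r2 = _fit(conc[idx], resp[idx])
            if r2 < r2_min or slope <= 0:
                continue
            back = (resp[idx] - intercept) / slope
            if np.all(np.abs(back - conc[idx]) <= accuracy_tol * conc[idx]):
                best = (start, start + length)
                break
        if best is not None:
            break

    if best is None:
        return CalibrationResult(
            np.nan, np.nan, np.nan, None, None, None, ("no-linear-range",)
        )
    lo, hi = best
    slope, intercept, r2 = _fit(conc[lo:hi], resp[lo:hi])
    flags: list[str] = []
    if noise_sd <= 0:
        lod = 0.0
        flags.append("lod-below-lowest-level")
    else:
        lod = 3.3 * noise_sd / slope
    return CalibrationResult(
        slope,
        intercept,
        r2,
        (float(conc[lo]), float(conc[hi - 1])),
        float(conc[lo]),
        float(lod),
        tuple(flags),
    )


def validation_filter(
    records: pd.DataFrame,
    *,
    repeatability_max: float = 20.0,
    apply_day_cv: bool = False,
    intra_day_max: float = 15.0,
    inter_day_max: float = 20.0,
) -> pd.DataFrame:
    """Retain compounds by repeatability CV and Kendrick grid outcome.

    ``records`` needs columns ``transition_id``, ``lipid_class``,
    ``repeatability_cv`` and ``kmd_flag``; thresholds are inclusive
    (CV == 20.0 passes).  With ``apply_day_cv`` the intra-/inter-day CV
    columns become exclusion criteria too, otherwise they are reported
    descriptively.  Returns the input with a boolean ``retained`` column.
    """
    out = records.copy()
    keep = (out["repeatability_cv"] <= repeatability_max) & (
        out["kmd_flag"] == PASS
    )
    if apply_day_cv:
        if "intra_day_cv" in out:
            keep &= out["intra_day_cv"] <= intra_day_max
        if "inter_day_cv" in out:
            keep &= out["inter_day_cv"] <= inter_day_max
    out["retained"] = keep
    return out


def retained_class_counts(filtered: pd.DataFrame) -> pd.DataFrame:
    """Per-class detected/validated counts in method-summary layout."""
    grp = filtered.groupby("lipid_class")
    return pd.DataFrame(
        {
            "detected": grp.size(),
            "validated": grp["retained"].sum().astype(int),
        }
    ).sort_index()
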