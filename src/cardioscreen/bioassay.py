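"""Bioassay statistics: MTT viability rates, heart-rate recovery, summaries.

The screen reads out two bioactivity coefficients per chromatographic
fraction:

* cell protection from an MTT plate —
  ``survival% = 100 * OD_tested / OD_control`` and
  ``protection% = 100 * (OD_model - OD_tested) / (OD_model - OD_control)``;
* heart-rate recovery in the larval arrhythmia model —
  ``R_i = 100 * (B_i - B_M) / (B_C - B_M)`` where B_C, B_M, B_i are the
  mean beat rates of the control, model (terfenadine-only) and treated
  groups.

R and protection are deliberately not clamped to [0, 100]: a fraction that
depresses heart rate below the model group must come out negative.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "survival_rate",
    "protection_rate",
    "recovery_rate",
    "recovery_vector",
    "normalized_heart_rate",
    "group_summary",
    "one_way_anova",
    "fraction_summary_table",
]


def survival_rate(od_tested_mean: float, od_control_mean: float) -> float:
    """Cell viability as a percentage of untreated control OD."""
    if od_control_mean <= 0:
        raise ValueError("control OD mean must be positive")
    return 100.0 * od_tested_mean / od_control_mean


def protection_rate(od_tested_mean: float, od_model_mean: float,
                    od_control_mean: float) -> float:
    """Rescue of oxidative damage: 100 at full rescue, 0 at model level.

    Linear in the tested OD between the model (0%) and control (100%)
    endpoints; may exceed that range. Undefined when model and control
    ODs coincide.
    """
    denom = od_model_mean - od_control_mean
    if denom == 0:
        raise ValueError("model and control OD means coincide; protection undefined")
    return 100.0 * (od_model_mean - od_tested_mean) / denom


def recovery_rate(b_i: float, b_m: float, b_c: float) -> float:
    """Normalized heart-rate recovery R_i = 100 (B_i - B_M)/(B_C - B_M).

    100% means the treated group beats like controls, 0% like the
    terfenadine model; values outside [0, 100] are meaningful (worse than
    model, or overshoot) and are not clamped.
    """
    denom = b_c - b_m
    if denom == 0:
        raise ValueError("control and model rates coincide; recovery undefined")
    return 100.0 * (b_i - b_m) / denom


def recovery_vector(
    treated_means: Mapping[str, float], b_m: float, b_c: float,
) -> pd.Series:
    """Per-fraction R_i (%) from group-mean beat rates."""
    return pd.Series(
        {fid: recovery_rate(b, b_m, b_c) for fid, b in treated_means.items()},
        name="R_percent",
    )


def normalized_heart_rate(b_i: float, b_c_mean: float) -> float:
    """Beat rate as a fraction of the control-group mean."""
    if b_c_mean <= 0:
        raise ValueError("control mean rate must be positive")
    return b_i / b_c_mean


def group_summary(values: Sequence[float]) -> tuple[float, float, int]:
    """(mean, sample SD with n-1 denominator, n)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty group")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, int(arr.size)


def one_way_anova(groups: Iterable[Sequence[float]]) -> tuple[float, float]:
    """Standard one-way ANOVA (F statistic, p value).

    Degenerate input (fewer than two groups, or any group with fewer than
    two observations) raises. When all groups are identical F is 0 and p
    is 1.
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    if np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def fraction_summary_table(
    rates: Mapping[str, Sequence[float]],
    control: Sequence[float],
    model: Sequence[float],
    plate: Mapping[str, Sequence[float]] | None = None,
) -> pd.DataFrame:
    """Per-fraction summary: n, mean, SD, R_i, p vs model (and MTT rates).

    ``rates`` maps fraction id -> per-larva beat rates; ``plate``
    optionally maps fraction id -> ODs, with ``control``/``model`` OD
    groups under those keys. No multiple-testing correction is applied
    (single-comparison convention of this assay family); treat borderline
    p values accordingly.
    """
    b_c, _, _ = group_summary(control)
    b_m, _, _ = group_summary(model)
    rows = []
    for fid, values in rates.items():
        mean, sd, n = group_summary(values)
        _, p = one_way_anova([values, list(model)])
        row = {
            "fraction_id": fid, "n": n, "mean_bpm": mean, "sd_bpm": sd,
            "R_percent": recovery_rate(mean, b_m, b_c),
            "normalized_rate": normalized_heart_rate(mean, b_c),
            "p_vs_model": p,
        }
        if plate is not None and fid in plate:
            od_c = float(np.mean(plate["control"]))
            od_m = float(np.mean(plate["model"]))
            od_t = float(np.mean(plate[fid]))
            row["survival_percent"] = survival_rate(od_t, od_c)
            row["protection_percent"] = protection_rate(od_t, od_m, od_c)
        rows.append(row)
    return pd.DataFrame(rows)
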