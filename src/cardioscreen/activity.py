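"""Activity-index scoring: rank compounds by abundance-weighted bioactivity.

Given a fraction x compound peak-area matrix A and a per-fraction
bioactivity coefficient R (heart-rate recovery %, or cell protection %),
each compound's distribution over fractions is normalized to sum to one,

    a_{i,j} = A_{i,j} / sum_i A_{i,j},

and its activity index is the abundance-weighted mean of the fraction
coefficients,

    AI_j = sum_i R_i * a_{i,j}.

A compound concentrated in protective fractions inherits a high AI; one
concentrated in rate-depressing fractions a negative AI. AI is invariant
to rescaling any compound's raw areas (only the distribution matters) and
is always bounded by min(R) and max(R). Compounds with a positive AI are
flagged as candidate actives.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "normalize_areas",
    "activity_indexes",
    "rank_compounds",
    "bioactive_map",
    "dual_scores",
]


def normalize_areas(areas: pd.DataFrame) -> pd.DataFrame:
    """Column-stochastic normalization: each compound's areas sum to 1.

    ``areas`` is fractions x compounds, non-negative. Compounds absent
    from every fraction (all-zero column) cannot be normalized; they are
    dropped with a warning rather than scored 0, which would masquerade
    as "neutral". An all-zero matrix raises.
    """
    if (areas.values < 0).any():
        raise ValueError("peak areas must be non-negative")
    sums = areas.sum(axis=0)
    zero = sums[sums == 0].index
    if len(zero) == len(areas.columns):
        raise ValueError("all compound columns are zero; nothing to normalize")
    if len(zero):
        warnings.warn(
            f"dropping {len(zero)} compound(s) with zero total area: "
            f"{list(zero)}", stacklevel=2)
        areas = areas.drop(columns=zero)
        sums = sums.drop(zero)
    return areas / sums


def activity_indexes(normalized: pd.DataFrame, recovery: pd.Series) -> pd.DataFrame:
    """Per-compound AI table with rank and positive flag.

    ``recovery`` must cover every fraction (row) of ``normalized``; extra
    fractions in ``recovery`` are ignored. Returns a DataFrame indexed by
    compound with columns ``AI``, ``rank`` (1 = highest AI, ties broken
    by compound id) and ``positive`` (AI > 0).
    """
    missing = [f for f in normalized.index if f not in recovery.index]
    if missing:
        raise ValueError(f"recovery vector missing fractions: {missing}")
    r = recovery.reindex(normalized.index).astype(float)
    ai = normalized.mul(r, axis=0).sum(axis=0)
    order = sorted(ai.index, key=lambda c: (-ai[c], str(c)))
    ranks = pd.Series({c: k + 1 for k, c in enumerate(order)}, name="rank")
    return pd.DataFrame({"AI": ai, "rank": ranks, "positive": ai > 0})


def rank_compounds(scores: pd.DataFrame) -> list:
    """Compound ids in descending-AI order (ties by id, deterministic)."""
    if scores.empty:
        raise ValueError("empty score table")
    return sorted(scores.index, key=lambda c: (-scores.at[c, "AI"], str(c)))


def bioactive_map(normalized: pd.DataFrame, recovery: pd.Series) -> pd.DataFrame:
    """Entrywise R_i * a_{i,j}; column sums reproduce the AIs.

    This is the "bio-active map": the content heatmap reweighted by each
    fraction's bioactivity, so positive (protective) and negative
    (deleterious) contributions are visible per compound per fraction.
    """
    missing = [f for f in normalized.index if f not in recovery.index]
    if missing:
        raise ValueError(f"recovery vector missing fractions: {missing}")
    return normalized.mul(recovery.reindex(normalized.index).astype(float), axis=0)


def dual_scores(
    ai_zebrafish: pd.DataFrame, cell_scores: pd.Series | pd.DataFrame,
) -> pd.DataFrame:
    """Join per-compound cell-protection AI (x) with zebrafish AI (y).

    Compounds in the upper-right quadrant protect cardiomyocytes *and*
    restore larval heart rate. Unmatched compounds on either side are
    reported in the ``unmatched`` attribute of the returned frame.
    """
    if isinstance(cell_scores, pd.DataFrame):
        cell = cell_scores["AI"]
    else:
        cell = cell_scores
    shared = ai_zebrafish.index.intersection(cell.index)
    if len(shared) == 0:
        raise ValueError("no shared compound ids between the two score sets")
    unmatched = sorted(
        set(ai_zebrafish.index).symmetric_difference(set(cell.index)))
    out = pd.DataFrame({
        "cell_AI": cell.loc[shared].astype(float),
        "zebrafish_AI": ai_zebrafish.loc[shared, "AI"].astype(float),
    })
    out.attrs["unmatched"] = unmatched
    return out
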