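"""Scoring and reliability of the LSRP and BIS-11 self-report scales.

The Levenson Self-Report Psychopathy scale has 26 four-point Likert
items split into a primary (16 items, callous/manipulative) and a
secondary (10 items, impulsive/antisocial) subscale; totals range
26-104, 16-64 and 10-40.  The Barratt Impulsiveness Scale (BIS-11) has
30 four-point items, total range 30-120; only the total is scored here.

Reverse-keyed items are mapped x -> 5 - x before summation.  The
published instruments contain reverse-keyed items, but the synthetic
generator emits already-oriented responses, so the packaged default key
has no reversals; users scoring real data must supply the published
keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ScaleKey", "LSRP_KEY", "BIS_KEY", "ScaleScores",
           "score_lsrp", "score_bis", "cronbach_alpha", "score_questionnaire"]


@dataclass(frozen=True)
class ScaleKey:
    """Subscale assignment and reverse-key map (1-based item indices)."""

    n_items: int
    primary_items: tuple[int, ...] = ()
    reverse_items: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for idx in (*self.primary_items, *self.reverse_items):
            if not 1 <= idx <= self.n_items:
                raise ValueError(f"item index {idx} outside 1..{self.n_items}")
        if len(set(self.primary_items)) != len(self.primary_items):
            raise ValueError("duplicate primary item indices")


#: default keys for generator output: LSRP items 1-16 primary, 17-26
#: secondary, no reversals (items are emitted already oriented)
LSRP_KEY = ScaleKey(26, primary_items=tuple(range(1, 17)))
BIS_KEY = ScaleKey(30)


@dataclass(frozen=True)
class ScaleScores:
    lsrp_total: int
    lsrp_primary: int
    lsrp_secondary: int
    bis_total: int | None = None

    def __post_init__(self) -> None:
        if self.lsrp_total != self.lsrp_primary + self.lsrp_secondary:
            raise ValueError("lsrp_total must equal primary + secondary")


def _validate_items(items: np.ndarray, n_expected: int, label: str) -> np.ndarray:
    arr = np.asarray(items)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != n_expected:
        raise ValueError(f"{label} requires exactly {n_expected} items, "
                         f"got {arr.shape[1]}")
    if np.any(pd.isna(arr)):
        raise ValueError(f"{label}: missing item responses are not allowed")
    arr = arr.astype(int)
    if arr.min() < 1 or arr.max() > 4:
        raise ValueError(f"{label}: responses must be integers in 1..4")
    return arr


def _apply_reverse(arr: np.ndarray, reverse_items: tuple[int, ...]) -> np.ndarray:
    out = arr.copy()
    for idx in reverse_items:
        out[:, idx - 1] = 5 - out[:, idx - 1]
    return out


def score_lsrp(items, key: ScaleKey = LSRP_KEY) -> pd.DataFrame:
    """Score 26 LSRP responses into total / primary / secondary sums.

    ``items`` is a length-26 vector or an (n, 26) array of integers 1..4.
    Returns one row per respondent.
    """
    if key.n_items != 26 or len(key.primary_items) != 16:
        raise ValueError("LSRP key must assign 16 of 26 items to primary")
    arr = _apply_reverse(_validate_items(items, 26, "LSRP"), key.reverse_items)
    primary_mask = np.zeros(26, dtype=bool)
    primary_mask[[i - 1 for i in key.primary_items]] = True
    return pd.DataFrame({
        "lsrp_primary": arr[:, primary_mask].sum(axis=1),
        "lsrp_secondary": arr[:, ~primary_mask].sum(axis=1),
        "lsrp_total": arr.sum(axis=1),
    })


def score_bis(items, key: ScaleKey = BIS_KEY) -> pd.Series:
    """Score 30 BIS-11 responses into the total (30-120)."""
    if key.n_items != 30:
        raise ValueError("BIS key must cover 30 items")
    arr = _apply_reverse(_validate_items(items, 30, "BIS-11"), key.reverse_items)
    return pd.Series(arr.sum(axis=1), name="bis_total")


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item var) / var(total)).

    Sample (n-1) variances throughout.  Requires >= 2 items, >= 2
    respondents and a non-degenerate total score.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an (n >= 2) x (k >= 2) item matrix")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance; alpha undefined")
    k = x.shape[1]
    return k / (k - 1) * (1 - x.var(axis=0, ddof=1).sum() / total_var)


def score_questionnaire(questionnaire: pd.DataFrame,
                        lsrp_key: ScaleKey = LSRP_KEY,
                        bis_key: ScaleKey = BIS_KEY) -> pd.DataFrame:
    """Score a questionnaire table (lsrp_item_01.. / bis_item_01.. columns).

    Returns participant_id + the four scale totals, carrying through any
    rating_* columns present.
    """
    lsrp_cols = [f"lsrp_item_{i:02d}" for i in range(1, 27)]
    bis_cols = [f"bis_item_{i:02d}" for i in range(1, 31)]
    missing = [c for c in lsrp_cols + bis_cols if c not in questionnaire]
    if missing:
        raise ValueError(f"questionnaire table lacks columns: {missing[:5]} ...")

    scores = score_lsrp(questionnaire[lsrp_cols].to_numpy(), lsrp_key)
    scores["bis_total"] = score_bis(questionnaire[bis_cols].to_numpy(), bis_key).values
    scores.insert(0, "participant_id", questionnaire["participant_id"].values)
    for col in questionnaire.columns:
        if col.startswith("rating_"):
            scores[col] = questionnaire[col].values
    return scores
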