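"""Individual-specific flagging of acute-inflammation CRP values.

A C-reactive protein (CRP) reading can be transiently elevated by an acute
illness; such readings should not be used as markers of a woman's *chronic*
inflammatory state.  The customary fix -- discard everything above an absolute
cut-point such as 10 mg/L -- also discards chronically high but stable values,
which are common in some subgroups and are exactly the exposure of interest.

The classifier here is individual-specific: a value is flagged only when it is
large *relative to the same woman's other CRP measurements*.  A value is deemed
acute when it exceeds ``f x comparator``, where the comparator is another
summary of her series and the multiplier ``f`` shrinks from 6 to 2 as the
comparator grows (a 6-fold excursion above a low baseline is suspicious; a
2-fold excursion above an already-high baseline is).  Up to three values per
woman can be flagged, through a three-step hierarchy that compares, in order:

1. the third-largest value against the trimmed mean (series mean excluding the
   three largest) -- fires => the three largest are all flagged;
2. the second-largest against the third-largest -- fires => the two largest are
   flagged;
3. the largest against the second-largest -- fires => the largest is flagged.

The first step that fires ends the hierarchy for that woman.  Comparisons are
strict, and each step evaluates ``f`` at its own comparator.  Steps whose
comparator is undefined (series too short) are skipped: step 1 needs at least
4 values, step 2 at least 3, step 3 at least 2; a single value is never
flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "multiplier",
    "trimmed_mean",
    "classify_acute",
    "classify_absolute",
    "classify_cohort",
    "compare_with_absolute",
    "AcuteFlagResult",
]


def multiplier(comparator: float) -> float:
    """Multiplier ``f`` applied to a comparator CRP value (mg/L).

    ``f = 6`` for comparator <= 1, ``6 / sqrt(comparator)`` for
    1 < comparator < 9, and ``2`` for comparator >= 9.  Continuous and
    non-increasing, with range [2, 6].

    Raises
    ------
    ValueError
        If ``comparator`` is not a positive finite number.
    """
    c = float(comparator)
    if not math.isfinite(c) or c <= 0:
        raise ValueError(f"comparator must be a positive finite CRP value, got {comparator!r}")
    if c <= 1.0:
        return 6.0
    if c >= 9.0:
        return 2.0
    return 6.0 / math.sqrt(c)


def trimmed_mean(values) -> float:
    """Mean CRP after excluding the first, second and third maxima.

    Ties are broken by removing three items (positions in the descending
    sort), so e.g. ``[5, 5, 5, 5]`` -> 5.0.

    Raises
    ------
    ValueError
        If fewer than 4 values are supplied (the comparator is undefined and
        the caller should fall through the hierarchy).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 4:
        raise ValueError("trimmed mean needs at least 4 values (three maxima are excluded)")
    kept = np.sort(arr)[:-3]
    return float(kept.mean())


@dataclass(frozen=True)
class AcuteFlagResult:
    """Outcome of the hierarchical classifier for one woman.

    Attributes
    ----------
    flagged_visit_ids : tuple
        Visit ids of the flagged values (0 to 3 of them).
    step_triggered : str
        ``"none"``, ``"step1"``, ``"step2"`` or ``"step3"``.
    comparator_used : float or None
        The comparator of the step that fired (mg/L).
    multiplier_used : float or None
        ``f`` evaluated at that comparator.
    """

    flagged_visit_ids: tuple = field(default_factory=tuple)
    step_triggered: str = "none"
    comparator_used: float | None = None
    multiplier_used: float | None = None


def _ordered_maxima(visit_ids, values):
    """Indices of values sorted descending, stable by visit order."""
    arr = np.asarray(values, dtype=float)
    # stable sort on negated values keeps original (visit) order among ties
    return np.argsort(-arr, kind="stable")


def classify_acute(series) -> AcuteFlagResult:
    """Run the three-step hierarchy on one woman's CRP series.

    Parameters
    ----------
    series : sequence of (visit_id, crp_mg_per_L) pairs
        Ordered by visit time.  All CRP values must be positive.

    Returns
    -------
    AcuteFlagResult
    """
    pairs = list(series)
    if not pairs:
        raise ValueError("CRP series is empty")
    visit_ids = [v for v, _ in pairs]
    if len(set(visit_ids)) != len(visit_ids):
        raise ValueError("visit ids must be unique within a woman's series")
    values = np.asarray([c for _, c in pairs], dtype=float)
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValueError("all CRP values must be positive and finite")

    n = len(values)
    order = _ordered_maxima(visit_ids, values)

    # Step 1: third maximum vs trimmed mean (needs >= 4 values).
    if n >= 4:
        tm = trimmed_mean(values)
        if tm > 0:
            f = multiplier(tm)
            third = values[order[2]]
            if third > f * tm:
                return AcuteFlagResult(
                    flagged_visit_ids=tuple(visit_ids[i] for i in order[:3]),
                    step_triggered="step1",
                    comparator_used=tm,
                    multiplier_used=f,
                )
    # Step 2: second maximum vs third maximum (needs >= 3 values).
    if n >= 3:
        third = float(values[order[2]])
        f = multiplier(third)
        second = values[order[1]]
        if second > f * third:
            return AcuteFlagResult(
                flagged_visit_ids=tuple(visit_ids[i] for i in order[:2]),
                step_triggered="step2",
                comparator_used=third,
                multiplier_used=f,
            )
    # Step 3: maximum vs second maximum (needs >= 2 values).
    if n >= 2:
        second = float(values[order[1]])
        f = multiplier(second)
        top = values[order[0]]
        if top > f * second:
            return AcuteFlagResult(
                flagged_visit_ids=(visit_ids[order[0]],),
                step_triggered="step3",
                comparator_used=second,
                multiplier_used=f,
            )
    return AcuteFlagResult()


def classify_absolute(series, cutpoint: float = 10.0) -> set:
    """Flag every value at or above an absolute cut-point (mg/L).

    The conventional alternative to the hierarchical rule; kept for
    comparative reporting.
    """
    if cutpoint <= 0:
        raise ValueError("cutpoint must be positive")
    return {visit for visit, crp in series if crp >= cutpoint}


def classify_cohort(visits: pd.DataFrame, crp_col: str = "crp") -> pd.DataFrame:
    """Apply the hierarchical classifier to every woman in a visit table.

    Uses each woman's *entire* CRP series across all her study visits (the
    classifier compares a value against previous and future measurements),
    before any exposure-period filtering.

    Parameters
    ----------
    visits : DataFrame
        Long format with columns ``woman_id``, ``visit`` and ``crp_col``;
        rows with missing CRP (visits at which CRP was not assayed) are
        ignored.

    Returns
    -------
    DataFrame
        One row per assayed woman-visit: ``woman_id``, ``visit``,
        ``acute_flag`` (bool), ``step``, ``comparator``, ``multiplier``.
    """
    out = []
    has_crp = visits[visits[crp_col].notna()]
    for woman, grp in has_crp.groupby("woman_id", sort=True):
        grp = grp.sort_values("visit")
        series = list(zip(grp["visit"].tolist(), grp[crp_col].tolist()))
        res = classify_acute(series)
        flagged = set(res.flagged_visit_ids)
        for visit, _ in series:
            out.append(
                {
                    "woman_id": woman,
                    "visit": visit,
                    "acute_flag": visit in flagged,
                    "step": res.step_triggered if visit in flagged else "none",
                    "comparator": res.comparator_used if visit in flagged else np.nan,
                    "multiplier": res.multiplier_used if visit in flagged else np.nan,
                }
            )
    if not out:
        return pd.DataFrame(
            columns=["woman_id", "visit", "acute_flag", "step", "comparator", "multiplier"]
        )
    return pd.DataFrame(out)


def compare_with_absolute(
    visits: pd.DataFrame, flags: pd.DataFrame, cutpoint: float = 10.0, crp_col: str = "crp"
) -> dict:
    """Confusion table: hierarchical flags vs an absolute cut-point.

    Returns counts of CRP observations that are flagged by both rules, by
    neither, retained by the hierarchy despite exceeding the cut-point
    ("retained_high"), and flagged by the hierarchy though below the
    cut-point ("flagged_low").
    """
    merged = visits[visits[crp_col].notna()][["woman_id", "visit", crp_col]].merge(
        flags[["woman_id", "visit", "acute_flag"]], on=["woman_id", "visit"], how="left"
    )
    merged["acute_flag"] = merged["acute_flag"].eq(True)
    high = merged[crp_col] >= cutpoint
    acute = merged["acute_flag"]
    return {
        "n_crp_observations": int(len(merged)),
        "cutpoint": float(cutpoint),
        "flagged_both": int((high & acute).sum()),
        "flagged_neither": int((~high & ~acute).sum()),
        "retained_high": int((high & ~acute).sum()),
        "flagged_low": int((~high & acute).sum()),
        "hierarchical_total": int(acute.sum()),
        "absolute_total": int(high.sum()),
    }
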