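"""Menopause-transition (MT) staging from menstrual histories.

Fine stages, assigned per visit from the reported months since last menses
(``msl``) and a regularity flag:

* premenopausal -- menses within the prior 3 months, unchanged from usual;
* early perimenopausal -- menses within the prior 3 months but less
  predictable than before;
* late perimenopausal -- >=3 but <12 consecutive months of amenorrhea;
* early postmenopausal -- from the visit at which >=12 consecutive months of
  amenorrhea is first observed (the menopause-identification visit);
* late postmenopausal -- beginning ``early_post_span`` attended visits after
  the identification visit (default 2: the identification visit and the next
  visit are early postmenopause, emulating the STRAW notion of later
  menopause; a span of 3 counts the identification visit among the "first 3
  postmenopausal visits").

Stages are ratcheted: a woman never moves to an earlier stage, so a
physiologically noisy report (e.g. a short menses-free gap right after the
final menstrual period) cannot demote her.

The analysis collapses fine stages to three: stage 1 = premenopause/early
perimenopause, stage 2 = late perimenopause/early postmenopause, stage 3 =
late postmenopause.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["assign_stages", "FINE_STAGES", "COMBINED_FROM_FINE"]

FINE_STAGES = ("premenopausal", "early_peri", "late_peri", "early_post", "late_post")

#: combined 3-level analysis stage for each fine stage
COMBINED_FROM_FINE = {
    "premenopausal": 1,
    "early_peri": 1,
    "late_peri": 2,
    "early_post": 2,
    "late_post": 3,
}

_ORD = {name: i for i, name in enumerate(FINE_STAGES)}


def assign_stages(
    visits: pd.DataFrame,
    *,
    early_post_span: int = 2,
    woman_col: str = "woman_id",
    time_col: str = "time_years",
    msl_col: str = "months_since_menses",
    predictable_col: str = "menses_predictable",
) -> pd.DataFrame:
    """Assign fine and combined MT stages to a time-ordered visit table.

    Parameters
    ----------
    visits : DataFrame
        One row per attended woman-visit, ordered (or orderable) by time
        within woman.
    early_post_span : int
        Number of attended visits, counting the menopause-identification
        visit itself, spent in early postmenopause before late postmenopause
        begins.  2 reads "late postmenopause starts two visits after the
        identification visit"; 3 reads "the first 3 postmenopausal visits".

    Returns
    -------
    DataFrame
        Copy of ``visits`` (sorted by woman and time) with ``fine_stage``
        (str) and ``stage`` (int 1/2/3) columns added.

    Raises
    ------
    ValueError
        If visit times are not strictly increasing within a woman, or
        ``early_post_span`` is not in {2, 3}.
    """
    if early_post_span not in (2, 3):
        raise ValueError(f"early_post_span must be 2 or 3, got {early_post_span}")
    # order by protocol visit index where available, else take rows as given;
    # visit *times* must then be strictly increasing (they are the clock for
    # the staging rules, so a non-monotone history is an input error).
    sort_cols = [woman_col] + (["visit"] if "visit" in visits.columns else [])
    df = visits.sort_values(sort_cols, kind="stable").copy()
    grp = df.groupby(woman_col, sort=False)

    dt = grp[time_col].diff()
    if (dt <= 0).any():
        bad = df.loc[dt <= 0, woman_col].iloc[0]
        raise ValueError(f"visit times are not strictly increasing for woman {bad!r}")

    msl = df[msl_col].to_numpy(dtype=float)
    predictable = df[predictable_col].to_numpy(dtype=bool)
    base = np.select(
        [msl >= 12.0, msl >= 3.0, ~predictable],
        [_ORD["early_post"], _ORD["late_peri"], _ORD["early_peri"]],
        default=_ORD["premenopausal"],
    )

    df["_base"] = base
    ratchet = grp["_base"].cummax().to_numpy()

    # Position of each visit within the woman, and of her identification visit.
    pos = grp.cumcount().to_numpy()
    post = ratchet == _ORD["early_post"]
    df["_post_pos"] = np.where(post, pos, np.nan)
    id_pos = grp["_post_pos"].transform("min").to_numpy()
    late = post & (pos - id_pos >= early_post_span)
    fine = np.where(late, _ORD["late_post"], ratchet)

    df["fine_stage"] = pd.Categorical.from_codes(fine.astype(int), categories=list(FINE_STAGES))
    df["fine_stage"] = df["fine_stage"].astype(str)
    df["stage"] = df["fine_stage"].map(COMBINED_FROM_FINE).astype(int)
    return df.drop(columns=["_base", "_post_pos"])
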