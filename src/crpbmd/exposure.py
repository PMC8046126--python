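"""Construction of qualifying exposure observations.

An exposure observation pairs a *first* visit -- at which CRP was measured
(and judged non-acute), BMD at the site of interest was measured, the MT
stage is known and all adjustment covariates are available -- with the
earliest subsequent visit 1.5 to 3.5 years later at which BMD at the same
site was measured again.  The observation carries the lagged exposure
(log2 CRP at the first visit), the outcome (annualized percent change in BMD
across the pair) and the stage/covariates at the first visit.  Pairs may
overlap: a visit can close one pair and open the next.

Hormone-therapy use censors a woman: visits from her first on-HT visit
onward are removed before pairing, and women on HT at baseline are removed
entirely.  Because a within-woman analysis needs at least two observations
per woman, women contributing fewer than two observations (per site) are
dropped.  A derivation "waterfall" of counts is kept so that candidate
visits reconcile exactly with emitted observations plus skip reasons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COVARIATES",
    "censor_at_ht",
    "annualized_slope",
    "build_observations",
    "filter_min_two",
    "change_from_first",
]

#: covariates that must be present at the pair's first visit (full model set)
REQUIRED_COVARIATES = [
    "bmi", "smoking", "diabetes", "alcohol",
    "bone_beneficial", "bone_adverse", "corticosteroids", "nsaids", "aspirin",
    "calcium", "vitd",
]

WINDOW = (1.5, 3.5)  # years between paired visits


def censor_at_ht(visits: pd.DataFrame, ht_col: str = "ht") -> pd.DataFrame:
    """Drop each woman's visits from her first HT-use visit onward.

    Women already on HT at their first visit are removed entirely.
    """
    df = visits.sort_values(["woman_id", "visit"], kind="stable")
    on_ht = df.groupby("woman_id")[ht_col].cummax().astype(bool)
    return df[~on_ht.to_numpy()].reset_index(drop=True)


def annualized_slope(bmd1: float, bmd2: float, delta_t: float):
    """Annualized percent change in BMD: ``100 (bmd2 - bmd1) / bmd1 / dt``.

    Positive = gain, negative = loss.  Inputs may be scalars or arrays;
    ``bmd1`` and ``delta_t`` must be positive.
    """
    b1 = np.asarray(bmd1, dtype=float)
    dt = np.asarray(delta_t, dtype=float)
    if np.any(b1 <= 0) or np.any(dt <= 0):
        raise ValueError("bmd1 and delta_t must be positive")
    out = 100.0 * (np.asarray(bmd2, dtype=float) - b1) / b1 / dt
    return float(out) if out.ndim == 0 else out


def build_observations(
    visits: pd.DataFrame,
    flags: pd.DataFrame,
    site: str,
    *,
    window: tuple = WINDOW,
    required_covariates=None,
) -> tuple[pd.DataFrame, dict]:
    """Build exposure observations for one BMD site.

    Parameters
    ----------
    visits : DataFrame
        HT-censored, staged visit table (columns of
        :data:`crpbmd.cohort.VISIT_COLUMNS` or compatible).
    flags : DataFrame
        Output of :func:`crpbmd.acute.classify_cohort` (``woman_id``,
        ``visit``, ``acute_flag``).
    site : str
        ``"LS"`` or ``"FN"``.

    Returns
    -------
    (observations, waterfall)
        ``observations``: one row per qualifying pair with columns
        ``woman_id, site, visit1, visit2, t1, t2, delta_t, log2_crp, slope,
        stage`` plus the covariates at the first visit.  ``waterfall``: dict
        of counts; candidate CRP visits reconcile exactly as
        ``candidates = acute + missing_covariate + missing_bmd + no_partner +
        observations``.
    """
    site = site.upper()
    if site not in ("LS", "FN"):
        raise ValueError(f"site must be 'LS' or 'FN', got {site!r}")
    bmd_col = "bmd_ls" if site == "LS" else "bmd_fn"
    lo, hi = window
    req = REQUIRED_COVARIATES if required_covariates is None else list(required_covariates)

    df = visits.sort_values(["woman_id", "visit"], kind="stable").merge(
        flags[["woman_id", "visit", "acute_flag"]], on=["woman_id", "visit"], how="left"
    )
    df["acute_flag"] = df["acute_flag"].eq(True)

    counts = {
        "site": site,
        "n_visits": int(len(df)),
        "n_crp_visits": 0,
        "excluded_acute": 0,
        "excluded_missing_covariate": 0,
        "excluded_missing_bmd": 0,
        "excluded_no_partner": 0,
        "n_observations": 0,
    }
    rows = []
    for woman, grp in df.groupby("woman_id", sort=True):
        t = grp["time_years"].to_numpy()
        bmd = grp[bmd_col].to_numpy()
        crp = grp["crp"].to_numpy()
        has_bmd = np.isfinite(bmd)
        cov_ok = grp[req].notna().all(axis=1).to_numpy()
        acute = grp["acute_flag"].to_numpy()
        m = len(grp)
        for j in range(m):
            if not np.isfinite(crp[j]):
                continue
            counts["n_crp_visits"] += 1
            if acute[j]:
                counts["excluded_acute"] += 1
                continue
            if not cov_ok[j]:
                counts["excluded_missing_covariate"] += 1
                continue
            if not has_bmd[j]:
                counts["excluded_missing_bmd"] += 1
                continue
            # earliest subsequent visit with BMD at this site, within window
            partner = -1
            for k in range(j + 1, m):
                dtk = t[k] - t[j]
                if dtk > hi:
                    break
                if dtk >= lo and has_bmd[k]:
                    partner = k
                    break
            if partner < 0:
                counts["excluded_no_partner"] += 1
                continue
            counts["n_observations"] += 1
            row = {
                "woman_id": woman,
                "site": site,
                "visit1": grp["visit"].iat[j],
                "visit2": grp["visit"].iat[partner],
                "t1": t[j],
                "t2": t[partner],
                "delta_t": t[partner] - t[j],
                "log2_crp": float(np.log2(crp[j])),
                "bmd_t1": bmd[j],
                "bmd_t2": bmd[partner],
                "slope": annualized_slope(bmd[j], bmd[partner], t[partner] - t[j]),
                "stage": int(grp["stage"].iat[j]),
            }
            for c in req:
                row[c] = grp[c].iat[j]
            rows.append(row)

    obs_cols = [
        "woman_id", "site", "visit1", "visit2", "t1", "t2", "delta_t",
        "log2_crp", "bmd_t1", "bmd_t2", "slope", "stage", *req,
    ]
    obs = pd.DataFrame(rows, columns=obs_cols)
    return obs, counts


def filter_min_two(obs: pd.DataFrame) -> pd.DataFrame:
    """Drop all observations of women contributing fewer than two.

    Within-woman change is only defined with at least two observations, so
    women with a single qualifying pair carry no information for the
    fixed-effects analysis.  Evaluated per analysis sample (one site).
    """
    n = obs.groupby("woman_id")["woman_id"].transform("size")
    return obs[n >= 2].reset_index(drop=True)


def change_from_first(obs: pd.DataFrame) -> pd.DataFrame:
    """Within-woman change from the first observation to each follow-up.

    For every follow-up observation, its log2 CRP and slope minus the
    woman's first-observation values, tagged with the *follow-up*
    observation's stage.  The first observation itself is the reference and
    is excluded from the output.
    """
    df = obs.sort_values(["woman_id", "t1"], kind="stable")
    first = df.groupby("woman_id").first()
    fu = df[df.groupby("woman_id").cumcount() > 0]
    ref = first.reindex(fu["woman_id"])
    return pd.DataFrame(
        {
            "woman_id": fu["woman_id"].to_numpy(),
            "stage": fu["stage"].to_numpy(),
            "d_log2_crp": fu["log2_crp"].to_numpy() - ref["log2_crp"].to_numpy(),
            "d_slope": fu["slope"].to_numpy() - ref["slope"].to_numpy(),
        }
    )
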