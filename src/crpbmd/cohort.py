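"""Seeded synthetic longitudinal cohort generator.

Generates per-visit records for a cohort of midlife women followed across the
menopause transition, together with the ground truth needed for
parameter-recovery testing.  The generative model, per woman:

* **Timeline.**  Enrolment age ~ U(42, 52).  Visits at ~annual waves with
  Gaussian jitter; each post-baseline visit is missed independently with
  ``missing_visit_prob``.  Late-perimenopause onset is drawn from a truncated
  normal (a small fraction are already past it at entry, so ~97% of women
  start in combined stage 1); the final menstrual period follows after a
  truncated-normal late-peri run-in.  Menstrual-history codes (months since
  last menses, predictability) are emitted per visit and the analysis staging
  rules (:mod:`crpbmd.staging`) are applied to them, so the stages that drive
  the bone model are exactly the stages the analysis will reconstruct.

* **CRP.**  log2 CRP = between-woman level + per-wave drift by stage + a
  chronic AR(1) deviation sampled at assay occasions (CRP is assayed every
  ``crp_assay_interval``-th wave and the chronic level is held between
  assays).  On spike visits the *observed* CRP is multiplied by a factor
  drawn log-uniformly from ``acute_spike_factor_range``; spikes do not enter
  the bone model (they are acute, not chronic, inflammation).

* **BMD.**  True BMD declines geometrically between consecutive waves at an
  annualized rate of ``stage_decline[stage] + beta_per_doubling[stage] x
  log2CRP_prev`` percent per year, where ``log2CRP_prev`` is the chronic
  (spike-free) log2 CRP at the most recent assay wave.  Observed BMD is the
  true value times log-normal measurement noise with sd equal to the site's
  short-term in-vivo CV.

* **HT and covariates.**  Hormone-therapy use starts with a per-visit hazard
  and is absorbing.  BMI drifts; binary covariates (smoking, diabetes,
  medications, supplements) switch on/off with per-visit hazards; alcohol
  category occasionally re-draws.  Covariates do not enter the bone model;
  they exist to exercise the adjustment and inclusion machinery.

Everything is drawn from one ``numpy.random.default_rng(seed)`` stream in a
fixed order, so generation is bit-reproducible given the config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import CohortConfig
from .staging import assign_stages

__all__ = ["generate_cohort", "summarize_cohort", "GroundTruth", "CohortSummary", "VISIT_COLUMNS"]

#: columns of the long-format visit table, one row per attended woman-visit
VISIT_COLUMNS = [
    "woman_id", "visit", "time_years", "age",
    "months_since_menses", "menses_predictable", "fine_stage", "stage",
    "crp", "ht", "bmd_ls", "bmd_fn",
    "bmi", "smoking", "diabetes", "alcohol",
    "bone_beneficial", "bone_adverse", "corticosteroids", "nsaids", "aspirin",
    "calcium", "vitd",
]


@dataclass
class GroundTruth:
    """Simulation truth for recovery tests.

    Attributes
    ----------
    women : DataFrame
        Per woman: realized ``stage2_entry_time`` and ``stage3_entry_time``
        (years; NaN if the stage was never reached during follow-up).
    chronic_log2_crp : DataFrame
        The spike-free log2 CRP path at every scheduled assay wave
        (``woman_id``, ``visit``, ``log2_crp_chronic``), attended or not.
    spikes : DataFrame
        Injected acute spikes (``woman_id``, ``visit``, ``factor``) at
        attended assay visits.
    beta_per_doubling_ls, beta_per_doubling_fn : tuple
        The configured CRP effects by stage, copied from the config.
    """

    women: pd.DataFrame
    chronic_log2_crp: pd.DataFrame
    spikes: pd.DataFrame
    beta_per_doubling_ls: tuple
    beta_per_doubling_fn: tuple

    def to_json(self, path) -> None:
        payload = {
            "beta_per_doubling_ls": list(self.beta_per_doubling_ls),
            "beta_per_doubling_fn": list(self.beta_per_doubling_fn),
            "women": self.women.to_dict(orient="list"),
            "chronic_log2_crp": self.chronic_log2_crp.to_dict(orient="list"),
            "spikes": self.spikes.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, allow_nan=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            women=pd.DataFrame(payload["women"]),
            chronic_log2_crp=pd.DataFrame(payload["chronic_log2_crp"]),
            spikes=pd.DataFrame(payload["spikes"]),
            beta_per_doubling_ls=tuple(payload["beta_per_doubling_ls"]),
            beta_per_doubling_fn=tuple(payload["beta_per_doubling_fn"]),
        )


def _truncated_normal(rng, mean, sd, low, size):
    a = (low - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _empty_truth(config: CohortConfig) -> GroundTruth:
    return GroundTruth(
        women=pd.DataFrame(columns=["woman_id", "stage2_entry_time", "stage3_entry_time"]),
        chronic_log2_crp=pd.DataFrame(columns=["woman_id", "visit", "log2_crp_chronic"]),
        spikes=pd.DataFrame(columns=["woman_id", "visit", "factor"]),
        beta_per_doubling_ls=tuple(config.beta_per_doubling_ls),
        beta_per_doubling_fn=tuple(config.beta_per_doubling_fn),
    )


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a seeded cohort.

    Returns
    -------
    (visits, truth)
        ``visits``: long-format table with :data:`VISIT_COLUMNS`, one row per
        attended woman-visit, sorted by woman and visit.  ``truth``: the
        :class:`GroundTruth` used to generate it.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, W = config.n_women, config.n_waves
    if n == 0:
        return pd.DataFrame(columns=VISIT_COLUMNS), _empty_truth(config)

    # ---- woman-level draws (fixed order for reproducibility) ----
    age0 = rng.uniform(42.0, 52.0, n)
    t_lateperi = _truncated_normal(rng, config.stage2_entry_mean, config.stage2_entry_sd, -2.0, n)
    run_in = _truncated_normal(rng, config.late_peri_dur_mean, config.late_peri_dur_sd, 0.25, n)
    t_fmp = t_lateperi + run_in
    t_earlyperi = t_lateperi - rng.uniform(1.0, 4.0, n)
    crp_level = rng.normal(config.crp_level_mean, config.crp_level_sd, n)
    bmd0_ls = np.clip(rng.normal(config.bmd_baseline_mean_ls, config.bmd_baseline_sd_ls, n), 0.4, None)
    bmd0_fn = np.clip(rng.normal(config.bmd_baseline_mean_fn, config.bmd_baseline_sd_fn, n), 0.3, None)
    bmi0 = np.clip(rng.normal(config.bmi_baseline_mean, config.bmi_baseline_sd, n), 15.0, None)
    alcohol0 = rng.choice(4, size=n, p=np.asarray(config.alcohol_baseline_probs))
    binary_names = list(config.binary_covariates)
    binary0 = {
        name: rng.random(n) < config.binary_covariates[name][0] for name in binary_names
    }
    ht0 = rng.random(n) < config.ht_baseline_prob

    # ---- visit schedule ----
    spacing = config.visit_spacing_years
    jitter = rng.normal(0.0, config.visit_time_jitter_sd, (n, W))
    np.clip(jitter, -0.4 * spacing, 0.4 * spacing, out=jitter)
    jitter[:, 0] = 0.0
    times = np.arange(W) * spacing + jitter
    attended = np.ones((n, W), dtype=bool)
    attended[:, 1:] = rng.random((n, W - 1)) >= config.missing_visit_prob

    # ---- menstrual history ----
    u_pre = rng.uniform(0.5, 2.9, (n, W))
    u_lp = rng.uniform(3.0, 11.9, (n, W))
    tl = t_lateperi[:, None]
    tf = t_fmp[:, None]
    msl = np.where(times < tl, u_pre, np.where(times <= tf, u_lp, 12.0 * (times - tf)))
    predictable = times < t_earlyperi[:, None]

    # ---- staging on attended visits (the analysis rule is the truth) ----
    wi, vi = np.nonzero(attended)
    staged = assign_stages(
        pd.DataFrame(
            {
                "woman_id": wi,
                "visit": vi,
                "time_years": times[wi, vi],
                "months_since_menses": msl[wi, vi],
                "menses_predictable": predictable[wi, vi],
            }
        ),
        early_post_span=config.early_post_span,
    )
    # stage per (woman, wave); missed waves carry the last attended stage
    stage_arr = np.zeros((n, W), dtype=float)
    stage_arr[:] = np.nan
    stage_arr[staged["woman_id"].to_numpy(), staged["visit"].to_numpy()] = staged["stage"].to_numpy()
    stage_arr = pd.DataFrame(stage_arr).ffill(axis=1).to_numpy().astype(int)

    # ---- CRP: drift, chronic AR(1) at assay occasions, spikes ----
    drift_rate = np.asarray(config.crp_drift_per_stage)[stage_arr - 1]
    drift = np.concatenate([np.zeros((n, 1)), np.cumsum(drift_rate[:, :-1], axis=1)], axis=1)

    interval = config.crp_assay_interval
    assay_waves = np.arange(0, W, interval)
    K = len(assay_waves)
    rho, sd_u = config.crp_ar1, config.crp_within_sd
    a = np.empty((n, K))
    a[:, 0] = rng.normal(0.0, sd_u, n) if sd_u > 0 else 0.0
    innov_sd = sd_u * np.sqrt(1.0 - rho**2)
    for k in range(1, K):
        a[:, k] = rho * a[:, k - 1] + (rng.normal(0.0, innov_sd, n) if sd_u > 0 else 0.0)
    chronic = crp_level[:, None] + drift[:, assay_waves] + a  # (n, K)

    spike = rng.random((n, K)) < config.acute_spike_prob
    lo, hi = config.acute_spike_factor_range
    factor = np.exp(rng.uniform(np.log(lo), np.log(hi), (n, K)))

    crp_obs = np.full((n, W), np.nan)
    crp_obs[:, assay_waves] = np.exp2(chronic) * np.where(spike, factor, 1.0)

    # ---- BMD paths ----
    block = (np.arange(W) // interval)  # assay occasion governing each wave
    decline_ls = np.asarray(config.stage_decline_ls)[stage_arr - 1]
    decline_fn = np.asarray(config.stage_decline_fn)[stage_arr - 1]
    beta_ls = np.asarray(config.beta_per_doubling_ls)[stage_arr - 1]
    beta_fn = np.asarray(config.beta_per_doubling_fn)[stage_arr - 1]
    chron_wave = chronic[:, block]  # (n, W): chronic log2 CRP at most recent assay

    true_ls = np.empty((n, W))
    true_fn = np.empty((n, W))
    true_ls[:, 0] = bmd0_ls
    true_fn[:, 0] = bmd0_fn
    dt = np.diff(times, axis=1)
    for v in range(W - 1):
        r_ls = np.clip((decline_ls[:, v] + beta_ls[:, v] * chron_wave[:, v]) / 100.0, -0.5, 0.5)
        r_fn = np.clip((decline_fn[:, v] + beta_fn[:, v] * chron_wave[:, v]) / 100.0, -0.5, 0.5)
        true_ls[:, v + 1] = true_ls[:, v] * (1.0 + r_ls) ** dt[:, v]
        true_fn[:, v + 1] = true_fn[:, v] * (1.0 + r_fn) ** dt[:, v]
    meas_ls = true_ls * np.exp(rng.normal(0.0, config.bmd_measurement_cv_ls, (n, W)))
    meas_fn = true_fn * np.exp(rng.normal(0.0, config.bmd_measurement_cv_fn, (n, W)))
    bmd_miss_ls = rng.random((n, W)) < config.bmd_missing_prob
    bmd_miss_fn = rng.random((n, W)) < config.bmd_missing_prob

    # ---- hormone therapy (absorbing) ----
    ht = np.empty((n, W), dtype=bool)
    ht[:, 0] = ht0
    for v in range(1, W):
        ht[:, v] = ht[:, v - 1] | (rng.random(n) < config.ht_initiation_hazard)

    # ---- covariates ----
    bmi = np.empty((n, W))
    bmi[:, 0] = bmi0
    incr = rng.normal(config.bmi_drift_mean * spacing, config.bmi_drift_sd, (n, W - 1))
    for v in range(1, W):
        bmi[:, v] = np.clip(bmi[:, v - 1] + incr[:, v - 1], 14.0, None)
    bmi_missing = rng.random((n, W)) < config.covariate_missing_prob

    binary = {name: np.empty((n, W), dtype=bool) for name in binary_names}
    for name in binary_names:
        _, on, off = config.binary_covariates[name]
        col = binary[name]
        col[:, 0] = binary0[name]
        for v in range(1, W):
            u = rng.random(n)
            col[:, v] = np.where(col[:, v - 1], u >= off, u < on)

    alcohol = np.empty((n, W), dtype=int)
    alcohol[:, 0] = alcohol0
    p_alc = np.asarray(config.alcohol_baseline_probs)
    for v in range(1, W):
        switch = rng.random(n) < config.alcohol_switch_prob
        redraw = rng.choice(4, size=n, p=p_alc)
        alcohol[:, v] = np.where(switch, redraw, alcohol[:, v - 1])

    # ---- assemble long table (attended visits only) ----
    visits = staged.copy()
    visits["age"] = age0[wi] + times[wi, vi]
    visits["crp"] = crp_obs[wi, vi]
    visits["ht"] = ht[wi, vi].astype(int)
    visits["bmd_ls"] = np.where(bmd_miss_ls[wi, vi], np.nan, meas_ls[wi, vi])
    visits["bmd_fn"] = np.where(bmd_miss_fn[wi, vi], np.nan, meas_fn[wi, vi])
    visits["bmi"] = np.where(bmi_missing[wi, vi], np.nan, bmi[wi, vi])
    for name in binary_names:
        visits[name] = binary[name][wi, vi].astype(int)
    visits["alcohol"] = alcohol[wi, vi]
    visits = visits[VISIT_COLUMNS].sort_values(["woman_id", "visit"]).reset_index(drop=True)

    # ---- ground truth ----
    entry = (
        visits[["woman_id", "time_years", "stage"]]
        .assign(
            s2=lambda d: d["time_years"].where(d["stage"] >= 2),
            s3=lambda d: d["time_years"].where(d["stage"] == 3),
        )
        .groupby("woman_id")
        .agg(stage2_entry_time=("s2", "min"), stage3_entry_time=("s3", "min"))
        .reindex(range(n))
        .reset_index()
        .rename(columns={"index": "woman_id"})
    )
    chronic_df = pd.DataFrame(
        {
            "woman_id": np.repeat(np.arange(n), K),
            "visit": np.tile(assay_waves, n),
            "log2_crp_chronic": chronic.ravel(),
        }
    )
    spike_attended = spike & attended[:, assay_waves]
    si, sk = np.nonzero(spike_attended)
    spikes_df = pd.DataFrame(
        {"woman_id": si, "visit": assay_waves[sk], "factor": factor[si, sk]}
    )
    truth = GroundTruth(
        women=entry,
        chronic_log2_crp=chronic_df,
        spikes=spikes_df,
        beta_per_doubling_ls=tuple(config.beta_per_doubling_ls),
        beta_per_doubling_fn=tuple(config.beta_per_doubling_fn),
    )
    return visits, truth


@dataclass
class CohortSummary:
    """Baseline descriptives plus change-during-follow-up counts."""

    n_women: int
    n_visits: int
    continuous: pd.DataFrame  # variable, mean, sd (at first attended visit)
    categorical: pd.DataFrame  # variable, level, n, pct (at first attended visit)
    changes: pd.DataFrame  # variable, new_since_baseline, stopped_since_baseline


_CONTINUOUS = ["age", "bmi", "log2_crp", "bmd_ls", "bmd_fn"]
_BINARY = [
    "smoking", "diabetes", "bone_beneficial", "bone_adverse",
    "corticosteroids", "nsaids", "aspirin", "calcium", "vitd",
]


def summarize_cohort(visits: pd.DataFrame) -> CohortSummary:
    """Descriptive summary of a visit table.

    Continuous variables are summarized as mean +/- SD at each woman's first
    attended visit (first visit with CRP assayed, for log2 CRP); categorical
    variables as counts (%) at the first visit.  For binary covariates the
    number of follow-up visits at which a woman newly reports "yes" ("new
    since baseline") or newly reports "no" ("stopped since baseline") is
    counted, relative to her baseline report.
    """
    if len(visits) == 0:
        raise ValueError("cannot summarize an empty visit table")
    df = visits.sort_values(["woman_id", "visit"])
    df = df.assign(log2_crp=np.log2(df["crp"]))
    first = df.groupby("woman_id").first()
    first_crp = df[df["crp"].notna()].groupby("woman_id").first()
    if len(first_crp):
        first = first.assign(log2_crp=first_crp["log2_crp"])

    cont = pd.DataFrame(
        {
            "variable": _CONTINUOUS,
            "mean": [first[c].mean() for c in _CONTINUOUS],
            "sd": [first[c].std(ddof=1) for c in _CONTINUOUS],
        }
    )

    cat_rows = []
    n_women = len(first)
    for var, levels in (("stage", [1, 2, 3]), ("alcohol", [0, 1, 2, 3])):
        if var not in first:
            continue
        counts = first[var].value_counts()
        for lev in levels:
            k = int(counts.get(lev, 0))
            cat_rows.append({"variable": var, "level": lev, "n": k, "pct": 100.0 * k / n_women})
    for var in _BINARY:
        k = int(first[var].sum())
        cat_rows.append({"variable": var, "level": 1, "n": k, "pct": 100.0 * k / n_women})
    cat = pd.DataFrame(cat_rows)

    base = df.groupby("woman_id").first()
    followup = df[df["visit"] > df.groupby("woman_id")["visit"].transform("min")]
    chg_rows = []
    for var in _BINARY:
        b = base[var].reindex(followup["woman_id"]).to_numpy()
        cur = followup[var].to_numpy()
        chg_rows.append(
            {
                "variable": var,
                "new_since_baseline": int(((b == 0) & (cur == 1)).sum()),
                "stopped_since_baseline": int(((b == 1) & (cur == 0)).sum()),
            }
        )
    changes = pd.DataFrame(chg_rows)
    return CohortSummary(
        n_women=n_women,
        n_visits=len(df),
        continuous=cont,
        categorical=cat,
        changes=changes,
    )
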