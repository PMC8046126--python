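"""Individual fixed-effects (IFE) estimation with cluster-robust inference.

The model for observation *t* of woman *i* is

    slope_it = beta * log2CRP_it + gamma' z_it + alpha_i + eps_it

where ``alpha_i`` is a woman-specific intercept absorbing every time-fixed
characteristic, measured or not.  Estimation uses the within transform:
every variable (outcome, exposure, covariates) has its woman-specific mean
subtracted, and ordinary least squares is run on the demeaned data.  Because
the exposure is log base-2 CRP, ``beta`` is the change in annualized BMD
slope (%/y) per within-woman *doubling* of CRP.

Standard errors are Huber-White sandwich estimates clustered by woman, with
the CR1 small-sample scaling ``G/(G-1) x (N-1)/(N-K)`` where the parameter
count ``K`` includes the G absorbed woman means (the proper within-estimator
degrees of freedom, matching least-squares-dummy-variables estimation).
Confidence intervals and p-values use the normal reference by default; a t
reference with G-1 degrees of freedom is available as a toggle.

Nested covariate sets mirror the analysis plan: model 1 adjusts for MT
stage, BMI, cigarette use, diabetes and alcohol; model 2 adds bone-
beneficial and bone-adverse medications, oral corticosteroids, NSAIDs and
aspirin; model 3 adds supplemental calcium and vitamin D.  Effect
modification by MT stage is assessed with stage x log2CRP interaction terms
(robust joint Wald test, pairwise contrasts) and with models stratified by
stage, re-demeaned within the stratum subsample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "COVARIATE_SETS",
    "within_demean",
    "fit_ife",
    "wald_interaction_test",
    "pairwise_stage_contrasts",
    "stage_effects",
    "descriptive_stage_comparison",
    "log2_geometric_mean",
    "log2_fold_change",
    "log2_percent_change",
    "effect_per_sd",
]

_BASE = {
    "crude": [],
    "model1": ["bmi", "smoking", "diabetes"],
}
_BASE["model2"] = _BASE["model1"] + [
    "bone_beneficial", "bone_adverse", "corticosteroids", "nsaids", "aspirin",
]
_BASE["model3"] = _BASE["model2"] + ["calcium", "vitd"]

#: plain covariate columns per nested set (stage and alcohol indicators are
#: expanded separately)
COVARIATE_SETS = _BASE

_WITHIN_VAR_TOL = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model definition.

    Parameters
    ----------
    covariate_set : {"crude", "model1", "model2", "model3"}
    interaction_with_stage : bool
        Add stage main effects and stage x log2CRP interaction terms.
    stratum : int or None
        Fit only on observations whose first-visit stage equals this value
        (1, 2 or 3), re-demeaned within the stratum subsample.  Mutually
        exclusive with ``interaction_with_stage``.
    ci_reference : {"normal", "t"}
        Reference distribution for CIs and p-values; "t" uses G-1 df.
    """

    covariate_set: str = "model3"
    interaction_with_stage: bool = False
    stratum: int | None = None
    ci_reference: str = "normal"

    def __post_init__(self):
        if self.covariate_set not in COVARIATE_SETS:
            raise ValueError(f"unknown covariate_set {self.covariate_set!r}")
        if self.stratum is not None and self.stratum not in (1, 2, 3):
            raise ValueError(f"stratum must be 1, 2 or 3, got {self.stratum}")
        if self.stratum is not None and self.interaction_with_stage:
            raise ValueError("stage interaction is undefined within a single stratum")
        if self.ci_reference not in ("normal", "t"):
            raise ValueError(f"ci_reference must be 'normal' or 't', got {self.ci_reference!r}")


@dataclass
class FitResult:
    """Fitted IFE model: coefficients, cluster-robust covariance, tests."""

    params: pd.Series
    bse: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    n_obs: int
    n_women: int
    df_model: int
    spec: ModelSpec
    dropped: list = field(default_factory=list)

    @property
    def beta(self) -> float:
        """Exposure coefficient: %/y change in BMD slope per CRP doubling."""
        return float(self.params["log2_crp"])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "robust_se": self.bse,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.pvalues,
            }
        )


def within_demean(df: pd.DataFrame, group: pd.Series, cols=None) -> pd.DataFrame:
    """Subtract the group (woman) mean from every column.

    Raises if any group has a single row: such women carry no within
    information and should have been filtered out upstream.
    """
    g = pd.Series(np.asarray(group), index=df.index)
    if (g.groupby(g).transform("size") < 2).any():
        raise ValueError("within_demean requires at least 2 observations per woman")
    cols = list(df.columns) if cols is None else list(cols)
    out = df.copy()
    out[cols] = df[cols] - df.groupby(g.to_numpy())[cols].transform("mean")
    return out


def _build_design(obs: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Named design-matrix columns (exposure first) for one ModelSpec."""
    X = pd.DataFrame(index=obs.index)
    X["log2_crp"] = obs["log2_crp"].astype(float)
    include_stage = spec.stratum is None and (
        spec.interaction_with_stage or spec.covariate_set != "crude"
    )
    if include_stage:
        for s in (2, 3):
            X[f"stage_{s}"] = (obs["stage"] == s).astype(float)
    if spec.interaction_with_stage:
        for s in (2, 3):
            X[f"log2_crp_x_stage{s}"] = X["log2_crp"] * X[f"stage_{s}"]
    for c in COVARIATE_SETS[spec.covariate_set]:
        X[c] = obs[c].astype(float)
    if spec.covariate_set != "crude":
        for a in (1, 2, 3):
            X[f"alcohol_{a}"] = (obs["alcohol"] == a).astype(float)
    return X


def _cluster_ols(X: np.ndarray, y: np.ndarray, codes: np.ndarray, n_groups: int,
                 k_absorbed: int = 0) -> tuple:
    """OLS with CR1 cluster-robust covariance.

    ``k_absorbed`` adds absorbed parameters (the woman means of a within
    fit) to K in the small-sample scale ``G/(G-1) x (N-1)/(N-K)``.
    """
    n, k = X.shape
    if n_groups < 2:
        raise ValueError("cluster-robust inference needs at least 2 women")
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    scores = np.zeros((n_groups, k))
    np.add.at(scores, codes, X * resid[:, None])
    meat = scores.T @ scores
    K = k + k_absorbed
    if n - K <= 0:
        raise ValueError("not enough observations for the requested model")
    c = (n_groups / (n_groups - 1.0)) * ((n - 1.0) / (n - K))
    V = c * XtX_inv @ meat @ XtX_inv
    return beta, V, resid


def _drop_rank_deficient(X: pd.DataFrame, tol: float = 1e-9) -> tuple[pd.DataFrame, list]:
    """Drop collinear columns (QR with column pivoting), keeping earlier ones."""
    A = X.to_numpy()
    if A.shape[1] == 0:
        return X, []
    r = np.linalg.matrix_rank(A)
    if r == A.shape[1]:
        return X, []
    keep: list[int] = []
    basis = np.zeros((A.shape[0], 0))
    for j in range(A.shape[1]):
        col = A[:, j]
        if basis.shape[1]:
            proj = basis @ np.linalg.lstsq(basis, col, rcond=None)[0]
            res = col - proj
        else:
            res = col
        if np.linalg.norm(res) > tol * max(1.0, np.linalg.norm(col)):
            keep.append(j)
            basis = np.column_stack([basis, col])
    dropped = [c for i, c in enumerate(X.columns) if i not in keep]
    return X.iloc[:, keep], dropped


def fit_ife(obs: pd.DataFrame, spec: ModelSpec | None = None) -> FitResult:
    """Fit an individual fixed-effects model to an observation table.

    ``obs`` must contain ``woman_id``, ``log2_crp``, ``slope``, ``stage``
    and the covariates of the requested set, with every woman contributing
    at least two observations (see :func:`crpbmd.exposure.filter_min_two`).
    Columns with no within-woman variance (time-fixed) are dropped with a
    warning and reported in ``FitResult.dropped``.
    """
    spec = ModelSpec() if spec is None else spec
    df = obs
    if spec.stratum is not None:
        df = df[df["stage"] == spec.stratum]
        sizes = df.groupby("woman_id")["woman_id"].transform("size")
        df = df[sizes >= 2]
        if len(df) == 0:
            raise ValueError(f"no women with >=2 observations in stratum {spec.stratum}")
    df = df.reset_index(drop=True)

    X = _build_design(df, spec)
    y = df["slope"].astype(float)
    codes, uniques = pd.factorize(df["woman_id"], sort=True)
    G = len(uniques)

    work = within_demean(pd.concat([X, y.rename("_y")], axis=1), pd.Series(codes))
    Xd, yd = work[X.columns], work["_y"].to_numpy()

    wvar = Xd.var(axis=0, ddof=0)
    fixed = [c for c in Xd.columns if wvar[c] < _WITHIN_VAR_TOL]
    if fixed:
        warnings.warn(
            f"dropping time-fixed column(s) with no within-woman variance: {fixed}",
            stacklevel=2,
        )
        Xd = Xd.drop(columns=fixed)
    Xd, collinear = _drop_rank_deficient(Xd)
    if collinear:
        warnings.warn(f"dropping collinear column(s): {collinear}", stacklevel=2)
    dropped = fixed + collinear
    if "log2_crp" in dropped:
        raise ValueError("exposure log2_crp has no within-woman variance; cannot fit")

    beta, V, _ = _cluster_ols(Xd.to_numpy(), yd, codes, G, k_absorbed=G)
    names = list(Xd.columns)
    se = np.sqrt(np.diag(V))
    if spec.ci_reference == "t":
        crit = stats.t.ppf(0.975, G - 1)
        pvals = 2.0 * stats.t.sf(np.abs(beta / se), G - 1)
    else:
        crit = stats.norm.ppf(0.975)
        pvals = 2.0 * stats.norm.sf(np.abs(beta / se))
    return FitResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        ci_low=pd.Series(beta - crit * se, index=names),
        ci_high=pd.Series(beta + crit * se, index=names),
        pvalues=pd.Series(pvals, index=names),
        cov=pd.DataFrame(V, index=names, columns=names),
        n_obs=len(df),
        n_women=G,
        df_model=len(names),
        spec=spec,
        dropped=dropped,
    )


_INTERACTION_TERMS = ["log2_crp_x_stage2", "log2_crp_x_stage3"]


def wald_interaction_test(fit: FitResult) -> dict:
    """Joint Wald chi-square test that both stage x CRP terms are zero.

    Uses the cluster-robust covariance; df = 2.
    """
    missing = [t for t in _INTERACTION_TERMS if t not in fit.params.index]
    if missing:
        raise ValueError(f"fit has no stage interaction terms: missing {missing}")
    b = fit.params[_INTERACTION_TERMS].to_numpy()
    V = fit.cov.loc[_INTERACTION_TERMS, _INTERACTION_TERMS].to_numpy()
    W = float(b @ np.linalg.solve(V, b))
    return {"statistic": W, "df": 2, "p": float(stats.chi2.sf(W, 2))}


def stage_effects(fit: FitResult) -> pd.DataFrame:
    """Stage-specific exposure effects from an interaction fit.

    Effect in stage 1 is the exposure coefficient; in stages 2 and 3 it is
    the exposure coefficient plus the corresponding interaction term.
    """
    if any(t not in fit.params.index for t in _INTERACTION_TERMS):
        raise ValueError("fit has no stage interaction terms")
    rows = []
    for s, contrast in ((1, {}), (2, {"log2_crp_x_stage2": 1.0}), (3, {"log2_crp_x_stage3": 1.0})):
        c = pd.Series(0.0, index=fit.params.index)
        c["log2_crp"] = 1.0
        for k, v in contrast.items():
            c[k] = v
        est = float(c @ fit.params)
        se = float(np.sqrt(c @ fit.cov @ c))
        rows.append(
            {
                "stage": s,
                "beta": est,
                "robust_se": se,
                "ci_low": est - 1.959963984540054 * se,
                "ci_high": est + 1.959963984540054 * se,
                "p": 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def pairwise_stage_contrasts(fit: FitResult) -> pd.DataFrame:
    """Pairwise differences of stage-specific exposure effects (robust)."""
    if any(t not in fit.params.index for t in _INTERACTION_TERMS):
        raise ValueError("fit has no stage interaction terms")
    contrasts = {
        "1v2": {"log2_crp_x_stage2": -1.0},
        "2v3": {"log2_crp_x_stage2": 1.0, "log2_crp_x_stage3": -1.0},
        "1v3": {"log2_crp_x_stage3": -1.0},
    }
    rows = []
    for name, weights in contrasts.items():
        c = pd.Series(0.0, index=fit.params.index)
        for k, v in weights.items():
            c[k] = v
        est = float(c @ fit.params)
        se = float(np.sqrt(c @ fit.cov @ c))
        rows.append(
            {
                "contrast": name,
                "difference": est,
                "robust_se": se,
                "p": 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def descriptive_stage_comparison(deltas: pd.DataFrame, value_cols=("d_log2_crp", "d_slope")) -> dict:
    """Per-stage means of within-woman changes, with robust comparisons.

    For each value column: per-stage mean +/- SD and a test that the mean
    differs from zero, plus pairwise stage differences; both from a
    cell-means regression of the change on stage indicators with
    woman-clustered Huber-White standard errors (repeated observations per
    woman are correlated).

    Returns ``{"means": DataFrame, "pairwise": DataFrame}``.
    """
    present = sorted(int(s) for s in deltas["stage"].unique())
    for s in (1, 2, 3):
        if s not in present:
            warnings.warn(f"no observations in stage {s}; omitted from comparison", stacklevel=2)
    mean_rows, pair_rows = [], []
    for col in value_cols:
        sub = deltas[deltas[col].notna()]
        codes, uniques = pd.factorize(sub["woman_id"], sort=True)
        D = np.column_stack([(sub["stage"] == s).to_numpy(float) for s in present])
        beta, V, _ = _cluster_ols(D, sub[col].to_numpy(float), codes, len(uniques))
        se = np.sqrt(np.diag(V))
        for i, s in enumerate(present):
            grp = sub.loc[sub["stage"] == s, col]
            mean_rows.append(
                {
                    "variable": col,
                    "stage": s,
                    "n": int(len(grp)),
                    "mean": float(grp.mean()),
                    "sd": float(grp.std(ddof=1)) if len(grp) > 1 else np.nan,
                    "p_mean_zero": 2.0 * stats.norm.sf(abs(beta[i] / se[i])) if se[i] > 0 else np.nan,
                }
            )
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                c = np.zeros(len(present))
                c[i], c[j] = 1.0, -1.0
                est = float(c @ beta)
                cse = float(np.sqrt(c @ V @ c))
                pair_rows.append(
                    {
                        "variable": col,
                        "contrast": f"{present[i]}v{present[j]}",
                        "difference": est,
                        "robust_se": cse,
                        "p": 2.0 * stats.norm.sf(abs(est / cse)) if cse > 0 else np.nan,
                    }
                )
    return {"means": pd.DataFrame(mean_rows), "pairwise": pd.DataFrame(pair_rows)}


# -- reporting-scale conversions ------------------------------------------


def log2_geometric_mean(mean_log2: float, digits: int = 2) -> float:
    """Geometric-mean CRP (mg/L) from a mean of log2 CRP: ``2**mean_log2``."""
    return round(float(2.0 ** mean_log2), digits)


def log2_fold_change(delta_log2: float, digits: int = 1) -> float:
    """Fold change on the raw scale from a log2 difference."""
    return round(float(2.0 ** delta_log2), digits)


def log2_percent_change(delta_log2: float, digits: int = 1) -> float:
    """Percent change on the raw scale from a log2 difference."""
    return round(float((2.0 ** delta_log2 - 1.0) * 100.0), digits)


def effect_per_sd(beta_per_doubling: float, sd_log2: float, digits: int = 2) -> float:
    """Effect of a 1-SD exposure change: beta (%/y per doubling) x SD(log2)."""
    return round(float(beta_per_doubling * sd_log2), digits)
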