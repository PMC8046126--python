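"""End-to-end pipeline: simulate -> classify -> stage -> build -> fit -> report.

Runs every step of the analysis on one cohort and writes all artifacts
(CSV/JSON) to a directory.  Deterministic given the config and seed: running
twice with the same inputs produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acute import classify_cohort, compare_with_absolute
from .cohort import generate_cohort, summarize_cohort
from .config import CohortConfig
from .exposure import build_observations, censor_at_ht, change_from_first, filter_min_two
from .ife import (
    ModelSpec,
    descriptive_stage_comparison,
    fit_ife,
    pairwise_stage_contrasts,
    stage_effects,
    wald_interaction_test,
)
from .staging import assign_stages

__all__ = ["PipelineConfig", "run_pipeline"]

_MODELS = ("crude", "model1", "model2", "model3")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    sites: tuple = ("LS", "FN")
    models: tuple = _MODELS
    absolute_cutpoint: float = 10.0
    ci_reference: str = "normal"
    out_dir: str = "pipeline_out"

    def __post_init__(self):
        for s in self.sites:
            if s.upper() not in ("LS", "FN"):
                raise ValueError(f"sites entries must be LS or FN, got {s!r}")
        for m in self.models:
            if m not in _MODELS:
                raise ValueError(f"unknown model {m!r}")
        if self.absolute_cutpoint <= 0:
            raise ValueError("absolute_cutpoint must be positive")
        if self.ci_reference not in ("normal", "t"):
            raise ValueError("ci_reference must be 'normal' or 't'")


def _fit_dict(fit) -> dict:
    return {
        "params": fit.params.round(10).to_dict(),
        "robust_se": fit.bse.round(10).to_dict(),
        "ci_low": fit.ci_low.round(10).to_dict(),
        "ci_high": fit.ci_high.round(10).to_dict(),
        "p": fit.pvalues.round(12).to_dict(),
        "n_obs": fit.n_obs,
        "n_women": fit.n_women,
        "dropped": list(fit.dropped),
    }


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, allow_nan=True) + "\n")


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the whole analysis; returns the artifact directory.

    Artifacts: ``visits.csv``, ``ground_truth.json``, ``flags.csv``,
    ``absolute_comparison.json``, ``table1_baseline.csv``,
    ``table1_changes.csv``, per-site ``obs_<site>.csv`` and
    ``waterfall_<site>.json``, ``table2_stage_changes.csv`` (+ pairwise),
    ``fits.json``, ``table3_stage_stratified.csv`` and ``run.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("simulate"):
        visits, truth = generate_cohort(config.cohort)
        visits.to_csv(out / "visits.csv", index=False)
        truth.to_json(out / "ground_truth.json")

    with _stage("stage"):
        bare = visits.drop(columns=["fine_stage", "stage"])
        staged = assign_stages(bare, early_post_span=config.cohort.early_post_span)

    with _stage("classify"):
        flags = classify_cohort(staged)
        flags.to_csv(out / "flags.csv", index=False)
        _write_json(
            out / "absolute_comparison.json",
            compare_with_absolute(staged, flags, cutpoint=config.absolute_cutpoint),
        )

    with _stage("censor"):
        censored = censor_at_ht(staged)

    with _stage("summarize"):
        summary = summarize_cohort(visits)
        summary.continuous.to_csv(out / "table1_baseline.csv", index=False)
        summary.changes.to_csv(out / "table1_changes.csv", index=False)

    obs_by_site: dict[str, pd.DataFrame] = {}
    with _stage("build"):
        for site in config.sites:
            obs, waterfall = build_observations(censored, flags, site)
            kept = filter_min_two(obs)
            waterfall["n_women_pre_filter"] = int(obs["woman_id"].nunique())
            waterfall["n_observations_final"] = int(len(kept))
            waterfall["n_women_final"] = int(kept["woman_id"].nunique())
            obs_by_site[site.upper()] = kept
            kept.to_csv(out / f"obs_{site.upper()}.csv", index=False)
            _write_json(out / f"waterfall_{site.upper()}.json", waterfall)

    with _stage("describe-change"):
        mean_tabs, pair_tabs = [], []
        for site, kept in obs_by_site.items():
            if len(kept) == 0:
                continue
            comp = descriptive_stage_comparison(change_from_first(kept))
            mean_tabs.append(comp["means"].assign(site=site))
            pair_tabs.append(comp["pairwise"].assign(site=site))
        if mean_tabs:
            pd.concat(mean_tabs).to_csv(out / "table2_stage_changes.csv", index=False)
            pd.concat(pair_tabs).to_csv(out / "table2_pairwise.csv", index=False)

    with _stage("fit"):
        fits: dict = {}
        table3_rows = []
        for site, kept in obs_by_site.items():
            fits[site] = {}
            for model in config.models:
                entry: dict = {}
                plain = fit_ife(
                    kept, ModelSpec(covariate_set=model, ci_reference=config.ci_reference)
                )
                entry["plain"] = _fit_dict(plain)
                inter = fit_ife(
                    kept,
                    ModelSpec(
                        covariate_set=model,
                        interaction_with_stage=True,
                        ci_reference=config.ci_reference,
                    ),
                )
                entry["interaction"] = _fit_dict(inter)
                entry["interaction"]["wald"] = wald_interaction_test(inter)
                entry["interaction"]["stage_effects"] = stage_effects(inter).to_dict(
                    orient="records"
                )
                entry["interaction"]["contrasts"] = pairwise_stage_contrasts(inter).to_dict(
                    orient="records"
                )
                entry["stratified"] = {}
                for stratum in (1, 2, 3):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        sf = fit_ife(
                            kept,
                            ModelSpec(
                                covariate_set=model,
                                stratum=stratum,
                                ci_reference=config.ci_reference,
                            ),
                        )
                    entry["stratified"][str(stratum)] = _fit_dict(sf)
                    table3_rows.append(
                        {
                            "site": site,
                            "model": model,
                            "stage": stratum,
                            "beta": sf.beta,
                            "ci_low": sf.ci_low["log2_crp"],
                            "ci_high": sf.ci_high["log2_crp"],
                            "p": sf.pvalues["log2_crp"],
                            "n_obs": sf.n_obs,
                            "n_women": sf.n_women,
                        }
                    )
                fits[site][model] = entry
        _write_json(out / "fits.json", fits)
        pd.DataFrame(table3_rows).to_csv(out / "table3_stage_stratified.csv", index=False)

    with _stage("log"):
        cfg_dict = {
            "cohort": config.cohort.to_dict(),
            "sites": list(config.sites),
            "models": list(config.models),
            "absolute_cutpoint": config.absolute_cutpoint,
            "ci_reference": config.ci_reference,
        }
        blob = json.dumps(cfg_dict, sort_keys=True).encode()
        _write_json(
            out / "run.json",
            {
                "config": cfg_dict,
                "config_sha256": hashlib.sha256(blob).hexdigest(),
                "versions": {
                    "crpbmd": __version__,
                    "numpy": np.__version__,
                    "pandas": pd.__version__,
                },
            },
        )
    return out
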