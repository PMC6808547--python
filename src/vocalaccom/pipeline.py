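"""End-to-end orchestration of the two translocation analyses.

Experiment 1 (environmental accommodation): per call type, PCA with
parallel-analysis retention on the two-condition subset, then a crossed pDFA
of condition controlled for individual — reported as a table of
(call type, n animals, n calls, % expected correct, % actual correct, p).

Experiment 2 (social accommodation): per call type, PCA on the pooled
translocated + baseline calls, projection of every call, a frozen baseline
centroid, per-call vocal-distance records, the accommodation mixed model with
LRT and R², the pre-vs-5+-weeks comparison, and bootstrapped weekly means.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .accommodation import (
    AccommodationModel,
    PrePostResult,
    compare_prepost,
    fit_accommodation_lme,
    weekly_bootstrap_summary,
)
from .acoustics import weekly_inclusion_filter
from .dimred import ParallelAnalysisPCA
from .distance import PopulationCentroid, build_distance_records, population_centroid
from .pdfa import PDFADesign, PDFAResult, crossed_pdfa
from .synth import N_PARAMS, param_columns

logger = logging.getLogger("vocalaccom")

__all__ = [
    "Experiment1Report",
    "Experiment2CallTypeResult",
    "Experiment2Report",
    "run_experiment1",
    "run_experiment2",
    "run_manifest",
]


def _call_type_table(features: pd.DataFrame, call_type: str) -> pd.DataFrame:
    sub = features[features["call_type"] == call_type].copy()
    cols = param_columns(call_type)
    missing = [c for c in cols if c not in sub.columns]
    if missing:
        raise ValueError(f"feature table lacks column(s) {missing} for {call_type}")
    return sub


def _fit_scores(
    sub: pd.DataFrame,
    call_type: str,
    pa_iter: int,
    seed: int | None,
) -> tuple[ParallelAnalysisPCA, pd.DataFrame]:
    cols = param_columns(call_type)
    model = ParallelAnalysisPCA(n_iter=pa_iter, random_state=seed).fit(sub[cols])
    scores = model.transform(sub[cols])
    out = sub.drop(columns=cols).reset_index(drop=True)
    for k in range(model.n_retained_):
        out[f"PC{k + 1}"] = scores[:, k]
    return model, out


@dataclass
class Experiment1Report:
    """Tables-1/2-shaped pDFA report."""

    rows: pd.DataFrame  # call_type, comparison, n_animals, n_calls, pct_*, p
    pc_models: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = ["Environmental accommodation: crossed pDFA of condition vs individual", ""]
        hdr = f"{'comparison':24s} {'call type':10s} {'animals':>7s} {'calls':>6s} {'% expected':>10s} {'% actual':>9s} {'p':>7s}"
        lines.append(hdr)
        lines.append("-" * len(hdr))
        for _, r in self.rows.iterrows():
            flag = "**" if r.p_value < 0.05 else ("~" if r.p_value < 0.1 else "")
            lines.append(
                f"{r.comparison:24s} {r.call_type:10s} {r.n_animals:7d} {r.n_calls:6d} "
                f"{r.pct_expected_correct:10.2f} {r.pct_actual_correct:9.2f} {r.p_value:7.3f} {flag}"
            )
        lines.append("")
        lines.append("** p < 0.05, ~ trend (p < 0.1)")
        return "\n".join(lines)


def run_experiment1(
    features: pd.DataFrame,
    *,
    comparisons: tuple[tuple[str, str], ...] = (("Before", "After1"), ("Before", "After2")),
    call_types: tuple[str, ...] | None = None,
    n_permutations: int = 1000,
    n_selection_rounds: int = 100,
    pa_iter: int = 10000,
    seed: int | None = None,
) -> Experiment1Report:
    """Condition-vs-condition pDFAs per call type on a feature table."""
    available = set(features["condition"].unique())
    for pair in comparisons:
        for cond in pair:
            if cond not in available:
                raise ValueError(
                    f"condition {cond!r} not in data; available: {sorted(available)}"
                )
    if call_types is None:
        call_types = tuple(pd.unique(features["call_type"]))
    rows = []
    pc_models: dict = {}
    rng = np.random.default_rng(seed)
    for pair in comparisons:
        for ct in call_types:
            sub = _call_type_table(features, ct)
            sub = sub[sub["condition"].isin(pair)]
            sub_seed = int(rng.integers(0, 2**31 - 1))
            model, scores = _fit_scores(sub, ct, pa_iter, sub_seed)
            pc_models[(pair, ct)] = model
            res = crossed_pdfa(
                scores,
                PDFADesign(
                    n_permutations=n_permutations,
                    n_selection_rounds=n_selection_rounds,
                    seed=int(rng.integers(0, 2**31 - 1)),
                ),
            )
            logger.info(
                "pDFA %s %s: %d calls, %%actual=%.2f %%expected=%.2f p=%.3f",
                "-vs-".join(pair), ct, res.n_calls,
                res.pct_actual_correct, res.pct_expected_correct, res.p_value,
            )
            rows.append(
                {
                    "comparison": " vs ".join(pair),
                    "call_type": ct,
                    "n_animals": res.n_individuals,
                    "n_calls": res.n_calls,
                    "pct_expected_correct": res.pct_expected_correct,
                    "pct_actual_correct": res.pct_actual_correct,
                    "p_value": res.p_value,
                }
            )
    return Experiment1Report(rows=pd.DataFrame(rows), pc_models=pc_models)


@dataclass
class Experiment2CallTypeResult:
    call_type: str
    pc_model: ParallelAnalysisPCA
    centroid: PopulationCentroid
    records: pd.DataFrame
    model: AccommodationModel
    prepost: PrePostResult
    weekly: pd.DataFrame


@dataclass
class Experiment2Report:
    """Table-3-shaped accommodation report plus plot-ready weekly data."""

    per_call_type: dict[str, Experiment2CallTypeResult]

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for ct, r in self.per_call_type.items():
            week_b = r.model.terms.loc["week", "B"]
            rows.append(
                {
                    "call_type": ct,
                    "n_retained": r.pc_model.n_retained_,
                    "retained_variance_pct": 100.0
                    * float(np.sum(r.pc_model.explained_variance_ratio_[: r.pc_model.n_retained_])),
                    "week_B": week_b,
                    "week_SE": r.model.terms.loc["week", "SE"],
                    "week_p": r.model.terms.loc["week", "p"],
                    "week_slope_sex_avg": r.model.week_slope,
                    "week_slope_se": r.model.week_slope_se,
                    "interaction_kept": r.model.interaction_kept,
                    "R2_marginal": r.model.r2_marginal,
                    "R2_conditional": r.model.r2_conditional,
                    "LRT_chi2": r.model.lrt_chi2,
                    "LRT_p": r.model.lrt_p,
                    "n_obs": r.model.n_obs,
                    "prepost_effect": r.prepost.condition_effect,
                    "prepost_p": r.prepost.condition_p,
                }
            )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = ["Social accommodation: ln vocal distance over exposure time", ""]
        for ct, r in self.per_call_type.items():
            m = r.model
            lines.append(f"{ct} (n_obs={m.n_obs} from {m.n_individuals} individuals)")
            lines.append(
                f"  retained PCs: {r.pc_model.n_retained_} "
                f"({100 * float(np.sum(r.pc_model.explained_variance_ratio_[: r.pc_model.n_retained_])):.1f}% of total variance)"
            )
            for term, row in m.terms.iterrows():
                tstr = "" if np.isnan(row.t) else f" t={row.t:8.3f} P={row.p:.4g}"
                lines.append(f"  {term:18s} B={row.B:8.3f} SE={row.SE:6.3f}{tstr}")
            lines.append(
                f"  R2_m={m.r2_marginal:.3f} R2_c={m.r2_conditional:.3f} "
                f"chi2_MLT={m.lrt_chi2:.3f} (df={m.lrt_df}, p={m.lrt_p:.4g})"
            )
            lines.append(
                f"  pre vs 5+ weeks: effect={r.prepost.condition_effect:+.3f} "
                f"(p={r.prepost.condition_p:.4g}; n={r.prepost.n_pre} pre, {r.prepost.n_post} post)"
            )
            lines.append("")
        return "\n".join(lines)


def run_experiment2(
    features: pd.DataFrame,
    *,
    baseline_colony: str = "ZH",
    translocated_colony: str = "MA",
    call_types: tuple[str, ...] | None = None,
    pa_iter: int = 10000,
    n_boot: int = 2000,
    min_calls_per_week: int = 5,
    seed: int | None = None,
) -> Experiment2Report:
    """Full social-accommodation analysis of a feature table.

    The PC model is fit per call type on the pooled analysis set
    (translocated + baseline calls), all calls are projected, the baseline
    centroid is computed once and frozen, and the distance records of the
    translocated animals feed the accommodation models.
    """
    if (features["colony"] == baseline_colony).sum() == 0:
        raise ValueError(f"no baseline colony {baseline_colony!r} calls in the data")
    n_baseline = features.loc[features["colony"] == baseline_colony, "caller_id"].nunique()
    if n_baseline < 2:
        raise ValueError("need >= 2 baseline individuals")
    if call_types is None:
        call_types = tuple(pd.unique(features["call_type"]))
    rng = np.random.default_rng(seed)
    out: dict[str, Experiment2CallTypeResult] = {}
    for ct in call_types:
        sub = _call_type_table(features, ct)
        n_in = len(sub)
        sub = weekly_inclusion_filter(sub, min_calls=min_calls_per_week)
        logger.info("%s: weekly 5-call filter kept %d/%d calls", ct, len(sub), n_in)
        model, scores = _fit_scores(sub, ct, pa_iter, int(rng.integers(0, 2**31 - 1)))
        pc_cols = [f"PC{k + 1}" for k in range(model.n_retained_)]
        proportions = model.explained_variance_ratio_[: model.n_retained_]
        baseline_scores = scores[scores["colony"] == baseline_colony]
        centroid = population_centroid(baseline_scores, pc_cols, call_type=ct)
        trans_scores = scores[scores["colony"] == translocated_colony]
        records = build_distance_records(trans_scores, centroid, proportions, pc_cols=pc_cols)
        lme = fit_accommodation_lme(records, call_type=ct)
        prepost = compare_prepost(records, call_type=ct)
        weekly = weekly_bootstrap_summary(
            records, n_boot=n_boot, seed=int(rng.integers(0, 2**31 - 1)),
            min_calls=min_calls_per_week,
        )
        out[ct] = Experiment2CallTypeResult(
            call_type=ct,
            pc_model=model,
            centroid=centroid,
            records=records,
            model=lme,
            prepost=prepost,
            weekly=weekly,
        )
    return Experiment2Report(per_call_type=out)


def run_manifest(config: dict, seed: int | None) -> dict:
    """Reproducibility manifest: config hash, seed, package version."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "vocalaccom_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
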