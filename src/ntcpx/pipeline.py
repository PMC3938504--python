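"""End-to-end analysis pipeline.

Given a cohort (read from CSV or generated synthetically), the pipeline
derives the binary grade 3+ endpoint, computes the LASSO shrinkage path and
entry-order ranking, runs the three selection procedures (nested-CV
optimal, Hosmer-Lemeshow/AUC suboptimal, bootstrap forward likelihood),
fits the corresponding maximum-likelihood NTCP models with odds-ratio
tables, and writes a performance report row per model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, Field

from . import io as ntcp_io
from .cohort import SyntheticConfig, generate_cohort
from .endpoint import derive_endpoint
from .factors import FACTOR_NAMES
from .lasso import LassoLogisticPath, nested_cv_select
from .metrics import evaluate_model
from .model import NtcpLogisticRegression, build_design_matrix, odds_ratio_table
from .selection import ForwardLikelihoodSelector, SuboptimalSelector

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Configuration of one end-to-end run."""

    cohort_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    timepoint: Literal["3m", "12m"] = "12m"
    hl_threshold: float = 0.05
    auc_gain_threshold: float = 0.05
    n_boot_forward: int = 2000
    n_boot_auc_ci: int = 2000
    cv_folds: int = 10
    n_penalties: int = 100
    seed: int = 0
    run_optimal_cv: bool = True
    run_forward: bool = True
    output_dir: str = "ntcpx_output"


@dataclass
class PipelineResult:
    endpoint_summary: dict
    ranking: list[str]
    traces: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    reports: list[dict] = field(default_factory=list)
    artifacts: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline seed=%d timepoint=%s hl_threshold=%g auc_gain_threshold=%g",
                config.seed, config.timepoint, config.hl_threshold, config.auc_gain_threshold)

    # --- cohort -----------------------------------------------------------
    if config.cohort_csv:
        cohort = ntcp_io.read_cohort(config.cohort_csv)
        logger.info("read cohort of %d records from %s", len(cohort), config.cohort_csv)
    elif config.synthetic is not None:
        syn = generate_cohort(config.synthetic)
        cohort = syn.frame
        logger.info("generated synthetic cohort of %d records (seed=%d)",
                    len(cohort), config.synthetic.seed)
        ntcp_io.write_cohort(cohort, out / "cohort.csv")
    else:
        raise ValueError("config needs either cohort_csv or a synthetic spec")

    # --- endpoint ---------------------------------------------------------
    ep = derive_endpoint(cohort, config.timepoint)
    ntcp_io.write_json(ep.summary(), out / "endpoint_summary.json")
    data, y = ep.included, ep.included["outcome"].to_numpy()
    logger.info("endpoint: %d assessed, %d excluded at baseline, %d analysable, %d events",
                ep.n_assessed, ep.n_excluded_baseline, len(data), ep.n_events)

    # --- LASSO path + ranking --------------------------------------------
    path_est = LassoLogisticPath(n_penalties=config.n_penalties).fit(data, y)
    ranking = path_est.ranking_
    path_est.path_.to_tidy_frame().to_csv(out / "lasso_path.csv", index=False)
    ntcp_io.write_json(ranking, out / "ranking.json")
    logger.info("LASSO ranking: %s", ranking)

    result = PipelineResult(endpoint_summary=ep.summary(), ranking=ranking)
    reports = []

    def fit_and_report(label: str, factors: list[str]) -> None:
        est = NtcpLogisticRegression(factors=factors).fit(data, y)
        result.models[label] = est.model_
        ntcp_io.write_model(est.model_, out / f"model_{label}.json")
        odds_ratio_table(est.model_).to_csv(out / f"or_table_{label}.csv", index=False)
        report = evaluate_model(est.model_, data, y, label=label,
                                n_boot=config.n_boot_auc_ci, seed=config.seed)
        reports.append(report.to_dict())

    # --- suboptimal (HL/AUC stopping) ------------------------------------
    sub = SuboptimalSelector(ranking=ranking, hl_threshold=config.hl_threshold,
                             auc_gain_threshold=config.auc_gain_threshold).fit(data, y)
    result.traces["lasso-suboptimal"] = sub.trace_.to_dict()
    ntcp_io.write_json(sub.trace_.to_dict(), out / "trace_lasso_suboptimal.json")
    if sub.selected_factors_ is None:
        logger.warning("suboptimal selection: no calibrated model at hl_threshold=%g",
                       config.hl_threshold)
    else:
        fit_and_report("lasso-suboptimal", sub.selected_factors_)

    # --- optimal (nested CV) ---------------------------------------------
    if config.run_optimal_cv:
        design, column_map = build_design_matrix(data, list(FACTOR_NAMES))
        cv = nested_cv_select(design, y, folds=config.cv_folds,
                              random_state=config.seed,
                              n_penalties=config.n_penalties, column_map=column_map)
        result.traces["lasso-optimal"] = {
            "chosen_penalty": cv.chosen_penalty, "chosen_t": cv.chosen_t,
            "selected_factors": cv.selected_factors,
            "outer_subsets": cv.outer_subsets,
        }
        ntcp_io.write_json(result.traces["lasso-optimal"], out / "trace_lasso_optimal.json")
        if cv.selected_factors:
            fit_and_report("lasso-optimal", cv.selected_factors)

    # --- forward likelihood comparator -----------------------------------
    if config.run_forward:
        fwd = ForwardLikelihoodSelector(n_boot=config.n_boot_forward,
                                        random_state=config.seed).fit(data, y)
        result.traces["forward-LL"] = fwd.trace_.to_dict()
        ntcp_io.write_json(fwd.trace_.to_dict(), out / "trace_forward_ll.json")
        fit_and_report("forward-LL", fwd.selected_factors_)

    result.reports = reports
    pd.DataFrame(reports).to_csv(out / "evaluation_report.csv", index=False)
    ntcp_io.write_json(reports, out / "evaluation_report.json")
    result.artifacts = {p.name: str(p) for p in sorted(out.iterdir())}
    return result
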