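"""End-to-end orchestration of the factorial stress analysis.

Runs simulate -> preprocess -> differential expression -> interaction ->
longitudinal clustering -> trend comparison -> report from a single
configuration, mirroring how the stages are meant to compose. Each stage
is importable on its own; this module only wires them together and
collects the outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .data import ExpressionMatrix, SampleMetadata
from .diffexpr import COMPARISONS, de_call
from .interaction import interaction_analysis
from .longclust import select_G, split_up_down
from .preprocess import (
    DEFAULT_DETECTION_THRESHOLD,
    condition_profiles,
    detection_filter,
    log_and_baseline,
)
from .report import (
    RunReport,
    interaction_table,
    stress_overview_table,
    trend_table,
)
from .simulate import SimulationConfig, simulate
from .trends import (
    DEFAULT_FC_LIMITING,
    DEFAULT_FC_OPTIMAL,
    detect_trend_change,
    paired_profile_set,
    summarize_trends,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    matrix: ExpressionMatrix
    metadata: SampleMetadata
    truth: object
    detected: list
    de: dict  # (organ, comparison) -> DataFrame
    interaction: dict  # organ -> DataFrame
    profiles: dict  # (organ, nitrogen) -> DataFrame
    cluster_models: dict  # (organ, nitrogen) -> (model, assignment, bic table)
    trend_results: dict  # organ -> DataFrame
    trend_summaries: dict  # organ -> (n_q, n_diff, pct)
    tables: dict = field(default_factory=dict)
    report: RunReport | None = None


def run_pipeline(
    config: SimulationConfig,
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    cluster_organs: tuple[str, ...] = ("leaf",),
    fc_opt: float = DEFAULT_FC_OPTIMAL,
    fc_lim: float = DEFAULT_FC_LIMITING,
    g_range=range(1, 9),
    n_restarts: int = 10,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the whole analysis on one synthetic experiment.

    ``seed`` overrides the config seed and also seeds every stochastic
    stage downstream. With ``out_dir`` set, stage outputs are written as
    TSV/JSON under that directory.
    """
    if seed is not None:
        import dataclasses

        config = dataclasses.replace(config, seed=seed)
    run_seed = config.seed

    report = RunReport(parameters={"fc_threshold": fc_threshold, "alpha": alpha,
                                   "detection_threshold": detection_threshold},
                       seed=run_seed)
    matrix, metadata, truth = simulate(config)
    report.add_stage("simulated", len(matrix.entity_ids))

    detected = detection_filter(matrix, metadata, threshold=detection_threshold)
    report.add_stage("detected", len(detected))
    filtered = matrix.subset(detected)
    logm = log_and_baseline(filtered)

    de = {}
    for organ in config.organs:
        for comp in COMPARISONS:
            de[(organ, comp)] = de_call(
                logm, metadata, organ, comp, fc_threshold=fc_threshold, alpha=alpha
            )

    inter = {
        organ: interaction_analysis(
            logm, metadata, organ, fc_threshold=fc_threshold, alpha=alpha
        )
        for organ in config.organs
    }

    profiles, cluster_models, trend_results, trend_summaries = {}, {}, {}, {}
    for organ in cluster_organs:
        p_opt = condition_profiles(logm, metadata, organ, "optimal")
        p_lim = condition_profiles(logm, metadata, organ, "limiting")
        profiles[(organ, "optimal")] = p_opt
        profiles[(organ, "limiting")] = p_lim

        from .longclust import prescreen_profiles

        for nitrogen, prof, fc in (("optimal", p_opt, fc_opt), ("limiting", p_lim, fc_lim)):
            keep = prescreen_profiles(prof, fc)
            report.add_stage(f"cluster_input_{organ}_{nitrogen}", len(keep))
            if len(keep) < 2:
                log.warning("too few profiles to cluster (%s, %s)", organ, nitrogen)
                continue
            model, assign, bic_table = select_G(
                prof.loc[keep], g_range, n_restarts=n_restarts, seed=run_seed
            )
            pair = (2, 1) if nitrogen == "optimal" else (3, 2)
            assign["subgroup"] = split_up_down(assign, prof.loc[keep], split_pair=pair)
            cluster_models[(organ, nitrogen)] = (model, assign, bic_table)

        qualifying, _stacked = paired_profile_set(p_opt, p_lim, fc_opt=fc_opt, fc_lim=fc_lim)
        report.add_stage(f"trend_qualifying_{organ}", len(qualifying))
        if (organ, "optimal") in cluster_models and qualifying:
            assign_opt = cluster_models[(organ, "optimal")][1]
            groups = assign_opt.loc[
                [e for e in qualifying if e in assign_opt.index], "map_group"
            ]
            res = detect_trend_change(
                p_opt, p_lim, list(groups.index), groups, seed=run_seed,
                n_restarts=n_restarts,
            )
            trend_results[organ] = res
            trend_summaries[organ] = summarize_trends(res)

    tables = {
        "stress_overview": stress_overview_table(de),
        "interaction": interaction_table(inter),
        "trends": trend_table(trend_summaries) if trend_summaries else pd.DataFrame(),
    }
    report.validate_monotone(["simulated", "detected"])

    result = PipelineResult(
        matrix=matrix, metadata=metadata, truth=truth, detected=detected,
        de=de, interaction=inter, profiles=profiles, cluster_models=cluster_models,
        trend_results=trend_results, trend_summaries=trend_summaries,
        tables=tables, report=report,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.matrix.to_tsv(out_dir / "expression_raw.tsv")
    result.metadata.to_tsv(out_dir / "sample_metadata.tsv")
    if hasattr(result.truth, "to_tsv"):
        result.truth.to_tsv(out_dir / "truth.tsv")
    pd.Series(result.detected, name="entity_id").to_csv(
        out_dir / "detected_entities.tsv", sep="\t", index=False
    )
    for (organ, comp), df in result.de.items():
        df.to_csv(out_dir / f"de_{organ}_{comp}.tsv", sep="\t")
    for organ, df in result.interaction.items():
        df.to_csv(out_dir / f"interaction_{organ}.tsv", sep="\t")
    for (organ, nitrogen), (model, assign, bic_table) in result.cluster_models.items():
        assign.to_csv(out_dir / f"clusters_{organ}_{nitrogen}.tsv", sep="\t")
        bic_table.to_csv(out_dir / f"bic_{organ}_{nitrogen}.tsv", sep="\t", index=False)
    for organ, df in result.trend_results.items():
        df.to_csv(out_dir / f"trends_{organ}.tsv", sep="\t")
    for name, table in result.tables.items():
        table.to_csv(out_dir / f"table_{name}.tsv", sep="\t")
    if result.report is not None:
        result.report.to_json(out_dir / "run_report.json")
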