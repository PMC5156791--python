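"""End-to-end orchestration: simulate/load -> DE -> network stats ->
candidate selection -> enrichment -> coverage -> validation -> report.

Each stage reads and writes plain TSV/JSON files in the run directory, so
any stage can also be run standalone from the CLI and a run is resumable
and fully auditable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import data_io, diff_expr, enrichment, regnet, reporting, selection
from . import synthetic_data as syn
from .config import RunConfig
from .data_io import ValidationError

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_candidates(cands: selection.CandidateSet, path: Path) -> None:
    rows = []
    by_id = {s.mirna_id: s for s in cands.all_stats}
    selected = cands.ids
    for s in cands.all_stats:
        p_nod, p_tfp = cands.pvalues.get(s.mirna_id, (float("nan"), float("nan")))
        rows.append(
            {
                "mirna": s.mirna_id,
                "N": s.n_targets,
                "NOD": s.nod,
                "TF": s.tf_targets,
                "TFP": s.tfp_rounded,
                "p_nod": p_nod,
                "p_tfp": p_tfp,
                "selected": s.mirna_id in selected,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> reporting.ValidationReport:
    """Execute the full analysis described by ``config``.

    Returns the assembled report; all stage outputs land in
    ``config.out_dir``.  Any stage failure is re-raised as
    :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = out / "inputs"
    inputs.mkdir(exist_ok=True)

    # ---- stage: inputs (simulate or load) ----
    stage = "inputs"
    try:
        if config.simulate:
            network, net_truth = syn.simulate_network(
                n_mirna=config.n_mirna,
                n_gene=config.n_gene,
                tf_fraction=config.tf_fraction,
                mean_out_degree=config.mean_out_degree,
                n_planted=config.n_planted,
                private_targets_per_planted=config.private_targets_per_planted,
                planted_tf_boost=config.planted_tf_boost,
                seed=config.seed,
            )
            expr, truth = syn.simulate_expression(
                network,
                n_control=config.n_control,
                n_case=config.n_case,
                de_fraction=config.de_fraction,
                lfc_magnitude=config.lfc_magnitude,
                d0=config.d0,
                s0sq=config.s0sq,
                seed=config.seed,
                planted_biomarkers=net_truth.planted_biomarkers,
            )
            gene_sets = syn.simulate_gene_sets(
                network,
                n_sets=config.n_gene_sets,
                size_low=config.gene_set_size_low,
                size_high=config.gene_set_size_high,
                n_enriched_for=net_truth.planted_biomarkers,
                enrichment_strength=config.enrichment_strength,
                seed=config.seed,
            )
            reported = syn.simulate_reported_biomarkers(
                truth, network, subtype=config.label, seed=config.seed
            )
            data_io.write_edge_list(network, inputs / "network.tsv", inputs / "tf_genes.txt")
            data_io.write_expression_matrix(
                expr, inputs / "expression.tsv", inputs / "groups.tsv"
            )
            data_io.write_gene_sets(gene_sets, inputs / "gene_sets.gmt")
            data_io.write_reported_biomarkers(reported, inputs / "reported_biomarkers.tsv")
            truth.to_json(inputs / "truth.json")
        else:
            expr = data_io.read_expression_matrix(config.matrix_path, config.groups_path)
            network = data_io.read_edge_list(config.network_path, config.tf_path)
            gene_sets = (
                data_io.read_gene_sets(config.gmt_path) if config.gmt_path else None
            )
            reported = (
                data_io.read_reported_biomarkers(config.reported_path)
                if config.reported_path
                else None
            )
            truth = (
                syn.SyntheticTruth.from_json(config.truth_path)
                if config.truth_path
                else None
            )
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise StageError(stage, e) from e

    digests = {
        p.name: reporting.file_digest(p) for p in sorted(inputs.glob("*")) if p.is_file()
    }

    # ---- stage: differential expression ----
    stage = "de"
    try:
        de = diff_expr.run_de(expr, alpha=config.de_alpha)
        de.table.to_csv(out / "de.tsv", sep="\t")
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- stage: condition network + stats ----
    stage = "netstats"
    try:
        cond = regnet.build_condition_network(network, de.de_mirnas, config.label)
        stats = regnet.compute_stats(cond)
        stats_df = regnet.stats_table(stats)
        stats_df.to_csv(out / "netstats.tsv", sep="\t", index=False)
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- stage: candidate selection ----
    stage = "select"
    try:
        if config.selection_mode == "permutation":
            cands = selection.select_candidates_permutation(
                cond,
                alpha=config.selection_alpha,
                n_iters=config.perm_iters,
                seed=config.seed,
            )
        else:
            cands = selection.select_candidates(
                stats, alpha=config.selection_alpha, condition_label=config.label
            )
        _write_candidates(cands, out / "candidates.tsv")
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- stage: enrichment + coverage ----
    enr_results: list[enrichment.EnrichmentResult] = []
    coverage: list[enrichment.PathwayCoverage] = []
    enr_summary = None
    if gene_sets is not None and cands.candidates:
        stage = "enrich"
        try:
            query = frozenset().union(
                *(regnet.unique_targets(cond, c.mirna_id) for c in cands.candidates)
            )
            universe = (
                network.genes if config.universe == "network" else gene_sets.all_genes()
            )
            enr_results = enrichment.enrich(
                query, gene_sets, universe, alpha=config.enrich_alpha
            )
            enrichment.enrichment_table(enr_results).to_csv(
                out / "enrichment.tsv", sep="\t", index=False
            )
            coverage = enrichment.pathway_coverage(
                cond, cands, enr_results, gene_sets, target_mode=config.coverage_target_mode
            )
            enrichment.coverage_table(coverage).to_csv(
                out / "coverage.tsv", sep="\t", index=False
            )
            enr_summary = {
                "n_tested": len(enr_results),
                "n_enriched": sum(r.enriched for r in enr_results),
            }
        except Exception as e:
            raise StageError(stage, e) from e

    # ---- stage: validation ----
    stage = "validate"
    validation = None
    truth_metrics = None
    try:
        if reported is not None and cands.candidates:
            overlap, pct = reporting.precision(cands.ids, reported.ids)
            validation = {
                "predicted": sorted(cands.ids),
                "reported": sorted(reported.ids),
                "overlap": sorted(overlap),
                "precision_percent": pct,
            }
        if truth is not None and truth.planted_biomarkers:
            sens, fdp = reporting.sensitivity_fdp(cands.ids, truth.planted_biomarkers)
            truth_metrics = {"sensitivity": sens, "false_discovery_proportion": fdp}
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- stage: report ----
    stage = "report"
    try:
        cand_stats_df = stats_df[stats_df["mirna"].isin(cands.ids)].reset_index(drop=True)
        table2 = reporting.candidate_table(
            cand_stats_df, enrichment.coverage_table(coverage) if coverage else None
        )
        table2.to_csv(out / "candidate_table.tsv", sep="\t", index=False)
        report = reporting.build_report(
            seed=config.seed,
            parameters=config.to_dict(),
            input_digests=digests,
            de_summary={
                "n_features": len(de.table),
                "n_de": int(de.table["is_de"].sum()),
                "d0": float(de.d0) if de.d0 != float("inf") else "inf",
                "s0sq": float(de.s0sq),
                "alpha": de.alpha,
            },
            stats_rows=stats_df,
            candidates={
                "condition": config.label,
                "n_candidates": len(cands.candidates),
                "ids": sorted(cands.ids),
            },
            enrichment_summary=enr_summary,
            validation=validation,
            truth_metrics=truth_metrics,
        )
        report.to_json(out / "report.json")
    except Exception as e:
        raise StageError(stage, e) from e
    log.info("run complete: %s", out)
    return report
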