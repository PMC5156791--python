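"""Literature-overlap precision, cross-condition overlaps and run reports.

Prediction precision is the percentage of predicted candidate miRNAs that
also appear in a literature-reported biomarker list (denominator: the
predicted set).  Cross-condition overlap partitions two candidate sets into
shared and condition-specific IDs.  The run report collects every stage's
summary with input digests and the master seed so a run is reproducible
and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable

import pandas as pd

from .data_io import ValidationError, normalize_mirna_id
from .regnet import round_half_up

log = logging.getLogger(__name__)


def _normalize_ids(ids: Iterable[str]) -> frozenset[str]:
    return frozenset(normalize_mirna_id(i) for i in ids)


def precision(predicted: Iterable[str], reported: Iterable[str]) -> tuple[frozenset[str], float]:
    """Overlap IDs and prediction precision in percent (1 decimal, half-up).

    Both ID collections are normalised before intersecting, so duplicates
    and case/prefix spelling differences cannot change the result.
    """
    pred = _normalize_ids(predicted)
    if not pred:
        raise ValidationError("empty predicted set")
    rep = _normalize_ids(reported)
    overlap = pred & rep
    pct = round_half_up(100.0 * len(overlap) / len(pred), 1)
    return overlap, pct


def cross_overlap(
    candidates_a: Iterable[str], candidates_b: Iterable[str]
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """(shared, only_a, only_b): a disjoint partition of the union."""
    a = _normalize_ids(candidates_a)
    b = _normalize_ids(candidates_b)
    return a & b, a - b, b - a


def sensitivity_fdp(predicted: Iterable[str], truth: Iterable[str]) -> tuple[float, float]:
    """Recovery of a planted-truth set: (sensitivity, false-discovery proportion)."""
    pred = _normalize_ids(predicted)
    true = _normalize_ids(truth)
    if not true:
        raise ValidationError("empty truth set")
    tp = len(pred & true)
    sens = tp / len(true)
    fdp = (len(pred) - tp) / len(pred) if pred else 0.0
    return sens, fdp


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class ValidationReport:
    """Assembled run report; ``body`` is the deterministic payload."""

    body: dict

    @property
    def body_sha256(self) -> str:
        canon = json.dumps(self.body, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()

    def to_json(self, path: str | Path, timestamp: bool = True) -> None:
        doc = {
            "body": self.body,
            "body_sha256": self.body_sha256,
        }
        if timestamp:
            doc["generated_at"] = datetime.now(timezone.utc).isoformat()
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def build_report(
    *,
    seed: int,
    parameters: dict,
    input_digests: dict[str, str],
    de_summary: dict,
    stats_rows: pd.DataFrame,
    candidates: dict[str, dict],
    enrichment_summary: dict | None = None,
    validation: dict | None = None,
    truth_metrics: dict | None = None,
) -> ValidationReport:
    """Combine stage outputs into one deterministic report.

    Raises if a required stage summary is missing; timestamps live outside
    the hashed body so identical runs produce identical digests.
    """
    required = {"de_summary": de_summary, "stats_rows": stats_rows, "candidates": candidates}
    for name, value in required.items():
        if value is None:
            raise ValidationError(f"missing stage output: {name}")
    body = {
        "seed": seed,
        "parameters": parameters,
        "inputs": input_digests,
        "de": de_summary,
        "network_stats": stats_rows.to_dict(orient="records"),
        "candidates": candidates,
    }
    if enrichment_summary is not None:
        body["enrichment"] = enrichment_summary
    if validation is not None:
        body["validation"] = validation
    if truth_metrics is not None:
        body["truth_metrics"] = truth_metrics
    return ValidationReport(body=body)


def candidate_table(
    stats_table: pd.DataFrame, coverage_table: pd.DataFrame | None
) -> pd.DataFrame:
    """Merged per-candidate table: mirna, N, NOD, TF, TFP, pathways, pathway_fraction."""
    out = stats_table.copy()
    if coverage_table is not None and len(coverage_table):
        out = out.merge(
            coverage_table[["mirna", "pathways", "pathway_fraction"]], on="mirna", how="left"
        )
        out["pathways"] = out["pathways"].fillna(0).astype(int)
        out["pathway_fraction"] = out["pathway_fraction"].fillna(0.0)
    else:
        out["pathways"] = 0
        out["pathway_fraction"] = 0.0
    return out[["mirna", "N", "NOD", "TF", "TFP", "pathways", "pathway_fraction"]]
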