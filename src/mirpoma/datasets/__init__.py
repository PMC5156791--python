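"""Bundled published summary data for acute coronary syndrome subtyping.

These small tables carry candidate-biomarker network statistics (N, NOD,
TF, enriched-pathway counts) and partial literature-reported biomarker
lists for the two ACS subtypes, AMI and UA.  They let the worked examples
and the validation arithmetic (TFP, prediction precision, cross-subtype
overlap, pathway coverage) run without any external data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..data_io import ReportedBiomarkerList, normalize_mirna_id, read_reported_biomarkers
from ..regnet import MiRNAStats

#: Published totals of significantly enriched pathways per subtype.
ENRICHED_PATHWAY_TOTALS = {"AMI": 35, "UA": 18}


def _path(name: str):
    return resources.files(__package__) / name


def load_candidate_stats() -> pd.DataFrame:
    """Candidate statistics for both subtypes, IDs normalised.

    Columns: subtype, mirna, N, NOD, TF, pathways.
    """
    with resources.as_file(_path("acs_candidate_stats.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    df["mirna"] = df["mirna"].map(normalize_mirna_id)
    return df


def candidate_ids(subtype: str) -> frozenset[str]:
    df = load_candidate_stats()
    return frozenset(df.loc[df["subtype"] == subtype, "mirna"])


def candidate_mirna_stats(subtype: str) -> list[MiRNAStats]:
    """The published per-miRNA statistics as MiRNAStats records."""
    df = load_candidate_stats()
    rows = df[df["subtype"] == subtype]
    return [
        MiRNAStats(
            mirna_id=r.mirna, n_targets=int(r.N), nod=int(r.NOD), tf_targets=int(r.TF)
        )
        for r in rows.itertuples()
    ]


def load_reported_biomarkers(subtype: str) -> ReportedBiomarkerList:
    name = f"reported_biomarkers_{subtype.lower()}.tsv"
    with resources.as_file(_path(name)) as p:
        return read_reported_biomarkers(p)
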