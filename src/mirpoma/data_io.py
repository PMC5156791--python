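"""Readers, writers and container types for the pipeline's file formats.

All formats are plain tab-separated text (UTF-8, ``#``-prefixed comment
lines ignored): an expression matrix (features x samples) with a companion
sample-group table, a miRNA->gene edge list with a transcription-factor
gene list, GMT gene sets, and a literature-reported biomarker table.

Identifier hygiene is centralised here: every miRNA ID that enters the
package passes through :func:`normalize_mirna_id` and every gene ID through
:func:`normalize_gene_id`, so that the same molecule spelled differently
across files ("hsa-miR-155", "miR-155") intersects correctly.  Star
(minor-arm) miRNAs keep their ``*`` marker and are never collapsed onto the
major arm.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CONTROL = "control"
DISEASE = "disease"

_GROUP_ALIASES = {
    "control": CONTROL,
    "ctrl": CONTROL,
    "normal": CONTROL,
    "healthy": CONTROL,
    "disease": DISEASE,
    "case": DISEASE,
}

ROLES = {"diagnostic", "prognostic", "both", "unknown"}
DIRECTIONS = {"up", "down", "mixed", "unknown"}

#: Unicode characters used in print for the star (minor-arm) marker.
_STAR_CHARS = "∗⁎＊"


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates a contract."""


def normalize_mirna_id(raw: str) -> str:
    """Canonicalise a miRNA identifier.

    Lowercases, strips the species prefix ``hsa-``, removes whitespace and
    typographic markup (carets, unicode asterisk variants), and moves any
    star marker to a single trailing ``*``.  Arm suffixes (``-3p``/``-5p``)
    are preserved.  The function is idempotent.

    >>> normalize_mirna_id("hsa-miR-155")
    'mir-155'
    >>> normalize_mirna_id("miR-340^*∗*^")
    'mir-340*'
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValidationError("empty miRNA identifier")
    s = raw.strip()
    for ch in _STAR_CHARS:
        s = s.replace(ch, "*")
    s = s.replace("^", "")
    s = re.sub(r"\s+", "", s)
    s = s.lower()
    while s.startswith("hsa-"):
        s = s[4:]
    starred = "*" in s
    s = s.replace("*", "")
    if not s:
        raise ValidationError(f"miRNA identifier {raw!r} is empty after normalization")
    return s + "*" if starred else s


def normalize_gene_id(raw: str) -> str:
    """Case-fold a gene identifier; no alias resolution is attempted."""
    if not isinstance(raw, str) or not raw.strip():
        raise ValidationError("empty gene identifier")
    return raw.strip().casefold()


def _normalize_group(raw: str, sample: str) -> str:
    key = raw.strip().lower()
    if key not in _GROUP_ALIASES:
        raise ValidationError(
            f"sample {sample!r} has unrecognised group label {raw!r} "
            f"(expected one of {sorted(set(_GROUP_ALIASES))})"
        )
    return _GROUP_ALIASES[key]


# ---------------------------------------------------------------------------
# container types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of log2-scale abundances with group labels.

    ``values`` is indexed by normalised miRNA IDs (rows) and sample IDs
    (columns); ``groups`` maps every sample ID to ``"control"`` or
    ``"disease"``.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature IDs: {dupes}")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample IDs in expression matrix")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValidationError(
                f"sample(s) missing from the groups table: {missing}"
            )
        bad = {g for g in self.groups.values()} - {CONTROL, DISEASE}
        if bad:
            raise ValidationError(f"unrecognised group labels: {sorted(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    @property
    def n_control(self) -> int:
        return len(self.samples_in_group(CONTROL))

    @property
    def n_disease(self) -> int:
        return len(self.samples_in_group(DISEASE))


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Bipartite miRNA->gene regulation network with TF annotation on genes.

    The miRNA and gene ID spaces are disjoint by construction (miRNA IDs are
    produced by :func:`normalize_mirna_id`, gene IDs by
    :func:`normalize_gene_id`), so self-loops cannot occur.
    """

    edges: frozenset[tuple[str, str]]
    tf_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.edges:
            raise ValidationError("empty network")
        extra_tf = self.tf_genes - self.genes
        if extra_tf:
            raise ValidationError(
                f"tf_genes not present in the network: {sorted(extra_tf)[:5]}"
            )

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.edges)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.edges)

    def targets(self, mirna: str) -> frozenset[str]:
        return frozenset(g for m, g in self.edges if m == mirna)

    def adjacency(self) -> dict[str, set[str]]:
        """miRNA -> set of target genes."""
        adj: dict[str, set[str]] = {}
        for m, g in self.edges:
            adj.setdefault(m, set()).add(g)
        return adj


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named pathway gene sets (GMT semantics: unique names, non-empty sets)."""

    sets: dict[str, GeneSet]

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValidationError(f"gene-set key {name!r} != name {gs.name!r}")
            if not gs.genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self:
            out |= gs.genes
        return frozenset(out)


@dataclass(frozen=True)
class BiomarkerRecord:
    mirna_id: str
    subtype: str = "unknown"
    role: str = "unknown"
    direction: str = "unknown"


@dataclass
class ReportedBiomarkerList:
    """Literature-reported biomarker miRNAs (IDs normalised on ingestion)."""

    records: list[BiomarkerRecord]

    def __post_init__(self) -> None:
        for r in self.records:
            if r.role not in ROLES:
                raise ValidationError(f"unknown biomarker role {r.role!r}")
            if r.direction not in DIRECTIONS:
                raise ValidationError(f"unknown direction {r.direction!r}")

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(r.mirna_id for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping comments/blanks."""
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n").rstrip("\r")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            yield i, stripped


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, label) TSV; an optional header is skipped."""
    groups: dict[str, str] = {}
    for lineno, line in _data_lines(Path(path)):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        sample, label = fields[0].strip(), fields[1].strip()
        if label.lower() not in _GROUP_ALIASES:
            # tolerate a single header row like "sample\tgroup"
            if not groups and sample.lower() in {"sample", "sample_id", "id"}:
                continue
            raise ValidationError(
                f"{path}:{lineno}: unrecognised group label {label!r}"
            )
        groups[sample] = _normalize_group(label, sample)
    if not groups:
        raise ValidationError(f"{path}: no sample-group assignments found")
    return groups


def read_expression_matrix(matrix_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Read a features x samples TSV plus the sample-group table.

    The matrix must have a header row of sample IDs and feature IDs in the
    first column.  Duplicate feature rows (after ID normalisation) are
    collapsed by their mean, with a logged warning.  A sample present in the
    matrix but absent from the groups file is an error; so is any
    non-numeric cell.
    """
    raw = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0, dtype=str)
    if raw.shape[1] == 0:
        raise ValidationError(f"{matrix_path}: no sample columns found")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{matrix_path}: non-numeric value {raw.iat[r, c]!r} at feature "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{matrix_path}: missing value at feature {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}"
        )
    numeric.index = [normalize_mirna_id(i) for i in numeric.index]
    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        log.warning(
            "%s: collapsing %d duplicate feature row(s) by mean", matrix_path, n_dup
        )
        order = list(dict.fromkeys(numeric.index))
        numeric = numeric.groupby(level=0, sort=False).mean().loc[order]
    numeric.columns = [str(c).strip() for c in numeric.columns]

    groups = read_groups(groups_path)
    missing = [s for s in numeric.columns if s not in groups]
    if missing:
        raise ValidationError(
            f"sample(s) {missing} present in {matrix_path} but absent from {groups_path}"
        )
    groups = {s: groups[s] for s in numeric.columns}
    return ExpressionMatrix(values=numeric.astype(float), groups=groups)


def read_edge_list(path: str | Path, tf_path: str | Path | None = None) -> RegulatoryNetwork:
    """Read a two-column (mirna, gene) TSV edge list and optional TF list.

    Duplicate edges are dropped (count logged).  TF genes absent from the
    network are excluded with a warning, so ``tf_genes`` is always a subset
    of the network's genes.
    """
    edges: set[tuple[str, str]] = set()
    n_dup = 0
    for lineno, line in _data_lines(Path(path)):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValidationError(
                f"{path}:{lineno}: expected 2 columns (mirna, gene), got {len(fields)}"
            )
        edge = (normalize_mirna_id(fields[0]), normalize_gene_id(fields[1]))
        if edge in edges:
            n_dup += 1
        edges.add(edge)
    if not edges:
        raise ValidationError(f"{path}: empty network")
    if n_dup:
        log.warning("%s: dropped %d duplicate edge(s)", path, n_dup)

    tf_genes: set[str] = set()
    if tf_path is not None:
        genes = {g for _, g in edges}
        extra = []
        for lineno, line in _data_lines(Path(tf_path)):
            gid = normalize_gene_id(line.split("\t")[0])
            if gid in genes:
                tf_genes.add(gid)
            else:
                extra.append(gid)
        if extra:
            log.warning(
                "%s: %d TF gene(s) absent from the network were ignored", tf_path, len(extra)
            )
    return RegulatoryNetwork(edges=frozenset(edges), tf_genes=frozenset(tf_genes))


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read standard GMT (name TAB description TAB gene...)."""
    sets: dict[str, GeneSet] = {}
    for lineno, line in _data_lines(Path(path)):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"{path}:{lineno}: GMT line needs >=3 fields (name, description, genes)"
            )
        name = fields[0].strip()
        if name in sets:
            raise ValidationError(f"{path}:{lineno}: duplicate pathway name {name!r}")
        genes = frozenset(normalize_gene_id(g) for g in fields[2:] if g.strip())
        if not genes:
            raise ValidationError(f"{path}:{lineno}: gene set {name!r} is empty")
        sets[name] = GeneSet(name=name, description=fields[1].strip(), genes=genes)
    if not sets:
        raise ValidationError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets)


def read_reported_biomarkers(path: str | Path) -> ReportedBiomarkerList:
    """Read a literature-reported biomarker TSV.

    The first column is the miRNA ID; optional further columns are subtype,
    role (diagnostic/prognostic/both) and direction (up/down/mixed).  A
    header row is recognised by an ID column named ``mirna``/``id``.
    Unknown role/direction values default to ``"unknown"``.
    """
    records: list[BiomarkerRecord] = []
    for lineno, line in _data_lines(Path(path)):
        fields = [f.strip() for f in line.split("\t")]
        if fields[0].lower() in {"mirna", "mirna_id", "id", "miRNA".lower()} and not records:
            continue
        subtype = fields[1] if len(fields) > 1 and fields[1] else "unknown"
        role = fields[2].lower() if len(fields) > 2 and fields[2] else "unknown"
        direction = fields[3].lower() if len(fields) > 3 and fields[3] else "unknown"
        records.append(
            BiomarkerRecord(
                mirna_id=normalize_mirna_id(fields[0]),
                subtype=subtype,
                role=role if role in ROLES else "unknown",
                direction=direction if direction in DIRECTIONS else "unknown",
            )
        )
    if not records:
        raise ValidationError(f"{path}: empty reported-biomarker file")
    return ReportedBiomarkerList(records=records)


# ---------------------------------------------------------------------------
# writers (sorted output so identical objects give identical bytes)
# ---------------------------------------------------------------------------


def write_expression_matrix(expr: ExpressionMatrix, matrix_path: str | Path, groups_path: str | Path) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="mirna")
    with open(groups_path, "w", encoding="utf-8") as fh:
        fh.write("sample\tgroup\n")
        for s in expr.sample_ids:
            fh.write(f"{s}\t{expr.groups[s]}\n")


def write_edge_list(network: RegulatoryNetwork, path: str | Path, tf_path: str | Path | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m, g in sorted(network.edges):
            fh.write(f"{m}\t{g}\n")
    if tf_path is not None:
        with open(tf_path, "w", encoding="utf-8") as fh:
            for g in sorted(network.tf_genes):
                fh.write(f"{g}\n")


def write_gene_sets(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(sets.sets):
            gs = sets[name]
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{gs.description}\t{genes}\n")


def write_reported_biomarkers(reported: ReportedBiomarkerList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna\tsubtype\trole\tdirection\n")
        for r in reported.records:
            fh.write(f"{r.mirna_id}\t{r.subtype}\t{r.role}\t{r.direction}\n")
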