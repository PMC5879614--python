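"""Join the three ingested sources into one modeling row per gene.

Per-gene features: the curated expression-experiment count (the label ``y``),
the count of journal publications already attributed for expression
annotation (``E``), the total count of distinct journal publications (``J``),
the fraction of journal publications with expression data (``P = E/J``, 0
when ``J = 0``), the distinct transgenic-construct count (``C``), and the
gene symbol as a categorical feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, InputFileError, RecordValidationError
from .ingest import ConstructComponentLink, GenePublicationLink, GeneRecord

logger = logging.getLogger(__name__)

#: Publication-type value marking journal articles in ZFIN-style exports.
DEFAULT_JOURNAL_TYPES = frozenset({"Journal"})

FEATURE_TABLE_COLUMNS = (
    "gene_id",
    "symbol",
    "y",
    "expr_pub_count",
    "total_journal_pub_count",
    "percent_expr_pubs",
    "construct_count",
    "name",
    "go_annotation_count",
    "go_pub_count",
)


@dataclass(frozen=True)
class GeneFeatures:
    """Assembled modeling row for one gene.

    ``name`` and the GO counts are carried along only for filtering and
    optional feature re-testing; they are not part of the default model.
    """

    gene_id: str
    symbol: str
    y: int
    expr_pub_count: int
    total_journal_pub_count: int
    percent_expr_pubs: float
    construct_count: int
    name: str = ""
    go_annotation_count: int = 0
    go_pub_count: int = 0

    def __post_init__(self):
        if not 0.0 <= self.percent_expr_pubs <= 1.0:
            raise RecordValidationError(
                f"percent_expr_pubs {self.percent_expr_pubs} outside [0, 1] "
                f"for gene {self.gene_id!r}"
            )
        for field in ("y", "expr_pub_count", "total_journal_pub_count",
                      "construct_count"):
            if getattr(self, field) < 0:
                raise RecordValidationError(
                    f"{field} must be >= 0 for gene {self.gene_id!r}"
                )


def count_journal_pubs(
    links: Iterable[GenePublicationLink],
    journal_type_values: Iterable[str] = DEFAULT_JOURNAL_TYPES,
) -> dict[str, int]:
    """Count distinct journal publications per gene.

    A publication linked to the same gene more than once counts once; genes
    with no journal links are absent from the result (the join later turns
    absence into 0).
    """
    journal_types = frozenset(journal_type_values)
    if not journal_types:
        raise ConfigurationError("journal_type_values must be non-empty")
    pubs_per_gene: dict[str, set[str]] = {}
    for link in links:
        if link.pub_type in journal_types:
            pubs_per_gene.setdefault(link.gene_id, set()).add(link.pub_id)
    return {gene_id: len(pubs) for gene_id, pubs in pubs_per_gene.items()}


def count_constructs(links: Iterable[ConstructComponentLink]) -> dict[str, int]:
    """Count distinct constructs per gene from the components file.

    The components file has one row per component relationship, so the same
    construct may appear in several rows for one gene; it counts once.
    """
    constructs_per_gene: dict[str, set[str]] = {}
    for link in links:
        constructs_per_gene.setdefault(link.gene_id, set()).add(
            link.construct_id
        )
    return {gene_id: len(ids) for gene_id, ids in constructs_per_gene.items()}


def build_feature_table(
    genes: Sequence[GeneRecord],
    pub_counts: Mapping[str, int],
    construct_counts: Mapping[str, int],
) -> list[GeneFeatures]:
    """Assemble one feature row per gene record.

    Genes absent from a count mapping get 0 (the null-to-zero join rule).
    ``P = E/J`` with ``P = 0`` when ``J = 0``.  On real export data ``E`` can
    occasionally exceed ``J``; such rows are kept with ``P`` clamped to 1 and
    a data-quality warning.
    """
    rows: list[GeneFeatures] = []
    seen: set[str] = set()
    for record in genes:
        if record.gene_id in seen:
            raise RecordValidationError(
                f"duplicate gene_id {record.gene_id!r} in gene records"
            )
        seen.add(record.gene_id)
        expr_pubs = record.expression_pub_count
        journal_pubs = int(pub_counts.get(record.gene_id, 0))
        if journal_pubs == 0:
            percent = 0.0
        else:
            percent = expr_pubs / journal_pubs
        if percent > 1.0:
            logger.warning(
                "gene %s has more expression publications (%d) than journal "
                "publications (%d); keeping row with percent clamped to 1",
                record.gene_id,
                expr_pubs,
                journal_pubs,
            )
            percent = 1.0
        rows.append(
            GeneFeatures(
                gene_id=record.gene_id,
                symbol=record.symbol,
                y=record.expression_experiment_count,
                expr_pub_count=expr_pubs,
                total_journal_pub_count=journal_pubs,
                percent_expr_pubs=percent,
                construct_count=int(construct_counts.get(record.gene_id, 0)),
                name=record.name,
                go_annotation_count=record.go_annotation_count,
                go_pub_count=record.go_pub_count,
            )
        )
    return rows


def to_dataframe(table: Sequence[GeneFeatures]) -> pd.DataFrame:
    """Feature table as a DataFrame with the canonical column order."""
    return pd.DataFrame(
        [
            {col: getattr(row, col) for col in FEATURE_TABLE_COLUMNS}
            for row in table
        ],
        columns=list(FEATURE_TABLE_COLUMNS),
    )


def write_feature_table(table: Sequence[GeneFeatures], path) -> None:
    to_dataframe(table).to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> list[GeneFeatures]:
    try:
        frame = pd.read_csv(path, sep="\t", dtype={"symbol": str, "name": str},
                            keep_default_na=False)
    except OSError as exc:
        raise InputFileError(f"cannot read {path}: {exc}") from exc
    return [
        GeneFeatures(
            gene_id=row.gene_id,
            symbol=str(row.symbol),
            y=int(row.y),
            expr_pub_count=int(row.expr_pub_count),
            total_journal_pub_count=int(row.total_journal_pub_count),
            percent_expr_pubs=float(row.percent_expr_pubs),
            construct_count=int(row.construct_count),
            name=str(row.name),
            go_annotation_count=int(row.go_annotation_count),
            go_pub_count=int(row.go_pub_count),
        )
        for row in frame.itertuples(index=False)
    ]
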