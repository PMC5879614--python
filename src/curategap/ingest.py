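"""Readers and writers for the three ZFIN-style tab-separated export files.

Three dialects are supported, each one record per line:

* **gene report** — one row per gene with curated annotation counts
  (gene ID, symbol, name, expression-experiment count, expression-publication
  count, GO-annotation count, GO-publication count);
* **gene–publication links** — gene symbol, gene ID, publication ID,
  publication type, optional PubMed ID;
* **construct components** — construct ID/name/type, related gene ID, gene
  symbol, gene type, relationship, and two sequence-ontology term IDs.

All readers validate row shape and numeric fields, report errors with line
numbers, and tolerate (with a warning) extra trailing columns, because the
upstream export schemas evolve.  Writers emit exactly the canonical columns so
that ``write`` then ``read`` is the identity.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import InputFileError, RecordValidationError, TSVFormatError

logger = logging.getLogger(__name__)

GENE_ID_PATTERN = re.compile(r"^ZDB-GENE-")
PUB_ID_PATTERN = re.compile(r"^ZDB-PUB-(\d{6})-(\d+)$")

#: Canonical column headers for each dialect, in file order.
GENE_REPORT_COLUMNS = (
    "gene_id",
    "symbol",
    "name",
    "expression_experiment_count",
    "expression_pub_count",
    "go_annotation_count",
    "go_pub_count",
)
GENE_PUBLICATION_COLUMNS = (
    "gene_symbol",
    "gene_id",
    "pub_id",
    "pub_type",
    "pmid",
)
CONSTRUCT_COMPONENT_COLUMNS = (
    "construct_id",
    "construct_name",
    "construct_type",
    "gene_id",
    "gene_symbol",
    "gene_type",
    "relationship",
    "construct_so_term",
    "marker_so_term",
)


@dataclass(frozen=True)
class GeneRecord:
    """One row of the per-gene report.

    ``expression_experiment_count`` is the modeling label: the number of
    curated expression experiments recorded for the gene.
    """

    gene_id: str
    symbol: str
    name: str
    expression_experiment_count: int
    expression_pub_count: int
    go_annotation_count: int = 0
    go_pub_count: int = 0

    def __post_init__(self):
        if not self.gene_id:
            raise RecordValidationError("gene_id must be non-empty")
        for field in (
            "expression_experiment_count",
            "expression_pub_count",
            "go_annotation_count",
            "go_pub_count",
        ):
            if getattr(self, field) < 0:
                raise RecordValidationError(
                    f"{field} must be >= 0 for gene {self.gene_id!r}"
                )


@dataclass(frozen=True)
class GenePublicationLink:
    """One gene-to-publication association row."""

    gene_symbol: str
    gene_id: str
    pub_id: str
    pub_type: str
    pmid: Optional[str] = None

    def __post_init__(self):
        if not self.gene_id:
            raise RecordValidationError("gene_id must be non-empty")
        if not self.pub_id:
            raise RecordValidationError("pub_id must be non-empty")


@dataclass(frozen=True)
class ConstructComponentLink:
    """One construct-component relationship row."""

    construct_id: str
    construct_name: str
    construct_type: str
    gene_id: str
    gene_symbol: str
    gene_type: str
    relationship: str
    construct_so_term: str
    marker_so_term: str

    def __post_init__(self):
        if not self.construct_id:
            raise RecordValidationError("construct_id must be non-empty")
        if not self.gene_id:
            raise RecordValidationError("gene_id must be non-empty")


def _parse_count(value: str, column: str, path, line_number: int) -> int:
    """Parse a numeric field; blank parses as 0 per the null-to-zero rule."""
    text = value.strip()
    if text == "":
        return 0
    try:
        number = int(float(text)) if "." in text else int(text)
    except ValueError:
        raise TSVFormatError(
            f"non-numeric value {value!r} in column {column!r}",
            path=path,
            line_number=line_number,
        ) from None
    if number < 0:
        raise RecordValidationError(
            f"{path}: line {line_number}: negative count {number} "
            f"in column {column!r}"
        )
    return number


def _iter_rows(path, n_columns: int, header: bool):
    """Yield (line_number, row) for each data row, padded/validated to shape."""
    path = Path(path)
    try:
        handle = path.open("r", encoding="utf-8", newline="")
    except OSError as exc:
        raise InputFileError(f"cannot read {path}: {exc}") from exc
    with handle:
        reader = csv.reader(handle, delimiter="\t", quoting=csv.QUOTE_NONE)
        warned_extra = False
        for line_number, row in enumerate(reader, start=1):
            if header and line_number == 1:
                continue
            if not row or all(field.strip() == "" for field in row):
                continue
            if len(row) > n_columns:
                if not warned_extra:
                    logger.warning(
                        "%s: line %d has %d columns, expected %d; "
                        "ignoring extras",
                        path,
                        line_number,
                        len(row),
                        n_columns,
                    )
                    warned_extra = True
                row = row[:n_columns]
            elif len(row) < n_columns:
                # Trailing optional columns may be omitted entirely.
                row = row + [""] * (n_columns - len(row))
            yield line_number, row


def read_gene_report(path, *, header: bool = True) -> list[GeneRecord]:
    """Read a per-gene report file into :class:`GeneRecord` objects.

    Blank numeric fields parse as 0.  Raises :class:`TSVFormatError` with the
    offending line number on malformed rows and
    :class:`RecordValidationError` on negative counts or duplicate gene IDs.
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for line_number, row in _iter_rows(path, len(GENE_REPORT_COLUMNS), header):
        gene_id, symbol, name = (field.strip() for field in row[:3])
        if not gene_id:
            raise TSVFormatError(
                "empty gene_id", path=path, line_number=line_number
            )
        if gene_id in seen:
            raise RecordValidationError(
                f"{path}: line {line_number}: duplicate gene_id {gene_id!r}"
            )
        seen.add(gene_id)
        counts = [
            _parse_count(row[i], GENE_REPORT_COLUMNS[i], path, line_number)
            for i in range(3, 7)
        ]
        records.append(GeneRecord(gene_id, symbol, name, *counts))
    return records


def read_gene_publications(path, *, header: bool = True) -> list[GenePublicationLink]:
    """Read a gene–publication link file.

    A missing PubMed ID becomes ``None``; publication types are preserved
    verbatim.
    """
    links: list[GenePublicationLink] = []
    for line_number, row in _iter_rows(
        path, len(GENE_PUBLICATION_COLUMNS), header
    ):
        gene_symbol, gene_id, pub_id, pub_type, pmid = (
            field.strip() for field in row
        )
        if not gene_id or not pub_id:
            raise TSVFormatError(
                "empty gene_id or pub_id", path=path, line_number=line_number
            )
        links.append(
            GenePublicationLink(
                gene_symbol=gene_symbol,
                gene_id=gene_id,
                pub_id=pub_id,
                pub_type=pub_type,
                pmid=pmid or None,
            )
        )
    return links


def read_construct_components(
    path, *, header: bool = True
) -> list[ConstructComponentLink]:
    """Read a construct-components file.

    Rows are returned as-is: a construct listed twice for one gene yields two
    links.  De-duplication happens downstream when constructs are counted.
    """
    links: list[ConstructComponentLink] = []
    for line_number, row in _iter_rows(
        path, len(CONSTRUCT_COMPONENT_COLUMNS), header
    ):
        values = [field.strip() for field in row]
        if not values[0] or not values[3]:
            raise TSVFormatError(
                "empty construct_id or gene_id",
                path=path,
                line_number=line_number,
            )
        links.append(ConstructComponentLink(*values))
    return links


def _write_tsv(path, columns: Sequence[str], rows: Iterable[Sequence[str]], header: bool):
    path = Path(path)
    try:
        handle = path.open("w", encoding="utf-8", newline="")
    except OSError as exc:
        raise InputFileError(f"cannot write {path}: {exc}") from exc
    with handle:
        if header:
            handle.write("\t".join(columns) + "\n")
        for row in rows:
            for field in row:
                if "\t" in field or "\n" in field:
                    raise RecordValidationError(
                        f"field {field!r} contains a tab or newline; "
                        "not representable in this dialect"
                    )
            handle.write("\t".join(row) + "\n")


def write_gene_report(records: Sequence[GeneRecord], path, *, header: bool = True) -> None:
    """Write gene records in the per-gene report dialect (lossless round-trip)."""
    _write_tsv(
        path,
        GENE_REPORT_COLUMNS,
        (
            (
                r.gene_id,
                r.symbol,
                r.name,
                str(r.expression_experiment_count),
                str(r.expression_pub_count),
                str(r.go_annotation_count),
                str(r.go_pub_count),
            )
            for r in records
        ),
        header,
    )


def write_gene_publications(
    links: Sequence[GenePublicationLink], path, *, header: bool = True
) -> None:
    """Write gene–publication links; ``pmid=None`` becomes an empty field."""
    _write_tsv(
        path,
        GENE_PUBLICATION_COLUMNS,
        (
            (l.gene_symbol, l.gene_id, l.pub_id, l.pub_type, l.pmid or "")
            for l in links
        ),
        header,
    )


def write_construct_components(
    links: Sequence[ConstructComponentLink], path, *, header: bool = True
) -> None:
    """Write construct-component links in file order."""
    _write_tsv(
        path,
        CONSTRUCT_COMPONENT_COLUMNS,
        (
            tuple(getattr(l, f.name) for f in fields(ConstructComponentLink))
            for l in links
        ),
        header,
    )
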