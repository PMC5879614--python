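"""Blinded validation sampling, confusion-matrix scoring, and ID-date parsing.

The manual step — reading publications to decide whether a gene really has
uncurated expression data — is human work.  This module draws the blinded
per-stratum samples, round-trips curator worksheets as TSV, scores the
resulting truth against the model's calls per side of the confidence band,
and parses record-entry dates out of ``ZDB-PUB-YYMMDD-N`` identifiers.
"""

from __future__ import annotations

import csv
import datetime
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import CurategapError, InputFileError, RecordValidationError
from .gap_calling import FLAG_LOWER, FLAG_NONE, FLAG_UPPER, GapReport
from .ingest import PUB_ID_PATTERN

STRATA = ("lower_outside", "lower_inside", "upper_outside", "upper_inside")


@dataclass(frozen=True)
class ValidationSample:
    gene_id: str
    stratum: str
    blinded_index: int


@dataclass(frozen=True)
class ValidationResult:
    """Curator verdict for one gene."""

    gene_id: str
    found_missing: bool
    first_missing_pub_id: Optional[str] = None
    assessment_date: Optional[datetime.date] = None

    def __post_init__(self):
        if self.first_missing_pub_id and not self.found_missing:
            raise RecordValidationError(
                f"gene {self.gene_id}: a first_missing_pub_id requires "
                "found_missing=True"
            )


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> Optional[float]:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None

    @property
    def recall(self) -> Optional[float]:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "precision": self.precision, "recall": self.recall,
        }


def _stratum_of(call) -> Optional[str]:
    if call.flag == FLAG_LOWER:
        return "lower_outside"
    if call.flag == FLAG_UPPER:
        return "upper_outside"
    if call.residual < 0:
        return "lower_inside"
    if call.residual > 0:
        return "upper_inside"
    return None  # residual exactly 0: neither side


def sample_for_validation(
    report: GapReport,
    n_per_stratum: Mapping[str, int],
    seed: int = 0,
) -> list[ValidationSample]:
    """Draw blinded validation samples per stratum.

    Genes are selected uniformly without replacement within each stratum
    (lower/upper crossed with inside/outside the band); the combined list is
    then re-shuffled so that the blinded order carries no stratum signal.
    Fully reproducible under ``seed``.
    """
    unknown = set(n_per_stratum) - set(STRATA)
    if unknown:
        raise CurategapError(f"unknown strata requested: {sorted(unknown)}")
    pools: dict[str, list[str]] = {s: [] for s in STRATA}
    for call in report.calls:
        if call.gene_id is None:
            raise CurategapError("cannot sample from calls without gene_ids")
        stratum = _stratum_of(call)
        if stratum is not None:
            pools[stratum].append(call.gene_id)

    rng = np.random.default_rng(seed)
    chosen: list[ValidationSample] = []
    for stratum in STRATA:
        n_requested = int(n_per_stratum.get(stratum, 0))
        if n_requested == 0:
            continue
        pool = pools[stratum]
        if n_requested > len(pool):
            raise CurategapError(
                f"stratum {stratum!r} has only {len(pool)} genes; "
                f"{n_requested} requested"
            )
        picks = rng.choice(len(pool), size=n_requested, replace=False)
        chosen.extend(
            ValidationSample(gene_id=pool[i], stratum=stratum, blinded_index=0)
            for i in picks
        )
    order = rng.permutation(len(chosen))
    return [
        ValidationSample(
            gene_id=chosen[i].gene_id,
            stratum=chosen[i].stratum,
            blinded_index=rank,
        )
        for rank, i in enumerate(order)
    ]


def score_calls(
    report: GapReport,
    truth: Iterable[ValidationResult],
) -> dict[str, ConfusionMatrix]:
    """Tally a confusion matrix per side (lower, upper) of the band.

    Prediction-positive means flagged (outside the interval); condition-
    positive means the curator found missing data.  Genes with residual
    exactly 0 cannot be attributed to a side and are rejected.
    """
    call_by_gene = {c.gene_id: c for c in report.calls if c.gene_id}
    cells = {
        "lower": {"tp": 0, "fp": 0, "fn": 0, "tn": 0},
        "upper": {"tp": 0, "fp": 0, "fn": 0, "tn": 0},
    }
    for result in truth:
        call = call_by_gene.get(result.gene_id)
        if call is None:
            raise CurategapError(
                f"validation result for unknown gene {result.gene_id!r}"
            )
        stratum = _stratum_of(call)
        if stratum is None:
            raise CurategapError(
                f"gene {result.gene_id!r} has residual 0; no side to score"
            )
        side = "lower" if stratum.startswith("lower") else "upper"
        predicted_positive = call.flag != FLAG_NONE
        if predicted_positive and result.found_missing:
            cells[side]["tp"] += 1
        elif predicted_positive:
            cells[side]["fp"] += 1
        elif result.found_missing:
            cells[side]["fn"] += 1
        else:
            cells[side]["tn"] += 1
    return {side: ConfusionMatrix(**counts) for side, counts in cells.items()}


def parse_pub_entry_date(pub_id: str, century_pivot: int = 50) -> tuple[int, int, int]:
    """Record-entry date encoded in a ``ZDB-PUB-YYMMDD-N`` identifier.

    Two-digit years at or above ``century_pivot`` map to the 1900s, below it
    to the 2000s.  The full date is validated (so Feb 30 is rejected, not
    just month 13).
    """
    match = PUB_ID_PATTERN.match(pub_id)
    if not match:
        raise RecordValidationError(
            f"publication ID {pub_id!r} does not match ZDB-PUB-YYMMDD-N"
        )
    digits = match.group(1)
    yy, month, day = int(digits[:2]), int(digits[2:4]), int(digits[4:6])
    year = 1900 + yy if yy >= century_pivot else 2000 + yy
    try:
        datetime.date(year, month, day)
    except ValueError as exc:
        raise RecordValidationError(
            f"publication ID {pub_id!r} encodes an invalid date: {exc}"
        ) from exc
    return year, month, day


def earliest_uncurated_by_year(
    results: Iterable[ValidationResult],
    century_pivot: int = 50,
) -> dict[int, int]:
    """Count genes by the entry year of their first uncurated publication.

    Each gene contributes once (its single recorded first-missing
    publication), so counts sum to the number of found-missing genes with a
    recorded publication ID.
    """
    counts: dict[int, int] = {}
    for result in results:
        if result.found_missing and result.first_missing_pub_id:
            year, _, _ = parse_pub_entry_date(
                result.first_missing_pub_id, century_pivot
            )
            counts[year] = counts.get(year, 0) + 1
    return dict(sorted(counts.items()))


WORKSHEET_COLUMNS = (
    "gene_id",
    "blinded_index",
    "found_missing",
    "first_missing_pub_id",
    "assessment_date",
)


def write_validation_worksheet(samples: Sequence[ValidationSample], path) -> None:
    """Blank worksheet for curators, one blinded row per sampled gene.

    The stratum column is deliberately omitted to preserve blinding.
    """
    ordered = sorted(samples, key=lambda s: s.blinded_index)
    try:
        handle = open(path, "w", encoding="utf-8", newline="")
    except OSError as exc:
        raise InputFileError(f"cannot write {path}: {exc}") from exc
    with handle:
        handle.write("\t".join(WORKSHEET_COLUMNS) + "\n")
        for sample in ordered:
            handle.write(f"{sample.gene_id}\t{sample.blinded_index}\t\t\t\n")


def read_validation_worksheet(path) -> list[ValidationResult]:
    """Parse a filled-in worksheet back into validation results."""
    try:
        handle = open(path, "r", encoding="utf-8", newline="")
    except OSError as exc:
        raise InputFileError(f"cannot read {path}: {exc}") from exc
    results: list[ValidationResult] = []
    with handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            raw = (row.get("found_missing") or "").strip().lower()
            if raw in ("", "na"):
                continue  # not yet assessed
            if raw not in ("true", "false", "yes", "no", "1", "0"):
                raise RecordValidationError(
                    f"unrecognized found_missing value {raw!r} for gene "
                    f"{row.get('gene_id')!r}"
                )
            found = raw in ("true", "yes", "1")
            date_text = (row.get("assessment_date") or "").strip()
            results.append(
                ValidationResult(
                    gene_id=(row.get("gene_id") or "").strip(),
                    found_missing=found,
                    first_missing_pub_id=(
                        (row.get("first_missing_pub_id") or "").strip() or None
                    ),
                    assessment_date=(
                        datetime.date.fromisoformat(date_text)
                        if date_text
                        else None
                    ),
                )
            )
    return results
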