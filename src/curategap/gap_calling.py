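"""Residuals, the 2x-RMSE confidence band, and per-gene incompleteness calls.

A gene whose residual ``r = y - y_hat`` falls strictly outside the interval
``[-ci, +ci]`` with ``ci = ci_multiplier * rmse`` (default multiplier 2,
approximating a 95% band) is flagged: ``lower`` when the database holds fewer
experiments than predicted — the signature of published-but-uncurated data —
and ``upper`` when it holds more.  ``|r|`` is reported as the predicted
missing (or surplus) magnitude for flagged genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import CurategapError

FLAG_NONE = "none"
FLAG_LOWER = "lower"
FLAG_UPPER = "upper"


@dataclass(frozen=True)
class GapCall:
    gene_id: Optional[str]
    y: float
    y_hat: float
    residual: float
    flag: str
    predicted_missing: float


@dataclass
class GapReport:
    """All calls for one scored gene set, with the interval that produced them."""

    rmse: float
    ci_multiplier: float
    ci: float
    calls: list[GapCall] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        tally = {FLAG_NONE: 0, FLAG_LOWER: 0, FLAG_UPPER: 0}
        for call in self.calls:
            tally[call.flag] += 1
        return tally

    def flagged(self, flag: str) -> list[GapCall]:
        return [c for c in self.calls if c.flag == flag]

    def summary(self) -> dict:
        return {
            "rmse": self.rmse,
            "ci_multiplier": self.ci_multiplier,
            "ci": self.ci,
            "n_calls": len(self.calls),
            "counts": self.counts,
        }


def compute_residuals(y, y_hat) -> np.ndarray:
    """Elementwise actual-minus-predicted."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise CurategapError(
            f"length mismatch: {y.shape[0]} actuals vs {y_hat.shape[0]} "
            "predictions"
        )
    return y - y_hat


def call_gaps(
    residuals,
    rmse: float,
    ci_multiplier: float = 2.0,
    *,
    gene_ids: Optional[Sequence[str]] = None,
    y=None,
    y_hat=None,
) -> GapReport:
    """Flag residuals strictly outside ``ci_multiplier * rmse``.

    A residual exactly on the boundary is NOT flagged (the band is closed).
    ``gene_ids``, ``y`` and ``y_hat`` are optional annotations carried into
    the calls.
    """
    if rmse <= 0:
        raise CurategapError("rmse must be > 0 to define a confidence interval")
    residuals = np.asarray(residuals, dtype=float).ravel()
    n = residuals.shape[0]
    if gene_ids is not None and len(gene_ids) != n:
        raise CurategapError("gene_ids length does not match residuals")
    y = np.full(n, np.nan) if y is None else np.asarray(y, dtype=float).ravel()
    y_hat = (
        np.full(n, np.nan) if y_hat is None
        else np.asarray(y_hat, dtype=float).ravel()
    )
    if y.shape[0] != n or y_hat.shape[0] != n:
        raise CurategapError("y / y_hat length does not match residuals")

    ci = ci_multiplier * rmse
    report = GapReport(rmse=float(rmse), ci_multiplier=float(ci_multiplier),
                       ci=float(ci))
    for i, r in enumerate(residuals):
        if r < -ci:
            flag = FLAG_LOWER
        elif r > ci:
            flag = FLAG_UPPER
        else:
            flag = FLAG_NONE
        report.calls.append(
            GapCall(
                gene_id=None if gene_ids is None else gene_ids[i],
                y=float(y[i]),
                y_hat=float(y_hat[i]),
                residual=float(r),
                flag=flag,
                predicted_missing=abs(float(r)) if flag != FLAG_NONE else 0.0,
            )
        )
    return report


def residual_histogram(
    residuals,
    bin_width: float,
    ci: Optional[float] = None,
) -> list[tuple[float, float, int, bool]]:
    """Half-open histogram bins ``[lo, hi)`` aligned to multiples of the width.

    Each bin is annotated with whether it lies entirely inside ``[-ci, +ci]``
    (always True when no interval is given).  Counts conserve the input size.
    """
    if bin_width <= 0:
        raise CurategapError("bin_width must be > 0")
    residuals = np.asarray(residuals, dtype=float).ravel()
    if residuals.size == 0:
        return []
    lo_edge = math.floor(residuals.min() / bin_width)
    hi_edge = math.floor(residuals.max() / bin_width) + 1
    bins: list[tuple[float, float, int, bool]] = []
    for k in range(lo_edge, hi_edge):
        lo, hi = k * bin_width, (k + 1) * bin_width
        count = int(np.sum((residuals >= lo) & (residuals < hi)))
        inside = True if ci is None else (lo >= -ci and hi <= ci)
        bins.append((lo, hi, count, inside))
    return bins


def write_calls(report: GapReport, path) -> None:
    """Every call (flagged or not) as TSV, in call order."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("gene_id\ty\ty_hat\tresidual\tflag\tpredicted_missing\n")
        for c in report.calls:
            handle.write(
                f"{c.gene_id or ''}\t{c.y!r}\t{c.y_hat!r}\t{c.residual!r}\t"
                f"{c.flag}\t{c.predicted_missing!r}\n"
            )


def read_calls(path, rmse: float, ci_multiplier: float = 2.0) -> GapReport:
    """Rebuild a :class:`GapReport` from a calls TSV plus its interval."""
    report = GapReport(
        rmse=float(rmse),
        ci_multiplier=float(ci_multiplier),
        ci=float(ci_multiplier) * float(rmse),
    )
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline()
        if not header.startswith("gene_id\t"):
            raise CurategapError(f"{path} is not a calls TSV")
        for line in handle:
            gene_id, y, y_hat, residual, flag, missing = (
                line.rstrip("\n").split("\t")
            )
            report.calls.append(
                GapCall(
                    gene_id=gene_id or None,
                    y=float(y),
                    y_hat=float(y_hat),
                    residual=float(residual),
                    flag=flag,
                    predicted_missing=float(missing),
                )
            )
    return report


def write_gap_report(report: GapReport, path) -> None:
    """Flagged genes as TSV, sorted by |residual| descending."""
    flagged = [c for c in report.calls if c.flag != FLAG_NONE]
    flagged.sort(key=lambda c: abs(c.residual), reverse=True)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(
            "gene_id\ty\ty_hat\tresidual\tflag\tpredicted_missing\n"
        )
        for c in flagged:
            handle.write(
                f"{c.gene_id or ''}\t{c.y:.6g}\t{c.y_hat:.6g}\t"
                f"{c.residual:.6g}\t{c.flag}\t{c.predicted_missing:.6g}\n"
            )
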