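"""Exclusion rules that reduce the full gene set to the modeling set.

Genes are dropped when they are withdrawn, are microRNA genes, carry a colon
in the symbol or name (unstudied-gene nomenclature), have a symbol starting
with ``unm_``, have no associated journal publications, or already have more
than a configurable number of curated expression experiments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .errors import ConfigurationError
from .feature_table import GeneFeatures

#: Rule names in fixed evaluation order (first match wins tally attribution).
RULE_ORDER = (
    "withdrawn",
    "mirna",
    "colon",
    "unm_prefix",
    "no_journal_pubs",
    "too_many_experiments",
)


@dataclass(frozen=True)
class FilterConfig:
    """Switches and parameters for the exclusion rules.

    ``max_expression_experiments`` is a strict cap: a gene with exactly that
    many experiments is retained ("more than" semantics).
    """

    exclude_withdrawn: bool = True
    exclude_mirna: bool = True
    exclude_colon: bool = True
    exclude_unm_prefix: bool = True
    require_journal_pubs: bool = True
    max_expression_experiments: int = 200
    mirna_symbol_patterns: tuple[str, ...] = (r"^mir",)
    withdrawn_markers: tuple[str, ...] = ("WITHDRAWN",)

    def __post_init__(self):
        if self.max_expression_experiments <= 0:
            raise ConfigurationError(
                "max_expression_experiments must be > 0"
            )

    @classmethod
    def disabled(cls) -> "FilterConfig":
        """A configuration with every rule switched off."""
        return cls(
            exclude_withdrawn=False,
            exclude_mirna=False,
            exclude_colon=False,
            exclude_unm_prefix=False,
            require_journal_pubs=False,
            max_expression_experiments=2**31,
        )


@dataclass
class FilterTally:
    """Audit trail: how many genes each rule excluded, and how many remain.

    Exclusions are attributed to the first matching rule in
    :data:`RULE_ORDER`, so ``retained + sum(excluded) == input`` exactly.
    """

    input_count: int = 0
    retained_count: int = 0
    excluded: dict[str, int] = field(
        default_factory=lambda: {rule: 0 for rule in RULE_ORDER}
    )

    def as_dict(self) -> dict:
        return {
            "input": self.input_count,
            "retained": self.retained_count,
            "excluded": dict(self.excluded),
        }


def _matching_rule(gene: GeneFeatures, config: FilterConfig) -> str | None:
    """Name of the first enabled rule the gene violates, or None."""
    if config.exclude_withdrawn:
        for marker in config.withdrawn_markers:
            if marker in gene.symbol or marker in gene.name:
                return "withdrawn"
    if config.exclude_mirna:
        for pattern in config.mirna_symbol_patterns:
            if re.search(pattern, gene.symbol):
                return "mirna"
    if config.exclude_colon and (":" in gene.symbol or ":" in gene.name):
        return "colon"
    if config.exclude_unm_prefix and gene.symbol.startswith("unm_"):
        return "unm_prefix"
    if config.require_journal_pubs and gene.total_journal_pub_count == 0:
        return "no_journal_pubs"
    if gene.y > config.max_expression_experiments:
        return "too_many_experiments"
    return None


def apply_exclusion_filters(
    table: Sequence[GeneFeatures],
    config: FilterConfig | None = None,
) -> tuple[list[GeneFeatures], FilterTally]:
    """Drop genes matching any enabled rule; tally exclusions per rule.

    Removal is order-independent (a gene is dropped if ANY rule matches);
    only the tally attribution depends on :data:`RULE_ORDER`.
    """
    if config is None:
        config = FilterConfig()
    tally = FilterTally(input_count=len(table))
    retained: list[GeneFeatures] = []
    for gene in table:
        rule = _matching_rule(gene, config)
        if rule is None:
            retained.append(gene)
        else:
            tally.excluded[rule] += 1
    tally.retained_count = len(retained)
    return retained, tally
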