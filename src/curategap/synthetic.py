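"""Generate export-dialect datasets with known ground-truth curation gaps.

The generator mimics a literature-curated database: every publication about a
gene is linked to it, but only a (configurable) fraction of the
expression-bearing publications have had their experiments curated.  The gap
between published and curated experiments per gene is the ground truth the
pipeline is later asked to recover.

Per gene the process is:

1. draw a journal-publication count from a negative binomial (heavy-tailed,
   like real per-gene literature counts);
2. flag each publication as expression-bearing with probability
   ``p_expression``; expression pubs draw a positive experiment count;
3. curate each expression pub independently with probability
   ``curation_coverage`` — curated pubs contribute their experiments to the
   observed label ``y`` and count toward the expression-publication feature;
4. a fraction of genes carry transgenic constructs, each of which attracts
   additional expression-free publications (the confounder the
   construct-count feature corrects for);
5. symbols are unique, with configurable fractions styled as colon-bearing,
   ``unm_``-prefixed, microRNA-like, or withdrawn so every filter rule has
   work to do.

``inject_gaps`` adds uncurated expression publications to chosen genes after
the fact, for targeted recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, CurategapError
from .ingest import (
    ConstructComponentLink,
    GenePublicationLink,
    GeneRecord,
    write_construct_components,
    write_gene_publications,
    write_gene_report,
)

JOURNAL_TYPE = "Journal"
NON_JOURNAL_TYPE = "Curation Note"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative process; all randomness flows from ``seed``."""

    n_genes: int = 1000
    seed: int = 0
    # journal publications per gene ~ NegBin(mean, dispersion)
    pub_mean: float = 8.0
    pub_dispersion: float = 2.0
    # probability a journal pub contains expression data for its gene
    p_expression: float = 0.6
    # experiments per expression pub ~ 1 + Poisson(mean - 1); mean >= 1
    experiments_mean: float = 2.0
    # fraction of expression pubs that are curated
    curation_coverage: float = 0.8
    # constructs
    construct_gene_fraction: float = 0.1
    construct_mean: float = 2.0
    extra_pubs_per_construct: float = 1.0
    # when True each construct attracts exactly round(extra_pubs_per_construct)
    # publications instead of a Poisson draw, making the confound exactly
    # linear in the construct count
    extra_pubs_deterministic: bool = False
    # non-journal publications per gene ~ Poisson(rate)
    non_journal_rate: float = 0.3
    # symbol-style fractions (remainder are ordinary symbols)
    colon_fraction: float = 0.05
    unm_fraction: float = 0.02
    mirna_fraction: float = 0.03
    withdrawn_fraction: float = 0.02

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        for name in ("p_expression", "curation_coverage",
                     "construct_gene_fraction", "colon_fraction",
                     "unm_fraction", "mirna_fraction", "withdrawn_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        style_total = (self.colon_fraction + self.unm_fraction
                       + self.mirna_fraction + self.withdrawn_fraction)
        if style_total > 1.0:
            raise ConfigurationError("symbol-style fractions sum above 1")
        if self.pub_mean < 0 or self.pub_dispersion <= 0:
            raise ConfigurationError("pub_mean >= 0 and pub_dispersion > 0 required")
        if self.experiments_mean < 1:
            raise ConfigurationError("experiments_mean must be >= 1")
        for name in ("construct_mean", "extra_pubs_per_construct",
                     "non_journal_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GeneTruth:
    """Published-vs-curated bookkeeping for one simulated gene."""

    gene_id: str
    total_experiments: int
    curated_experiments: int

    @property
    def true_missing(self) -> int:
        return self.total_experiments - self.curated_experiments

    @property
    def is_gap_gene(self) -> bool:
        return self.true_missing > 0

    def __post_init__(self):
        if not 0 <= self.curated_experiments <= self.total_experiments:
            raise CurategapError(
                f"gene {self.gene_id}: curated count outside [0, total]"
            )


@dataclass
class SyntheticDataset:
    """The three emitted files plus ground truth, as in-memory records."""

    config: SimulationConfig
    gene_records: list[GeneRecord]
    pub_links: list[GenePublicationLink]
    construct_links: list[ConstructComponentLink]
    truth: dict[str, GeneTruth]
    _next_pub_serial: int = 0

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_gene_report(self.gene_records, out_dir / "MachineLearningReport.txt")
        write_gene_publications(self.pub_links, out_dir / "GenePublication.txt")
        write_construct_components(
            self.construct_links, out_dir / "ConstructComponents.txt"
        )
        with open(out_dir / "ground_truth.tsv", "w", encoding="utf-8") as fh:
            fh.write(
                "gene_id\ttotal_experiments\tcurated_experiments\t"
                "true_missing\tis_gap_gene\n"
            )
            for truth in self.truth.values():
                fh.write(
                    f"{truth.gene_id}\t{truth.total_experiments}\t"
                    f"{truth.curated_experiments}\t{truth.true_missing}\t"
                    f"{str(truth.is_gap_gene).lower()}\n"
                )


def _negative_binomial(rng, mean: float, dispersion: float, size: int):
    """NB parameterized by mean and dispersion k (variance = m + m^2/k)."""
    if mean == 0:
        return np.zeros(size, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _positive_count(rng, mean: float, size: int):
    """1 + Poisson(mean - 1): positive integers with the requested mean."""
    return 1 + rng.poisson(mean - 1.0, size=size)


def _pub_id(serial: int, rng) -> str:
    year = int(rng.integers(96, 117)) % 100  # entry years 1996..2016
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 29))
    return f"ZDB-PUB-{year:02d}{month:02d}{day:02d}-{serial}"


def _make_symbol(index: int, style: str) -> tuple[str, str]:
    """(symbol, name) for a gene; unique per index, styled per filter rule."""
    if style == "colon":
        return f"si:ch211-{index}g", f"si:ch211-{index}g"
    if style == "unm":
        return f"unm_s{index}", f"unnamed {index}"
    if style == "mirna":
        return f"mir{index}", f"microRNA {index}"
    if style == "withdrawn":
        return f"wg{index}aa", f"WITHDRAWN:gene {index}"
    return f"g{index}aa", f"gene {index} name"


def simulate_curated_database(config: SimulationConfig) -> SyntheticDataset:
    """Run the generative process; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    styles = np.array(["plain"] * n, dtype=object)
    style_probs = [
        ("colon", config.colon_fraction),
        ("unm", config.unm_fraction),
        ("mirna", config.mirna_fraction),
        ("withdrawn", config.withdrawn_fraction),
    ]
    draw = rng.random(n)
    cumulative = 0.0
    for style, fraction in style_probs:
        styles[(draw >= cumulative) & (draw < cumulative + fraction)] = style
        cumulative += fraction

    pub_counts = _negative_binomial(rng, config.pub_mean,
                                    config.pub_dispersion, n)
    has_construct = rng.random(n) < config.construct_gene_fraction

    gene_records: list[GeneRecord] = []
    pub_links: list[GenePublicationLink] = []
    construct_links: list[ConstructComponentLink] = []
    truth: dict[str, GeneTruth] = {}
    pub_serial = 1
    construct_serial = 1

    for i in range(n):
        gene_id = f"ZDB-GENE-{30101 + (i % 28):06d}-{i + 1}"
        symbol, name = _make_symbol(i + 1, styles[i])

        total_experiments = 0
        curated_experiments = 0
        curated_expr_pubs = 0
        n_journal = int(pub_counts[i])

        def link(pub_type: str) -> str:
            nonlocal pub_serial
            pub_id = _pub_id(pub_serial, rng)
            pub_serial += 1
            pmid = str(int(rng.integers(10_000_000, 30_000_000)))
            pub_links.append(
                GenePublicationLink(
                    gene_symbol=symbol,
                    gene_id=gene_id,
                    pub_id=pub_id,
                    pub_type=pub_type,
                    pmid=pmid if rng.random() < 0.9 else None,
                )
            )
            return pub_id

        for _ in range(n_journal):
            link(JOURNAL_TYPE)
            if rng.random() < config.p_expression:
                experiments = int(_positive_count(rng, config.experiments_mean, 1)[0])
                total_experiments += experiments
                if rng.random() < config.curation_coverage:
                    curated_experiments += experiments
                    curated_expr_pubs += 1

        for _ in range(int(rng.poisson(config.non_journal_rate))):
            link(NON_JOURNAL_TYPE)

        if has_construct[i] and config.construct_mean >= 1:
            n_constructs = int(_positive_count(rng, config.construct_mean, 1)[0])
            for _ in range(n_constructs):
                construct_id = f"ZDB-TGCONSTRCT-{150101:06d}-{construct_serial}"
                construct_serial += 1
                construct_links.append(
                    ConstructComponentLink(
                        construct_id=construct_id,
                        construct_name=f"Tg({symbol}:EGFP)",
                        construct_type="TGCONSTRCT",
                        gene_id=gene_id,
                        gene_symbol=symbol,
                        gene_type="protein_coding_gene",
                        relationship="promoter of",
                        construct_so_term="SO:0000902",
                        marker_so_term="SO:0000704",
                    )
                )
                # construct publications mention the gene but carry no
                # expression data for it
                n_extra = (
                    int(round(config.extra_pubs_per_construct))
                    if config.extra_pubs_deterministic
                    else int(rng.poisson(config.extra_pubs_per_construct))
                )
                for _ in range(n_extra):
                    link(JOURNAL_TYPE)

        gene_records.append(
            GeneRecord(
                gene_id=gene_id,
                symbol=symbol,
                name=name,
                expression_experiment_count=curated_experiments,
                expression_pub_count=curated_expr_pubs,
                go_annotation_count=int(rng.poisson(0.5)),
                go_pub_count=int(rng.poisson(0.3)),
            )
        )
        truth[gene_id] = GeneTruth(
            gene_id=gene_id,
            total_experiments=total_experiments,
            curated_experiments=curated_experiments,
        )

    return SyntheticDataset(
        config=config,
        gene_records=gene_records,
        pub_links=pub_links,
        construct_links=construct_links,
        truth=truth,
        _next_pub_serial=pub_serial,
    )


def inject_gaps(
    dataset: SyntheticDataset,
    gene_ids: Sequence[str],
    n_uncurated_pubs: int,
    experiments_per_pub: int = 2,
    seed: int = 0,
) -> SyntheticDataset:
    """Attach uncurated expression publications to the given genes.

    Each target gene gains ``n_uncurated_pubs`` journal publications that
    carry ``experiments_per_pub`` published-but-uncurated experiments: the
    journal-publication feature rises while the label and the
    expression-publication feature stay fixed, and ground truth gains the
    missing experiments.  Returns a new dataset; the input is untouched.
    """
    if n_uncurated_pubs < 0 or experiments_per_pub < 0:
        raise ConfigurationError("injection counts must be >= 0")
    known = {r.gene_id: r for r in dataset.gene_records}
    for gene_id in gene_ids:
        if gene_id not in known:
            raise CurategapError(f"unknown gene {gene_id!r} for injection")

    rng = np.random.default_rng(seed)
    new_links = list(dataset.pub_links)
    new_truth = dict(dataset.truth)
    serial = dataset._next_pub_serial
    for gene_id in gene_ids:
        record = known[gene_id]
        for _ in range(n_uncurated_pubs):
            new_links.append(
                GenePublicationLink(
                    gene_symbol=record.symbol,
                    gene_id=gene_id,
                    pub_id=_pub_id(serial, rng),
                    pub_type=JOURNAL_TYPE,
                    pmid=str(int(rng.integers(10_000_000, 30_000_000))),
                )
            )
            serial += 1
        old = new_truth[gene_id]
        new_truth[gene_id] = GeneTruth(
            gene_id=gene_id,
            total_experiments=(
                old.total_experiments + n_uncurated_pubs * experiments_per_pub
            ),
            curated_experiments=old.curated_experiments,
        )
    return SyntheticDataset(
        config=dataset.config,
        gene_records=list(dataset.gene_records),
        pub_links=new_links,
        construct_links=list(dataset.construct_links),
        truth=new_truth,
        _next_pub_serial=serial,
    )
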