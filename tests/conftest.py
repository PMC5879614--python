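import pytest

from curategap.feature_table import GeneFeatures
from curategap.ingest import (
    ConstructComponentLink,
    GenePublicationLink,
    GeneRecord,
)


def make_gene(i, **overrides):
    defaults = dict(
        gene_id=f"ZDB-GENE-000101-{i}",
        symbol=f"g{i}aa",
        name=f"gene {i}",
        y=2 * i,
        expr_pub_count=i,
        total_journal_pub_count=2 * i,
        percent_expr_pubs=0.5 if i else 0.0,
        construct_count=0,
    )
    defaults.update(overrides)
    return GeneFeatures(**defaults)


@pytest.fixture
def gene_records():
    return [
        GeneRecord(f"ZDB-GENE-000101-{i}", f"g{i}aa", f"gene {i}", i, i, 0, 0)
        for i in range(1, 6)
    ]


@pytest.fixture
def pub_link():
    def _make(gene_id, pub_id, pub_type="Journal", symbol="g1aa", pmid=None):
        return GenePublicationLink(
            gene_symbol=symbol,
            gene_id=gene_id,
            pub_id=pub_id,
            pub_type=pub_type,
            pmid=pmid,
        )

    return _make


@pytest.fixture
def construct_link():
    def _make(construct_id, gene_id, symbol="g1aa"):
        return ConstructComponentLink(
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

    return _make
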