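import numpy as np
import pytest

from pfamdiff import CountTable, GeneRecord


def make_gene(gene_id, length=1000, pfams=(), phylum="unknown",
              genus="unknown", community_id="A"):
    return GeneRecord(
        gene_id=gene_id,
        length=length,
        pfams=frozenset(pfams),
        phylum=phylum,
        genus=genus,
        community_id=community_id,
    )


def make_counts(community_id, counts):
    return CountTable(community_id=community_id, counts=dict(counts))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_catalog():
    """Two-community toy data: disjoint genes, overlapping families."""
    cat_a = [
        make_gene("a1", 1500, {"PF00001"}, "Proteobacteria", "Pseudoxanthomonas", "A"),
        make_gene("a2", 1000, {"PF00001", "PF00002"}, "Bacteroidetes", "Niastella", "A"),
        make_gene("a3", 500, {"PF00002"}, "Bacteroidetes", "Niastella", "A"),
        make_gene("a4", 2000, set(), community_id="A"),
    ]
    cat_b = [
        make_gene("b1", 1500, {"PF00001"}, "Actinobacteria", "Micromonospora", "B"),
        make_gene("b2", 750, {"PF00002"}, "Actinobacteria", "Micromonospora", "B"),
        make_gene("b3", 1000, {"PF00003"}, "Firmicutes", "Thermobacillus", "B"),
    ]
    cnt_a = make_counts("A", {"a1": 300, "a2": 200, "a3": 100, "a4": 50})
    cnt_b = make_counts("B", {"b1": 150, "b2": 75, "b3": 0})
    return {"A": cat_a, "B": cat_b}, {"A": cnt_a, "B": cnt_b}
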