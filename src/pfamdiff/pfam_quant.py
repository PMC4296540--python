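"""Length normalization, Pfam collation and size-factor normalization.

The quantity compared between communities is, per Pfam i and community A,

    P_iA = p_iA / S_A,   p_iA = sum_j g_jiA / l_jiA

where g is the mapped read count of the j-th gene annotated to Pfam i, l its
length in nucleotides, and S_A a median-of-ratios size factor correcting
for sequencing-depth differences: S_A is the median over Pfams of
p_iA / (prod_B p_iB)^(1/m), the ratio of each Pfam's length-normalized
count to its geometric mean across the m communities. Pfams with zero
expression in any community are dropped from the median (their geometric
mean vanishes). Genes with several Pfam annotations contribute their full
normalized count to each family; genes without any annotation are excluded
from collation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .catalog_io import CountTable, GeneRecord
from .errors import EstimationError


@dataclass(frozen=True)
class PfamAggregate:
    """Per-Pfam, per-community expression summary."""

    pfam: str
    community_id: str
    p_raw: float  # length-normalized read-count sum
    n_expressed: int  # annotated genes with count >= 1
    P_norm: float  # p_raw / size factor


@dataclass
class SizeFactors:
    factors: dict[str, float]

    def __getitem__(self, community_id: str) -> float:
        return self.factors[community_id]


def length_normalize(
    catalog: Sequence[GeneRecord], counts: CountTable
) -> dict[str, float]:
    """Per-gene normalized count g/l (reads per nucleotide of gene)."""
    index = {r.gene_id: r.length for r in catalog}
    out: dict[str, float] = {}
    for gid, length in index.items():
        c = counts.counts.get(gid, 0)
        out[gid] = c / length if c else 0.0
    return out


def collate_by_pfam(
    norm_counts: Mapping[str, float], catalog: Sequence[GeneRecord]
) -> dict[str, tuple[float, int]]:
    """Collate per-gene normalized counts into per-Pfam (p_raw, n_expressed).

    A gene with k annotations contributes its full value to each of the k
    Pfams; unannotated genes contribute nowhere. ``n_expressed`` counts the
    annotated genes with raw count >= 1 (i.e. nonzero normalized value).
    """
    out: dict[str, list] = {}
    for rec in catalog:
        if not rec.pfams:
            continue
        v = norm_counts.get(rec.gene_id, 0.0)
        expressed = v > 0.0
        for pf in rec.pfams:
            acc = out.setdefault(pf, [0.0, 0])
            acc[0] += v
            acc[1] += int(expressed)
    return {pf: (p, n) for pf, (p, n) in out.items()}


def collate_raw_counts(
    counts: CountTable, catalog: Sequence[GeneRecord]
) -> dict[str, int]:
    """Per-Pfam summed mapped read counts (no length normalization).

    Same collation rules as :func:`collate_by_pfam` — a multi-annotated
    gene contributes its full count to each family, unannotated genes to
    none. This is the integer-count view the negative-binomial machinery
    consumes.
    """
    out: dict[str, int] = {}
    for rec in catalog:
        if not rec.pfams:
            continue
        c = counts.counts.get(rec.gene_id, 0)
        for pf in rec.pfams:
            out[pf] = out.get(pf, 0) + c
    return out


def compute_size_factors(
    p_raw_tables: Mapping[str, Mapping[str, float]]
) -> SizeFactors:
    """Median-of-ratios size factors from per-community p_raw tables.

    ``p_raw_tables`` maps community_id -> {pfam -> p_raw}. Pfams with zero
    (or missing) p_raw in any community are excluded; if none remain an
    :class:`EstimationError` is raised. The median of an even-length ratio
    set is the mean of the two central values.
    """
    communities = list(p_raw_tables)
    if len(communities) < 2:
        raise EstimationError("size factors require at least two communities")
    shared = [
        pf
        for pf in set().union(*(set(t) for t in p_raw_tables.values()))
        if all(p_raw_tables[c].get(pf, 0.0) > 0.0 for c in communities)
    ]
    if not shared:
        raise EstimationError(
            "no Pfam with positive expression in every community; "
            "size factors are undefined"
        )
    shared.sort()
    m = len(communities)
    p = {
        c: np.array([p_raw_tables[c][pf] for pf in shared], dtype=float)
        for c in communities
    }
    if m == 2:
        # direct sqrt keeps the reciprocal identity S_A*S_B = 1 exact when
        # the per-Pfam ratios are exactly representable
        a, b = communities
        gm = np.sqrt(p[a] * p[b])
    else:
        gm = np.exp(sum(np.log(p[c]) for c in communities) / m)
    factors = {c: float(np.median(p[c] / gm)) for c in communities}
    return SizeFactors(factors)


def normalize_pfam_expression(
    p_raw_tables: Mapping[str, Mapping[str, tuple[float, int]]],
    size_factors: SizeFactors,
) -> list[PfamAggregate]:
    """Attach size-normalized expression P = p_raw/S to every Pfam in every
    community. ``p_raw_tables`` maps community -> {pfam -> (p_raw,
    n_expressed)} as produced by :func:`collate_by_pfam`."""
    out: list[PfamAggregate] = []
    for cid, table in p_raw_tables.items():
        s = size_factors[cid]
        for pf, (p_raw, n_exp) in sorted(table.items()):
            out.append(
                PfamAggregate(
                    pfam=pf,
                    community_id=cid,
                    p_raw=p_raw,
                    n_expressed=n_exp,
                    P_norm=p_raw / s,
                )
            )
    return out


def aggregate_communities(
    catalogs: Mapping[str, Sequence[GeneRecord]],
    count_tables: Mapping[str, CountTable],
) -> tuple[list[PfamAggregate], SizeFactors, dict[str, dict[str, float]]]:
    """End-to-end collation for several communities.

    Returns the per-Pfam aggregates, the size factors, and the per-gene
    normalized counts per community (needed downstream by the pseudo-Pfam
    sampling pools and the profiling layers).
    """
    norm: dict[str, dict[str, float]] = {}
    collated: dict[str, dict[str, tuple[float, int]]] = {}
    for cid, catalog in catalogs.items():
        norm[cid] = length_normalize(catalog, count_tables[cid])
        collated[cid] = collate_by_pfam(norm[cid], catalog)
    p_only = {
        cid: {pf: p for pf, (p, _) in table.items()}
        for cid, table in collated.items()
    }
    sf = compute_size_factors(p_only)
    aggregates = normalize_pfam_expression(collated, sf)
    return aggregates, sf, norm


def aggregate_lookup(
    aggregates: Sequence[PfamAggregate],
) -> dict[tuple[str, str], PfamAggregate]:
    """Index aggregates by (community_id, pfam)."""
    return {(a.community_id, a.pfam): a for a in aggregates}
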