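"""Descriptive profiling layers: sequencing-metric percentages,
lignocellulolytic GH composition, fold changes, genus/phylum attribution,
dominant-gene breakdowns and rarefaction curves."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .catalog_io import (
    CountTable,
    GeneRecord,
    PfamTargetList,
    UNKNOWN_TAXON,
    normalize_accession,
)
from .errors import ValidationError


@dataclass(frozen=True)
class SequencingMetrics:
    """Raw sequencing/processing tallies for one community. The chain
    total >= mRNA >= mapped >= lignocellulolytic must hold."""

    community_id: str
    total_reads: int
    mrna_reads: int
    mapped_mrna_reads: int
    lignocellulolytic_reads: int

    def __post_init__(self) -> None:
        chain = (
            self.total_reads,
            self.mrna_reads,
            self.mapped_mrna_reads,
            self.lignocellulolytic_reads,
        )
        if any(c < 0 for c in chain) or any(
            chain[i] < chain[i + 1] for i in range(3)
        ):
            raise ValidationError(
                f"metrics for {self.community_id!r} violate "
                "total >= mRNA >= mapped >= lignocellulolytic"
            )


def sequencing_metrics_report(metrics: SequencingMetrics) -> dict[str, float]:
    """Derived percentages, rounded as conventionally printed:

    - ``rrna_pct``: reads filtered out as rRNA, (total - mRNA)/total (1 dp)
    - ``mapped_pct``: mRNA reads mapped to genes, mapped/mRNA (1 dp)
    - ``lignocellulolytic_pct``: share of mapped expression in the target
      GH Pfams, ligno/mapped (2 dp)
    """
    rrna = (metrics.total_reads - metrics.mrna_reads) / metrics.total_reads * 100
    mapped = metrics.mapped_mrna_reads / metrics.mrna_reads * 100
    ligno = (
        metrics.lignocellulolytic_reads / metrics.mapped_mrna_reads * 100
    )
    return {
        "rrna_pct": round(rrna, 1),
        "mapped_pct": round(mapped, 1),
        "lignocellulolytic_pct": round(ligno, 2),
    }


@dataclass
class CompositionProfile:
    community_id: str
    shares: dict[str, float]  # GH-family label -> % of lignocellulolytic GH transcriptome


def composition_profile(
    p_raw_table: Mapping[str, float],
    target_pfams: PfamTargetList,
    community_id: str,
) -> CompositionProfile:
    """Percent of the lignocellulolytic GH transcriptome per GH family.

    The denominator is the summed length-normalized expression over the
    GH-category target families only; CBM families are reported by other
    layers, not here. Shares are size-factor free (a common divisor would
    cancel)."""
    gh = target_pfams.by_category("GH")
    total = sum(p_raw_table.get(t.accession, 0.0) for t in gh)
    if total <= 0:
        raise ValidationError(
            f"community {community_id!r}: no GH-family expression; "
            "composition undefined"
        )
    shares = {
        t.label: p_raw_table.get(t.accession, 0.0) / total * 100 for t in gh
    }
    return CompositionProfile(community_id=community_id, shares=shares)


def fold_change(P_A: float, P_B: float) -> tuple[float | None, str]:
    """Fold change max/min and the direction of overexpression.

    Returns ``(fold, direction)`` with direction in {"A", "B", "tie",
    "not_detected"}. If exactly one side is zero the fold is undefined
    (None); if both are zero the family was not detected."""
    if P_A == 0 and P_B == 0:
        return None, "not_detected"
    if P_A == 0:
        return None, "B"
    if P_B == 0:
        return None, "A"
    if P_A == P_B:
        return 1.0, "tie"
    if P_A > P_B:
        return P_A / P_B, "A"
    return P_B / P_A, "B"


@dataclass
class TaxonAttribution:
    pfam: str
    label: str
    genus_shares: dict[str, float]  # % of the family's normalized transcripts
    phylum_shares: dict[str, float]
    dominant_list: list[tuple[str, float]]  # shortest prefix with cumulative > 50%


def _attribution_for(
    norm_counts: Mapping[str, float],
    catalog: Sequence[GeneRecord],
    accession: str,
) -> tuple[dict[str, float], dict[str, float]]:
    genus_tot: dict[str, float] = {}
    phylum_tot: dict[str, float] = {}
    total = 0.0
    for rec in catalog:
        if accession not in rec.pfams:
            continue
        v = norm_counts.get(rec.gene_id, 0.0)
        if v <= 0:
            continue
        total += v
        genus_tot[rec.genus] = genus_tot.get(rec.genus, 0.0) + v
        phylum_tot[rec.phylum] = phylum_tot.get(rec.phylum, 0.0) + v
    if total <= 0:
        return {}, {}
    return (
        {g: v / total * 100 for g, v in genus_tot.items()},
        {p: v / total * 100 for p, v in phylum_tot.items()},
    )


def genus_attribution(
    norm_counts: Mapping[str, float],
    catalog: Sequence[GeneRecord],
    target_pfams: PfamTargetList,
) -> list[TaxonAttribution]:
    """Per target family: genus and phylum shares of the family's
    normalized transcripts, plus the shortest descending-share genus prefix
    whose cumulative share strictly exceeds 50% (ties broken by genus
    name). Families with no expression are omitted."""
    out: list[TaxonAttribution] = []
    for t in target_pfams:
        genus, phylum = _attribution_for(norm_counts, catalog, t.accession)
        if not genus:
            continue
        ranked = sorted(genus.items(), key=lambda kv: (-kv[1], kv[0]))
        dominant: list[tuple[str, float]] = []
        cum = 0.0
        for g, share in ranked:
            dominant.append((g, share))
            cum += share
            if cum > 50.0:
                break
        out.append(
            TaxonAttribution(
                pfam=t.accession,
                label=t.label,
                genus_shares=genus,
                phylum_shares=phylum,
                dominant_list=dominant,
            )
        )
    return out


def top_genes(
    norm_counts: Mapping[str, float],
    catalog: Sequence[GeneRecord],
    pfam: str,
    coverage: float = 0.90,
) -> list[tuple[str, float]]:
    """Genes carrying the bulk of one family's expression.

    Genes annotated to ``pfam`` sorted by descending normalized count (ties
    by gene_id); returns the shortest prefix whose cumulative share of the
    family's expression is >= ``coverage``, as (gene_id, share) pairs.
    Zero-expression families give an empty list."""
    acc = normalize_accession(pfam)
    vals = [
        (r.gene_id, norm_counts.get(r.gene_id, 0.0))
        for r in catalog
        if acc in r.pfams and norm_counts.get(r.gene_id, 0.0) > 0
    ]
    total = sum(v for _, v in vals)
    if total <= 0:
        return []
    vals.sort(key=lambda kv: (-kv[1], kv[0]))
    out: list[tuple[str, float]] = []
    cum = 0.0
    for gid, v in vals:
        share = v / total
        out.append((gid, share))
        cum += share
        if cum >= coverage:
            break
    return out


def rarefaction_curve(
    counts: CountTable,
    grid: Sequence[int],
    reps: int = 200,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, float]]:
    """Expected number of distinct expressed genes at subsampled depths.

    At each depth m, ``reps`` subsamples of m reads are drawn without
    replacement from the mapped-read multiset (a multivariate
    hypergeometric draw over genes) and the mean number of genes with >= 1
    read is reported. Depths beyond the total mapped reads raise."""
    if rng is None:
        rng = np.random.default_rng()
    gene_counts = np.array(
        [c for c in counts.counts.values() if c > 0], dtype=np.int64
    )
    total = int(gene_counts.sum())
    out: list[tuple[int, float]] = []
    for m in grid:
        if m < 0 or m > total:
            raise ValueError(f"depth {m} outside [0, {total}]")
        if m == 0:
            out.append((0, 0.0))
            continue
        if m == total:
            out.append((m, float(gene_counts.size)))
            continue
        detected = np.empty(reps)
        for r in range(reps):
            draw = rng.multivariate_hypergeometric(gene_counts, m)
            detected[r] = np.count_nonzero(draw)
        out.append((m, float(detected.mean())))
    return out
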