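"""Reading, writing and validation of gene catalogs, count tables and
target-Pfam lists.

A *gene catalog* is one community's annotated gene set: every row carries a
gene identifier, the gene length in nucleotides, zero or more Pfam domain
annotations (semicolon separated), and a phylum/genus bin from phylogenetic
binning of the metagenome. A *count table* carries the mapped mRNA read
count per gene for the same community; genes absent from the count file are
unexpressed (count 0), because a metagenome typically contains many genes
with no mapped transcript.

All files are plain TSV so catalogs exported from annotation pipelines can
be joined by hand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError

UNKNOWN_TAXON = "unknown"

_ACCESSION_RE = re.compile(r"^(?:PF|Pfam|pfam|pf)?(\d{4,6})$")


def normalize_accession(acc: str) -> str:
    """Canonicalize a Pfam accession: ``Pfam02011``/``pf02011`` -> ``PF02011``.

    Strings that do not look like Pfam accessions are returned stripped but
    otherwise untouched, so ad-hoc category labels can flow through the
    pipeline unharmed.
    """
    acc = acc.strip()
    m = _ACCESSION_RE.match(acc)
    if m:
        return f"PF{int(m.group(1)):05d}"
    return acc


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene in one community's catalog."""

    gene_id: str
    length: int  # nucleotides
    pfams: frozenset[str]
    phylum: str = UNKNOWN_TAXON
    genus: str = UNKNOWN_TAXON
    community_id: str = ""

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(
                f"gene {self.gene_id!r}: length must be >= 1, got {self.length}"
            )


@dataclass
class CountTable:
    """Mapped mRNA read count per gene for one community.

    ``counts`` has an entry for every catalog gene; genes without mapped
    reads carry 0.
    """

    community_id: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def expressed_genes(self) -> set[str]:
        """Genes with at least one mapped read."""
        return {g for g, c in self.counts.items() if c >= 1}


@dataclass(frozen=True)
class PfamTarget:
    accession: str
    label: str
    category: str  # "GH" or "CBM"


@dataclass
class PfamTargetList:
    entries: list[PfamTarget]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.accession in seen:
                raise ValidationError(f"duplicate target accession {e.accession}")
            seen.add(e.accession)
            if e.category not in ("GH", "CBM"):
                raise ValidationError(
                    f"target {e.accession}: category must be GH or CBM, "
                    f"got {e.category!r}"
                )

    def accessions(self) -> list[str]:
        return [e.accession for e in self.entries]

    def label_of(self, accession: str) -> str:
        for e in self.entries:
            if e.accession == normalize_accession(accession):
                return e.label
        raise KeyError(accession)

    def by_category(self, category: str) -> list[PfamTarget]:
        return [e for e in self.entries if e.category == category]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


# The 33 glycoside hydrolase (GH) and carbohydrate binding module (CBM)
# families relevant to lignocellulose deconstruction that the comparison
# targets by default: cellulases, hemicellulases, oligosaccharide-active
# enzymes and their carbohydrate-binding domains.
_BUILTIN_TARGETS: tuple[tuple[str, str, str], ...] = (
    ("PF00150", "GH5", "GH"),
    ("PF00232", "GH1", "GH"),
    ("PF00331", "GH10", "GH"),
    ("PF00457", "GH11", "GH"),
    ("PF00722", "GH16", "GH"),
    ("PF00759", "GH9", "GH"),
    ("PF00840", "GH7", "GH"),
    ("PF00933", "GH3", "GH"),
    ("PF01270", "GH8", "GH"),
    ("PF01341", "GH6", "GH"),
    ("PF01670", "GH12", "GH"),
    ("PF01915", "GH3C", "GH"),
    ("PF02011", "GH48", "GH"),
    ("PF02015", "GH45", "GH"),
    ("PF02156", "GH26", "GH"),
    ("PF03443", "GH61", "GH"),
    ("PF03648", "GH67N", "GH"),
    ("PF03664", "GH62", "GH"),
    ("PF04616", "GH43", "GH"),
    ("PF07477", "GH67C", "GH"),
    ("PF07488", "GH67M", "GH"),
    ("PF00553", "CBM2", "CBM"),
    ("PF00734", "CBM1", "CBM"),
    ("PF00942", "CBM3", "CBM"),
    ("PF02013", "CBM10", "CBM"),
    ("PF02018", "CBM4,9", "CBM"),
    ("PF03067", "CBM33", "CBM"),
    ("PF03422", "CBM6", "CBM"),
    ("PF03424", "CBM17,28", "CBM"),
    ("PF03425", "CBM11", "CBM"),
    ("PF03426", "CBM15", "CBM"),
    ("PF09212", "CBM27", "CBM"),
    ("PF09478", "CBM49", "CBM"),
)

CATALOG_COLUMNS = ["gene_id", "length", "pfams", "phylum", "genus"]
COUNT_COLUMNS = ["gene_id", "count"]


def load_target_pfams(source: str | Path = "builtin") -> PfamTargetList:
    """Load the target-Pfam list: ``"builtin"`` for the default 33 GH/CBM
    families, or a path to a TSV with columns accession, label, category."""
    if isinstance(source, str) and source == "builtin":
        return PfamTargetList(
            [PfamTarget(a, l, c) for a, l, c in _BUILTIN_TARGETS]
        )
    df = pd.read_csv(source, sep="\t", dtype=str).fillna("")
    required = {"accession", "label", "category"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"target-Pfam file must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    entries = [
        PfamTarget(normalize_accession(r.accession), r.label, r.category)
        for r in df.itertuples()
    ]
    return PfamTargetList(entries)


def _parse_pfams(cell: str) -> frozenset[str]:
    if not cell or not cell.strip():
        return frozenset()
    return frozenset(
        normalize_accession(p) for p in cell.split(";") if p.strip()
    )


def read_gene_catalog(path: str | Path, community_id: str) -> list[GeneRecord]:
    """Read a gene-catalog TSV (columns gene_id, length, pfams, phylum,
    genus) into a list of :class:`GeneRecord`.

    Blank pfams cells yield an empty annotation set (the gene is retained:
    unannotated genes still contribute to totals and rarefaction, they are
    only excluded from Pfam collation). Blank taxon cells become
    ``"unknown"``. Duplicate gene ids and non-positive lengths raise
    :class:`ValidationError`.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "pfams": str, "phylum": str, "genus": str}
    )
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"catalog {path}: missing columns {sorted(missing)}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(
            f"catalog {path}: duplicate gene_id {dup.iloc[0]!r}"
        )
    records: list[GeneRecord] = []
    for row in df.itertuples():
        length = int(row.length)
        if length < 1:
            raise ValidationError(
                f"catalog {path}: gene {row.gene_id!r} has non-positive "
                f"length {length}"
            )
        records.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                length=length,
                pfams=_parse_pfams("" if pd.isna(row.pfams) else str(row.pfams)),
                phylum=_clean_taxon(row.phylum),
                genus=_clean_taxon(row.genus),
                community_id=community_id,
            )
        )
    return records


def _clean_taxon(cell) -> str:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return UNKNOWN_TAXON
    s = str(cell).strip()
    return s if s else UNKNOWN_TAXON


def write_gene_catalog(records: Sequence[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "length": [r.length for r in records],
            "pfams": [";".join(sorted(r.pfams)) for r in records],
            "phylum": [r.phylum for r in records],
            "genus": [r.genus for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_count_table(
    path: str | Path, catalog: Sequence[GeneRecord]
) -> CountTable:
    """Read a count TSV (columns gene_id, count) against its catalog.

    Catalog genes absent from the file get count 0. A gene id not present
    in the catalog, or a negative/non-integer count, raises
    :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"count table {path}: missing columns {sorted(missing)}")
    community_id = catalog[0].community_id if catalog else ""
    known = {r.gene_id for r in catalog}
    counts = {g: 0 for g in known}
    # plain column iteration: "count" clashes with namedtuple methods
    for gid, c in zip(df["gene_id"].astype(str), df["count"]):
        if gid not in known:
            raise ValidationError(
                f"count table {path}: gene_id {gid!r} not in catalog"
            )
        if float(c) != int(c) or int(c) < 0:
            raise ValidationError(
                f"count table {path}: gene {gid!r} has invalid count {c!r}"
            )
        counts[gid] = int(c)
    return CountTable(community_id=community_id, counts=counts)


def write_count_table(table: CountTable, path: str | Path, *, sparse: bool = False) -> None:
    """Write a count table; with ``sparse=True`` only expressed genes are
    written (readers zero-fill from the catalog)."""
    items = sorted(table.counts.items())
    if sparse:
        items = [(g, c) for g, c in items if c > 0]
    pd.DataFrame(items, columns=COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


def validate_pair(catalog: Sequence[GeneRecord], table: CountTable) -> None:
    """Cross-check a catalog/count-table pair; raises ValidationError."""
    known = {r.gene_id for r in catalog}
    extra = set(table.counts) - known
    if extra:
        raise ValidationError(
            f"count table references unknown gene_id(s): {sorted(extra)[:5]}"
        )
    neg = [g for g, c in table.counts.items() if c < 0]
    if neg:
        raise ValidationError(f"negative counts for gene(s): {sorted(neg)[:5]}")


def catalog_index(catalog: Iterable[GeneRecord]) -> dict[str, GeneRecord]:
    return {r.gene_id: r for r in catalog}
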