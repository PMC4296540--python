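"""End-to-end orchestration: from two catalog/count pairs to a combined
differential-expression report over the target families."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog_io import CountTable, GeneRecord, PfamTargetList, load_target_pfams
from .nb_test import FDR_THRESHOLD, run_nb_test
from .pfam_quant import aggregate_communities, collate_raw_counts
from .profiling import fold_change
from .pseudo_pfam import (
    DEFAULT_REPS,
    DEFAULT_RUNS,
    build_sampling_pool,
    run_pseudo_pfam_test,
)

REPORT_COLUMNS = [
    "pfam",
    "label",
    "p_raw_count_A",
    "p_raw_count_B",
    "n_A",
    "n_B",
    "P_A",
    "P_B",
    "D",
    "fold_change",
    "direction",
    "p_pseudo",
    "p_nb",
    "p_nb_adjusted",
    "significant",
]


def differential_expression_report(
    catalogs: Mapping[str, Sequence[GeneRecord]],
    count_tables: Mapping[str, CountTable],
    target_pfams: PfamTargetList | None = None,
    reps: int = DEFAULT_REPS,
    n_runs: int = DEFAULT_RUNS,
    seed: int = 0,
    threshold: float = FDR_THRESHOLD,
    overexpressed_in: str | None = None,
) -> pd.DataFrame:
    """Run both differential-expression tests and assemble the combined
    per-family report.

    Community "A" is the lexicographically first id, "B" the second. The
    pseudo-Pfam test is directional: ``overexpressed_in`` (default B)
    names the community whose overexpression it probes, so a small
    ``p_pseudo`` supports overexpression there while families
    overexpressed on the other side drift toward p = 1. The
    ``significant`` column is the consensus call: mean pseudo-Pfam P-value
    <= threshold AND BH-adjusted NB P-value <= threshold. Families
    expressed in neither community carry NaN statistics and direction
    ``not_detected``; a family with zero expression on exactly one side
    has an undefined (NaN) fold change but keeps its tests.
    """
    if target_pfams is None:
        target_pfams = load_target_pfams("builtin")
    cids = sorted(catalogs)
    if len(cids) != 2 or set(cids) != set(count_tables):
        raise ValueError("exactly two matching catalog/count pairs required")
    cid_A, cid_B = cids

    aggregates, size_factors, norm = aggregate_communities(catalogs, count_tables)
    pools = {
        cid: build_sampling_pool(
            catalogs[cid], norm[cid], size_factors[cid], cid
        )
        for cid in cids
    }
    pseudo = {
        r.pfam: r
        for r in run_pseudo_pfam_test(
            aggregates,
            pools,
            target_pfams,
            reps=reps,
            n_runs=n_runs,
            seed=seed,
            overexpressed_in=overexpressed_in,
        )
    }
    raw_count_tables = {
        cid: collate_raw_counts(count_tables[cid], catalogs[cid])
        for cid in cids
    }
    nb = {
        r.pfam: r
        for r in run_nb_test(raw_count_tables, size_factors, target_pfams)
    }
    agg = {(a.community_id, a.pfam): a for a in aggregates}

    rows = []
    for t in target_pfams:
        a = agg.get((cid_A, t.accession))
        b = agg.get((cid_B, t.accession))
        P_A = a.P_norm if a else 0.0
        P_B = b.P_norm if b else 0.0
        fold, direction = fold_change(P_A, P_B)
        ps = pseudo.get(t.accession)
        nbr = nb.get(t.accession)
        p_pseudo = ps.p_mean if ps is not None and ps.detected else np.nan
        p_nb = nbr.p_raw if nbr else np.nan
        p_nb_adj = nbr.p_adjusted if nbr else np.nan
        significant = (
            not np.isnan(p_pseudo)
            and not np.isnan(p_nb_adj)
            and p_pseudo <= threshold
            and p_nb_adj <= threshold
        )
        rows.append(
            {
                "pfam": t.accession,
                "label": t.label,
                "p_raw_count_A": a.p_raw if a else 0.0,
                "p_raw_count_B": b.p_raw if b else 0.0,
                "n_A": a.n_expressed if a else 0,
                "n_B": b.n_expressed if b else 0,
                "P_A": P_A,
                "P_B": P_B,
                "D": P_A - P_B,
                "fold_change": np.nan if fold is None else fold,
                "direction": direction,
                "p_pseudo": p_pseudo,
                "p_nb": p_nb,
                "p_nb_adjusted": p_nb_adj,
                "significant": significant,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
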