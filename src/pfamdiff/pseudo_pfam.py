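"""Monte-Carlo "pseudo-Pfam" significance test for between-community
differences in Pfam-level expression.

Communities enriched under different conditions can share essentially no
genes, so per-gene fold changes are undefined. The test instead asks: is
the observed difference D_i = P_iA - P_iB for Pfam i larger than the
difference between two *randomly assembled* gene groups of the same sizes?
A pseudo-Pfam for community A is a uniform draw, without replacement, of
n_iA genes from the pool of all annotated, expressed genes of A; its
normalized read counts are summed and the pseudo-difference
D_pseudo = sum_A - sum_B recorded. Repeating this (default 10,000 times)
builds a null distribution of differences arising by chance, and the
P-value is the probability of a pseudo-difference >= D_i — a directional
test of overexpression in the community whose P enters the difference
with a plus sign (families overexpressed on the other side get P-values
near 1). The whole procedure is run several times (default 3) and the
per-run P-values averaged.

P-values use add-one smoothing, (b+1)/(N+1), so a difference exceeding
every pseudo-difference reports 1/(N+1) rather than 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .catalog_io import GeneRecord, PfamTargetList
from .pfam_quant import PfamAggregate, SizeFactors

DEFAULT_REPS = 10_000
DEFAULT_RUNS = 3


@dataclass
class SamplingPool:
    """Per-gene size- and length-normalized counts (g/l/S) for one
    community's genes that carry >= 1 Pfam annotation and a nonzero read
    count — the population pseudo-Pfams are drawn from."""

    community_id: str
    values: np.ndarray  # positive floats

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("sampling-pool values must all be positive")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class PseudoPfamResult:
    pfam: str
    D_obs: float
    p_values: list[float]  # one per Monte-Carlo run
    p_mean: float
    reps_per_run: int
    n_runs: int
    seed: int
    detected: bool = True  # False when the Pfam is expressed in neither community

    @property
    def not_detected(self) -> bool:
        return not self.detected


def build_sampling_pool(
    catalog: Sequence[GeneRecord],
    norm_counts: Mapping[str, float],
    size_factor: float,
    community_id: str,
) -> SamplingPool:
    """Pool of g/l/S values over annotated genes with nonzero counts.

    Any annotated gene qualifies — including genes annotated only to
    families outside the target list — because the null asks what random
    gene groups of matched size do, not what other target families do.
    """
    vals = [
        norm_counts[r.gene_id] / size_factor
        for r in catalog
        if r.pfams and norm_counts.get(r.gene_id, 0.0) > 0.0
    ]
    return SamplingPool(community_id=community_id, values=np.array(vals))


def observed_difference(P_A: float, P_B: float) -> float:
    """Signed expression difference D = P_A - P_B."""
    return P_A - P_B


def sample_pseudo_pfam(
    pool: SamplingPool, n: int, rng: np.random.Generator
) -> float:
    """Sum of ``n`` pool values drawn uniformly without replacement.

    ``n = 0`` (a family with no expressed genes in this community) sums to
    0. ``n`` exceeding the pool raises: the caller should cap n at the pool
    size.
    """
    if n == 0:
        return 0.0
    if n > len(pool):
        raise ValueError(
            f"group size {n} exceeds pool size {len(pool)}; "
            "cap n at the pool size"
        )
    idx = rng.choice(len(pool), size=n, replace=False)
    return float(pool.values[idx].sum())


def permutation_null(
    pool_A: SamplingPool,
    pool_B: SamplingPool,
    n_A: int,
    n_B: int,
    reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """``reps`` independent pseudo-differences (pseudo-sum A − pseudo-sum B)."""
    out = np.empty(reps)
    for r in range(reps):
        out[r] = sample_pseudo_pfam(pool_A, n_A, rng) - sample_pseudo_pfam(
            pool_B, n_B, rng
        )
    return out


def pseudo_pfam_pvalue(D_obs: float, null: np.ndarray) -> float:
    """Monte-Carlo P-value P(D_pseudo >= D_obs) with add-one smoothing.

    The signed >= rule makes this a one-sided test of overexpression in
    the community whose expression enters D with a plus sign: a family
    strongly overexpressed there gets p near 0, one strongly overexpressed
    in the other community gets p near 1, and under the null (the family
    behaves like a random gene group) p is uniform on (0, 1] by
    probability-integral transform.
    """
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("empty null distribution")
    b = int(np.sum(null >= D_obs))
    return (b + 1) / (null.size + 1)


def _prefix_sums(
    pool: SamplingPool, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """(reps, N) cumulative sums of independently permuted pool values.

    Row r column n-1 is the sum of a uniform without-replacement draw of n
    values — one permutation serves every group size at once.
    """
    n = len(pool)
    keys = rng.random((reps, n))
    order = np.argsort(keys, axis=1)
    permuted = pool.values[order]
    return np.cumsum(permuted, axis=1)


def run_pseudo_pfam_test(
    aggregates: Sequence[PfamAggregate],
    pools: Mapping[str, SamplingPool],
    target_pfams: PfamTargetList,
    reps: int = DEFAULT_REPS,
    n_runs: int = DEFAULT_RUNS,
    seed: int = 0,
    overexpressed_in: str | None = None,
) -> list[PseudoPfamResult]:
    """Run the pseudo-Pfam test for every target family.

    ``pools`` maps the two community ids to their sampling pools;
    ``aggregates`` must carry both communities. The test is directional:
    ``overexpressed_in`` names the community whose overexpression is under
    test (default: the lexicographically second id); D_obs is that
    community's P minus the other's, and small P-values mean
    overexpression there. Families expressed in neither community are
    flagged not-detected and get no P-value.

    Within a run, all families' null sums are read off one set of ``reps``
    random permutations per community (the prefix of a uniform random
    permutation is a uniform without-replacement draw, so each family's
    null marginal is exact); run-to-run draws are independent, and the
    reported P-value averages the runs.
    """
    cids = sorted(pools)
    if len(cids) != 2:
        raise ValueError("pseudo-Pfam test compares exactly two communities")
    if overexpressed_in is None:
        overexpressed_in = cids[1]
    if overexpressed_in not in cids:
        raise ValueError(f"unknown community {overexpressed_in!r}")
    # community A is the one under test: D = P_A - P_B
    cid_A = overexpressed_in
    cid_B = cids[0] if overexpressed_in == cids[1] else cids[1]
    agg = {(a.community_id, a.pfam): a for a in aggregates}

    rng = np.random.default_rng(seed)
    cums: list[tuple[np.ndarray, np.ndarray]] = []
    needed_A = needed_B = 0
    per_pfam: list[tuple[str, float, int, int]] = []
    for t in target_pfams:
        a = agg.get((cid_A, t.accession))
        b = agg.get((cid_B, t.accession))
        P_A = a.P_norm if a else 0.0
        P_B = b.P_norm if b else 0.0
        n_A = min(a.n_expressed if a else 0, len(pools[cid_A]))
        n_B = min(b.n_expressed if b else 0, len(pools[cid_B]))
        per_pfam.append((t.accession, observed_difference(P_A, P_B), n_A, n_B))
        needed_A = max(needed_A, n_A)
        needed_B = max(needed_B, n_B)

    for _ in range(n_runs):
        cum_A = _prefix_sums(pools[cid_A], reps, rng) if needed_A else None
        cum_B = _prefix_sums(pools[cid_B], reps, rng) if needed_B else None
        cums.append((cum_A, cum_B))

    results: list[PseudoPfamResult] = []
    for pfam, D_obs, n_A, n_B in per_pfam:
        if n_A == 0 and n_B == 0 and D_obs == 0.0:
            results.append(
                PseudoPfamResult(
                    pfam=pfam,
                    D_obs=0.0,
                    p_values=[],
                    p_mean=float("nan"),
                    reps_per_run=reps,
                    n_runs=n_runs,
                    seed=seed,
                    detected=False,
                )
            )
            continue
        p_values = []
        for cum_A, cum_B in cums:
            sums_A = cum_A[:, n_A - 1] if n_A else np.zeros(reps)
            sums_B = cum_B[:, n_B - 1] if n_B else np.zeros(reps)
            p_values.append(pseudo_pfam_pvalue(D_obs, sums_A - sums_B))
        results.append(
            PseudoPfamResult(
                pfam=pfam,
                D_obs=D_obs,
                p_values=p_values,
                p_mean=float(np.mean(p_values)),
                reps_per_run=reps,
                n_runs=n_runs,
                seed=seed,
            )
        )
    return results
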