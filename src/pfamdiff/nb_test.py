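"""Negative-binomial test for Pfam-level differential expression without
replicates, in the pooled-duplicate style of Anders & Huber's
median-of-ratios/NB framework.

With a single metatranscriptome per community, the two communities'
size-normalized Pfam counts are temporarily pooled and treated as duplicate
samples to estimate a common dispersion; this assumes most Pfams are not
differentially expressed and therefore *over*estimates the variance when
that assumption fails, costing power rather than type-I error. Each Pfam is
then tested with a two-sided conditional test: holding the total count
k_S = k_A + k_B fixed, the P-value is the probability mass of all splits
(a, k_S - a) whose joint NB probability does not exceed that of the
observed split, normalized by the total mass over splits. Raw P-values are
Benjamini-Hochberg adjusted.

Counts entering the machinery are the per-Pfam summed mapped read counts
(a multi-annotated gene counts once per family), rounded half-to-even so
arbitrary collated tables always reduce to integers. Length normalization
is deliberately absent here: the NB model describes read-count noise, and
the size factors already absorb depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog_io import PfamTargetList
from .errors import EstimationError
from .pfam_quant import SizeFactors

# relative slack when comparing joint probabilities for the "<= observed"
# rule, absorbing order-of-evaluation rounding in ties
_TIE_REL_TOL = 1e-12

FDR_THRESHOLD = 0.10


@dataclass
class DispersionModel:
    """Parametric mean-variance model  var = mu + alpha * mu^2."""

    alpha: float
    fit_pairs: list[tuple[float, float]]  # (common-scale mean, excess variance)

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("dispersion alpha must be >= 0")


@dataclass
class NBTestResult:
    pfam: str
    k_A: int
    k_B: int
    p_raw: float
    p_adjusted: float = float("nan")


def pfam_count_matrix(
    count_tables: Mapping[str, Mapping[str, float]],
    target_pfams: PfamTargetList,
) -> dict[str, tuple[int, int]]:
    """Per-target-Pfam integer counts (k_A, k_B).

    ``count_tables`` maps community id -> {pfam -> per-Pfam read-count
    sum} (see :func:`pfamdiff.pfam_quant.collate_raw_counts`); values are
    rounded half-to-even so the NB machinery always sees integers. Pfams
    with zero in both communities are dropped. Communities are taken in
    sorted id order."""
    cids = sorted(count_tables)
    if len(cids) != 2:
        raise ValueError("count matrix requires exactly two communities")
    a, b = cids
    out: dict[str, tuple[int, int]] = {}
    for t in target_pfams:
        k_A = int(np.rint(count_tables[a].get(t.accession, 0.0)))
        k_B = int(np.rint(count_tables[b].get(t.accession, 0.0)))
        if k_A == 0 and k_B == 0:
            continue
        out[t.accession] = (k_A, k_B)
    return out


def estimate_pooled_dispersion(
    counts: Mapping[str, tuple[int, int]],
    size_factors: SizeFactors,
    community_ids: Sequence[str] | None = None,
) -> DispersionModel:
    """Estimate a single dispersion alpha from the two communities treated
    as duplicates.

    Per Pfam: size-normalized counts z_j = k_j/S_j, common-scale mean
    q = mean(z), sample variance w = sum (z_j - q)^2 (unbiased, one degree
    of freedom), shot-noise term q * xi with xi = mean(1/S_j). The excess
    w - q*xi estimates alpha * q^2; alpha is fit by least squares of excess
    against q^2 over Pfams with positive excess and clamped at 0.
    """
    if community_ids is None:
        community_ids = sorted(size_factors.factors)
    if len(community_ids) != 2:
        raise ValueError("pooled dispersion requires exactly two communities")
    s = np.array([size_factors[c] for c in community_ids])
    xi = float(np.mean(1.0 / s))
    usable = {pf: kk for pf, kk in counts.items() if sum(kk) > 0}
    if len(usable) < 3:
        raise EstimationError(
            f"need >= 3 Pfams with positive counts to estimate dispersion, "
            f"got {len(usable)}"
        )
    ratios: list[float] = []
    pairs: list[tuple[float, float]] = []
    for k_A, k_B in usable.values():
        z = np.array([k_A, k_B]) / s
        q = float(z.mean())
        w = float(((z - q) ** 2).sum())  # unbiased with n-1 = 1
        excess = w - q * xi
        pairs.append((q, excess))
        if excess > 0:
            ratios.append(excess / q**2)
    if not ratios:
        return DispersionModel(alpha=0.0, fit_pairs=pairs)
    # median of per-Pfam moment estimates: under "most Pfams are not
    # differentially expressed" the median tracks the non-DE majority
    # (the same reasoning as median-of-ratios size factors), so a few
    # drastically discordant Pfams cannot inflate alpha enough to excuse
    # their own discordance; restricting to positive excess still biases
    # alpha upward when many Pfams are truly DE (power, not type-I, pays)
    alpha = float(np.median(ratios))
    return DispersionModel(alpha=max(alpha, 0.0), fit_pairs=pairs)


def _nb_logpmf(k: np.ndarray, mu: float, alpha: float) -> np.ndarray:
    """log pmf of NB with mean mu, variance mu + alpha mu^2 (Poisson at
    alpha = 0)."""
    if alpha == 0.0:
        return stats.poisson.logpmf(k, mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return stats.nbinom.logpmf(k, r, p)


def nb_conditional_test(
    k_A: int,
    k_B: int,
    S_A: float,
    S_B: float,
    model: DispersionModel,
) -> float:
    """Two-sided conditional NB test of equal per-unit expression.

    Under the null both counts share a common per-unit rate, estimated as
    the mean of the size-normalized counts q0 = (k_A/S_A + k_B/S_B)/2;
    marginal means are q0*S_A and q0*S_B with variance mu + alpha mu^2.
    Conditional on the total k_S = k_A + k_B, the P-value sums the joint
    probabilities of all splits no more probable than the observed one,
    divided by the total over splits. Capped at 1.
    """
    if k_A < 0 or k_B < 0:
        raise ValueError("counts must be non-negative")
    k_S = k_A + k_B
    if k_S < 1:
        raise ValueError("total count must be >= 1")
    q0 = (k_A / S_A + k_B / S_B) / 2.0
    a = np.arange(k_S + 1)
    logj = _nb_logpmf(a, q0 * S_A, model.alpha) + _nb_logpmf(
        k_S - a, q0 * S_B, model.alpha
    )
    logj -= logj.max()  # stabilize
    j = np.exp(logj)
    obs = j[k_A]
    p = float(j[j <= obs * (1.0 + _TIE_REL_TOL)].sum() / j.sum())
    return min(p, 1.0)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted P-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in p_adj]


def run_nb_test(
    count_tables: Mapping[str, Mapping[str, float]],
    size_factors: SizeFactors,
    target_pfams: PfamTargetList,
) -> list[NBTestResult]:
    """Full NB pipeline: count matrix, pooled dispersion, conditional test
    per Pfam, BH adjustment. ``count_tables`` holds per-Pfam read-count
    sums per community."""
    cids = sorted(count_tables)
    counts = pfam_count_matrix(count_tables, target_pfams)
    model = estimate_pooled_dispersion(counts, size_factors, cids)
    S_A, S_B = (size_factors[c] for c in cids)
    results = [
        NBTestResult(pfam=pf, k_A=kk[0], k_B=kk[1],
                     p_raw=nb_conditional_test(kk[0], kk[1], S_A, S_B, model))
        for pf, kk in counts.items()
    ]
    for r, adj in zip(results, bh_adjust([r.p_raw for r in results])):
        r.p_adjusted = adj
    return results


def call_significance(
    p_values: Mapping[str, float], threshold: float = FDR_THRESHOLD
) -> dict[str, bool]:
    """Significance calls at an inclusive threshold (p <= threshold).

    For the pseudo-Pfam method pass the raw mean P-values (no multiplicity
    adjustment, by design: false negatives are costlier than false
    positives here); for the NB method pass BH-adjusted P-values. A
    consensus call is the AND of the two methods' calls. NaN (not
    detected) is never significant.
    """
    return {
        pf: (not np.isnan(p)) and p <= threshold for pf, p in p_values.items()
    }
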