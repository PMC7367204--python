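"""Differential expression calls and set statistics.

Differential features are called against wild-type with a plain fold-change
rule rather than a count model: a feature is *up* when
log2((mut + psi)/(wt + psi)) > log2(threshold) (strictly) AND the larger of
the two RPKM values exceeds a noise floor (default 1 RPKM, strictly).  The
floor is the noise control; the pseudocount psi only guards division by
zero.  Set-level statistics follow: upper-tail hypergeometric overlap of
differential gene sets, a Mann-Whitney U test for synergy of fold inductions
(double vs single perturbation), and one-sided Fisher's exact enrichment of
annotation terms with Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ExpressionTable

__all__ = [
    "DifferentialCall",
    "OverlapResult",
    "SynergyResult",
    "EnrichmentResult",
    "call_differential",
    "calls_to_frame",
    "direction_set",
    "category_fractions",
    "hypergeometric_overlap",
    "synergy_test",
    "term_enrichment",
    "fold_induction",
]


@dataclass(frozen=True)
class DifferentialCall:
    feature_id: str
    strand_class: str
    log2_fc: float
    max_rpkm: float
    direction: str  # up | down | unchanged


@dataclass(frozen=True)
class OverlapResult:
    n_A: int
    n_B: int
    n_intersection: int
    n_universe: int
    p_value: float


@dataclass(frozen=True)
class SynergyResult:
    median_double: float
    median_single: float
    u_statistic: float
    p_value: float
    n_double: int
    n_single: int
    method: str


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    n_set_term: int
    n_set_notterm: int
    n_notset_term: int
    n_notset_notterm: int
    odds_ratio: float
    p_value: float
    p_bonferroni: float


def call_differential(
    mutant: ExpressionTable,
    wild_type: ExpressionTable,
    threshold: float = 2.0,
    floor: float = 1.0,
    pseudocount: float = 0.1,
) -> list[DifferentialCall]:
    """Fold-change calls of mutant vs wild-type, feature by feature.

    Every feature receives a call; boundary cases (exactly ``threshold``-fold
    or exactly at the floor) are *unchanged* under the strict inequalities.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    if floor < 0:
        raise ValueError("floor must be >= 0")
    key = ["feature_id", "strand_class"]
    m = mutant.data.sort_values(key).reset_index(drop=True)
    w = wild_type.data.sort_values(key).reset_index(drop=True)
    if not (m["feature_id"].equals(w["feature_id"])
            and m["strand_class"].equals(w["strand_class"])):
        raise ValueError("mutant and wild-type tables have mismatched feature sets")

    mv = m["rpkm"].to_numpy()
    wv = w["rpkm"].to_numpy()
    with np.errstate(divide="ignore"):
        lfc = np.log2((mv + pseudocount) / (wv + pseudocount))
    max_rpkm = np.maximum(mv, wv)
    cut = math.log2(threshold)
    up = (lfc > cut) & (max_rpkm > floor)
    down = (lfc < -cut) & (max_rpkm > floor)

    calls = []
    for i in range(len(m)):
        direction = "up" if up[i] else ("down" if down[i] else "unchanged")
        calls.append(DifferentialCall(
            m["feature_id"].iloc[i], m["strand_class"].iloc[i],
            float(lfc[i]), float(max_rpkm[i]), direction))
    return calls


def calls_to_frame(calls: list[DifferentialCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.feature_id, c.strand_class, c.log2_fc, c.max_rpkm, c.direction) for c in calls],
        columns=["feature_id", "strand_class", "log2_fc", "max_rpkm", "direction"],
    )


def direction_set(calls: list[DifferentialCall], strand_class: str, direction: str) -> set[str]:
    """Feature ids with the given strand class and call direction."""
    return {c.feature_id for c in calls
            if c.strand_class == strand_class and c.direction == direction}


def category_fractions(
    calls_by_condition: dict[str, list[DifferentialCall]],
    n_protein_coding: int,
) -> pd.DataFrame:
    """Percent of protein-coding genes called per strand class and direction.

    Returns a tidy frame with columns condition, strand_class, direction,
    n_calls, percent.
    """
    if n_protein_coding <= 0:
        raise ValueError("empty gene universe")
    rows = []
    for cond, calls in calls_by_condition.items():
        for sc in ("sense", "antisense", "intergenic"):
            for d in ("up", "down"):
                n = sum(1 for c in calls if c.strand_class == sc and c.direction == d)
                rows.append((cond, sc, d, n, 100.0 * n / n_protein_coding))
    return pd.DataFrame(rows, columns=["condition", "strand_class", "direction",
                                       "n_calls", "percent"])


def hypergeometric_overlap(set_A: set, set_B: set, universe: set) -> OverlapResult:
    """Upper-tail hypergeometric p for the overlap of two gene sets.

    p = P[X >= |A n B|] with population |universe|, |A| successes and |B|
    draws.
    """
    if not (set_A <= universe and set_B <= universe):
        raise ValueError("A and B must be subsets of the universe")
    N, K, n = len(universe), len(set_A), len(set_B)
    k = len(set_A & set_B)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapResult(K, n, k, N, min(1.0, max(0.0, p)))


def synergy_test(fold_double: list[float], fold_single: list[float]) -> SynergyResult:
    """Two-sided Mann-Whitney U comparing fold-induction distributions.

    Uses the exact permutation null when both samples have n <= 8 and no
    ties; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(fold_double, dtype=float)
    y = np.asarray(fold_single, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    exact = x.size <= 8 and y.size <= 8 and np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return SynergyResult(
        median_double=float(np.median(x)),
        median_single=float(np.median(y)),
        u_statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        n_double=int(x.size),
        n_single=int(y.size),
        method=method,
    )


def fold_induction(
    mutant: ExpressionTable,
    wild_type: ExpressionTable,
    feature_ids: set[str],
    strand_class: str = "antisense",
    pseudocount: float = 0.1,
) -> pd.Series:
    """Per-feature fold induction (mut + psi)/(wt + psi) over a gene set."""
    mv = mutant.rpkm_series(strand_class)
    wv = wild_type.rpkm_series(strand_class)
    ids = sorted(feature_ids)
    return pd.Series(
        (mv[ids].to_numpy() + pseudocount) / (wv[ids].to_numpy() + pseudocount),
        index=ids,
    )


def term_enrichment(
    gene_set: set, term_map: dict[str, set], universe: set
) -> list[EnrichmentResult]:
    """One-sided Fisher's exact enrichment per term, Bonferroni-corrected.

    The 2x2 table for a term counts membership in ``gene_set`` against
    membership in the term, within ``universe``.
    """
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    n_terms = len(term_map)
    results = []
    for term in sorted(term_map):
        tset = term_map[term]
        if not tset <= universe:
            raise ValueError(f"term {term!r} contains ids outside the universe")
        a = len(gene_set & tset)
        b = len(gene_set) - a
        c = len(tset) - a
        d = len(universe) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        results.append(EnrichmentResult(
            term, a, b, c, d, float(odds), float(p), float(min(1.0, p * n_terms))))
    results.sort(key=lambda r: (r.p_value, r.term))
    return results
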