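"""Shared test utilities: random data builders and brute-force oracles.

The oracles here are intentionally naive (pure-python linear scans and
exhaustive enumerations) and independent of the package's data structures,
so they can serve as ground truth for the optimized implementations.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from antisenseq.annotation import GeneFeature, GenomeAnnotation


def make_random_annotation(rng, n_genes=200, n_chroms=2, chrom_len=20000,
                           min_len=60, max_len=400, coding_frac=0.85) -> GenomeAnnotation:
    """Densely packed random genes; overlaps between genes are frequent."""
    feats = []
    for i in range(n_genes):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, chrom_len - length))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "protein_coding" if rng.random() < coding_frac else "non_coding"
        feats.append(GeneFeature(f"g{i:04d}", chrom, start, start + length, strand, biotype))
    return GenomeAnnotation(feats, {f"chr{c}": chrom_len for c in range(1, n_chroms + 1)})


def make_random_reads(rng, annotation, n=1000, min_len=20, max_len=80) -> pd.DataFrame:
    chroms = sorted(annotation.chrom_sizes)
    ci = rng.integers(0, len(chroms), n)
    lens = rng.integers(min_len, max_len + 1, n)
    sizes = np.array([annotation.chrom_sizes[chroms[i]] for i in ci])
    starts = (rng.random(n) * (sizes - lens)).astype(np.int64)
    return pd.DataFrame({
        "chrom": np.array(chroms, dtype=object)[ci],
        "start": starts,
        "end": starts + lens,
        "strand": np.where(rng.random(n) < 0.5, "+", "-"),
    })


def brute_force_assign(chrom, start, end, strand, features,
                       convention="read_is_transcript_strand", min_overlap=1):
    """Naive read classification by scanning every feature."""
    if convention == "read_is_transcript_strand":
        eff = strand
    else:
        eff = "-" if strand == "+" else "+"
    same, opp = [], []
    for f in features:
        if f.chrom != chrom:
            continue
        ov = min(end, f.end) - max(start, f.start)
        if ov < min_overlap:
            continue
        (same if f.strand == eff else opp).append((ov, f.gene_id))
    if same:
        same.sort(key=lambda t: (-t[0], t[1]))
        return "sense", same[0][1]
    if len(opp) == 1:
        return "antisense", opp[0][1]
    if len(opp) >= 2:
        return "discarded", None
    return "intergenic", None


def hypergeom_tail_by_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P[|draw of n from N| intersects the first K elements in >= k] by
    enumerating every possible draw."""
    pop = list(range(N))
    A = set(range(K))
    total = hits = 0
    for draw in combinations(pop, n):
        total += 1
        if len(A & set(draw)) >= k:
            hits += 1
    return hits / total


def _u_statistic(xs, ys) -> float:
    u = 0.0
    for a in xs:
        for b in ys:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def mannwhitney_exact_by_enumeration(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating every relabeling."""
    pooled = list(x) + list(y)
    n1 = len(x)
    idx = range(len(pooled))
    u_obs = _u_statistic(x, y)
    us = []
    for comb in combinations(idx, n1):
        cset = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in cset]
        us.append(_u_statistic(xs, ys))
    us = np.asarray(us)
    lo = float((us <= u_obs + 1e-12).mean())
    hi = float((us >= u_obs - 1e-12).mean())
    return min(1.0, 2.0 * min(lo, hi))
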