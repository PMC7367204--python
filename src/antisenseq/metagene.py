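"""Metagene matrices, profiles, occupancy clusters and the CPS trough.

Rows are always oriented 5' -> 3': for a minus-strand gene the genomic
window is mirrored so bin 0 is the 5'-most bin.  Anchored matrices average
per-base signal in fixed windows around the TSS or CPS; scaled matrices
resample each gene body (with configurable offsets from the TSS and CPS)
into a fixed number of equal-width bins via an exact cumulative-sum
integral, so a linear ramp stays linear whatever the gene length.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .annotation import GeneFeature
from .chip import CoverageTrack

log = logging.getLogger(__name__)

__all__ = [
    "AnchorSpec",
    "MetageneMatrix",
    "GeneClusterAssignment",
    "anchored_matrix",
    "scaled_matrix",
    "profile",
    "cluster_genes",
    "trough_statistic",
]


@dataclass(frozen=True)
class AnchorSpec:
    anchor: str  # TSS | CPS | scaled
    upstream_bp: int = 500
    downstream_bp: int = 500
    n_body_bins: int = 100
    from_tss_bp: int = 200
    before_cps_bp: int = 200

    def __post_init__(self):
        if self.anchor not in ("TSS", "CPS", "scaled"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("flanks must be >= 0")
        if self.anchor == "scaled" and self.n_body_bins < 1:
            raise ValueError("n_body_bins must be >= 1")


@dataclass
class MetageneMatrix:
    gene_ids: list[str]
    values: np.ndarray  # genes x bins
    anchor_spec: AnchorSpec
    bin_size: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("row count does not match gene list")

    def to_tsv(self, path, sidecar: str | None = None) -> None:
        df = pd.DataFrame(self.values, columns=[f"bin{i}" for i in range(self.values.shape[1])])
        df.insert(0, "gene_id", self.gene_ids)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        if sidecar:
            with open(sidecar, "w") as fh:
                json.dump({"anchor_spec": asdict(self.anchor_spec),
                           "bin_size": self.bin_size}, fh, indent=1, sort_keys=True)
                fh.write("\n")


@dataclass
class GeneClusterAssignment:
    clusters: dict[str, int]  # gene_id -> cluster index (0 = highest scores)
    scores: dict[str, float]
    order: list[str]  # gene ids sorted by descending score (ties: gene_id)


def _window(gene: GeneFeature, anchor: str, up: int, down: int) -> tuple[int, int]:
    """Genomic [start, end) of an oriented anchor window."""
    a = gene.tss if anchor == "TSS" else gene.cps
    if gene.strand == "+":
        return a - up, a + down
    return a - down + 1, a + up + 1


def anchored_matrix(
    track: CoverageTrack,
    genes: list[GeneFeature],
    spec: AnchorSpec,
) -> MetageneMatrix:
    """Per-gene mean signal in bins around the TSS or CPS.

    Genes whose window falls off the chromosome (or off the track) are
    dropped with a log message; the remaining rows are strand-oriented.
    """
    if spec.anchor not in ("TSS", "CPS"):
        raise ValueError("anchored_matrix needs anchor TSS or CPS")
    if not genes:
        raise ValueError("empty gene list")
    if track.bin_size != 1:
        raise ValueError("anchored_matrix expects a per-base track")
    width = spec.upstream_bp + spec.downstream_bp
    bin_size = _infer_bin(width)
    n_bins = width // bin_size
    rows, kept = [], []
    for g in genes:
        v = track.values.get(g.chrom)
        if v is None:
            log.info("dropping %s: no track for %s", g.gene_id, g.chrom)
            continue
        s, e = _window(g, spec.anchor, spec.upstream_bp, spec.downstream_bp)
        if s < 0 or e > len(v):
            log.info("dropping %s: window [%d, %d) off chromosome", g.gene_id, s, e)
            continue
        w = v[s:e]
        if g.strand == "-":
            w = w[::-1]
        rows.append(w.reshape(n_bins, bin_size).mean(axis=1))
        kept.append(g.gene_id)
    if not rows:
        raise ValueError("no gene window fits the track")
    return MetageneMatrix(kept, np.vstack(rows), spec, bin_size)


def _infer_bin(width: int, target: int = 10) -> int:
    """Largest divisor of the window width that is <= the target bin size."""
    for b in range(min(target, width), 0, -1):
        if width % b == 0:
            return b
    return 1


def _resample_equal_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean signal in n equal-width bins, exact for fractional bin edges."""
    csum = np.concatenate([[0.0], np.cumsum(values)])
    edges = np.linspace(0.0, len(values), n_bins + 1)
    integral = np.interp(edges, np.arange(len(values) + 1), csum)
    widths = np.diff(edges)
    return np.diff(integral) / widths


def scaled_matrix(
    track: CoverageTrack,
    genes: list[GeneFeature],
    spec: AnchorSpec,
) -> MetageneMatrix:
    """Gene bodies rescaled to a common number of bins.

    The body runs from ``from_tss_bp`` downstream of the TSS to
    ``before_cps_bp`` upstream of the CPS; genes too short for one base per
    bin boundary (body < n_body_bins is allowed, body <= 0 is not) are
    dropped with a log message.
    """
    if not genes:
        raise ValueError("empty gene list")
    if track.bin_size != 1:
        raise ValueError("scaled_matrix expects a per-base track")
    rows, kept = [], []
    for g in genes:
        v = track.values.get(g.chrom)
        if v is None:
            continue
        if g.strand == "+":
            s, e = g.start + spec.from_tss_bp, g.end - spec.before_cps_bp
        else:
            s, e = g.start + spec.before_cps_bp, g.end - spec.from_tss_bp
        if e - s < spec.n_body_bins or s < 0 or e > len(v):
            log.info("dropping %s: body [%d, %d) too short or off chromosome",
                     g.gene_id, s, e)
            continue
        body = v[s:e]
        if g.strand == "-":
            body = body[::-1]
        rows.append(_resample_equal_bins(body, spec.n_body_bins))
        kept.append(g.gene_id)
    if not rows:
        raise ValueError("all genes too short for the scaled body")
    return MetageneMatrix(kept, np.vstack(rows), spec, bin_size=0)


def profile(matrix: MetageneMatrix, stat: str = "mean") -> np.ndarray:
    """Column-wise mean or median, ignoring NaN-masked cells."""
    if matrix.values.size == 0:
        raise ValueError("empty matrix")
    if stat not in ("mean", "median"):
        raise ValueError(f"unknown statistic {stat!r}")
    with np.errstate(invalid="ignore"):
        valid = np.isfinite(matrix.values).sum(axis=0)
        if (valid == 0).any():
            log.warning("%d profile bins have no valid cells (NaN)", int((valid == 0).sum()))
        fn = np.nanmean if stat == "mean" else np.nanmedian
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return fn(matrix.values, axis=0)


def cluster_genes(
    scores: dict[str, float],
    mode: str = "fixed_size",
    k_or_size: int = 500,
) -> GeneClusterAssignment:
    """Order genes by descending score and slice into clusters.

    ``fixed_size`` makes consecutive blocks of ``k_or_size`` genes (the last
    block may be smaller); ``quantile`` makes ``k_or_size`` groups whose
    sizes differ by at most one.  Ties in the score are broken by gene_id so
    the ordering is deterministic.
    """
    if not scores:
        raise ValueError("empty score map")
    if k_or_size < 1:
        raise ValueError("k_or_size must be >= 1")
    if any(not np.isfinite(v) for v in scores.values()):
        raise ValueError("scores must be finite")
    order = sorted(scores, key=lambda g: (-scores[g], g))
    clusters: dict[str, int] = {}
    if mode == "fixed_size":
        for i, g in enumerate(order):
            clusters[g] = i // k_or_size
    elif mode == "quantile":
        for ci, chunk in enumerate(np.array_split(np.asarray(order, dtype=object), k_or_size)):
            for g in chunk:
                clusters[g] = ci
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GeneClusterAssignment(clusters, dict(scores), order)


def trough_statistic(profile_values: np.ndarray, anchor_bin: int, flank_bins: int) -> float:
    """Depth of a trough at an anchor, relative to its shoulders.

    Returns (minimum within anchor +/- flank_bins) / (mean of the two
    shoulder bins at anchor -/+ flank_bins).  A flat profile gives 1.0; a
    multiplicative dip to fraction f of the local level gives ~f.
    """
    p = np.asarray(profile_values, dtype=float)
    lo, hi = anchor_bin - flank_bins, anchor_bin + flank_bins
    if lo < 0 or hi >= len(p):
        raise ValueError("trough window exceeds profile bounds")
    shoulders = 0.5 * (p[lo] + p[hi])
    if shoulders == 0 or not np.isfinite(shoulders):
        raise ValueError("zero or undefined shoulder level")
    return float(np.nanmin(p[lo: hi + 1]) / shoulders)
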