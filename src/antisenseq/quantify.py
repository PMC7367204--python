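"""Stranded read classification and RPKM quantification.

Reads are classified against a gene annotation into *sense* (same strand as
an overlapping gene), *antisense* (opposite strand of exactly one gene;
reads antisense to more than one gene are discarded as ambiguous),
*intergenic* (no gene overlap) or *discarded*.  Per-gene counts are
normalized to reads per kilobase per million library reads (RPKM), computed
separately for the sense and antisense strand of each gene, and replicate
tables are combined by arithmetic mean.

Classification rules
--------------------
The effective transcript strand of a read depends on the library protocol:
``read_is_transcript_strand`` (default) takes the read strand at face value;
``read_is_opposite`` flips it (dUTP-style libraries).  Given the effective
strand:

1. overlaps >= 1 gene on the same strand -> sense, assigned to the gene with
   the largest overlap (ties broken by lexicographically smallest gene_id);
2. else overlaps exactly one opposite-strand gene -> antisense to that gene;
3. else overlaps >= 2 opposite-strand genes -> discarded (ambiguous);
4. else -> intergenic, tallied into fixed-width windows between loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneFeature, GenomeAnnotation, IntervalIndex

__all__ = [
    "Assignment",
    "StrandedCounts",
    "ExpressionTable",
    "assign_read",
    "classify_reads",
    "count_reads",
    "intergenic_windows",
    "rpkm_normalize",
    "average_replicates",
    "read_reads",
]

CONVENTIONS = ("read_is_transcript_strand", "read_is_opposite")
READ_COLUMNS = ["chrom", "start", "end", "strand"]


@dataclass(frozen=True)
class Assignment:
    read_id: str
    category: str  # sense | antisense | intergenic | discarded
    gene_id: str | None

    def __post_init__(self):
        has_gene = self.gene_id is not None
        if has_gene != (self.category in ("sense", "antisense")):
            raise ValueError("gene_id must be set iff category is sense/antisense")


def _effective_plus(strand: str, convention: str) -> bool:
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    is_plus = strand == "+"
    return is_plus if convention == "read_is_transcript_strand" else not is_plus


def assign_read(
    read,
    index: IntervalIndex,
    convention: str = "read_is_transcript_strand",
    min_overlap: int = 1,
) -> Assignment:
    """Classify a single stranded read interval.

    ``read`` is a (read_id, chrom, start, end, strand) tuple or any object
    with those attributes.
    """
    if isinstance(read, (tuple, list)):
        read_id, chrom, start, end, strand = read
    else:
        read_id, chrom, start, end, strand = (
            read.read_id, read.chrom, read.start, read.end, read.strand)
    eff_plus = _effective_plus(strand, convention)
    hits = index.query(chrom, start, end)
    same: list[tuple[int, str]] = []
    n_opp = 0
    opp_gene = None
    for g in hits:
        ov = min(end, g.end) - max(start, g.start)
        if ov < min_overlap:
            continue
        if (g.strand == "+") == eff_plus:
            same.append((ov, g.gene_id))
        else:
            n_opp += 1
            opp_gene = g.gene_id
    if same:
        same.sort(key=lambda t: (-t[0], t[1]))
        return Assignment(read_id, "sense", same[0][1])
    if n_opp == 1:
        return Assignment(read_id, "antisense", opp_gene)
    if n_opp >= 2:
        return Assignment(read_id, "discarded", None)
    return Assignment(read_id, "intergenic", None)


def classify_reads(
    reads: pd.DataFrame,
    annotation: GenomeAnnotation,
    convention: str = "read_is_transcript_strand",
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Vectorized classification of a read table.

    ``reads`` needs columns chrom, start, end, strand.  Returns a DataFrame
    (same index) with columns ``category`` and ``gene_id``.  Semantics are
    identical to :func:`assign_read` applied row-wise.
    """
    n = len(reads)
    category = np.full(n, "intergenic", dtype=object)
    gene_out = np.full(n, None, dtype=object)

    chroms = reads["chrom"].to_numpy()
    starts = reads["start"].to_numpy(dtype=np.int64)
    ends = reads["end"].to_numpy(dtype=np.int64)
    eff_plus = reads["strand"].to_numpy() == "+"
    if convention == "read_is_opposite":
        eff_plus = ~eff_plus
    elif convention != "read_is_transcript_strand":
        raise ValueError(f"unknown convention {convention!r}")

    unknown = set(np.unique(chroms)) - set(annotation.chrom_sizes)
    if unknown:
        raise KeyError(f"reads on unknown chromosome(s): {sorted(unknown)}")

    by_chrom: dict[str, list[GeneFeature]] = {}
    for f in annotation.features:
        by_chrom.setdefault(f.chrom, []).append(f)

    for chrom, gfs in by_chrom.items():
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        order = np.argsort(starts[sel], kind="stable")
        sel = sel[order]
        rs, re_, ep = starts[sel], ends[sel], eff_plus[sel]
        max_len = int((re_ - rs).max())
        m = sel.size

        # lexicographic rank of gene ids for the sense tie-break
        ids = [g.gene_id for g in gfs]
        rank_of = {gid: r for r, gid in enumerate(sorted(ids))}

        best_ov = np.zeros(m, dtype=np.int64)
        best_rank = np.full(m, len(ids), dtype=np.int64)
        best_gi = np.full(m, -1, dtype=np.int64)
        opp_cnt = np.zeros(m, dtype=np.int64)
        opp_gi = np.full(m, -1, dtype=np.int64)

        for gi, g in enumerate(gfs):
            lo = int(np.searchsorted(rs, g.start - max_len, side="left"))
            hi = int(np.searchsorted(rs, g.end, side="left"))
            if lo >= hi:
                continue
            ov = np.minimum(re_[lo:hi], g.end) - np.maximum(rs[lo:hi], g.start)
            hit = ov >= min_overlap
            if not hit.any():
                continue
            same = hit & (ep[lo:hi] == (g.strand == "+"))
            r = rank_of[g.gene_id]
            upd = same & (
                (ov > best_ov[lo:hi])
                | ((ov == best_ov[lo:hi]) & (r < best_rank[lo:hi]))
            )
            if upd.any():
                idx = np.flatnonzero(upd) + lo
                best_ov[idx] = ov[upd]
                best_rank[idx] = r
                best_gi[idx] = gi
            opp = hit & ~same
            if opp.any():
                idx = np.flatnonzero(opp) + lo
                opp_cnt[idx] += 1
                opp_gi[idx] = gi

        gid_arr = np.array(ids, dtype=object)
        is_sense = best_gi >= 0
        is_anti = ~is_sense & (opp_cnt == 1)
        is_disc = ~is_sense & (opp_cnt >= 2)
        category[sel[is_sense]] = "sense"
        gene_out[sel[is_sense]] = gid_arr[best_gi[is_sense]]
        category[sel[is_anti]] = "antisense"
        gene_out[sel[is_anti]] = gid_arr[opp_gi[is_anti]]
        category[sel[is_disc]] = "discarded"

    return pd.DataFrame({"category": category, "gene_id": gene_out}, index=reads.index)


def intergenic_windows(annotation: GenomeAnnotation, width: int = 500) -> pd.DataFrame:
    """Fixed-width windows tiling the regions between annotated loci.

    Both coding and non-coding loci bound the intergenic space.  The last
    window of each gap may be shorter than ``width``.
    """
    rows = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in annotation.chrom_sizes}
    for f in annotation.features:
        occupied[f.chrom].append((f.start, f.end))
    for chrom in sorted(annotation.chrom_sizes):
        size = annotation.chrom_sizes[chrom]
        merged: list[list[int]] = []
        for s, e in sorted(occupied[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        gaps = []
        prev = 0
        for s, e in merged:
            if s > prev:
                gaps.append((prev, s))
            prev = max(prev, e)
        if prev < size:
            gaps.append((prev, size))
        for gs, ge in gaps:
            for ws in range(gs, ge, width):
                we = min(ws + width, ge)
                rows.append((f"ig_{chrom}_{ws}", chrom, ws, we))
    return pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end"])


@dataclass
class StrandedCounts:
    """Per-gene sense/antisense counts plus intergenic window tallies."""

    gene_counts: pd.DataFrame  # index gene_id; columns sense, antisense
    intergenic_counts: pd.DataFrame  # feature_id, chrom, start, end, count
    discarded: int
    n_reads: int
    sample: str | None = None

    @property
    def sense_total(self) -> int:
        return int(self.gene_counts["sense"].sum())

    @property
    def antisense_total(self) -> int:
        return int(self.gene_counts["antisense"].sum())

    @property
    def intergenic_total(self) -> int:
        return int(self.intergenic_counts["count"].sum())

    @property
    def assigned_total(self) -> int:
        """Reads assigned to any category except discarded."""
        return self.sense_total + self.antisense_total + self.intergenic_total

    def check_conservation(self) -> None:
        total = self.assigned_total + self.discarded
        if total != self.n_reads:
            raise AssertionError(
                f"read conservation violated: {total} classified vs {self.n_reads} input"
            )


def count_reads(
    reads: pd.DataFrame,
    annotation: GenomeAnnotation,
    convention: str = "read_is_transcript_strand",
    min_overlap: int = 1,
    intergenic_bin: int = 500,
    sample: str | None = None,
) -> StrandedCounts:
    """Aggregate read classifications into per-feature counts.

    Intergenic reads are placed into the window containing the read midpoint
    (equivalent to largest-overlap for contiguous windows, left window on an
    exact tie).
    """
    cls = classify_reads(reads, annotation, convention, min_overlap)
    gene_ids = [f.gene_id for f in annotation.features]
    gc = pd.DataFrame(0, index=pd.Index(gene_ids, name="gene_id"),
                      columns=["sense", "antisense"], dtype=np.int64)
    for cat in ("sense", "antisense"):
        vc = cls.loc[cls["category"] == cat, "gene_id"].value_counts()
        gc.loc[vc.index, cat] = vc.to_numpy()

    win = intergenic_windows(annotation, intergenic_bin)
    win = win.assign(count=0)
    ig_mask = (cls["category"] == "intergenic").to_numpy()
    if ig_mask.any() and len(win):
        chroms = reads["chrom"].to_numpy()[ig_mask]
        mids = ((reads["start"].to_numpy() + reads["end"].to_numpy() - 1) // 2)[ig_mask]
        for chrom, sub in win.groupby("chrom", sort=False):
            rmask = chroms == chrom
            if not rmask.any():
                continue
            ws = sub["start"].to_numpy()
            idx = np.clip(np.searchsorted(ws, mids[rmask], side="right") - 1, 0, len(ws) - 1)
            bc = np.bincount(idx, minlength=len(ws))
            win.loc[sub.index, "count"] = sub["count"].to_numpy() + bc

    counts = StrandedCounts(
        gene_counts=gc,
        intergenic_counts=win,
        discarded=int((cls["category"] == "discarded").sum()),
        n_reads=len(reads),
        sample=sample,
    )
    counts.check_conservation()
    return counts


@dataclass
class ExpressionTable:
    """Per-feature, per-strand-class RPKM values.

    ``data`` has columns feature_id, strand_class, length, rpkm.  Replicate
    averaging is recorded in ``n_replicates``.
    """

    data: pd.DataFrame
    n_replicates: int = 1
    sample: str | None = None

    def __post_init__(self):
        missing = {"feature_id", "strand_class", "length", "rpkm"} - set(self.data.columns)
        if missing:
            raise ValueError(f"ExpressionTable missing columns {sorted(missing)}")

    def rpkm_series(self, strand_class: str) -> pd.Series:
        sub = self.data[self.data["strand_class"] == strand_class]
        return pd.Series(sub["rpkm"].to_numpy(), index=sub["feature_id"].to_numpy())

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "sample", self.sample if self.sample is not None else ".")
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, n_replicates: int = 1) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t")
        sample = None
        if "sample" in df.columns:
            vals = df["sample"].unique()
            sample = None if list(vals) == ["."] else str(vals[0])
            df = df.drop(columns="sample")
        return cls(df.reset_index(drop=True), n_replicates=n_replicates, sample=sample)


def rpkm_normalize(
    counts: StrandedCounts,
    annotation: GenomeAnnotation,
    library: str = "assigned",
    antisense_coding_only: bool = True,
) -> ExpressionTable:
    """RPKM = count * 1e9 / (feature_length_bp * library_size).

    ``library='assigned'`` (default) counts sense + antisense + intergenic
    reads and excludes discarded ambiguous reads; ``library='all'`` uses
    every input read.  Antisense rows are emitted for protein-coding genes
    only unless ``antisense_coding_only=False``.
    """
    if library == "assigned":
        lib = counts.assigned_total
    elif library == "all":
        lib = counts.n_reads
    else:
        raise ValueError(f"unknown library definition {library!r}")
    if lib <= 0:
        raise ValueError("library size is zero; cannot normalize")

    feats = {f.gene_id: f for f in annotation.features}
    rows = []
    for gid, row in counts.gene_counts.iterrows():
        f = feats[gid]
        rows.append((gid, "sense", f.length,
                     row["sense"] * 1e9 / (f.length * lib)))
        if f.biotype == "protein_coding" or not antisense_coding_only:
            rows.append((gid, "antisense", f.length,
                         row["antisense"] * 1e9 / (f.length * lib)))
    for _, w in counts.intergenic_counts.iterrows():
        length = w["end"] - w["start"]
        rows.append((w["feature_id"], "intergenic", length,
                     w["count"] * 1e9 / (length * lib)))
    df = pd.DataFrame(rows, columns=["feature_id", "strand_class", "length", "rpkm"])
    return ExpressionTable(df, n_replicates=1, sample=counts.sample)


def average_replicates(tables: list[ExpressionTable]) -> ExpressionTable:
    """Arithmetic mean of replicate RPKM tables over identical feature sets."""
    if not tables:
        raise ValueError("no replicate tables given")
    key = ["feature_id", "strand_class"]
    ref = tables[0].data.sort_values(key).reset_index(drop=True)
    stacked = np.empty((len(tables), len(ref)))
    for i, t in enumerate(tables):
        d = t.data.sort_values(key).reset_index(drop=True)
        if not (d["feature_id"].equals(ref["feature_id"])
                and d["strand_class"].equals(ref["strand_class"])):
            raise ValueError("replicate tables have mismatched feature sets")
        stacked[i] = d["rpkm"].to_numpy()
    out = ref.copy()
    out["rpkm"] = stacked.mean(axis=0)
    return ExpressionTable(out, n_replicates=len(tables))


def read_reads(path) -> pd.DataFrame:
    """Read stranded read intervals from BED6 (or SAM via pysam).

    SAM strand comes from the 0x10 flag; unmapped records are skipped.
    """
    p = str(path)
    if p.endswith(".sam") or p.endswith(".bam"):
        import pysam

        rows = []
        with pysam.AlignmentFile(p, check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                rows.append((rec.reference_name, rec.reference_start,
                             rec.reference_end, "-" if rec.is_reverse else "+"))
        return pd.DataFrame(rows, columns=READ_COLUMNS)
    try:
        df = pd.read_csv(p, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "name", "score", "strand"],
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty:
        return pd.DataFrame({"chrom": pd.Series(dtype=object),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64),
                             "strand": pd.Series(dtype=object)})
    return df[READ_COLUMNS].copy()
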