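"""Gene annotations and stranded interval queries.

All coordinates are 0-based half-open internally.  GFF3 (1-based closed) is
converted at the parsing boundary; BED is taken as-is.  The transcription
start site (TSS) and cleavage/polyadenylation site (CPS) are derived from the
feature endpoints: for a ``+`` strand gene TSS = start and CPS = end - 1, for
a ``-`` strand gene TSS = end - 1 and CPS = start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

__all__ = [
    "GeneFeature",
    "GenomeAnnotation",
    "IntervalIndex",
    "AnnotationParseError",
    "read_annotation",
    "write_annotation",
    "read_chrom_sizes",
    "write_chrom_sizes",
]

BIOTYPES = ("protein_coding", "non_coding")


class AnnotationParseError(ValueError):
    """Raised when an annotation file cannot be parsed; names the line."""


@dataclass(frozen=True)
class GeneFeature:
    """A stranded gene-level interval (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.gene_id}: unknown biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site (base coordinate)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def cps(self) -> int:
        """Cleavage/polyadenylation site (base coordinate)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class GenomeAnnotation:
    """A set of gene features plus chromosome lengths.

    Features may overlap each other; disambiguation of overlapping genes is
    the read classifier's job, not the annotation's.
    """

    features: list[GeneFeature]
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.gene_id in seen:
                raise ValueError(f"duplicate gene_id {f.gene_id!r}")
            seen.add(f.gene_id)
        if self.chrom_sizes:
            for f in self.features:
                size = self.chrom_sizes.get(f.chrom)
                if size is None:
                    raise ValueError(f"{f.gene_id}: chromosome {f.chrom!r} not in chrom_sizes")
                if f.end > size:
                    raise ValueError(
                        f"{f.gene_id}: end {f.end} exceeds {f.chrom} length {size}"
                    )
        else:
            # infer sizes from the right-most feature per chromosome
            for f in self.features:
                cur = self.chrom_sizes.get(f.chrom, 0)
                self.chrom_sizes[f.chrom] = max(cur, f.end)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def by_id(self, gene_id: str) -> GeneFeature:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        raise KeyError(gene_id)

    def protein_coding(self) -> list[GeneFeature]:
        return [f for f in self.features if f.biotype == "protein_coding"]


class IntervalIndex:
    """Stranded interval index over an annotation.

    Query results are, by contract, identical to a brute-force linear scan
    over all features; deterministic order (start, then gene_id).
    """

    def __init__(self, annotation: GenomeAnnotation):
        self.annotation = annotation
        self._trees: dict[str, IntervalTree] = {}
        for f in annotation.features:
            self._trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
        # chromosomes with sizes but no genes still answer queries (empty)
        for chrom in annotation.chrom_sizes:
            self._trees.setdefault(chrom, IntervalTree())

    def query(self, chrom: str, start: int, end: int) -> list[GeneFeature]:
        if start >= end:
            raise ValueError(f"require start < end, got [{start}, {end})")
        if chrom not in self._trees:
            raise KeyError(f"unknown chromosome {chrom!r}")
        hits = [iv.data for iv in self._trees[chrom].overlap(start, end)]
        hits.sort(key=lambda f: (f.start, f.gene_id))
        return hits


# Alias used by callers in operation style.
def query_overlaps(index: IntervalIndex, chrom: str, start: int, end: int) -> list[GeneFeature]:
    return index.query(chrom, start, end)


def _infer_format(path: str) -> str:
    p = str(path).lower()
    if p.endswith((".gff", ".gff3")):
        return "gff3"
    if p.endswith(".bed"):
        return "bed6"
    raise ValueError(f"cannot infer annotation format from {path!r}; pass format=")


def read_annotation(
    path,
    format: str | None = None,
    chrom_sizes: dict[str, int] | str | None = None,
    feature_type: str = "gene",
) -> GenomeAnnotation:
    """Read a gene-level annotation from GFF3 or BED6.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open.
    Chromosome sizes come from ``##sequence-region`` pragmas (GFF3) or from
    the ``chrom_sizes`` argument (dict, or path to a two-column TSV); for BED
    without sizes they are inferred from feature extents.
    """
    fmt = format or _infer_format(path)
    if isinstance(chrom_sizes, (str, bytes)) or hasattr(chrom_sizes, "read_text"):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    sizes: dict[str, int] = dict(chrom_sizes or {})
    features: list[GeneFeature] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser")):
                continue
            if fmt == "gff3" and line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    sizes[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            try:
                if fmt == "gff3":
                    f = _parse_gff3_line(line, feature_type)
                elif fmt == "bed6":
                    f = _parse_bed6_line(line)
                else:
                    raise ValueError(f"unknown format {fmt!r}")
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
            if f is not None:
                features.append(f)
    return GenomeAnnotation(features, sizes)


def _parse_gff3_line(line: str, feature_type: str) -> GeneFeature | None:
    cols = line.split("\t")
    if len(cols) != 9:
        raise ValueError(f"expected 9 tab-separated columns, got {len(cols)}")
    chrom, _source, ftype, start1, end1, _score, strand, _frame, attrs = cols
    if ftype != feature_type:
        return None
    attr = dict(
        kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
    )
    gene_id = attr.get("ID") or attr.get("gene_id")
    if gene_id is None:
        raise ValueError("record lacks ID attribute")
    biotype = attr.get("biotype", attr.get("gene_biotype", "protein_coding"))
    return GeneFeature(gene_id, chrom, int(start1) - 1, int(end1), strand, biotype)


def _parse_bed6_line(line: str) -> GeneFeature:
    cols = line.split("\t")
    if len(cols) == 1:
        cols = line.split()
    if len(cols) < 6:
        raise ValueError(f"expected >= 6 BED columns, got {len(cols)}")
    chrom, start, end, name, score, strand = cols[:6]
    biotype = "non_coding" if score == "1" else "protein_coding"
    return GeneFeature(name, chrom, int(start), int(end), strand, biotype)


def write_annotation(annotation: GenomeAnnotation, path, format: str | None = None) -> None:
    """Write GFF3 (with ##sequence-region pragmas) or BED6.

    BED6 stores the biotype in the score column (0 = protein_coding,
    1 = non_coding) so that round-trips preserve it.
    """
    fmt = format or _infer_format(path)
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            for chrom in sorted(annotation.chrom_sizes):
                fh.write(f"##sequence-region {chrom} 1 {annotation.chrom_sizes[chrom]}\n")
            for f in annotation.features:
                fh.write(
                    f"{f.chrom}\tantisenseq\tgene\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t"
                    f"ID={f.gene_id};biotype={f.biotype}\n"
                )
        elif fmt == "bed6":
            for f in annotation.features:
                score = "1" if f.biotype == "non_coding" else "0"
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.gene_id}\t{score}\t{f.strand}\n")
        else:
            raise ValueError(f"unknown format {fmt!r}")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")
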