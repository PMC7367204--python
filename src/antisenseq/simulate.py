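"""Synthetic study generator with planted ground truth.

Emulates a fission-yeast-style experiment: four strains (wild type, an
analog-sensitive kinase mutant ``cdk9as``, a histone H2B ubiquitylation-site
mutant ``htb1KR``, and the double mutant) each treated with vehicle (DMSO)
or the inhibitor (3MBPP1), in replicate stranded RNA-seq libraries, plus
spike-in ChIP coverage tracks.  Antisense induction is planted in four
disjoint gene subsets:

``cdk9_only``    induced whenever Cdk9 is inhibited (cdk9as allele + drug);
``h2bub1_only``  induced whenever H2Bub1 is absent (htb1KR allele);
``shared``       induced by either perturbation alone (``single_fold``) and
                 super-additively by both (``double_fold``);
``double_only``  induced only when both pathways are lost.

Sense expression levels are calibrated so that the configured RPKM values
are (in expectation) the RPKM values the quantifier measures: the sum of
rpkm x length over all emitted features is scaled to 1e9, the identity any
real RPKM table satisfies.  Reads are fixed-length single-end intervals on
the transcript strand, placed fully inside their feature; counts are exact
(rounded expectation), Poisson, or negative binomial.

ChIP tracks are deterministic per-base shapes: a 5' ramp, a gene-body
plateau proportional to a per-gene expression score, an optional
TSS-proximal peak, and a multiplicative trough over the CPS whose depth can
be set to zero to emulate the effaced-trough regime of H2Bub1-deficient
cells.  Spike-in material is represented as scalar read counts per sample;
IP-efficiency and depth factors perturb observed tracks and spike counts
together so spike normalization can cancel them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import GeneFeature, GenomeAnnotation, write_annotation, write_chrom_sizes
from .chip import CoverageTrack, SpikeInStats
from .quantify import intergenic_windows

__all__ = [
    "STRAINS",
    "TREATMENTS",
    "SUBSETS",
    "RnaSeqConfig",
    "ChipAntibodyConfig",
    "ChipConditionConfig",
    "ChipConfig",
    "ChipSample",
    "SyntheticDataset",
    "perturbations",
    "antisense_fold",
    "generate_annotation_truth",
    "planted_set",
    "sample_reads",
    "generate_rnaseq",
    "generate_chip",
    "write_dataset",
    "read_dataset",
]

STRAINS = ("WT", "cdk9as", "htb1KR", "cdk9as_htb1KR")
TREATMENTS = ("DMSO", "3MBPP1")
SUBSETS = ("none", "cdk9_only", "h2bub1_only", "shared", "double_only")


@dataclass
class RnaSeqConfig:
    """Generator parameters for the RNA-seq arm of the design."""

    n_genes: int = 2000
    n_chroms: int = 3
    gene_length_log_mean: float = float(np.log(1300.0))
    gene_length_log_sigma: float = 0.35
    gene_length_min: int = 500
    gene_length_max: int = 4000
    gap_min: int = 200
    gap_max: int = 1000
    read_length: int = 50
    depth: int = 1_000_000
    replicates: int = 2
    noise: str = "poisson"  # none | poisson | nbinom
    nb_dispersion: float = 10.0  # negative binomial size parameter
    # planted antisense subsets
    n_cdk9_only: int = 60
    n_h2bub1_only: int = 60
    n_shared: int = 30
    n_double_only: int = 400
    single_fold: float = 4.0
    double_fold: float = 12.0
    double_only_fold: float = 4.0
    planted_baseline_min: float = 5.0
    planted_baseline_max: float = 15.0
    # background expression
    sense_log_sigma: float = 1.0
    background_antisense_log_median: float = float(np.log(0.05))
    background_antisense_log_sigma: float = 0.5
    intergenic_rpkm: float = 0.05
    intergenic_bin: int = 500

    def validate(self) -> None:
        n_planted = self.n_cdk9_only + self.n_h2bub1_only + self.n_shared + self.n_double_only
        if n_planted > self.n_genes:
            raise ValueError(f"planted subsets ({n_planted}) exceed n_genes ({self.n_genes})")
        if self.depth <= 0:
            raise ValueError("library depth must be positive")
        if self.noise not in ("none", "poisson", "nbinom"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.gene_length_min <= self.read_length:
            raise ValueError("genes must be longer than one read")


@dataclass
class ChipAntibodyConfig:
    """Gene-body shape for one antibody's IP track."""

    name: str
    plateau_scale: float = 20.0  # mean plateau coverage (arbitrary units)
    ramp_len: int = 100
    tss_peak_height: float = 0.0  # amplitude as a multiple of the plateau
    tss_peak_center: int = 50
    tss_peak_sigma: int = 50
    trough_depth: float = 0.6  # fraction removed over the CPS (0 = no trough)
    trough_halfwidth: int = 30
    post_cps: int = 100
    decay_len: int = 100
    background: float = 0.5

    def validate(self) -> None:
        for name in ("plateau_scale", "ramp_len", "tss_peak_height", "tss_peak_sigma",
                     "trough_depth", "trough_halfwidth", "post_cps", "decay_len",
                     "background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.name}: negative shape parameter {name}")
        if self.trough_depth > 1:
            raise ValueError(f"{self.name}: trough_depth must be in [0, 1]")


@dataclass
class ChipConditionConfig:
    """Per-condition biological and technical modifiers."""

    name: str
    signal_factor: float = 1.0  # biological occupancy change
    trough_depth_override: float | None = None  # 0.0 emulates the effaced trough
    depth_factor: float = 1.0  # technical sequencing-depth change
    ip_efficiency: float = 1.0  # technical IP recovery change


@dataclass
class ChipConfig:
    antibodies: list[ChipAntibodyConfig] = field(default_factory=lambda: [
        ChipAntibodyConfig("RNAPII", tss_peak_height=0.5),
        ChipAntibodyConfig("Spt5"),
        ChipAntibodyConfig("pSpt5", plateau_scale=10.0),
        ChipAntibodyConfig("H2B", trough_depth=0.0, plateau_scale=15.0),
        ChipAntibodyConfig("H2Bub1", plateau_scale=8.0),
    ])
    conditions: list[ChipConditionConfig] = field(default_factory=lambda: [
        ChipConditionConfig("control"),
        ChipConditionConfig("h2bub1_deficient", trough_depth_override=0.0),
    ])
    input_coverage: float = 20.0
    spike_fraction: float = 0.10
    expression_log_sigma: float = 0.5
    read_length: int = 50


@dataclass
class ChipSample:
    ip_track: CoverageTrack
    input_track: CoverageTrack
    spike: SpikeInStats


@dataclass
class SyntheticDataset:
    annotation: GenomeAnnotation
    truth: pd.DataFrame
    samples: dict = field(default_factory=dict)  # (strain, treatment, rep) -> reads
    chip: dict = field(default_factory=dict)  # (antibody, condition) -> ChipSample
    seed: int = 0
    rna_config: RnaSeqConfig | None = None
    chip_config: ChipConfig | None = None

    def design(self) -> pd.DataFrame:
        rows = [(f"{s}.{t}.rep{r}", s, t, r) for (s, t, r) in sorted(self.samples)]
        return pd.DataFrame(rows, columns=["sample", "strain", "treatment", "replicate"])


def perturbations(strain: str, treatment: str) -> tuple[bool, bool]:
    """(Cdk9 inhibited, H2Bub1 absent) for a strain/treatment cell.

    The analog-sensitive kinase is inhibited only when the allele is present
    AND the inhibitor is applied; the ubiquitylation-site mutation acts
    constitutively.
    """
    cdk9_off = "cdk9as" in strain and treatment == "3MBPP1"
    h2bub1_off = "htb1KR" in strain
    return cdk9_off, h2bub1_off


def antisense_fold(subset: str, strain: str, treatment: str, cfg: RnaSeqConfig) -> float:
    cdk9_off, hub_off = perturbations(strain, treatment)
    if subset == "cdk9_only":
        return cfg.single_fold if cdk9_off else 1.0
    if subset == "h2bub1_only":
        return cfg.single_fold if hub_off else 1.0
    if subset == "shared":
        if cdk9_off and hub_off:
            return cfg.double_fold
        return cfg.single_fold if (cdk9_off or hub_off) else 1.0
    if subset == "double_only":
        return cfg.double_only_fold if (cdk9_off and hub_off) else 1.0
    return 1.0


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def generate_annotation_truth(
    config: RnaSeqConfig, seed: int
) -> tuple[GenomeAnnotation, pd.DataFrame]:
    """Lay out a toy genome and the planted truth table.

    Genes are placed non-overlapping with intergenic gaps on ``n_chroms``
    chromosomes, random strand.  The truth table carries the planted subset,
    calibrated baseline sense/antisense RPKM and the antisense fold for
    every strain x treatment condition.
    """
    config.validate()
    rng = _rng(seed, 0)
    n = config.n_genes
    lengths = np.clip(
        np.round(rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sigma, n)),
        config.gene_length_min, config.gene_length_max).astype(int)
    gaps = rng.integers(config.gap_min, config.gap_max + 1, n + config.n_chroms)
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    per_chrom = np.array_split(np.arange(n), config.n_chroms)
    features: list[GeneFeature] = []
    chrom_sizes: dict[str, int] = {}
    width = len(str(n))
    gi = 0  # one gap before the first gene of each chromosome, one after each gene
    for ci, idxs in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = int(gaps[gi])
        gi += 1
        for i in idxs:
            start = pos
            end = start + int(lengths[i])
            features.append(GeneFeature(f"g{i:0{width}d}", chrom, start, end, str(strands[i])))
            pos = end + int(gaps[gi % len(gaps)])
            gi += 1
        chrom_sizes[chrom] = pos
    annotation = GenomeAnnotation(features, chrom_sizes)

    # planted subsets (disjoint, drawn without replacement)
    sizes = [config.n_cdk9_only, config.n_h2bub1_only, config.n_shared, config.n_double_only]
    picked = rng.choice(n, size=sum(sizes), replace=False)
    subset = np.full(n, "none", dtype=object)
    off = 0
    for name, k in zip(("cdk9_only", "h2bub1_only", "shared", "double_only"), sizes):
        subset[picked[off: off + k]] = name
        off += k

    planted = subset != "none"
    anti = np.exp(rng.normal(config.background_antisense_log_median,
                             config.background_antisense_log_sigma, n))
    anti[planted] = rng.uniform(config.planted_baseline_min,
                                config.planted_baseline_max, int(planted.sum()))
    sense_shape = rng.lognormal(0.0, config.sense_log_sigma, n)

    # calibrate sense levels so sum(rpkm * length) over all features = 1e9,
    # the identity a measured RPKM table satisfies; then configured values
    # are also the expected measured values.
    ig = intergenic_windows(annotation, config.intergenic_bin)
    w_ig = float((config.intergenic_rpkm * (ig["end"] - ig["start"])).sum())
    w_anti = float((anti * lengths).sum())
    w_target = 1e9 - w_anti - w_ig
    if w_target <= 0:
        raise ValueError("antisense/intergenic weight exceeds the RPKM budget")
    sense = sense_shape * (w_target / float((sense_shape * lengths).sum()))

    truth = pd.DataFrame({
        "gene_id": [f.gene_id for f in features],
        "subset": subset,
        "baseline_sense_rpkm": sense,
        "baseline_antisense_rpkm": anti,
    })
    for s in STRAINS:
        for t in TREATMENTS:
            truth[f"fold_{s}_{t}"] = [
                antisense_fold(sub, s, t, config) for sub in subset]
    return annotation, truth


def planted_set(truth: pd.DataFrame, strain: str, treatment: str) -> set[str]:
    """Gene ids with a planted antisense fold > 1 in the given condition."""
    col = f"fold_{strain}_{treatment}"
    return set(truth.loc[truth[col] > 1, "gene_id"])


def _draw_counts(expected: np.ndarray, config: RnaSeqConfig,
                 rng: np.random.Generator) -> np.ndarray:
    if config.noise == "none":
        return np.rint(expected).astype(np.int64)
    if config.noise == "poisson":
        return rng.poisson(expected).astype(np.int64)
    size = config.nb_dispersion
    p = size / (size + np.maximum(expected, 1e-300))
    out = rng.negative_binomial(size, p)
    out[expected == 0] = 0
    return out.astype(np.int64)


def _place_reads(counts: np.ndarray, starts: np.ndarray, spans: np.ndarray,
                 config: RnaSeqConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized read placement: feature index and start per read."""
    fidx = np.repeat(np.arange(len(counts)), counts)
    if len(fidx) == 0:
        return fidx, np.empty(0, dtype=np.int64)
    if config.noise == "none":
        cum = np.concatenate([[0], np.cumsum(counts)])
        j = np.arange(len(fidx)) - cum[fidx]
        frac = (j + 0.5) / counts[fidx]
        off = np.floor(frac * (spans[fidx] + 1)).astype(np.int64)
    else:
        off = rng.integers(0, spans[fidx] + 1)
    return fidx, starts[fidx] + off


def sample_reads(
    annotation: GenomeAnnotation,
    truth: pd.DataFrame,
    config: RnaSeqConfig,
    strain: str,
    treatment: str,
    replicate: int,
    seed: int,
) -> pd.DataFrame:
    """Stranded read intervals for one library (columns chrom/start/end/strand).

    Deterministic given (seed, strain, treatment, replicate); independent of
    the order in which samples are generated.
    """
    config.validate()
    si, ti = STRAINS.index(strain), TREATMENTS.index(treatment)
    rng = _rng(seed, 1, si, ti, replicate)
    rl = config.read_length
    feats = annotation.features
    g_chrom = np.array([f.chrom for f in feats], dtype=object)
    g_start = np.array([f.start for f in feats], dtype=np.int64)
    g_len = np.array([f.length for f in feats], dtype=np.int64)
    g_plus = np.array([f.strand == "+" for f in feats])
    spans = g_len - rl

    fold = truth[f"fold_{strain}_{treatment}"].to_numpy(dtype=float)
    e_sense = truth["baseline_sense_rpkm"].to_numpy() * g_len * config.depth / 1e9
    e_anti = truth["baseline_antisense_rpkm"].to_numpy() * fold * g_len * config.depth / 1e9

    parts = []
    for expected, sense_strand in ((e_sense, True), (e_anti, False)):
        c = _draw_counts(expected, config, rng)
        fidx, starts = _place_reads(c, g_start, spans, config, rng)
        plus = g_plus[fidx] if sense_strand else ~g_plus[fidx]
        parts.append(pd.DataFrame({
            "chrom": g_chrom[fidx],
            "start": starts,
            "end": starts + rl,
            "strand": np.where(plus, "+", "-"),
        }))

    ig = intergenic_windows(annotation, config.intergenic_bin)
    w_len = (ig["end"] - ig["start"]).to_numpy(dtype=np.int64)
    e_ig = config.intergenic_rpkm * w_len * config.depth / 1e9
    c = _draw_counts(e_ig, config, rng)
    ig_rl = np.minimum(rl, w_len)  # short terminal windows get shorter reads
    fidx, starts = _place_reads(c, ig["start"].to_numpy(np.int64),
                                w_len - ig_rl, config, rng)
    ig_strand = np.where(rng.random(len(fidx)) < 0.5, "+", "-")
    parts.append(pd.DataFrame({
        "chrom": ig["chrom"].to_numpy(dtype=object)[fidx],
        "start": starts,
        "end": starts + ig_rl[fidx],
        "strand": ig_strand,
    }))
    reads = pd.concat(parts, ignore_index=True)
    return reads.sort_values(["chrom", "start", "end", "strand"],
                             kind="stable").reset_index(drop=True)


def generate_rnaseq(config: RnaSeqConfig, seed: int) -> SyntheticDataset:
    """Materialize the full strain x treatment x replicate read-set design."""
    annotation, truth = generate_annotation_truth(config, seed)
    ds = SyntheticDataset(annotation, truth, seed=seed, rna_config=config)
    for s in STRAINS:
        for t in TREATMENTS:
            for r in range(1, config.replicates + 1):
                ds.samples[(s, t, r)] = sample_reads(annotation, truth, config, s, t, r, seed)
    return ds


def _gene_shape(length: int, ab: ChipAntibodyConfig, trough_depth: float) -> np.ndarray:
    """Oriented (5'->3') unit-plateau shape covering gene body + 3' tail."""
    total = length + ab.post_cps + ab.decay_len
    t = np.arange(total)
    shape = np.ones(total)
    if ab.ramp_len > 0:
        ramp = t < ab.ramp_len
        shape[ramp] = t[ramp] / ab.ramp_len
    tail = t >= length + ab.post_cps
    if ab.decay_len > 0:
        shape[tail] = 1.0 - (t[tail] - length - ab.post_cps) / ab.decay_len
    if ab.tss_peak_height > 0:
        shape += ab.tss_peak_height * np.exp(
            -0.5 * ((t - ab.tss_peak_center) / ab.tss_peak_sigma) ** 2)
    if trough_depth > 0:
        cps = length - 1
        notch = np.abs(t - cps) <= ab.trough_halfwidth
        shape[notch] *= 1.0 - trough_depth
    return shape


def generate_chip(
    annotation: GenomeAnnotation,
    config: ChipConfig,
    seed: int,
) -> dict[tuple[str, str], ChipSample]:
    """Per-base IP and input tracks plus spike-in read counts.

    The per-gene expression score is drawn once and shared across all
    antibodies and conditions, so ratio tracks and clusters see a consistent
    occupancy ranking.
    """
    for ab in config.antibodies:
        ab.validate()
    if not 0 < config.spike_fraction < 1:
        raise ValueError("spike_fraction must be in (0, 1)")
    rng = _rng(seed, 2)
    feats = annotation.features
    expr = np.exp(rng.normal(0.0, config.expression_log_sigma, len(feats)))

    out: dict[tuple[str, str], ChipSample] = {}
    sizes = annotation.chrom_sizes
    input_true = {c: np.full(n, config.input_coverage) for c, n in sizes.items()}
    f = config.spike_fraction
    for ab in config.antibodies:
        for cond in config.conditions:
            depth = getattr(cond, "trough_depth_override", None)
            trough = ab.trough_depth if depth is None else depth
            ip_true = {c: np.full(n, ab.background) for c, n in sizes.items()}
            for g, score in zip(feats, expr):
                shape = _gene_shape(g.length, ab, trough) * (ab.plateau_scale * score)
                arr = ip_true[g.chrom]
                if g.strand == "+":
                    s = g.start
                    e = min(s + len(shape), len(arr))
                    arr[s:e] += shape[: e - s]
                else:
                    e = g.end
                    s = max(e - len(shape), 0)
                    arr[s:e] += shape[::-1][len(shape) - (e - s):]
            ip_true = {c: v * cond.signal_factor for c, v in ip_true.items()}

            rl = config.read_length
            ip_target_true = sum(v.sum() for v in ip_true.values()) / rl
            in_target_true = sum(v.sum() for v in input_true.values()) / rl
            base_spike_ip = f / (1 - f) * ip_target_true
            base_spike_in = f / (1 - f) * in_target_true

            tech_ip = cond.depth_factor * cond.ip_efficiency
            tech_in = cond.depth_factor
            ip_track = CoverageTrack({c: v * tech_ip for c, v in ip_true.items()},
                                     1, f"{ab.name}.{cond.name}.ip")
            input_track = CoverageTrack({c: v * tech_in for c, v in input_true.items()},
                                        1, f"{ab.name}.{cond.name}.input")
            spike = SpikeInStats(
                ip_target_reads=int(round(ip_target_true * tech_ip)),
                ip_spike_reads=max(1, int(round(base_spike_ip * tech_ip))),
                input_target_reads=int(round(in_target_true * tech_in)),
                input_spike_reads=max(1, int(round(base_spike_in * tech_in))),
            )
            out[(ab.name, cond.name)] = ChipSample(ip_track, input_track, spike)
    return out


# ---------------------------------------------------------------------------
# on-disk form


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict:
    """Write the dataset as plain-text files and return a checksum manifest.

    Layout: annotation (GFF3 + BED6 + chrom sizes), one BED6 per sample
    under ``reads/``, bedGraph IP/input pairs plus a spike-count TSV under
    ``chip/``, the truth and design tables, and ``manifest.json``.
    """
    from pathlib import Path

    out = Path(out_dir)
    (out / "reads").mkdir(parents=True, exist_ok=True)
    (out / "chip").mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    write_annotation(dataset.annotation, out / "annotation.gff3", "gff3")
    write_annotation(dataset.annotation, out / "annotation.bed", "bed6")
    write_chrom_sizes(dataset.annotation.chrom_sizes, out / "chrom_sizes.tsv")
    dataset.truth.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.10g")
    dataset.design().to_csv(out / "design.tsv", sep="\t", index=False)
    files += ["annotation.gff3", "annotation.bed", "chrom_sizes.tsv", "truth.tsv", "design.tsv"]

    for (s, t, r), reads in sorted(dataset.samples.items()):
        rel = f"reads/{s}.{t}.rep{r}.bed"
        with open(out / rel, "w") as fh:
            for i, row in enumerate(reads.itertuples(index=False)):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tr{i}\t0\t{row.strand}\n")
        files.append(rel)

    spike_rows = []
    for (ab, cond), cs in sorted(dataset.chip.items()):
        for kind, track in (("ip", cs.ip_track), ("input", cs.input_track)):
            rel = f"chip/{ab}.{cond}.{kind}.bedgraph"
            track.to_bedgraph(out / rel)
            files.append(rel)
        spike_rows.append((ab, cond, cs.spike.ip_target_reads, cs.spike.ip_spike_reads,
                           cs.spike.input_target_reads, cs.spike.input_spike_reads))
    if spike_rows:
        pd.DataFrame(spike_rows, columns=[
            "antibody", "condition", "ip_target_reads", "ip_spike_reads",
            "input_target_reads", "input_spike_reads",
        ]).to_csv(out / "chip" / "spike_counts.tsv", sep="\t", index=False)
        files.append("chip/spike_counts.tsv")

    manifest = {
        "seed": dataset.seed,
        "rna_config": asdict(dataset.rna_config) if dataset.rna_config else None,
        "files": {rel: {"sha256": _sha256(out / rel), "bytes": (out / rel).stat().st_size}
                  for rel in sorted(files)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def read_dataset(out_dir) -> SyntheticDataset:
    """Rebuild an in-memory dataset from :func:`write_dataset` output."""
    from pathlib import Path

    from .annotation import read_annotation
    from .chip import read_bedgraph
    from .quantify import read_reads

    out = Path(out_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    annotation = read_annotation(out / "annotation.gff3", "gff3")
    truth = pd.read_csv(out / "truth.tsv", sep="\t")
    ds = SyntheticDataset(annotation, truth, seed=manifest.get("seed", 0))
    design = pd.read_csv(out / "design.tsv", sep="\t")
    for row in design.itertuples(index=False):
        reads = read_reads(out / "reads" / f"{row.sample}.bed")
        ds.samples[(row.strain, row.treatment, int(row.replicate))] = reads
    spike_path = out / "chip" / "spike_counts.tsv"
    if spike_path.exists():
        spikes = pd.read_csv(spike_path, sep="\t")
        for row in spikes.itertuples(index=False):
            ip = read_bedgraph(out / "chip" / f"{row.antibody}.{row.condition}.ip.bedgraph",
                               annotation.chrom_sizes, 1)
            inp = read_bedgraph(out / "chip" / f"{row.antibody}.{row.condition}.input.bedgraph",
                                annotation.chrom_sizes, 1)
            ds.chip[(row.antibody, row.condition)] = ChipSample(
                ip, inp, SpikeInStats(int(row.ip_target_reads), int(row.ip_spike_reads),
                                      int(row.input_target_reads), int(row.input_spike_reads)))
    return ds
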