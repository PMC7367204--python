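"""End-to-end orchestration: simulate -> quantify -> call -> compare -> ChIP.

A run is driven by a single :class:`RunConfig` (loadable from YAML/JSON).
Every stage writes its intermediates under the output directory and the
final report is JSON + Markdown with no timestamps, so identical config +
seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential as diff
from . import metagene as mg
from .annotation import GenomeAnnotation
from .chip import normalized_signal, ratio_track
from .quantify import (ExpressionTable, average_replicates, count_reads,
                       rpkm_normalize)
from .simulate import (STRAINS, TREATMENTS, ChipConfig, RnaSeqConfig,
                       SyntheticDataset, generate_annotation_truth,
                       generate_chip, planted_set, read_dataset, sample_reads)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "validate", "load_config"]


@dataclass
class RunConfig:
    out_dir: str = "run_out"
    seed: int = 0
    dataset_dir: str | None = None  # pre-written dataset; otherwise simulate
    rna: RnaSeqConfig = field(default_factory=RnaSeqConfig)
    chip: ChipConfig | None = field(default_factory=ChipConfig)
    simulate_chip: bool = True
    convention: str = "read_is_transcript_strand"
    library: str = "assigned"
    fold_threshold: float = 2.0
    rpkm_floor: float = 1.0
    pseudocount: float = 0.1
    chip_pseudocount: float = 1.0
    metagene_flank_bp: int = 500
    cluster_size: int = 500
    trough_flank_bp: int = 50
    ratio_pairs: list = field(default_factory=lambda: [["pSpt5", "Spt5"], ["H2Bub1", "H2B"]])
    term_map_path: str | None = None

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build(cls, data: dict):
    names = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for k, v in data.items():
        if k not in names:
            raise ValueError(f"unknown config key {k!r} for {cls.__name__}")
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text)
    data = dict(data or {})
    if "rna" in data and isinstance(data["rna"], dict):
        data["rna"] = _build(RnaSeqConfig, data["rna"])
    if "chip" in data and isinstance(data["chip"], dict):
        from .simulate import ChipAntibodyConfig, ChipConditionConfig

        cdata = dict(data["chip"])
        if "antibodies" in cdata:
            cdata["antibodies"] = [_build(ChipAntibodyConfig, a) for a in cdata["antibodies"]]
        if "conditions" in cdata:
            cdata["conditions"] = [_build(ChipConditionConfig, c) for c in cdata["conditions"]]
        data["chip"] = _build(ChipConfig, cdata)
    return _build(RunConfig, data)


def validate(config: RunConfig) -> list[str]:
    """Static sanity checks; returns diagnostics (empty when clean)."""
    diags = []
    if config.fold_threshold <= 1:
        diags.append(f"fold_threshold must exceed 1 (got {config.fold_threshold})")
    if config.rpkm_floor < 0:
        diags.append("rpkm_floor must be >= 0")
    if config.pseudocount < 0:
        diags.append("pseudocount must be >= 0")
    if config.convention not in ("read_is_transcript_strand", "read_is_opposite"):
        diags.append(f"unknown strand convention {config.convention!r}")
    if config.dataset_dir is not None:
        root = Path(config.dataset_dir)
        if not root.exists():
            diags.append(f"dataset_dir {config.dataset_dir!r} does not exist")
        else:
            for rel in ("annotation.gff3", "design.tsv", "manifest.json"):
                if not (root / rel).exists():
                    diags.append(f"dataset_dir missing {rel}")
            design_path = root / "design.tsv"
            if design_path.exists():
                design = pd.read_csv(design_path, sep="\t")
                for s in STRAINS:
                    for t in TREATMENTS:
                        n = int(((design["strain"] == s) & (design["treatment"] == t)).sum())
                        if n < 1:
                            diags.append(f"design has no replicate for {s} x {t}")
    else:
        try:
            config.rna.validate()
        except ValueError as exc:
            diags.append(str(exc))
    return diags


def _condition_tables(config: RunConfig, annotation: GenomeAnnotation,
                      dataset: SyntheticDataset | None, truth: pd.DataFrame | None,
                      out: Path) -> tuple[dict, dict]:
    """Quantify every sample, average replicates per condition."""
    tables: dict[tuple[str, str], ExpressionTable] = {}
    stats: dict[str, dict] = {}
    for s in STRAINS:
        for t in TREATMENTS:
            reps = []
            r = 1
            while True:
                if dataset is not None:
                    key = (s, t, r)
                    if key not in dataset.samples:
                        break
                    reads = dataset.samples[key]
                else:
                    if r > config.rna.replicates:
                        break
                    reads = sample_reads(annotation, truth, config.rna, s, t, r, config.seed)
                counts = count_reads(reads, annotation, config.convention,
                                     sample=f"{s}.{t}.rep{r}")
                counts.check_conservation()
                stats[f"{s}.{t}.rep{r}"] = {
                    "n_reads": counts.n_reads,
                    "sense": counts.sense_total,
                    "antisense": counts.antisense_total,
                    "intergenic": counts.intergenic_total,
                    "discarded": counts.discarded,
                }
                reps.append(rpkm_normalize(counts, annotation, library=config.library))
                r += 1
            if not reps:
                raise RuntimeError(f"no replicate libraries for {s} x {t}")
            avg = average_replicates(reps)
            avg.sample = f"{s}.{t}"
            avg.to_tsv(out / "rpkm" / f"{s}.{t}.tsv")
            tables[(s, t)] = avg
    return tables, stats


def _truth_confusion(called: set, planted: set, universe: set) -> dict:
    tp = len(called & planted)
    fp = len(called - planted)
    fn = len(planted - called)
    tn = len(universe) - tp - fp - fn
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "fdr": fp / len(called) if called else 0.0,
    }


def run(config: RunConfig) -> dict:
    """Execute all stages; returns the report dict (also written to disk)."""
    t0 = time.monotonic()
    out = Path(config.out_dir)
    for sub in ("rpkm", "calls", "chip", "metagene"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config_hash": config.content_hash()}
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")

    # ---- stage: inputs -------------------------------------------------
    stage = "inputs"
    try:
        dataset = None
        truth = None
        chip_samples = {}
        if config.dataset_dir is not None:
            dataset = read_dataset(config.dataset_dir)
            annotation, truth = dataset.annotation, dataset.truth
            chip_samples = dataset.chip
        else:
            annotation, truth = generate_annotation_truth(config.rna, config.seed)
            if config.chip is not None and config.simulate_chip:
                chip_samples = generate_chip(annotation, config.chip, config.seed)
        log.info("[%s] %d genes on %d chromosomes", stage, len(annotation),
                 len(annotation.chrom_sizes))

        # ---- stage: quantify ------------------------------------------
        stage = "quantify"
        tables, sample_stats = _condition_tables(config, annotation, dataset, truth, out)
        report["samples"] = sample_stats

        # ---- stage: differential calls --------------------------------
        stage = "diffcall"
        pc_genes = {f.gene_id for f in annotation.protein_coding()}
        calls_by_cond: dict[str, list] = {}
        for s in STRAINS:
            for t in TREATMENTS:
                if s == "WT":
                    continue
                calls = diff.call_differential(
                    tables[(s, t)], tables[("WT", t)],
                    threshold=config.fold_threshold, floor=config.rpkm_floor,
                    pseudocount=config.pseudocount)
                cond = f"{s}.{t}"
                calls_by_cond[cond] = calls
                diff.calls_to_frame(calls).to_csv(
                    out / "calls" / f"{cond}.tsv", sep="\t", index=False,
                    float_format="%.6g")
        fractions = diff.category_fractions(calls_by_cond, len(pc_genes))
        fractions.to_csv(out / "calls" / "category_fractions.tsv", sep="\t",
                         index=False, float_format="%.6g")
        report["category_fractions"] = {
            f"{r.condition}.{r.strand_class}.{r.direction}": round(r.percent, 4)
            for r in fractions.itertuples(index=False)}

        # ---- stage: compare (overlap / synergy / truth) ----------------
        stage = "compare"
        drug = TREATMENTS[1]
        up = {s: diff.direction_set(calls_by_cond[f"{s}.{drug}"], "antisense", "up")
              for s in STRAINS if s != "WT"}
        overlaps = {}
        for a, b in (("cdk9as", "htb1KR"), ("cdk9as", "cdk9as_htb1KR"),
                     ("htb1KR", "cdk9as_htb1KR")):
            r = diff.hypergeometric_overlap(up[a], up[b], pc_genes)
            overlaps[f"{a}&{b}"] = asdict(r)
        overlaps["three_way_intersection"] = len(up["cdk9as"] & up["htb1KR"]
                                                 & up["cdk9as_htb1KR"])
        report["antisense_up_overlap"] = overlaps

        shared = up["cdk9as"] & up["htb1KR"]
        report["n_shared_antisense_up"] = len(shared)
        synergy = {}
        if shared:
            f_double = diff.fold_induction(tables[("cdk9as_htb1KR", drug)],
                                           tables[("WT", drug)], shared,
                                           pseudocount=config.pseudocount)
            for single in ("cdk9as", "htb1KR"):
                f_single = diff.fold_induction(tables[(single, drug)],
                                               tables[("WT", drug)], shared,
                                               pseudocount=config.pseudocount)
                synergy[f"double_vs_{single}"] = asdict(
                    diff.synergy_test(list(f_double), list(f_single)))
        report["synergy"] = synergy
        with open(out / "calls" / "compare.json", "w") as fh:
            json.dump({"overlaps": overlaps, "synergy": synergy}, fh,
                      indent=1, sort_keys=True)
            fh.write("\n")

        if config.term_map_path:
            term_df = pd.read_csv(config.term_map_path, sep="\t",
                                  names=["term", "gene_id"], comment="#")
            term_map = {t: set(g["gene_id"]) & pc_genes
                        for t, g in term_df.groupby("term")}
            enr = diff.term_enrichment(up["cdk9as"], term_map, pc_genes)
            pd.DataFrame([asdict(e) for e in enr]).to_csv(
                out / "calls" / "enrichment.tsv", sep="\t", index=False,
                float_format="%.6g")
            report["enrichment_top_terms"] = [
                {"term": e.term, "p_bonferroni": e.p_bonferroni}
                for e in enr[:5]]

        if truth is not None and "subset" in truth.columns:
            confusion = {}
            for s in STRAINS:
                if s == "WT":
                    continue
                planted = planted_set(truth, s, drug)
                confusion[f"{s}.{drug}"] = _truth_confusion(up[s], planted, pc_genes)
            report["truth_recovery"] = confusion

        # ---- stage: ChIP + metagene ------------------------------------
        stage = "chip"
        if chip_samples:
            report["chip"] = _chip_stage(config, annotation, chip_samples, out)

        report["runtime_stage"] = "complete"
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log.info("pipeline finished in %.1f s", time.monotonic() - t0)
    _write_report(report, out)
    return report


def _chip_stage(config: RunConfig, annotation: GenomeAnnotation,
                chip_samples: dict, out: Path) -> dict:
    """Normalize tracks, build ratio metagenes, clusters and trough stats."""
    flank = config.metagene_flank_bp
    norm = {}
    for (ab, cond), cs in sorted(chip_samples.items()):
        norm[(ab, cond)] = normalized_signal(cs.ip_track, cs.input_track, cs.spike,
                                             pseudocount=config.chip_pseudocount)
    conditions = sorted({cond for _, cond in norm})
    genes = annotation.protein_coding()
    spec_cps = mg.AnchorSpec("CPS", upstream_bp=flank, downstream_bp=flank)
    result: dict = {"trough": {}, "profiles": {}, "clusters": {}}

    for cond in conditions:
        # CPS-centered trough on the most polymerase-like antibody available
        ab = next((a for a in ("RNAPII", "Spt5") if (a, cond) in norm), None)
        if ab is not None:
            mat = mg.anchored_matrix(norm[(ab, cond)], genes, spec_cps)
            prof = mg.profile(mat, "mean")
            np.savetxt(out / "metagene" / f"{ab}.{cond}.cps_profile.tsv", prof,
                       fmt="%.8g")
            anchor_bin = flank // mat.bin_size
            flank_bins = config.trough_flank_bp // mat.bin_size
            result["trough"][cond] = round(float(
                mg.trough_statistic(prof, anchor_bin, flank_bins)), 6)
            result["profiles"][f"{ab}.{cond}.cps_mean"] = round(float(prof.mean()), 6)

        for num, den in config.ratio_pairs:
            if (num, cond) in norm and (den, cond) in norm:
                r = ratio_track(norm[(num, cond)], norm[(den, cond)], "log2",
                                pseudocount=config.chip_pseudocount)
                mat = mg.scaled_matrix(r, genes, mg.AnchorSpec("scaled"))
                mat.to_tsv(out / "metagene" / f"{num}_{den}.{cond}.scaled.tsv")
                scores = {g: float(v) for g, v in zip(mat.gene_ids,
                                                      mat.values.mean(axis=1))}
                k = max(1, min(config.cluster_size, len(scores)))
                cl = mg.cluster_genes(scores, "fixed_size", k)
                sizes = pd.Series(cl.clusters).value_counts().sort_index()
                result["clusters"][f"{num}/{den}.{cond}"] = {
                    "n_clusters": int(sizes.size),
                    "cluster_size": int(sizes.iloc[0]),
                    "mean_log2_ratio": round(float(np.mean(list(scores.values()))), 6),
                }
    return result


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    lines = ["# Pipeline report", ""]
    lines.append(f"- seed: {report['seed']}")
    lines.append(f"- config hash: {report['config_hash']}")
    if "n_shared_antisense_up" in report:
        lines.append(f"- shared antisense-up genes (both single mutants, drug): "
                     f"{report['n_shared_antisense_up']}")
    for key in ("category_fractions", "antisense_up_overlap", "synergy",
                "truth_recovery", "chip"):
        if key in report:
            lines.append("")
            lines.append(f"## {key}")
            lines.append("```json")
            lines.append(json.dumps(report[key], indent=1, sort_keys=True))
            lines.append("```")
    (out / "report.md").write_text("\n".join(lines) + "\n")
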