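import numpy as np
import pandas as pd
import pytest

from antisenseq.annotation import GeneFeature, GenomeAnnotation, IntervalIndex
from antisenseq.quantify import (ExpressionTable, StrandedCounts, assign_read,
                                 average_replicates, classify_reads,
                                 count_reads, intergenic_windows, read_reads,
                                 rpkm_normalize)
from helpers import brute_force_assign, make_random_annotation, make_random_reads


@pytest.fixture
def toy_index(toy_annotation):
    return IntervalIndex(toy_annotation)


class TestAssignRead:
    def test_same_strand_read_is_sense(self, toy_index):
        a = assign_read(("r1", "chrI", 200, 250, "+"), toy_index)
        assert (a.category, a.gene_id) == ("sense", "geneA")

    def test_opposite_strand_single_gene_is_antisense(self, toy_index):
        a = assign_read(("r1", "chrI", 200, 250, "-"), toy_index)
        assert (a.category, a.gene_id) == ("antisense", "geneA")

    def test_antisense_to_two_genes_is_discarded(self, toy_index):
        # + read across the two overlapping - strand genes geneB/geneC
        a = assign_read(("r1", "chrI", 1140, 1210, "+"), toy_index)
        assert (a.category, a.gene_id) == ("discarded", None)

    def test_sense_multi_overlap_takes_largest(self, toy_index):
        # - read covering 40 bp of geneB and 60 bp of geneC
        a = assign_read(("r1", "chrI", 1160, 1260, "-"), toy_index)
        assert (a.category, a.gene_id) == ("sense", "geneC")

    def test_sense_tie_breaks_lexicographically(self):
        ann = GenomeAnnotation([
            GeneFeature("gB", "chrI", 100, 200, "+"),
            GeneFeature("gA", "chrI", 150, 250, "+"),
        ])
        a = assign_read(("r1", "chrI", 140, 210, "+"), IntervalIndex(ann))
        # 60 bp overlap with gB, 60 bp with gA -> smallest id wins
        assert a.gene_id == "gA"

    def test_sense_takes_precedence_over_antisense(self):
        ann = GenomeAnnotation([
            GeneFeature("plus", "chrI", 100, 300, "+"),
            GeneFeature("minus", "chrI", 200, 400, "-"),
        ])
        a = assign_read(("r1", "chrI", 220, 280, "+"), IntervalIndex(ann))
        assert (a.category, a.gene_id) == ("sense", "plus")

    def test_no_overlap_is_intergenic(self, toy_index):
        a = assign_read(("r1", "chrI", 2500, 2550, "+"), toy_index)
        assert (a.category, a.gene_id) == ("intergenic", None)

    def test_opposite_convention_flips_effective_strand(self, toy_index):
        a = assign_read(("r1", "chrI", 200, 250, "-"), toy_index,
                        convention="read_is_opposite")
        assert (a.category, a.gene_id) == ("sense", "geneA")

    def test_unknown_chrom_raises(self, toy_index):
        with pytest.raises(KeyError):
            assign_read(("r1", "chrX", 0, 50, "+"), toy_index)


class TestClassifyReads:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("convention",
                             ["read_is_transcript_strand", "read_is_opposite"])
    def test_matches_brute_force_oracle(self, seed, convention):
        rng = np.random.default_rng(seed)
        ann = make_random_annotation(rng, n_genes=120, chrom_len=12000)
        reads = make_random_reads(rng, ann, n=800)
        got = classify_reads(reads, ann, convention)
        for i in range(len(reads)):
            r = reads.iloc[i]
            cat, gid = brute_force_assign(r["chrom"], r["start"], r["end"],
                                          r["strand"], ann.features, convention)
            assert got["category"].iloc[i] == cat, f"read {i}"
            assert got["gene_id"].iloc[i] == gid, f"read {i}"

    def test_agrees_with_assign_read(self, toy_annotation, rng):
        reads = make_random_reads(rng, toy_annotation, n=400)
        idx = IntervalIndex(toy_annotation)
        got = classify_reads(reads, toy_annotation)
        for i in range(len(reads)):
            r = reads.iloc[i]
            a = assign_read((f"r{i}", r["chrom"], r["start"], r["end"], r["strand"]), idx)
            assert (got["category"].iloc[i], got["gene_id"].iloc[i]) == (a.category, a.gene_id)

    def test_unknown_chrom_raises(self, toy_annotation):
        reads = pd.DataFrame({"chrom": ["chrX"], "start": [0], "end": [50], "strand": ["+"]})
        with pytest.raises(KeyError):
            classify_reads(reads, toy_annotation)


class TestCountReads:
    def test_conservation_and_oracle_aggregation(self, rng):
        ann = make_random_annotation(rng, n_genes=100, chrom_len=10000)
        reads = make_random_reads(rng, ann, n=2000)
        counts = count_reads(reads, ann)
        counts.check_conservation()
        # aggregate the per-read oracle and compare tallies
        sense = {}
        anti = {}
        n_disc = n_ig = 0
        for r in reads.itertuples(index=False):
            cat, gid = brute_force_assign(r.chrom, r.start, r.end, r.strand, ann.features)
            if cat == "sense":
                sense[gid] = sense.get(gid, 0) + 1
            elif cat == "antisense":
                anti[gid] = anti.get(gid, 0) + 1
            elif cat == "discarded":
                n_disc += 1
            else:
                n_ig += 1
        for gid in counts.gene_counts.index:
            assert counts.gene_counts.loc[gid, "sense"] == sense.get(gid, 0)
            assert counts.gene_counts.loc[gid, "antisense"] == anti.get(gid, 0)
        assert counts.discarded == n_disc
        assert counts.intergenic_total == n_ig

    def test_planted_counts_recovered(self, toy_annotation):
        rows = ([("chrI", 150, 200, "+")] * 5 + [("chrI", 150, 200, "-")] * 3)
        reads = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
        counts = count_reads(reads, toy_annotation)
        assert counts.gene_counts.loc["geneA", "sense"] == 5
        assert counts.gene_counts.loc["geneA", "antisense"] == 3

    def test_empty_read_set_gives_zero_counts(self, toy_annotation):
        reads = pd.DataFrame({"chrom": pd.Series(dtype=object),
                              "start": pd.Series(dtype=np.int64),
                              "end": pd.Series(dtype=np.int64),
                              "strand": pd.Series(dtype=object)})
        counts = count_reads(reads, toy_annotation)
        assert counts.n_reads == 0
        assert counts.gene_counts.to_numpy().sum() == 0
        assert counts.intergenic_total == 0

    def test_intergenic_windows_tile_gaps(self, toy_annotation):
        win = intergenic_windows(toy_annotation, 500)
        # windows never overlap features and cover only gap bases
        for w in win.itertuples(index=False):
            for f in toy_annotation.features:
                if f.chrom == w.chrom:
                    assert w.end <= f.start or w.start >= f.end


def _expression_table(pairs, length=1000):
    df = pd.DataFrame([(fid, sc, length, rpkm) for fid, sc, rpkm in pairs],
                      columns=["feature_id", "strand_class", "length", "rpkm"])
    return ExpressionTable(df)


class TestRpkm:
    def _counts(self, ann, sense, lib_pad):
        gc = pd.DataFrame({"sense": sense, "antisense": [0] * len(sense)},
                          index=pd.Index([f.gene_id for f in ann.features], name="gene_id"))
        win = intergenic_windows(ann, 500).assign(count=0)
        win.loc[win.index[0], "count"] = lib_pad
        return StrandedCounts(gc, win, discarded=0, n_reads=int(sum(sense)) + lib_pad)

    def test_formula_identity(self):
        ann = GenomeAnnotation([GeneFeature("g1", "chrI", 0, 1000, "+")], {"chrI": 2_000_000})
        counts = self._counts(ann, [10], lib_pad=1_000_000 - 10)
        table = rpkm_normalize(counts, ann)
        assert table.rpkm_series("sense")["g1"] == pytest.approx(10.0)

    def test_invariant_under_library_scaling(self, rng):
        ann = make_random_annotation(rng, n_genes=30, chrom_len=50000,
                                     coding_frac=1.0)
        sense = rng.integers(0, 50, 30).tolist()
        t1 = rpkm_normalize(self._counts(ann, sense, 500), ann)
        t2 = rpkm_normalize(self._counts(ann, [2 * s for s in sense], 1000), ann)
        np.testing.assert_allclose(t1.rpkm_series("sense").to_numpy(),
                                   t2.rpkm_series("sense").to_numpy(), rtol=1e-12)

    def test_matches_one_line_oracle(self, rng):
        ann = make_random_annotation(rng, n_genes=40, chrom_len=50000, coding_frac=1.0)
        sense = rng.integers(0, 100, 40).tolist()
        counts = self._counts(ann, sense, 777)
        lib = sum(sense) + 777
        table = rpkm_normalize(counts, ann)
        for f, c in zip(ann.features, sense):
            expected = c * 1e9 / (f.length * lib)
            assert table.rpkm_series("sense")[f.gene_id] == pytest.approx(expected, rel=1e-12)

    def test_zero_library_raises(self):
        ann = GenomeAnnotation([GeneFeature("g1", "chrI", 0, 1000, "+")], {"chrI": 2000})
        counts = self._counts(ann, [0], lib_pad=0)
        with pytest.raises(ValueError, match="library"):
            rpkm_normalize(counts, ann)

    def test_antisense_restricted_to_coding_by_default(self, toy_annotation):
        reads = pd.DataFrame([("chrII", 850, 900, "+")],
                             columns=["chrom", "start", "end", "strand"])
        counts = count_reads(reads, toy_annotation)
        assert counts.gene_counts.loc["nc1", "antisense"] == 1
        table = rpkm_normalize(counts, toy_annotation)
        assert "nc1" not in set(table.rpkm_series("antisense").index)
        table2 = rpkm_normalize(counts, toy_annotation, antisense_coding_only=False)
        assert table2.rpkm_series("antisense")["nc1"] > 0


class TestAverageReplicates:
    def test_mean_of_two(self):
        t1 = _expression_table([("g1", "sense", 2.0)])
        t2 = _expression_table([("g1", "sense", 4.0)])
        avg = average_replicates([t1, t2])
        assert avg.rpkm_series("sense")["g1"] == pytest.approx(3.0)
        assert avg.n_replicates == 2

    def test_single_replicate_is_identity(self):
        t = _expression_table([("g1", "sense", 2.5), ("g1", "antisense", 0.5)])
        avg = average_replicates([t])
        pd.testing.assert_frame_equal(
            avg.data.sort_values(["feature_id", "strand_class"]).reset_index(drop=True),
            t.data.sort_values(["feature_id", "strand_class"]).reset_index(drop=True))

    def test_matches_oracle_mean(self, rng):
        ids = [f"g{i}" for i in range(20)]
        tables = []
        vals = rng.random((4, 20)) * 100
        for row in vals:
            tables.append(_expression_table([(g, "sense", v) for g, v in zip(ids, row)]))
        avg = average_replicates(tables)
        np.testing.assert_allclose(
            avg.rpkm_series("sense")[ids].to_numpy(), vals.mean(axis=0), rtol=1e-12)

    def test_mismatched_features_raise(self):
        t1 = _expression_table([("g1", "sense", 2.0)])
        t2 = _expression_table([("g2", "sense", 4.0)])
        with pytest.raises(ValueError, match="mismatch"):
            average_replicates([t1, t2])


class TestReadIO:
    def test_bed_round_trip(self, tmp_path, rng, toy_annotation):
        reads = make_random_reads(rng, toy_annotation, n=50)
        p = tmp_path / "r.bed"
        with open(p, "w") as fh:
            for i, r in enumerate(reads.itertuples(index=False)):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tr{i}\t0\t{r.strand}\n")
        back = read_reads(p)
        pd.testing.assert_frame_equal(back, reads.astype({"start": np.int64, "end": np.int64}))

    def test_empty_bed_is_valid(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        back = read_reads(p)
        assert len(back) == 0
        assert list(back.columns) == ["chrom", "start", "end", "strand"]

    def test_expression_table_tsv_round_trip(self, tmp_path):
        t = _expression_table([("g1", "sense", 2.5), ("g1", "antisense", 0.125)])
        t.sample = "WT.DMSO"
        p = tmp_path / "t.tsv"
        t.to_tsv(p)
        back = ExpressionTable.from_tsv(p)
        assert back.sample == "WT.DMSO"
        pd.testing.assert_frame_equal(back.data, t.data)
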