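"""Strand-aware eRNA read filtering, region detection and designation."""

import numpy as np
import pandas as pd
import pytest

from epiretina.erna import (
    ErnaCandidate,
    count_reads_in_regions,
    designate_ernas,
    detect_transcribed_regions,
    erna_deregulation_report,
    filter_reads_for_erna,
)
from epiretina.genome import (
    GeneModel,
    GenomeAnnotation,
    Interval,
    ReadAlignment,
    ReadLibrary,
    extend_gene_region,
)
from epiretina.peaks import Peak, PeakSet


@pytest.fixture()
def gene_plus():
    """One + strand protein-coding gene; extended span [7000, 30000)."""
    return GenomeAnnotation(
        [GeneModel("gc", "chr1", "+", 10_000, 20_000, [9_000], "protein_coding")],
        {"chr1": 100_000},
    )


# the packaged 5-read regression toy: 1 split, 1 genic-antisense, 3 retained
TOY_READS = [
    ReadAlignment("chr1", 15_000, 15_050, "+", split_mapped=True),  # rule 1
    ReadAlignment("chr1", 15_000, 15_050, "-"),  # antisense genic signal: rule 2
    ReadAlignment("chr1", 15_000, 15_050, "+"),  # sense read = antisense transcription
    ReadAlignment("chr1", 50_000, 50_050, "-"),  # outside the extended span
    ReadAlignment("chr1", 60_000, 60_050, "+"),  # intergenic
]


class TestFiltering:
    def test_toy_fixture_three_of_five_survive(self, gene_plus):
        out = filter_reads_for_erna(ReadLibrary.from_reads(TOY_READS), gene_plus)
        assert len(out) == 3
        survivors = {(int(r.start), str(r.strand)) for r in out}
        assert survivors == {(15_000, "+"), (50_000, "-"), (60_000, "+")}

    def test_idempotent(self, gene_plus):
        lib = ReadLibrary.from_reads(TOY_READS)
        once = filter_reads_for_erna(lib, gene_plus)
        twice = filter_reads_for_erna(once, gene_plus)
        assert np.array_equal(once.start, twice.start)
        assert np.array_equal(once.strand, twice.strand)

    def test_rules_commute(self, gene_plus):
        """Split removal then strand overlap equals the combined filter."""
        lib = ReadLibrary.from_reads(TOY_READS)
        split_first = filter_reads_for_erna(
            lib.subset(~lib.split_mapped), gene_plus
        )
        combined = filter_reads_for_erna(lib, gene_plus)
        assert np.array_equal(split_first.start, combined.start)

    def test_inverted_strand_convention(self, gene_plus):
        out = filter_reads_for_erna(
            ReadLibrary.from_reads(TOY_READS), gene_plus, invert_strand_rule=True
        )
        survivors = {(int(r.start), str(r.strand)) for r in out}
        # now the sense read is removed and the antisense one kept
        assert (15_000, "-") in survivors
        assert (15_000, "+") not in survivors

    def test_non_excluded_biotype_not_masked(self):
        ann = GenomeAnnotation(
            [GeneModel("linc", "chr1", "+", 10_000, 20_000, [5_000], "lincRNA")],
            {"chr1": 100_000},
        )
        lib = ReadLibrary.from_reads([ReadAlignment("chr1", 15_000, 15_050, "-")])
        assert len(filter_reads_for_erna(lib, ann)) == 1

    def test_extension_bounds_used(self, gene_plus):
        ext = extend_gene_region(gene_plus["gc"], 3000, 10_000, 100_000)
        assert (ext.start, ext.end) == (7_000, 30_000)
        inside = ReadAlignment("chr1", 29_900, 29_950, "-")
        outside = ReadAlignment("chr1", 30_100, 30_150, "-")
        out = filter_reads_for_erna(
            ReadLibrary.from_reads([inside, outside]), gene_plus
        )
        assert len(out) == 1 and int(out.start[0]) == 30_100


class TestDetection:
    def _block_reads(self, rng, strand, n=200, lo=40_000, hi=42_000):
        starts = rng.integers(lo, hi - 50, size=n).astype(np.int64)
        return ReadLibrary(
            np.full(n, "chr1", dtype=object), starts, starts + 50,
            np.full(n, strand, dtype="U1"),
        )

    def test_planted_block_detected_with_strand(self):
        rng = np.random.default_rng(0)
        block = self._block_reads(rng, "+")
        sparse = self._block_reads(rng, "-", n=10, lo=0, hi=100_000)
        regions = detect_transcribed_regions(
            ReadLibrary.concat([block, sparse]), {"chr1": 100_000}
        )
        plus = [r for r in regions if r.strand == "+"]
        assert len(plus) == 1
        assert plus[0].start <= 40_200 and plus[0].end >= 41_800

    def test_strand_symmetry(self):
        rng = np.random.default_rng(1)
        starts = rng.integers(10_000, 12_000, size=150).astype(np.int64)
        both = ReadLibrary(
            np.repeat(np.array(["chr1"], dtype=object), 300),
            np.concatenate([starts, starts]),
            np.concatenate([starts + 50, starts + 50]),
            np.array(["+"] * 150 + ["-"] * 150, dtype="U1"),
        )
        regions = detect_transcribed_regions(both, {"chr1": 100_000})
        plus = [(r.start, r.end) for r in regions if r.strand == "+"]
        minus = [(r.start, r.end) for r in regions if r.strand == "-"]
        assert plus == minus and len(plus) == 1

    def test_empty_strand_gives_no_regions(self):
        rng = np.random.default_rng(2)
        plus_only = self._block_reads(rng, "+")
        regions = detect_transcribed_regions(plus_only, {"chr1": 100_000})
        assert all(r.strand == "+" for r in regions)


class TestDesignation:
    def _peaks(self, intervals):
        return PeakSet([Peak(iv, 1.0) for iv in intervals])

    def test_coverage_conjunction(self, gene_plus):
        region = Interval("chr1", 40_000, 42_000, "+")
        k9_full = self._peaks([Interval("chr1", 39_000, 43_000)])
        k27_partial = self._peaks([Interval("chr1", 40_000, 40_600)])  # 0.3
        out = designate_ernas([region], k9_full, k27_partial, gene_plus)
        assert out[0].h3k9ac_coverage == 1.0
        assert out[0].h3k27ac_coverage == pytest.approx(0.3)
        assert not out[0].is_erna

    def test_both_marks_covered_is_erna(self, gene_plus):
        region = Interval("chr1", 40_000, 42_000, "+")
        cover = self._peaks([Interval("chr1", 39_000, 43_000)])
        out = designate_ernas(
            [region], cover, cover, gene_plus, photoreceptor_genes={"gc"}
        )
        assert out[0].is_erna
        assert out[0].annotated_gene == "gc"
        assert out[0].is_photoreceptor_locus


class TestReport:
    def _candidate(self, length=25_096, gene="gc"):
        return ErnaCandidate(
            interval=Interval("chr1", 10_000, 10_000 + length, "+"),
            strand="+",
            is_erna=True,
            annotated_gene=gene,
        )

    def test_length_column_reports_interval_length(self, gene_plus):
        """A 25,096 bp candidate reports exactly 25,096 (packaged toy)."""
        cand = self._candidate(25_096)
        counts = pd.DataFrame(
            {"WT_1": [100], "WT_2": [110], "SCA7_1": [40], "SCA7_2": [45]},
            index=["erna_1"],
        )
        rep = erna_deregulation_report(
            [cand], counts, ["WT_1", "WT_2"], ["SCA7_1", "SCA7_2"]
        )
        assert rep.loc[0, "erna_length"] == 25_096

    def test_concordant_down_flag(self):
        cand = self._candidate()
        rng = np.random.default_rng(0)
        wt = rng.poisson(200, 4)
        mut = rng.poisson(200 * 2 ** -1.2, 3)
        counts = pd.DataFrame(
            [np.concatenate([wt, mut])],
            index=["erna_1"],
            columns=[f"WT_{i}" for i in range(4)] + [f"M_{i}" for i in range(3)],
        )
        mrna = pd.DataFrame({"log2fc": [-1.5], "adj_p": [0.001]}, index=["gc"])
        rep = erna_deregulation_report(
            [cand], counts, [f"WT_{i}" for i in range(4)],
            [f"M_{i}" for i in range(3)], mrna_table=mrna,
        )
        assert rep.loc[0, "erna_log2fc"] < 0
        assert bool(rep.loc[0, "concordantly_down"])

    def test_non_deregulated_control_not_flagged(self):
        cand = self._candidate(gene="ctrl")
        counts = pd.DataFrame(
            [[200, 210, 190, 205, 200, 195, 208]],
            index=["erna_1"],
            columns=[f"WT_{i}" for i in range(4)] + [f"M_{i}" for i in range(3)],
        )
        mrna = pd.DataFrame({"log2fc": [0.01], "adj_p": [0.9]}, index=["ctrl"])
        rep = erna_deregulation_report(
            [cand], counts, [f"WT_{i}" for i in range(4)],
            [f"M_{i}" for i in range(3)], mrna_table=mrna,
        )
        assert not bool(rep.loc[0, "concordantly_down"])

    def test_all_zero_candidate_flagged_undefined(self):
        cand = self._candidate()
        counts = pd.DataFrame(
            [[0] * 7],
            index=["erna_1"],
            columns=[f"WT_{i}" for i in range(4)] + [f"M_{i}" for i in range(3)],
        )
        rep = erna_deregulation_report(
            [cand], counts, [f"WT_{i}" for i in range(4)],
            [f"M_{i}" for i in range(3)],
        )
        assert not rep.loc[0, "counts_defined"]
        assert not bool(rep.loc[0, "concordantly_down"])


class TestEndToEndOnSimulation:
    def test_planted_ernas_designated_and_masked_strand_clean(self, small_dataset):
        ds = small_dataset
        ann = ds.annotation
        filtered = [filter_reads_for_erna(l, ann) for l in ds.rna["WT"]]
        pooled = ReadLibrary.concat(filtered)
        regions = detect_transcribed_regions(pooled, ann.chrom_sizes)
        # every planted eRNA interval is recovered by a same-strand region
        found = 0
        for gid in ds.truth.gene_ids("broad_identity"):
            es, ee, strand = ds.truth.genes[gid].erna
            found += any(
                r.strand == strand
                and min(r.end, ee) - max(r.start, es) > 0.5 * (ee - es)
                for r in regions
            )
        assert found >= 0.9 * len(ds.truth.gene_ids("broad_identity"))
        # no region overlaps an extended protein-coding gene on the strand
        # whose reads the filter removes
        for r in regions:
            for g in ann.genes_on(r.chrom):
                if g.biotype != "protein_coding":
                    continue
                ext = extend_gene_region(g, 3000, 10_000, ann.chrom_sizes[g.chrom])
                overlap = min(r.end, ext.end) - max(r.start, ext.start)
                if overlap > 0:
                    assert r.strand == g.strand

    def test_region_counts_recover_planted_fold_change(self, small_dataset):
        ds = small_dataset
        ann = ds.annotation
        filtered = {
            g: [filter_reads_for_erna(l, ann) for l in ds.rna[g]]
            for g in ("WT", "SCA7")
        }
        candidates = [
            ErnaCandidate(
                interval=Interval("chr1", g.erna[0], g.erna[1], g.erna[2]),
                strand=g.erna[2],
                is_erna=True,
                annotated_gene=g.gene_id,
            )
            for g in ds.truth.genes.values()
            if g.erna is not None
        ]
        samples = {
            f"{g}_{i + 1}": lib
            for g in ("WT", "SCA7")
            for i, lib in enumerate(filtered[g])
        }
        counts = count_reads_in_regions(candidates, samples)
        wt_cols = [c for c in counts.columns if c.startswith("WT")]
        mut_cols = [c for c in counts.columns if c.startswith("SCA7")]
        ratio = (
            counts[mut_cols].mean(axis=1) / counts[wt_cols].mean(axis=1)
        ).median()
        assert ratio == pytest.approx(2 ** -1.2, rel=0.25)
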