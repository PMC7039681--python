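"""BED I/O, promoter windows, acetylation classification, target tests."""

import numpy as np
import pandas as pd
import pytest

from burstline.chip_targets import (classify_acetylation, gene_targets,
                                    promoter_windows, read_bed,
                                    target_burst_comparison, write_bed,
                                    _build_trees, _overlaps)


def _bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestBedIO:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t600\n")
        t = read_bed(p)
        assert t.iloc[0].tolist() == ["chr1", 100, 600]

    def test_round_trip(self, tmp_path, rng):
        start = rng.integers(0, 10_000, 50)
        t = _bed([(f"chr{i%3+1}", s, s + 500) for i, s in enumerate(start)])
        p = tmp_path / "b.bed"
        write_bed(t, p)
        pd.testing.assert_frame_equal(read_bed(p), t.astype({"start": int, "end": int}))

    @pytest.mark.parametrize("line", ["chr1\t600\t100", "chr1\t-5\t100",
                                      "chr1\t100", "chr1\tx\t200"])
    def test_malformed_line_names_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\n" + line + "\n")
        with pytest.raises(ValueError, match=":2:"):
            read_bed(p)

    def test_comments_and_track_lines_skipped(self, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text("# comment\ntrack name=x\nchr2\t10\t20\n")
        assert len(read_bed(p)) == 1


class TestPromoterWindows:
    def test_plus_strand_minus_1kb_plus_500(self):
        tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                            "pos": [10_000], "strand": ["+"]})
        w = promoter_windows(tss)
        assert (w["start"].iloc[0], w["end"].iloc[0]) == (9000, 10_500)

    def test_minus_strand_mirrored(self):
        tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                            "pos": [10_000], "strand": ["-"]})
        w = promoter_windows(tss)
        assert (w["start"].iloc[0], w["end"].iloc[0]) == (9500, 11_000)

    def test_clamped_at_zero(self):
        tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                            "pos": [200], "strand": ["+"]})
        w = promoter_windows(tss)
        assert (w["start"].iloc[0], w["end"].iloc[0]) == (0, 700)

    def test_unknown_strand_raises(self):
        tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                            "pos": [100], "strand": ["."]})
        with pytest.raises(ValueError, match="strand"):
            promoter_windows(tss)


class TestOverlapAlgebra:
    def test_agrees_with_brute_force_oracle(self, rng):
        """Interval-tree overlap flags equal O(n*m) all-pairs enumeration."""
        chroms = [f"chr{c}" for c in range(1, 4)]
        def random_intervals(n):
            start = rng.integers(0, 50_000, n)
            length = rng.integers(1, 800, n)
            return _bed([(chroms[i % 3], s, s + l)
                         for i, (s, l) in enumerate(zip(start, length))])
        peaks = random_intervals(1000)
        queries = random_intervals(1000)
        trees = _build_trees(peaks)
        fast = _overlaps(trees, queries["chrom"], queries["start"], queries["end"])
        slow = np.zeros(len(queries), dtype=bool)
        for i, (qc, qs, qe) in enumerate(queries.itertuples(index=False)):
            for pc, ps, pe in peaks.itertuples(index=False):
                if qc == pc and qs < pe and ps < qe:
                    slow[i] = True
                    break
        assert np.array_equal(fast, slow)


def _single_promoter():
    return pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                         "start": [1000], "end": [2500], "strand": ["+"]})


def _classify_one(k9_wt, k27_wt, k9_ko, k27_ko=None):
    hit = _bed([("chr1", 1200, 1700)])
    empty = _bed([])
    return classify_acetylation(
        _single_promoter(),
        k4me3_wt=hit, k9ac_wt=hit if k9_wt else empty,
        k27ac_wt=hit if k27_wt else empty,
        k9ac_ko=hit if k9_ko else empty,
        k27ac_ko=hit if (k27_ko if k27_ko is not None else k27_wt) else empty,
        k4me3_ko=hit)


class TestClassification:
    def test_wt_exclusive_k9only_is_target(self):
        ann, _ = _classify_one(k9_wt=True, k27_wt=False, k9_ko=False)
        assert ann["category_WT"].iloc[0] == "K9only"
        assert ann["target"].iloc[0]

    def test_dual_acetylation_is_not_target(self):
        ann, _ = _classify_one(k9_wt=True, k27_wt=True, k9_ko=False)
        assert ann["category_WT"].iloc[0] == "dual"
        assert not ann["target"].iloc[0]

    def test_k9_in_both_genotypes_is_not_target(self):
        ann, _ = _classify_one(k9_wt=True, k27_wt=False, k9_ko=True)
        assert ann["category_WT"].iloc[0] == "K9only"
        assert not ann["target"].iloc[0]

    def test_empty_k4me3_raises(self):
        with pytest.raises(ValueError, match="H3K4me3"):
            classify_acetylation(_single_promoter(), _bed([]), _bed([]), _bed([]),
                                 _bed([]), _bed([]), _bed([]))

    def test_categories_partition_assessable_promoters(self, small_experiment):
        tss, peaks = small_experiment["tss"], small_experiment["peaks"]
        ann, counts = classify_acetylation(
            promoter_windows(tss),
            peaks[("H3K4me3", "WT")], peaks[("H3K9ac", "WT")],
            peaks[("H3K27ac", "WT")], peaks[("H3K9ac", "KO")],
            peaks[("H3K27ac", "KO")], peaks[("H3K4me3", "KO")])
        for _, row in counts.iterrows():
            total = sum(row[c] for c in ("K9only", "K27only", "dual", "none"))
            assert total == row["assessable"]

    def test_recovers_truth_target_set_exactly(self, small_experiment):
        truth, tss, peaks = (small_experiment["truth"], small_experiment["tss"],
                             small_experiment["peaks"])
        ann, _ = classify_acetylation(
            promoter_windows(tss),
            peaks[("H3K4me3", "WT")], peaks[("H3K9ac", "WT")],
            peaks[("H3K27ac", "WT")], peaks[("H3K9ac", "KO")],
            peaks[("H3K27ac", "KO")], peaks[("H3K4me3", "KO")])
        recovered = set(gene_targets(ann).query("target")["gene_id"])
        expected = set(truth.loc[truth["target"], "gene_id"])
        assert recovered == expected


class TestTargetBurstComparison:
    @staticmethod
    def _diff_table(n_t, n_nt, shift, rng):
        genes = [f"g{i}" for i in range(n_t + n_nt)]
        fb = np.concatenate([rng.normal(-0.4 + shift, 0.1, n_t),
                             rng.normal(-0.4, 0.1, n_nt)])
        f_wt = rng.lognormal(0, 0.3, n_t + n_nt)
        table = pd.DataFrame({"gene_id": genes, "f_WT": f_wt,
                              "f_KO": f_wt * (1 + fb), "Fburst": fb})
        ann = pd.DataFrame({"gene_id": genes,
                            "target": [True] * n_t + [False] * n_nt})
        return table, ann

    def test_distinct_groups_detected(self, rng):
        table, ann = self._diff_table(30, 120, shift=-0.3, rng=rng)
        res = target_burst_comparison(table, ann)
        assert res["Fburst"]["pvalue"] < 0.01
        assert res["Fburst"]["median_targets"] < res["Fburst"]["median_non_targets"]

    def test_identical_groups_are_null(self, rng):
        table, ann = self._diff_table(50, 50, shift=0.0, rng=rng)
        # same Fburst multiset in both groups: the rank test must not fire
        values = rng.normal(-0.4, 0.1, 50)
        table["Fburst"] = np.concatenate([values, values])
        res = target_burst_comparison(table, ann)
        assert res["Fburst"]["pvalue"] > 0.9
        assert res["Fburst"]["median_targets"] == res["Fburst"]["median_non_targets"]

    def test_all_non_target_raises(self, rng):
        table, ann = self._diff_table(30, 120, shift=0.0, rng=rng)
        ann["target"] = False
        with pytest.raises(ValueError):
            target_burst_comparison(table, ann)
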