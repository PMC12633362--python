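import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modstoich.pileup import (
    CANON,
    FAIL,
    MOD,
    PileupConfig,
    classify_call,
    classify_calls,
    filter_by_coverage,
    merge_site_tables,
    motif_mask,
    pileup_calls,
    read_bedmethyl,
    read_calls_table,
    write_bedmethyl,
    write_calls_table,
)

from conftest import make_site_table


class TestClassify:
    @pytest.mark.parametrize(
        "p,tau,expected",
        [
            (0.995, 0.99, MOD),
            (0.005, 0.99, CANON),
            (0.50, 0.99, FAIL),
            (0.99, 0.99, MOD),  # inclusive boundary
            (0.01, 0.99, CANON),  # canonical confidence exactly 0.99
            (0.0, 0.99, CANON),
            (1.0, 0.99, MOD),
            (0.7, 0.6, MOD),
            (0.5, 0.51, FAIL),
        ],
    )
    def test_examples(self, p, tau, expected):
        assert classify_call(p, tau) == expected

    @pytest.mark.parametrize("p", [-0.1, 1.1])
    def test_rejects_out_of_range_probability(self, p):
        with pytest.raises(ValueError):
            classify_call(p, 0.99)

    @pytest.mark.parametrize("tau", [0.5, 0.3, 1.01])
    def test_rejects_bad_tau(self, tau):
        with pytest.raises(ValueError):
            classify_call(0.9, tau)

    @given(
        p=st.floats(0, 1, allow_nan=False),
        tau=st.floats(0.501, 1.0, allow_nan=False),
    )
    def test_exactly_one_label(self, p, tau):
        label = classify_call(p, tau)
        assert label in (MOD, CANON, FAIL)
        # the label is uniquely determined by the two confidence tests
        assert (label == MOD) == (p >= tau)
        assert (label == CANON) == (p < tau and (1 - p) >= tau)

    def test_vectorized_matches_scalar(self, rng):
        p = rng.random(500)
        vec = classify_calls(p, 0.99)
        assert list(vec) == [classify_call(x, 0.99) for x in p]


class TestPileup:
    def test_single_site_counts(self, small_calls):
        table = pileup_calls(small_calls, PileupConfig(tau=0.99))
        row = table.df.iloc[0]
        assert (row.n_mod, row.n_canon, row.n_fail) == (6, 3, 1)
        assert row.valid_cov == 9
        assert row.f == pytest.approx(6 / 9)

    def test_empty_stream(self):
        table = pileup_calls(pd.DataFrame(
            columns=["read_id", "chrom", "pos0", "strand", "p_mod"]))
        assert table.n_sites == 0

    def test_all_fail_gives_null_stoichiometry(self):
        calls = pd.DataFrame(
            {"read_id": ["a", "b"], "chrom": "chr1", "pos0": 5,
             "strand": "+", "p_mod": [0.4, 0.6]}
        )
        table = pileup_calls(calls)
        row = table.df.iloc[0]
        assert row.valid_cov == 0
        assert np.isnan(row.f)

    def test_duplicate_read_at_site_is_error(self, small_calls):
        dup = pd.concat([small_calls, small_calls.iloc[[0]]])
        with pytest.raises(ValueError, match="r0"):
            pileup_calls(dup)

    def test_malformed_strand_is_error(self, small_calls):
        bad = small_calls.assign(strand=".")
        with pytest.raises(ValueError, match="strand"):
            pileup_calls(bad)

    def test_oracle_equivalence_random_calls(self, rng):
        """Pileup counts must equal an independent brute-force tally."""
        n = 2000
        calls = pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(n)],
                "chrom": rng.choice(["chr1", "chr2"], n),
                "pos0": rng.integers(0, 30, n),
                "strand": rng.choice(["+", "-"], n),
                "p_mod": rng.random(n),
            }
        )
        tau = 0.99
        # brute force: plain dict tally, no shared code path
        expected = {}
        for c in calls.itertuples(index=False):
            key = (c.chrom, c.pos0, c.strand)
            tally = expected.setdefault(key, [0, 0, 0])
            if c.p_mod >= tau:
                tally[0] += 1
            elif 1 - c.p_mod >= tau:
                tally[1] += 1
            else:
                tally[2] += 1
        table = pileup_calls(calls, PileupConfig(tau=tau))
        assert table.n_sites == len(expected)
        for row in table.df.itertuples(index=False):
            assert expected[(row.chrom, row.pos0, row.strand)] == [
                row.n_mod, row.n_canon, row.n_fail
            ]
            assert row.n_mod + row.n_canon + row.n_fail == sum(
                expected[(row.chrom, row.pos0, row.strand)]
            )


class TestMerge:
    def test_counts_sum_and_f_recomputed(self):
        a = make_site_table([("chr1", 7, "+", 3, 7, 0)])
        b = make_site_table([("chr1", 7, "+", 2, 8, 1)])
        merged = merge_site_tables([a, b])
        row = merged.df.iloc[0]
        assert (row.n_mod, row.n_canon, row.n_fail) == (5, 15, 1)
        assert row.f == pytest.approx(0.25)

    def test_merge_with_empty_is_identity(self):
        a = make_site_table([("chr1", 7, "+", 3, 7, 0), ("chr2", 1, "-", 4, 6, 2)])
        empty = make_site_table([])
        merged = merge_site_tables([a, empty])
        pd.testing.assert_frame_equal(
            merged.df.reset_index(drop=True), a.df.reset_index(drop=True)
        )

    def test_tau_mismatch_is_error(self):
        a = make_site_table([("chr1", 7, "+", 3, 7, 0)], tau=0.99)
        b = make_site_table([("chr1", 7, "+", 2, 8, 0)], tau=0.95)
        with pytest.raises(ValueError, match="tau"):
            merge_site_tables([a, b])

    def test_homomorphism_with_pileup(self, rng):
        """merge(pileup(A), pileup(B)) == pileup(A ∪ B) for disjoint reads."""
        def random_calls(prefix, n):
            return pd.DataFrame(
                {
                    "read_id": [f"{prefix}{i}" for i in range(n)],
                    "chrom": "chr1",
                    "pos0": rng.integers(0, 20, n),
                    "strand": "+",
                    "p_mod": rng.random(n),
                }
            )

        a, b = random_calls("a", 400), random_calls("b", 300)
        merged = merge_site_tables([pileup_calls(a), pileup_calls(b)])
        direct = pileup_calls(pd.concat([a, b], ignore_index=True))
        pd.testing.assert_frame_equal(
            merged.df[["chrom", "pos0", "strand", "n_mod", "n_canon", "n_fail"]],
            direct.df[["chrom", "pos0", "strand", "n_mod", "n_canon", "n_fail"]],
        )


class TestCoverageFilter:
    @pytest.mark.parametrize(
        "valid_cov,threshold,kept", [(50, 50, True), (49, 50, False)]
    )
    def test_inclusive_boundary(self, valid_cov, threshold, kept):
        table = make_site_table([("chr1", 0, "+", valid_cov, 0, 0)])
        out = filter_by_coverage(table, threshold)
        assert out.n_sites == (1 if kept else 0)

    def test_zero_threshold_is_identity(self):
        table = make_site_table(
            [("chr1", 0, "+", 1, 0, 0), ("chr1", 5, "+", 0, 0, 3)]
        )
        assert filter_by_coverage(table, 0).n_sites == 2


class TestMotifMask:
    @pytest.fixture
    def fasta(self, tmp_path):
        # chr1: positions 0-9; DRACH center at pos 2 is GGACT (kept)
        # chrM: AGTCC has center T on + but revcomp GGACT on -
        path = tmp_path / "ref.fa"
        path.write_text(">chr1\nGGACTGGGCT\n>chrM\nAGTCC\n")
        return str(path)

    def test_plus_strand_match_and_mismatch(self, fasta):
        table = make_site_table(
            [("chr1", 2, "+", 5, 5, 0),   # GGACT -> kept
             ("chr1", 7, "+", 5, 5, 0)]   # GGGCT -> center not A
        )
        out = motif_mask(table, fasta, "DRACH")
        assert out.df["pos0"].tolist() == [2]

    def test_minus_strand_uses_reverse_complement(self, fasta):
        # plus-strand 5-mer AGTCC reverse-complements to GGACT
        table = make_site_table([("chrM", 2, "-", 1, 1, 0)])
        out = motif_mask(table, fasta, "DRACH")
        assert out.n_sites == 1

    def test_contig_edge_dropped(self, fasta):
        table = make_site_table([("chr1", 1, "+", 1, 1, 0)])
        assert motif_mask(table, fasta, "DRACH").n_sites == 0

    def test_absent_chromosome_is_error(self, fasta):
        table = make_site_table([("chrZ", 2, "+", 1, 1, 0)])
        with pytest.raises(KeyError, match="chrZ"):
            motif_mask(table, fasta, "DRACH")

    @pytest.mark.parametrize("motif", ["DRAC", "DRGCH"])
    def test_rejects_invalid_motif(self, fasta, motif):
        table = make_site_table([("chr1", 2, "+", 1, 1, 0)])
        with pytest.raises(ValueError):
            motif_mask(table, fasta, motif)


class TestIO:
    def test_calls_table_round_trip(self, tmp_path, small_calls):
        path = tmp_path / "calls.tsv"
        write_calls_table(small_calls, path)
        back = read_calls_table(path)
        assert len(back) == len(small_calls)
        assert back["read_id"].tolist() == small_calls["read_id"].tolist()
        np.testing.assert_allclose(back["p_mod"], small_calls["p_mod"], rtol=1e-5)

    @pytest.mark.parametrize(
        "line,match",
        [
            ("r1\tchr1\t5\t+", "5 tab-separated columns"),
            ("r1\tchr1\t5\t+\tnotanumber", "notanumber"),
            ("r1\tchr1\t5\t+\t1.5", "outside"),
            ("r1\tchr1\t5\t*\t0.5", "strand"),
        ],
    )
    def test_malformed_calls_row_reports_line(self, tmp_path, line, match):
        path = tmp_path / "bad.tsv"
        path.write_text("#header\n" + line + "\n")
        with pytest.raises(ValueError, match="2"):  # 1-based line number
            read_calls_table(path)

    def test_bedmethyl_round_trip(self, tmp_path):
        table = make_site_table(
            [
                ("chr1", 10, "+", 3, 7, 1),
                ("chr1", 99, "-", 0, 55, 2),
                ("chr2", 0, "+", 123, 456, 78),
            ]
        )
        path = tmp_path / "sites.bed"
        write_bedmethyl(table, path)
        back = read_bedmethyl(path)
        for col in ("n_mod", "n_canon", "n_fail"):
            assert back.df[col].tolist() == table.df[col].tolist()
        np.testing.assert_allclose(back.df["f"], table.df["f"], atol=1e-6)

    def test_bedmethyl_rejects_multibase_record(self, tmp_path):
        path = tmp_path / "bad.bed"
        fields = ["chr1", "10", "12", "a", "10", "+", "10", "12",
                  "255,0,0", "10", "30.00", "3", "7", "0", "0", "1", "0", "0"]
        path.write_text("\t".join(fields) + "\n")
        with pytest.raises(ValueError, match="single-base"):
            read_bedmethyl(path)

    def test_bedmethyl_header_skipped(self, tmp_path):
        table = make_site_table([("chr1", 10, "+", 3, 7, 1)])
        path = tmp_path / "sites.bed"
        write_bedmethyl(table, path)
        path.write_text("#comment\n" + path.read_text())
        assert read_bedmethyl(path).n_sites == 1


class TestModBamAdapter:
    def test_extracts_probabilities_from_mm_ml_tags(self, tmp_path):
        import pysam

        from modstoich.pileup import calls_from_modbam

        sam = tmp_path / "reads.sam"
        header = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:100\n"
        # AAAA aligned at 0-based position 10; all four A's carry m6A calls
        rec = (
            "read1\t0\tchr1\t11\t60\t4M\t*\t0\t0\tAAAA\tIIII\t"
            "MM:Z:A+a,0,0,0,0;\tML:B:C,255,200,100,0\n"
        )
        sam.write_text(header + rec)
        calls = calls_from_modbam(str(sam))
        assert calls["pos0"].tolist() == [10, 11, 12, 13]
        np.testing.assert_allclose(
            calls["p_mod"],
            [(q + 0.5) / 256 for q in (255, 200, 100, 0)],
        )
        assert (calls["strand"] == "+").all()
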