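"""Summary-stat I/O, greedy clumping, and allele harmonization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import record
from mrkit.sumstats import (
    AssociationRecord, SumstatsError, clump, harmonize,
    read_r2_table, read_sumstats, write_sumstats,
)

HEADER = "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"


def _write(tmp_path, rows, header=HEADER):
    p = tmp_path / "sumstats.tsv"
    p.write_text(header + "".join(rows))
    return p


class TestReadWrite:
    def test_well_formed_file_reads_all_rows(self, tmp_path):
        rows = [f"rs{i}\t1\t{1000 * (i + 1)}\tA\tG\t0.2\t0.1\t0.01\t1e-9\t5000\n"
                for i in range(3)]
        records, rejected = read_sumstats(_write(tmp_path, rows))
        assert len(records) == 3 and rejected == []
        assert records[0].snp_id == "rs0" and records[0].beta == 0.1

    def test_nonpositive_se_row_rejected_with_line_number(self, tmp_path):
        rows = ["rs1\t1\t1000\tA\tG\t0.2\t0.1\t0.0\t1e-9\t5000\n",
                "rs2\t1\t2000\tA\tG\t0.2\t0.1\t0.01\t1e-9\t5000\n"]
        records, rejected = read_sumstats(_write(tmp_path, rows))
        assert [r.snp_id for r in records] == ["rs2"]
        assert rejected == [(2, "nonpositive SE")]

    def test_lowercase_alleles_uppercased(self, tmp_path):
        rows = ["rs1\t1\t1000\ta\tg\t0.2\t0.1\t0.01\t1e-9\t5000\n"]
        records, _ = read_sumstats(_write(tmp_path, rows))
        assert (records[0].effect_allele, records[0].other_allele) == ("A", "G")

    def test_indel_and_multiallelic_rejected(self, tmp_path):
        rows = ["rs1\t1\t1000\tAT\tG\t0.2\t0.1\t0.01\t1e-9\t5000\n",
                "rs2\t1\t2000\tA\tA\t0.2\t0.1\t0.01\t1e-9\t5000\n"]
        records, rejected = read_sumstats(_write(tmp_path, rows))
        assert records == [] and len(rejected) == 2

    def test_missing_mandatory_column_is_configuration_error(self, tmp_path):
        p = _write(tmp_path, ["rs1\t1\tA\tG\t0.1\t0.01\t1e-9\n"],
                   header="SNP\tCHR\tEA\tOA\tBETA\tSE\tP\n")
        with pytest.raises(SumstatsError, match="POS"):
            read_sumstats(p)

    def test_column_map_dialect(self, tmp_path):
        p = tmp_path / "dialect.tsv"
        p.write_text("rsid\tchrom\tbp\ta1\ta2\tfreq\tb\tstderr\tpv\tsize\n"
                     "rs1\t2\t500\tC\tT\t0.4\t-0.2\t0.02\t1e-20\t999\n")
        records, _ = read_sumstats(p, column_map={
            "SNP": "rsid", "CHR": "chrom", "POS": "bp", "EA": "a1", "OA": "a2",
            "EAF": "freq", "BETA": "b", "SE": "stderr", "P": "pv", "N": "size"})
        assert records[0].beta == -0.2 and records[0].n == 999

    def test_round_trip(self, tmp_path):
        recs = [record(snp_id=f"rs{i}", pos=1000 + i, beta=0.1 * i + 0.01)
                for i in range(4)]
        p = tmp_path / "out.tsv"
        write_sumstats(recs, p)
        back, rejected = read_sumstats(p)
        assert rejected == [] and back == recs


class TestClump:
    def test_ld_pair_keeps_smaller_pvalue(self):
        a = record(snp_id="a", pos=1000, pval=1e-10)
        b = record(snp_id="b", pos=6000, pval=1e-9)
        kept = clump([a, b], {("a", "b"): 0.5, ("b", "a"): 0.5})
        assert [r.snp_id for r in kept] == ["a"]

    def test_sub_threshold_ld_keeps_both(self):
        a = record(snp_id="a", pos=1000, pval=1e-10)
        b = record(snp_id="b", pos=6000, pval=1e-9)
        kept = clump([a, b], {("a", "b"): 0.0005, ("b", "a"): 0.0005})
        assert [r.snp_id for r in kept] == ["a", "b"]

    def test_chain_keeps_endpoints(self):
        # A--B and B--C in LD, A--C independent; greedy by p keeps A then C
        a = record(snp_id="a", pos=1000, pval=1e-12)
        b = record(snp_id="b", pos=2000, pval=1e-10)
        c = record(snp_id="c", pos=3000, pval=1e-8)
        r2 = {}
        for x, y, v in [("a", "b", 0.2), ("b", "c", 0.2), ("a", "c", 0.0)]:
            r2[(x, y)] = r2[(y, x)] = v
        kept = clump([a, b, c], r2)
        assert [r.snp_id for r in kept] == ["a", "c"]

    def test_missing_r2_for_in_window_pair_names_pair(self):
        a = record(snp_id="a", pos=1000, pval=1e-10)
        b = record(snp_id="b", pos=6000, pval=1e-9)
        with pytest.raises(SumstatsError, match=r"\(a, b\)"):
            clump([a, b], {})

    def test_distant_pair_needs_no_r2(self):
        a = record(snp_id="a", pos=1000, pval=1e-10)
        b = record(snp_id="b", pos=1000 + 10_001_000, pval=1e-9)
        assert len(clump([a, b], {})) == 2

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.data())
    def test_greedy_result_is_valid_against_full_accepted_set(self, data):
        n = data.draw(st.integers(2, 8))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        recs = [record(snp_id=f"s{i}", chrom=str(rng.integers(1, 3)),
                       pos=int(rng.integers(1, 20_000) * 1000),
                       pval=float(rng.uniform(1e-12, 1e-6))) for i in range(n)]
        r2 = {}
        for i in range(n):
            for k in range(i + 1, n):
                v = float(rng.choice([0.0, 0.0005, 0.3, 0.9]))
                r2[(recs[i].snp_id, recs[k].snp_id)] = v
                r2[(recs[k].snp_id, recs[i].snp_id)] = v
        kept = clump(recs, r2, r2_max=0.001, window_kb=10_000)
        kept_ids = {r.snp_id for r in kept}
        by_id = {r.snp_id: r for r in recs}

        def conflict(x, y):
            return (x.chrom == y.chrom and abs(x.pos_bp - y.pos_bp) <= 10_000_000
                    and r2[(x.snp_id, y.snp_id)] >= 0.001)

        # accepted SNPs are pairwise compatible
        for x in kept:
            for y in kept:
                if x.snp_id != y.snp_id:
                    assert not conflict(x, y)
        # every rejected SNP conflicts with an accepted SNP of smaller p-value
        for r in recs:
            if r.snp_id not in kept_ids:
                assert any(conflict(r, by_id[k]) and by_id[k].pval < r.pval
                           for k in kept_ids)


def _pal(eaf, beta=0.05, **kw):
    return record(ea="A", oa="T", eaf=eaf, beta=beta, **kw)


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        exp = [record(ea="A", oa="G", beta=0.1)]
        out = [record(ea="G", oa="A", beta=0.05, eaf=0.7)]
        h = harmonize(exp, out)
        assert h.alpha_hat[0] == pytest.approx(-0.05)

    def test_palindrome_oriented_by_frequency(self):
        # frequencies 0.10 vs 0.89 agree only after strand/effect flip
        h = harmonize([_pal(0.10)], [_pal(0.89, beta=0.05)])
        assert h.alpha_hat[0] == pytest.approx(-0.05)

    def test_palindrome_matching_frequency_kept_as_is(self):
        h = harmonize([_pal(0.10)], [_pal(0.12, beta=0.05)])
        assert h.alpha_hat[0] == pytest.approx(0.05)

    def test_high_maf_palindrome_dropped_ambiguous(self):
        h = harmonize([_pal(0.48), record(snp_id="rs2")],
                      [_pal(0.48), record(snp_id="rs2")])
        assert ("rs1", "ambiguous palindrome") in h.dropped

    def test_palindrome_without_frequency_dropped(self):
        h = harmonize([_pal(None), record(snp_id="rs2")],
                      [_pal(0.2), record(snp_id="rs2")])
        assert ("rs1", "palindrome without frequency") in h.dropped

    def test_missing_in_outcome_and_allele_mismatch_reasons(self):
        exp = [record(snp_id="rs1", ea="A", oa="G"),
               record(snp_id="rs2", ea="A", oa="G"),
               record(snp_id="rs3", ea="A", oa="G")]
        out = [record(snp_id="rs2", ea="A", oa="C"),
               record(snp_id="rs3", ea="A", oa="G")]
        h = harmonize(exp, out)
        assert ("rs1", "missing in outcome") in h.dropped
        assert ("rs2", "allele mismatch") in h.dropped
        assert h.snp_ids == ["rs3"]

    def test_strand_flipped_nonpalindrome_dropped_explicitly(self):
        exp = [record(snp_id="rs1", ea="A", oa="G"), record(snp_id="rs2")]
        out = [record(snp_id="rs1", ea="T", oa="C"), record(snp_id="rs2")]
        h = harmonize(exp, out)
        assert ("rs1", "strand mismatch") in h.dropped

    def test_conservation_of_input_snps(self):
        exp = [record(snp_id=f"rs{i}", ea="A", oa="G") for i in range(5)]
        out = [record(snp_id="rs0", ea="A", oa="G"),
               record(snp_id="rs1", ea="G", oa="A"),
               record(snp_id="rs2", ea="A", oa="C")]
        h = harmonize(exp, out)
        assert len(h.snp_ids) + len(h.dropped) == len(exp)
        assert set(h.snp_ids) | {s for s, _ in h.dropped} == {r.snp_id for r in exp}

    def test_idempotence_on_aligned_pair(self):
        exp = [record(snp_id=f"rs{i}", ea="A", oa="G", beta=0.1 * (i + 1))
               for i in range(3)]
        out = [record(snp_id=f"rs{i}", ea="A", oa="G", beta=0.02 * (i + 1))
               for i in range(3)]
        h = harmonize(exp, out)
        assert np.allclose(h.alpha_hat, [0.02, 0.04, 0.06])
        assert h.dropped == []

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(-0.5, 0.5), min_size=1, max_size=6))
    def test_sign_coherence_under_global_allele_swap(self, betas):
        exp = [record(snp_id=f"rs{i}", ea="A", oa="G") for i in range(len(betas))]
        out = [record(snp_id=f"rs{i}", ea="A", oa="G", beta=b, eaf=0.3)
               for i, b in enumerate(betas)]
        swapped = [record(snp_id=f"rs{i}", ea="G", oa="A", beta=b, eaf=0.7)
                   for i, b in enumerate(betas)]
        direct = harmonize(exp, out)
        flipped = harmonize(exp, swapped)
        assert np.allclose(flipped.alpha_hat, -direct.alpha_hat)

    def test_empty_intersection_raises(self):
        with pytest.raises(SumstatsError, match="no usable instruments"):
            harmonize([record(snp_id="rs1")], [record(snp_id="rs2")])


def test_r2_table_symmetric_completion(tmp_path):
    p = tmp_path / "ld.tsv"
    p.write_text("snp_a\tsnp_b\tr2\nrs1\trs2\t0.3\n")
    table = read_r2_table(p)
    assert table[("rs1", "rs2")] == table[("rs2", "rs1")] == 0.3
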