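"""Hit-table parsing and threshold filtering."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoscan.hits import (
    HitTableError,
    ProteinHit,
    filter_blast_hits,
    filter_hmm_hits,
    read_blast_table,
    read_feature_table,
    read_hmmer_table,
)

TBLOUT_HEADER = "# target name  accession query name  accession  ...\n"


def tblout_line(protein, profile, full, b1, evalue="1.0e-50"):
    return (
        f"{protein} -          {profile} -          {evalue} {full:.1f}   0.1 "
        f"{evalue} {b1:.1f}   0.1   1.0   1   0   0   1   1   1   1 some protein\n"
    )


def domtblout_line(protein, profile, full, dom_score, dom_i=1, dom_n=1):
    return (
        f"{protein} -          450 {profile} -          420 1.0e-50 {full:.1f} 0.1 "
        f"{dom_i} {dom_n} 1.0e-40 1.0e-42 {dom_score:.1f} 0.1 "
        f"1 420 3 440 1 450 0.95 some protein\n"
    )


class TestReadHmmer:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "x.tblout"
        p.write_text(TBLOUT_HEADER + tblout_line("WP_1.1", "GPE00530", 310.0, 305.0))
        (hit,) = read_hmmer_table(p, "tblout", genome_id="G1")
        assert hit.protein_id == "WP_1.1" and hit.gpe_id == "GPE00530"
        assert hit.best1dom_bits == 305.0 and hit.full_bits == 310.0
        assert hit.genome_id == "G1"

    def test_comments_only_gives_empty_list(self, tmp_path):
        p = tmp_path / "x.tblout"
        p.write_text(TBLOUT_HEADER + "# nothing here\n\n")
        assert read_hmmer_table(p) == []

    def test_duplicate_rows_keep_max_best1dom(self, tmp_path):
        scores = [120.0, 180.0, 150.0]
        p = tmp_path / "x.tblout"
        p.write_text("".join(tblout_line("WP_1.1", "GPE01030", s + 1, s) for s in scores))
        (hit,) = read_hmmer_table(p)
        assert hit.best1dom_bits == max(scores)  # brute-force max over rows

    def test_domtblout_best_domain(self, tmp_path):
        p = tmp_path / "x.domtblout"
        p.write_text(
            domtblout_line("WP_1.1", "GPE01030", 300.0, 120.0, 1, 2)
            + domtblout_line("WP_1.1", "GPE01030", 300.0, 250.0, 2, 2)
        )
        (hit,) = read_hmmer_table(p, "domtblout")
        assert hit.best1dom_bits == 250.0 and hit.full_bits == 300.0

    def test_truncated_row_reports_line_number(self, tmp_path):
        p = tmp_path / "x.tblout"
        p.write_text(TBLOUT_HEADER + "WP_1.1 - GPE00530 broken\n")
        with pytest.raises(HitTableError, match=r":2: truncated"):
            read_hmmer_table(p)

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(HitTableError, match="dialect"):
            read_hmmer_table(tmp_path / "x", "pfamtab")

    def test_cross_check_against_biopython(self, tmp_path):
        """On a duplicate-free table our parser agrees with Bio.SearchIO."""
        SearchIO = pytest.importorskip("Bio.SearchIO")
        p = tmp_path / "x.tblout"
        rows = [("WP_1.1", "GPE01030", 200.0, 180.0), ("WP_2.1", "GPE01030", 90.5, 88.2)]
        p.write_text(TBLOUT_HEADER + "".join(tblout_line(*r) for r in rows))
        ours = {(h.protein_id, h.gpe_id): h for h in read_hmmer_table(p)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for qr in SearchIO.parse(str(p), "hmmer3-tab"):
                for bio_hit in qr:
                    h = ours[(bio_hit.id, qr.id)]
                    assert h.full_bits == pytest.approx(bio_hit.bitscore)
                    assert h.best1dom_bits == pytest.approx(bio_hit.hsps[0].bitscore)


BLAST_COLS = ("qseqid", "sseqid", "pident", "ppos", "length", "qlen", "evalue", "bitscore")


class TestReadBlast:
    def test_coverage_computed_from_lengths(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("PdeG\tWP_1.1\t40.0\t45.0\t285\t300\t1e-30\t250\n")
        (hit,) = read_blast_table(p, BLAST_COLS, query_to_family={"PdeG": "GPE80010"})
        assert hit.coverage_pct == pytest.approx(95.0)
        assert hit.similarity_pct == 45.0
        assert hit.gpe_id == "GPE80010"

    def test_declared_coverage_column_used_verbatim(self, tmp_path):
        cols = ("qseqid", "sseqid", "ppos", "qcovs")
        p = tmp_path / "b.tsv"
        p.write_text("Q\tWP_1.1\t50.0\t83.0\n")
        (hit,) = read_blast_table(p, cols)
        assert hit.coverage_pct == 83.0

    def test_overlong_alignment_clamped_with_warning(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("Q\tWP_1.1\t40.0\t45.0\t330\t300\t1e-30\t250\n")
        with pytest.warns(UserWarning, match="clamped"):
            (hit,) = read_blast_table(p, BLAST_COLS)
        assert hit.coverage_pct == 100.0  # manual: 100*330/300 = 110 -> clamp

    def test_missing_required_column_named(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("")
        with pytest.raises(HitTableError, match="ppos"):
            read_blast_table(p, ("qseqid", "sseqid", "length", "qlen"))
        with pytest.raises(HitTableError, match="qcovs"):
            read_blast_table(p, ("qseqid", "sseqid", "ppos"))

    def test_multiple_hsps_keep_max_bitscore(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text(
            "Q\tWP_1.1\t40.0\t45.0\t150\t300\t1e-10\t100\n"
            "Q\tWP_1.1\t42.0\t48.0\t285\t300\t1e-30\t250\n"
        )
        (hit,) = read_blast_table(p, BLAST_COLS)
        assert hit.full_bits == 250.0 and hit.coverage_pct == pytest.approx(95.0)


FEATURE_HEADER = (
    "# feature\tclass\tassembly\tassembly_unit\tseq_type\tchromosome\t"
    "genomic_accession\tstart\tend\tstrand\tproduct_accession\t"
    "non-redundant_refseq\trelated_accession\tname\tsymbol\tGeneID\t"
    "locus_tag\tfeature_interval_length\tproduct_length\tattributes\n"
)


def feature_row(feature, replicon, start, pid):
    return (
        f"{feature}\twith_protein\tA\tP\tchromosome\t1\t{replicon}\t{start}\t"
        f"{start + 900}\t+\t{pid}\t\t\tx\t\t\tL{start}\t900\t300\t\n"
    )


class TestReadFeatures:
    def test_ordinal_by_start_per_replicon(self, tmp_path):
        p = tmp_path / "ft.txt"
        p.write_text(
            FEATURE_HEADER
            + feature_row("CDS", "R1", 5000, "WP_3.1")
            + feature_row("CDS", "R1", 1000, "WP_1.1")
            + feature_row("CDS", "R2", 9000, "WP_9.1")
            + feature_row("CDS", "R1", 3000, "WP_2.1")
        )
        recs = read_feature_table(p, genome_id="G1")
        by_id = {r.protein_id: r for r in recs}
        assert [by_id[f"WP_{i}.1"].ordinal_index for i in (1, 2, 3)] == [1, 2, 3]
        assert by_id["WP_9.1"].ordinal_index == 1  # replicons numbered independently

    def test_non_cds_rows_excluded(self, tmp_path):
        p = tmp_path / "ft.txt"
        p.write_text(
            FEATURE_HEADER
            + feature_row("gene", "R1", 1000, "")
            + feature_row("CDS", "R1", 1000, "WP_1.1")
            + feature_row("rRNA", "R1", 2000, "WP_X.1")
        )
        recs = read_feature_table(p)
        assert [r.protein_id for r in recs] == ["WP_1.1"]

    def test_header_mismatch_names_columns(self, tmp_path):
        p = tmp_path / "ft.txt"
        p.write_text("foo\tbar\n1\t2\n")
        with pytest.raises(HitTableError, match="genomic_accession"):
            read_feature_table(p)


class TestFilters:
    @pytest.mark.parametrize(
        "bits, expected", [(305.0, True), (303.0, True), (302.9, False)]
    )
    def test_hmm_threshold_inclusive(self, reg, bits, expected):
        h = ProteinHit("G1", "WP_1.1", "GPE00530", best1dom_bits=bits, full_bits=bits)
        (out,) = filter_hmm_hits([h], reg)
        assert out.passes_threshold is expected

    def test_unregistered_profile_rejected(self, reg):
        h = ProteinHit("G1", "WP_1.1", "GPE99999", best1dom_bits=500.0)
        with pytest.raises(KeyError):
            filter_hmm_hits([h], reg)

    @pytest.mark.parametrize(
        "sim, cov, expected",
        [
            (30.0, 90.0, True),  # default cutoffs, inclusive
            (95.0, 89.9, False),  # conjunction: coverage narrowly fails
            (29.9, 100.0, False),
        ],
    )
    def test_blast_default_cutoffs(self, reg, sim, cov, expected):
        h = ProteinHit("G1", "WP_1.1", "GPE80020", similarity_pct=sim, coverage_pct=cov)
        (out,) = filter_blast_hits([h], reg)
        assert out.passes_threshold is expected

    def test_pdeg_raised_similarity_cutoff(self, reg):
        pdeg = reg.family_by_query_name("PdeG").gpe_id
        lo = ProteinHit("G1", "WP_1.1", pdeg, similarity_pct=65.0, coverage_pct=95.0)
        hi = ProteinHit("G1", "WP_2.1", pdeg, similarity_pct=70.0, coverage_pct=95.0)
        lo, hi = filter_blast_hits([lo, hi], reg)
        assert not lo.passes_threshold and hi.passes_threshold

    @given(
        scores=st.lists(
            st.floats(0, 600, allow_nan=False), min_size=1, max_size=30
        ),
        seed=st.integers(0, 5),
    )
    @settings(max_examples=40, deadline=None)
    def test_filter_idempotent_and_order_independent(self, reg, scores, seed):
        import random

        fams = sorted(reg.hmm_families())
        rnd = random.Random(seed)
        hits = [
            ProteinHit("G1", f"WP_{i}.1", rnd.choice(fams), best1dom_bits=s, full_bits=s)
            for i, s in enumerate(scores)
        ]
        once = filter_hmm_hits(hits, reg)
        assert filter_hmm_hits(once, reg) == once
        shuffled = list(hits)
        rnd.shuffle(shuffled)
        key = lambda h: h.protein_id
        assert sorted(filter_hmm_hits(shuffled, reg), key=key) == sorted(once, key=key)

    def test_lowering_threshold_is_monotone(self, reg):
        """A lower cutoff never shrinks the passing set."""
        import dataclasses

        fam = reg.enzyme_families["GPE01030"]
        hits = [
            ProteinHit("G1", f"WP_{i}.1", "GPE01030", best1dom_bits=s, full_bits=s)
            for i, s in enumerate([10.0, 100.0, 319.9, 320.0, 500.0])
        ]
        passed_hi = {h.protein_id for h in filter_hmm_hits(hits, reg) if h.passes_threshold}
        lowered = dataclasses.replace(fam, threshold_bits=fam.threshold_bits - 100)
        reg2 = dataclasses.replace(
            reg, enzyme_families={**reg.enzyme_families, "GPE01030": lowered}
        )
        passed_lo = {h.protein_id for h in filter_hmm_hits(hits, reg2) if h.passes_threshold}
        assert passed_hi <= passed_lo
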