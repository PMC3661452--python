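"""Motif/RSS scanning, ORF detection and functionality classification."""

import itertools

import numpy as np
import pytest

from bovigh._seq import revcomp
from bovigh.config import ScanConfig
from bovigh.germline_scan import (FunctionalityReport, GenomicContig,
                                  check_rss_competence, classify_functionality,
                                  detect_orf_and_leader,
                                  find_regulatory_elements, find_rss,
                                  scan_contig, scan_motif)


def brute_force_motif(seq, motif, max_mismatch, exact_positions=()):
    """Independent sliding-window enumeration over both strands."""
    hits = set()
    m = len(motif)
    for strand in "+-":
        pattern = motif if strand == "+" else revcomp(motif)
        exact = (set(exact_positions) if strand == "+"
                 else {m - 1 - p for p in exact_positions})
        for i in range(len(seq) - m + 1):
            win = seq[i:i + m]
            mism = sum(1 for a, b in zip(win, pattern)
                       if a != b or a == "N")
            ok_exact = all(win[j] == pattern[j] != "N" for j in exact)
            if mism <= max_mismatch and ok_exact:
                hits.add((i, i + m, strand, mism))
    return hits


class TestScanMotif:
    def test_exact_hit(self):
        contig = GenomicContig("c", "TTCACAGTGAA")
        hits = [h for h in scan_motif(contig, "CACAGTG", 0)
                if h.strand == "+"]
        assert [(h.start, h.end, h.mismatches) for h in hits] == [(2, 9, 0)]

    def test_mismatch_threshold(self):
        contig = GenomicContig("c", "TTCACAGTGAA")
        assert not [h for h in scan_motif(contig, "CACAGTA", 0)
                    if h.strand == "+"]
        hits = [h for h in scan_motif(contig, "CACAGTA", 1)
                if h.strand == "+" and h.start == 2]
        assert hits and hits[0].mismatches == 1

    def test_n_never_matches(self):
        contig = GenomicContig("c", "TTCACNGTGAA")
        hits = [h for h in scan_motif(contig, "CACAGTG", 0)
                if h.strand == "+"]
        assert not hits
        hits = [h for h in scan_motif(contig, "CACAGTG", 1)
                if h.strand == "+"]
        assert hits and hits[0].mismatches == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGTN"), size=400,
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        motif = "".join(rng.choice(list("ACGT"), size=6))
        contig = GenomicContig("c", seq)
        got = {(h.start, h.end, h.strand, h.mismatches)
               for h in scan_motif(contig, motif, 1, exact_positions=(0,))}
        assert got == brute_force_motif(seq, motif, 1, (0,))

    def test_bad_inputs(self):
        contig = GenomicContig("c", "ACGTACGT")
        with pytest.raises(ValueError):
            scan_motif(contig, "ACZ T", 0)
        with pytest.raises(ValueError):
            scan_motif(contig, "ACG", 0)
        with pytest.raises(ValueError):
            GenomicContig("c", "")


class TestRSS:
    CFG = ScanConfig()

    def test_competence_examples(self):
        from bovigh.germline_scan import RSS, MotifHit

        def make(hept, nona, spacer):
            h = MotifHit("heptamer", 0, 7, "+", 0, hept)
            n = MotifHit("nonamer", 7 + spacer, 16 + spacer, "+", 0, nona)
            return check_rss_competence(RSS(h, n, spacer, 23))

        bad_hept = make("GACAGTG", "ACAAAAACC", 23)
        assert not bad_hept.competent and bad_hept.defects == ["heptamer_first3"]
        bad_nona = make("CACAGTG", "ACAGTAACC", 23)
        assert not bad_nona.competent and bad_nona.defects == ["nonamer_A_run"]
        good = make("CACAGTG", "ACAAAAACC", 23)
        assert good.competent and not good.defects

    def test_downstream_planting(self, rng):
        left = "".join(rng.choice(list("ACGT"), size=60))
        seq = left + "CACAGTG" + "T" * 23 + "ACAAAAACC"
        contig = GenomicContig("c", seq)
        out = find_rss(contig, 60, "+", "downstream", 23)
        assert len(out) == 1 and out[0].competent
        assert out[0].heptamer.start == 60 and out[0].spacer_length == 23

    def test_spacer_tolerance_marks_incompetent(self, rng):
        left = "".join(rng.choice(list("ACGT"), size=60))
        seq = left + "CACAGTG" + "T" * 22 + "ACAAAAACC"
        contig = GenomicContig("c", seq)
        out = find_rss(contig, 60, "+", "downstream", 23, spacer_tolerance=1)
        assert len(out) == 1
        assert not out[0].competent and out[0].defects == ["spacer_length"]

    def test_upstream_planting(self, rng):
        right = "".join(rng.choice(list("ACGT"), size=50))
        seq = revcomp("ACAAAAACC") + "G" * 23 + revcomp("CACAGTG") + right
        contig = GenomicContig("c", seq)
        out = find_rss(contig, 39, "+", "upstream", 23)
        assert len(out) == 1 and out[0].competent
        assert out[0].heptamer.strand == "-"

    def test_minus_strand_mirrors_plus(self, rng):
        left = "".join(rng.choice(list("ACGT"), size=40))
        seq = left + "CACAGTG" + "T" * 12 + "ACAAAAACC" + "GG"
        contig = GenomicContig("c", seq)
        plus = find_rss(contig, 40, "+", "downstream", 12)
        rc = GenomicContig("c", revcomp(seq))
        minus = find_rss(rc, len(seq) - 40, "-", "downstream", 12)
        assert len(plus) == len(minus) == 1
        assert minus[0].competent == plus[0].competent
        assert minus[0].heptamer.seq == plus[0].heptamer.seq

    def test_all_pairs_within_tolerance(self, rng):
        # two heptamers x two nonamers; only gaps within 23+-1 pair up
        seq = ("CACAGTG" + "A" * 0 + "CACAGTG" + "T" * 16
               + "ACAAAAACC" + "T" * 3 + "ACAAAAACC")
        contig = GenomicContig("c", "GG" + seq)
        out = find_rss(contig, 2, "+", "downstream", 23, spacer_tolerance=1)
        expected = set()
        for hs in (2, 9):
            for ns in (32, 44):
                gap = ns - (hs + 7)
                if abs(gap - 23) <= 1:
                    expected.add((hs, ns))
        assert {(r.heptamer.start, r.nonamer.start) for r in out} == expected


class TestRegulatoryAndOrf:
    def test_promoter_planting(self, rng):
        filler = "".join(rng.choice(list("CG"), size=40))
        seq = filler + "ATGCAAAT" + "C" * 20 + "TATAAA" + "C" * 26 + "ATGAAA"
        contig = GenomicContig("c", seq)
        hits = find_regulatory_elements(contig, 100, 130,
                                        leader_start=len(seq) - 6)
        kinds = {h.kind: h for h in hits}
        assert kinds["octamer"].start == 40
        assert kinds["tata"].start == 68

    def test_compositional_equality_with_scan_motif(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        contig = GenomicContig("c", seq)
        cfg = ScanConfig()
        hits = find_regulatory_elements(contig, 350, 390, cfg,
                                        leader_start=350)
        window = GenomicContig("w", seq[50:350])
        expected = {(h.start + 50, h.strand)
                    for h in scan_motif(window, cfg.octamer, 0)}
        got = {(h.start, h.strand) for h in hits if h.kind == "octamer"}
        assert got == expected

    def _build_gene(self, rng, exon2, defect=None):
        donor = "GT" if defect != "splice" else "GG"
        leader = "ATG" + "".join(rng.choice(list("ACG"), size=45))
        intron = donor + "".join(rng.choice(list("ACGT"), size=70)) + "AG"
        pre = "".join(rng.choice(list("ACGT"), size=120))
        seq = pre + leader + intron + exon2
        return seq, len(pre) + len(leader) + len(intron), len(pre)

    def test_leader_and_splice_recovered(self, rng, small_locus):
        exon2 = small_locus.refs_scan.v_refs["IGHV1"]
        seq, exon_start, leader_start = self._build_gene(rng, exon2)
        contig = GenomicContig("c", seq)
        orf = detect_orf_and_leader(contig, 0, len(seq), exon_start=exon_start)
        assert orf.leader_coords == (leader_start, leader_start + 48)
        assert "stop" not in orf.defects and not orf.defects

    def test_frameshift_detected(self, rng, small_locus):
        exon2 = small_locus.refs_scan.v_refs["IGHV1"]
        broken = exon2[:150] + exon2[151:]
        seq, exon_start, _ = self._build_gene(rng, broken)
        contig = GenomicContig("c", seq)
        orf = detect_orf_and_leader(contig, 0, len(seq), exon_start=exon_start,
                                    expected_exon=exon2)
        assert "frameshift" in orf.defects

    def test_stop_detected(self, rng, small_locus):
        exon2 = small_locus.refs_scan.v_refs["IGHV1"]
        broken = exon2[:120] + "TAA" + exon2[123:]
        seq, exon_start, _ = self._build_gene(rng, broken)
        contig = GenomicContig("c", seq)
        orf = detect_orf_and_leader(contig, 0, len(seq), exon_start=exon_start)
        assert "stop" in orf.defects and "*" in orf.aa

    def test_short_region_rejected(self):
        contig = GenomicContig("c", "ACGT" * 30)
        with pytest.raises(ValueError):
            detect_orf_and_leader(contig, 0, 100)


def classify_oracle(report, fragment_length=None, min_v_exon=270):
    """Independent restatement: collect defects, apply strict precedence."""
    psi = []
    if not report.no_stop:
        psi.append("stop")
    if not report.orf_intact:
        psi.append("frameshift")
    if fragment_length is not None and fragment_length < min_v_exon:
        psi.append("fragment")
    if not report.rss_ok:
        psi.append("rss")
    orf = [f for f, ok in (("splice", report.splice_ok),
                           ("regulatory", report.regulatory_ok),
                           ("conserved", report.conserved_residues_ok))
           if not ok]
    for cls, cond in (("Psi", bool(psi)), ("ORF", bool(orf)),
                      ("ORF_orphon", not report.on_main_locus),
                      ("F_putative", not report.complete_sequence),
                      ("F", True)):
        if cond:
            return cls


class TestClassifyFunctionality:
    def test_exhaustive_truth_table(self):
        fields = ["orf_intact", "no_stop", "splice_ok", "rss_ok",
                  "regulatory_ok", "conserved_residues_ok",
                  "complete_sequence", "on_main_locus"]
        for values in itertools.product([True, False], repeat=8):
            report = FunctionalityReport(**dict(zip(fields, values)))
            for frag in (None, 77, 300):
                assert classify_functionality(report, frag) == \
                    classify_oracle(report, frag)

    def test_named_examples(self):
        assert classify_functionality(FunctionalityReport(no_stop=False)) == "Psi"
        assert classify_functionality(FunctionalityReport(on_main_locus=False)) \
            == "ORF_orphon"
        assert classify_functionality(FunctionalityReport(),
                                      fragment_length=77) == "Psi"
        assert classify_functionality(FunctionalityReport(splice_ok=False)) \
            == "ORF"
        assert classify_functionality(
            FunctionalityReport(complete_sequence=False)) == "F_putative"
        assert classify_functionality(FunctionalityReport()) == "F"


class TestScanContig:
    def test_truth_recovery(self, small_locus):
        anns = scan_contig(small_locus.contigs[0], small_locus.refs_scan)
        truth = small_locus.truth.set_index("name")
        found = {a.name: a for a in anns}
        ok = sum(1 for name, row in truth.iterrows()
                 if name in found
                 and found[name].functionality == row.functionality)
        assert ok / len(truth) >= 0.9

    def test_psi_has_defect_f_has_none(self, small_locus):
        for a in scan_contig(small_locus.contigs[0], small_locus.refs_scan):
            if a.functionality == "Psi":
                assert a.defect_list
            if a.functionality == "F":
                assert not a.defect_list

    def test_reverse_complement_invariance(self, small_locus):
        contig = small_locus.contigs[0]
        anns = scan_contig(contig, small_locus.refs_scan)
        L = len(contig.sequence)
        rc = GenomicContig(contig.id, revcomp(contig.sequence),
                           contig.locus_label, contig.is_main_locus)
        rc_anns = scan_contig(rc, small_locus.refs_scan)
        fwd = {(a.name, a.start, a.end, a.strand, a.functionality)
               for a in anns}
        mirrored = {(a.name, L - a.end, L - a.start,
                     "+" if a.strand == "-" else "-", a.functionality)
                    for a in rc_anns}
        assert fwd == mirrored

    def test_all_n_contig_is_empty(self, small_locus, caplog):
        contig = GenomicContig("n", "N" * 500)
        assert scan_contig(contig, small_locus.refs_scan) == []
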