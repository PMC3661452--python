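"""Isotype calling, V(D)J assignment, numbering, CDR3 and junctions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bovigh._seq import KYTE_DOOLITTLE, revcomp
from bovigh.primers import FORWARD_PRIMER, REVERSE_PRIMERS
from bovigh.repertoire import (ExpressedSequence, analyze_repertoire,
                               annotate_dj_junction, assign_segments,
                               call_isotype, classify_cdr3_group,
                               composition_profile, conserved_residue_check,
                               detect_csns, extract_regions, imgt_number,
                               insilico_pcr, summarize_by_isotype)
from conftest import as_expressed

AA = sorted(KYTE_DOOLITTLE)


# ---------------------------------------------------------------------------
# isotype and PCR


class TestIsotype:
    def test_exact_fragment(self, small_locus, clean_repertoire):
        reads, truth = clean_repertoire
        calls = [call_isotype(seq, small_locus.refs_expr.c_refs)
                 for seq in as_expressed(reads)]
        assert calls == list(truth.isotype)

    def test_igg_subtypes_collapse(self, small_locus, rng):
        stub = small_locus.c_stubs["IgG2"]
        read = "".join(rng.choice(list("ACGT"), size=300)) + stub[:80]
        assert call_isotype(ExpressedSequence("x", read),
                            small_locus.refs_expr.c_refs) == "IgG"

    def test_no_fragment_is_unknown(self, small_locus, rng):
        read = "".join(rng.choice(list("ACGT"), size=400))
        assert call_isotype(ExpressedSequence("x", read),
                            small_locus.refs_expr.c_refs) == "unknown"


class TestInsilicoPCR:
    def test_product_arithmetic(self, rng):
        fwd = "ACGTACGTACGTACGTA"
        rev = "TTGGCCAATTGGCCAAT"
        spacer = "".join(rng.choice(list("ACG"), size=400))
        template = fwd + spacer + revcomp(rev)
        assert insilico_pcr(template, fwd, rev) == [len(fwd) + 400 + len(rev)]

    def test_missing_site_gives_no_product(self, rng):
        fwd = "ACGTACGTACGTACGTA"
        rev = "TTGGCCAATTGGCCAAT"
        template = fwd + "".join(rng.choice(list("ACG"), size=200))
        assert insilico_pcr(template, fwd, rev) == []

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            insilico_pcr("ACGT" * 100, "ACGT", "ACGTACGTACGTACG")

    def test_mu_product_matches_table_geometry(self, small_locus):
        """Short-CDR3 IgM amplicons approximate the printed 795 bp."""
        from bovigh.synthetic import RepertoireSimSpec, simulate_repertoire

        reads, truth = simulate_repertoire(
            small_locus,
            RepertoireSimSpec(per_isotype={"IgM": 6},
                              group_proportions=(1.0, 0.0, 0.0),
                              shm_rate=0.0, seed=2))
        fwd = FORWARD_PRIMER[1]
        rev = REVERSE_PRIMERS["IgM"][1]
        for _, nt in reads:
            products = insilico_pcr(nt, fwd, rev)
            assert len(products) == 1
            assert abs(products[0] - 795) <= 30


# ---------------------------------------------------------------------------
# V(D)J assignment


class TestAssignSegments:
    def test_zero_mutation_exact_recovery(self, small_locus, clean_repertoire):
        reads, truth = clean_repertoire
        t = truth.set_index("id")
        for seq in as_expressed(reads):
            asg = assign_segments(seq, small_locus.refs_expr)
            row = t.loc[seq.id]
            assert asg.v.name == row.v_name
            assert asg.j.name == row.j_name
            assert asg.d is not None and asg.d.name == row.d_name
            assert asg.v_end <= asg.d.q_start <= asg.d.q_end <= asg.j_start

    def test_shm_recovery_rate(self, small_locus, small_repertoire):
        reads, truth = small_repertoire
        t = truth.set_index("id")
        ok_v = ok_j = 0
        for seq in as_expressed(reads):
            asg = assign_segments(seq, small_locus.refs_expr)
            ok_v += asg.v.name == t.loc[seq.id].v_name
            ok_j += asg.j.name == t.loc[seq.id].j_name
        assert ok_v / len(reads) >= 0.95
        assert ok_j / len(reads) >= 0.95

    def test_homologous_d_flags_ambiguity(self, small_locus, rng):
        """Two near-identical D references within the margin -> ambiguous."""
        gs = small_locus.refs_expr
        d = gs.d_refs["IGHD2"]
        twin = d[:20] + ("A" if d[20] != "A" else "C") + d[21:]
        gs2 = type(gs)(v_refs=gs.v_refs, d_refs={"IGHD2": d, "IGHDX": twin},
                       j_refs=gs.j_refs, c_refs={},
                       functionality=gs.functionality)
        from bovigh.synthetic import RepertoireSimSpec, simulate_repertoire
        reads, truth = simulate_repertoire(
            small_locus,
            RepertoireSimSpec(per_isotype={"IgM": 5},
                              group_proportions=(0, 0, 1.0),
                              shm_rate=0.0, seed=4))
        flagged = 0
        for seq in as_expressed(reads):
            asg = assign_segments(seq, gs2)
            flagged += asg.d_ambiguous
            assert {n for n, _ in asg.d_candidates} >= {"IGHD2", "IGHDX"}
        assert flagged == len(reads)

    def test_unassignable_raises(self, small_locus, rng):
        junk = "".join(rng.choice(list("ACGT"), size=400))
        with pytest.raises(ValueError, match="unassignable"):
            assign_segments(ExpressedSequence("x", junk),
                            small_locus.refs_expr)


# ---------------------------------------------------------------------------
# IMGT numbering and regions


def build_domain(rng, cdr1=8, cdr2=7, cdr3=12):
    alph = [c for c in AA if c not in "CW"]

    def rand(n):
        return "".join(rng.choice(alph, size=n))

    aa = (rand(21) + "C" + rand(3) + rand(cdr1) + rand(2) + "W" + rand(14)
          + rand(cdr2) + rand(22) + "L" + rand(12) + "YYC"
          + rand(cdr3) + "WGQGTLVTVSS")
    return aa


class TestNumbering:
    def test_anchors_and_region_lengths(self, rng):
        aa = build_domain(rng)
        dom = imgt_number(aa)
        assert dom.residue("23") == "C" and dom.residue("104") == "C"
        assert dom.residue("41") == "W" and dom.residue("89") == "L"
        assert dom.residue("118") == "W" and dom.residue("119") == "G"
        regions = extract_regions(dom)
        assert len(regions["CDR1"]) == 8 and len(regions["CDR2"]) == 7
        # 8-residue CDR1 leaves 4 gapped positions in the 27-38 span
        labels_2738 = [r for l, r in zip(dom.labels, dom.residues)
                       if l.isdigit() and 27 <= int(l) <= 38]
        assert labels_2738.count(".") == 4

    def test_degap_round_trip(self, rng):
        for cdr3 in (5, 13, 25, 55):
            aa = build_domain(rng, cdr3=cdr3)
            assert imgt_number(aa).degapped() == aa

    def test_partition_property(self, rng):
        aa = build_domain(rng, cdr3=21)
        regions = extract_regions(imgt_number(aa))
        order = ["FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4"]
        assert "".join(regions[r] for r in order) == aa

    def test_cdr3_lengths(self, rng):
        for cdr3 in (5, 13, 30, 55):
            aa = build_domain(rng, cdr3=cdr3)
            assert len(extract_regions(imgt_number(aa))["CDR3"]) == cdr3

    def test_missing_anchor_raises(self):
        with pytest.raises(ValueError, match="unnumberable"):
            imgt_number("A" * 100)

    def test_conserved_flags(self, rng):
        aa = build_domain(rng)
        assert conserved_residue_check(imgt_number(aa)) == []
        # substitute Trp118 by Ser: position flagged
        i118 = len(aa) - 11
        mutated = aa[:i118] + "S" + aa[i118 + 1:]
        flags = conserved_residue_check(imgt_number(mutated))
        assert any(f.startswith("118:") for f in flags)
        # Gly119 -> Asp
        mutated = aa[:i118 + 1] + "D" + aa[i118 + 2:]
        flags = conserved_residue_check(imgt_number(mutated))
        assert any(f.startswith("119:") for f in flags)


# ---------------------------------------------------------------------------
# CDR3 groups, composition, junctions


class TestGroups:
    @pytest.mark.parametrize("length,group", [
        (8, 1), (10, 1), (11, 2), (12, 2), (25, 2), (31, 2), (40, 2),
        (47, 2), (48, 3), (61, 3),
    ])
    def test_boundaries(self, length, group):
        assert classify_cdr3_group(length) == group

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            classify_cdr3_group(2)

    def test_monotone_and_total(self):
        groups = [classify_cdr3_group(n) for n in range(3, 80)]
        assert groups == sorted(groups)
        assert set(groups) == {1, 2, 3}


class TestComposition:
    def test_direct_count(self):
        rec = composition_profile("GYGYC")
        assert (rec.n_gly, rec.n_tyr, rec.n_cys, rec.length) == (2, 2, 1, 5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet=AA, min_size=1, max_size=60))
    def test_tallies_match_letter_oracle(self, s):
        rec = composition_profile(s)
        assert rec.n_cys == sum(1 for c in s if c == "C")
        assert rec.n_gly == sum(1 for c in s if c == "G")
        assert rec.n_tyr == sum(1 for c in s if c == "Y")
        assert rec.n_aromatic == sum(1 for c in s if c in "FWYH")
        hydro = sum(1 for c in s if KYTE_DOOLITTLE[c] < 0) / len(s)
        assert rec.hydrophilic_fraction == pytest.approx(hydro)

    def test_central_cys_cluster(self):
        cdr3 = "G" * 25 + "CCCCCC" + "G" * 25
        rec = composition_profile(cdr3)
        assert rec.n_cys == 6 and 0.4 <= rec.cys_center <= 0.6

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError):
            composition_profile("GYB")


class TestJunctions:
    def test_csns_window(self):
        assert detect_csns("AAAAAAGCA" + "CAAAGG")[0] == "CSNS"     # 15 nt
        assert detect_csns("GCGCGCGC")[0] == "N-region"             # 8 nt
        assert detect_csns("")[0] == "none"
        # 15 nt but A-poor
        assert detect_csns("GCGCGCGCGCGCGCG")[0] == "N-region"

    def test_csns_boundary_fraction(self):
        ins = "A" * 6 + "G" * 9        # 15 nt, A fraction 0.40
        assert detect_csns(ins)[0] == "CSNS"

    def test_dj_palindrome(self):
        # untrimmed J starting GACT; insert ends with revcomp("GAC")
        assert annotate_dj_junction("GTC", "GAG", "GACT") == "P"
        assert annotate_dj_junction("AACTC", "GAG", "GACT") == "mixed"
        assert annotate_dj_junction("AAA", "GAG", "GACT") == "N"
        assert annotate_dj_junction("", "GAG", "GACT") == "none"

    def test_dj_truth_accuracy(self, small_locus, clean_repertoire):
        """On recorded junction nucleotides the classifier is >=90% right."""
        reads, truth = clean_repertoire
        d_refs = small_locus.refs_expr.d_refs
        j_ref = small_locus.refs_expr.j_refs[small_locus.j_used]
        reads = dict(reads)
        ok = n = 0
        for _, row in truth.iterrows():
            d = d_refs[row.d_name]
            d_end = d[:row.d_left_trim + row.d_keep]
            expected = ("none" if row.dj_n_len + row.dj_p_len == 0
                        else "P" if row.dj_n_len == 0
                        else "N" if row.dj_p_len == 0 else "mixed")
            # junction coordinates known exactly at zero mutation
            lo = (57 + 285 + row.v_keep + row.csns_len + row.vd_n_len
                  + row.d_keep)
            insert = reads[row.id][lo:lo + row.dj_n_len + row.dj_p_len]
            got = annotate_dj_junction(
                insert, d_end, j_ref[12 - row.j_keep:],
                d_untrimmed=row.d_left_trim + row.d_keep == len(d),
                j_untrimmed=row.j_keep == 12)
            n += 1
            ok += got == expected
        assert n > 0 and ok / n >= 0.9


class TestPipeline:
    def test_cdr1_cdr2_invariance(self, small_locus, small_repertoire):
        reads, _ = small_repertoire
        df = analyze_repertoire(as_expressed(reads), small_locus.refs_expr)
        assert (df.cdr1_len == 8).all()
        assert (df.cdr2_len == 7).all()

    def test_group_recovery(self, small_locus, small_repertoire):
        reads, truth = small_repertoire
        df = analyze_repertoire(as_expressed(reads), small_locus.refs_expr)
        m = df.merge(truth, on="id", suffixes=("", "_t"))
        assert (m.group == m.group_t).mean() >= 0.95

    def test_summary_matches_brute_force(self, small_locus, small_repertoire):
        reads, _ = small_repertoire
        df = analyze_repertoire(as_expressed(reads), small_locus.refs_expr)
        summary = summarize_by_isotype(df).set_index("isotype")
        for iso, sub in df.groupby("isotype"):
            assert summary.loc[iso, "cdr3_len_mean"] == \
                pytest.approx(round(sub.cdr3_len.mean(), 2))
            assert summary.loc[iso, "variable_aa_len_sd"] == \
                pytest.approx(round(sub.variable_aa_len.std(ddof=1), 2))
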