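"""Germline immunoglobulin gene-segment annotation.

Locates V/D/J/C candidates in genomic contigs by identity to a reference
set, attaches recombination signal sequences (RSS) and regulatory
elements, detects open-reading-frame defects, and assigns each candidate
one of the functionality classes used in immunogenetics annotation:

``F``
    functional: intact ORF, splice sites, RSS and regulatory elements.
``F_putative``
    putatively functional but the sequence is incomplete (Ns or contig
    truncation) — written ``(F)`` in locus maps.
``ORF``
    open reading frame with defects in splice sites, regulatory elements
    or conserved residues that may preclude expression of a functional
    protein.
``ORF_orphon``
    a fully functional gene located outside the main heavy-chain locus
    chromosome — written ``(ORF)``.
``Psi``
    pseudogene: stop codon, frameshift, fragmented locus, or an RSS
    defect at a recombination-critical position.

Recombination competence of an RSS follows the functional assays cited
throughout the immunogenetics literature: the first three heptamer
nucleotides (CAC), a run of three adenosines in the nonamer, and the
exact 12/23 spacer length are each required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import Align

from ._seq import IUPAC_DNA, check_dna, revcomp, translate
from .config import ScanConfig
from .reference import GermlineSet

logger = logging.getLogger("bovigh.germline_scan")

_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GenomicContig:
    id: str
    sequence: str
    locus_label: str = "unplaced"
    is_main_locus: bool = False

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        check_dna(self.sequence, what=f"contig {self.id!r}")


@dataclass
class MotifHit:
    kind: str
    start: int          # 0-based half-open, plus-strand coordinates
    end: int
    strand: str         # '+' or '-'
    mismatches: int
    seq: str            # matched bases in motif orientation

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("empty MotifHit interval")


@dataclass
class RSS:
    heptamer: MotifHit
    nonamer: MotifHit
    spacer_length: int
    spacer_class: int           # 12 or 23
    competent: bool = False
    defects: list[str] = field(default_factory=list)


@dataclass
class FunctionalityReport:
    orf_intact: bool = True            # no frameshift
    no_stop: bool = True
    splice_ok: bool = True
    rss_ok: bool = True                # no recombination-critical defect
    regulatory_ok: bool = True
    conserved_residues_ok: bool = True
    complete_sequence: bool = True     # no Ns / contig truncation
    on_main_locus: bool = True


@dataclass
class OrfCandidate:
    leader_coords: tuple[int, int] | None
    v_coords: tuple[int, int]
    frame: int
    aa: str
    defects: list[str]


@dataclass
class GeneSegmentAnnotation:
    segment_type: str                  # V, D, J, C
    name: str
    start: int
    end: int
    strand: str
    functionality: str
    identity: float
    leader_coords: tuple[int, int] | None = None
    frame: int = 0
    defect_list: list[str] = field(default_factory=list)
    rss_list: list[RSS] = field(default_factory=list)
    regulatory: list[MotifHit] = field(default_factory=list)
    sequence: str = ""


# ---------------------------------------------------------------------------
# motif scanning


def _pattern_matrix(motif: str) -> list[str]:
    return [_IUPAC_SETS[b] for b in motif]


def _scan(seq: str, motif: str, max_mismatch: int, exact_positions=(),
          kind: str = "primer_site", strands: str = "+-") -> list[MotifHit]:
    """Hamming scan of ``motif`` over both strands of ``seq``.

    An ``N`` in the target never counts as a match.  Degenerate IUPAC
    symbols in the motif match their expansion.
    """
    n, m = len(seq), len(motif)
    hits: list[MotifHit] = []
    if n < m:
        return hits
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(arr, m)

    def run(pattern: str, strand: str, exact_idx):
        ok = np.zeros((n - m + 1, m), dtype=bool)
        for j, allowed in enumerate(_pattern_matrix(pattern)):
            col = win[:, j]
            match = np.zeros(n - m + 1, dtype=bool)
            for b in allowed:
                match |= col == ord(b)
            ok[:, j] = match  # 'N' in target matches nothing by design
        mism = m - ok.sum(axis=1)
        keep = mism <= max_mismatch
        if len(exact_idx):
            keep &= ok[:, list(exact_idx)].all(axis=1)
        for i in np.nonzero(keep)[0]:
            window = seq[i : i + m]
            hits.append(MotifHit(kind, int(i), int(i + m), strand,
                                 int(mism[i]),
                                 window if strand == "+" else revcomp(window)))

    if "+" in strands:
        run(motif, "+", list(exact_positions))
    rc = revcomp(motif)
    if "-" in strands and rc != motif:
        run(rc, "-", [m - 1 - j for j in exact_positions])
    elif "-" in strands and rc == motif:
        # palindromic motif: a plus hit is also a minus hit
        for h in list(hits):
            hits.append(MotifHit(kind, h.start, h.end, "-", h.mismatches, h.seq))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_motif(contig: GenomicContig, motif: str, max_mismatch: int = 0,
               exact_positions=(), kind: str = "primer_site") -> list[MotifHit]:
    """Find all approximate occurrences of ``motif`` on both strands.

    Returns every window whose Hamming distance to the motif is at most
    ``max_mismatch`` and which matches exactly at ``exact_positions``
    (indices into the motif).  Hits are sorted by start coordinate.
    """
    motif = motif.upper()
    if len(motif) < 4:
        raise ValueError("motif must be at least 4 nt")
    bad = set(motif) - IUPAC_DNA
    if bad:
        raise ValueError(f"motif contains non-IUPAC symbols: {sorted(bad)}")
    if any(p < 0 or p >= len(motif) for p in exact_positions):
        raise ValueError("exact_positions outside motif")
    if not contig.sequence:
        raise ValueError("empty contig")
    return _scan(contig.sequence, motif, max_mismatch, exact_positions, kind)


# ---------------------------------------------------------------------------
# recombination signal sequences


def check_rss_competence(rss: RSS) -> RSS:
    """Fill competence flags from the recombination-critical criteria.

    Competent iff the heptamer begins with CAC, the nonamer contains a
    run of three adenosines, and the spacer length equals the 12/23
    spacer class exactly.  Each failed criterion is appended to
    ``defects``.
    """
    rss.defects = []
    if not rss.heptamer.seq.startswith("CAC"):
        rss.defects.append("heptamer_first3")
    if "AAA" not in rss.nonamer.seq:
        rss.defects.append("nonamer_A_run")
    if rss.spacer_length != rss.spacer_class:
        rss.defects.append("spacer_length")
    rss.competent = not rss.defects
    return rss


def find_rss(contig: GenomicContig, anchor: int, strand: str, side: str,
             spacer_class: int, spacer_tolerance: int | None = None,
             config: ScanConfig | None = None) -> list[RSS]:
    """Pair heptamer/nonamer hits flanking ``anchor`` into candidate RSS.

    ``side`` is relative to the gene segment's own orientation
    (``downstream`` of a V, ``upstream`` of a J).  The heptamer abuts
    the coding segment; the nonamer lies beyond the spacer.  No
    candidate pair is not an error: an empty list is returned.
    """
    cfg = config or ScanConfig()
    tol = cfg.spacer_tolerance if spacer_tolerance is None else spacer_tolerance
    if not 0 <= anchor <= len(contig.sequence):
        raise ValueError("anchor outside contig")
    if side not in ("upstream", "downstream"):
        raise ValueError(f"bad side {side!r}")
    if spacer_class not in (12, 23):
        raise ValueError("spacer_class must be 12 or 23")

    if strand == "-":
        # analyze on the reverse complement and mirror coordinates back
        L = len(contig.sequence)
        rc = GenomicContig(contig.id, revcomp(contig.sequence),
                           contig.locus_label, contig.is_main_locus)
        out = find_rss(rc, L - anchor, "+", side, spacer_class, tol, cfg)
        for r in out:
            for h in (r.heptamer, r.nonamer):
                h.start, h.end = L - h.end, L - h.start
                h.strand = "-" if h.strand == "+" else "+"
        return out

    seq = contig.sequence
    win = cfg.rss_search_window
    span = win + len(cfg.heptamer) + spacer_class + tol + len(cfg.nonamer) + 4
    out: list[RSS] = []
    if side == "downstream":
        lo, hi = anchor, min(len(seq), anchor + span)
        sub = seq[lo:hi]
        heps = _scan(sub, cfg.heptamer, cfg.heptamer_max_mismatch, (),
                     "heptamer", strands="+")
        nons = _scan(sub, cfg.nonamer, cfg.nonamer_max_mismatch, (),
                     "nonamer", strands="+")
        for h in heps:
            if h.start > win:
                continue
            for nn in nons:
                gap = nn.start - h.end
                if abs(gap - spacer_class) <= tol:
                    hh = MotifHit(h.kind, h.start + lo, h.end + lo, "+",
                                  h.mismatches, h.seq)
                    nh = MotifHit(nn.kind, nn.start + lo, nn.end + lo, "+",
                                  nn.mismatches, nn.seq)
                    out.append(check_rss_competence(
                        RSS(hh, nh, gap, spacer_class)))
    else:
        lo, hi = max(0, anchor - span), anchor
        sub = seq[lo:hi]
        heps = _scan(sub, cfg.heptamer, cfg.heptamer_max_mismatch, (),
                     "heptamer", strands="-")
        nons = _scan(sub, cfg.nonamer, cfg.nonamer_max_mismatch, (),
                     "nonamer", strands="-")
        heps = [h for h in heps if h.strand == "-"]
        nons = [nn for nn in nons if nn.strand == "-"]
        for h in heps:
            if (hi - lo) - h.end > win:
                continue
            for nn in nons:
                gap = h.start - nn.end
                if abs(gap - spacer_class) <= tol:
                    hh = MotifHit(h.kind, h.start + lo, h.end + lo, "-",
                                  h.mismatches, h.seq)
                    nh = MotifHit(nn.kind, nn.start + lo, nn.end + lo, "-",
                                  nn.mismatches, nn.seq)
                    out.append(check_rss_competence(
                        RSS(hh, nh, gap, spacer_class)))
    out.sort(key=lambda r: (r.heptamer.start, r.nonamer.start))
    return out


# ---------------------------------------------------------------------------
# regulatory elements and the leader/ORF model


def find_regulatory_elements(contig: GenomicContig, v_start: int, v_end: int,
                             config: ScanConfig | None = None,
                             leader_start: int | None = None,
                             polya_anchor: int | None = None) -> list[MotifHit]:
    """Report promoter octamer / TATA-box / splice-site / poly-A hits.

    Octamer and TATA are searched in a window upstream of the leader ATG
    (or the candidate start when the leader is unknown); splice donors
    (GT) and acceptors (AG) within the candidate's leader window; poly-A
    downstream of ``polya_anchor`` when given.  Each element is a plain
    Hamming scan with its configured tolerance, so absence is simply an
    empty report — the functionality classifier decides what absence
    means.
    """
    cfg = config or ScanConfig()
    seq = contig.sequence
    ref = leader_start if leader_start is not None else v_start
    hits: list[MotifHit] = []

    def window_scan(lo, hi, motif, mism, kind, strands="+-", min_len=4):
        lo, hi = max(0, lo), min(len(seq), hi)
        if hi - lo < len(motif):
            return
        for h in _scan(seq[lo:hi], motif, mism, (), kind, strands=strands):
            hits.append(MotifHit(h.kind, h.start + lo, h.end + lo, h.strand,
                                 h.mismatches, h.seq))

    window_scan(ref - cfg.promoter_window, ref, cfg.octamer, 0, "octamer")
    window_scan(ref - cfg.promoter_window, ref, cfg.tata_box,
                cfg.tata_max_mismatch, "tata", strands="+")
    if leader_start is not None:
        lo, hi = leader_start, v_start
        for i in range(max(0, lo), min(len(seq) - 1, hi)):
            two = seq[i : i + 2]
            if two == "GT":
                hits.append(MotifHit("splice_donor", i, i + 2, "+", 0, two))
            if two == "AG":
                hits.append(MotifHit("splice_acceptor", i, i + 2, "+", 0, two))
    if polya_anchor is not None:
        window_scan(polya_anchor, polya_anchor + cfg.polya_window,
                    cfg.polya, 0, "polyA", strands="+")
    hits.sort(key=lambda h: (h.start, h.kind))
    return hits


LEADER_EXON1_LEN = 48  # ATG + 45 nt; fixed-length leader model


def detect_orf_and_leader(contig: GenomicContig, region_start: int,
                          region_end: int, exon_start: int | None = None,
                          expected_exon: str | None = None,
                          config: ScanConfig | None = None) -> OrfCandidate:
    """Locate the ATG-initiated leader and assess the V exon reading frame.

    ``exon_start`` (the start of the spliced V exon, normally known from
    reference matching) anchors the search; the leader first exon is
    modeled with a fixed length of 48 nt followed by a GT..AG intron.
    Stop codons and — when ``expected_exon`` is supplied — frameshifts
    (net indels not a multiple of three against the reference) are
    recorded as defects.  Translation uses the standard genetic code;
    codons containing N become X.
    """
    cfg = config or ScanConfig()
    if region_end - region_start < 200:
        raise ValueError("region shorter than minimum (200 nt)")
    seq = contig.sequence
    if exon_start is None:
        exon_start = region_start
    exon = seq[exon_start:region_end]
    defects: list[str] = []

    # leader: nearest upstream ATG whose fixed-length exon1 ends in GT
    leader = None
    splice_ok = False
    lo = max(region_start, exon_start - cfg.leader_window)
    for p in range(exon_start - LEADER_EXON1_LEN - 4, lo - 1, -1):
        if seq[p : p + 3] == "ATG":
            donor = seq[p + LEADER_EXON1_LEN : p + LEADER_EXON1_LEN + 2]
            acceptor = seq[exon_start - 2 : exon_start]
            leader = (p, p + LEADER_EXON1_LEN)
            splice_ok = donor == "GT" and acceptor == "AG"
            if splice_ok:
                break
    if leader is None:
        defects.append("leader_missing")
    elif not splice_ok:
        defects.append("splice_defect")

    frame = (3 - LEADER_EXON1_LEN % 3) % 3 if leader else 0
    aa = translate(exon[frame:])
    if "*" in aa:
        defects.append("stop")

    if expected_exon is not None:
        res = edlib.align(exon, expected_exon, mode="NW", task="path")
        cigar = res["cigar"] or ""
        shift = 0
        num = ""
        for ch in cigar:
            if ch.isdigit():
                num += ch
            else:
                if ch == "I":
                    shift += int(num)
                elif ch == "D":
                    shift -= int(num)
                num = ""
        if shift % 3 != 0:
            defects.append("frameshift")

    return OrfCandidate(leader, (exon_start, region_end), frame, aa, defects)


# ---------------------------------------------------------------------------
# functionality classification


PSI_DEFECTS = ("stop", "frameshift", "fragment", "rss_incompetent")


def classify_functionality(report: FunctionalityReport,
                           fragment_length: int | None = None,
                           min_v_exon: int = 270) -> str:
    """Map a per-criterion report to a functionality class.

    The precedence is Psi > ORF > ORF_orphon > F_putative > F: coding or
    recombination-critical defects always win, expression-level defects
    come next, then location, then sequence completeness.  The mapping
    is total and deterministic in the report fields alone.
    """
    if (not report.no_stop or not report.orf_intact or not report.rss_ok
            or (fragment_length is not None and fragment_length < min_v_exon)):
        return "Psi"
    if not (report.splice_ok and report.regulatory_ok
            and report.conserved_residues_ok):
        return "ORF"
    if not report.on_main_locus:
        return "ORF_orphon"
    if not report.complete_sequence:
        return "F_putative"
    return "F"


# ---------------------------------------------------------------------------
# full-contig scan


_TILE = 60


def _candidate_intervals(seq: str, refs: dict[str, str], floor: float,
                         min_len_frac: float = 0.25) -> list[tuple[int, int, str]]:
    """Tile every reference over the contig with edlib infix search.

    Returns merged candidate intervals per strand.  Tiling (rather than
    whole-reference search) keeps truncated copies — fragmented loci —
    discoverable.
    """
    found: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
    for ref in refs.values():
        for strand, r in (("+", ref), ("-", revcomp(ref))):
            step = max(1, _TILE // 2)
            tiles = [r[i:i + _TILE] for i in range(0, max(1, len(r) - _TILE + 1), step)]
            if len(r) < _TILE:
                tiles = [r]
            for tile in tiles:
                k = int(len(tile) * (1 - floor / 100.0))
                res = edlib.align(tile, seq, mode="HW", task="locations", k=k)
                if res["editDistance"] == -1:
                    continue
                for s, e in res["locations"]:
                    found[strand].append((s, e + 1))
    out = []
    merge_gap = 40      # tiles step 30, so same-segment hits overlap;
                        # a larger gap would bridge adjacent genes
    for strand, ivs in found.items():
        ivs.sort()
        cur = None
        for s, e in ivs:
            if cur and s - cur[1] <= merge_gap:
                cur[1] = max(cur[1], e)
            else:
                if cur:
                    out.append((cur[0], cur[1], strand))
                cur = [s, e]
        if cur:
            out.append((cur[0], cur[1], strand))
    min_len = min(50, min_len_frac * min(len(r) for r in refs.values()))
    return [(s, e, st) for s, e, st in out if e - s >= min_len]


_LOCAL_ALIGNER = Align.PairwiseAligner(
    mode="local", match_score=2, mismatch_score=-2,
    open_gap_score=-6, extend_gap_score=-1,
)


def _best_reference(window: str, refs: dict[str, str], top_n: int = 3):
    """Rank references by edlib distance, refine the best few locally.

    Returns (name, identity%, (start, end) on window, matched_ref_span).
    """
    ranked = sorted(
        refs.items(),
        key=lambda kv: (edlib.align(kv[1], window, mode="HW")["editDistance"]
                        / max(1, len(kv[1])), kv[0]),
    )

    def evaluate(name, ref, best):
        alns = _LOCAL_ALIGNER.align(window, ref)
        if len(alns) == 0:
            return best
        aln = alns[0]
        tpairs, qpairs = aln.aligned
        matches = sum(
            1
            for (ts, te), (qs, qe) in zip(tpairs, qpairs)
            for a, b in zip(window[ts:te], ref[qs:qe])
            if a == b and a != "N"
        )
        cols = sum(te - ts for ts, te in tpairs)
        ident = 100.0 * matches / cols if cols else 0.0
        span = (int(tpairs[0][0]), int(tpairs[-1][-1]))
        ref_span = int(qpairs[-1][-1] - qpairs[0][0])
        if best is None or (ident, ref_span, name) > (best[1], best[3],
                                                      best[0]):
            best = (name, ident, span, ref_span)
        return best

    best = None
    for name, ref in ranked[:top_n]:
        best = evaluate(name, ref, best)
    if best is not None and 45 <= best[3] < 0.5 * len(refs[best[0]]):
        # fragmentary candidate: the quick edit-distance ranking is
        # dominated by the unaligned reference tail, so check every ref
        for name, ref in ranked[top_n:]:
            best = evaluate(name, ref, best)
    return best


def _analyze_v(sub: str, name: str, s: int, e: int, ref: str, cfg: ScanConfig,
               on_main: bool, truncated: bool) -> GeneSegmentAnnotation:
    """Classify one plus-oriented V candidate found at sub[s:e]."""
    from .repertoire import conserved_residue_check, imgt_number

    contig = GenomicContig("window", sub)
    matched = e - s
    segment = sub[s:e]
    defects: list[str] = []
    report = FunctionalityReport(on_main_locus=on_main)
    leader_coords = None
    frame = 0
    rss_list = []
    regulatory = []

    if matched < cfg.min_v_exon:
        defects.append("fragment")
        report.orf_intact = False
        functionality = classify_functionality(report, fragment_length=matched,
                                               min_v_exon=cfg.min_v_exon)
        return GeneSegmentAnnotation("V", name, s, e, "+", functionality,
                                     0.0, None, 0, defects, [], [], segment)

    region_start = max(0, s - cfg.leader_window - cfg.promoter_window)
    orf = detect_orf_and_leader(contig, region_start, e, exon_start=s,
                                expected_exon=ref, config=cfg)
    leader_coords = orf.leader_coords
    frame = orf.frame
    defects.extend(orf.defects)
    report.no_stop = "stop" not in orf.defects
    report.orf_intact = "frameshift" not in orf.defects
    report.splice_ok = ("splice_defect" not in orf.defects
                        and "leader_missing" not in orf.defects)

    rss_list = find_rss(contig, e, "+", "downstream", 23, config=cfg)
    if not rss_list:
        report.rss_ok = False
        defects.append("rss_incompetent")
    else:
        best_rss = max(rss_list, key=lambda r: r.competent)
        rss_list = [best_rss]
        if not best_rss.competent:
            report.rss_ok = False
            defects.append("rss_incompetent")

    leader_start = leader_coords[0] if leader_coords else None
    regulatory = find_regulatory_elements(contig, s, e, cfg,
                                          leader_start=leader_start)
    kinds = {h.kind for h in regulatory}
    if "octamer" not in kinds or "tata" not in kinds:
        report.regulatory_ok = False
        defects.append("regulatory_missing")
    if "leader_missing" in orf.defects:
        report.regulatory_ok = False

    # conserved-residue check on the numbered translation (leader part 2
    # occupies the first 4 codons of the exon)
    aa_v = orf.aa[4:]
    if report.no_stop and "X" not in aa_v:
        try:
            num = imgt_number(aa_v, partial=True)
            flags = conserved_residue_check(num)
            if flags:
                report.conserved_residues_ok = False
                defects.extend(f"conserved_{f}" for f in flags)
        except ValueError:
            report.conserved_residues_ok = False
            defects.append("conserved_anchor_missing")

    if "N" in segment or truncated:
        report.complete_sequence = False

    functionality = classify_functionality(report)
    return GeneSegmentAnnotation("V", name, s, e, "+", functionality, 0.0,
                                 leader_coords, frame, defects, rss_list,
                                 regulatory, segment)


def _analyze_dj(sub: str, seg_type: str, name: str, s: int, e: int,
                cfg: ScanConfig, on_main: bool) -> GeneSegmentAnnotation:
    contig = GenomicContig("window", sub)
    report = FunctionalityReport(on_main_locus=on_main)
    defects: list[str] = []
    segment = sub[s:e]
    rss_list = []
    if seg_type == "D":
        up = find_rss(contig, s, "+", "upstream", 12, config=cfg)
        down = find_rss(contig, e, "+", "downstream", 12, config=cfg)
        for side_hits in (up, down):
            if not side_hits:
                report.rss_ok = False
            else:
                best = max(side_hits, key=lambda r: r.competent)
                rss_list.append(best)
                if not best.competent:
                    report.rss_ok = False
        if not report.rss_ok:
            defects.append("rss_incompetent")
    else:  # J
        up = find_rss(contig, s, "+", "upstream", 23, config=cfg)
        if not up:
            report.rss_ok = False
            defects.append("rss_incompetent")
        else:
            best = max(up, key=lambda r: r.competent)
            rss_list.append(best)
            if not best.competent:
                report.rss_ok = False
                defects.append("rss_incompetent")
        aas = [translate(segment[f:]) for f in range(3)]
        import re
        if not any(re.search(r"[WF]G.G", aa) for aa in aas):
            report.conserved_residues_ok = False
            defects.append("conserved_J_motif")
    if "N" in segment:
        report.complete_sequence = False
    functionality = classify_functionality(report)
    return GeneSegmentAnnotation(seg_type, name, s, e, "+", functionality,
                                 0.0, None, 0, defects, rss_list, [], segment)


def _analyze_c(sub: str, name: str, s: int, e: int, cfg: ScanConfig,
               on_main: bool) -> GeneSegmentAnnotation:
    contig = GenomicContig("window", sub)
    report = FunctionalityReport(on_main_locus=on_main)
    defects: list[str] = []
    regulatory = find_regulatory_elements(contig, s, e, cfg, polya_anchor=e)
    if not any(h.kind == "polyA" for h in regulatory):
        report.regulatory_ok = False
        defects.append("polyA_missing")
    segment = sub[s:e]
    if "N" in segment:
        report.complete_sequence = False
    functionality = classify_functionality(report)
    return GeneSegmentAnnotation("C", name, s, e, "+", functionality, 0.0,
                                 None, 0, defects, [], regulatory, segment)


def scan_contig(contig: GenomicContig, germline: GermlineSet,
                config: ScanConfig | None = None) -> list[GeneSegmentAnnotation]:
    """Annotate every V/D/J/C gene segment detectable on a contig.

    Candidates are located by identity to the reference set (tiled edlib
    infix search above the configured identity floor), refined by local
    alignment against the best-ranked references, then analyzed in their
    own transcription orientation: leaders/ORFs, flanking RSS, and
    regulatory elements.  Output is ordered by plus-strand coordinate,
    with the transcription direction in the ``strand`` field.
    """
    cfg = config or ScanConfig()
    seq = contig.sequence
    if set(seq) <= {"N"}:
        logger.warning("contig %s contains only Ns; nothing to scan", contig.id)
        return []
    annotations: list[GeneSegmentAnnotation] = []
    pad = cfg.leader_window + cfg.promoter_window + 100

    for seg_type in ("V", "D", "J", "C"):
        refs = germline.refs(seg_type)
        if not refs:
            continue
        floor = cfg.identity_floor if seg_type in ("V", "C") else 80.0
        for iv_start, iv_end, strand in _candidate_intervals(seq, refs, floor):
            margin = 40
            w0 = max(0, iv_start - margin)
            w1 = min(len(seq), iv_end + margin)
            window = seq[w0:w1]
            if strand == "-":
                window = revcomp(window)
            best = _best_reference(window, refs)
            if best is None:
                continue
            name, ident, (ws, we), ref_span = best
            if ident < floor:
                continue
            # a credible candidate must cover a minimum stretch of its
            # reference (fragmented V loci are still detectable)
            min_span = 70 if seg_type == "V" \
                else int(0.6 * len(refs[name]))
            if ref_span < min_span:
                continue
            # re-extract an analysis window with room for promoter and RSS
            if strand == "+":
                seg_s, seg_e = w0 + ws, w0 + we
                a0 = max(0, seg_s - pad)
                a1 = min(len(seq), seg_e + 120)
                sub = seq[a0:a1]
                s_local, e_local = seg_s - a0, seg_e - a0
                truncated = seg_s < 5 or seg_e > len(seq) - 5
            else:
                # window was reverse-complemented: map back to plus coords
                Lw = w1 - w0
                seg_s, seg_e = w0 + Lw - we, w0 + Lw - ws
                a0 = max(0, seg_s - 120)
                a1 = min(len(seq), seg_e + pad)
                sub = revcomp(seq[a0:a1])
                s_local, e_local = a1 - seg_e, a1 - seg_s
                truncated = seg_s < 5 or seg_e > len(seq) - 5

            if seg_type == "V":
                ann = _analyze_v(sub, name, s_local, e_local,
                                 refs[name], cfg, contig.is_main_locus,
                                 truncated)
            elif seg_type in ("D", "J"):
                ann = _analyze_dj(sub, seg_type, name, s_local, e_local, cfg,
                                  contig.is_main_locus)
            else:
                ann = _analyze_c(sub, name, s_local, e_local, cfg,
                                 contig.is_main_locus)
            ann.identity = ident
            # map coordinates back to the plus strand of the full contig
            if strand == "+":
                off = a0
                ann.start, ann.end = ann.start + off, ann.end + off
                if ann.leader_coords:
                    ann.leader_coords = (ann.leader_coords[0] + off,
                                         ann.leader_coords[1] + off)
            else:
                Ls = a1 - a0
                ann.start, ann.end = a0 + Ls - ann.end, a0 + Ls - ann.start
                if ann.leader_coords:
                    ls, le = ann.leader_coords
                    ann.leader_coords = (a0 + Ls - le, a0 + Ls - ls)
            ann.strand = strand
            annotations.append(ann)

    # deduplicate overlapping calls of the same type (keep best identity)
    annotations.sort(key=lambda a: (a.segment_type, a.start))
    dedup: list[GeneSegmentAnnotation] = []
    for ann in annotations:
        if (dedup and dedup[-1].segment_type == ann.segment_type
                and ann.start < dedup[-1].end):
            if ann.identity > dedup[-1].identity:
                dedup[-1] = ann
        else:
            dedup.append(ann)
    dedup.sort(key=lambda a: (a.start, a.end))
    return dedup
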