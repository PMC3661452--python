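"""Expressed variable-region analysis.

Each cDNA read is processed as: isotype call from the amplified constant
fragment, V/D/J segment assignment by identity to the germline set,
IMGT-style numbering of the translated domain (conserved anchors Cys23,
Trp41, Leu89, Cys104 and the J-region [WF]118-Gly119-X-Gly121 motif),
CDR extraction, CDR3H length grouping, composition statistics, and
annotation of the V-D and D-J junctions (A-rich conserved short
nucleotide sequences — CSNS — versus N and P nucleotides).

CDR3H length groups follow the three observed bands: group 1 up to 10
residues, group 3 from 48 residues, group 2 between them.  Lengths 11
and 32-47 fall between the observed bands and are assigned to group 2 by
a nearest-interval rule, flagged ``interpolated``.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import Align

from ._seq import AROMATIC, KYTE_DOOLITTLE, check_dna, revcomp, translate
from .config import RepertoireConfig
from .reference import GermlineSet

logger = logging.getLogger("bovigh.repertoire")


# ---------------------------------------------------------------------------
# domain types


ISOTYPES = ("IgM", "IgD", "IgG", "IgE", "IgA", "unknown")


@dataclass
class ExpressedSequence:
    id: str
    nt: str
    isotype: str = "unknown"

    def __post_init__(self):
        self.nt = self.nt.upper()
        check_dna(self.nt, what=f"sequence {self.id!r}")
        if len(self.nt) < 300:
            raise ValueError(f"sequence {self.id!r} shorter than 300 nt")


@dataclass
class SegmentMatch:
    name: str
    identity: float            # percent
    q_start: int               # query coordinates, 0-based half-open
    q_end: int
    r_start: int               # reference coordinates covered
    r_end: int
    cigar: str = ""


@dataclass
class VDJAssignment:
    v: SegmentMatch
    j: SegmentMatch
    d: SegmentMatch | None = None
    d_candidates: list[tuple[str, float]] = field(default_factory=list)
    d_ambiguous: bool = False
    v_end_adj: int | None = None       # junction-side boundaries after
    j_start_adj: int | None = None     # terminal-run trimming

    @property
    def v_end(self) -> int:
        return self.v.q_end if self.v_end_adj is None else self.v_end_adj

    @property
    def j_start(self) -> int:
        return self.j.q_start if self.j_start_adj is None else self.j_start_adj

    @property
    def d_start(self) -> int | None:
        return self.d.q_start if self.d else None

    @property
    def d_end(self) -> int | None:
        return self.d.q_end if self.d else None


REGION_BOUNDS = {
    "FR1": (1, 26), "CDR1": (27, 38), "FR2": (39, 55), "CDR2": (56, 65),
    "FR3": (66, 104), "CDR3": (105, 117), "FR4": (118, 128),
}

CONSERVED = {23: "C", 41: "W", 89: "L", 104: "C", 118: "WF", 119: "G", 121: "G"}


@dataclass
class NumberedDomain:
    """IMGT position -> residue map; ``.`` marks a gapped position."""

    labels: list[str]
    residues: list[str]

    def residue(self, label: str) -> str | None:
        try:
            res = self.residues[self.labels.index(str(label))]
        except ValueError:
            return None
        return None if res == "." else res

    def degapped(self) -> str:
        return "".join(r for r in self.residues if r != ".")

    def region(self, name: str) -> str:
        lo, hi = REGION_BOUNDS[name]
        out = []
        for lab, res in zip(self.labels, self.residues):
            base = int(lab.split(".")[0])
            in_span = lo <= base <= hi
            if name == "CDR3" and lab.startswith("112."):
                in_span = True
            if in_span and res != ".":
                out.append(res)
        return "".join(out)


@dataclass
class CDR3Record:
    aa: str
    length: int
    group: int
    interpolated: bool
    n_cys: int
    n_gly: int
    n_tyr: int
    n_ser: int
    n_aromatic: int
    hydrophilic_fraction: float
    cys_center: float | None


@dataclass
class JunctionAnnotation:
    vd_insert: str
    vd_class: str              # CSNS, N-region, none
    a_fraction: float
    dj_insert: str
    dj_class: str              # N, P, mixed, none


# ---------------------------------------------------------------------------
# isotype calling and in-silico PCR


_C_ALIGNER = Align.PairwiseAligner(
    mode="local", match_score=2, mismatch_score=-2,
    open_gap_score=-6, extend_gap_score=-1,
)


def _local_identity(window: str, ref: str):
    """Best local alignment of ``ref`` in ``window``.

    Returns ``(score, identity%, (t_start, t_end), (r_start, r_end))``.
    """
    alns = _C_ALIGNER.align(window, ref)
    if len(alns) == 0:
        return None
    aln = alns[0]
    tpairs, qpairs = aln.aligned
    matches = sum(
        1
        for (ts, te), (qs, qe) in zip(tpairs, qpairs)
        for a, b in zip(window[ts:te], ref[qs:qe])
        if a == b and a != "N"
    )
    cols = sum(te - ts for ts, te in tpairs)
    if cols == 0:
        return None
    return (float(aln.score), 100.0 * matches / cols,
            (int(tpairs[0][0]), int(tpairs[-1][-1])),
            (int(qpairs[0][0]), int(qpairs[-1][-1])))


def collapse_isotype(name: str) -> str:
    """IgG subclasses (IgG1..IgG3) are not distinguished further."""
    return "IgG" if name.upper().startswith("IGG") else name


def call_isotype(seq: ExpressedSequence | str, c_refs: dict[str, str],
                 config: RepertoireConfig | None = None) -> str:
    """Assign the isotype from the amplified constant-region fragment.

    The read tail (the amplified constant fragment) is searched inside
    each constant reference; the highest-identity reference wins, with
    ties resolved lexicographically.  IgG subclass references collapse
    to ``IgG``.  Below the identity floor against every reference the
    call is ``unknown``.
    """
    cfg = config or RepertoireConfig()
    nt = seq.nt if isinstance(seq, ExpressedSequence) else seq
    tail = nt[-60:]
    best_name, best_ident = None, -1.0
    for name in sorted(c_refs):
        res = edlib.align(tail, c_refs[name], mode="HW")
        if res["editDistance"] < 0:
            continue
        ident = 100.0 * (len(tail) - res["editDistance"]) / len(tail)
        if ident > best_ident:
            best_name, best_ident = name, ident
    if best_name is None or best_ident < cfg.isotype_identity_floor:
        logger.warning("no constant fragment recognized for %s",
                       getattr(seq, "id", "<seq>"))
        return "unknown"
    return collapse_isotype(best_name)


def insilico_pcr(template: str, fwd: str, rev: str,
                 max_mismatch: int = 0) -> list[int]:
    """Predict PCR product lengths on a plus-strand template.

    For each forward-primer site and each downstream reverse-complemented
    reverse-primer site, the product length is the span from the forward
    site start to the reverse site end.
    """
    from .germline_scan import _scan

    template = template.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 nt")
    fwd_hits = _scan(template, fwd.upper(), max_mismatch, strands="+")
    rev_hits = _scan(template, revcomp(rev.upper()), max_mismatch, strands="+")
    products = []
    for f in fwd_hits:
        for r in rev_hits:
            if r.start >= f.end:
                products.append(r.end - f.start)
    return sorted(products)


# ---------------------------------------------------------------------------
# V(D)J assignment


def _hw_match(ref: str, target: str, name: str) -> SegmentMatch | None:
    res = edlib.align(ref, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    s, e = res["locations"][0]
    ident = 100.0 * (len(ref) - res["editDistance"]) / len(ref)
    m = SegmentMatch(name, ident, int(s), int(e) + 1, 0, len(ref),
                     res["cigar"] or "")
    # terminal substitutions make the alignment endpoint ambiguous (a
    # mismatch and a terminal insertion cost the same); prefer the
    # full-span interpretation when the span falls just short
    if 0 < len(ref) - (m.q_end - m.q_start) <= 2 \
            and m.q_start + len(ref) <= len(target):
        m.q_end = m.q_start + len(ref)
    return m


def _d_match(junction: str, ref: str, min_run: int = 5):
    """Local D alignment with mismatch-tolerant ends trimmed back.

    The local aligner happily extends through net-positive blocks of
    chance matches in the non-templated junction flanks; requiring each
    alignment end to terminate in ``min_run`` consecutive exact matches
    keeps the estimated D boundaries on templated sequence.  Returns
    ``(score, identity%, (t_start, t_end), (r_start, r_end))``.
    """
    alns = _C_ALIGNER.align(junction, ref)
    if len(alns) == 0:
        return None
    aln = alns[0]
    tpairs, qpairs = aln.aligned
    cols = [(ti, ri, junction[ti] == ref[ri] and junction[ti] != "N")
            for (ts, te), (rs, re_) in zip(tpairs, qpairs)
            for ti, ri in zip(range(ts, te), range(rs, re_))]
    if not cols:
        return None

    def run_at(i, step):
        n = 0
        while 0 <= i < len(cols) and cols[i][2]:
            n += 1
            if n >= min_run:
                return True
            i += step
        return False

    lo, hi = 0, len(cols) - 1
    while lo <= hi and not run_at(lo, +1):
        lo += 1
    while hi >= lo and not run_at(hi, -1):
        hi -= 1
    if hi - lo + 1 < min_run:
        return None
    kept = cols[lo:hi + 1]
    matches = sum(1 for _, _, m in kept if m)
    ident = 100.0 * matches / len(kept)
    return (float(aln.score), ident,
            (kept[0][0], kept[-1][0] + 1), (kept[0][1], kept[-1][1] + 1))


def _cigar_columns(ref: str, read: str, q_start: int, cigar: str):
    """Per-column (read_pos, is_match) pairs of an edlib HW alignment."""
    cols = []
    r = 0
    t = q_start
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=XM":
            for _ in range(n):
                cols.append((t, ref[r] == read[t] and read[t] != "N"))
                r += 1
                t += 1
        elif ch == "I":
            cols.append((t, False))
            r += n
        elif ch == "D":
            for _ in range(n):
                cols.append((t, False))
                t += 1
    return cols


def _trim_boundary(ref: str, read: str, m: SegmentMatch, edge: str,
                   min_run: int = 3) -> int:
    """Junction-side boundary of a segment match, trimmed back until the
    alignment terminates in ``min_run`` consecutive exact matches.

    A trimmed germline end absorbed into the alignment shows up as a
    mismatch-rich terminal stretch; trimming it keeps the junction
    coordinates on genuinely templated sequence.
    """
    cols = _cigar_columns(ref, read, m.q_start, m.cigar)
    if not cols:
        return m.q_end if edge == "end" else m.q_start

    def ok(i, step):
        n = 0
        while 0 <= i < len(cols) and cols[i][1]:
            n += 1
            if n >= min_run:
                return True
            i += step
        return False

    if edge == "end":
        i = len(cols) - 1
        while i >= 0 and not ok(i, -1):
            i -= 1
        return cols[i][0] + 1 if i >= 0 else m.q_start
    i = 0
    while i < len(cols) and not ok(i, +1):
        i += 1
    return cols[i][0] if i < len(cols) else m.q_end


def _has_seed(junction: str, ref: str, k: int) -> bool:
    """True when the junction shares a k-nt exact contiguous run with
    the reference."""
    if len(junction) < k or len(ref) < k:
        return False
    kmers = {junction[i:i + k] for i in range(len(junction) - k + 1)}
    return any(ref[i:i + k] in kmers for i in range(len(ref) - k + 1))


def _longest_common_run(a: str, b: str) -> int:
    """Longest exact common substring, via diagonal run-length scan."""
    if not a or not b:
        return 0
    A = np.frombuffer(a.encode(), np.uint8)
    B = np.frombuffer(b.encode(), np.uint8)
    best = 0
    for off in range(-len(B) + 1, len(A)):
        d = np.equal(A[max(0, off):max(0, off) + len(B) + min(0, off)],
                     B[max(0, -off):max(0, -off) + len(A) - max(0, off)])
        if d.size == 0 or not d.any():
            continue
        # max run of True
        padded = np.concatenate(([0], d.view(np.int8), [0]))
        edges = np.flatnonzero(np.diff(padded))
        runs = edges[1::2] - edges[0::2]
        if runs.size:
            best = max(best, int(runs.max()))
    return best


def assign_segments(seq: ExpressedSequence | str, germline: GermlineSet,
                    config: RepertoireConfig | None = None) -> VDJAssignment:
    """Assign the best-matching germline V, D and J to an expressed read.

    V and J are chosen by best global-overlap identity (full reference
    against the read; ties broken by longer aligned span, then name);
    D is a local match inside the V..J junction requiring a contiguous
    exact seed.  When the two best D candidates lie within the ambiguity
    margin the D call is flagged ambiguous — with highly homologous
    germline D segments an unambiguous annotation is not always possible.
    """
    cfg = config or RepertoireConfig()
    nt = seq.nt if isinstance(seq, ExpressedSequence) else nt_check(seq)
    if not germline.v_refs or not germline.j_refs:
        raise ValueError("germline V and J reference sets must be non-empty")

    best_v = None
    for name in sorted(germline.v_refs):
        m = _hw_match(germline.v_refs[name], nt, name)
        if m is None:
            continue
        if (best_v is None
                or (m.identity, m.q_end - m.q_start) >
                   (best_v.identity, best_v.q_end - best_v.q_start)):
            best_v = m
    if best_v is None or best_v.identity < cfg.v_identity_floor:
        raise ValueError("unassignable: no V above the identity floor")

    tail = nt[best_v.q_end:]
    best_j = None
    for name in sorted(germline.j_refs):
        m = _hw_match(germline.j_refs[name], tail, name)
        if m is None:
            continue
        if (best_j is None
                or (m.identity, m.q_end - m.q_start) >
                   (best_j.identity, best_j.q_end - best_j.q_start)):
            best_j = m
    if best_j is None:
        raise ValueError("unassignable: no J match downstream of V")
    best_j.q_start += best_v.q_end
    best_j.q_end += best_v.q_end

    # junction-side boundaries: an alignment that absorbed a trimmed
    # germline end is cut back to its last confidently templated base
    v_ref_seq = germline.v_refs[best_v.name]
    j_ref_seq = germline.j_refs[best_j.name]
    v_end_adj = _trim_boundary(v_ref_seq, nt, best_v, "end")
    j_start_adj = _trim_boundary(j_ref_seq, nt, best_j, "start")

    # the D search window covers the junction plus fixed margins: when a
    # heavily trimmed V or J forces its alignment to absorb junction
    # bases, the retained D must still fall inside the searched region
    jct_lo = max(best_v.q_start, v_end_adj - 6)
    jct_hi = min(len(nt), j_start_adj + 12)
    junction = nt[jct_lo:jct_hi]
    cands: list[tuple[float, str, float, SegmentMatch]] = []
    for name in sorted(germline.d_refs):
        ref = germline.d_refs[name]
        if not _has_seed(junction, ref, cfg.d_seed_length):
            continue
        hit = _d_match(junction, ref)
        if hit is None:
            continue
        score, ident, (ts, te), (rs, re_) = hit
        m = SegmentMatch(name, ident, jct_lo + ts, jct_lo + te,
                         rs, re_)
        cands.append((score, name, ident, m))
    # rank by alignment score: identity alone would let a short segment
    # matching perfectly inside a homologous long D outrank the long one
    cands.sort(key=lambda c: (-c[0], c[1]))

    asg = VDJAssignment(v=best_v, j=best_j, v_end_adj=v_end_adj,
                        j_start_adj=j_start_adj)
    asg.d_candidates = [(n, i) for _, n, i, _ in cands]
    if cands:
        asg.d = cands[0][3]
        if len(cands) > 1 and abs(cands[0][2] - cands[1][2]) \
                < cfg.d_ambiguity_margin:
            asg.d_ambiguous = True
        # where the D match overlaps an absorbed V tail or J head, the
        # templated D evidence wins and the junction boundaries yield
        if asg.d.q_start < asg.v_end_adj:
            asg.v_end_adj = asg.d.q_start
        if asg.d.q_end > asg.j_start_adj:
            asg.j_start_adj = asg.d.q_end
    return asg


def nt_check(seq: str) -> str:
    check_dna(seq.upper(), what="sequence")
    return seq.upper()


# ---------------------------------------------------------------------------
# IMGT-style numbering


def _loop_fill(residues: str, lo: int, hi: int) -> list[tuple[str, str]]:
    """Place a CDR loop into span [lo, hi] with gaps at the loop middle;
    the extra residue of an odd loop goes to the N-terminal half."""
    slots = hi - lo + 1
    L = len(residues)
    if L > slots:
        raise ValueError("loop longer than span")
    front = math.ceil(L / 2)
    back = L - front
    out = []
    for i in range(front):
        out.append((str(lo + i), residues[i]))
    for i in range(slots - L):
        out.append((str(lo + front + i), "."))
    for i in range(back):
        out.append((str(hi - back + 1 + i), residues[front + i]))
    return out


def imgt_number(aa: str, partial: bool = False) -> NumberedDomain:
    """Anchor-based IMGT numbering of a translated variable domain.

    Anchors: the first Cys (-> position 23), the following conserved Trp
    (-> 41), the FR3-terminal Cys (-> 104, recognized in its Tyr-bearing
    context), and the J-region [WF]-G-x-G motif (-> 118 onward).  CDR
    gaps are inserted at loop midpoints; CDR3 loops longer than 13
    residues receive insertion positions 111.1/112.1 etc.  ``partial``
    permits a domain that ends before the J anchor (a germline V).
    """
    aa = aa.upper().strip("*")
    if "*" in aa:
        raise ValueError("internal stop codon in domain translation")
    i23 = aa.find("C", 0, 40)
    if i23 < 0:
        raise ValueError("unnumberable: no Cys23 anchor")
    if i23 > 22:
        raise ValueError("unnumberable: too many residues before Cys23")
    i41 = aa.find("W", i23 + 5, i23 + 26)
    if i41 < 0:
        raise ValueError("unnumberable: no Trp41 anchor")

    # Cys104: a Cys at a distance from Trp41 compatible with a 0-10
    # residue CDR2, preferably in a Tyr context (…Y[YFX]C104)
    candidates = [i for i in range(i41 + 45, min(len(aa), i41 + 70))
                  if i < len(aa) and aa[i] == "C"
                  and 0 <= (i - i41 - 1) - 51 <= 10]
    preferred = [i for i in candidates if "Y" in aa[max(0, i - 2):i]]
    if preferred:
        i104 = preferred[0]
    elif candidates:
        i104 = candidates[0]
    else:
        raise ValueError("unnumberable: no Cys104 anchor")

    m = re.search(r"[WF]G.G", aa[i104 + 1:])
    i118 = i104 + 1 + m.start() if m else None
    if i118 is None:
        # a substituted anchor residue (Trp118>Ser, or Gly119>Asp with
        # Trp118 intact) still leaves enough of the motif; fall back to
        # G-x-G or to a lone [WF] at a plausible FR4 distance from the end
        for pattern in (r"(?=.G.G)", r"(?=[WF])"):
            for m2 in re.finditer(pattern, aa[i104 + 1:]):
                cand = i104 + 1 + m2.start()
                if 4 <= len(aa) - cand <= 11:
                    i118 = cand
                    break
            if i118 is not None:
                break
    if i118 is None and not partial:
        raise ValueError("unnumberable: no J-region [WF]-G-x-G anchor")

    labels: list[str] = []
    residues: list[str] = []

    def put(pairs):
        for lab, res in pairs:
            labels.append(lab)
            residues.append(res)

    # FR1: 1..22 with the gap around position 10, then Cys23 and 24-26
    fr1 = aa[:i23]
    head = fr1[:9]
    rest = fr1[9:]
    put((str(i + 1), r) for i, r in enumerate(head))
    n_gap = 22 - len(fr1)
    put((str(len(head) + 1 + i), ".") for i in range(n_gap))
    put((str(22 - len(rest) + 1 + i), r) for i, r in enumerate(rest))
    put([("23", aa[i23])])
    put((str(24 + i), r) for i, r in enumerate(aa[i23 + 1:i23 + 4]))

    # CDR1 loop between positions 26 and 39-40 + Trp41
    cdr1 = aa[i23 + 4:i41 - 2]
    put(_loop_fill(cdr1, 27, 38))
    put((str(39 + i), r) for i, r in enumerate(aa[i41 - 2:i41]))
    put([("41", aa[i41])])

    # FR2 remainder 42-55
    fr2 = aa[i41 + 1:i41 + 15]
    if len(fr2) < 14:
        raise ValueError("unnumberable: truncated FR2")
    put((str(42 + i), r) for i, r in enumerate(fr2))

    # CDR2 56-65, then FR3 66..103 (gap toward position 73) and Cys104
    cdr2_len = (i104 - i41 - 1) - 51
    cdr2 = aa[i41 + 15:i41 + 15 + cdr2_len]
    put(_loop_fill(cdr2, 56, 65))
    fr3 = aa[i41 + 15 + cdr2_len:i104]
    head3 = fr3[:7]
    rest3 = fr3[7:]
    put((str(66 + i), r) for i, r in enumerate(head3))
    put((str(66 + len(head3) + i), ".") for i in range(38 - len(fr3)))
    put((str(103 - len(rest3) + 1 + i), r) for i, r in enumerate(rest3))
    put([("104", aa[i104])])

    # CDR3 105-117 (+ 111.x/112.x insertions for long loops)
    cdr3 = aa[i104 + 1:] if i118 is None else aa[i104 + 1:i118]
    if len(cdr3) <= 13:
        put(_loop_fill(cdr3, 105, 117))
    else:
        extra = len(cdr3) - 13
        a = math.ceil(extra / 2)
        b = extra - a
        put((str(105 + i), r) for i, r in enumerate(cdr3[:7]))
        put((f"111.{i + 1}", r) for i, r in enumerate(cdr3[7:7 + a]))
        put((f"112.{b - i}", r) for i, r in enumerate(cdr3[7 + a:7 + a + b]))
        put((str(112 + i), r) for i, r in enumerate(cdr3[7 + extra:]))

    # FR4 118-128
    if i118 is not None:
        fr4 = aa[i118:]
        if len(fr4) > 11:
            raise ValueError("residues extend beyond FR4 position 128")
        put((str(118 + i), r) for i, r in enumerate(fr4))

    dom = NumberedDomain(labels, residues)
    assert dom.degapped() == aa
    return dom


def extract_regions(num: NumberedDomain) -> dict[str, str]:
    """FR/CDR partition of a numbered domain (gap-free residue strings).

    CDR3H comprises the residues strictly between positions 104 and 118.
    The concatenation FR1+CDR1+...+FR4 equals the de-gapped domain.
    """
    return {name: num.region(name) for name in REGION_BOUNDS}


def conserved_residue_check(num: NumberedDomain) -> list[str]:
    """Flag substitutions of the conserved framework residues.

    Checks Cys23, Trp41, Leu89, Cys104 and the J-region [WF]118-Gly119-
    X120-Gly121 motif; positions absent from the domain (e.g. a germline
    V without J) are not flagged.  Returns one flag per violated
    position, formatted ``<pos>:<expected»observed>``.
    """
    flags = []
    for pos, expected in CONSERVED.items():
        res = num.residue(str(pos))
        if res is None:
            continue
        if res not in expected:
            flags.append(f"{pos}:{expected}>{res}")
    return flags


# ---------------------------------------------------------------------------
# CDR3 grouping, composition, junction annotation


def classify_cdr3_group(length: int) -> int:
    """CDR3H length group: 1 (<=10 aa), 3 (>=48 aa), else 2.

    The observed bands are 5-10, 12-31 and 48+ residues; lengths 11 and
    32-47 between the bands fall to group 2 by the nearest-interval rule
    (see :func:`group_is_interpolated`).
    """
    if length < 3:
        raise ValueError("CDR3 shorter than 3 residues")
    if length <= 10:
        return 1
    if length >= 48:
        return 3
    return 2


def group_is_interpolated(length: int) -> bool:
    return length == 11 or 32 <= length <= 47


def composition_profile(cdr3: str) -> CDR3Record:
    """Residue tallies and hydropathy summary of one CDR3H.

    Hydrophilic residues are those with a negative Kyte-Doolittle
    hydropathy; ``cys_center`` is the mean relative position of the Cys
    residues in [0, 1] (midpoint convention), None without Cys.
    """
    if not cdr3:
        raise ValueError("empty CDR3")
    bad = set(cdr3) - set(KYTE_DOOLITTLE)
    if bad:
        raise ValueError(f"non-standard residues in CDR3: {sorted(bad)}")
    L = len(cdr3)
    cys_pos = [i for i, r in enumerate(cdr3) if r == "C"]
    return CDR3Record(
        aa=cdr3,
        length=L,
        group=classify_cdr3_group(L) if L >= 3 else 0,
        interpolated=group_is_interpolated(L) if L >= 3 else False,
        n_cys=cdr3.count("C"),
        n_gly=cdr3.count("G"),
        n_tyr=cdr3.count("Y"),
        n_ser=cdr3.count("S"),
        n_aromatic=sum(1 for r in cdr3 if r in AROMATIC),
        hydrophilic_fraction=sum(1 for r in cdr3 if KYTE_DOOLITTLE[r] < 0) / L,
        cys_center=(sum((p + 0.5) / L for p in cys_pos) / len(cys_pos)
                    if cys_pos else None),
    )


def detect_csns(insert: str, config: RepertoireConfig | None = None):
    """Classify the V-D junction insert.

    An insert of 13-18 nt with an A fraction at or above the threshold is
    a conserved short nucleotide sequence (CSNS); any other non-empty
    insert is an N-region; an empty insert is ``none``.  Returns
    ``(classification, a_fraction)``.
    """
    cfg = config or RepertoireConfig()
    if not insert:
        return "none", 0.0
    a_frac = insert.count("A") / len(insert)
    if (cfg.csns_min_len <= len(insert) <= cfg.csns_max_len
            and a_frac >= cfg.csns_a_fraction):
        return "CSNS", a_frac
    return "N-region", a_frac


def annotate_dj_junction(insert: str, d_ref_end: str, j_ref_start: str,
                         d_untrimmed: bool = True, j_untrimmed: bool = True,
                         config: RepertoireConfig | None = None) -> str:
    """Classify the D-J junction insert as N, P, mixed or none.

    P nucleotides are leading/trailing bases of the insert that form a
    reverse-complement palindrome (up to 3 nt) with the untrimmed
    adjacent germline end; everything else is non-templated N.
    """
    cfg = config or RepertoireConfig()
    if not insert:
        return "none"
    p_lead = 0
    if d_untrimmed and d_ref_end:
        for k in range(min(cfg.p_max_len, len(insert), len(d_ref_end)), 0, -1):
            if insert[:k] == revcomp(d_ref_end[-k:]):
                p_lead = k
                break
    p_trail = 0
    if j_untrimmed and j_ref_start:
        for k in range(min(cfg.p_max_len, len(insert) - p_lead,
                           len(j_ref_start)), 0, -1):
            if insert[len(insert) - k:] == revcomp(j_ref_start[:k]):
                p_trail = k
                break
    p_total = p_lead + p_trail
    if p_total == 0:
        return "N"
    if p_total >= len(insert):
        return "P"
    return "mixed"


# ---------------------------------------------------------------------------
# read-level pipeline: germline-anchored region projection


def _project(cigar: str, ref_pos: int, t_start: int) -> int:
    """Map a reference offset through an edlib CIGAR onto the target.

    ``=``/``X``/``M`` consume both sequences, ``I`` the reference only,
    ``D`` the target only.  Positions beyond the alignment clamp to its
    end.
    """
    r = t = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=XM":
            if r + n > ref_pos:
                return t_start + t + (ref_pos - r)
            r += n
            t += n
        elif ch == "I":
            if r + n > ref_pos:
                return t_start + t
            r += n
        elif ch == "D":
            t += n
    return t_start + t


@dataclass
class VLandmarks:
    """Nucleotide offsets of IMGT region boundaries within a germline V."""

    cdr1_nt: tuple[int, int]
    cdr2_nt: tuple[int, int]
    cys104_codon_end: int      # nt offset just past the Cys104 codon
    aa: str


_LANDMARK_CACHE: dict[str, "VLandmarks"] = {}


def v_landmarks(v_ref: str) -> VLandmarks:
    """Locate CDR1/CDR2 and the Cys104 codon in a germline V reference.

    The reference is expected to be the V region in reading frame 0
    (no leader).  Results are cached per sequence.
    """
    lm = _LANDMARK_CACHE.get(v_ref)
    if lm is not None:
        return lm
    aa = translate(v_ref)
    num = imgt_number(aa, partial=True)
    idx = {}
    i = 0
    for lab, res in zip(num.labels, num.residues):
        if res == ".":
            continue
        idx[lab] = i
        i += 1

    def span(lo, hi):
        members = [v for k, v in idx.items()
                   if "." not in k and lo <= int(k) <= hi]
        if not members:
            raise ValueError(f"no residues in span {lo}-{hi}")
        return (min(members) * 3, (max(members) + 1) * 3)

    lm = VLandmarks(
        cdr1_nt=span(*REGION_BOUNDS["CDR1"]),
        cdr2_nt=span(*REGION_BOUNDS["CDR2"]),
        cys104_codon_end=(idx["104"] + 1) * 3,
        aa=aa,
    )
    _LANDMARK_CACHE[v_ref] = lm
    return lm


def j_w118_offset(j_ref: str) -> int:
    """Nucleotide offset of the J-region [WF]118 codon (frame 0)."""
    aa = translate(j_ref)
    m = re.search(r"[WF]G.G", aa)
    if not m:
        raise ValueError("J reference lacks the [WF]-G-x-G motif")
    return m.start() * 3


def analyze_sequence(seq: ExpressedSequence, germline: GermlineSet,
                     config: RepertoireConfig | None = None) -> dict:
    """Full per-read analysis: isotype, V(D)J, regions, CDR3, junctions.

    Region boundaries are obtained by projecting the numbered germline V
    (and the J-region Trp118) through the read alignments, which keeps
    CDR coordinates stable under somatic point mutation even when an
    anchor residue itself is substituted.
    """
    cfg = config or RepertoireConfig()
    nt = seq.nt
    isotype = call_isotype(seq, germline.c_refs, cfg) if germline.c_refs \
        else seq.isotype
    asg = assign_segments(seq, germline, cfg)
    v_ref = germline.v_refs[asg.v.name]
    j_ref = germline.j_refs[asg.j.name]
    lm = v_landmarks(v_ref)

    def vmap(ref_pos):
        return _project(asg.v.cigar, ref_pos, asg.v.q_start)

    def jmap(ref_pos):
        return _project(asg.j.cigar, ref_pos, asg.j.q_start)

    cdr3_start = vmap(lm.cys104_codon_end)
    cdr3_end = jmap(j_w118_offset(j_ref))
    cdr3_nt = nt[cdr3_start:cdr3_end]
    cdr3_aa = translate(cdr3_nt)
    cdr3_len = len(cdr3_aa)

    # substitution tie-breaks in the alignment path can shift a projected
    # boundary by one base; rounding keeps the residue count exact
    cdr1_len = round((vmap(lm.cdr1_nt[1]) - vmap(lm.cdr1_nt[0])) / 3)
    cdr2_len = round((vmap(lm.cdr2_nt[1]) - vmap(lm.cdr2_nt[0])) / 3)
    variable_aa = (asg.j.q_end - asg.v.q_start) // 3

    row = {
        "id": seq.id,
        "isotype": isotype,
        "v_name": asg.v.name,
        "v_identity": round(asg.v.identity, 2),
        "d_name": asg.d.name if asg.d else "",
        "d_identity": round(asg.d.identity, 2) if asg.d else float("nan"),
        "d_ambiguous": asg.d_ambiguous,
        "j_name": asg.j.name,
        "j_identity": round(asg.j.identity, 2),
        "variable_aa_len": variable_aa,
        "cdr1_len": cdr1_len,
        "cdr2_len": cdr2_len,
        "cdr3_len": cdr3_len,
        "cdr3_aa": cdr3_aa,
    }

    if cdr3_len >= 3:
        row["group"] = classify_cdr3_group(cdr3_len)
        row["interpolated"] = group_is_interpolated(cdr3_len)
    else:
        row["group"] = 0
        row["interpolated"] = False
    clean = cdr3_aa and set(cdr3_aa) <= set(KYTE_DOOLITTLE)
    if clean:
        prof = composition_profile(cdr3_aa)
        row.update(
            n_cys=prof.n_cys, n_gly=prof.n_gly, n_tyr=prof.n_tyr,
            n_ser=prof.n_ser, n_aromatic=prof.n_aromatic,
            hydrophilic_fraction=round(prof.hydrophilic_fraction, 4),
            cys_center=(round(prof.cys_center, 4)
                        if prof.cys_center is not None else float("nan")),
        )
    else:
        row.update(n_cys=-1, n_gly=-1, n_tyr=-1, n_ser=-1, n_aromatic=-1,
                   hydrophilic_fraction=float("nan"),
                   cys_center=float("nan"))

    # junction annotation
    if asg.d is not None:
        d_ref = germline.d_refs[asg.d.name]
        vd_insert = nt[asg.v_end:asg.d.q_start]
        vd_class, a_frac = detect_csns(vd_insert, cfg)
        if vd_class != "CSNS":
            # point mutations near the 5' end of the retained D shift the
            # estimated boundary rightward, lengthening the apparent
            # insert; tolerate a few nucleotides of slip
            for k in range(1, 8):
                if len(vd_insert) - k < cfg.csns_min_len:
                    break
                cls2, af2 = detect_csns(vd_insert[:-k], cfg)
                if cls2 == "CSNS":
                    vd_class, a_frac = cls2, af2
                    break
        dj_insert = nt[asg.d.q_end:asg.j_start]
        dj_class = annotate_dj_junction(
            dj_insert, d_ref, j_ref,
            d_untrimmed=asg.d.r_end == len(d_ref),
            j_untrimmed=True, config=cfg)
    else:
        vd_insert, vd_class, a_frac, dj_class = "", "NA", 0.0, "NA"
    row.update(vd_insert_len=len(vd_insert), vd_class=vd_class,
               vd_a_fraction=round(a_frac, 4), dj_class=dj_class)

    # conserved-residue flags on the read's own translated domain
    domain_aa = translate(nt[asg.v.q_start:asg.j.q_end])
    if "*" in domain_aa.rstrip("*"):
        row["conserved_flags"] = "internal_stop"
    else:
        try:
            flags = conserved_residue_check(imgt_number(domain_aa))
            row["conserved_flags"] = ";".join(flags)
        except ValueError:
            row["conserved_flags"] = "unnumberable"
    return row


def analyze_repertoire(seqs, germline: GermlineSet,
                       config: RepertoireConfig | None = None):
    """Analyze an iterable of reads into a per-sequence DataFrame.

    Unassignable reads are reported with ``v_name == 'unassignable'``
    and NaN metrics rather than aborting the batch.
    """
    import pandas as pd

    rows = []
    for seq in seqs:
        try:
            rows.append(analyze_sequence(seq, germline, config))
        except ValueError as err:
            logger.warning("sequence %s: %s", seq.id, err)
            rows.append({"id": seq.id, "isotype": "unknown",
                         "v_name": "unassignable"})
    return pd.DataFrame(rows)


def summarize_by_isotype(report):
    """Per-isotype mean +/- SD of the variable-region and CDR lengths."""
    import pandas as pd

    cols = ["variable_aa_len", "cdr1_len", "cdr2_len", "cdr3_len"]
    rows = []
    for isotype, sub in report.groupby("isotype", sort=True):
        ok = sub.dropna(subset=[c for c in cols if c in sub])
        row = {"isotype": isotype, "n": len(ok)}
        for c in cols:
            mean = float(ok[c].mean()) if len(ok) else float("nan")
            sd = float(ok[c].std(ddof=1)) if len(ok) > 1 else 0.0
            row[f"{c}_mean"] = round(mean, 2)
            row[f"{c}_sd"] = round(sd, 2)
            row[c] = f"{mean:.2f}±{sd:.2f}"
        rows.append(row)
    return pd.DataFrame(rows)
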