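"""Seeded generators for germline loci and expressed repertoires.

The germline generator emits genomic contigs carrying a two-family V
repertoire (families produced by mutating family founders, with
within/between-family identity bands enforced by rejection sampling),
D segments of configurable lengths, a J cluster, and per-isotype
constant-region stubs whose primer geometry mirrors the isotype-specific
amplification setup.  Every planted segment comes with its intended
functionality class and defect in a truth table.

The repertoire generator recombines V + (CSNS) + N + D + N/P + J +
constant stub.  Group-3 draws (exceptionally long CDR3H) always use the
longest D together with an A-rich CSNS insert at the V-D junction;
group-1 draws use the short D segments with trimming.  Junction
components are codon-quantized so every emitted read is productive
(no internal stop), mirroring the in-frame selection of expressed
rearrangements; somatic hypermutation with RGYW/WRCY hotspot bias is
applied on top.  All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import hamming, mutate_substitutions, revcomp, translate
from .germline_scan import GenomicContig
from .primers import FORWARD_PRIMER, REVERSE_PRIMERS
from .reference import GermlineSet

# amino-acid alphabet for non-anchor positions: no Cys/Trp, so numbering
# anchors stay unique by construction
_SAFE_AA = "ADEFGHIKLMNPQRSTVY"
_D_AA = "GYSGYSGYSDANT"          # Gly/Tyr/Ser-rich D reading frame

_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"), "R": ("CGT", "CGC", "CGG"),
    "N": ("AAT", "AAC"), "D": ("GAT", "GAC"), "C": ("TGT", "TGC"),
    "Q": ("CAA", "CAG"), "E": ("GAA", "GAG"),
    "G": ("GGT", "GGC", "GGA", "GGG"), "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"), "L": ("CTT", "CTC", "CTA", "CTG"),
    "K": ("AAA", "AAG"), "M": ("ATG",), "F": ("TTT", "TTC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"), "W": ("TGG",),
    "Y": ("TAT", "TAC"), "V": ("GTT", "GTC", "GTA", "GTG"),
}

HEPTAMER = "CACAGTG"
NONAMER = "ACAAAAACC"
OCTAMER = "ATGCAAAT"
TATA = "TATAAA"
POLYA = "AATAAA"

LEADER_PART2_NT = 12       # leader part 2 inside the V exon (4 codons)
V_REGION_NT = 291          # FR1..Cys104 (285 nt) + 6-nt CDR3 head
V_EXON_NT = LEADER_PART2_NT + V_REGION_NT
FRAGMENT_NT = 77           # fragmented pseudogene loci
J_NT = 45                  # 4 CDR3-tail codons + [W]GQGTLVTVSS
J_HEAD_NT = 12             # J contribution to CDR3 (before Trp118)


def _rand_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n)) if n else ""


def _rand_aa(rng, n, alphabet=_SAFE_AA):
    return "".join(rng.choice(list(alphabet), size=n)) if n else ""


def _codons_for(aa: str, rng) -> str:
    return "".join(_CODONS[r][rng.integers(0, len(_CODONS[r]))] for r in aa)


# ---------------------------------------------------------------------------
# specs and results


@dataclass
class GermlineSimSpec:
    n_v: int = 36
    n_d: int = 3
    n_j: int = 6
    n_families: int = 2
    within_family_identity: float = 85.0
    between_family_identity: float = 65.0
    pseudogene_fraction: float = 0.5
    fragment_fraction: float = 2 / 36
    n_functional: int = 13
    d_lengths: tuple = (15, 36, 148)
    plant_rss: bool = True
    isotypes: tuple = ("IgM", "IgD", "IgG1", "IgG2", "IgG3", "IgE", "IgA")
    seed: int = 0

    def __post_init__(self):
        if self.within_family_identity <= self.between_family_identity:
            raise ValueError("within-family identity must exceed "
                             "between-family identity")
        for frac in (self.pseudogene_fraction, self.fragment_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_v < self.n_functional:
            raise ValueError("n_functional exceeds n_v")


@dataclass
class GermlineSim:
    spec: GermlineSimSpec
    contigs: list
    truth: pd.DataFrame
    refs_scan: GermlineSet      # V records = full V exon (leader part 2 + V)
    refs_expr: GermlineSet      # V records = V region in reading frame 0
    leader_nt: str              # spliced leader (exon 1 + part 2), 60 nt
    v_regions: dict
    c_stubs: dict
    c_offsets: dict             # reverse-primer offset within each stub
    long_v: str
    j_used: str

    @property
    def functional_v(self) -> list[str]:
        t = self.truth
        return sorted(t[(t.segment_type == "V")
                        & (t.functionality == "F")].name)


@dataclass
class RepertoireSimSpec:
    per_isotype: dict = field(default_factory=lambda: {
        "IgM": 20, "IgD": 20, "IgG": 20, "IgE": 20, "IgA": 20})
    group_proportions: tuple = (0.07, 0.74, 0.19)
    csns_probability: float = 0.3     # CSNS rate in mid-length (group 2) CDR3H
    shm_rate: float = 0.02
    hotspot_multiplier: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        if not 0 <= self.shm_rate <= 1:
            raise ValueError("shm_rate must lie in [0, 1]")


# ---------------------------------------------------------------------------
# somatic hypermutation


_HOTSPOT_RGYW = re.compile(r"(?=[AG]G[CT][AT])")
_HOTSPOT_WRCY = re.compile(r"(?=[AT][AG]C[CT])")


def hotspot_positions(nt: str) -> np.ndarray:
    """Mutable hotspot positions: the G of RGYW and the C of WRCY."""
    pos = {m.start() + 1 for m in _HOTSPOT_RGYW.finditer(nt)}
    pos |= {m.start() + 2 for m in _HOTSPOT_WRCY.finditer(nt)}
    return np.array(sorted(pos), dtype=int)


def apply_shm(nt: str, rate: float, hotspot_multiplier: float = 3.0,
              seed=0) -> tuple[str, list[int]]:
    """Hotspot-biased somatic point mutation.

    Each site mutates with probability ``rate``, multiplied at RGYW/WRCY
    hotspot positions; substitutions favor transitions 2:1 over each
    transversion.  Returns the mutated sequence and mutated positions.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if rate == 0 or not nt:
        return nt, []
    p = np.full(len(nt), rate)
    hs = hotspot_positions(nt)
    if hs.size:
        p[hs] = np.minimum(1.0, rate * hotspot_multiplier)
    positions = np.nonzero(rng.random(len(nt)) < p)[0]
    return mutate_substitutions(nt, positions, rng), positions.tolist()


# ---------------------------------------------------------------------------
# germline locus simulation


def _founder_aa(rng) -> str:
    """A V-domain template with canonical anchors and 8/7-residue CDRs."""
    return (_rand_aa(rng, 21) + "C"                       # FR1, Cys23
            + _rand_aa(rng, 3)                            # 24-26
            + _rand_aa(rng, 8)                            # CDR1 (8 aa)
            + _rand_aa(rng, 2) + "W"                      # 39-40, Trp41
            + _rand_aa(rng, 14)                           # FR2 42-55
            + _rand_aa(rng, 7)                            # CDR2 (7 aa)
            + _rand_aa(rng, 22) + "L"                     # FR3 66-88, Leu89
            + _rand_aa(rng, 12) + "YY" + "C"              # 90-101, YY, Cys104
            + "AK")                                       # CDR3 head


_ANCHOR_IDX = frozenset([21, 35, 79, 92, 93, 94])


def _mutate_aa(aa: str, p: float, rng) -> str:
    out = list(aa)
    for i in range(len(out)):
        if i in _ANCHOR_IDX:
            continue
        if rng.random() < p:
            choices = [c for c in _SAFE_AA if c != out[i]]
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _derive_nt(founder_aa, founder_nt, member_aa, rng) -> str:
    """Member nucleotides: founder codons where the residue is unchanged,
    a random codon of the new residue elsewhere."""
    out = []
    for i, (fa, ma) in enumerate(zip(founder_aa, member_aa)):
        if fa == ma:
            out.append(founder_nt[3 * i:3 * i + 3])
        else:
            out.append(_CODONS[ma][rng.integers(0, len(_CODONS[ma]))])
    return "".join(out)


def _identity_pct(a: str, b: str) -> float:
    return 100.0 * (1 - hamming(a, b) / len(a))


def _make_families(spec: GermlineSimSpec, rng):
    """V-region nucleotide sequences per family, rejection-sampled into
    the requested identity bands (tolerance about 3 points)."""
    n_fam = max(1, spec.n_families)
    within, between = spec.within_family_identity, spec.between_family_identity
    # aa mutation rates: a random codon of a new residue differs from the
    # old codon at ~75% of its bases; anchors never mutate
    n_aa = len(_founder_aa(np.random.default_rng(0)))
    F = 0.75 * (n_aa - len(_ANCHOR_IDX)) / n_aa
    p_member = (1 - within / 100) / (2 * F)
    q = max(0.05, min(0.95, ((1 - between / 100) - 2 * p_member * F)
                      / (F * (1 - 2 * p_member))))
    base_aa = _founder_aa(rng)
    base_nt = _codons_for(base_aa, rng)
    founders_aa, founders_nt = [base_aa], [base_nt]
    for _ in range(1, n_fam):
        fa = _mutate_aa(base_aa, q, rng)
        founders_aa.append(fa)
        founders_nt.append(_derive_nt(base_aa, base_nt, fa, rng))

    def member(fam_idx, same_family, other_family):
        for _try in range(500):
            ma = _mutate_aa(founders_aa[fam_idx], p_member, rng)
            mn = _derive_nt(founders_aa[fam_idx], founders_nt[fam_idx],
                            ma, rng)
            if not all(_identity_pct(mn, e) >= within - 3
                       for e in same_family):
                continue
            if not all(_identity_pct(mn, e) <= between + 5
                       for e in other_family):
                continue
            return mn
        raise ValueError("cannot achieve the requested identity bands")

    return founders_nt, member


_V_DEFECT_CYCLE_PSI = ("stop", "frameshift", "rss_heptamer",
                       "rss_nonamer", "rss_spacer")
_V_DEFECT_CYCLE_ORF = ("octamer", "splice", "conserved")


def _v_cassette(rng, leader_exon1, exon2, defect: str | None,
                plant_rss: bool) -> tuple[str, int, int]:
    """One V gene cassette; returns (sequence, exon2 start, exon2 end)."""
    octamer = OCTAMER if defect != "octamer" else "ATGCGGAT"
    donor = "GT" if defect != "splice" else "GG"
    heptamer, nonamer, spacer = HEPTAMER, NONAMER, 23
    if defect == "rss_heptamer":
        heptamer = "TACAGTG"
    elif defect == "rss_nonamer":
        nonamer = "ACAGTAACC"
    elif defect == "rss_spacer":
        spacer = 22

    exon2 = exon2
    if defect == "stop":
        i = 40 * 3
        exon2 = exon2[:i] + "TAA" + exon2[i + 3:]
    elif defect == "frameshift":
        i = 150
        exon2 = exon2[:i] + exon2[i + 1:]
    elif defect == "conserved":
        i = (4 + 35) * 3            # Trp41 codon within the exon
        exon2 = exon2[:i] + "CGT" + exon2[i + 3:]

    if defect == "fragment":
        seq = exon2[:FRAGMENT_NT]
        return seq, 0, len(seq)

    intron = donor + _rand_dna(rng, 71) + "AG"
    promoter = octamer + _rand_dna(rng, 20) + TATA + _rand_dna(rng, 25)
    parts = [promoter, leader_exon1, intron, exon2]
    if plant_rss:
        parts.append(heptamer + _rand_dna(rng, spacer) + nonamer)
    seq = "".join(parts)
    s = len(promoter) + len(leader_exon1) + len(intron)
    return seq, s, s + len(exon2)


def simulate_germline(spec: GermlineSimSpec | None = None) -> GermlineSim:
    """Generate a germline heavy-chain locus with full ground truth.

    Families are derived from mutated founders (family 1 carries all
    functional segments); the requested pseudogene/fragment fractions
    and functional count are realized exactly, with defects cycling over
    stop codons, frameshifts, recombination-critical RSS mutations
    (pseudogenes) and regulatory/splice/conserved-residue alterations
    (ORFs).  Same seed, same bytes.
    """
    spec = spec or GermlineSimSpec()
    rng = np.random.default_rng(spec.seed)

    # leader: ATG + forward-primer annealing site + safe codons (60 nt)
    fwd = FORWARD_PRIMER[1]
    leader_nt = "ATG" + fwd + "A" + _codons_for(_rand_aa(rng, 12), rng)
    assert len(leader_nt) == 60 and "*" not in translate(leader_nt)
    leader_exon1, leader_part2 = leader_nt[:48], leader_nt[48:]

    # family structure and functionality classes
    n_v = spec.n_v
    n_psi = int(round(spec.pseudogene_fraction * n_v))
    n_frag = min(int(round(spec.fragment_fraction * n_v)), n_psi)
    n_f = min(spec.n_functional, n_v - n_psi)
    n_orf = n_v - n_psi - n_f
    if spec.n_families >= 2:
        f2_size = min(n_psi, max(1, int(round(n_v * 0.45))))
    else:
        f2_size = 0
    f1_size = n_v - f2_size
    f1_psi = n_psi - f2_size

    families = [1] * f1_size + [2] * f2_size
    classes = (["F"] * n_f + ["ORF"] * n_orf + ["Psi"] * f1_psi
               + ["Psi"] * f2_size)
    # shuffle class labels within family 1 so functional segments are not
    # a contiguous block; the designated long-CDR3 V stays functional
    f1_classes = classes[:f1_size]
    rng.shuffle(f1_classes)
    classes = f1_classes + classes[f1_size:]
    long_idx = min(9, f1_size - 1)          # IGHV10 when available
    if classes[long_idx] != "F":
        swap = classes.index("F")
        classes[long_idx], classes[swap] = classes[swap], classes[long_idx]

    founders_nt, member = _make_families(spec, rng)
    psi_cycle = iter(_V_DEFECT_CYCLE_PSI * n_v)
    orf_cycle = iter(_V_DEFECT_CYCLE_ORF * n_v)
    frag_budget = n_frag

    v_regions: dict[str, str] = {}
    v_defects: dict[str, str | None] = {}
    per_family: dict[int, list[str]] = {1: [], 2: []}
    for i in range(n_v):
        fam = families[i]
        name = f"IGHV{i + 1}"
        other = per_family[2] if fam == 1 else per_family[1]
        vr = member(fam - 1, per_family[fam], other)
        per_family[fam].append(vr)
        v_regions[name] = vr
        if classes[i] == "F":
            v_defects[name] = None
        elif classes[i] == "ORF":
            v_defects[name] = next(orf_cycle)
        else:
            if fam == 2 and frag_budget > 0:
                v_defects[name] = "fragment"
                frag_budget -= 1
            else:
                v_defects[name] = next(psi_cycle)

    # D, J, C references
    d_names = (("IGHDQ52", "IGHD4", "IGHD2") if spec.n_d == 3
               and tuple(spec.d_lengths) == (15, 36, 148)
               else tuple(f"IGHD{i + 1}" for i in range(spec.n_d)))
    d_refs = {}
    for i in range(spec.n_d):
        length = (spec.d_lengths[i] if i < len(spec.d_lengths)
                  else int(rng.integers(18, 40)))
        nt = _codons_for(_rand_aa(rng, length // 3, _D_AA), rng)
        nt += _rand_dna(rng, length - len(nt)).replace("T", "G")
        d_refs[d_names[i]] = nt

    j_refs = {}
    j_used = "IGHJ1"
    for i in range(spec.n_j):
        name = f"IGHJ{i + 1}"
        if name == j_used:
            aa = "G" + _rand_aa(rng, 3, "ADEGHIKLMNPQRSTVY") + "WGQGTLVTVSS"
            j_refs[name] = "GGC" + _codons_for(aa[1:], rng)
        else:
            # no Trp/Phe, so the J motif is genuinely absent
            aa = _rand_aa(rng, J_NT // 3, "ADEGHIKLMNPQRSTVY")
            j_refs[name] = _codons_for(aa, rng)

    # constant-region stubs with the isotype-specific primer geometry:
    # the reverse primer site sits so a short-CDR3 amplicon matches the
    # approximate product size of the primer table
    pre_c_nominal = 45 + LEADER_PART2_NT + 285 + 3 * 8 + (J_NT - J_HEAD_NT)
    c_stubs, c_offsets = {}, {}
    for iso in spec.isotypes:
        rev_name, rev_seq, target = REVERSE_PRIMERS[
            "IgG" if iso.startswith("IgG") else iso]
        off = max(10, target - pre_c_nominal - len(rev_seq))
        c_stubs[iso] = (_rand_dna(rng, off) + revcomp(rev_seq)
                        + _rand_dna(rng, 10))
        c_offsets[iso] = off

    # assemble the main-locus contig
    parts: list[str] = []
    rows: list[dict] = []
    cursor = 0

    def emit(seq):
        nonlocal cursor
        parts.append(seq)
        cursor += len(seq)

    def record(name, seg_type, fam, functionality, defect, s, e):
        rows.append({"name": name, "segment_type": seg_type, "family": fam,
                     "functionality": functionality,
                     "defect": defect or "", "start": s, "end": e,
                     "strand": "+", "contig": "BTA21_sim"})

    emit(_rand_dna(rng, int(rng.integers(250, 400))))
    for i in range(spec.n_j):
        name = f"IGHJ{i + 1}"
        cassette = (revcomp(NONAMER) + _rand_dna(rng, 23) + revcomp(HEPTAMER)
                    + j_refs[name]) if spec.plant_rss else j_refs[name]
        s = cursor + len(cassette) - J_NT
        emit(cassette)
        record(name, "J", 0, "F" if name == j_used else "ORF",
               None if name == j_used else "conserved_J_motif",
               s, s + J_NT)
        emit(_rand_dna(rng, int(rng.integers(120, 220))))

    for iso in spec.isotypes:
        s = cursor
        emit(c_stubs[iso])
        record(iso, "C", 0, "F", None, s, cursor)
        emit(_rand_dna(rng, 20) + POLYA)
        emit(_rand_dna(rng, int(rng.integers(150, 250))))

    d_cycle = list(d_refs)
    for i in range(n_v):
        name = f"IGHV{i + 1}"
        cassette, s, e = _v_cassette(
            rng, leader_exon1, leader_part2 + v_regions[name],
            v_defects[name], spec.plant_rss)
        record(name, "V", families[i], classes[i], v_defects[name],
               cursor + s, cursor + e)
        emit(cassette)
        emit(_rand_dna(rng, int(rng.integers(250, 400))))
        if i == 5:                  # D cluster between the 6th and 7th V
            for d_name in d_cycle:
                dseq = d_refs[d_name]
                if spec.plant_rss:
                    cassette = (revcomp(NONAMER) + _rand_dna(rng, 12)
                                + revcomp(HEPTAMER) + dseq + HEPTAMER
                                + _rand_dna(rng, 12) + NONAMER)
                    s = cursor + len(NONAMER) + 12 + len(HEPTAMER)
                else:
                    cassette, s = dseq, cursor
                record(d_name, "D", 0, "F", None, s, s + len(dseq))
                emit(cassette)
                emit(_rand_dna(rng, int(rng.integers(150, 250))))

    contig = GenomicContig("BTA21_sim", "".join(parts),
                           locus_label="BTA21", is_main_locus=True)
    truth = pd.DataFrame(rows).sort_values("start").reset_index(drop=True)

    functionality = {r["name"]: r["functionality"] for r in rows}
    refs_scan = GermlineSet(
        v_refs={n: leader_part2 + v for n, v in v_regions.items()},
        d_refs=dict(d_refs), j_refs=dict(j_refs),
        c_refs=dict(c_stubs), functionality=dict(functionality))
    refs_expr = GermlineSet(
        v_refs=dict(v_regions), d_refs=dict(d_refs), j_refs=dict(j_refs),
        c_refs=dict(c_stubs), functionality=dict(functionality))

    return GermlineSim(
        spec=spec, contigs=[contig], truth=truth, refs_scan=refs_scan,
        refs_expr=refs_expr, leader_nt=leader_nt, v_regions=v_regions,
        c_stubs=c_stubs, c_offsets=c_offsets,
        long_v=f"IGHV{long_idx + 1}", j_used=j_used)


# ---------------------------------------------------------------------------
# expressed-repertoire simulation


_GROUP_LEN = {1: (5, 10), 2: (12, 31), 3: (48, 62)}


def _draw_csns(rng, length: int) -> str:
    """A-rich insert (no T, so no stop codon can arise inside it)."""
    while True:
        s = "".join(rng.choice(["A", "C", "G"], size=length,
                               p=[0.6, 0.2, 0.2]))
        if s.count("A") / length >= 0.4:
            return s


def _draw_n(rng, length: int) -> str:
    return "".join(rng.choice(["A", "C", "G"], size=length)) if length else ""


def _junction_plan(rng, group: int, L: int, d_len: int, want_csns: bool):
    """Codon-quantized junction budget summing to 3*L nucleotides."""
    d_cap = 3 * (d_len // 3)
    v_keep, j_keep = 6, J_HEAD_NT
    csns = int(rng.integers(13, 19)) if want_csns else 0
    n1 = (3 - csns % 3) % 3 if csns else 3 * int(rng.integers(0, 3))
    p_len = int(rng.integers(1, 4)) if rng.random() < 0.5 else 0
    n2 = 3 * int(rng.integers(0, 3)) + (3 - p_len % 3) % 3

    def rem():
        return 3 * L - (v_keep + csns + n1 + p_len + n2 + j_keep)

    while rem() > d_cap:
        n2 += 3
    d_min = min(15, d_cap)
    while rem() < d_min:
        if n2 >= 3:
            n2 -= 3
        elif p_len or n2:
            p_len, n2 = 0, 0
        elif not csns and n1 >= 3:
            n1 -= 3
        elif j_keep >= 3:
            j_keep -= 3
            p_len, n2 = 0, 0        # a trimmed J forfeits P nucleotides
        elif v_keep >= 3:
            v_keep -= 3
        else:
            break
    d_keep = max(3, rem())
    return v_keep, csns, n1, d_keep, n2, p_len, j_keep


def simulate_repertoire(germline: GermlineSim,
                        spec: RepertoireSimSpec | None = None):
    """Emit expressed V(D)J reads with a per-read truth table.

    Returns ``(reads, truth)`` where reads are ``(id, nt)`` amplicons
    spanning the forward-primer site through the reverse-primer site of
    the drawn isotype.
    """
    spec = spec or RepertoireSimSpec()
    rng = np.random.default_rng(spec.seed)
    functional_v = germline.functional_v
    if not functional_v or not germline.refs_expr.d_refs \
            or germline.j_used not in germline.refs_expr.j_refs:
        raise ValueError("germline must provide functional V, D and J")
    d_refs = germline.refs_expr.d_refs
    d_by_len = sorted(d_refs, key=lambda n: (len(d_refs[n]), n))
    longest_d = d_by_len[-1]
    short_ds = [n for n in d_by_len if len(d_refs[n]) <= 36] or d_by_len[:1]
    if 3 * _GROUP_LEN[3][0] > len(d_refs[longest_d]) + 60:
        raise ValueError("no D segment long enough for group-3 CDR3H")
    j_ref = germline.refs_expr.j_refs[germline.j_used]
    j_head, j_rest = j_ref[:J_HEAD_NT], j_ref[J_HEAD_NT:]

    reads, rows = [], []
    counter = 0
    for isotype, count in spec.per_isotype.items():
        stub_names = [n for n in germline.c_stubs
                      if ("IgG" if n.startswith("IgG") else n) == isotype]
        if not stub_names:
            raise ValueError(f"no constant stub for isotype {isotype}")
        for _ in range(count):
            counter += 1
            group = 1 + int(rng.choice(3, p=spec.group_proportions))
            L = int(rng.integers(_GROUP_LEN[group][0],
                                 _GROUP_LEN[group][1] + 1))
            v_name = germline.long_v if group == 3 \
                else functional_v[rng.integers(0, len(functional_v))]
            d_name = (longest_d if group == 3
                      else short_ds[rng.integers(0, len(short_ds))]
                      if group == 1
                      else d_by_len[rng.integers(0, len(d_by_len))])
            # CSNS extends the CDR3H; it is only planted where the
            # insert fits without trimming beyond the germline ends
            want_csns = group == 3 or (
                group == 2 and L >= 17
                and rng.random() < spec.csns_probability)
            v_keep, csns_len, n1, d_keep, n2, p_len, j_keep = _junction_plan(
                rng, group, L, len(d_refs[d_name]), want_csns)
            d_ref = d_refs[d_name]
            d_cap = 3 * (len(d_ref) // 3)
            p_seq = revcomp(j_ref[:p_len]) if p_len else ""
            # redraw until the junction boundaries are identifiable: an
            # insert base that happens to continue the germline D would
            # make the planted boundary unrecoverable by any annotator
            for _attempt in range(50):
                lt = 3 * int(rng.integers(0, (d_cap - d_keep) // 3 + 1))
                csns_seq = _draw_csns(rng, csns_len) if csns_len else ""
                n1_seq = _draw_n(rng, n1)
                n2_seq = _draw_n(rng, n2)
                vd_ins = csns_seq + n1_seq
                dj_ins = n2_seq + p_seq
                if vd_ins and lt > 0 and vd_ins[-1] == d_ref[lt - 1]:
                    continue
                if dj_ins and lt + d_keep < len(d_ref) \
                        and dj_ins[0] == d_ref[lt + d_keep]:
                    continue
                # also reject inserts that mimic the adjacent D flank so
                # closely that an aligner would extend into them
                if vd_ins and lt >= 5 and sum(
                        a == b for a, b in zip(vd_ins[-5:],
                                               d_ref[lt - 5:lt])) >= 4:
                    continue
                if dj_ins and lt + d_keep + 5 <= len(d_ref) and sum(
                        a == b for a, b in zip(dj_ins[:5],
                                               d_ref[lt + d_keep:
                                                     lt + d_keep + 5])) >= 4:
                    continue
                # and reject N bases that mimic P nucleotides: a chance
                # palindrome at either flank would be indistinguishable
                # from a genuine P insertion
                if (dj_ins and p_len == 0 and j_keep == J_HEAD_NT
                        and dj_ins[-1] == revcomp(j_ref[0])):
                    continue
                if (dj_ins and lt + d_keep == len(d_ref)
                        and dj_ins[0] == revcomp(d_ref[-1])):
                    continue
                break
            d_sub = d_ref[lt:lt + d_keep]
            cdr3 = (germline.v_regions[v_name][285:285 + v_keep]
                    + vd_ins + d_sub
                    + dj_ins + j_head[J_HEAD_NT - j_keep:])
            assert len(cdr3) == 3 * L, (len(cdr3), 3 * L)

            sub = stub_names[rng.integers(0, len(stub_names))]
            stub_cut = germline.c_offsets[sub] + \
                len(REVERSE_PRIMERS["IgG" if sub.startswith("IgG")
                                    else sub][1])
            transcript = (germline.leader_nt
                          + germline.v_regions[v_name][:285]
                          + cdr3 + j_rest)
            vdj_len = len(transcript)
            transcript += germline.c_stubs[sub][:stub_cut]
            assert "*" not in translate(transcript[:vdj_len]), "unproductive"

            mutated, positions = apply_shm(
                transcript[:vdj_len], spec.shm_rate,
                spec.hotspot_multiplier, rng)
            read = (mutated + transcript[vdj_len:])[3:]
            seq_id = f"SIM{counter:04d}"
            reads.append((seq_id, read))
            rows.append({
                "id": seq_id, "isotype": isotype, "c_gene": sub,
                "v_name": v_name, "d_name": d_name,
                "j_name": germline.j_used, "group": group, "cdr3_len": L,
                "v_keep": v_keep, "csns_len": csns_len, "vd_n_len": n1,
                "d_left_trim": lt, "d_keep": d_keep, "dj_n_len": n2,
                "dj_p_len": p_len, "j_keep": j_keep,
                "n_mutations": len(positions),
            })
    return reads, pd.DataFrame(rows)
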