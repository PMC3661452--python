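"""Low-level DNA/protein helpers shared across modules."""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

DNA = set("ACGTN")
IUPAC_DNA = set("ACGTRYSWKMBDHVN")

# Kyte-Doolittle hydropathy index; residues with negative values are
# counted as hydrophilic throughout the package.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AROMATIC = frozenset("FWYH")

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(nt: str) -> str:
    """Translate a nucleotide string; codons containing N become X.

    Trailing bases that do not complete a codon are ignored.  Stop codons
    are rendered as ``*``.
    """
    out = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(str(Seq(codon).translate()))
    return "".join(out)


def check_dna(seq: str, *, allow_iupac: bool = False, what: str = "sequence") -> None:
    allowed = IUPAC_DNA if allow_iupac else DNA
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"{what} contains non-DNA symbols: {sorted(bad)}")
    if not seq:
        raise ValueError(f"{what} is empty")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate_substitutions(
    nt: str, positions: np.ndarray, rng: np.random.Generator
) -> str:
    """Substitute bases at ``positions``, transitions twice as likely as
    each transversion."""
    seq = list(nt)
    for p in positions:
        base = seq[p]
        if base not in _TRANSITION:
            continue
        ts = _TRANSITION[base]
        tvs = [b for b in "ACGT" if b != base and b != ts]
        seq[p] = str(rng.choice([ts, ts, tvs[0], tvs[1]]))
    return "".join(seq)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))
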