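"""Isotype-specific primer set for amplifying complete variable regions.

One universal forward primer anneals in the leader; each isotype has its
own reverse primer annealing in the first constant domain (CH1), except
IgM and IgD whose CH1 are too similar, so their reverse primers bind in
CH2 — hence their larger approximate product sizes.  The IgG subtypes
share one reverse primer and are not distinguished further.
"""

from __future__ import annotations

import pandas as pd

FORWARD_PRIMER = ("BoLH_BACK", "ACCCACTGTGGACCCTCCTC")

REVERSE_PRIMERS = {
    "IgM": ("BoIgMCH2_FOR", "TGCCGTCACCAGAGAGGCTGT", 795),
    "IgD": ("BoIgDCH2_FOR", "TGCGTGCTGACCGCCTTGTT", 805),
    "IgG": ("BoIgG1-3CH1_FOR", "GGCACCCGAGTTCCAGGTCA", 536),
    "IgE": ("BoIgECH1_FOR", "GCCCAGCCTTACACGGGCTT", 467),
    "IgA": ("BoIgACH1_FOR", "GCCAGCACGGCAGGGAAGTT", 574),
}

GAPDH_CONTROL = ("GAPDH_for", "TGGTCACCAGGGCTGCT",
                 "GAPDH_rev", "GGAGGGGCCATCCACAGTCT", 527)


def default_primer_table() -> pd.DataFrame:
    """The primer set as a table (one row per primer)."""
    rows = [{"name": FORWARD_PRIMER[0], "direction": "forward",
             "isotype": "all", "sequence": FORWARD_PRIMER[1],
             "product_bp": pd.NA}]
    for isotype, (name, seq, size) in REVERSE_PRIMERS.items():
        rows.append({"name": name, "direction": "reverse", "isotype": isotype,
                     "sequence": seq, "product_bp": size})
    return pd.DataFrame(rows)


def load_primer_table(path) -> pd.DataFrame:
    """Read a tab-separated primer table (columns as default_primer_table)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "direction", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"primer table lacks columns: {sorted(missing)}")
    return df
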