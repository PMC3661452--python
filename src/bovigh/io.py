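"""FASTA and tab-separated table I/O.

All tabular outputs carry a ``#`` comment header embedding the seed and a
hash of the configuration so runs are traceable; the readers here skip
those comments, so every table round-trips through the package's own I/O.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-FASTA file into ``(id, sequence)`` pairs (uppercased)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        records.append((rec.description, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path: str | Path, wrap: int = 60) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seqs)


def write_table(df: pd.DataFrame, path: str | Path, *, seed=None, config_hash=None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if config_hash is not None:
            fh.write(f"# config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
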