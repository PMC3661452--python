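"""Germline reference sets (V/D/J/C) used by both the locus scanner and
the expressed-repertoire analyzer."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import io as _io


@dataclass
class GermlineSet:
    """Named germline segment sequences with functionality labels.

    FASTA headers may carry a functionality label after a ``|``
    (e.g. ``IGHV3|F``); unlabeled records default to ``F``.
    """

    v_refs: dict[str, str] = field(default_factory=dict)
    d_refs: dict[str, str] = field(default_factory=dict)
    j_refs: dict[str, str] = field(default_factory=dict)
    c_refs: dict[str, str] = field(default_factory=dict)
    functionality: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        names = (
            list(self.v_refs) + list(self.d_refs)
            + list(self.j_refs) + list(self.c_refs)
        )
        if len(set(names)) != len(names):
            raise ValueError("duplicate segment names across reference sets")

    def refs(self, segment_type: str) -> dict[str, str]:
        return {"V": self.v_refs, "D": self.d_refs,
                "J": self.j_refs, "C": self.c_refs}[segment_type]

    @property
    def functional_j(self) -> dict[str, str]:
        return {n: s for n, s in self.j_refs.items()
                if self.functionality.get(n, "F") in ("F", "F_putative")}

    @classmethod
    def from_fastas(cls, v=None, d=None, j=None, c=None) -> "GermlineSet":
        gs = cls()
        for path, target in ((v, gs.v_refs), (d, gs.d_refs),
                             (j, gs.j_refs), (c, gs.c_refs)):
            if path is None:
                continue
            for header, seq in _io.read_fasta(Path(path)):
                name, _, label = header.partition("|")
                name = name.split()[0]
                target[name] = seq
                gs.functionality[name] = label.split()[0] if label else "F"
        gs.__post_init__()
        return gs
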