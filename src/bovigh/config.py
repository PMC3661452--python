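"""Configuration defaults for locus scanning and repertoire analysis.

The annotation rules the package applies (motif consensi, search windows,
identity floors, classification thresholds) are deliberately exposed as
plain dataclass fields so a run can be reproduced from a small key=value
text file.  The recombination-signal and promoter consensi are the
canonical immunogenetics motifs; they are configuration, not discovery.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class ScanConfig:
    """Parameters of the germline locus scanner."""

    # recombination signal sequence (RSS)
    heptamer: str = "CACAGTG"
    nonamer: str = "ACAAAAACC"
    heptamer_max_mismatch: int = 2     # outside critical first three bases
    nonamer_max_mismatch: int = 2
    spacer_tolerance: int = 1          # nt; non-exact spacer -> incompetent
    rss_search_window: int = 12        # nt between segment end and heptamer

    # regulatory elements
    octamer: str = "ATGCAAAT"          # either strand, exact
    tata_box: str = "TATAAA"           # <=1 mismatch
    tata_max_mismatch: int = 1
    polya: str = "AATAAA"
    promoter_window: int = 300         # upstream of the leader ATG
    polya_window: int = 500            # downstream of a constant gene

    # candidate detection
    identity_floor: float = 60.0       # percent identity to a reference
    min_candidate_span: int = 150      # nt of reference coverage required
    min_v_exon: int = 270              # shorter V matches are fragments
    leader_window: int = 400           # nt upstream searched for the leader

    def config_hash(self) -> str:
        text = repr(dataclasses.asdict(self))
        return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass
class RepertoireConfig:
    """Parameters of the expressed-repertoire analyzer."""

    isotype_identity_floor: float = 70.0   # percent; below -> unknown
    v_identity_floor: float = 60.0
    d_seed_length: int = 8                 # minimum contiguous exact D match
    d_ambiguity_margin: float = 5.0        # identity points
    csns_min_len: int = 13
    csns_max_len: int = 18
    csns_a_fraction: float = 1.0 / 3.0
    p_max_len: int = 3                     # palindromic nucleotides checked
    group1_max: int = 10                   # CDR3H length thresholds (aa)
    group3_min: int = 48

    def config_hash(self) -> str:
        text = repr(dataclasses.asdict(self))
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _coerce(current, raw: str):
    if isinstance(current, bool):
        return raw.strip().lower() in {"1", "true", "yes"}
    if isinstance(current, int):
        return int(raw)
    if isinstance(current, float):
        return float(raw)
    return raw.strip()


def load_config(path: str | Path, cls=ScanConfig):
    """Read a plain-text ``key = value`` file into a config dataclass.

    Lines starting with ``#`` and blank lines are ignored; unknown keys
    raise, so typos never silently fall back to defaults.
    """
    cfg = cls()
    names = {f.name for f in dataclasses.fields(cls)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = line.partition("=")
        key = key.strip()
        if key not in names:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        setattr(cfg, key, _coerce(getattr(cfg, key), raw))
    return cfg
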