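"""Small shared nucleotide-sequence helpers (DNA alphabet; T is read as U)."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Base pairs accepted in helices: Watson-Crick plus the G-U (G-T) wobble.
PAIRS = frozenset(
    {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
)

BASES = "ACGT"


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def can_pair(a: str, b: str) -> bool:
    """True when bases *a* and *b* can form a WC or wobble pair."""
    return (a.upper(), b.upper()) in PAIRS


def pairing_partners(base: str) -> str:
    """All bases that pair with *base* (WC + wobble)."""
    b = base.upper()
    return "".join(x for x in BASES if (b, x) in PAIRS)


def non_pairing(base: str) -> str:
    """All bases that cannot pair with *base*."""
    b = base.upper()
    return "".join(x for x in BASES if (b, x) not in PAIRS)


def encode(seq: str) -> np.ndarray:
    """Encode ACGT (case-insensitive) as uint8 codes 0..3; other bases get 4."""
    lut = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


#: 5x5 boolean table: PAIR_TABLE[code_a, code_b] is True for WC/wobble pairs.
PAIR_TABLE = np.zeros((5, 5), dtype=bool)
for _a, _b in PAIRS:
    PAIR_TABLE[BASES.index(_a), BASES.index(_b)] = True
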