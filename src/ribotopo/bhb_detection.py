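"""Detection of bulge-helix-bulge (BHB) processing motifs in pre-rRNA sequence.

The BHB motif is the substrate of the archaeal tRNA splicing endonuclease: a
short central stem (canonically 4 bp) flanked by two symmetric single-stranded
bulges (canonically 3 nt), embedded between two longer "flanking" helices.  The
endonuclease cleaves at symmetric positions within the two bulges, and a tRNA
ligase joins the resulting 5'-OH / 2',3'-cyclic-phosphate ends.  Applied to an
rRNA operon this releases and circularizes the rRNA insert while joining the
spacer flanks into a by-product molecule.

Coordinate conventions
----------------------
All public coordinates are 1-based inclusive.  A motif is anchored on the two
central stem strands: ``stem5_start`` (= i) is the first position of the stem
half on the upstream strand, ``stem3_start`` (= j) the first position of the
stem half on the downstream strand (j > i).  The geometry along the sequence is

    strand A (upstream, 5'->3'):   flank5 helix | bulge A | stem A | flank3 helix
    strand B (downstream, 5'->3'): flank3 helix | bulge B | stem B | flank5 helix

with antiparallel pairing ``s[i+t] ~ s[j+S-1-t]`` in the stem,
``(i-B-1-t, j+S+t)`` in the flank5 (outer) helix and ``(i+S+t, j-B-1-t)`` in
the flank3 (inner) helix, where S is the stem length and B the bulge length.
A cleavage "site" is reported as the position p such that scission occurs in
the bond between p and p+1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._seq import PAIR_TABLE, can_pair, encode

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BHBParams:
    """Geometry of a bulge-helix-bulge processing stalk.

    ``flank5_helix_len``/``flank3_helix_len`` are the lengths (bp) of the two
    helices flanking the central stem: flank5 is the outer helix formed by the
    distal spacer strands, flank3 the inner helix adjacent to the insert.
    ``cleavage_offset_5`` / ``cleavage_offset_3`` position the scission bonds
    relative to the mature ends of the insert: the 5'-side cut falls
    ``cleavage_offset_5`` nt upstream of the mature 5' end, the 3'-side cut
    ``cleavage_offset_3`` nt downstream of the mature 3' end (0/0 means the
    cuts present the mature ends directly).
    """

    bulge_len: int = 3
    stem_len: int = 4
    flank5_helix_len: int = 21
    flank3_helix_len: int = 14
    cleavage_offset_5: int = 0
    cleavage_offset_3: int = 0

    def __post_init__(self) -> None:
        if self.bulge_len < 1 or self.stem_len < 1:
            raise ValueError("bulge_len and stem_len must be >= 1")
        if self.flank5_helix_len < 0 or self.flank3_helix_len < 0:
            raise ValueError("flank helix lengths must be >= 0")
        if self.cleavage_offset_5 < 0 or self.cleavage_offset_3 < 0:
            raise ValueError("cleavage offsets must be >= 0")


#: Canonical LSU stalk: 3-4-3 BHB, 21/14 bp flanking helices, cuts at the
#: mature ends.
LSU_BHB_DEFAULTS = BHBParams()

#: Canonical SSU stalk: 3-4-3 BHB, 13/19 bp flanking helices, cuts 62 nt
#: upstream of the mature 5' end and 27 nt downstream of the mature 3' end.
SSU_BHB_DEFAULTS = BHBParams(
    flank5_helix_len=13,
    flank3_helix_len=19,
    cleavage_offset_5=62,
    cleavage_offset_3=27,
)


@dataclass
class BHBMotif:
    """A detected (or planted) bulge-helix-bulge motif, 1-based coordinates."""

    stem5_start: int
    stem3_start: int
    stem_len: int
    bulge_len: int
    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    stem_pairs: list[tuple[int, int]]
    bulges: tuple[tuple[int, int], tuple[int, int]]
    flank_helices: tuple[int, int]  # (flank5_len, flank3_len) in bp
    predicted_cleavages: tuple[int, int]  # bond 5' positions (p, p+1 cut)
    score: int

    @property
    def footprint(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.left_arm, self.right_arm)


@dataclass
class LigationProduct:
    """One product of BHB cleavage-plus-ligation, in precursor coordinates."""

    name: str
    topology: str  # "circular" | "linear"
    intervals: list[tuple[int, int]]
    junction: Optional[tuple[int, int]] = None  # (donor, acceptor)


def _measure_flanks(
    s: str, i: int, j: int, stem_len: int, bulge_len: int, max_extend: Optional[int]
) -> tuple[int, int]:
    """Count consecutive WC/wobble pairs of the two flanking helices.

    i, j are 1-based stem starts; returns (flank5_len, flank3_len).
    """
    L = len(s)
    S, B = stem_len, bulge_len
    # outer (flank5) helix: pairs (i-B-1-t, j+S+t)
    f5 = 0
    while True:
        a, b = i - B - 1 - f5, j + S + f5
        if a < 1 or b > L or (max_extend is not None and f5 >= max_extend):
            break
        if not can_pair(s[a - 1], s[b - 1]):
            break
        f5 += 1
    # inner (flank3) helix: pairs (i+S+t, j-B-1-t); arms must not overlap
    u_cap = (j - i - S - B) // 2
    f3 = 0
    while f3 < u_cap:
        a, b = i + S + f3, j - B - 1 - f3
        if max_extend is not None and f3 >= max_extend:
            break
        if not can_pair(s[a - 1], s[b - 1]):
            break
        f3 += 1
    return f5, f3


def _make_motif(
    s: str,
    i: int,
    j: int,
    params: BHBParams,
    f5: int,
    f3: int,
    cleavage_k: int = 2,
) -> BHBMotif:
    S, B = params.stem_len, params.bulge_len
    stem_pairs = [(i + t, j + S - 1 - t) for t in range(S)]
    bulges = ((i - B, i - 1), (j - B, j - 1))
    p5 = i - B + cleavage_k - 1
    p3 = j - B + cleavage_k - 1
    return BHBMotif(
        stem5_start=i,
        stem3_start=j,
        stem_len=S,
        bulge_len=B,
        left_arm=(i - B - f5, i + S + f3 - 1),
        right_arm=(j - B - f3, j + S + f5 - 1),
        stem_pairs=stem_pairs,
        bulges=bulges,
        flank_helices=(f5, f3),
        predicted_cleavages=(p5, p3),
        score=S + f5 + f3,
    )


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def find_bhb_motifs(
    sequence: str,
    params: Optional[BHBParams] = None,
    search_window: Optional[int] = None,
    region: Optional[tuple[int, int]] = None,
    min_flank: int = 8,
    min_score: Optional[int] = None,
    strict: bool = True,
) -> list[BHBMotif]:
    """Enumerate BHB motifs by complementarity (WC + G-U wobble; no energies).

    Exhaustively tests ordered stem-anchor pairs (i, j): the central stem must
    pair antiparallel over ``params.stem_len`` positions, the two
    ``params.bulge_len``-nt bulges must be present (and, with ``strict``, not
    extendable into the stem), and both flanking helices must reach at least
    ``min_flank`` bp.  Overlapping hits are resolved greedily by score (stem
    plus flank pairs), ties by smallest i.

    ``region`` restricts both arms to a 1-based inclusive interval;
    ``search_window`` caps the distance ``j - i`` between the stem anchors.
    """
    params = params or BHBParams()
    S, B = params.stem_len, params.bulge_len
    L = len(sequence)
    if L < 2 * (S + B) + 2 * min_flank:
        return []

    offset = 0
    s = sequence
    if region is not None:
        lo, hi = region
        if lo < 1 or hi > L:
            log.warning(
                "search region (%d, %d) clamped to sequence bounds (1, %d)", lo, hi, L
            )
            lo, hi = max(1, lo), min(L, hi)
        s = sequence[lo - 1 : hi]
        offset = lo - 1
    n = len(s)
    if n < S:
        return []
    if search_window is not None and search_window > n:
        log.warning("search_window %d larger than sequence; clamped", search_window)
        search_window = n

    codes = encode(s)
    P = PAIR_TABLE[codes[:, None], codes[None, :]]
    M = n - S + 1
    stem_ok = np.ones((M, M), dtype=bool)
    for t in range(S):
        stem_ok &= P[t : t + M, S - 1 - t : S - 1 - t + M]
    # ordered anchors with room for the bulges and both flank helices
    i0, j0 = np.nonzero(stem_ok)
    sep = j0 - i0
    keep = sep > S + B + 2 * min_flank - 1
    if search_window is not None:
        keep &= sep <= search_window
    i0, j0 = i0[keep], j0[keep]

    candidates: list[BHBMotif] = []
    for a, b in zip(i0.tolist(), j0.tolist()):
        i = a + 1 + offset  # 1-based stem5 start in full-sequence coordinates
        j = b + 1 + offset
        if i - B - min_flank < 1 or j + S + min_flank - 1 > L:
            continue
        if strict:
            # bulges must not be consumed by stem extension
            if can_pair(sequence[i - 2], sequence[j + S - 1]):
                continue
            if can_pair(sequence[i + S - 1], sequence[j - 2]):
                continue
        f5, f3 = _measure_flanks(sequence, i, j, S, B, None)
        if f5 < min_flank or f3 < min_flank:
            continue
        motif = _make_motif(sequence, i, j, params, f5, f3)
        if min_score is not None and motif.score < min_score:
            continue
        candidates.append(motif)

    candidates.sort(key=lambda m: (-m.score, m.stem5_start, m.stem3_start))
    accepted: list[BHBMotif] = []
    for m in candidates:
        clash = any(
            _overlaps(fa, fb)
            for fa in m.footprint
            for acc in accepted
            for fb in acc.footprint
        )
        if not clash:
            accepted.append(m)
    accepted.sort(key=lambda m: m.stem5_start)
    return accepted


def annotate_flank_helices(
    sequence: str, motif: BHBMotif, max_extend: Optional[int] = None
) -> tuple[int, int]:
    """Measure the two helices flanking *motif* by outward base-pair extension.

    Extends pairing outward from the bulges, counting consecutive WC/wobble
    pairs, stopping at the first non-pair, at ``max_extend``, or (for the
    inner helix) where the two arms would collide.  Returns
    ``(flank5_len, flank3_len)`` in bp.
    """
    return _measure_flanks(
        sequence,
        motif.stem5_start,
        motif.stem3_start,
        motif.stem_len,
        motif.bulge_len,
        max_extend,
    )


def predict_cleavage_sites(
    motif: BHBMotif, rule: str = "symmetric_after_k", k: int = 2
) -> tuple[int, int]:
    """Predict the two scission bonds of endonuclease cleavage.

    With the default rule the cut falls after the k-th bulge nucleotide,
    counted 5'->3' on each strand, symmetrically in both bulges.  Returns the
    1-based positions (p5, p3) such that cleavage severs the bonds
    (p5, p5+1) and (p3, p3+1).
    """
    if rule != "symmetric_after_k":
        raise ValueError(f"unknown cleavage rule: {rule!r}")
    if k >= motif.bulge_len + 1:
        raise ValueError(
            f"cleavage index k={k} outside bulge of length {motif.bulge_len}"
        )
    (a1, _), (b1, _) = motif.bulges
    return (a1 + k - 1, b1 + k - 1)


def predict_ligation_products(
    motif: BHBMotif,
    seq_len: int,
    topology_of_input: str = "linear",
    region: Optional[tuple[int, int]] = None,
) -> list[LigationProduct]:
    """Enumerate the ligation products of BHB processing of a precursor.

    Cleavage at the two predicted bonds releases the insert, whose cut ends
    are joined into a circle (junction donor = 3'-side cut position, acceptor
    = first inserted position), while the two flank pieces are joined into a
    single by-product molecule.  ``region`` bounds the precursor (defaults to
    the whole sequence); a motif with no residues outside the cuts yields a
    single circular product.
    """
    p5, p3 = motif.predicted_cleavages
    lo, hi = region if region is not None else (1, seq_len)
    products = [
        LigationProduct(
            name="circularized_insert",
            topology="circular",
            intervals=[(p5 + 1, p3)],
            junction=(p3, p5 + 1),
        )
    ]
    up = (lo, p5) if p5 >= lo else None
    down = (p3 + 1, hi) if p3 + 1 <= hi else None
    if topology_of_input == "circular":
        # on a circular precursor the two flanks are one contiguous piece
        if up or down:
            products.append(
                LigationProduct(
                    name="joined_flanks",
                    topology="circular",
                    intervals=[x for x in (down, up) if x],
                    junction=(p5, p3 + 1),
                )
            )
        return products
    if up and down:
        products.append(
            LigationProduct(
                name="joined_flanks",
                topology="linear",
                intervals=[up, down],
                junction=(p5, p3 + 1),
            )
        )
    elif up or down:
        products.append(
            LigationProduct(
                name="residual_flank",
                topology="linear",
                intervals=[up or down],
            )
        )
    return products


def count_compensatory_changes(
    alignment: Sequence[str], motif: BHBMotif
) -> dict[tuple[int, int], int]:
    """Count compensatory (pairing-preserving) double substitutions per pair.

    ``alignment`` is a list of equal-length pre-aligned sequences (the first
    is the reference carrying *motif*).  For every stem and flank pair of the
    motif, counts the aligned sequences that differ from the reference at
    either position while still forming a WC/wobble pair -- covariation
    support for the helix.  Columns with gaps are skipped.
    """
    ref = alignment[0]
    f5, f3 = motif.flank_helices
    i, j = motif.stem5_start, motif.stem3_start
    S, B = motif.stem_len, motif.bulge_len
    pairs = list(motif.stem_pairs)
    pairs += [(i - B - 1 - t, j + S + t) for t in range(f5)]
    pairs += [(i + S + t, j - B - 1 - t) for t in range(f3)]
    counts: dict[tuple[int, int], int] = {}
    for a, b in pairs:
        n = 0
        ra, rb = ref[a - 1], ref[b - 1]
        for seq in alignment[1:]:
            xa, xb = seq[a - 1], seq[b - 1]
            if "-" in (xa, xb):
                continue
            if (xa != ra or xb != rb) and can_pair(xa, xb):
                n += 1
        counts[(a, b)] = n
    return counts
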