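"""Calling native molecule ends, excised segments and hidden breaks.

A native 5' end of an RNA species leaves two coupled signatures in a
read-end profile from a size-selected fragment library: a pile-up of 5'
read-ends at the terminal nucleotide, and a depletion of 3' read-ends over
the following ``size_min - 1`` positions, because a fragment carrying the
native end must be at least ``size_min`` nt long to survive gel selection
and therefore first deposits a 3' read-end at offset ``size_min``.  3' ends
mirror this.  An excised internal segment shows as an interval of near-zero
coverage bounded by a 3'-end call on its left and a 5'-end call on its
right; a hidden break shows the same bounding calls with no coverage gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .readend_profiling import ReadEndProfile

log = logging.getLogger(__name__)


@dataclass
class EndCall:
    position: int  # 1-based
    kind: str  # five_prime | three_prime
    support: int  # read-end count at the position
    depletion_width: int  # observed run of zero complementary ends
    score: float  # robust enrichment z-score
    chemistry: str = "unknown"  # P5 | OH5 | unknown (5' ends only)

    def __post_init__(self) -> None:
        if self.support <= 0:
            raise ValueError("end call must have positive support")
        if self.depletion_width < 0:
            raise ValueError("depletion width must be >= 0")


@dataclass
class ExcisionCall:
    interval: tuple[int, int]  # 1-based inclusive
    coverage_ratio: float  # mean interior / mean flanking coverage
    left_end: Optional[EndCall] = None  # three_prime at interval[0]-1
    right_end: Optional[EndCall] = None  # five_prime at interval[1]+1

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0] + 1


def _robust_z(x: float, window: np.ndarray) -> float:
    if window.size == 0:
        return 0.0
    med = float(np.median(window))
    mad = float(np.median(np.abs(window - med)))
    scale = max(1.4826 * mad, np.sqrt(max(med, 0.0)), 1.0)
    return (x - med) / scale


def _call_five_prime(
    c5: np.ndarray,
    c3: np.ndarray,
    size_min: int,
    min_support: int,
    z_threshold: float,
    alpha: float,
    clipfrac5: Optional[np.ndarray] = None,
    max_clipfrac: float = 0.9,
) -> list[EndCall]:
    L = len(c5)
    calls: list[EndCall] = []
    w = 2 * size_min
    for p0 in range(L):
        x = int(c5[p0])
        if x < min_support:
            continue
        # starts that exist only after soft-clipping mean the molecule
        # continues upstream (junction seam or annotation overhang), not a
        # native end; a genuine 5'-P end is only partially chimerized
        if clipfrac5 is not None and clipfrac5[p0] > max_clipfrac:
            continue
        left = c5[p0 - 1] if p0 > 0 else -1
        right = c5[p0 + 1] if p0 < L - 1 else -1
        # local maximum; among equal adjacent counts keep the 5'-most
        if not (x > left and x >= right):
            continue
        flank = np.concatenate(
            (c5[max(0, p0 - w) : p0], c5[p0 + 1 : p0 + 1 + w])
        )
        z = _robust_z(x, flank)
        if z < z_threshold:
            continue
        # depletion of 3' read-ends over [p, p + size_min - 2]: a retained
        # fragment starting at the native end first ends at offset size_min
        dep_lo, dep_hi = p0, min(L, p0 + size_min - 1)  # half-open
        observed = int(c3[dep_lo:dep_hi].sum())
        bg = np.concatenate(
            (c3[max(0, p0 - w) : p0], c3[p0 + size_min - 1 : p0 + size_min - 1 + w])
        )
        rate = float(np.median(bg)) if bg.size else 0.0
        mu = rate * (dep_hi - dep_lo)
        if mu <= 0:
            if observed > 0:
                continue
        else:
            bound = float(sps.poisson.ppf(alpha, mu))
            if observed > bound:
                continue
        run = 0
        while p0 + run < L and c3[p0 + run] == 0:
            run += 1
        calls.append(
            EndCall(
                position=p0 + 1,
                kind="five_prime",
                support=x,
                depletion_width=run,
                score=float(z),
            )
        )
    return calls


def call_ends(
    profile: ReadEndProfile,
    size_min: int = 20,
    min_support: int = 20,
    z_threshold: float = 5.0,
    alpha: float = 0.01,
    max_clipfrac: float = 0.9,
) -> list[EndCall]:
    """Call native 5' and 3' ends from a read-end profile.

    A five_prime call at p requires: count5[p] >= ``min_support``; count5[p]
    a local maximum with robust z >= ``z_threshold`` against the flanking
    2 x ``size_min`` windows; and 3' read-ends depleted over
    [p, p + size_min - 2] below the Poisson ``alpha`` bound implied by the
    flanking median rate.  Candidate 5' positions where more than
    ``max_clipfrac`` of the starting alignments are soft-clipped are
    rejected: a start that only exists after clipping means the molecule
    continues upstream.  three_prime calls are the exact mirror (computed on
    the reversed profile, which makes the reversal symmetry structural).
    Calls are returned sorted by decreasing score.
    """
    if profile.length < 2 * size_min:
        raise ValueError("profile shorter than two size-selection windows")
    if profile.n_alignments == 0 or profile.coverage.max() == 0:
        raise ValueError("profile has no depth")
    calls = _call_five_prime(
        profile.count5,
        profile.count3,
        size_min,
        min_support,
        z_threshold,
        alpha,
        clipfrac5=profile.clipfrac5,
        max_clipfrac=max_clipfrac,
    )
    mirrored = _call_five_prime(
        profile.count3[::-1],
        profile.count5[::-1],
        size_min,
        min_support,
        z_threshold,
        alpha,
    )
    for c in mirrored:
        calls.append(
            EndCall(
                position=profile.length - c.position + 1,
                kind="three_prime",
                support=c.support,
                depletion_width=c.depletion_width,
                score=c.score,
            )
        )
    calls.sort(key=lambda c: (-c.score, c.position))
    return calls


def detect_excision(
    profile: ReadEndProfile,
    max_ratio: float = 0.05,
    min_len: int = 10,
    flank: int = 100,
    end_calls: Optional[Sequence[EndCall]] = None,
    snap_slack: int = 5,
) -> list[ExcisionCall]:
    """Detect excised internal segments as maximal low-coverage intervals.

    A candidate interval has per-position coverage <= ``max_ratio`` times the
    median coverage of its ``flank``-nt flanking windows and length >=
    ``min_len``.  Intervals touching the reference boundaries are not
    reported (they reflect annotation overhang, not excision).  Each call is
    annotated with bounding end calls (three_prime at left-1, five_prime at
    right+1) when supplied.

    Boundary refinement: residual molecules of the excised segment deposit
    edge fragments (every surviving copy contributes a terminal fragment that
    covers its outermost nucleotides), so the first/last excised positions
    can sit just above the per-position threshold.  When a bounding end call
    lies within ``snap_slack`` nt of a run edge, the interval is snapped to
    it: the called cleavage sites define the excised segment more precisely
    than per-position coverage does.
    """
    cov = profile.coverage.astype(float)
    L = profile.length
    covered = cov[cov > 0]
    if covered.size == 0:
        return []
    global_med = float(np.median(covered))
    low = cov <= max_ratio * global_med

    calls: list[ExcisionCall] = []
    p = 0
    while p < L:
        if not low[p]:
            p += 1
            continue
        q = p
        while q + 1 < L and low[q + 1]:
            q += 1
        # refine against the local flanking median
        lo_fl = cov[max(0, p - flank) : p]
        hi_fl = cov[q + 1 : q + 1 + flank]
        flank_all = np.concatenate((lo_fl, hi_fl))
        if flank_all.size:
            local_med = float(np.median(flank_all))
            thresh = max_ratio * local_med
            while p <= q and cov[p] > thresh:
                p += 1
            while q >= p and cov[q] > thresh:
                q -= 1
            if end_calls and q >= p:
                for ec in end_calls:
                    # snap left edge out to a bounding three_prime call
                    if ec.kind == "three_prime" and 0 < p - ec.position <= snap_slack:
                        p = ec.position  # 0-based run start = call pos (1-based) + 1
                    # snap right edge out to a bounding five_prime call
                    if (
                        ec.kind == "five_prime"
                        and 0 < ec.position - 1 - (q + 1) <= snap_slack
                    ):
                        q = ec.position - 2  # 0-based run end: call pos - 1, 1-based
        if q >= p and (q - p + 1) >= min_len and p > 0 and q < L - 1:
            flank_mean = float(np.mean(flank_all)) if flank_all.size else 0.0
            interior = float(np.mean(cov[p : q + 1]))
            ratio = interior / flank_mean if flank_mean > 0 else 0.0
            call = ExcisionCall(interval=(p + 1, q + 1), coverage_ratio=ratio)
            if end_calls:
                for ec in end_calls:
                    if ec.kind == "three_prime" and ec.position == p:
                        call.left_end = ec
                    if ec.kind == "five_prime" and ec.position == q + 2:
                        call.right_end = ec
            calls.append(call)
        p = q + 1
    return calls


def detect_hidden_breaks(
    end_calls: Sequence[EndCall], max_gap: int = 50
) -> list[tuple[EndCall, EndCall]]:
    """Pair adjacent (three_prime, five_prime) calls as candidate breaks.

    A three_prime call at q pairs with a five_prime call at p when
    0 <= p - q - 1 <= ``max_gap``; the molecule's own termini fail this
    adjacency (their gap is negative), so a linear molecule yields no pair.
    Whether a pair is a true hidden break or flanks an excised segment is
    decided downstream by whether coverage drops in the gap.
    """
    threes = [c for c in end_calls if c.kind == "three_prime"]
    fives = [c for c in end_calls if c.kind == "five_prime"]
    pairs = []
    for t in threes:
        for f in fives:
            gap = f.position - t.position - 1
            if 0 <= gap <= max_gap:
                pairs.append((t, f))
    pairs.sort(key=lambda tf: tf[0].position)
    return pairs


def write_end_calls_bed(
    calls: Sequence[EndCall], path, reference_id: str = "ref"
) -> None:
    """BED6: name = kind/chemistry, score = enrichment z (capped at 1000)."""
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: c.position):
            name = f"{c.kind}/{c.chemistry}"
            score = min(1000, int(round(c.score)))
            fh.write(
                f"{reference_id}\t{c.position - 1}\t{c.position}\t{name}\t{score}\t+\n"
            )


def write_excisions_bed(
    calls: Sequence[ExcisionCall], path, reference_id: str = "ref"
) -> None:
    with open(path, "w") as fh:
        for c in calls:
            a, b = c.interval
            fh.write(
                f"{reference_id}\t{a - 1}\t{b}\texcision/ratio={c.coverage_ratio:.4f}"
                f"\t0\t+\n"
            )
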