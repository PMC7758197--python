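"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive algorithms (full scans, quadruple loops) and
share no code path with the production implementations they verify.
"""

from __future__ import annotations

from ribotopo._seq import can_pair


def leftmost_exact_match(read: str, reference: str):
    """1-based leftmost position where *read* occurs verbatim, else None."""
    best = None
    for p in range(len(reference) - len(read) + 1):
        if reference[p : p + len(read)] == read:
            best = p + 1
            break
    return best


def enumerate_fragments_from_end(position: int, size_min: int, size_max: int):
    """All (start, end) fragments anchored at a native 5' end that survive
    size selection; exhaustive enumeration."""
    return [
        (position, position + ln - 1) for ln in range(size_min, size_max + 1)
    ]


def bhb_quadruple_loop(seq: str, stem_len: int, bulge_len: int, min_flank: int):
    """Naive exhaustive BHB search: quadruple-nested scanning.

    Returns the same (stem5_start, stem3_start, flank5, flank3, score)
    tuples as the production detector, after identical greedy overlap
    resolution, for strict 3-4-3-style geometry.
    """
    S, B = stem_len, bulge_len
    L = len(seq)
    cands = []
    for i in range(1, L + 1):
        if i - B - min_flank < 1:
            continue
        for j in range(i + S + B + 2 * min_flank, L + 1):
            if j + S + min_flank - 1 > L:
                break
            # central stem, antiparallel
            stem_ok = True
            for t in range(S):
                if not can_pair(seq[i + t - 1], seq[j + S - 1 - t - 1]):
                    stem_ok = False
                    break
            if not stem_ok:
                continue
            # strict: bulges may not be consumed by stem extension
            if can_pair(seq[i - 2], seq[j + S - 1]):
                continue
            if can_pair(seq[i + S - 1], seq[j - 2]):
                continue
            # outer (flank5) helix
            f5 = 0
            while True:
                a, b = i - B - 1 - f5, j + S + f5
                if a < 1 or b > L or not can_pair(seq[a - 1], seq[b - 1]):
                    break
                f5 += 1
            # inner (flank3) helix, arms must not collide
            cap = (j - i - S - B) // 2
            f3 = 0
            while f3 < cap:
                a, b = i + S + f3, j - B - 1 - f3
                if not can_pair(seq[a - 1], seq[b - 1]):
                    break
                f3 += 1
            if f5 < min_flank or f3 < min_flank:
                continue
            cands.append((i, j, f5, f3, S + f5 + f3))
    # identical greedy overlap resolution: best score, then smallest anchors
    cands.sort(key=lambda c: (-c[4], c[0], c[1]))
    accepted = []

    def arms(c):
        i, j, f5, f3, _ = c
        return ((i - B - f5, i + S + f3 - 1), (j - B - f3, j + S + f5 - 1))

    def overlaps(x, y):
        return x[0] <= y[1] and y[0] <= x[1]

    for c in cands:
        if not any(
            overlaps(a, b) for a in arms(c) for acc in accepted for b in arms(acc)
        ):
            accepted.append(c)
    accepted.sort(key=lambda c: c[0])
    return accepted
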