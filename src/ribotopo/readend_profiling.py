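"""Read mapping and per-position read-end profiling.

The central data structure is the :class:`ReadEndProfile`: per reference
position, the number of alignments starting there (5' read-ends), ending
there (3' read-ends), the coverage, the mismatch fraction, and the fraction
of starting alignments that carry a 5' soft-clip.  End-capturing fragment
libraries make molecule architecture legible in this profile: native ends
pile up read-ends and deplete the complementary end type over the first
``size_min`` nucleotides (sub-minimum fragments are lost to gel selection),
2'-O-methylation depletes both end types at the protected bond, and
non-colinear junctions surface as 5'-clipped or unmapped reads.

The mapper is a seed-and-extend exact-substring aligner for short (20-80 nt)
stranded RNA-fragment reads: gap-free, forward strand only.  For every read
it reports the longest suffix that aligns within the mismatch budget, with
the unaligned prefix as a 5' soft-clip; a ligation chimera therefore aligns
at its genuine fragment's start with the random partner as clip.  Because a
suffix is anchored by an exact ``min_seed``-mer at its start, alignments
always begin on a run of matches, which keeps 5'-end counts sharp at native
ends (partner tails cannot smear alignment starts upstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

from .synthetic_data import ReadRecord

log = logging.getLogger(__name__)


@dataclass
class Alignment:
    """A gap-free forward-strand alignment block (1-based inclusive)."""

    read_id: str
    reference_id: str
    start: int
    end: int
    clip5_len: int
    mismatches: tuple[int, ...] = ()  # reference positions

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("alignment start must be <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ReadEndProfile:
    """Per-position read-end counts for one reference."""

    reference_id: str
    length: int
    count5: np.ndarray  # alignments starting at each position
    count3: np.ndarray  # alignments ending at each position
    coverage: np.ndarray
    snpfrac: np.ndarray  # fraction of covering reads mismatching there
    clipfrac5: np.ndarray  # fraction of starts carrying a 5' soft-clip
    circular: bool = False
    n_alignments: int = 0

    def reversed(self) -> "ReadEndProfile":
        """The profile of the reverse-oriented molecule: 5' and 3' read-end
        roles swap and positions mirror."""
        return ReadEndProfile(
            reference_id=self.reference_id + "_rev",
            length=self.length,
            count5=self.count3[::-1].copy(),
            count3=self.count5[::-1].copy(),
            coverage=self.coverage[::-1].copy(),
            snpfrac=self.snpfrac[::-1].copy(),
            clipfrac5=np.zeros(self.length),
            circular=self.circular,
            n_alignments=self.n_alignments,
        )


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------


class ReferenceIndex:
    """Exact k-mer index of a reference sequence."""

    def __init__(self, sequence: str, k: int = 15, reference_id: str = "ref"):
        self.sequence = sequence
        self.k = k
        self.reference_id = reference_id
        self.array = np.frombuffer(sequence.encode(), dtype=np.uint8)
        index: dict[str, list[int]] = {}
        for p in range(len(sequence) - k + 1):
            index.setdefault(sequence[p : p + k], []).append(p)
        self.index = index

    def lookup(self, kmer: str) -> list[int]:
        return self.index.get(kmer, [])


def _align_one(
    seq: str,
    idx: ReferenceIndex,
    max_mismatch_frac: float,
) -> Optional[tuple[int, int, tuple[int, ...]]]:
    """Best alignment of one read: (clip5, ref_start0, mismatch ref pos 1-based)."""
    n = len(seq)
    k = idx.k
    ref = idx.sequence
    arr = idx.array
    L = len(ref)
    for c in range(0, n - k + 1):
        hits = idx.lookup(seq[c : c + k])
        if not hits:
            continue
        suffix = seq[c:]
        m = len(suffix)
        budget = int(max_mismatch_frac * m)
        best: Optional[tuple[int, int, tuple[int, ...]]] = None
        sarr: Optional[np.ndarray] = None
        for p in hits:
            if p + m > L:
                continue  # no 3' clipping: suffix must fit the reference
            if ref[p : p + m] == suffix:
                cand = (0, p, ())
            else:
                if sarr is None:
                    sarr = np.frombuffer(suffix.encode(), dtype=np.uint8)
                mm = np.flatnonzero(arr[p : p + m] != sarr)
                if mm.size > budget:
                    continue
                cand = (int(mm.size), p, tuple((p + int(x) + 1) for x in mm))
            if best is None or cand[:2] < best[:2]:
                best = cand  # fewest mismatches, then leftmost position
        if best is not None:
            return c, best[1], best[2]
    return None


def align_reads(
    reads: Sequence[ReadRecord],
    reference: str,
    min_seed: int = 15,
    max_mismatch_frac: float = 0.1,
    reference_id: str = "ref",
    stats: Optional[dict] = None,
) -> list[Alignment]:
    """Map reads to *reference* (forward strand, gap-free).

    Reads shorter than ``min_seed`` and reads whose every suffix exceeds the
    mismatch budget are left unaligned (counted in ``stats['unaligned']``
    when a dict is supplied, and logged).
    """
    idx = ReferenceIndex(reference, k=min_seed, reference_id=reference_id)
    alignments: list[Alignment] = []
    unaligned = 0
    for read in reads:
        if len(read.sequence) < min_seed:
            unaligned += 1
            continue
        hit = _align_one(read.sequence, idx, max_mismatch_frac)
        if hit is None:
            unaligned += 1
            continue
        clip5, p0, mism = hit
        alen = len(read.sequence) - clip5
        alignments.append(
            Alignment(
                read_id=read.read_id,
                reference_id=reference_id,
                start=p0 + 1,
                end=p0 + alen,
                clip5_len=clip5,
                mismatches=mism,
            )
        )
    if stats is not None:
        stats["unaligned"] = unaligned
        stats["aligned"] = len(alignments)
    if unaligned:
        log.debug("%d/%d reads unaligned", unaligned, len(reads))
    return alignments


# ---------------------------------------------------------------------------
# SAM/BAM interchange
# ---------------------------------------------------------------------------


def _md_tag(ref: str, start0: int, read_part: str, mismatches: set[int]) -> str:
    md, run = [], 0
    for off in range(len(read_part)):
        pos1 = start0 + off + 1
        if pos1 in mismatches:
            md.append(str(run))
            md.append(ref[start0 + off])
            run = 0
        else:
            run += 1
    md.append(str(run))
    return "".join(md)


def write_alignments(
    alignments: Sequence[Alignment],
    reads: dict[str, str],
    reference: str,
    path,
    reference_id: str = "ref",
) -> None:
    """Write alignments as SAM (with NM/MD so mismatches round-trip)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": reference_id, "LN": len(reference)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            seq = reads[aln.read_id]
            a = pysam.AlignedSegment(out.header)
            a.query_name = aln.read_id
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = 0
            a.reference_start = aln.start - 1
            a.mapping_quality = 60
            cigar = []
            if aln.clip5_len:
                cigar.append((4, aln.clip5_len))
            cigar.append((0, aln.length))
            a.cigartuples = cigar
            a.set_tag("NM", len(aln.mismatches))
            a.set_tag(
                "MD",
                _md_tag(
                    reference,
                    aln.start - 1,
                    seq[aln.clip5_len :],
                    set(aln.mismatches),
                ),
            )
            out.write(a)


def read_alignments(path, reference: Optional[str] = None) -> list[Alignment]:
    """Ingest SAM/BAM into :class:`Alignment` records (lossless for gap-free
    forward-strand records).

    Mismatch positions come from the MD tag when present, otherwise they are
    reconstructed against *reference*.  Reverse-strand records are rejected
    with a warning counter (fragment libraries are stranded).
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    out: list[Alignment] = []
    n_reverse = 0
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.is_reverse:
                n_reverse += 1
                continue
            clip5 = 0
            ct = rec.cigartuples or []
            if ct and ct[0][0] in (4, 5):
                clip5 = ct[0][1]
            start = rec.reference_start + 1
            end = rec.reference_end  # pysam: 0-based exclusive == 1-based incl.
            mism: list[int] = []
            if rec.has_tag("MD"):
                for qpos, rpos, base in rec.get_aligned_pairs(
                    matches_only=True, with_seq=True
                ):
                    if base is not None and base.islower():
                        mism.append(rpos + 1)
            elif reference is not None and rec.query_sequence is not None:
                part = rec.query_sequence[clip5:]
                for off, b in enumerate(part):
                    if off + start - 1 < len(reference) and (
                        reference[start - 1 + off].upper() != b.upper()
                    ):
                        mism.append(start + off)
            out.append(
                Alignment(
                    read_id=rec.query_name,
                    reference_id=rec.reference_name or "ref",
                    start=start,
                    end=end,
                    clip5_len=clip5,
                    mismatches=tuple(mism),
                )
            )
    if n_reverse:
        log.warning("rejected %d reverse-strand records", n_reverse)
    return out


# ---------------------------------------------------------------------------
# profiling
# ---------------------------------------------------------------------------


def compute_profile(
    alignments: Sequence[Alignment],
    reference: str,
    circular: bool = False,
    reference_id: str = "ref",
) -> ReadEndProfile:
    """Tally per-position read-end counts, coverage and mismatch fractions.

    For a circular reference, alignment coordinates wrap modulo the length
    (an alignment may run past position L and continue at 1).
    """
    L = len(reference)
    c5 = np.zeros(L, dtype=np.int64)
    c3 = np.zeros(L, dtype=np.int64)
    cov = np.zeros(L, dtype=np.int64)
    snp = np.zeros(L, dtype=np.int64)
    clip = np.zeros(L, dtype=np.int64)
    for aln in alignments:
        s, e = aln.start, aln.end
        if not circular and (s < 1 or e > L):
            raise ValueError(
                f"alignment {aln.read_id} out of bounds for {reference_id}"
            )
        s0 = (s - 1) % L
        e0 = (e - 1) % L
        c5[s0] += 1
        c3[e0] += 1
        if aln.clip5_len:
            clip[s0] += 1
        if s0 <= e0:
            cov[s0 : e0 + 1] += 1
        else:  # wrapping block on a circular reference
            cov[s0:] += 1
            cov[: e0 + 1] += 1
        for m in aln.mismatches:
            snp[(m - 1) % L] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        snpfrac = np.where(cov > 0, snp / np.maximum(cov, 1), 0.0)
        clipfrac5 = np.where(c5 > 0, clip / np.maximum(c5, 1), 0.0)
    return ReadEndProfile(
        reference_id=reference_id,
        length=L,
        count5=c5,
        count3=c3,
        coverage=cov,
        snpfrac=snpfrac,
        clipfrac5=clipfrac5,
        circular=circular,
        n_alignments=len(alignments),
    )


def protection_score(
    profile: ReadEndProfile, i: int, w: int = 6
) -> Optional[float]:
    """Read-end depletion score at nucleotide *i* (1 = fully protected bond).

    Both read-end types reflect scission 3' of nucleotide i, so the end count
    at i is ``count5[i+1] + count3[i]``.  The score is one minus that count
    relative to its mean over a +/-w window (i excluded), floored at 0.
    Returns None where the local mean is zero (score undefined).
    """
    L = profile.length
    if not 2 <= i <= L - 1:
        raise ValueError("protection score defined for interior positions only")

    def end_count(x: int) -> int:
        return int(profile.count5[x]) + int(profile.count3[x - 1])

    neighbours = [
        x for x in range(max(1, i - w), min(L - 1, i + w) + 1) if x != i
    ]
    mean = float(np.mean([end_count(x) for x in neighbours]))
    if mean == 0:
        return None
    return max(0.0, 1.0 - end_count(i) / mean)


def profile_to_frame(profile: ReadEndProfile):
    """Consolidated per-position table (pandas DataFrame)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "position": np.arange(1, profile.length + 1),
            "count5": profile.count5,
            "count3": profile.count3,
            "coverage": profile.coverage,
            "snpfrac": profile.snpfrac,
            "clipfrac5": profile.clipfrac5,
        }
    )


def write_profile(profile: ReadEndProfile, out_dir, prefix: str = "profile") -> None:
    """Write the consolidated TSV plus bedGraph-style tracks."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = profile_to_frame(profile)
    frame.to_csv(out / f"{prefix}.tsv", sep="\t", index=False)
    for track in ("count5", "count3", "coverage", "snpfrac"):
        with open(out / f"{prefix}.{track}.bedgraph", "w") as fh:
            vals = frame[track].to_numpy()
            for pos0, v in enumerate(vals):
                if v:
                    fh.write(
                        f"{profile.reference_id}\t{pos0}\t{pos0 + 1}\t{v}\n"
                    )
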