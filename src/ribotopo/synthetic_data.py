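"""Synthetic archaeal pre-rRNA operons and fragment-library simulation.

This module builds pre-rRNA operons with a known processing architecture
(BHB processing stalks flanking the SSU and LSU, an excisable helix near the
LSU 3' end, ribose-methylation sites), applies processing scenarios to derive
mature species with full ground truth, and simulates the fragment libraries of
an alkaline-fragmentation / gel-size-selection sequencing protocol, including
the ligation chimeras that arise at processing-derived 5'-phosphate ends.

Chemistry model
---------------
Alkaline scission proceeds by transesterification and leaves a 5'-OH on the
downstream fragment and a 2',3'-cyclic phosphate on the upstream fragment.
Hydrolytic processing cleavages instead leave 5'-phosphate / 3'-OH ends.
During library cloning only 5'-P ends can be ligated to a co-purified
fragment, so chimeric reads are diagnostic of hydrolytic processing ends.

Coordinates are 1-based inclusive in every public record; internal slicing is
0-based half-open.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import BASES, complement, non_pairing
from .bhb_detection import (
    BHBMotif,
    BHBParams,
    LSU_BHB_DEFAULTS,
    SSU_BHB_DEFAULTS,
    find_bhb_motifs,
)

log = logging.getLogger(__name__)

SCENARIOS = (
    "unprocessed",
    "linear",
    "circular",
    "permuted_with_excision",
    "hidden_break",
)

SEGMENT_ROLES = ("ETS5", "SSU", "ITS1", "tRNA", "ITS2", "LSU", "ETS3")


class OperonSizeError(ValueError):
    """A segment is too short to host its planted helices/motif."""


class ScenarioConfigError(ValueError):
    """A processing scenario requires a motif absent from the spec."""


@dataclass(frozen=True)
class OperonSpec:
    """Declarative architecture of a synthetic pre-rRNA operon.

    ``segments`` is an ordered list of (name, role, length-in-nt) tuples that
    tile the operon contiguously.  ``h98_interval`` is given in conventional
    (1-based) LSU coordinates and must lie strictly inside the LSU segment.
    ``methyl_positions`` are 1-based operon coordinates of 2'-O-methylated
    nucleotides.
    """

    segments: tuple[tuple[str, str, int], ...]
    lsu_bhb: Optional[BHBParams] = LSU_BHB_DEFAULTS
    ssu_bhb: Optional[BHBParams] = SSU_BHB_DEFAULTS
    h98_interval: Optional[tuple[int, int]] = (2927, 2967)
    methyl_positions: frozenset[int] = frozenset()
    rng_seed: int = 0

    @property
    def length(self) -> int:
        return sum(s[2] for s in self.segments)

    def segment_intervals(self) -> dict[str, tuple[int, int]]:
        out, pos = {}, 1
        for name, _role, seglen in self.segments:
            out[name] = (pos, pos + seglen - 1)
            pos += seglen
        return out

    def role_interval(self, role: str) -> Optional[tuple[int, int]]:
        pos = 1
        for _name, r, seglen in self.segments:
            if r == role:
                return (pos, pos + seglen - 1)
            pos += seglen
        return None

    def validate(self) -> None:
        if not self.segments:
            raise ValueError("operon spec has no segments")
        for name, role, seglen in self.segments:
            if seglen < 1:
                raise OperonSizeError(f"segment {name!r} has non-positive length")
        if self.h98_interval is not None:
            lsu = self.role_interval("LSU")
            if lsu is None:
                raise ValueError("h98_interval given but no LSU segment present")
            h5, h3 = self.h98_interval
            lsu_len = lsu[1] - lsu[0] + 1
            if not (1 < h5 <= h3 < lsu_len):
                raise ValueError(
                    "h98_interval must lie strictly inside the LSU segment"
                )
        bad = [p for p in self.methyl_positions if not 1 <= p <= self.length]
        if bad:
            raise ValueError(f"methyl positions outside operon: {sorted(bad)}")


def default_operon_spec(rng_seed: int = 0) -> OperonSpec:
    """The default operon: conventional segment order, LSU of 3,096 nt with an
    excisable 41-nt helix at 2,927-2,967 (leaving a 129-nt 3' block), canonical
    3-4-3 BHB stalks with 21/14 bp (LSU) and 13/19 bp (SSU) flanking helices,
    and SSU cleavage offsets of 62/27 nt.

    Spacer/SSU lengths are scaled-down placeholders large enough to host the
    planted stalks; the LSU geometry is full-size so all conventional LSU
    coordinates are meaningful.
    """
    segments = (
        ("ETS5", "ETS5", 100),
        ("SSU", "SSU", 300),
        ("ITS1", "ITS1", 60),
        ("tRNA", "tRNA", 80),
        ("ITS2", "ITS2", 60),
        ("LSU", "LSU", 3096),
        ("ETS3", "ETS3", 50),
    )
    # a few 2'-O-methyl marks inside the LSU (operon coordinates); the LSU
    # starts at operon position 601
    methyls = frozenset({601 + 799, 601 + 1511, 601 + 2587})
    return OperonSpec(
        segments=segments, methyl_positions=methyls, rng_seed=rng_seed
    )


@dataclass
class OperonTruth:
    """Ground truth recorded while building an operon."""

    length: int
    segment_intervals: dict[str, tuple[int, int]]
    mature: dict[str, tuple[int, int]]  # role -> operon interval
    motifs: dict[str, BHBMotif]  # role -> planted motif
    h98_operon: Optional[tuple[int, int]]
    h98_conventional: Optional[tuple[int, int]]
    methyl_positions: frozenset[int]
    spec: OperonSpec


@dataclass
class TruthAnnotation:
    """Per-species ground truth emitted by :func:`apply_processing`."""

    species_id: str
    topology: str  # linear | circular | circularly_permuted
    reference_id: str  # which conventional reference the coords refer to
    conv_intervals: list[tuple[int, int]]  # blocks in conventional coords
    mature_intervals: list[tuple[int, int]]  # blocks in operon coords
    junctions: list[tuple[int, int]]  # (donor, acceptor), conventional coords
    excised_intervals: list[tuple[int, int]]  # conventional coords
    termini: dict[str, Optional[int]]  # kind -> conventional position
    end_chemistries: dict[str, Optional[str]]  # 5P|5OH|cyclicP|3OH|unknown3
    methyl_sites: tuple[int, ...]  # molecule (species) coordinates
    is_byproduct: bool = False

    def __post_init__(self) -> None:
        if self.topology == "circularly_permuted":
            assert len(self.junctions) == 1, "permuted species has one junction"
        for exc in self.excised_intervals:
            for blk in self.conv_intervals:
                if exc[0] <= blk[1] and blk[0] <= exc[1]:
                    raise ValueError("excised interval overlaps mature block")


@dataclass
class SpeciesRecord:
    species_id: str
    sequence: str
    circular: bool
    annotation: TruthAnnotation


@dataclass(frozen=True)
class LibraryConfig:
    """Parameters of the fragment-library simulation.

    ``cleavage_prob`` is the per-internucleotide-bond probability of alkaline
    scission; a bond 3' of a 2'-O-methylated nucleotide is cleaved with
    probability ``cleavage_prob * protection_factor`` (0 = full protection).
    Only fragments of ``size_min``..``size_max`` nt survive gel selection.
    ``chimera_prob`` is the probability that a retained fragment whose 5'
    terminus carries a 5'-phosphate is prepended with a random co-purified
    fragment during ligation.
    """

    cleavage_prob: float = 1.0 / 30.0
    protection_factor: float = 0.0
    size_min: int = 20
    size_max: int = 40
    n_molecules: int = 800  # ~200x mean depth over the default LSU
    chimera_prob: float = 0.3
    read_len: int = 80
    sequencing_error_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cleavage_prob <= 1.0:
            raise ValueError("cleavage_prob must be in [0, 1]")
        if not 0.0 <= self.protection_factor <= 1.0:
            raise ValueError("protection_factor must be in [0, 1]")
        if self.size_min > self.size_max:
            raise ValueError("size_min must be <= size_max")
        if not 0.0 <= self.chimera_prob <= 1.0:
            raise ValueError("chimera_prob must be in [0, 1]")


@dataclass
class Fragment:
    species_id: str
    start: int  # 1-based molecule coordinate
    end: int  # may exceed molecule length for a wrapping circular fragment
    sequence: str
    chem5: str
    chem3: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    species_id: str
    start: int  # genuine-part provenance, 1-based molecule coordinates
    end: int
    chimera_partner: Optional[tuple[str, tuple[int, int]]] = None


# ---------------------------------------------------------------------------
# operon construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _StalkPlan:
    """Planted coordinates of one BHB stalk (1-based operon positions)."""

    role: str
    i: int  # stem start, upstream strand
    j: int  # stem start, downstream strand
    params: BHBParams

    @property
    def features(self) -> dict[str, tuple[int, int]]:
        S, B = self.params.stem_len, self.params.bulge_len
        f5 = self.params.flank5_helix_len
        f3 = self.params.flank3_helix_len
        i, j = self.i, self.j
        return {
            "flank5_A": (i - B - f5, i - B - 1),
            "bulge_A": (i - B, i - 1),
            "stem_A": (i, i + S - 1),
            "flank3_A": (i + S, i + S + f3 - 1),
            "flank3_B": (j - B - f3, j - B - 1),
            "bulge_B": (j - B, j - 1),
            "stem_B": (j, j + S - 1),
            "flank5_B": (j + S, j + S + f5 - 1),
        }

    @property
    def extent(self) -> tuple[int, int]:
        feats = self.features.values()
        return (min(a for a, _ in feats), max(b for _, b in feats))


def _plan_stalk(role: str, mature: tuple[int, int], params: BHBParams) -> _StalkPlan:
    # with the symmetric_after_2 cleavage rule, anchoring the stems at
    # i = m5 - off5 + 1 and j = m3 + off3 + 2 places the scission bonds at
    # (m5-off5-1 | m5-off5) and (m3+off3 | m3+off3+1)
    m5, m3 = mature
    return _StalkPlan(
        role=role,
        i=m5 - params.cleavage_offset_5 + 1,
        j=m3 + params.cleavage_offset_3 + 2,
        params=params,
    )


def _check_stalk_fits(
    plan: _StalkPlan, spec: OperonSpec, mature: tuple[int, int]
) -> None:
    intervals = spec.segment_intervals()
    lo, hi = plan.extent
    # +/-1 margin for the helix-termination breaker bases
    if lo - 1 < 1 or hi + 1 > spec.length:
        raise OperonSizeError(
            f"{plan.role} processing stalk does not fit in the operon"
        )
    # locate the spacer segments immediately flanking the insert
    up_end, down_start = mature[0] - 1, mature[1] + 1
    for name, (a, b) in intervals.items():
        if b == up_end and lo - 1 < a:
            raise OperonSizeError(
                f"segment {name!r} too short to host the {plan.role} stalk helices"
            )
        if a == down_start and hi + 1 > b:
            raise OperonSizeError(
                f"segment {name!r} too short to host the {plan.role} stalk helices"
            )


def _plant_stalk(
    seq: list[str], plan: _StalkPlan, rng: np.random.Generator
) -> None:
    """Write one BHB stalk into *seq* (a mutable list of bases, 0-based)."""
    S, B = plan.params.stem_len, plan.params.bulge_len
    f5, f3 = plan.params.flank5_helix_len, plan.params.flank3_helix_len
    i, j = plan.i, plan.j
    at_mature_ends = (
        plan.params.cleavage_offset_5 == 0 and plan.params.cleavage_offset_3 == 0
    )

    def put(pos: int, base: str) -> None:
        seq[pos - 1] = base

    def get(pos: int) -> str:
        return seq[pos - 1]

    def rand_base(exclude: str = "") -> str:
        choices = [b for b in BASES if b not in exclude]
        return choices[rng.integers(len(choices))]

    # flank5 (outer) helix: pairs (i-B-1-t, j+S+t)
    for t in range(f5):
        a, b = i - B - 1 - t, j + S + t
        # when the cut sits at the mature 5' end we want the first mature
        # nucleotide (last bulge-A base) to be G; G fails to pair only with
        # A/G partners, so the innermost flank5 base on strand A must then be
        # T or C (its strand-B complement being A or G)
        if t == 0 and at_mature_ends:
            base = "TC"[rng.integers(2)]
        else:
            base = rand_base()
        put(a, base)
        put(b, complement(base))
    # central stem: pairs (i+t, j+S-1-t)
    for t in range(S):
        base = rand_base()
        put(i + t, base)
        put(j + S - 1 - t, complement(base))
    # flank3 (inner) helix: pairs (i+S+t, j-B-1-t)
    for t in range(f3):
        base = rand_base()
        put(i + S + t, base)
        put(j - B - 1 - t, complement(base))
    # bulges; keep them from extending the stem or the flank helices
    for t in range(B):
        put(i - B + t, rand_base())
        put(j - B + t, rand_base())
    if at_mature_ends:
        put(i - 1, "G")  # mature 5' nucleotide (e.g. G1 of the LSU)
        put(j - 2, "C")  # mature 3' nucleotide (e.g. C3096)
    else:
        allowed = non_pairing(get(j + S))
        put(i - 1, allowed[rng.integers(len(allowed))])
    allowed = non_pairing(get(i + S))
    put(j - 1, allowed[rng.integers(len(allowed))])
    # terminate the helices exactly at their design lengths
    a_out, b_out = i - B - f5 - 1, j + S + f5
    allowed = non_pairing(get(a_out))
    put(b_out, allowed[rng.integers(len(allowed))])
    a3_out, b3_out = i + S + f3, j - B - f3 - 1
    allowed = non_pairing(get(a3_out))
    put(b3_out, allowed[rng.integers(len(allowed))])


def _stalk_clean(
    sequence: str, plan: _StalkPlan, pad: int = 50
) -> Optional[BHBMotif]:
    """The planted motif, if it is the only one detected around *plan*."""
    lo, hi = plan.extent
    region = (max(1, lo - pad), min(len(sequence), hi + pad))
    hits = find_bhb_motifs(sequence, plan.params, region=region, min_flank=8)
    if len(hits) != 1:
        return None
    m = hits[0]
    ok = (
        m.stem5_start == plan.i
        and m.stem3_start == plan.j
        and m.flank_helices
        == (plan.params.flank5_helix_len, plan.params.flank3_helix_len)
    )
    return m if ok else None


def build_operon(
    spec: OperonSpec, max_attempts: int = 50
) -> tuple[str, OperonTruth]:
    """Build the operon sequence and its ground truth.

    Random fill is reproducible from ``spec.rng_seed``.  The fill is
    rejection-sampled: if the BHB detector, scanned over a planted stalk's
    neighbourhood, reports anything except the planted motif with its exact
    design geometry, the fill is redrawn (logged).
    """
    spec.validate()
    L = spec.length
    rng = np.random.default_rng(spec.rng_seed)

    plans: list[_StalkPlan] = []
    mature: dict[str, tuple[int, int]] = {}
    for role, params in (("SSU", spec.ssu_bhb), ("LSU", spec.lsu_bhb)):
        interval = spec.role_interval(role)
        if interval is not None:
            mature[role] = interval
        if params is not None and interval is not None:
            plan = _plan_stalk(role, interval, params)
            _check_stalk_fits(plan, spec, interval)
            plans.append(plan)
    if not plans and not mature:
        # degenerate spec: a bare segment with no processing architecture
        name, _role, _len = spec.segments[0]
    occupied: set[int] = set()
    for plan in plans:
        feats = set()
        for a, b in plan.features.values():
            feats.update(range(a, b + 1))
        if occupied & feats:
            raise OperonSizeError("planted stalks overlap; enlarge the segments")
        occupied |= feats

    motifs: dict[str, BHBMotif] = {}
    for attempt in range(max_attempts):
        seq = [BASES[k] for k in rng.integers(0, 4, size=L)]
        for plan in plans:
            _plant_stalk(seq, plan, rng)
        sequence = "".join(seq)
        detected = {p.role: _stalk_clean(sequence, p) for p in plans}
        if all(m is not None for m in detected.values()):
            motifs = {role: m for role, m in detected.items()}
            break
        log.warning(
            "rejection sampling: spurious motif near a planted stalk "
            "(attempt %d); redrawing fill",
            attempt + 1,
        )
    else:
        raise RuntimeError("could not build a clean operon fill")

    h98_operon = None
    if spec.h98_interval is not None and "LSU" in mature:
        m5 = mature["LSU"][0]
        h98_operon = (m5 + spec.h98_interval[0] - 1, m5 + spec.h98_interval[1] - 1)

    truth = OperonTruth(
        length=L,
        segment_intervals=spec.segment_intervals(),
        mature=mature,
        motifs=motifs,
        h98_operon=h98_operon,
        h98_conventional=spec.h98_interval,
        methyl_positions=spec.methyl_positions,
        spec=spec,
    )
    return sequence, truth


def conventional_reference(
    reference: str, truth: OperonTruth, role: str = "LSU"
) -> str:
    """The conventional (transcription-order) mature sequence of *role*."""
    m5, m3 = truth.mature[role]
    return reference[m5 - 1 : m3]


# ---------------------------------------------------------------------------
# processing scenarios
# ---------------------------------------------------------------------------


def _block_map(blocks: list[tuple[int, int]]):
    """Map conventional coordinate -> molecule coordinate for ordered blocks."""

    def convert(pos: int) -> Optional[int]:
        mol = 0
        for a, b in blocks:
            if a <= pos <= b:
                return mol + (pos - a) + 1
            mol += b - a + 1
        return None

    return convert


def _species_methyls(
    truth: OperonTruth, conv_blocks: list[tuple[int, int]], m5: int
) -> tuple[int, ...]:
    convert = _block_map(conv_blocks)
    out = []
    for p in sorted(truth.methyl_positions):
        conv = p - m5 + 1
        mol = convert(conv)
        if mol is not None:
            out.append(mol)
    return tuple(out)


def apply_processing(
    reference: str,
    truth: OperonTruth,
    scenario: str,
    break_position: Optional[int] = None,
) -> list[SpeciesRecord]:
    """Derive the molecular species of a processing *scenario* with truth.

    Scenarios (all operate on the LSU; coordinates in the annotations are
    conventional mature-LSU coordinates unless ``reference_id`` says operon):

    - ``unprocessed``: the primary transcript as one linear molecule.
    - ``linear``: conventionally processed linear LSU (BHB-cut ends:
      5'-OH / 2',3'-cyclic-P chemistry, no ligation).
    - ``circular``: covalently closed LSU circle (cut + ligated, helix
      retained), as in species where the circle is the mature form.
    - ``permuted_with_excision``: circularized LSU with the excisable helix
      (H98) removed by hydrolytic cuts, yielding the circularly permuted
      mature molecule (new 5'-P / 3'-OH termini) plus turnover by-products:
      the excised helix and the joined ITS2-3'ETS spacer molecule.
    - ``hidden_break``: one hydrolytic break inside an otherwise linear LSU,
      producing two fragments that would stay associated in the ribosome.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if "LSU" not in truth.mature:
        raise ScenarioConfigError("scenario requires an LSU segment")
    m5, m3 = truth.mature["LSU"]
    conv = reference[m5 - 1 : m3]
    L = len(conv)

    if scenario == "unprocessed":
        ann = TruthAnnotation(
            species_id="precursor",
            topology="linear",
            reference_id="operon",
            conv_intervals=[(1, truth.length)],
            mature_intervals=[(1, truth.length)],
            junctions=[],
            excised_intervals=[],
            termini={"five_prime": 1, "three_prime": truth.length},
            end_chemistries={"five_prime": "5P", "three_prime": "3OH"},
            methyl_sites=tuple(sorted(truth.methyl_positions)),
        )
        return [SpeciesRecord("precursor", reference, False, ann)]

    if scenario == "linear":
        blocks = [(1, L)]
        ann = TruthAnnotation(
            species_id="LSU_linear",
            topology="linear",
            reference_id="LSU",
            conv_intervals=blocks,
            mature_intervals=[(m5, m3)],
            junctions=[],
            excised_intervals=[],
            termini={"five_prime": 1, "three_prime": L},
            end_chemistries={"five_prime": "5OH", "three_prime": "cyclicP"},
            methyl_sites=_species_methyls(truth, blocks, m5),
        )
        return [SpeciesRecord("LSU_linear", conv, False, ann)]

    if scenario == "circular":
        if truth.spec.lsu_bhb is None:
            raise ScenarioConfigError(
                "circular scenario requires the LSU BHB motif"
            )
        blocks = [(1, L)]
        ann = TruthAnnotation(
            species_id="LSU_circle",
            topology="circular",
            reference_id="LSU",
            conv_intervals=blocks,
            mature_intervals=[(m5, m3)],
            junctions=[(L, 1)],
            excised_intervals=[],
            termini={"five_prime": None, "three_prime": None},
            end_chemistries={"five_prime": None, "three_prime": None},
            methyl_sites=_species_methyls(truth, blocks, m5),
        )
        return [SpeciesRecord("LSU_circle", conv, True, ann)]

    if scenario == "hidden_break":
        b = break_position if break_position is not None else L // 2
        if not 1 <= b < L:
            raise ValueError("break_position outside the LSU")
        species = []
        ann5 = TruthAnnotation(
            species_id="LSU_5p_fragment",
            topology="linear",
            reference_id="LSU",
            conv_intervals=[(1, b)],
            mature_intervals=[(m5, m5 + b - 1)],
            junctions=[],
            excised_intervals=[],
            termini={"five_prime": 1, "three_prime": b},
            end_chemistries={"five_prime": "5OH", "three_prime": "3OH"},
            methyl_sites=_species_methyls(truth, [(1, b)], m5),
        )
        species.append(SpeciesRecord("LSU_5p_fragment", conv[:b], False, ann5))
        ann3 = TruthAnnotation(
            species_id="LSU_3p_fragment",
            topology="linear",
            reference_id="LSU",
            conv_intervals=[(b + 1, L)],
            mature_intervals=[(m5 + b, m3)],
            junctions=[],
            excised_intervals=[],
            termini={"five_prime": b + 1, "three_prime": L},
            end_chemistries={"five_prime": "5P", "three_prime": "cyclicP"},
            methyl_sites=_species_methyls(truth, [(b + 1, L)], m5),
        )
        species.append(SpeciesRecord("LSU_3p_fragment", conv[b:], False, ann3))
        return species

    # permuted_with_excision
    if truth.spec.lsu_bhb is None or truth.h98_conventional is None:
        raise ScenarioConfigError(
            "permuted_with_excision requires the LSU BHB motif and an "
            "excisable-helix interval"
        )
    h5, h3 = truth.h98_conventional
    blocks = [(h3 + 1, L), (1, h5 - 1)]
    permuted_seq = conv[h3:] + conv[: h5 - 1]
    ann = TruthAnnotation(
        species_id="LSU_permuted",
        topology="circularly_permuted",
        reference_id="LSU",
        conv_intervals=blocks,
        mature_intervals=[(m5 + h3, m3), (m5, m5 + h5 - 2)],
        junctions=[(L, 1)],
        excised_intervals=[(h5, h3)],
        termini={"five_prime": h3 + 1, "three_prime": h5 - 1},
        end_chemistries={"five_prime": "5P", "three_prime": "3OH"},
        methyl_sites=_species_methyls(truth, blocks, m5),
    )
    species = [SpeciesRecord("LSU_permuted", permuted_seq, False, ann)]

    # by-product 1: the excised helix (turned over)
    h98_seq = conv[h5 - 1 : h3]
    ann_h98 = TruthAnnotation(
        species_id="H98_fragment",
        topology="linear",
        reference_id="LSU",
        conv_intervals=[(h5, h3)],
        mature_intervals=[(m5 + h5 - 1, m5 + h3 - 1)],
        junctions=[],
        excised_intervals=[],
        termini={"five_prime": h5, "three_prime": h3},
        end_chemistries={"five_prime": "5P", "three_prime": "unknown3"},
        methyl_sites=(),
        is_byproduct=True,
    )
    species.append(SpeciesRecord("H98_fragment", h98_seq, False, ann_h98))

    # by-product 2: the joined ITS2-3'ETS spacer molecule (turned over)
    segs = truth.segment_intervals
    its2 = next(
        ((a, b) for n, (a, b) in segs.items() if b == m5 - 1), None
    )
    ets3 = next(
        ((a, b) for n, (a, b) in segs.items() if a == m3 + 1), None
    )
    if its2 is not None and ets3 is not None:
        motif = truth.motifs.get("LSU")
        p5, p3 = motif.predicted_cleavages if motif else (m5 - 1, m3)
        spacer_seq = reference[its2[0] - 1 : p5] + reference[p3 : ets3[1]]
        ann_sp = TruthAnnotation(
            species_id="ITS2_ETS3_spacer",
            topology="linear",
            reference_id="operon",
            conv_intervals=[(its2[0], p5), (p3 + 1, ets3[1])],
            mature_intervals=[(its2[0], p5), (p3 + 1, ets3[1])],
            junctions=[(p5, p3 + 1)],
            excised_intervals=[],
            termini={"five_prime": its2[0], "three_prime": ets3[1]},
            end_chemistries={"five_prime": "5OH", "three_prime": "cyclicP"},
            methyl_sites=(),
            is_byproduct=True,
        )
        species.append(
            SpeciesRecord("ITS2_ETS3_spacer", spacer_seq, False, ann_sp)
        )
    return species


# ---------------------------------------------------------------------------
# fragmentation and library construction
# ---------------------------------------------------------------------------


def fragment_rna(
    sequence: str,
    methyl_positions: Sequence[int],
    config: LibraryConfig,
    *,
    circular: bool = False,
    chem5: str = "5OH",
    chem3: str = "cyclicP",
    species_id: str = "species",
    rng: Optional[np.random.Generator] = None,
) -> list[Fragment]:
    """Partially fragment ``config.n_molecules`` copies of one molecule.

    Each internucleotide bond is cleaved independently with probability
    ``cleavage_prob``, scaled by ``protection_factor`` when the nucleotide on
    the bond's 5' side is 2'-O-methylated.  Alkaline scission yields 5'-OH /
    2',3'-cyclic-P ends; pre-existing termini keep their ``chem5``/``chem3``.
    Only fragments within the size-selection window are returned.  A circular
    molecule is fragmented on the circle (no implicit ends); an uncut circle
    yields no fragment.
    """
    n = len(sequence)
    if n == 0:
        return []
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n_bonds = n if circular else n - 1
    p = np.full(n_bonds, config.cleavage_prob)
    for m in methyl_positions:
        # bond m sits 3' of nucleotide m (1-based); on a circle bond n is
        # 3' of the last nucleotide
        if 1 <= m <= n_bonds:
            p[m - 1] *= config.protection_factor
    doubled = sequence + sequence
    out: list[Fragment] = []
    smin, smax = config.size_min, config.size_max
    for _ in range(config.n_molecules):
        if n_bonds > 0:
            cuts = np.flatnonzero(rng.random(n_bonds) < p)
        else:
            cuts = np.empty(0, dtype=int)
        if circular:
            if cuts.size == 0:
                continue  # uncut circle: no linear fragment enters the library
            starts = (cuts + 1) % n + 1  # fragment starts after each cut bond
            lens = np.diff(np.append(cuts, cuts[0] + n))
            for s, ln in zip(starts.tolist(), lens.tolist()):
                if smin <= ln <= smax:
                    out.append(
                        Fragment(
                            species_id,
                            s,
                            s + ln - 1,
                            doubled[s - 1 : s - 1 + ln],
                            "5OH",
                            "cyclicP",
                        )
                    )
        else:
            bounds = np.concatenate(([0], cuts + 1, [n]))
            for k in range(len(bounds) - 1):
                a, b = int(bounds[k]), int(bounds[k + 1])
                ln = b - a
                if smin <= ln <= smax:
                    out.append(
                        Fragment(
                            species_id,
                            a + 1,
                            b,
                            sequence[a:b],
                            chem5 if a == 0 else "5OH",
                            chem3 if b == n else "cyclicP",
                        )
                    )
    return out


def fragment_species(
    record: SpeciesRecord,
    config: LibraryConfig,
    rng: Optional[np.random.Generator] = None,
    n_molecules: Optional[int] = None,
) -> list[Fragment]:
    """Fragment a species record, honouring its truth end chemistries."""
    chem = record.annotation.end_chemistries
    cfg = config
    if n_molecules is not None and n_molecules != config.n_molecules:
        cfg = LibraryConfig(**{**asdict(config), "n_molecules": n_molecules})
    return fragment_rna(
        record.sequence,
        record.annotation.methyl_sites,
        cfg,
        circular=record.circular,
        chem5=chem.get("five_prime") or "5OH",
        chem3=chem.get("three_prime") or "cyclicP",
        species_id=record.species_id,
        rng=rng,
    )


def build_library(
    fragments: Sequence[Fragment],
    config: LibraryConfig,
    rng: Optional[np.random.Generator] = None,
    id_prefix: str = "read",
) -> list[ReadRecord]:
    """Turn retained fragments into sequencing reads.

    Fragments with a 5'-phosphate terminus are, with ``chimera_prob``,
    prepended with a uniformly sampled retained fragment (the ligation-chimera
    cloning artifact); 5'-OH fragments are never chimerized.  Reads are the
    first ``read_len`` nt of each (possibly chimerized) insert.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if not fragments:
        log.warning("build_library called with an empty fragment list")
        return []
    reads: list[ReadRecord] = []
    n = len(fragments)
    for idx, frag in enumerate(fragments):
        partner = None
        insert = frag.sequence
        if frag.chem5 == "5P" and rng.random() < config.chimera_prob:
            p = fragments[int(rng.integers(n))]
            partner = (p.species_id, (p.start, p.end))
            insert = p.sequence + frag.sequence
        seq = insert[: config.read_len]
        if config.sequencing_error_rate > 0:
            arr = list(seq)
            errs = np.flatnonzero(
                rng.random(len(arr)) < config.sequencing_error_rate
            )
            for e in errs:
                alt = [b for b in BASES if b != arr[e]]
                arr[e] = alt[int(rng.integers(3))]
            seq = "".join(arr)
        reads.append(
            ReadRecord(
                read_id=f"{id_prefix}|{frag.species_id}|{idx}",
                sequence=seq,
                species_id=frag.species_id,
                start=frag.start,
                end=frag.end,
                chimera_partner=partner,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# scenario driver and file output
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    spec: OperonSpec
    scenario: str
    reference: str  # full operon
    truth: OperonTruth
    species: list[SpeciesRecord]
    reads: list[ReadRecord]

    @property
    def lsu_reference(self) -> str:
        return conventional_reference(self.reference, self.truth, "LSU")

    def species_by_id(self, species_id: str) -> SpeciesRecord:
        for rec in self.species:
            if rec.species_id == species_id:
                return rec
        raise KeyError(species_id)


def simulate_scenario(
    spec: Optional[OperonSpec] = None,
    scenario: str = "permuted_with_excision",
    config: Optional[LibraryConfig] = None,
    seed: Optional[int] = None,
    byproduct_fraction: float = 0.01,
    include_byproducts: bool = True,
) -> SimResult:
    """Build an operon, apply *scenario*, fragment and clone the library.

    Mature species are fragmented at ``config.n_molecules`` molecules each;
    turnover by-products at ``byproduct_fraction`` of that (they are present
    at trace levels in the cell).  ``seed`` overrides both the operon fill
    seed and the library seed for one-knob reproducibility.
    """
    if spec is None:
        spec = default_operon_spec(rng_seed=seed if seed is not None else 0)
    elif seed is not None:
        spec = OperonSpec(**{**asdict_spec(spec), "rng_seed": seed})
    config = config or LibraryConfig()
    rng = np.random.default_rng(
        config.rng_seed if seed is None else seed
    )
    reference, truth = build_operon(spec)
    species = apply_processing(reference, truth, scenario)
    fragments: list[Fragment] = []
    for rec in species:
        if rec.annotation.is_byproduct:
            if not include_byproducts:
                continue
            n_mol = max(1, int(round(byproduct_fraction * config.n_molecules)))
        else:
            n_mol = config.n_molecules
        fragments.extend(fragment_species(rec, config, rng=rng, n_molecules=n_mol))
    reads = build_library(fragments, config, rng=rng)
    return SimResult(spec, scenario, reference, truth, species, reads)


def asdict_spec(spec: OperonSpec) -> dict:
    return {
        "segments": spec.segments,
        "lsu_bhb": spec.lsu_bhb,
        "ssu_bhb": spec.ssu_bhb,
        "h98_interval": spec.h98_interval,
        "methyl_positions": spec.methyl_positions,
        "rng_seed": spec.rng_seed,
    }


def _open_text(path, mode="wt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_fasta(records: dict[str, str], path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with _open_text(path) as fh:
        SeqIO.write(recs, fh, "fasta")


def write_fastq(reads: Sequence[ReadRecord], path) -> None:
    """Write reads as FASTQ with constant quality ('I', phred 40)."""
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        recs.append(rec)
    with _open_text(path) as fh:
        SeqIO.write(recs, fh, "fastq")


def read_fastq(path) -> list[ReadRecord]:
    """Load external reads; provenance fields are filled with placeholders."""
    out = []
    with _open_text(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            out.append(ReadRecord(rec.id, str(rec.seq), "external", 0, 0))
    return out


def truth_to_json(sim: SimResult, path=None) -> str:
    """Serialize the per-species truth (deterministic key order)."""
    payload = {
        "scenario": sim.scenario,
        "operon_length": sim.truth.length,
        "mature": {k: list(v) for k, v in sorted(sim.truth.mature.items())},
        "h98_conventional": list(sim.truth.h98_conventional)
        if sim.truth.h98_conventional
        else None,
        "species": [
            {
                "id": rec.species_id,
                "topology": rec.annotation.topology,
                "reference": rec.annotation.reference_id,
                "length": len(rec.sequence),
                "circular": rec.circular,
                "conv_intervals": [list(b) for b in rec.annotation.conv_intervals],
                "junctions": [list(j) for j in rec.annotation.junctions],
                "excised": [list(e) for e in rec.annotation.excised_intervals],
                "termini": rec.annotation.termini,
                "end_chemistries": rec.annotation.end_chemistries,
                "is_byproduct": rec.annotation.is_byproduct,
            }
            for rec in sim.species
        ],
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        with _open_text(path) as fh:
            fh.write(text + "\n")
    return text
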