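"""Integration of end, excision and junction calls into a processing model.

The per-species verdict distinguishes four topologies of a mature rRNA
relative to its conventional (transcription-order) annotation:

- ``linear``: free termini at (or near) the annotation boundaries, no
  processing junction.
- ``circular``: a processing junction joining the 3' to the 5' coordinate
  with no free termini anywhere (the covalently closed circle is the mature
  form).
- ``circularly_permuted``: a processing junction plus two free termini
  *internal* to the annotation, with an excised segment between them -- the
  circle was re-opened at a different site than it was closed.
- ``fragmented``: adjacent three_prime/five_prime call pairs (hidden breaks)
  not explained by an excised low-coverage segment.

Verdict precedence is fragmented > circularly_permuted > circular > linear;
evidence conflicting with a verdict downgrades to the weaker verdict with a
warning.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .end_calling import (
    EndCall,
    ExcisionCall,
    call_ends,
    detect_excision,
    detect_hidden_breaks,
    write_end_calls_bed,
    write_excisions_bed,
)
from .junction_discovery import (
    JunctionCall,
    circularize_reference,
    dedupe_circular_alignments,
    find_junctions,
    infer_end_chemistry,
    write_junctions_bedpe,
    write_junctions_tsv,
)
from .readend_profiling import (
    Alignment,
    ReadEndProfile,
    align_reads,
    compute_profile,
    write_profile,
)
from .synthetic_data import (
    LibraryConfig,
    OperonSpec,
    SimResult,
    simulate_scenario,
)

log = logging.getLogger(__name__)

VERDICTS = (
    "linear",
    "circular",
    "circularly_permuted",
    "fragmented",
    "insufficient_data",
)


@dataclass
class ProcessingModel:
    """Per-species processing topology with its supporting evidence."""

    reference_id: str
    length: int
    verdict: str
    termini: list[dict] = field(default_factory=list)
    junctions: list[dict] = field(default_factory=list)
    excised: list[dict] = field(default_factory=list)
    segments: list[tuple[int, int]] = field(default_factory=list)
    byproducts: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segments"] = [list(s) for s in self.segments]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProcessingModel":
        d = dict(d)
        d["segments"] = [tuple(s) for s in d.get("segments", [])]
        return cls(**d)


def _near(a: int, b: int, tol: int) -> bool:
    return abs(a - b) <= tol


def assemble_model(
    end_calls: Sequence[EndCall],
    excisions: Sequence[ExcisionCall],
    junctions: Sequence[JunctionCall],
    motifs=None,
    annotation: Optional[dict] = None,
    boundary_tol: int = 3,
    junction_support_min: int = 2,
    break_max_gap: int = 50,
) -> ProcessingModel:
    """Apply the topology decision rules to one species' evidence.

    ``annotation`` must carry the conventional reference name and length,
    e.g. ``{"reference_id": "LSU", "length": 3096}``.  ``motifs`` (detected
    BHB motifs, optional) are recorded as supporting evidence only.
    """
    annotation = annotation or {}
    ref_id = annotation.get("reference_id", "ref")
    L = int(annotation.get("length", 0))
    warnings: list[str] = []

    fives = sorted(
        (c for c in end_calls if c.kind == "five_prime"), key=lambda c: -c.score
    )
    threes = sorted(
        (c for c in end_calls if c.kind == "three_prime"), key=lambda c: -c.score
    )
    proc_junctions = [
        j
        for j in junctions
        if j.verdict == "processing_junction" and j.support >= junction_support_min
    ]

    def excised_covers(gap: tuple[int, int]) -> bool:
        if gap[0] > gap[1]:
            return False  # empty gap: nothing for an excision to explain
        return any(
            e.interval[0] <= gap[0] and gap[1] <= e.interval[1] for e in excisions
        )

    break_pairs = [
        (t, f)
        for t, f in detect_hidden_breaks(end_calls, max_gap=break_max_gap)
        if not excised_covers((t.position + 1, f.position - 1))
    ]

    model = ProcessingModel(reference_id=ref_id, length=L, verdict="insufficient_data")
    model.termini = [
        {"position": c.position, "kind": c.kind, "chemistry": c.chemistry,
         "support": c.support}
        for c in sorted(end_calls, key=lambda c: c.position)
    ]
    model.junctions = [
        {"donor": j.donor, "acceptor": j.acceptor, "support": j.support,
         "partner_diversity": round(j.partner_diversity, 4), "verdict": j.verdict}
        for j in junctions
    ]
    model.excised = [
        {"interval": list(e.interval), "coverage_ratio": round(e.coverage_ratio, 4),
         "fate": "turned_over"}
        for e in excisions
    ]

    if not end_calls and not proc_junctions and not excisions:
        model.warnings = warnings
        return model  # insufficient_data

    if break_pairs:
        model.verdict = "fragmented"
        if L:
            bounds = sorted({1, L} | {t.position for t, _ in break_pairs}
                            | {f.position for _, f in break_pairs})
            segs, lo = [], 1
            for t, f in sorted(break_pairs, key=lambda p: p[0].position):
                segs.append((lo, t.position))
                lo = f.position
            segs.append((lo, L))
            model.segments = segs
        if proc_junctions:
            warnings.append(
                "processing junction present alongside hidden breaks; "
                "verdict kept at fragmented"
            )
        model.warnings = warnings
        return model

    internal_fives = [
        c for c in fives if L and not _near(c.position, 1, boundary_tol)
    ]
    internal_threes = [
        c for c in threes if L and not _near(c.position, L, boundary_tol)
    ]
    if proc_junctions and internal_fives and internal_threes:
        five, three = internal_fives[0], internal_threes[0]
        gap = (three.position + 1, five.position - 1)
        if gap[0] <= gap[1] and excised_covers(gap):
            model.verdict = "circularly_permuted"
            model.segments = [(five.position, L), (1, three.position)]
            model.byproducts = [
                f"excised segment {e.interval[0]}-{e.interval[1]} (turned over)"
                for e in excisions
            ]
            model.warnings = warnings
            return model
        warnings.append(
            "junction and internal termini found but no excised segment "
            "between them; downgrading"
        )

    if proc_junctions and not end_calls:
        model.verdict = "circular"
        model.segments = [(1, L)] if L else []
        model.warnings = warnings
        return model

    if fives and threes and not proc_junctions:
        five, three = fives[0], threes[0]
        if L and _near(five.position, 1, boundary_tol) and _near(
            three.position, L, boundary_tol
        ):
            model.verdict = "linear"
            model.segments = [(five.position, three.position)]
            model.warnings = warnings
            return model
        warnings.append(
            "termini not at annotation boundaries and no junction; "
            "insufficient evidence for a topology"
        )

    if proc_junctions and end_calls:
        warnings.append(
            "processing junction coexists with terminus calls that do not "
            "fit a permutation; downgrading to linear"
        )
        if fives and threes:
            model.verdict = "linear"
            model.segments = [(fives[0].position, threes[0].position)]
    model.warnings = warnings
    return model


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------


def model_to_markdown(model: ProcessingModel) -> str:
    lines = [
        f"# Processing model: {model.reference_id}",
        "",
        f"- verdict: **{model.verdict}**",
        f"- reference length: {model.length} nt",
    ]
    if model.segments:
        order = " + ".join(f"{a}-{b}" for a, b in model.segments)
        lines.append(f"- mature segment order (conventional coordinates): {order}")
    if model.termini:
        lines.append("- termini:")
        for t in model.termini:
            lines.append(
                f"  - {t['kind']} at {t['position']} "
                f"(chemistry {t['chemistry']}, support {t['support']})"
            )
    if model.junctions:
        lines.append("- junctions:")
        for j in model.junctions:
            lines.append(
                f"  - {j['donor']} -> {j['acceptor']} "
                f"({j['verdict']}, support {j['support']})"
            )
    if model.byproducts:
        # turnover products are shown in parentheses, as in processing diagrams
        joined = "; ".join(model.byproducts)
        lines.append(f"- by-products: ({joined})")
    if model.warnings:
        lines.append("- warnings:")
        for w in model.warnings:
            lines.append(f"  - {w}")
    return "\n".join(lines) + "\n"


def write_report(
    model: ProcessingModel,
    out_dir,
    formats: Sequence[str] = ("json", "md"),
    evidence: Optional[dict] = None,
) -> dict[str, pathlib.Path]:
    """Write the model (JSON/Markdown) and optional evidence tracks.

    ``evidence`` may carry ``end_calls``, ``excisions``, ``junctions`` and
    ``motifs`` sequences; they are written as BED6 / TSV / BEDPE / GFF3.
    Field ordering is deterministic.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, pathlib.Path] = {}
    if "json" in formats:
        p = out / "model.json"
        with open(p, "w") as fh:
            json.dump(model.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written["json"] = p
    if "md" in formats:
        p = out / "model.md"
        p.write_text(model_to_markdown(model))
        written["md"] = p
    evidence = evidence or {}
    if "end_calls" in evidence:
        p = out / "ends.bed"
        write_end_calls_bed(evidence["end_calls"], p, model.reference_id)
        written["ends_bed"] = p
    if "excisions" in evidence:
        p = out / "excisions.bed"
        write_excisions_bed(evidence["excisions"], p, model.reference_id)
        written["excisions_bed"] = p
    if "junctions" in evidence:
        p = out / "junctions.tsv"
        write_junctions_tsv(evidence["junctions"], p, model.reference_id)
        written["junctions_tsv"] = p
        p2 = out / "junctions.bedpe"
        write_junctions_bedpe(evidence["junctions"], p2, model.reference_id)
        written["junctions_bedpe"] = p2
    if "motifs" in evidence:
        p = out / "motifs.gff3"
        _write_motifs_gff3(evidence["motifs"], p, model.reference_id)
        written["motifs_gff3"] = p
    return written


def _write_motifs_gff3(motifs, path, reference_id: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for n, m in enumerate(motifs, 1):
            mid = f"bhb{n}"
            rows = [
                ("BHB_stem", m.stem5_start, m.stem5_start + m.stem_len - 1),
                ("BHB_stem", m.stem3_start, m.stem3_start + m.stem_len - 1),
                ("BHB_bulge", *m.bulges[0]),
                ("BHB_bulge", *m.bulges[1]),
                ("flank_helix", *m.left_arm),
                ("flank_helix", *m.right_arm),
                ("predicted_cleavage", m.predicted_cleavages[0],
                 m.predicted_cleavages[0]),
                ("predicted_cleavage", m.predicted_cleavages[1],
                 m.predicted_cleavages[1]),
            ]
            for feat, a, b in rows:
                fh.write(
                    f"{reference_id}\tribotopo\t{feat}\t{a}\t{b}\t{m.score}"
                    f"\t+\t.\tParent={mid}\n"
                )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    sim: SimResult
    reference: str  # conventional reference the calls refer to
    alignments: list[Alignment]
    profile: ReadEndProfile
    end_calls: list[EndCall]
    excisions: list[ExcisionCall]
    junctions: list[JunctionCall]
    model: ProcessingModel
    mapper_stats: dict


def run_pipeline(
    spec: Optional[OperonSpec] = None,
    scenario: str = "permuted_with_excision",
    config: Optional[LibraryConfig] = None,
    seed: int = 0,
    byproduct_fraction: float = 0.01,
    min_support: int = 20,
    z_threshold: float = 5.0,
    junction_min_support: int = 2,
) -> PipelineResult:
    """simulate -> map -> profile -> call -> junctions -> model, one seed.

    The conventional mature-LSU sequence is the mapping reference; junction
    discovery re-aligns only the reads that were unaligned or 5'-clipped on
    it, as candidates for non-colinear placements.

    When a supported processing junction is found, all reads are remapped to
    the doubled (circularized) reference and ends/excisions are re-called on
    the wrapped profile.  On the linear reference, reads spanning the seam of
    a circular or permuted molecule can only align by clipping their upstream
    part, which piles spurious 5' starts at the acceptor coordinate; on the
    cyclic reference those reads map end-to-end and the artifact disappears,
    leaving only genuine molecule termini.
    """
    config = config or LibraryConfig()
    sim = simulate_scenario(
        spec=spec,
        scenario=scenario,
        config=config,
        seed=seed,
        byproduct_fraction=byproduct_fraction,
    )
    reference = sim.lsu_reference
    stats: dict = {}
    alignments = align_reads(
        sim.reads, reference, reference_id="LSU", stats=stats
    )
    profile = compute_profile(alignments, reference, reference_id="LSU")
    end_calls = call_ends(
        profile,
        size_min=config.size_min,
        min_support=min_support,
        z_threshold=z_threshold,
    )
    excisions = detect_excision(profile, end_calls=end_calls)

    aligned_ids = {a.read_id for a in alignments}
    clipped_ids = {a.read_id for a in alignments if a.clip5_len >= 8}
    junction_reads = [
        r
        for r in sim.reads
        if r.read_id not in aligned_ids or r.read_id in clipped_ids
    ]
    junctions = find_junctions(
        junction_reads,
        reference,
        end_calls,
        min_support=junction_min_support,
        min_seed=min(15, config.size_min - 5),
    )

    supported = [
        j
        for j in junctions
        if j.verdict == "processing_junction" and j.support >= junction_min_support
    ]
    if supported:
        doubled, cmap = circularize_reference(reference)
        alignments = dedupe_circular_alignments(
            align_reads(sim.reads, doubled, reference_id="LSU", stats=stats),
            cmap,
        )
        profile = compute_profile(
            alignments, reference, circular=True, reference_id="LSU"
        )
        end_calls = call_ends(
            profile,
            size_min=config.size_min,
            min_support=min_support,
            z_threshold=z_threshold,
        )
        excisions = detect_excision(profile, end_calls=end_calls)

    read_seqs = {r.read_id: r.sequence for r in sim.reads}
    for call in end_calls:
        if call.kind == "five_prime":
            call.chemistry = infer_end_chemistry(
                call, profile, alignments, reads=read_seqs
            )

    model = assemble_model(
        end_calls,
        excisions,
        junctions,
        annotation={"reference_id": "LSU", "length": len(reference)},
        junction_support_min=junction_min_support,
    )
    return PipelineResult(
        sim=sim,
        reference=reference,
        alignments=alignments,
        profile=profile,
        end_calls=end_calls,
        excisions=excisions,
        junctions=junctions,
        model=model,
        mapper_stats=stats,
    )


def expected_verdict(scenario: str) -> str:
    """The truth topology verdict for each simulation scenario."""
    return {
        "linear": "linear",
        "circular": "circular",
        "permuted_with_excision": "circularly_permuted",
        "hidden_break": "fragmented",
        "unprocessed": "insufficient_data",
    }[scenario]
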