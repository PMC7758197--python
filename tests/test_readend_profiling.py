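"""Mapper, SAM interchange and read-end profile computation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import leftmost_exact_match

from ribotopo import (
    LibraryConfig,
    ReadRecord,
    align_reads,
    apply_processing,
    compute_profile,
    protection_score,
    read_alignments,
    simulate_scenario,
    write_alignments,
)
from ribotopo.readend_profiling import ReadEndProfile
from ribotopo._seq import BASES


def _random_seq(rng, n):
    return "".join(BASES[k] for k in rng.integers(0, 4, size=n))


def _read(seq, rid="r0"):
    return ReadRecord(rid, seq, "test", 1, len(seq))


class TestMapper:
    def test_verbatim_read_aligns_without_clip_or_mismatch(self):
        rng = np.random.default_rng(0)
        ref = _random_seq(rng, 200)
        (aln,) = align_reads([_read(ref[50:80])], ref)
        assert (aln.start, aln.end) == (51, 80)
        assert aln.clip5_len == 0
        assert aln.mismatches == ()

    def test_chimeric_read_clips_its_random_partner(self):
        rng = np.random.default_rng(1)
        ref = _random_seq(rng, 300)
        partner = _random_seq(rng, 10)
        read = _read(partner + ref[100:130])
        (aln,) = align_reads([read], ref)
        assert aln.start == 101
        assert aln.clip5_len == 10

    def test_read_shorter_than_seed_is_counted_unaligned(self):
        rng = np.random.default_rng(2)
        ref = _random_seq(rng, 100)
        stats = {}
        out = align_reads([_read(ref[10:20])], ref, min_seed=15, stats=stats)
        assert out == []
        assert stats["unaligned"] == 1

    def test_permutation_junction_reads_clip_or_fail_on_linear_reference(
        self, permuted_run
    ):
        """Reads spanning the new junction cannot map contiguously on the
        conventional reference: their upstream part is clipped or the read
        is dropped."""
        sim = permuted_run.sim
        perm = sim.species_by_id("LSU_permuted")
        junction_mol_pos = 129  # molecule coordinate of the junction donor
        spanning = [
            r
            for r in sim.reads
            if r.species_id == "LSU_permuted"
            and r.start <= junction_mol_pos - 5
            and r.end >= junction_mol_pos + 15
            and r.chimera_partner is None
        ]
        assert len(spanning) > 20
        by_id = {a.read_id: a for a in permuted_run.alignments}
        # pass 2 aligned on the doubled reference; re-map on the linear one
        linear_alns = {
            a.read_id: a
            for a in align_reads(spanning, permuted_run.reference)
        }
        for r in spanning:
            aln = linear_alns.get(r.read_id)
            assert aln is None or aln.clip5_len > 0

    def test_mapper_matches_string_search_oracle(self):
        """Exact-substring reads: aligner == leftmost string search (the
        100-seed sweep lives in the acceptance suite)."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(60, 300))
            ref = _random_seq(rng, n)
            reads = []
            for k in range(10):
                start = int(rng.integers(0, n - 20))
                ln = int(rng.integers(20, min(41, n - start + 1)))
                reads.append(
                    ReadRecord(f"r{k}", ref[start : start + ln], "t", start + 1,
                               start + ln)
                )
            alns = {a.read_id: a for a in align_reads(reads, ref)}
            for r in reads:
                expected = leftmost_exact_match(r.sequence, ref)
                assert alns[r.read_id].start == expected
                assert alns[r.read_id].clip5_len == 0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.data())
    def test_substring_reads_always_map_at_an_exact_occurrence(self, seed, data):
        rng = np.random.default_rng(seed)
        ref = _random_seq(rng, 120)
        start = data.draw(st.integers(0, 90))
        ln = data.draw(st.integers(20, 30))
        read = _read(ref[start : start + ln])
        (aln,) = align_reads([read], ref)
        got = ref[aln.start - 1 : aln.end]
        assert got == read.sequence
        assert aln.start <= start + 1  # leftmost placement


class TestProfile:
    def test_end_count_conservation_and_coverage_identity(self, linear_profile):
        _, alns, prof = linear_profile
        assert prof.count5.sum() == prof.count3.sum() == len(alns)
        cum = np.cumsum(prof.count5) - np.concatenate(
            ([0], np.cumsum(prof.count3)[:-1])
        )
        assert np.array_equal(prof.coverage, cum)

    def test_native_end_depletion_first_3prime_end_at_offset_20(
        self, linear_profile
    ):
        """With >=20 nt retention, positions 1..19 downstream of a native 5'
        end carry no 3' read-ends; the first appears at the 20th."""
        _, _, prof = linear_profile
        first = next(i for i in range(1, 100) if prof.count3[i - 1] > 0)
        assert first == 20

    def test_clip_signal_is_confined_to_the_chimerized_end(self, permuted_run):
        prof = permuted_run.profile
        # the hydrolytic 5'-P end accumulates clipped chimeras...
        assert prof.clipfrac5[2967] > 0.05
        # ...while ordinary interior starts are unclipped
        interior = prof.clipfrac5[100:2900]
        starts = prof.count5[100:2900] > 0
        assert float(np.median(interior[starts])) == 0.0

    def test_profile_counts_wrap_on_a_rotated_circular_reference(self):
        """Rotating a circular reference rotates count5/count3 exactly."""
        sim = simulate_scenario(
            scenario="circular", seed=4, config=LibraryConfig(n_molecules=150)
        )
        ref = sim.lsu_reference
        L = len(ref)
        k = 500
        rotated = ref[k:] + ref[:k]
        profs = []
        for reference in (ref, rotated):
            alns = align_reads(sim.reads, reference + reference)
            from ribotopo.junction_discovery import (
                CircularMap,
                dedupe_circular_alignments,
            )

            alns = dedupe_circular_alignments(alns, CircularMap(L))
            profs.append(compute_profile(alns, reference, circular=True))
        a, b = profs
        assert np.array_equal(a.count5, np.roll(b.count5, k))
        assert np.array_equal(a.count3, np.roll(b.count3, k))

    def test_alignment_out_of_bounds_is_a_hard_error(self):
        from ribotopo.readend_profiling import Alignment

        bad = Alignment("r", "ref", 90, 120, 0)
        with pytest.raises(ValueError):
            compute_profile([bad], "A" * 100)


class TestProtectionScore:
    def test_uniform_profile_scores_zero_everywhere(self):
        L = 60
        prof = ReadEndProfile(
            reference_id="u",
            length=L,
            count5=np.full(L, 5),
            count3=np.full(L, 5),
            coverage=np.full(L, 100),
            snpfrac=np.zeros(L),
            clipfrac5=np.zeros(L),
            n_alignments=300,
        )
        assert all(protection_score(prof, i) == 0.0 for i in range(2, L))

    def test_fully_protected_methyl_scores_one(self, linear_profile):
        sim, _, prof = linear_profile
        rec = sim.species_by_id("LSU_linear")
        for m in rec.annotation.methyl_sites:
            assert protection_score(prof, m) == 1.0

    def test_unmethylated_background_scores_stay_low(self, linear_profile):
        """95th percentile < 0.5 at >=100x depth."""
        sim, _, prof = linear_profile
        methyls = set(sim.species_by_id("LSU_linear").annotation.methyl_sites)
        scores = [
            s
            for i in range(50, prof.length - 50)
            if i not in methyls
            and (s := protection_score(prof, i)) is not None
        ]
        assert float(np.percentile(scores, 95)) < 0.5

    def test_zero_local_mean_is_reported_missing(self):
        L = 60
        prof = ReadEndProfile(
            reference_id="z",
            length=L,
            count5=np.zeros(L, dtype=int),
            count3=np.zeros(L, dtype=int),
            coverage=np.zeros(L, dtype=int),
            snpfrac=np.zeros(L),
            clipfrac5=np.zeros(L),
        )
        assert protection_score(prof, 30) is None


class TestSamInterchange:
    def test_roundtrip_preserves_alignments(self, tmp_path):
        rng = np.random.default_rng(5)
        ref = _random_seq(rng, 300)
        partner = _random_seq(rng, 12)
        reads = [
            _read(ref[40:75], "plain"),
            _read(partner + ref[200:235], "chimera"),
        ]
        alns = align_reads(reads, ref)
        sam = tmp_path / "test.sam"
        write_alignments(
            alns, {r.read_id: r.sequence for r in reads}, ref, sam
        )
        back = read_alignments(sam)
        assert [
            (a.read_id, a.start, a.end, a.clip5_len, a.mismatches) for a in back
        ] == [
            (a.read_id, a.start, a.end, a.clip5_len, a.mismatches) for a in alns
        ]

    def test_soft_clip_cigar_parses_into_clip_and_block(self, tmp_path):
        sam = tmp_path / "clip.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ref\tLN:100\n"
            "r1\t0\tref\t11\t60\t10S30M\t*\t0\t0\t"
            + "A" * 40
            + "\t*\n"
        )
        (aln,) = read_alignments(sam)
        assert aln.clip5_len == 10
        assert aln.length == 30
        assert (aln.start, aln.end) == (11, 40)

    def test_empty_sam_yields_empty_list(self, tmp_path):
        sam = tmp_path / "empty.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:ref\tLN:100\n")
        assert read_alignments(sam) == []

    def test_reverse_strand_records_are_rejected(self, tmp_path):
        sam = tmp_path / "rev.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ref\tLN:100\n"
            "r1\t16\tref\t11\t60\t30M\t*\t0\t0\t" + "A" * 30 + "\t*\n"
        )
        assert read_alignments(sam) == []
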