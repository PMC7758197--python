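"""Operon construction, processing scenarios, fragmentation, library."""

import io

import numpy as np
import pytest
from scipy import stats as sps

from ribotopo import (
    LibraryConfig,
    OperonSpec,
    apply_processing,
    build_library,
    build_operon,
    default_operon_spec,
    fragment_rna,
    simulate_scenario,
)
from ribotopo.synthetic_data import (
    OperonSizeError,
    fragment_species,
    truth_to_json,
    write_fastq,
)


class TestBuildOperon:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reference_length_equals_sum_of_segments(self, seed):
        spec = default_operon_spec(rng_seed=seed)
        ref, truth = build_operon(spec)
        assert len(ref) == sum(s[2] for s in spec.segments)
        assert truth.length == len(ref)

    def test_default_excisable_helix_is_41_nt(self, default_build):
        _, truth = default_build
        h5, h3 = truth.h98_conventional
        assert (h5, h3) == (2927, 2967)
        assert h3 - h5 + 1 == 41

    def test_degenerate_spec_has_no_motifs_or_junctions(self):
        spec = OperonSpec(
            segments=(("X", "LSU", 500),),
            lsu_bhb=None,
            ssu_bhb=None,
            h98_interval=None,
            rng_seed=0,
        )
        ref, truth = build_operon(spec)
        assert len(ref) == 500
        assert truth.motifs == {}
        species = apply_processing(ref, truth, "linear")
        assert all(not s.annotation.junctions for s in species)

    def test_undersized_spacer_raises_naming_the_segment(self):
        base = default_operon_spec()
        segments = tuple(
            (n, r, 8 if n == "ITS2" else ln) for n, r, ln in base.segments
        )
        spec = OperonSpec(
            segments=segments,
            methyl_positions=frozenset(),
            h98_interval=base.h98_interval,
        )
        with pytest.raises(OperonSizeError, match="ITS2"):
            build_operon(spec)


class TestApplyProcessing:
    def test_permuted_mature_length_and_junction_block(self, default_build):
        ref, truth = default_build
        species = apply_processing(ref, truth, "permuted_with_excision")
        perm = next(s for s in species if s.species_id == "LSU_permuted")
        assert len(perm.sequence) == 3096 - 41 == 3055
        # the 129-nt 3' block is appended at the 5' end, junction follows it
        first_block = perm.annotation.conv_intervals[0]
        assert first_block == (2968, 3096)
        assert first_block[1] - first_block[0] + 1 == 129
        assert perm.annotation.junctions == [(3096, 1)]
        assert perm.annotation.termini == {
            "five_prime": 2968,
            "three_prime": 2926,
        }
        assert perm.annotation.end_chemistries["five_prime"] == "5P"
        # the permuted sequence is the rotation of the conventional one
        conv = ref[truth.mature["LSU"][0] - 1 : truth.mature["LSU"][1]]
        assert perm.sequence == conv[2967:] + conv[:2926]

    def test_permuted_byproducts_include_joined_spacer_molecule(
        self, default_build
    ):
        ref, truth = default_build
        species = apply_processing(ref, truth, "permuted_with_excision")
        ids = {s.species_id for s in species}
        assert "ITS2_ETS3_spacer" in ids
        assert "H98_fragment" in ids
        spacer = next(s for s in species if s.species_id == "ITS2_ETS3_spacer")
        assert spacer.annotation.is_byproduct
        assert len(spacer.annotation.junctions) == 1

    def test_linear_species_is_the_annotated_mature_interval(
        self, default_build
    ):
        ref, truth = default_build
        m5, m3 = truth.mature["LSU"]
        (rec,) = apply_processing(ref, truth, "linear")
        assert rec.sequence == ref[m5 - 1 : m3]
        assert rec.annotation.junctions == []

    def test_circular_species_is_covalently_closed(self, default_build):
        ref, truth = default_build
        (rec,) = apply_processing(ref, truth, "circular")
        assert rec.circular
        assert rec.annotation.termini["five_prime"] is None

    def test_hidden_break_yields_two_fragments_partitioning_the_lsu(
        self, default_build
    ):
        ref, truth = default_build
        recs = apply_processing(ref, truth, "hidden_break")
        assert len(recs) == 2
        total = sum(len(r.sequence) for r in recs)
        assert total == 3096
        frag3 = next(r for r in recs if r.species_id == "LSU_3p_fragment")
        assert frag3.annotation.end_chemistries["five_prime"] == "5P"


class TestFragmentation:
    def test_retained_fragments_obey_size_selection(self, default_build):
        ref, truth = default_build
        (rec,) = apply_processing(ref, truth, "linear")
        frags = fragment_species(
            rec, LibraryConfig(n_molecules=400), rng=np.random.default_rng(0)
        )
        lengths = [f.length for f in frags]
        assert min(lengths) >= 20 and max(lengths) <= 40
        # saturation: with >=1e4 fragments both bounds are reached exactly
        assert len(lengths) >= 10_000
        assert min(lengths) == 20 and max(lengths) == 40

    def test_no_cleavage_returns_the_whole_molecule(self):
        cfg = LibraryConfig(cleavage_prob=0.0, n_molecules=1)
        frags = fragment_rna(
            "ACGTACGTACGTACGTACGTACGTACGTAC", [], cfg,
            rng=np.random.default_rng(0),
        )
        assert len(frags) == 1
        assert frags[0].length == 30
        assert (frags[0].start, frags[0].end) == (1, 30)

    def test_full_cleavage_retains_nothing(self):
        cfg = LibraryConfig(cleavage_prob=1.0, n_molecules=3)
        frags = fragment_rna(
            "ACGTACGTACGTACGTACGTACGTACGTAC", [], cfg,
            rng=np.random.default_rng(0),
        )
        assert frags == []  # every fragment is 1 nt, below size_min

    def test_fragments_match_their_provenance_exactly(self, default_build):
        ref, truth = default_build
        species = apply_processing(ref, truth, "permuted_with_excision")
        rng = np.random.default_rng(2)
        cfg = LibraryConfig(n_molecules=50)
        for rec in species:
            doubled = rec.sequence + rec.sequence
            for f in fragment_species(rec, cfg, rng=rng):
                assert f.sequence == doubled[f.start - 1 : f.end], rec.species_id

    def test_full_protection_leaves_no_boundary_after_methyl(
        self, default_build
    ):
        ref, truth = default_build
        (rec,) = apply_processing(ref, truth, "linear")
        assert rec.annotation.methyl_sites  # the default spec has methyls
        cfg = LibraryConfig(protection_factor=0.0, n_molecules=500)
        frags = fragment_species(rec, cfg, rng=np.random.default_rng(3))
        methyls = set(rec.annotation.methyl_sites)
        for f in frags:
            # a cut 3' of nucleotide m would start a fragment at m+1 or end
            # one at m
            assert (f.start - 1) not in methyls
            assert f.end not in methyls or f.end == len(rec.sequence)

    def test_circular_fragment_ends_are_uniform(self, default_build):
        """Chi-square test of 5'-end positions on a circle, alpha = 0.01."""
        ref, truth = default_build
        (rec,) = apply_processing(ref, truth, "circular")
        cfg = LibraryConfig(n_molecules=2000, protection_factor=1.0)
        frags = fragment_species(rec, cfg, rng=np.random.default_rng(0))
        counts = np.zeros(len(rec.sequence))
        for f in frags:
            counts[(f.start - 1) % len(rec.sequence)] += 1
        _, p = sps.chisquare(counts)
        assert p > 0.01


class TestLibrary:
    def _linear_fragments(self, default_build, chem5="5P", n=400, seed=0):
        ref, truth = default_build
        (rec,) = apply_processing(ref, truth, "linear")
        rec.annotation.end_chemistries["five_prime"] = chem5
        return fragment_species(
            rec, LibraryConfig(n_molecules=n), rng=np.random.default_rng(seed)
        )

    def test_chimera_prob_zero_makes_no_chimeras(self, default_build):
        frags = self._linear_fragments(default_build)
        cfg = LibraryConfig(chimera_prob=0.0)
        reads = build_library(frags, cfg, rng=np.random.default_rng(0))
        assert all(r.chimera_partner is None for r in reads)

    def test_alkaline_ends_never_chimerize(self, default_build):
        # a circular species yields only 5'-OH fragment ends
        ref, truth = default_build
        (rec,) = apply_processing(ref, truth, "circular")
        frags = fragment_species(
            rec, LibraryConfig(n_molecules=200), rng=np.random.default_rng(1)
        )
        assert all(f.chem5 == "5OH" for f in frags)
        reads = build_library(
            frags, LibraryConfig(chimera_prob=1.0), rng=np.random.default_rng(0)
        )
        assert all(r.chimera_partner is None for r in reads)

    def test_chimera_fraction_matches_binomial_expectation(self, default_build):
        frags = self._linear_fragments(default_build, chem5="5P", n=3000)
        eligible = [f for f in frags if f.chem5 == "5P"]
        assert len(eligible) >= 500
        cfg = LibraryConfig(chimera_prob=0.5)
        reads = build_library(frags, cfg, rng=np.random.default_rng(0))
        n_chim = sum(1 for r in reads if r.chimera_partner is not None)
        n = len(eligible)
        # within 3 binomial standard deviations of p = 0.5
        sd = np.sqrt(n * 0.25)
        assert abs(n_chim - 0.5 * n) <= 3 * sd

    def test_empty_fragment_list_gives_empty_library(self):
        assert build_library([], LibraryConfig()) == []


class TestReproducibility:
    def test_identical_seeds_give_byte_identical_outputs(self):
        runs = []
        for _ in range(2):
            sim = simulate_scenario(
                scenario="permuted_with_excision", seed=11
            )
            buf = io.StringIO()
            from Bio import SeqIO
            from Bio.Seq import Seq
            from Bio.SeqRecord import SeqRecord

            recs = []
            for r in sim.reads:
                rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
                rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
                recs.append(rec)
            SeqIO.write(recs, buf, "fastq")
            runs.append((buf.getvalue(), truth_to_json(sim)))
        assert runs[0] == runs[1]
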