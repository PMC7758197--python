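# Methods

## Library model

The generator emulates an end-capturing fragment-library protocol of the
RiboMeth-seq family. A molecule is fragmented by cleaving every
internucleotide bond independently with probability `cleavage_prob`
(default 1/30, giving a mean fragment length near the middle of the size
window); a bond 3' of a 2'-O-methylated nucleotide is cleaved with
probability `cleavage_prob * protection_factor` (default 0: full
protection, i.e. saturating methylation). Alkaline scission proceeds by
transesterification and labels the new ends 5'-OH / 2',3'-cyclic-phosphate;
pre-existing termini keep the chemistry recorded in the species truth
(hydrolytic processing cuts leave 5'-P / 3'-OH, BHB/endonuclease cuts leave
5'-OH / cyclic-P). Only fragments of `size_min`–`size_max` nt
(default 20–40, the gel-purified fraction) are retained. A circular species
is fragmented on the circle — no implicit ends, and an uncut circle yields
no library fragment.

Cloning chimeras: with probability `chimera_prob` (default 0.3), a retained
fragment whose 5' terminus is a 5'-phosphate is prepended with a uniformly
sampled retained fragment; 5'-OH fragments never chimerize. Reads are the
first `read_len` (default 80) nt of the insert with constant quality, no
sequencing errors by default (`sequencing_error_rate` is a config option).
`n_molecules` defaults to 800, which yields ~200x median coverage of the
default 3,096-nt LSU.

What the generator does **not** model: reverse-transcription drop-off,
adaptor content, platform-specific error modes, ragged exonucleolytic ends,
and non-uniform alkaline scission beyond methyl protection. Passing tests
therefore demonstrate correctness of the inference logic under an idealized
but protocol-shaped library, not robustness to every real-data artifact.

## Synthetic operon

The default operon is ETS5(100) – SSU(300) – ITS1(60) – tRNA(80) – ITS2(60)
– LSU(3096) – ETS3(50). The LSU is full-size so conventional LSU
coordinates are meaningful: the excisable helix occupies 2,927–2,967
(41 nt), leaving a 129-nt 3' block, and the circularization junction joins
C3096 to G1 (the generator fixes those two identities). The SSU and
spacers are scaled-down placeholders, sized only to host their stalk
helices; nothing downstream depends on SSU length.

Both processing stalks are planted as antiparallel complementarity: a
central 4-bp stem, two 3-nt bulges on opposite strands/sides (the canonical
3-4-3 BHB), and flanking helices of 21/14 bp (LSU) or 13/19 bp (SSU).
Cleavage follows the symmetric rule "after the 2nd bulge nucleotide,
5'→3' per strand", which places the LSU cuts exactly at the mature ends
(offsets 0/0) and the SSU cuts 62 nt upstream / 27 nt downstream of the
mature SSU ends. Helix boundaries are terminated by deliberately
non-pairing bases so annotated lengths are exact, and the random fill is
rejection-sampled: if the detector scanned over a planted stalk's
neighbourhood reports anything but the planted motif, the fill is redrawn
(logged; a few percent of draws).

Coordinates are 1-based inclusive in every public record and 0-based
half-open internally. Whether circularization precedes helix excision is
not observable in the mature truth; the simulator produces the permuted
product directly (circularize-then-excise order).

By-products of the permuted scenario (the excised helix and the joined
ITS2–3'ETS spacer molecule) are simulated at `byproduct_fraction` of the
mature molecule count (default 0.01, trace turnover material).

## Mapper

A seed-and-extend exact-substring aligner for 20–80-nt stranded RNA
fragment reads: forward strand only, gap-free. For each read it scans clip
lengths c = 0, 1, … and reports the first (longest) suffix whose leading
`min_seed`-mer (default 15) has an exact reference hit and whose full
extension stays within `max_mismatch_frac` (default 0.1); ties go to fewest
mismatches, then the leftmost position. The unaligned prefix becomes a 5'
soft-clip. Because every alignment is anchored by an exact seed at its
start, chimera partner tails cannot smear alignment starts upstream of a
native end — the chimera signal lands in the clip fraction, with the
mismatch fraction retained as a secondary signal for externally produced
alignments. Known consequences: no 3' clipping (a suffix must fit the
reference, which is why seam-spanning reads on a linear reference either
clip or drop), and a sequencing error in the first 15 nt of a read converts
into a short 5' clip.

## End calling

A five_prime call at p requires: `count5[p] >= min_support` (default 20); a
local maximum with robust z-score (median/MAD, scale floored at
sqrt(median)) `>= z_threshold` (default 5) against the flanking
2x`size_min` windows; 3'-end depletion over `[p, p+size_min-2]` at or below
the Poisson alpha = 0.01 quantile implied by the flanking median rate; and
a soft-clip fraction at p of at most `max_clipfrac` (default 0.9) — a start
that exists only after clipping means the molecule continues upstream
(junction seam or annotation overhang), whereas a genuine 5'-P end is only
partially chimerized. three_prime calls are computed on the reversed
profile, which makes the mirror symmetry structural. Adjacent equal-count
candidates resolve to the 5'-most.

Excised segments are maximal runs with per-position coverage at or below
`max_ratio` (default 0.05) times the local flanking median, length >=
`min_len` (default 10), not touching the reference boundaries. Because
every residual copy of an excised segment contributes terminal fragments,
the outermost excised positions can sit just above the per-position
threshold; when a bounding end call lies within `snap_slack` (default 5) nt
of a run edge, the interval is snapped to the call — the cleavage sites
define the segment more precisely than coverage does. The 0.05 default
reflects the observed scale of residual excised/unligated species (a few
percent); no sharper value is published, so it is exposed in config.

Hidden-break pairing joins a three_prime call at q to a five_prime call at
p when `0 <= p - q - 1 <= max_gap` (default 50). A pair whose gap is
covered by an excision call is not fragmentation evidence (the gap is
physically absent), which is how excision-bounding calls at a 41-nt gap are
discounted.

## Junctions and chemistry

Junction discovery is candidate-driven (mirroring the observe-ends-first
workflow): donors are called 3' ends plus the conventional end L, acceptors
are called 5' ends plus position 1; for each non-colinear pair a joined
reference is built from `flank`-nt windows and reads that were unaligned or
5'-clipped on the conventional reference are realigned. A read supports a
junction with >= `min_overhang` (default 10) matched nt on each side and is
assigned to its best candidate only. Partner diversity = distinct
upstream-flank sequences (Hamming <= 1 tolerated) / support; <= 0.2 is a
processing junction, >= 0.8 a ligation artifact, support 1 always
ambiguous. A blind all-pairs mode is not provided; candidates are always
nominated by end calls or the trivial circularization.

When a supported processing junction exists, the pipeline remaps all reads
to the doubled reference and re-calls ends/excisions on the wrapped
profile: seam-spanning reads then align end-to-end and the clip pile-up at
the acceptor disappears, leaving only genuine molecule termini. This
doubled-reference pass is what separates `circular` (junction, no termini)
from `circularly_permuted` (junction + internal termini + excised interval
between them).

5'-end chemistry: a called 5' end is P5 when more than `chim_threshold`
(default 0.05) of its starting reads carry a >= 5-nt clip (or an upstream
mismatch cluster) **and** those flanks are heterogeneous; homogeneous
flanks indicate a real upstream junction and do not count. With
`chimera_prob` 0 a 5'-P end is indistinguishable from 5'-OH — an inherent,
documented false negative: chemistry is only observable through the
cloning artifact. Conversely, chimeras whose sampled partner happens to end
at a molecule terminus can assemble into a low-support junction candidate
at exactly the excision-skip coordinates; these never reach the
processing_junction verdict (identical flanks at support ~2 stay
ambiguous) and are ignored by the verdict rules.

## BHB detection

Pure complementarity, no thermodynamics: Watson-Crick and G-U wobble pairs
count equally (archaeal rRNA helices contain wobbles; the argument is a
pairing diagram, not an energy). The detector enumerates ordered stem
anchor pairs (i, j) — numpy antidiagonal prefilter for the 4-bp stem, then
per-candidate validation — requiring strict geometry (the bulges may not be
absorbed by stem extension), both flanking helices >= `min_flank`
(default 8) bp, and resolving overlaps greedily by score (stem + flank
pairs), ties to the smallest anchor. Equivalence with a naive
quadruple-loop oracle is asserted over 100 random sequences in the test
suite. The cleavage rule ("after the k-th bulge nucleotide", k = 2) is
parameterized rather than asserted, since only its consequence — cuts
landing at the mature ends for offsets 0/0 — is fixed by the architecture;
ligation products follow by joining the insert-side cut ends (circle) and
the flank-side cut ends (joined spacer molecule). A compensatory-change
counter over pre-aligned sequences supports covariation checks; building
alignments is out of scope.

## Verdict assembly

Precedence: fragmented > circularly_permuted > circular > linear, with
`insufficient_data` when no evidence class is present or nothing fits.
The order is a design choice (a decision procedure is implied, not
published): breaks are the most specific signal, and a junction downgrades
through permuted -> circular -> linear as its corroborating termini
disappear. "Near annotation boundary" for the linear verdict is ±3 nt
(`boundary_tol`); processing junctions need support >= 2 to enter the
rules. Conflicting evidence downgrades with a warning rather than erroring.

## Problem sizes and determinism

The test suite simulates at ~200x median depth (800 molecules over the
3,096-nt LSU), 4 scenarios x 20 seeds for the recovery properties, 50
seeds for planted-motif recovery, and 100 random sequences for each oracle
equivalence; the whole suite runs in about one to two minutes on one CPU.
All randomness flows through `numpy.random.default_rng` seeded from the
operon spec / library config (a single pipeline seed overrides both), so
identical seeds give byte-identical FASTQ, truth JSON and reports.
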