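# ribotopo

Inference of rRNA processing **topology** — linear, covalently circular,
circularly permuted, or fragmented — from the read-end architecture of
alkaline-fragmentation sequencing libraries (RiboMeth-seq-style protocols).

## The problem

In archaea, pre-rRNA processing routes the SSU and LSU rRNAs through
bulge-helix-bulge (BHB) motifs: the spacers flanking each rRNA co-fold into a
long processing stalk, the tRNA splicing endonuclease cuts symmetrically
within the two 3-nt bulges of a central 4-bp stem (the 3-4-3 BHB), and a
ligase joins the cut ends — producing covalently **circular** intermediates.
In some thermophiles the circle is re-opened at a *different* site than it
was closed: an internal helix near the conventional 5'/3' ends is excised by
hydrolytic cleavages and the molecule ends up **circularly permuted**, with
the old 3'-terminal block appended to the new 5' end and a new internal
junction joining the conventional 3' coordinate L to coordinate 1.

Libraries built from partially alkali-degraded RNA read this architecture
out directly. Writing `c5[i]` and `c3[i]` for the number of read 5'/3' ends
at position *i*:

- a native 5' end at *p* gives a pile-up of `c5[p]` **and** a depletion of
  `c3` over `[p, p + s - 2]`, because gel selection discards fragments
  shorter than `s` (= 20 nt) — so the first possible 3' read-end sits at
  offset 20;
- an excised internal segment shows as an interval of near-zero coverage
  bounded by a 3'-end call on its left and a 5'-end call on its right;
- a junction absent from the linear reference strands reads across it:
  they surface as 5'-soft-clipped or unmapped and remap end-to-end on a
  doubled ("circularized") reference;
- end chemistry is legible through a cloning artifact: only hydrolytic
  5'-phosphate ends ligate random co-purified fragments into chimeric
  reads, while the 5'-OH ends left by alkaline or BHB (transesterification)
  cleavage do not. A called 5' end whose reads carry *heterogeneous*
  clipped prefixes is therefore 5'-P; homogeneous prefixes mean a real
  upstream junction instead.

`ribotopo` implements this whole chain of inference, plus a synthetic-data
generator that simulates the library protocol (Bernoulli scission per bond,
2'-O-methyl protection, 20–40 nt size selection, ligation chimeras) from a
declarative operon architecture with full ground truth — so every stage is
testable end to end without touching real data.

## Worked example

```python
from ribotopo import run_pipeline

result = run_pipeline(scenario="permuted_with_excision", seed=1)
model = result.model

print(f"verdict: {model.verdict}")
for t in model.termini:
    print(f"terminus: {t['kind']} at {t['position']} ({t['chemistry']}, {t['support']} reads)")
for j in model.junctions:
    print(f"junction: {j['donor']} -> {j['acceptor']} ({j['verdict']}, {j['support']} reads)")
for e in model.excised:
    print(f"excised: {e['interval'][0]}-{e['interval'][1]} (coverage ratio {e['coverage_ratio']})")
print(f"mature segment order: {model.segments}")
```

prints

```
verdict: circularly_permuted
terminus: three_prime at 2926 (unknown, 212 reads)
terminus: five_prime at 2968 (P5, 179 reads)
junction: 3096 -> 1 (processing_junction, 83 reads)
excised: 2927-2967 (coverage ratio 0.0195)
mature segment order: [(2968, 3096), (1, 2926)]
```

Read it as: on a 3,096-nt LSU, the mature molecule starts at conventional
position 2968 (a 5'-phosphate end — hydrolytic cleavage), runs through the
old 3' end (3096), continues across a covalent junction into position 1 and
terminates at 2926; the 41-nt segment 2927–2967 was excised and turned over
(residual coverage ~2% of flanking). That is a circular permutation: the
129-nt block 2968–3096 is appended to the 5' end.

The same pipeline returns `linear`, `circular` or `fragmented` for the
corresponding simulation scenarios, and `insufficient_data` when profiling
an unprocessed precursor on a mature-sequence window (no free ends, no
junction in view).

A shell interface mirrors the stages:

```
ribotopo simulate --scenario permuted_with_excision --seed 1 --out sim/
ribotopo profile  --reads sim/reads.fastq --ref lsu.fa --out prof/
ribotopo call     --profile prof/ --out calls/
ribotopo junctions --reads sim/reads.fastq --ref lsu.fa --out junc/
ribotopo scan-bhb --ref operon.fa --out bhb/
ribotopo run-all  --scenario permuted_with_excision --seed 1 --out out/
```

## Layout

| module | contents |
| --- | --- |
| `ribotopo.synthetic_data` | operon builder, processing scenarios, fragment/library simulator |
| `ribotopo.readend_profiling` | seed-and-extend mapper, SAM I/O, read-end profiles, protection score |
| `ribotopo.end_calling` | native-end calls, excised-segment detection, hidden-break pairing |
| `ribotopo.junction_discovery` | circularized remapping, junction calls, 5'-P/5'-OH classification |
| `ribotopo.bhb_detection` | BHB motif search, flank annotation, cleavage/ligation prediction |
| `ribotopo.topology_report` | verdict assembly, JSON/Markdown/BED reports, end-to-end pipeline |

See `docs/methods.md` for the model, parameter defaults and limitations.
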