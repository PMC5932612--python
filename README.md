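# chainmap

Chained-fusion structural variant analysis of optical genome maps, with a
bundled rearranged-genome simulator.

## The problem

Cancer genomes — liposarcoma neochromosomes being an extreme case — can
carry *chained fusions*: derivative chromosomes stitched together from tens
of donor fragments of many chromosomes, with further inversions,
duplications and shattered micro-fragments at the junctions.  Short-read
sequencing sees each junction at base-pair resolution but cannot recover the
long-range order, orientation and copy structure of the chain; optical
genome mapping (fluorescent labels at nicking-enzyme motifs,
GCTCTTCN^ for Nt.BspQI, imaged along megabase DNA molecules) sees exactly
that long-range architecture but nothing below ~1 kb.  `chainmap` implements
the analysis that joins the two: it

1. digests a reference genome in silico into label maps (`chainmap.digest`),
2. aligns rearranged consensus maps *mosaically* — piecewise, to multiple
   reference loci in both orientations (`chainmap.align`),
3. classifies the junctions between aligned segments into insertions,
   deletions, inversions and intra-/inter-chromosomal translocations, and
   applies molecule-support, N-gap/SegDup, size and common-breakpoint
   filters (`chainmap.svcall`),
4. selects *fusion maps* (maps carrying a complex rearrangement), merges
   their donor fragments, deduplicates fusion junctions and checks
   concordance with external fusion lists (`chainmap.fusion`),
5. explains the unalignable gaps inside fusion junctions by path search
   through a graph of short-read breakend calls (`chainmap.traverse`), and
6. runs the accompanying statistics: insertion-vs-deletion size rank-sum
   test, breakpoint-clustering test against a uniform-placement null,
   SV-count vs chromosome-length correlation (`chainmap.stats`).

A synthetic-data module (`chainmap.simulate`) generates complete study
replicates — reference, derivative chromosomes with chained fusions and
scrambled junction content, noisy consensus maps/molecules, matched breakend
calls with quality scores, and a machine-readable truth set — so every stage
is testable against ground truth.  `chainmap.pipeline` orchestrates
end-to-end runs with checksummed, byte-reproducible artifacts.

The model and its parameters are documented in [docs/methods.md](docs/methods.md).

## The core computation

A query map is an ordered label-position vector; alignment is a local
dynamic program over label pairs scoring match reward m = 3 per paired
label, −1 per skipped label (≤ 4 per step), and a sizing penalty
((Δq − Δr)/(0.02·Δr + 500 bp))² per chained interval, reflecting the
platform's ~2% relative sizing error.  A maximum-score set of
query-disjoint local segments (weighted interval scheduling) is the mosaic;
every adjacency between consecutive segments is a candidate SV, classified
by chromosome, separation (> 5 Mb ⇒ intra-chromosomal translocation),
orientation, and query-vs-reference gap difference (indel size
= |Δq − Δr|).  Unaligned fusion gaps are traversed through the breakend
graph: junction edges are quality-filtered (> 500) sequencing calls, segment
edges are reference walks between compatible breakends, and a gap is
*supported* when an alternating path lands within 100 kb of both optical
anchors with |path length − optical gap| < 100 kb, the closest-length path
winning.

Breakend side convention (BEDPE strands map to joined sides):

    strand +  :   ----retained----][--partner--->      side = right
                                  pos
    strand -  :   <---partner----][----retained---     side = left
                                  pos

## Worked example

```python
import numpy as np
from chainmap import align, simulate, svcall
from chainmap.types import Thresholds

# a 4-chromosome toy genome and one derivative chromosome with 3 events
_, ref = simulate.simulate_reference(7, chrom_len=[3e6, 2e6, 2e6, 2e6], gc=0.41)
plan, derivative, truth = simulate.simulate_derivative(ref, seed=11, n_events=3)

# one noisy consensus-map measurement of the derivative
rng = np.random.default_rng(0)
cmap = simulate.noisy_map(derivative, simulate.NoiseModel(), rng, "map01")

mosaic = align.mosaic(cmap, ref, Thresholds())
for call in svcall.classify(mosaic):
    size = f"{call.size/1e3:.1f} kb" if call.size is not None else "--"
    print(f"{call.sv_type:22s} {call.ref_bp1[0]}:{call.ref_bp1[1]:>10.0f}"
          f"  ->  {call.ref_bp2[0]}:{call.ref_bp2[1]:>10.0f}  size {size}")
```

prints

```
deletion               chr01:    734540  ->  chr01:    823348  size 59.7 kb
deletion               chr01:   1371827  ->  chr01:   1454429  size 56.3 kb
inter_translocation    chr01:   2023524  ->  chr03:    596364  size --
```

The derivative was built as chr01 with two ~60 kb deletions fused to a
chr03 fragment (truth sizes 61.4 kb and 56.3 kb); the calls recover the
event types, breakpoints at the junction-adjacent labels, and sizes within
the platform's ~2% sizing error.

The same stages are available from the shell:

```
chainmap simulate --preset liposarcoma-like --seed 1 --outdir run/
chainmap digest ref.fa ref.cmap
chainmap align consensus.cmap ref.cmap out.xmap
chainmap call-sv out.xmap sv.tsv --ngaps gaps.bed --segdups segdups.bed
chainmap dedup sv.tsv fusions.tsv
chainmap run --config run.yaml
```

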