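# Methods

`chainmap` analyses complex genomic rearrangements (chained fusions) from
optical genome maps.  This note documents the models and procedures each
module implements, the parameters that matter, the design choices made where
the design was genuinely open, and what the bundled simulator does and does
not emulate.

## The measurement and its representation

Optical genome mapping images megabase-scale DNA molecules whose
nicking-endonuclease recognition sites (default Nt.BspQI, GCTCTTCN^) carry
fluorescent labels.  A map is therefore an ordered list of label positions
along a DNA segment — no sequence, but long-range structure.  All maps
(reference chromosome digests, consensus maps, molecules) are `LabelMap`
objects with 1-based inclusive bp coordinates, the Bionano CMAP/XMAP
convention; BED/BEDPE inputs are converted on read.

**In silico digestion** scans both strands for the recognition motif and
places a label at the nick coordinate (motif start + `nick_offset`,
default 7, projected onto forward coordinates for reverse-strand matches).
Overlapping occurrences each produce a label; matches containing N never
occur because the scan is an exact ACGT match.  The instrument cannot
resolve labels closer than about 1 kb, so `apply_resolution` merges runs of
labels closer than `min_sep` (default 1,000 bp) to their run mean —
single-linkage, idempotent, and applied to opposite-strand nick pairs within
resolution distance as well (the platform cannot distinguish them).  At the
default motif and GC 0.41 the expected raw density is ~9.1 labels/100 kb,
inside the 8–11/100 kb band typical for a human genome.

## Molecule filtering

`filter_molecules` keeps molecules with length ≥ 150 kb, ≥ 9 label sites,
and label-to-background signal-to-noise ratio above 2.75.  The length and
label-count comparisons are inclusive; the SNR comparison is strict, read
directly from the stated rule ("greater 2.75"); `snr_strict=False` flips the
boundary for users who prefer an inclusive reading.

## Mosaic alignment

The aligner is a Smith–Waterman-style dynamic program over *label index*
pairs.  Pairing a query label with a reference label earns `match_score`
(default 3); extending a chain from pair (i′, j′) to (i, j) pays
`skip_penalty` (default 1) per skipped label on either map (at most
`max_skip_labels` = 4 per step) plus a sizing penalty

((q_gap − r_gap) / (σ_rel · r_gap + σ_0))²,   σ_rel = 0.02, σ_0 = 500 bp,

which models the platform's relative interval-sizing error with a floor for
short intervals.  Chains may restart anywhere (local alignment), so a
rearranged query decomposes into several local segments.  Segments require
≥ `min_seg_labels` = 9 pairs (mirroring the molecule label-count filter) and
score ≥ `min_seg_score` = 25; nine exactly matching labels always pass.

For speed, all reference chromosomes are concatenated onto one axis with
50 Mb spacers (`ReferenceIndex`); the quadratic sizing penalty makes spacer
crossings impossible, so one DP per orientation replaces one per
chromosome-orientation pair.

Three refinements handle junction-adjacent pathologies that a plain local DP
gets wrong:

* **Iterative extraction.** High-scoring chains are read out greedily; query
  labels (not reference labels — duplicated query content legitimately
  re-aligns to one locus) are then masked and the DP re-run on the
  remainder, so a chain whose traceback strays into an already-extracted
  chain is recovered rather than lost.
* **End trimming.**  Local alignment with a generous match reward tends to
  extend a few lucky sloppy pairs past a true segment end into a
  rearrangement junction, dragging the breakpoint tens of kb.  Each chain is
  re-scored with a stern per-step reward (`end_trim_reward` = 1) minus its
  chaining penalty, and only the maximum-scoring contiguous subchain is
  kept.  Well-chained interiors are untouched; sloppy ends fall off.
* **Anchor-run gate.** A chain shorter than `anchor_exempt_pairs` = 15 must
  contain a run of ≥ `min_anchor_pairs` = 6 consecutive no-skip steps whose
  sizing penalty is ≤ 1.  A genuine locus produces such runs; a chain
  assembled by coincidence across scrambled junction content almost never
  does.  Long chains are exempt because the run test is noisy at 10% label
  dropout while false 15-pair chains are not observed.

`mosaic` then selects a maximum-score set of query-non-overlapping segments
by weighted interval scheduling.  Selection tolerates up to
`select_overlap_labels` = 8 shared labels so that interleaved
junction-region chains can coexist; surplus boundary pairs are afterwards
trimmed from whichever side chains them more poorly, restoring the ≤ 2
shared-boundary-label invariant of the final mosaic.  Ties are broken by
higher score, then lower reference id, then leftmost reference start, making
alignment deterministic.

## SV classification and filters

Each adjacent segment pair of a mosaic is one candidate SV:

* different chromosomes → inter-chromosomal translocation;
* same chromosome, separation > 5 Mb → intra-chromosomal translocation;
* same chromosome, opposite orientation (≤ 5 Mb) → inversion — one junction;
  a full inversion is two calls flanking one reference interval, and
  `pair_inversion_junctions` fills in the size only when both are observed;
* same chromosome, same orientation but order-reversed by more than
  `collinear_slack` (50 kb, covering boundary-label jitter) →
  intra-chromosomal translocation (it cannot be an indel, and the 5 Mb rule
  addresses separation, not order);
* collinear → insertion if the query gap exceeds the (signed) reference gap,
  else deletion, with size = |query_gap − ref_gap|.

Four filters annotate `filters_failed`; exclusion is their union, so the
outcome is independent of application order:

1. **Single-molecule support** — a call needs ≥ 10 molecules whose
   alignments span each breakpoint ± 2 labels on the consensus map.
2. **N-gaps** — any single-base overlap of the SV interval (indels: the full
   reference interval; inversions/translocations: each breakpoint ± 10 kb)
   excludes the call.
3. **Segmental duplications** — ≥ 20% overlap of the same intervals.
4. **Size and blacklist** — indels < 1 kb (strict) are below the platform's
   sizing resolution; translocations whose both breakpoints fall within
   10 kb of a known common-breakpoint pair (either pairing order) are
   flagged `_common`.

## Fusion maps, donor fragments, deduplication, concordance

A *complex genomic rearrangement* (CGR) is any translocation or inversion,
or an indel whose sample-vs-reference breakpoint distance exceeds 100 kb.
Fusion maps are consensus maps with ≥ 1 passing CGR, plus haplomap partners
of such maps.  Donor fragments are the merged reference intervals of
fusion-map segments, after dropping segments overlapping N-gaps by any base
or SegDups by ≥ 50%; supporting maps are counted with haplomap pairs as one.
The summed fusion-map alignment depth is the copy-number profile, and
breakpoints are tallied per SV type in 1 Mb windows.

Two fusion junctions are duplicates when both reference breakpoint pairs lie
within 10 kb (tested in both pairing orders, orientation ignored) and their
junction-gap sizes differ by ≤ 10 kb.  The predicate is not transitive, so
`dedup_fusions` takes its single-linkage closure (clusters can exceed 10 kb
diameter; this is stated in output metadata) — which also makes the result
independent of input order.  The compared size is the unaligned
junction-interval length.  Cluster representatives come from the longest
supporting map, then lexicographic id.  Concordance with an external fusion
list requires both breakpoints within 100 kb, either pairing order.

## Breakend-graph traversal of fusion gaps

Fusion junctions typically contain a stretch of query that aligns nowhere —
chains of fragments too small to align optically but large enough to carry
short-read breakpoints.  Quality-filtered breakend calls (> 500, strict)
define a graph: nodes are breakends (chrom, pos, side), junction edges are
the calls (weight = untemplated insertion length), and segment edges are
implicit reference walks from a `side=left` node rightward to a downstream
`side=right` node (weight = distance), instantiated lazily.

A gap traversal is an alternating junction/segment path from a breakend
within 100 kb of the gap's left optical anchor (on the matching side) to one
within 100 kb of the right anchor.  Path length = anchor offsets + segment
lengths + insertion lengths; both the anchor offsets and the inserted
untemplated sequence count toward the traversed length, since the traversal
spans anchor to anchor.  A path is feasible when |path_len − optical_gap| <
100 kb (strict).  Paths are simple in junction edges (a sequencing call is
evidence once) but may revisit chromosomes, since micro-fragments can be
duplicated.  The search is depth-first with a 15-junction cap and prunes
once the cumulative length exceeds gap + tolerance (length only grows).
Among feasible paths the minimum |path_len − gap| wins; ties prefer fewer
junctions, then the lexicographically smallest edge-id sequence.

## Statistics

* **Insertion vs deletion sizes** — two-sided Wilcoxon rank-sum
  (Mann–Whitney) with tie correction and continuity correction
  (`scipy.stats.mannwhitneyu`, asymptotic).  The statistic equals exact
  enumeration; the asymptotic p-value tracks the exact permutation p-value
  to within ~0.1 at single-digit sample sizes and tightly for realistic n.
* **Breakpoint clustering** — observed adjacent-breakpoint distances
  (per chromosome, pooled) are compared against uniform placement of the
  same per-chromosome counts over the covered intervals.  The covered
  support defaults to the merged donor fragments (breakpoints can only fall
  where maps align); a whole-genome alternative is a one-line change of the
  `covered` argument.  The two-sample Kolmogorov–Smirnov statistic is
  computed against a pooled null sample (`pool_reps` placements), and its
  p-value by Monte Carlo rank among `n_null` (default 199) independent null
  replicates measured identically — exchangeable by construction, with
  seeded uniform tie-breaking because the KS statistic is discrete, hence
  exactly calibrated.  Within-replicate spacings are not i.i.d. (their sum
  is constrained), which is precisely why the null distribution is
  simulated rather than taken from the asymptotic KS formula.
* **SV proportion vs chromosome length** — Pearson correlation; constant
  input is flagged degenerate rather than returning a spurious coefficient.

## The simulator and what it emulates

`simulate` is first-class, tested code that generates the study conditions
end to end and a machine-readable truth set.

* **Reference** — 20 chromosomes totalling ~59.8 Mb (chr01 = 8 Mb,
  chr12 = 6 Mb, chr15 = 5 Mb, seventeen at 2.4 Mb), i.i.d. sequence at
  GC 0.41, digested and resolution-merged.  The three long chromosomes are
  the designated donors, emulating the concentration of neochromosome donor
  sequence on a few chromosomes.  The scale (toy genome rather than GRCh38)
  keeps a full study replicate at a few seconds; all rule thresholds are in
  absolute bp and unchanged.
* **Derivatives** — each derivative chromosome is a chain of donor fragments
  (250–600 kb) linked by events drawn per junction: inter-chromosomal fusion
  (0.50), intra-chromosomal fusion at > 5 Mb separation (0.10), inversion
  (0.10), deletion (0.15), insertion (0.15); deletion/insertion sizes are
  uniform 20–300 kb.  Translocation and inversion junctions carry a
  scrambled micro-fragment chain with probability `junction_insert_p` = 0.8,
  of 2–10 pieces of 1–50 kb shredded from anywhere in the genome —
  dispersed, so their label patterns are unique rather than repetitive.
  Candidate micro-fragments carrying more than 6 labels are re-drawn: the
  defining property of junction content is that it is sub-alignable, and an
  occasional label-dense 50 kb piece would otherwise align and split the
  junction.  Insertions are realised as micro-fragment chains between
  collinear donors, so short-read breakpoints exist for them too.
* **Measurement** — consensus maps are direct noisy measurements of the
  derivative (window sampling for molecules): each inter-label interval is
  scaled by 1 + N(0, 0.02), labels are dropped i.i.d. at 0.10, false labels
  arrive at 8×10⁻⁶/bp, and 1 kb resolution merging is applied.  Assembly is
  out of scope, so haplomap pairs are two noise replicates of one derivative
  sharing a pair id.  A zero-noise model turns every map into an exact
  window.
* **Breakends** — every true junction of a translocation/inversion chain is
  emitted as a breakend call.  The marginal probability of a quality above
  the 500 cutoff is `detection` (default 0.95), but detection failures
  cluster by locus: each chain draws a "locus detectable" latent
  (`locus_detect_p` = 0.92) and junctions of detectable loci are always
  called, the rest at the conditional rate preserving the marginal.
  Clustered dropout is what real SV callers exhibit (coverage and
  mappability act locus-wise), and it is the regime consistent with an
  ~80% per-gap support rate at ~5–6 breakpoints per gap; independent
  per-junction dropout at the same marginal would make long chains almost
  never fully recoverable.  False calls are added at rate `fdr` (0.05)
  at uniform positions.

What the simulator does **not** emulate: real assembly (consensus maps are
measured directly, so assembly chimeras and phasing errors are absent);
sequence-level repeats and segmental duplications (the i.i.d. reference has
no homology structure, so region filters are exercised with synthetic
tracks); fragile-site and coverage biases; mechanism-faithful
breakage–fusion–bridge dynamics (only its copy-number/orientation
signatures).  Passing tests therefore demonstrate the correctness of the
analysis logic under the stated measurement model, not performance on real
cell-line data.

## Evaluation conventions

A called SV matches a truth event when the types agree (intra/inter
translocation interchangeable) and both reference breakpoints lie within
100 kb in either pairing order — the same tolerance the concordance rule
uses, and generous enough that a single dropped junction-adjacent label
(which moves the measured breakpoint to the next label, tens of kb at
~9 labels/100 kb) does not mask a genuine recovery.  At zero noise the
stricter ±1-label criterion is used.  Recall is measured on classification
plus the size filter; molecule-support confirmation is exercised separately
(it measures coverage, not detection).

Problem sizes used throughout tests and the acceptance script: the ~60 Mb
toy reference; 10 derivative maps per replicate with 4 events each
(recovery/recall, 20 noisy replicates); 4 derivatives × 5 fusion events × 5
replicates = 100 fusion gaps (traversal); 1,000 null replicates at
`n_null` = 199 (calibration); 100 randomized instances per brute-force
oracle; 60 noise-free unrearranged windows for the alignment specificity
property.

## Known limitations

* Alignment confidence is a raw DP score, not a calibrated p-value; scores
  are comparable within a run only.
* Sub-1 kb indels are out of scope (platform sizing limit), as is
  copy-number-aware genotyping.
* The intra-translocation rule keys on reference separation only; a
  deletion-like adjacency with an extreme query gap is still classified by
  the 5 Mb separation rule.
* `dedup_fusions` clusters by single linkage; a long chain of pairwise-close
  junctions collapses into one cluster whose diameter exceeds the pairwise
  tolerance.
* The breakend graph trusts call orientations; side-incompatible true
  junctions (e.g. mis-oriented calls) cannot be traversed.
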