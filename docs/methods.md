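# Methods

## Setting and model

`regap` targets single-end pyrosequencing-style re-sequencing: reads of
a few hundred bases from a genome whose reference is known, with the
goal of a gap-free consensus of the sequenced individual.  The obstacle
is repeats longer than the read length.  A read wholly inside one of
several (near-)identical repeat copies scores equally at every copy; a
single-best-placement mapper must pick one (here: the smallest
coordinate), so the interiors of all other copies receive no coverage
and the mapping consensus breaks there.  The method's premise is that
those breaks are *locally* repairable: the reads belonging to a repeat
region, assembled on their own, reconstruct it completely, because the
region's unique flanks pin its boundary-spanning reads and the interior
reads — wherever the mapper put them — are recoverable by sequence
overlap.

The pipeline has three stages, all deterministic for fixed inputs and
configuration.

### 1. Anchors and repeat regions

Mapped reads (built-in seed-and-extend mapper, or SAM / mapping-TSV
input) are piled onto the reference.  Maximal intervals with depth ≥
`min_depth` (default 3) become consensus contigs: per column, the
majority base over all reads aligned there, ties broken toward the
reference base and then alphabetically; zero-vote columns fall back to
the reference.  Contigs of length ≥ `gap_size` survive as **anchors**.
Everything else — the footprints of filtered short contigs together
with intervals that never reached `min_depth`, merged when adjacent —
becomes a **repeat region**.  Anchors and regions alternate and
partition the reference exactly.

The gap size is the method's central parameter (default 500 bp).  It
should sit at or above the read length: repeats shorter than a read are
resolved by mapping alone, so contig fragments shorter than that scale
signal a repeat break rather than genuine unique sequence.

### 2. Iterative local re-assembly

Each region's bin holds every read whose mapped interval intersects the
region ± `flank` (default: mean mapped read length, so boundary-spanning
reads are always recruited).  The bin is assembled by greedy
overlap-layout-consensus: among all pairs, in all four end-overlap
geometries (head/tail × orientation), the longest qualifying
suffix/prefix overlap is merged first; ties prefer the larger combined
length, then the lexicographically smallest id pair, then forward
orientation.  The merged sequence keeps the predecessor's bases over the
overlap.  Output contigs contained in a longer contig (within the
mismatch budget) are dropped — without contained-sequence removal,
reads strictly inside already-merged neighbours survive as redundant
singletons.

Overlap acceptance is substitution-only by default at the API level
(`best_overlap`): the longest suffix/prefix match with mismatch fraction
≤ `max_merge_mismatch_frac`.  The pipeline additionally enables an
**indel-tolerant mode** (`edit_overlaps`, default on): when exact
matching fails, the successor's first `min_overlap` bases are located in
the predecessor's tail by edlib infix alignment and the implied overlap
is verified by a prefix-anchored alignment.  This mode is what makes
assembly work under flow-chemistry noise — two reads drawn over the
same locus disagree at *either* read's indels, and an exact
suffix/prefix match survives only until the first such disagreement
(mean distance ≈ 1/(2·indel rate) ≈ 38 bp at the default error model,
i.e. *below* the minimum overlap).

After each assembly round, additional reads are recruited: any read in
the recruitment pool whose end overlaps a current contig end (same
four-geometry test) joins the bin, and the region is re-assembled from
scratch.  Because a recruited read can extend a contig by at most
(read length − `min_overlap`) per end, the number of rounds scales with
repeat span / read length; the cap `max_iters` (default 25) is a
convergence safety valve, not a tuning parameter.  Iteration stops when
no new read is recruited (a read-set fixpoint — assembly is
deterministic, so the contig set is then also fixed) or when a single
region contig end-overlaps both flanking anchors.

**Recruitment pool.**  Only reads whose mapper placement is *ambiguous*
— a second placement within `ambiguity_margin` (default 0.01) identity
of the best — are recruitable outside a region's own bin.  This is the
one deliberate restriction on an otherwise unrestricted
"recruit any overlapping read" loop, and it is load-bearing: at a repeat tip, the
longest-overlap read in the full read set is often a *boundary* read of
a different copy, and merging it grafts that copy's unique flank onto
the region (a chimera that then fails to stitch).  Boundary reads carry
unique flank sequence, score measurably worse at the wrong copy, and
are therefore unambiguous; interior repeat reads score identically at
every copy and remain recruitable.  At zero divergence the margin could
be 0; 0.01 tolerates reads whose flank overhang is a few bases.

Finally each region contig is polished once against the region's own
read bin: every read is infix-aligned to the contig (both
orientations), columns vote over {A, C, G, T, deletion} and majority
insertions are applied, ties keeping the existing base.  Pairwise
greedy merging keeps predecessor bases, so unpolished region contigs
carry roughly the per-read error rate; a single vote pass brings them
to anchor-level accuracy at ≥ 10x.

### 3. Stitching and metrics

Anchors and region contigs are walked in reference order.  At each
junction the best end overlap between the growing contig and the next
piece (four geometries, so reverse-oriented region contigs and
leading/trailing regions splice correctly) is applied; conflicting
overlap columns take the higher-mean-depth side's base, so anchors
outvote repeat contigs.  When a junction fails, a held region contig
may still bridge into the next anchor from the right side of the break;
otherwise the contig is closed and a new one starts — breaks produce
contig ends, never N runs.  With `circular`, a single final contig is
checked for a terminal self-overlap and linearised.

Metrics follow the standard definitions: NG(X) is the contig length at
which the descending cumulative contig length first reaches X% of the
genome size; LG(X) the number of contigs in that prefix; both are
undefined (reported `NA`, never 0) when unreachable.  Gap filling
counts pre-existing *inter-anchor* gaps (intervals strictly between
consecutive anchors; reference-end coverage taper is not a gap in this
sense) that are completely covered by one final contig's reference
projection (edlib infix alignment, best orientation).

## Synthetic data

The simulator plants repeat families — `dispersed` (separated identical
copies), `tandem` (head-to-tail), `inverted` (second arm the reverse
complement of the first) — into an i.i.d. uniform ACGT background, with
optional per-copy substitution divergence, copies kept ≥ 1 kb apart and
from the genome ends so each has unique flanking context.  Reads are
single-end: count `round(coverage · L / mean_len)`, starts uniform,
strands uniform, truncated-normal lengths (min 30).  Errors are applied
per base: substitutions at `sub_rate` (default 0.1%), insertions and
deletions at `ins_rate`/`del_rate` (default 0.5% each) multiplied by
`homopolymer_indel_multiplier` (default 3) inside homopolymer runs ≥ 3
— the signature error mode of 454/IonTorrent chemistry.  A `circular`
flag lets reads run across the origin of a circular molecule.

What the simulator does *not* model: flowgram-level signal, calibrated
quality scores, coverage biases (GC, priming), structural differences
between sample and reference, and paired ends.  Passing tests therefore
demonstrate repeat resolution under idealised uniform sampling; on real
data, coverage bias and sample/reference divergence would add failure
modes the tests do not probe.  Linear uniform sampling also leaves the
first/last few tens of bases of a genome uncovered in expectation
(mean ≈ read_length/coverage per end); assemblies of linear simulations
are judged with that in mind.

## Study fixtures and problem sizes

The test suite and the acceptance script use desk-scale fixtures chosen
to exhibit every mechanism: a 100 kb genome with one dispersed family
(2 kb unit, 3 copies — two broken interiors) plus one inverted repeat
(3 kb arms — one broken arm), re-sequenced at 15x (zero-noise) and 20x
(default error model) with 400 b reads; a 20 kb / 2 kb-arm
inverted-repeat fixture for the coverage sweep (1–20x, 3 replicate read
sets); a repeat-free 100 kb genome at 40x (10,000 reads) for mapper
recovery.  These sizes keep a full suite run in minutes on one core
while leaving each repeat several times longer than a read.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere internally; SAM input is
  converted on read.
- Mapper: k = 15 seeds on every read position, diagonal binning at the
  band width (30), all bins within 2× of the best evaluated, edlib
  semi-global extension; identity = match columns / alignment columns;
  ties broken to the smallest coordinate, then '+'.  Reported
  `secondary_identity` is the best alternative placement seen.
- `max_merge_mismatch_frac` defaults to 0.05: an overlap between two
  reads accumulates both reads' errors (≈ 2·1.4% at the default model),
  so a 2% budget would reject most true noisy overlaps.
- Greedy tie-breaks, consensus tie-breaks, and output ordering are
  fully specified so byte-identical reruns are a contract, not an
  accident.
- Degenerate inputs: zero reads → empty assembly with zeroed metrics;
  empty region bins remain gaps; coverage 0 → zero reads (not an
  error); all-N references index to nothing.

## Known limitations

- Repeat copies with zero divergence are reconstructed from a pooled
  interior read stock; the per-copy sequences are correct only because
  they are identical.  Divergent copies (≳ the ambiguity margin) keep
  their reads pinned to the right locus and resolve per-copy, but
  divergence *at* the margin boundary can mis-pool reads.
- Greedy OLC has no repeat-graph reasoning; a repeat region containing
  *internal* structure longer than a read and absent from the flanks
  can still collapse.
- Single reference sequence per run; no split/chimeric read alignments;
  no scaffolding.
- The mapper is built for references up to a few megabases; its Python
  k-mer index is not meant for mammalian-scale genomes.
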