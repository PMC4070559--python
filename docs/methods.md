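# Methods

`vdjwin` identifies and quantifies lymphocyte clones in V(D)J
recombination reads by a two-stage procedure: alignment-free junction
*window* detection per read, then per-clone analysis (representative
sequence and dynamic-programming V(D)J designation). This note records
the model, the parameters that matter, the numerical conventions, what
the synthetic data does and does not emulate, and the design choices
made where the design was genuinely open.

## Germline model and index

A locus is a set of named germline V genes, J genes, and (for
VDJ-recombining loci) D genes. Sequences are uppercased with U→T at load
time so the index sees one alphabet. The k-word index is built over the
forward strands of the V and J sets only — D genes are too short and too
diverged to contribute reliable words and are never indexed. Each
seed-masked word is labeled V, J, or AMBIGUOUS (present in both sets);
words containing N are skipped at build and at query time, a
conservative choice that avoids fabricated labels. For seed weight
k ≤ 12 the index is a flat 4^k table (16 MiB of labels at k = 12); above
that a hash map is used. Both storages answer identically; building
takes O(r + 4^k) for a germline of total size r and is fast enough that
persistence (JSON dump/reload) is optional.

Spaced seeds trade contiguity for substitution tolerance: the default
TRG seed `#####-#####` (weight 10, span 11) ignores the middle base of
an 11-mer, so a read word still matches its germline word when a
substitution falls on the ignored position. Defaults per locus: weight
10 for TRG; weight 12 (`######-######`) for TRB/IGH; weight 13
(`######-#######`) for TRA. Only the weights of the non-TRG seeds are
conventional; their patterns here extend the weight-10 shape with a
single central don't-care, and any pattern can be supplied explicitly.

## Window prediction

Scanning a read classifies the word at every start position, forward and
reverse-complement. A word answering on exactly one strand with label V
or J is *informative*; AMBIGUOUS labels and two-strand conflicts are
kept in the scan output but never count as evidence. The strand with the
majority of informative hits wins; a minority of at most
`strand_tolerance` (default 1) stray hits is dropped, more discards the
read (`UNSEG_STRAND_CONFLICT`) — a strict zero would throw away reads
containing a single chance hit. Reads lacking V or J evidence are
`UNSEG_TOO_FEW`; V words occurring after J words (in the oriented read)
are `UNSEG_ORDER`. This order check is also what protects accuracy at
high mutation loads: a chance J-labeled word inside the V region almost
always precedes genuine V words and discards the read rather than
mislocating its center.

With e the last base covered by the last V word and s the first base of
the first J word, the predicted junction center is ⌊(e+s)/2⌋ (tie broken
by floor; the window must lie between the last V word and the first J
word, and "centered" is made exact by this convention). Overlapping
last-V/first-J words (e ≥ s) are allowed — junction deletions can
legitimately bring them together. The window
`read[center−w/2, center−w/2+w)` is reported in V→J orientation; windows
that would cross a read end are discarded (`UNSEG_WINDOW_OOB`) rather
than clipped, because clipped windows would break exact-match
clustering. w defaults to 40 bp for VJ loci and 60 bp for VDJ loci,
whose two N regions plus D need more room; w must be even.

## Clones

Without sequencing errors, all reads of one clone yield the identical
window, so the default clone definition is exact window identity — the
most stringent definition available, deliberately preferring to split
what belongs together over merging what does not. Ordering is
deterministic everywhere: read count descending, then window
lexicographic. Optional merging compares windows by a unit-cost edit
distance whose operations are reported in three classes — substitutions,
plain indels, and homopolymer indels (an indel whose base equals a
neighbouring base in the other sequence, the signature error of
flow-based sequencers) — each bounded separately, all bounds 0 by
default. The merge pass is greedy against the seed windows of
already-formed clusters in abundance order; chains are intentionally not
followed (a window two edits from a cluster seed starts its own
cluster). Alignment ties in the distance computation resolve toward
fewer indels, then leftmost edits, so the reported triple is
reproducible. User-specified window pairs merge unconditionally before
the automatic pass. Selection keeps the `top_n` (20) most abundant
clones with at least `min_reads` (10) reads, plus any *followed* window
regardless of rank; dropped clones still count toward the segmented
total used for abundance fractions.

## Representative sequence

One sequence per selected clone receives the costly designation. k-mers
(k = the locus seed weight by default) are counted as present-per-read,
matching a threshold expressed as a fraction of the clone's reads
(default 0.5, T = ⌈threshold·size⌉). Maximal runs of read positions
whose every k-mer reaches T are candidate regions; the longest candidate
fully containing the clone window wins (ties: earliest read, then
leftmost), falling back to the longest candidate merely overlapping the
window, then to the window string itself. Full containment is preferred
over the weaker "overlaps" requirement because the designation step
needs germline flanks on both sides of the junction.

## V(D)J designation

For a representative of length ℓ the designation runs in O(ℓr): every V
gene is aligned semi-globally against the sequence (match +2, mismatch
−1, linear gap −2; free leading trims on both sequence and gene,
implemented with a local-alignment floor so an alignment may start at
any offset pair; the gene's 3' trim is free and reported as deletions),
every J gene mirrored from the right, and the split x maximizing
bestV(x) + bestJ(x) fixes v_end < j_start with the bases between them as
the N region. Equal-score ties prefer the shortest alignment (earliest V
end, latest J start): score-neutral gap+match extensions past the
junction would otherwise be chosen and make the printed deletion counts
inconsistent with the sequence. Designations below `min_score` (10) on
either side flag the clone as window-only rather than inventing gene
calls. On VDJ loci a D gene is then placed inside the N region with the
same scoring, accepted at `d_min_score` (8, about four net matches),
splitting N into N1/D/N2.

Attribution near the junction is inherently ambiguous when junction
bases coincide with germline ends. The reported designation is therefore
required to be *reconstructible*: when the chosen V and J genes match
the sequence exactly up to a junction insert of at most
`exact_junction_max` (25) bases, the deletion counts and N region are
read off that exact decomposition, which rebuilds the sequence
byte-for-byte; otherwise (mutated representatives) the scored alignment
boundaries are used. The designation's `score` field is always the
alignment-score maximum, independent of this attribution choice.
`reconstruct_from_designation` inverts the notation and is used both by
the simulator and by tests.

## Simulator

The generator emulates a TRγ-like locus: uniform-ACGT V genes of
250–310 bp, J genes of 40–70 bp, optionally D genes of 10–35 bp,
regenerated (bounded retries) until the locus seed yields an index with
zero AMBIGUOUS words, as real TRγ does under the weight-10 seed.
Recombinations draw genes uniformly, junction deletions uniformly in
[0, 8] and N lengths uniformly in [0, 10] — plausible ranges for TRγ
junctions, configurable, and parameters rather than biological claims.
Clones are rejection-sampled until each full sequence is distinct and
individually detectable (its error-free sequence yields a valid,
clone-unique window under the locus defaults): a clone the junction
assay cannot see is not a usable ground-truth clone, and this guarantee
is what makes the error-free round trip (exact recovery of all clones
with truth-equal counts) a testable contract.

Reads are drawn per an abundance profile (explicit fractions or
`geometric(ratio)`, default geometric(0.5) over the clones), as full
amplicons or uniform random fragments. Substitutions are i.i.d. per base
(never restoring the original base) at rates chosen per experiment —
1–2% emulates sequencer-plus-low-hypermutation noise, 6–9% heavy
hypermutation; homopolymer indels (±1 base per run of length ≥ 2, rate
per run) emulate flow-sequencer chemistry. Strand is randomized by
default. Ground truth records each read's clone and its junction center
in V→J orientation, with indels before the junction shifting the
recorded center. Everything derives from one integer seed;
byte-identical outputs are a tested contract.

What the simulator does **not** model: PCR amplification bias and
chimeras, primer/adapter sequences, clustered (AID-targeted)
hypermutation, quality-score structure, concatenation artifacts, and
germline allele polymorphism. Passing tests therefore demonstrate the
algorithmic contracts and error-model robustness, not performance on any
particular library preparation.

## Problem sizes and numerical conventions

The accuracy analyses in `scripts/acceptance.py` use 5 V / 3 J genes, 10
clones and 10,000 amplicon reads per dataset — sizes chosen so the whole
script re-simulates and re-analyses everything from scratch in seconds
while leaving binomial noise on a 99% fraction near ±0.2 points.
Property suites use 10,000 randomized index queries, 1,000 randomized
designation instances against a brute-force split enumeration, ≥ 50
clones for the exact-window invariant, and 100,000 reads for abundance
recovery down to clone fractions of 10⁻³ (4 binomial SD band). All
coordinates in outputs are 0-based half-open; FASTQ qualities are read
and ignored; all stages are deterministic given inputs and
configuration.

## Known limitations

- Clone windows, not full junctions: two rearrangements identical
  across the w-window (rare, likelier at small w or on low-diversity
  loci) are merged.
- The greedy merge is order-dependent by design (deterministic, near
  linear); it is not a globally optimal clustering.
- The designation is a first hint, not an IMGT-grade junction analysis:
  no productivity/frame calls, no per-allele mutation profiling, and
  boundary attribution inside the junction remains conventional.
- Reads whose window would cross a read end are dropped, so very short
  fragments reduce sensitivity rather than yielding partial windows.
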