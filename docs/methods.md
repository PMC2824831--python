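# Methods

This note documents the models, rules and numerical choices behind estkit:
what each stage assumes, which parameters matter, and what the simulator
does and does not emulate.

## The screening cascade

A read enters as bases plus per-base phred scores and leaves with exactly
one terminal status: `PASS`, `INSERTLESS`, `CONTAMINANT`, `LOW_QUALITY`,
`LOW_COMPLEXITY`, `SHORT` or `DUPLICATE`. Stages run in this order: vector
masking → insertless classification → quality trimming → first length
filter → polyA/T trimming → second length filter and low-complexity filter
→ per-clone dedup → sister propagation → contaminant screen (followed by a
second, idempotent propagation pass so contaminant states reach sisters).
No stage ever returns a non-`PASS` read to `PASS`, and re-running the
cascade on its own trimmed output changes nothing.

**Vector masking.** End-anchored comparison of the read's prefix/suffix
against every offset of each vector sequence (and its reverse complement),
keeping the longest run with mismatch rate ≤ 5 % and length ≥ `min_match`
(20 bp); interior hits are found by exact 12-mer seeding with
mismatch-tolerant extension. Two robustness rules compensate for frayed
base calls near the read start: an unmasked 5′ stub shorter than
`min_match` before the first hit is folded into the mask (it cannot be
confirmed as insert), and unmasked islands shorter than `min_match`
between hits are bridged. Without these, occasional error clusters in the
first ~50 bases fragment the vector hit and push good clones into the
second insertless clause below.

**Insertless rule.** A clone read is insertless when the 5′-anchored
masked run is ≥ 200 bases, or when it is shorter and the unmasked stretch
immediately following it is < 100 bases. This is a pure function of those
two run lengths; the test suite checks it exhaustively against the
two-clause definition.

**Quality trimming.** The kept interval is the longest one in which every
full 11-base window has mean phred ≥ 15 (candidate intervals shorter than
the window are judged by their own mean); ties go to the 5′-most interval.
Trimming operates within each unmasked segment, and the best segment wins.
An equivalent formulation — enumerate all O(L²) intervals and test the
window condition — serves as the independent oracle in tests. Reads whose
best interval is shorter than 100 bases become `LOW_QUALITY`.

**PolyA/T tails.** A tail is a run of ≥ 12 A's starting within 50 bases of
the 3′ end (or T's ending within 50 bases of the 5′ end), tolerating one
non-target base per 12 bases of run, with both run boundaries required to
be the target base so the tolerance cannot eat flanking insert sequence.
The read is flagged and the run is trimmed through its end; detection runs
twice so a read can lose both a 3′ A-tail and a 5′ T-tail. Tails are
searched after quality trimming because the decayed 3′ region often hides
the tail beyond the kept interval.

**Low complexity.** The fraction of positions covered by homopolymer runs
≥ 5 or perfect tandem runs of a 2–3-mer with ≥ 4 copies (union of covered
positions over length). This run-coverage definition was chosen over a
DUST-style score because it is exactly brute-forceable, which makes the
filter auditable; reads above 50 % coverage are removed. Length and
complexity are re-checked after tail trimming (`SHORT` /
`LOW_COMPLEXITY`).

**Clone-level rules.** When a clone was resequenced, the passing read with
the longest kept interval is retained per direction (ties to the
lexicographically smaller id, for determinism); the rest become
`DUPLICATE`. Insertless and contaminant states are clone-level properties
and copy to the sister read; quality-type failures are read-level and do
not. When sisters carry *different* propagating states each keeps its own
and a warning is logged. Contaminant screening marks any read with a
strong hit (E ≤ 1e−5 by default) to a listed subject id.

## Clustering and consensus

**Overlap detection.** Local alignment with match +1, mismatch −2, gap −3
(via Biopython's `PairwiseAligner`); the penalty ratio makes the 98 %
identity cut sharp — one mismatch costs three matches of headroom.
Identity is identities over aligned columns (gap columns included); the
span is the column count, and overlaps spanning < 32 columns are
discarded. Candidate pairs must share an exact 16-mer (strand-neutral
bucket keys), and pairs already connected through earlier edges are not
re-aligned — a pure optimisation that cannot change the resulting
connected components.

**Double linkage.** Clusters are merged when ≥ 2 distinct clones each
have one end read in one cluster and the sister in the other; components
of that graph define the merged clusters. Requiring two bridging clones
means a single chimeric clone cannot fuse unrelated clusters. Bridging is
counted in clones, not reads, so a resequenced clone still counts once.

**Consensus.** The longest member seeds the layout; remaining members are
placed by pairwise alignment (better strand wins) when they match at
≥ 90 % identity, and placement proceeds in rounds against the growing
consensus so chains of tiled reads coalesce even when they never touch the
backbone directly. Columns are resolved by majority vote, ties toward the
alphabetically first base; flanks extending past the aligned region are
placed ungapped, which is exact for substitution-only differences and a
reasonable approximation otherwise. Members failing the identity threshold
seed further contigs recursively, so every cluster member lands in exactly
one contig. This is deliberately not a full assembler: no quality-aware
alignment, no clipping, no scaffolding.

## Markers

The canonical form of an SSR motif is the lexicographic minimum over all
cyclic rotations of the motif and of its reverse complement; homopolymers
and periodic motifs (e.g. ACAC as a 4-mer) are invalid and rejected. Under
this equivalence there are exactly 4 dinucleotide, 10 trinucleotide and 33
tetranucleotide classes (verified by exhaustive enumeration). Detection
reports maximal perfect tandem stretches meeting the copy minima
(6/5/4 for 2/3/4-mers — conventional microsatellite-survey settings,
configurable); a stretch may end mid-copy, with the interval covering the
whole stretch and `copies` counting full copies. Overlapping reports of
one locus at different unit lengths resolve to the smallest unit.
Interrupted (imperfect) repeats are out of scope.

SNP calling takes per-column member bases of a contig alignment: depth ≥ 4
after excluding gaps and N, exactly two observed bases, both seen ≥ 2
times; columns with three or more bases are skipped and logged. Transitions
are {A,G} and {C,T}; everything else is a transversion. SSR location
relative to a CDS interval is decided by the hit midpoint on the
strand-oriented axis, so straddling hits are assigned, not split.

## Homology-table post-processing

Strong matches are rows with E ≤ 1e−5 (`EVALUE` mode) or bit score ≥ 40
(`BITSCORE` mode, inclusive). Best hits are chosen by highest bit score,
then lowest E-value, then lexicographically smallest subject id — a total,
deterministic order. Full-length assessment uses the single best protein
alignment per query: the subject misses 3 × (s_start − 1) nucleotides of
coding sequence on the N-terminal side and 3 × (s_len − s_end) on the
C-terminal side, and the query is full-length when its unaligned flanks
cover both; a reversed query (q_start > q_end in the tabular dialect)
swaps which flank faces the N-terminus. Adding sequence to both query ends
can therefore never flip a full-length verdict to negative. Ribosomal
hits are split out by a case-insensitive "ribosomal protein" substring in
the subject description (configurable pattern).

For three-way reciprocal best hits, (a, b, c) is a triad iff all six
within-triangle best-hit arrows are mutual. Venn pairwise regions count
reciprocal best pairs for a species pair that do not extend to a triad,
and exclusive regions count sequences seen in the tables that are in no
reciprocal pair; this pairwise-region convention is output metadata — other
definitions are possible and the triad set itself does not depend on it.

Report-table percentages are rounded half-up to one decimal. Aggregated
totals rows sum the count columns and recompute percentages from the
pooled counts; a totals percentage is never an average of per-library
percentages. Externally supplied report rows whose category counts do not
sum to their stated cluster total are accepted with a logged warning so
their percentage arithmetic can still be audited.

## The simulator

`simdata` emulates a directional cDNA library: each clone samples a
transcript (uniformly for normalized libraries, rank^−1 Zipf weights
otherwise — a statistical stand-in for duplex-specific-nuclease
flattening, not a chemistry model), takes a 5′-truncated insert, and emits
a 5′ read (vector + insert…) and a 3′ read (vector + reverse complement of
insert + polyA tail). Quality follows a linear decay (start 40,
0.05/base, Gaussian noise sd 3, floored at 2), which collapses past ~500
bases and exercises the trimmer. Substitutions are drawn per base at the
rate the phred score promises (10^(−q/10)) scaled by `error_rate`
(1.0 = as promised, 0 = error-free), so errors concentrate in the decayed
tail as they do in real basecalls. Planted artifact fractions
(insertless, contaminant, low-complexity clones) are honored exactly as
rounded counts, with the ground truth returned alongside the reads.

Transcripts are random sequences rejection-checked to < 90 % pairwise
identity; they have no splice forms, no shared domains, no GC structure,
and the simulator produces no chimeras, no indel errors and no
chromatogram-level artifacts. Passing tests on simulated data therefore
demonstrates algorithmic correctness under the stated read model, not
robustness to every failure mode of real trace data.

Default problem sizes used by the test suite — 8–50 transcripts, 40–1,000
clones — were chosen as the smallest scales at which the pipeline's
behaviour (double-linkage merging, abundance evenness, artifact-rate
recovery) is statistically unambiguous.

## Known limitations

* The assembler is substitution-oriented; members whose differences from
  the consensus are dominated by indels may be placed suboptimally or
  seed separate contigs.
* Vector masking assumes vector at the read ends (as in directional
  libraries); a vector fragment buried mid-read with no exact 12-mer seed
  can be missed.
* SSR detection reports perfect repeats only.
* Full-length assessment trusts the single best alignment; chained HSPs
  from frameshifted queries are not combined.
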