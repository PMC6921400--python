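# Methods

This note documents the model and procedure implemented by `varatree`, the
parameter defaults and why they hold their values, the numerical and design
choices made where the design was genuinely open, what the synthetic data
emulate, and the known limitations.

## Problem setting

Seed-and-extend read alignment against a linear reference treats every
difference between read and reference as an edit. When a read spans a
variant that is already catalogued — a SNP from a population panel, a known
indel — those edits are spurious: they inflate the edit distance, depress
mapping quality, and for indels beyond the aligner's edit budget they cause
soft clipping or unmapped reads. `varatree` charges known variation zero
edits during extension while keeping the genome index linear: variation is
materialized only locally, per seed, in small throwaway structures.

## The variation-aware reference

Each reference position carries a 4-bit allele mask (one bit per
nucleotide). Loading a FASTA sets exactly the reference base's bit;
integrating a variant set ORs each SNP alternate's bit into its site. The
reference base is never altered, so decoding always reproduces the input
FASTA. A read base matches a site iff `mask & bit(base) != 0` — this single
operation is what makes SNP-tolerance free inside all inner loops.

Insertions and deletions cannot be expressed per-site; they are stored in a
separate per-chromosome interval index ("ALT-seq" records) queryable by
half-open window. Record normalization converts VCF's anchored
representation (`REF=A, ALT=ATT`) to anchorless events at the first
affected base; multi-allelic lines split into independent records; complex
substitutions and symbolic alleles are skipped with a log message.

Decisions the input formats leave open, resolved here:

* **Non-ACGT reference bases** get an all-bits mask (they never block a
  window) but are excluded from seeding; a read `N` encodes to `0` and
  matches nothing. Permissive reference / strict read avoids inflating
  mapping confidence from ambiguous sequence.
* **Coordinates** are 0-based half-open everywhere internally; conversion
  happens once at the VCF boundary (input) and the SAM boundary (output).

## The variation tree

For one side of one seed, the extension windows (there may be several when
the seed hits repeated loci) are inserted into a radix trie keyed on the
site codes: nodes are maximal shared fragments, children of a node are
ordered alphabetically by leading reference base, and each window spells
exactly one root-to-leaf chain. With one window and no variants the tree
degenerates to a single chain.

Regional INDELs attach to the chain nodes covering their position. SNPs are
*not* tree edges — they already live inside the node labels' site codes, so
only INDELs multiply paths. A deletion may end beyond the window; a pseudo
node holding the out-of-window reference bases is created so the deletion
has a well-defined end node, and the haplotype resumes from the window's
context when available.

**Paths.** Every subset of non-overlapping attached INDELs on one window
realizes a haplotype path. Subsets are enumerated in (size, id-tuple)
order — variant-free first — giving deterministic ids; paths realizing an
identical code sequence are de-duplicated keeping the smallest id, with all
source windows kept in the survivor's provenance. Two insertions at the
same point, or any two variants with overlapping reference intervals, never
share a path (their composition is undefined). Each path precomputes its
realized mask sequence, a coordinate map (reference offset per haplotype
base, `-1` for inserted bases), and its step list (node fragments and
variant edges) for the traversal kernel.

One boundary rule deserves note: the interval index's window query is
strictly half-open (an insertion at `pos == end` is not returned), but tree
construction *accepts* an insertion sitting exactly on a window's right
edge. A left-of-seed window ends at the seed junction, and an insertion at
that junction belongs to the left extension; without the inclusive edge it
would be unreachable.

## Breadth-first traversal (VATR)

A queue of frontier entries extends an exact, SNP-tolerant match along all
live paths. Three entry kinds exist — the successor node of a fully matched
node, a newly reached variant edge, and the end node of a deletion edge —
and every (path, step, offset, read offset) state is processed at most
once. Deletion edges consume zero read bases; insertion edges match the
read against the inserted allele exactly (inserted bases carry single-bit
codes; there is no SNP tolerance inside an allele — the 4-bit codes exist
only at reference sites). An entry leaves the queue into one of three
buckets: `mismatch`, `hap_end` (path exhausted, read remaining), or
`ran_to_end` (read exhausted).

## Generalized Landau–Vishkin (VARA)

The classical algorithm stores, for edit distance `e` and diagonal `d`, the
farthest-reaching match `L[e][d]`, seeded from
`max(L[e-1][d]+1, L[e-1][d-1], L[e-1][d+1]+1)` and then slid along exact
matches; the least `e` that consumes the read is the edit distance, in
O(e·n) cell updates. The generalization replaces the single sequence with
the path set: each cell holds per-path farthest-reaching states (a 3-D
structure), the slide is the SNP-tolerant match run over the path's
realized haplotype, and when several transitions reach the same path on the
same diagonal only the longest extension survives (ties: smaller resume
cursor, then smaller path id). Candidates are emitted at the least `e` at
which any path consumes the read (optionally exhaustively up to `e_max`),
ordered by (e, fewest taken variants, path id) — parsimony in variant usage
breaks ties.

Two frame conventions were possible for `d`: reference frame (variant edges
displace the diagonal by ±k at zero cost) or haplotype frame (variants are
already applied in the path's realized sequence, so its diagonal is
ordinary). The implementation uses the haplotype frame — the two are
equivalent because variant edges cost nothing, and the reference
displacement is recovered exactly from the path's coordinate map during
CIGAR restoration. Because the paths are pre-enumerated, the per-path slide
is the degenerate form of the breadth-first traversal; the queue kernel is
exercised directly by its own tests and by the tree machinery.

Alignment orientation is semiglobal: the read end adjacent to the seed is
pinned to the window boundary and the far end is free. A `global` mode
(both ends pinned) also exists; it is the mode in which the degenerate
zero-variant case coincides exactly with the classical algorithm on a
string pair, and it is used by the equivalence tests.

**Parameters.**

| parameter | default | rationale |
|---|---|---|
| `e_max` | ⌈0.06 · read length⌉ | covers Illumina error rates plus small unindexed variants |
| large-variant length | 4 bp | 1–3 bp indels are ubiquitous; the prune targets large ones |
| large variants allowed | 3 per 100 bp (⌈3·len/100⌉) | several structural variants in one short read are implausible |
| path cap | 4096 | combinatorial safety valve; overflow retries with fewer variants per path and flags the result as pruned |
| max variants per path | 6 | with non-overlap and the window sizes used, deeper stacking is unreachable |

## CIGAR restoration

A candidate's CIGAR is against the variant haplotype. Composition with the
path's coordinate map produces the reference CIGAR: matches over inserted
bases become I; ALT deletions of inserted bases vanish; reference positions
skipped between consecutive consumed bases (taken deletions) materialize as
D; and adjacent insertion/deletion runs produced at variant junctions are
paired base-by-base into M (match-or-mismatch — the SAM `M` dialect is used
throughout, never `=`/`X`). The pairing pass is single left-to-right:
leftovers are not re-paired with later runs, which keeps the composition
deterministic and position-stable. Edge deletions are trimmed (they do not
anchor an alignment); POS is the leftmost reference base consumed, and an
alignment beginning inside an insertion anchors on the first reference base
after it. Soft clips pass through unchanged.

## The mapper

Seeding is a plain k-mer hash over the reference (k = 16, sampling stride
8, repeat cap 64, reverse strand by read reverse-complement) — deliberately
ordinary, since the contribution of the method is the extension stage.
Seed hits are grouped per (chromosome, diagonal), widened into exact
SNP-tolerant blocks, and diagonals within 50 bp merge into a cluster (an
indel shifts the diagonal by its length, so cluster width bounds the indel
reach).

The dispatch rule: if the best block covers the whole read, emit the exact
candidate. Otherwise count the read bases unexplained by exact blocks *on
the anchor diagonal* — coverage contributed by shifted diagonals is itself
the indel signal and must not suppress the trigger. If at least `g = 5`
bases are unexplained the side windows get regional variants and the full
variation-tree extension; below that, the same kernel runs on a
variant-free window, which is plain banded extension for mismatch-only
reads. Two implementation details matter for correctness near junctions:

* an exact block can overrun an insertion point by a few chance-matching
  bases, hiding the junction *inside* the block where neither side window
  can take the variant — blocks are trimmed back to any insertion junction
  within 12 bp of an edge (the chance of a longer overrun decays as 4^-n);
* deletions partially overlapping a window boundary are applied clipped;
  the remaining deleted span is emitted as D at the splice, which leaves
  the reported position exact.

Pairing prefers proper FR pairs with insert within `mean ± 4·sd`
(500 ± 25 model by default), minimizing summed edits plus clipped bases;
a mate with no candidates is rescued by searching insert-anchored windows
(± 4·sd, widened by one read length) next to its mapped partner, using
index hits restricted to the window plus brute-force probes — this is what
places reads whose own seeds are all repeat-flagged. Mapping quality is a
monotone gap score, `40·(s2−s1)/max(1,s2)` capped at 60 and 0 on ties,
where `s1`, `s2` are the best and second-best pair scores; the data leave
no principled mapq definition, so the score is config-exposed. If the best
candidate explains less than the whole read within `e_max`, the unexplained
terminal run is emitted as S. NM counts edits against the *reference*
(taken variants included); the reported `e` counts only unexplained edits.

## Synthetic data

The generator emulates a variant-incorporated-genome benchmark at desk
scale. Defaults are the study conditions used by the acceptance runs: a
200 kb uniform-random single-chromosome genome; SNPs at 1e-3/bp and
insertions and deletions at 1e-4/bp each, non-overlapping, with geometric
lengths (p = 0.3) truncated at 20 bp; 20,000 read pairs of 100 bp (or
10,000 of 250 bp) drawn FR from the *variant-applied* genome with insert
N(500, 25) and i.i.d. base errors at 0.2%; constant base qualities. Truth
records carry original-reference coordinates of each end's leftmost aligned
base (a read starting inside an insertion anchors on the base after it,
matching the aligner's POS convention) and the ids of variants spanned.
A dense-region preset (5 kb at 10× variant density) emulates
high-diversity-region analyses. Everything is deterministic under the
seed.

What the generator does *not* emulate — and hence what passing tests do not
show: empirical error profiles (quality-dependent, indel sequencing
errors), GC and coverage bias, diploid genotypes and phasing, repeat
structure of real genomes (uniform-random sequence is nearly repeat-free,
so seeding ambiguity is much rarer than on a real genome), and structural
variation beyond simple indels. Accuracy numbers on these data are
therefore upper bounds on real-data behaviour; the algorithmic guarantees
(oracle equivalence of the extension, CIGAR round trips) are
scale-independent.

## Evaluation

An end is scored correct when chromosome, strand, and position within a
tolerance (default 10 bp) match truth; unmapped ends are incorrect.
Soft-clip counts are SAM records containing S, with a sub-count restricted
to ends whose truth spans at least one variant. The tolerance parameter
exists because position equivalence under indels is representation-
dependent; 10 bp is well below the insert scale yet above indel-placement
ambiguity.

## Known limitations

* Overlapping catalogued variants never combine on one path; nested or
  conflicting records are offered only individually.
* Unit-cost Levenshtein scoring: no affine gaps, no base-quality weighting.
* Single-end mode exists only as the degenerate unpaired fallback.
* The seed index is rebuilt at map time from the stored reference (cheap at
  the scales targeted); only the variation-aware reference and the INDEL
  records persist on disk, under a format-version header.
* SAM output only (no BAM/CRAM), primary alignments only, no XA-style
  multi-mapping report.
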