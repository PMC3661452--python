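# Methods

`bovigh` reimplements, as a tested pipeline, the analysis workflow used to
annotate the bovine immunoglobulin heavy-chain (IGH) locus and to
characterize expressed heavy-chain variable regions across isotypes: the
germline scan with functionality classification, expressed V(D)J
assignment with IMGT-style complementarity-determining-region (CDR)
delineation, CDR3H length-group and composition analysis with junction
annotation, and neighbor-joining family phylogenetics. Because the
original genomic and cDNA data live in external archives, the package
ships a first-class synthetic-data generator that emulates the statistical
structure of that system with full ground truth, so every stage can be
validated by parameter recovery.

## Germline annotation model

A gene segment candidate is located by identity to a reference set:
each reference is tiled into 60-nt windows searched with bit-parallel
infix alignment (edlib), merged hits form candidate intervals, and the
best reference per interval is chosen by local alignment (identity, then
covered reference span). Tiling keeps 77-bp fragmented loci — which the
locus genuinely contains — discoverable, and a fragmentary best hit
triggers an exhaustive re-ranking because edit distance over a mostly
unaligned reference is uninformative.

Each V candidate is then analyzed in its own transcription orientation:

- **Leader/ORF.** The leader is modeled as a fixed 48-nt first exon
  (ATG + 45 nt) followed by a GT..AG intron and a 12-nt leader part 2 at
  the start of the V exon. (Real L-part2 is typically 11 nt; 12 keeps
  every exon in reading frame 0 and changes nothing else.) Stop codons
  are read from the translation; frameshifts are net indels (not a
  multiple of three) against the matched reference.
- **Recombination signal sequences (RSS).** Canonical heptamer CACAGTG
  and nonamer ACAAAAACC, 23-nt spacer downstream of V, 12-nt spacers on
  both D flanks, 23-nt spacer upstream of J. Up to two mismatches are
  tolerated in heptamer/nonamer and ±1 nt in the spacer *for detection*;
  competence additionally requires the recombination-critical criteria
  exactly: heptamer starting CAC, three consecutive adenosines in the
  nonamer, and the exact spacer length.
- **Regulatory elements.** Octamer ATGCAAAT (either strand, exact) and
  TATA box TATAAA (≤1 mismatch) within 300 nt upstream of the leader ATG;
  poly-A signal AATAAA within 500 nt downstream of a constant gene.
  These consensi are configuration (`ScanConfig`), not discovery.
- **Functionality classes.** `F` (all criteria pass), `F_putative`
  (incomplete sequence: Ns or contig truncation), `ORF` (splice,
  regulatory or conserved-residue defect), `ORF_orphon` (fully functional
  but off the main locus chromosome), `Psi` (stop, frameshift, fragment
  < 270 nt, or a recombination-critical RSS defect). The mapping is a
  pure function of the per-criterion report with strict precedence
  Psi > ORF > ORF_orphon > F_putative > F, exhaustively tested over all
  2^8 report combinations.

Coordinates are 0-based half-open internally and 1-based inclusive in
reports; minus-strand features are reported in plus-strand coordinates
with a strand flag, and scanning is reverse-complement invariant.

## Expressed-repertoire model

Reads are isotype-restricted amplicons (universal leader forward primer,
isotype-specific reverse primer). Analysis per read:

1. **Isotype** — the read tail is searched inside each constant
   reference; best identity wins, IgG subclasses collapse to "IgG",
   below 70% identity the call is `unknown`.
2. **V and J** — best global-overlap identity of each full reference
   inside the read (edlib infix; ties to longer span, then name).
   Junction-side boundaries are then trimmed until the alignment
   terminates in three consecutive exact matches: an alignment that
   absorbed a trimmed germline end is mismatch-rich there, and the
   junction must not inherit those bases.
3. **D** — local alignment of each D reference inside the junction
   (plus small fixed margins of 6/12 nt, since a heavily trimmed V or J
   can drag its alignment over the junction). A candidate requires an
   8-nt contiguous exact seed; alignment ends must terminate in a 5-nt
   exact run (the non-templated flanks are A-rich enough to fool a
   plain local aligner). Candidates are ranked by alignment score —
   identity alone would let a short D matching perfectly inside a
   homologous long D win — and the call is flagged ambiguous when the
   top two identities lie within 5 points, mirroring the fact that
   highly homologous germline D segments cannot always be annotated
   unambiguously. Where the chosen D overlaps an absorbed V tail or J
   head, the templated D evidence wins and the junction boundary yields.
4. **Numbering and regions** — the germline V is numbered once with the
   anchor-based IMGT scheme (Cys23, Trp41, Leu89, Cys104 in its
   Tyr-bearing context, J [W/F]118-G119-X-G121; CDR gaps at loop
   midpoints, insertions 111.1/112.1… for CDR3 loops beyond 13
   residues), and region boundaries are projected through the read
   alignment. Projection keeps CDR coordinates stable even when an
   anchor residue itself is mutated; projected spans are rounded to
   whole codons because tie-broken alignment paths can shift a boundary
   by one base. The read's own translation is numbered directly for the
   conserved-residue flags, with fallbacks when position 118 or 119 is
   substituted. One reported substitution in the source material
   (Trp118>Ser attributed to TTG>TCG, although TTG encodes Leu) is
   flagged by the checker as a position-118 violation; the codon
   inconsistency is noted here and left unresolved.
5. **CDR3H groups** — group 1 ≤ 10 aa, group 3 ≥ 48 aa, group 2
   otherwise; lengths 11 and 32–47 fall between the observed bands and
   are assigned to group 2 by a nearest-interval rule and flagged
   `interpolated`.
6. **Composition** — counts of Cys/Gly/Tyr/Ser and aromatics
   ({F,W,Y,H}); hydrophilic fraction = residues with negative
   Kyte–Doolittle hydropathy; `cys_center` = mean relative Cys position
   (midpoint convention).
7. **Junctions** — a V–D insert of 13–18 nt with A-fraction ≥ 1/3 is a
   conserved short nucleotide sequence (CSNS); any other non-empty
   insert is an N-region. The pipeline tolerates a few nucleotides of
   boundary slip (a point mutation at the 5' end of the retained D
   pushes the estimated boundary rightward) before rejecting the CSNS
   window. D–J inserts are split into P nucleotides (reverse-complement
   palindromes of ≤3 nt against the untrimmed adjacent germline end)
   and non-templated N.

## Phylogenetics

Distances are `1 − identity/100` with pairwise gap exclusion. The
progressive aligner merges profiles along a neighbor-joining guide tree
with a sum-of-pairs score (match +1, mismatch −1, linear gap cost 3); the
stiff gap cost matters: with cheap gaps, spurious gap columns inflate the
gap-excluded identity between families by 5–10 points and can merge them.
Neighbor joining is the standard Saitou–Nei agglomeration with a
deterministic lexicographic tie-break; negative branch lengths are
clamped to zero and counted. Bootstrap support resamples alignment
columns with replacement, fully seeded. Rooting places the root on the
edge separating a (required monophyletic) outgroup. Families are
single-linkage components at an identity threshold of 75% — midway
between the reported within-family floor (~79.5%) and between-family
ceiling (~69.7%) — reported with per-family minimum within-identity and
the global maximum between-identity.

## Synthetic data: what it emulates, and what it does not

The germline generator plants, on one main-locus contig: a six-member J
cluster (one predominant functional J; the others lack the J motif),
per-isotype constant stubs, and a two-family V repertoire with D
segments between the 6th and 7th V. Families are produced by mutating
family founders at the amino-acid level (anchors never mutate) and
re-encoding codons, with rejection sampling onto the requested identity
bands (defaults: within ≥ ~85%, between ≤ ~65–70%, matching the
two-family structure with all functional segments in family 1). Defaults
mirror the study conditions: 36 V of which 13 functional, two 77-bp
fragments (family 2), remaining pseudogenes split across stop /
frameshift / RSS-critical defects, five ORF-class segments (promoter,
splice or conserved-residue defects), D lengths 15/36/148 nt.

Constant-region stubs carry the reverse-primer annealing site at the
offset that makes a short-CDR3H amplicon match the approximate product
size of the primer table (795/805/536/467/574 bp); the IgM/IgD primers
bind the second constant domain, which is why their stubs are several
hundred nt — a fixed-length stub cannot reproduce that geometry.

The repertoire generator draws a CDR3H length group from a three-point
mixture (defaults 7%/74%/19%, the proportions observed across the 100
analyzed sequences), a length uniform within the group band (5–10,
12–31, 48–62 aa), then assembles
V + (CSNS) + N + D + N/P + J + constant stub. Group 3 always uses the
longest D plus an A-rich CSNS at the V–D junction and a designated
functional V; group 1 uses the short D segments with trimming. Junction
arithmetic is codon-quantized so every read is productive, mirroring
in-frame selection of expressed rearrangements; at least 15 nt of D are
retained; and inserts are redrawn when they would chance-continue the
flanking germline D or mimic a P nucleotide — such boundaries would be
unrecoverable by any annotator, so planted truth is kept identifiable.
CSNS inserts are drawn A-rich (A ≈ 0.6, no T, A-fraction ≥ 0.4) rather
than as one literal conserved motif, and group-2 CSNS is only planted
where the insert fits without trimming beyond the germline ends
(CDR3H ≥ 17 aa), consistent with its description as an
extension mechanism. Somatic hypermutation is substitution-only at a
per-site rate (default 2%, a test setting, not a biological estimate),
multiplied (default ×3) at RGYW/WRCY hotspot positions, transitions
favored 2:1 over each transversion.

Features of real data the generator does not emulate: insertions and
deletions from sequencing or somatic mutation, gene conversion (for
which the source analysis found no heavy-chain evidence), clonal
structure, allelic variation, chimeric PCR artifacts, and real promoter
architecture beyond the consensus motifs. Passing recovery tests
therefore demonstrate correctness of the annotation logic under the
stated model, not field performance on arbitrary sequencing data.

## Numerical and size choices

Simulation sizes used by the test-suite and the acceptance script — a
36-segment germline locus (~45 kb contig) and 500 expressed reads — are
the study's own scale (20 sequences per isotype in the source work; 100
per isotype here for tighter rate estimates). Bootstrap uses 100
replicates in tests (1000 in the original workflow; support for the
family split is saturated at either setting). All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; identical
seeds give byte-identical FASTA and tables. Degenerate inputs are
handled explicitly: all-N contigs scan to an empty annotation list with
a warning, unassignable reads are reported rather than aborting a batch,
and an alignment with no comparable columns has no defined identity
(error in the API, maximal distance inside bootstrap resampling).
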