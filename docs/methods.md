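# Methods

This note records the conventions, models and deliberate design choices
behind mitocharter, in the spirit of a methods appendix: what each
statistic means, which knobs matter, what the simulator does and does
not emulate, and where the edges of validity lie.

## Coordinates and the circular model

All coordinates are 1-based and fully inclusive, matching the feature
tables printed in mitogenome reports. A feature with `end < start` on a
circular genome wraps across the origin; its length is
`(genome_length − start + 1) + end`. No half-open conversion happens
anywhere internally, so numbers in reports can be compared digit for
digit with published tables.

Strands are `H` (heavy; the deposited reference strand) and `L` (its
complement). GenBank `complement(...)` locations map to `L`, and a
`join()` spanning the origin becomes a single wrap-around feature.

### Gene vocabulary

Annotations are restricted to a closed 37-token vocabulary (13 PCGs,
2 rRNAs, 22 tRNAs). Free-text labels are canonicalized through a
packaged synonym table (`data/gene_synonyms.tsv`) plus a tRNA parser, so
new spellings are added as data, not code. The duplicated leucine and
serine tRNAs are disambiguated by the codon family they serve:

| token | codons read | anticodon (DNA) |
|-------|-------------|-----------------|
| trnL1 | CUN | TAG |
| trnL2 | UUR | TAA |
| trnS1 | UCN | TGA |
| trnS2 | AGN | GCT |

The same numbering is used for the split codon families (Leu1 = CUN,
Ser1 = UCN), keeping tRNA names and RSCU family labels consistent.
Note that some annotation pipelines number the serine tRNAs the other
way around; this package's convention follows the reference fixture.
Labels that cannot be disambiguated (a bare `trnS` with no anticodon)
are rejected rather than guessed; in gene-order comparisons such genes
would be dropped with a warning rather than positionally inferred.

## The intergenic ledger

For each feature the ledger stores the signed gap preceding it:
`gap(i) = start(i) − end(i−1) − 1`, with the first feature's gap
wrapping around the origin. Positive gaps are intergenic spacers,
zero means abutting genes, and negative gaps are overlaps of adjacent
features. Zero gaps count as neither spacers nor overlaps — this is the
dialect used by the reference table, where 22 spacers are reported over
37 features. The ledger closes the circle exactly:
Σ feature lengths + Σ signed gaps = genome length
(15,065 + 730 = 15,795 on the packaged fixture), and it is invariant
under rotation of the coordinate origin, including the case where a
feature spans the origin. Prose reports quote overlaps as positive
magnitudes ("7 bp"); tables keep the sign.

Length ties in per-category extremes are broken by the
lexicographically first gene token (the fixture has two 70 bp tRNAs;
trnG is reported).

## Composition and skews

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C); both are undefined (and
reported absent) when the denominator is zero. IUPAC ambiguity codes are
excluded from counts and all denominators and tallied separately.
Whole-genome statistics are computed on the deposited reference strand,
matching how comparative tables are built from NCBI records; per-gene
and per-class statistics default to the sense strand (reverse
complement for L-strand genes), matching how PCG/rRNA compositions are
quoted. AT content (A% + T%) is strand-invariant; skews flip sign under
reverse complement. Reports round percentages to 2 decimals and skews
to 6, the conventional printed precision.

`skews_from_percentages` recomputes a published composition table from
its own percentage columns; because the inputs are rounded to 0.01%,
recomputed skews can differ from count-based ones by up to a few 10⁻⁴,
which bounds the agreement one should expect.

## Genetic code and RSCU

The default code is NCBI translation table 5 (invertebrate
mitochondrial: AGA/AGG → Ser, AUA → Met, UGA → Trp), the standard for
molluscan mitogenomes; the table id is configurable. Codon tables come
from Biopython; translation drops the terminal stop, reports ambiguous
codons as `X`, and raises on internal stops with the codon position.

Synonymous families are codon boxes: sense codons grouped by amino acid
and first two bases. Under table 5 this yields exactly nine 4-codon
families (Ala, Arg, Gly, Leu1, Pro, Ser1, Ser2, Thr, Val) and thirteen
2-codon families. RSCU is computed within these split families, not
within merged amino acids. The default counting policy includes start
codons and excludes terminal stops — this makes hand counts
reproducible (total codons = Σ length/3 − 1) — and both switches are
explicit, since published figures rarely state their policy. Codons are
DNA internally and rendered in RNA alphabet for display.

## Signed circular gene orders

A gene arrangement is a circular list of (gene, orientation) pairs;
a circular molecule has no origin and no preferred reading direction,
so two arrangements are equal when one is a rotation of the other or a
rotation of its reflection with all signs flipped. `normalize` picks
the canonical representative (anchor gene first, reading direction
chosen so the anchor is +; cox1 by default, as comparative figures are
conventionally drawn).

The default comparison subset is PCG+rRNA (15 genes), because tRNA
positions drift even between species described as sharing "the same
gene order"; all-37 and PCG-13 modes are available.

**Breakpoint distance** counts signed circular adjacencies of one order
absent from the other, where an adjacency (a, b) is conserved by
(a, b) or its mirror (−b, −a). It is symmetric, invariant under
rotation/reflection of either argument, and zero exactly for equal
orders. **Shared blocks** partition the common genes into maximal runs
contiguous in both orders, each tagged same-strand or inverted.

**Rearrangement search** finds a shortest script of segment reversals
(sign-flipping) and two-segment block swaps, up to 3 operations, by
bidirectional breadth-first search with canonical-form hashing and
deterministic tie-breaking (operations enumerated in sorted index
order; candidate scripts re-verified by application). Operations are
defined on a linear representative of each order, so a script that
would require a segment spanning the chosen origin of that
representative can be missed within the bound; the rearrangements
reported in comparative mitogenomics (a reversed block, a reversed
block exchanged with a neighbour) are representable and found. This is
a deliberate trade: a full sorting-by-reversals solver is out of scope,
and at ≤ 3 ops and n ≤ 37 the bounded search is exact enough for
hypothesis checking.

## Supermatrix preparation

Per-gene amino-acid alignments are inputs, not products — alignment
belongs upstream. Blocks are concatenated in a fixed canonical order
(cox1, cox2, cox3, cob, nad1–nad6, nad4l, atp6, atp8) with 1-based
inclusive partition intervals; a taxon missing from a block gets an
all-gap row with a warning. The gap-column filter removes columns whose
gap fraction exceeds a threshold and recomputes partitions; it is
idempotent and transparent, and deliberately weaker than block-based
alignment trimmers (it judges columns only, not conservation context) —
results derived through it should be described accordingly.

p-distances are computed over columns where neither row is gapped.
The neighbor-joining tree (via scikit-bio, with taxa pre-sorted so
tie-breaking is deterministic) is a smoke-test instrument: on additive
distances it provably recovers the generating splits, which is what the
tests exercise. It is not a substitute for model-based inference.

## The simulator

`simulate_genome` emulates the study system at its documented scale:
the packaged reference gene order and strands as the default template;
PCG lengths as in-frame multiples of 3 in [165, 1731] bp, tRNAs in
[60, 75], rRNAs in [700, 1500] (the observed extremes of the reference
genome); intergenic gaps uniform in [0, 30] bp with one long spacer of
[200, 400] bp placed before cox3 (mirroring the 364 bp spacer observed
there); sense-strand base composition targeting AT = 0.65 with
AT skew 0.08 and GC skew −0.17 (the reference genome's values). CDSs
are built codon-wise from the biased base pool with stop codons
rejected in the body, an ATG start and a random TAA/TAG stop, so every
simulated PCG translates cleanly under table 5. Genome length is
emergent (typically 16–18 kb). All randomness flows through one numpy
Generator seeded by the spec, so identical spec + seed gives
byte-identical FASTA and tables.

What it does **not** emulate: overlapping genes (gaps are never
negative), indels, tRNA secondary structure, replication-origin
composition asymmetries along the circle, a control region, or
nucleotide-level phylogenetic signal. Tests that pass on simulated
genomes therefore validate the arithmetic and the conventions, not the
biology of any particular real genome; the packaged published fixture
covers the latter for the annotation-level statistics.

`evolve_family` evolves the translated PCGs along a user-supplied
Newick tree with site-independent amino-acid substitutions
(probability min(1, rate × branch length) per site per branch, uniform
replacement). It produces aligned, gap-free blocks with divergence
increasing along path length — sufficient for supermatrix and NJ
recovery tests, and nothing more (no rate heterogeneity, no
exchangeability matrix, no back-substitution modelling beyond what the
uniform process implies).

## Numerical and degenerate-input choices

- Empty sequences, empty gene subsets, missing anchors, ragged
  alignment blocks, and linear annotations with wrapped features are
  errors, not warnings; dialect-level issues (a stored Length column
  that disagrees with coordinates, an unknown feature label in a
  GenBank record) warn and continue.
- Skews with zero denominators are absent values (None), never 0.
- Report formatting: percentages 2 d.p., skews 6 d.p.; thousands
  separators are accepted on input and never written.
- The feature-table round trip (write → read) is exact, with Length and
  Intergenic recomputed rather than copied.

## Known limitations

- The rearrangement search bound (≤ 3 ops) and its linear-segment
  enumeration are documented above; distances beyond that need a proper
  sorting-by-reversals implementation.
- Whole-genome composition assumes the deposited strand is the heavy
  strand, as in the reference records; records deposited the other way
  around will show mirrored skews.
- The gap-column filter is not a conservation-aware trimmer.
- Sequence-derived statistics for the packaged reference annotation
  require fetching the deposited record; the fixture carries
  coordinates and codons only.
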