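# Methods

This note documents the models, rules and numerical choices behind
`sigmark`, what the synthetic benchmarks do and do not demonstrate, and
the design decisions taken where the underlying conventions are
informal.

## Signature indel (CSI) detection

### The model

A clade-specific signature indel is a rare genomic change — an insertion
or deletion introduced once in the common ancestor of a clade and
inherited vertically — embedded in a region conserved enough that its
presence/absence can be read reliably from an alignment of homologs.
Two properties are required:

1. **Clade-restricted gap pattern.** The indel locus is modelled as a
   maximal run of gap-containing alignment columns (columns in which at
   least one sequence is gapped).  Such runs are structural: they never
   overlap and cannot be extended without crossing a fully
   residue-bearing column, so no tie-breaking between candidate
   intervals is ever needed and the scan is deterministic.  A run is an
   *insertion* candidate when every out-group sequence has zero
   residues across it while every in-group sequence carries between
   `min_indel_len` (default 1) and `max_indel_len` (default 30)
   residues; a *deletion* candidate is the mirror image.  Evaluating the
   pattern over the whole gap run means that an out-group sequence
   aligning even a single residue inside the region — i.e. carrying a
   shorter independent indel at the same locus — disqualifies the
   candidate, since the signature would not be exclusive to the clade.
2. **Conserved flanks.** For each side of the block, up to `window_len`
   (default 40) adjacent columns are examined and a column is counted as
   conserved iff no sequence has a gap or `X` there and all residues are
   identical or fall within a single similarity class.  A candidate is
   called only when both flanks reach `min_conserved` (default 5)
   conserved columns.  The defaults take the most permissive reading of
   the conventional "5–6 conserved residues within 30–40 positions"
   rule — widest window, lowest count — and expose both knobs for
   stricter scans.

The similarity classes default to the Clustal "strong similarity"
groups (STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW), the de facto
convention in alignment viewers.  `X` never matches anything, and a
column containing any gap or `X` is never conserved — the strictest
reading, preventing gap-rich flanks from qualifying.

Variable-length insertions (different in-group genomes carrying
different insert sizes at one locus) are admitted and reported as a
size range; deletions are required to be uniform (all out-group
sequences losing the same number of residues), matching how fixed-size
deletions present in practice.

Flank conservation is evaluated across **all** records in the supplied
alignment, in-group and out-group alike.  Published signature figures
are often rendered from a representative subset of taxa; any such
subsetting is deliberately the caller's responsibility, not the
scanner's.

### Coordinates, presence calls and fragments

All coordinates are 1-based closed intervals.  An indel's position is
reported in the ungapped numbering of a reference sequence (default:
the first in-group record); for a deletion, where the reference itself
is gapped at the locus, the span brackets the junction (the residues
immediately left and right of the deleted segment).

Presence of a called CSI in any homolog — including homologs added
after discovery to verify specificity against a database — is decided
per record: *present* when the residue count inside the block lies in
the recorded size range (insertion) or is zero (deletion); *absent*
otherwise; *missing_data* when the record is gap-only across the block
**and** both flanking windows, i.e. a truncated homolog (typical of
incomplete metagenome-assembled genomes) that carries no information at
the locus and should not be scored as lacking the marker.

For database verification, `extract_indel_fragment` cuts the ungapped
indel-containing fragment, by default 80 aa (bounds 60–100: long enough
to anchor a specific search, short enough that the indel region
dominates), centred on the indel as nearly as the termini allow, with
deterministic integer arithmetic.

## Specificity assignment

Given the set of genomes carrying a marker and a user-supplied clade
tree, the marker is assigned the **smallest clade** `C` with
`|presence ∩ C| / |C| ≥ min_coverage` and `|presence \ C| ≤
max_exceptions`.  Defaults: `min_coverage = 0.75`, `max_exceptions = 0`.
The coverage tolerance reflects the practical reality that a quarter of
a clade may be represented by incomplete assemblies in which a genuinely
present marker is undetected (9 of 12 genomes is exactly 0.75);
exceptions default to zero because out-of-clade carriers (deep-branching
relatives, lateral transfer) should be a documented, deliberate
allowance — raising `max_exceptions` to 1 admits them — never the
default.  Genomes unknown to the tree are counted as external
exceptions rather than raising errors, so hit tables referencing taxa
outside the configured taxonomy degrade gracefully.  With
`max_exceptions = 0` every qualifying clade must contain the presence
set, so qualifying clades form a nested chain and the smallest is
unique; with a positive exception budget disjoint clades can tie in
rare constructed cases, broken deterministically by (fewest genomes,
greatest depth, name).

## Signature protein (CSP) classification

The classifier consumes tabular homology hits (the standard 12-column
tab-separated format, plus a 13th subject-genome column or a sidecar
mapping) and applies a two-threshold E-value partition:

- a hit with E < `e_sig` (default 0.01) marks real homology;
- an out-group hit with E ≥ `e_excl` (default 1.0) is noise and is
  ignored;
- out-group hits in the gray zone `e_sig ≤ E < e_excl` disqualify the
  query unless `max_gray_outgroup` (default 0) admits them.  The
  tolerance exists because taxon-restriction rules are usually stated
  with a "generally" hedge; the strict default makes any allowance an
  explicit, recorded choice.

A query is accepted as a CSP iff it has no significant out-group hit,
its gray-zone out-group hits are within tolerance, and its presence set
(genomes with a significant hit, plus the query's own genome when
given — the self match is real even when a table omits it) defines a
clade under the coverage rule above.  Every rejection carries
machine-readable reasons plus the disqualifying hits, sorted by
(E-value, subject) for determinism; classification is invariant under
hit order.  In-group genomes whose only hits fall in the gray zone are
treated as absent from the presence set.

The per-query hit cap (default 500, mirroring the max-target-sequences
search setting) is applied at read time by ascending (E-value, subject
id); hits beyond the cap are flagged rather than dropped, so the parsed
table remains a faithful image of the input.

## Supermatrix construction

Per-marker alignments keyed by genome are concatenated in input order
into a single alignment with an explicit partition map (`marker =
start-end`).  Genomes lacking a marker are gap-filled by default —
incomplete assemblies are the norm, and dropping a genome for one
missing ortholog would discard most metagenome-derived taxa; a
`drop_genome` policy is available when complete rows are required.  A
genome absent from every marker is an error rather than an all-gap row.

Column trimming is a transparent two-threshold filter: keep exactly the
columns with gap fraction ≤ `max_gap_frac` (default 0.5) **and** modal
similarity-class fraction among non-gap residues ≥ `min_conserved_frac`
(default 0.5).  It is deliberately **not** a re-implementation of
block-based trimmers such as Gblocks — those impose block-level rules
that belong to their own publications — and the kept-column indices are
reported so externally trimmed alignments can be substituted
column-for-column.  The filter is idempotent and never touches rows.
Output formats (FASTA, relaxed PHYLIP, partition file) feed external
tree builders; tree inference itself is out of scope.

## Signature excerpts

Signature figures conventionally show a short window around the indel
with dash-identity encoding: the top line is the reference, and a dash
in any other line means "same residue as the top line".  Because the
dash also serves as the gap symbol in plain alignments, the published
convention is ambiguous to parse; excerpts here use `.` for gaps in all
rows (including the reference, which therefore never contains a dash)
and reserve `-` strictly for identity.  This makes the encoding
lossless: `decode_signature` reconstructs the exact sub-alignment, and
the round trip is property-tested.  Carrier rows come first, then up to
`outgroup_sample` (default 10) non-carrier rows in input order — a
deterministic stand-in for the "few representative strains" shown in
figures.  Each row is annotated with the ungapped position at which its
window begins.

## Synthetic data: what it emulates, what it does not

The generator exists so that every pipeline stage can be scored against
exact planted truth without downloading genomes or running homology
searches.

**Families.** A root sequence (uniform over 20 amino acids, default
400 aa) evolves star-wise: each genome mutates every site independently
with probability `sub_prob` (default 0.05), never back to the original
residue.  A planted indel is placed at one locus drawn far enough from
the termini to leave full flanks; `flank_protect` (default 40) columns
on each side mutate at `protected_sub_prob` (default 0) instead.
Insertions draw a per-carrier length in `[len_min, len_max]` (default
1–8); deletions use a single length.  The alignment is produced by
construction — gaps are placed exactly where the indel is — so truth
block columns are exact and no aligner is involved.  Decoy modes
generate families that must yield zero calls: `nonspecific_indel` leaks
the indel into one out-group genome, `weak_flank` mutates the flanks at
0.5 per site, `partial_clade` plants the indel in only half the clade.

Deliberate simplifications: star topology rather than tree-path
evolution (sufficient to produce the group-restricted-indel /
conserved-flank structure the scanner tests; phylogenetically
correlated substitutions are a non-goal), one indel locus per family
(a protein with two signature indels is represented by two families),
no realistic substitution model, and no aligner noise.  Consequently a
perfect recovery score on the benchmark shows the scanner implements
its stated rule exactly; it does **not** show robustness to alignment
error, compositional bias, or flanks conserved only by selective
constraint — on real data those remain the caller's risks.

**Hit tables.** E-values are drawn directly rather than computed from
sequences (the classifier consumes E-values only): planted
clade-restricted queries get one hit per in-group genome with log10 E
uniform in (−80, −20) and, per out-group genome, no hit with
probability 0.7 or a weak hit with E uniform in (1, 10); contaminated
decoys additionally receive one out-group hit below 0.01; the remaining
decoys are cosmopolitan proteins with strong hits everywhere.  The
default study shape is 12 in-group + 12 out-group genomes, 500 queries,
half planted, 50 contaminated.

Everything is deterministic under its seed: family `i` of a benchmark
uses seed `seed + i`, so any family regenerates independently, and the
on-disk bundle writes a manifest with per-file SHA-256 checksums that
replays byte-identically.

## Verification

The test suite checks each operation against an independent oracle:
exhaustive interval enumeration for the scanner, exhaustive clade-wise
predicate evaluation for specificity, brute-force prefix counting for
coordinates, per-column re-evaluation for flank scores and trimming,
an independent sort for the hit cap, and generator truth for recovery,
decoy control and classifier precision/recall.  `scripts/acceptance.py`
recomputes the same metrics end-to-end from freshly generated inputs
(problem sizes: 100 random alignments up to 12 × 120, 200 signature +
200 decoy families of 24 genomes × ~400 columns, a 0–40 flank-threshold
sweep, 500 queries, 54 markers, 1,000 coordinate strings — sizes chosen
to exercise every code path while keeping a single-CPU run in tens of
seconds) and writes them as JSON.

## Known limitations

- Inputs must already be aligned; alignment construction and its
  artefacts are out of scope.
- The scanner requires the indel pattern to be exact: a single
  divergent in-group sequence inside the block (or one out-group
  residue anywhere in the gap run) vetoes the candidate.  Whether
  near-miss patterns should ever be admitted is a judgement call the
  package leaves to the user via `min_indel_len`/`max_indel_len` and
  re-scanning with adjusted in-groups.
- Whether flank conservation should be required across distant
  out-group taxa or only near relatives is not standardised; the
  implementation requires all supplied records, and users who want the
  laxer reading should subset the alignment.
- The column trimmer is not Gblocks and makes no claim of equivalence.
- Published indel-position ranges sometimes denote the displayed figure
  excerpt rather than the indel itself; the records here report the
  indel's own reference span, and the excerpt window is available from
  the report module when the other convention is wanted.
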