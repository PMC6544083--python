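# sigmark

Discovery of clade-specific molecular signatures in bacterial proteomes:
**conserved signature indels (CSIs)** in protein multiple-sequence
alignments and **conserved signature proteins (CSPs)** from homology
hit tables, plus the surrounding plumbing a phylogenomic study needs —
clade-specificity assignment, publication-style signature excerpts, and
concatenated supermatrices for tree building.

It is written for microbial taxonomists and comparative genomicists who
delineate higher taxa (family, order, class) with discrete molecular
markers rather than 16S rRNA identity alone, and who want the marker
calls to be scripted, deterministic, and testable instead of manual.

## The markers

**CSI.** An insertion or deletion in a conserved protein region that is
present in all members of a monophyletic group and absent outside it.
Operationally, a column block in an alignment of homologs whose gap
pattern splits in-group from out-group, flanked on each side by at least
`min_conserved` = 5 conserved columns within a `window_len` = 40-column
window (a column is conserved when no sequence has a gap or `X` and all
residues are identical or share one Clustal strong-similarity class).
Indels with poorly conserved flanks are discarded: conserved flanks are
what distinguishes a fixed, vertically inherited rare genomic change
from ordinary alignment noise.

**CSP.** A protein whose significant homologs (E-value < `e_sig` = 0.01)
all come from genomes of one clade, while genomes outside the clade show
no hit or only noise-level similarity (E-value > `e_excl` = 1.0).
Out-group hits in the gray zone between the two thresholds disqualify
the protein unless an explicit tolerance admits them.

Each accepted marker is assigned the smallest clade whose genomes carry
it (coverage ≥ 0.75 by default, tolerating incomplete
metagenome-assembled genomes; out-of-clade carriers are counted as
exceptions with a default budget of 0).

## Worked example

Everything below runs offline on synthetic data with planted,
exactly-known signatures (see `sigmark.simulate`):

```bash
sigmark simulate --out demo --seed 4 --families 4
sigmark scan-csi --alignment demo/alignments/sig0000.fasta \
    --taxonomy demo/taxonomy.tsv --ingroup CladeA --out demo/scan
# -> 1 CSI(s) written to demo/scan.csi.tsv
cat demo/scan.csi.tsv
```

```
marker_id  indel_type  size   ref_span  flank_left  flank_right  specificity  coverage  col_start  col_end
sig0000    insertion   2-8aa  147-153   40          40           CladeA       1.000     147        154
```

Read: in this family the 12 `CladeA` genomes share an insertion of 2–8
residues (lengths vary per genome) at positions 147–153 of the reference
sequence, with all 40 flanking columns conserved on both sides; every
`CladeA` genome carries it (coverage 1.000) and no genome outside does,
so the indel defines `CladeA`.  `demo/scan.csi1.txt` holds the
dash-identity excerpt (dashes mean "same residue as the top line", `.`
marks gaps) that would appear as a figure panel.

The same bundle exercises the CSP classifier:

```bash
sigmark simulate --out demo2 --seed 4 --families 1 --queries 20
sigmark classify-csp --hits demo2/hits.tsv --taxonomy demo2/taxonomy.tsv \
    --ingroup CladeA --out demo2/csp.tsv
# -> 10/20 queries classified as CSP -> demo2/csp.tsv
```

Ten of the twenty simulated proteins were planted as clade-restricted;
exactly those ten are accepted, and each rejection lists its
machine-readable reason and the disqualifying hits.

From Python the same operations are three calls:

```python
from sigmark import read_alignment, read_taxonomy, call_csis

tree = read_taxonomy("demo/taxonomy.tsv")
aln = read_alignment("demo/alignments/sig0000.fasta")
csis = call_csis(aln, tree.genomes_under("CladeA"), tree=tree)
```

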