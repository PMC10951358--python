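# Methods

`diagmark` implements a distance-based species-authentication workflow for
multi-accession DNA-barcode panels: divergence-hotspot discovery on
whole-genome alignments, diagnostic-site calling on amplicon alignments,
distance-matrix phylogenetics, and a monophyly-based discrimination
statistic. This note records the models, conventions and design choices; all
empirical numbers cited here are the ones the analysis scripts and tests
compute.

## Coordinates, characters and missing data

Alignments are gapped, equal-length sequence sets addressed by 1-based,
inclusive column coordinates, the convention in which diagnostic positions
are reported in barcoding tables. `-` is the only accepted gap character
(`.` is rejected at parse time to avoid silent mixed conventions). IUPAC
ambiguity codes and `N` are kept verbatim but treated as missing by every
analysis: they never count as a diagnostic state, never contribute to
nucleotide diversity, and are skipped in pairwise distance comparison.
Accession identifiers are the first whitespace-delimited token of the FASTA
header, matching GenBank export convention.

Locus concatenation defaults to the intersection of accession sets (dropped
accessions are logged) because real amplicon panels rarely have perfectly
equal coverage; a `strict` policy is available when identical sets are a
data-integrity requirement. A partition record keeps per-locus intervals so
positions on a concatenation can always be mapped back to locus-local
coordinates.

## Nucleotide diversity and hotspot calling

Nucleotide diversity is the mean proportion of pairwise differences per
usable site:

    pi = (1 / L_u) * sum_{c in usable} [ #{i<j : s_i[c] != s_j[c]} / C(n,2) ]

where a usable column carries an unambiguous base in *every* sequence
(column-wise exclusion). Windows are placed on alignment columns — gap
columns count toward the window span but not toward pi — so reported window
and hotspot coordinates stay in alignment space, directly comparable to
positions on the genome alignment. Defaults are a 600-bp window stepped by
200 bp. Trailing partial windows are dropped rather than padded so all pi
values average over the same span; windows with no usable site get an
undefined (NaN) pi and are excluded from hotspot calling with a warning.

Hotspot calling selects windows with pi strictly greater than the threshold
(default 0.05) and merges overlapping or book-ended windows into regions.
One subtlety: region *count* is not globally monotone in the threshold —
raising it can split a merged region in two when more than
`window/step − 1` consecutive interior windows drop out. The guaranteed
monotonicities, asserted by the property tests, are that the set of
contributing windows and the total covered span only shrink as the
threshold rises; with well-separated diversity blocks the count is monotone
as well.

## Diagnostic sites

A column is **variable** when at least two distinct bases occur among
defined ingroup states, and **parsimony-informative** when at least two
bases are each carried by at least two accessions. The informative-site
count uses the parsimony definition because it is the standard,
reproducible reading of "informative variable nucleotide" in barcoding
tables; counts under other definitions will differ.

A **species-specific SNP** for taxon T at a column requires (i) every
accession of T to share one base, (ii) no other ingroup accession to carry
that base, and (iii) every other ingroup accession to have a defined base
there. Requirement (iii) is deliberate: a column where other accessions
show gaps or ambiguities cannot distinguish a private substitution from an
alignment-length artefact, so such "substitution-like" columns are not
called. Under a clean two-state, two-taxon partition both taxa are
internally fixed and mutually exclusive, and both sites are reported. The
outgroup is excluded from all specificity and informativeness computations.

**InDel events** are maximal runs of contiguous columns sharing one
per-accession gap/base presence pattern. An event is attributed to a taxon
when that taxon's accessions are exactly the sequence bearers (an
*insertion*) or exactly the gap bearers (a *deletion*). When both readings
are available — a two-taxon panel split cleanly into a sequence-bearing and
a gap-bearing taxon — the insertion reading takes precedence, so polarity
and attribution are always mutually consistent; without an outgroup in the
computation the choice is a labelling convention, not an inference.
Events touching an alignment end are flagged `edge=True` because terminal
gaps usually reflect amplicon length rather than biology.

## Distances

Pairwise comparison uses pairwise deletion: each pair of sequences is
compared over the columns where both carry an unambiguous base. This
preserves information in panels of unequal coverage; the matrix records the
convention. From the transition proportion P (A↔G, C↔T), transversion
proportion Q, and pooled GC fraction theta of the two sequences:

* p-distance: `d = P + Q`
* JC69: `d = −(3/4) ln(1 − 4p/3)`
* K2P: `d = −(1/2) ln(1 − 2P − Q) − (1/4) ln(1 − 2Q)`
* T3P: `d = −h ln(1 − P/h − Q) − (1/2)(1 − h) ln(1 − 2Q)`, `h = 2θ(1−θ)`

T3P collapses to K2P at θ = 0.5, and K2P to JC69 when transitions are one
third of differences — both identities are asserted numerically. Gamma rate
heterogeneity with shape `a` replaces each `−ln(w)` by `a (w^(−1/a) − 1)`;
the default shape is 1.0 when a gamma model is requested without one, since
published model labels rarely report estimated shapes. Gamma has no
p-distance form and is ignored for that model with a warning; likewise
"+Invariable" corrections are not implemented (the distance form is
under-determined without an invariant-fraction estimate) and map to the
base model with a warning. A pair whose log argument is non-positive is
*saturated*: it is flagged and assigned twice the largest finite distance so
tree building can proceed while the problem stays visible.

## Trees, rooting and discrimination

Neighbour joining follows Saitou–Nei: iteratively join the pair minimizing
`Q(i,j) = (r−2) d(i,j) − R_i − R_j`, with branch lengths
`l_i = d(i,j)/2 + (R_i − R_j)/(2(r−2))` and the final three nodes solved by
the three-point formulas. Ties are broken by the smallest (row, column)
index pair in current label order, making output deterministic across runs
and platforms. Negative branch lengths — a standard NJ artefact on
non-additive matrices — are clamped to zero with the deficit moved to the
sister branch, conserving path lengths. On additive matrices NJ recovers
the generating topology exactly; the tests verify this against exhaustive
least-squares fitting over all unrooted topologies (≤ 6 leaves) and against
an independent NJ implementation.

UPGMA is average-linkage clustering with node heights at half the merge
distance; output is ultrametric to numerical precision.

Rooting places the root on the edge separating the outgroup accessions from
the ingroup, splitting that edge's length equally. Monophyly is assessed
only on outgroup-rooted trees (requesting it on an unrooted tree is an
error, never a silent midpoint root): a taxon is monophyletic when the MRCA
of its accessions has exactly those accessions as leaf descendants; a
singleton is trivially monophyletic. The **discrimination success rate** is
`100 × (number of monophyletic ingroup taxa) / (number of ingroup taxa)`.

Bootstrap support resamples alignment columns with replacement, rebuilds the
tree per replicate, and scores each internal edge of the point-estimate tree
by the percentage of successful replicates containing the same unrooted
bipartition (restricted to shared leaves). Replicates in which some pair
loses all comparable sites are skipped with a warning and excluded from the
denominator. The seed is mandatory in the CLI; default replicates 1000.

## Synthetic data: what it emulates and what it does not

The generator emulates the design of a multi-accession authentication
panel: six ingroup taxa (five accessions each by default), amplicon-sized
loci (430, 735, 340, 460 bp by default), fixed taxon-private planted SNPs,
contiguous taxon-private insertions/deletions, i.i.d. intra-taxon background
substitutions (default rate 0.002 per site per accession, uniform over the
three alternatives), and one outgroup derived from the ancestral sequence
at 0.05 divergence — external to all ingroup taxa, as a rooting outgroup
should be. Planted columns are excluded from background mutation so the
truth table stays exact; insertions shift downstream coordinates, and the
truth table reports final alignment positions. Identical seeds give
byte-identical outputs.

It does **not** simulate coalescent genealogies, branch-process
substitution, rate heterogeneity, recombination, alignment error, or
sequencing noise. Passing tests therefore demonstrate that the pipeline's
logic is correct under its stated assumptions (fixed diagnostics, low
within-taxon noise, clean alignments), not that real herbal-market samples
will reach the same discrimination rates: real data add alignment
ambiguity, shared polymorphism and missing data that can only lower them.

The deterministic worked-example panel plants the full published set of
diagnostic positions — six private substitutions for *P. scabiosifolia*,
five for *P. villosa* subsp. *punctifolia*, three for *P. scabra*, two for
*P. heterophylla*, one SNP plus the 24-bp private insertion
(GAAGGGGTATGTTATTATTTTATT, psaI-ycf4 columns 185–208) for *P. villosa*
subsp. *villosa*, and none for *P. monandra*, whose substitution-like petA
column 24 is masked by missing leading sequence in two other accessions —
over a 37-accession, 6-taxon panel with locus lengths atpB 430, petA 735,
psaI-ycf4 340 and rpl2-rpl23 1090 (long enough to span every cited
position). The panel is invariant elsewhere, so taxa without private
variants in a locus are not separable from each other in that locus — which
is exactly the behaviour the combination sweep in
`analysis/04_trees_discrimination.py` illustrates.

## Problem sizes

The analysis scripts and tests are sized for a laptop-class single-core
run: the end-to-end discrimination check uses 6 taxa × 5 accessions × 700 bp
over 20 seeds; the oracle-equivalence checks use 200 random alignments
(≤ 8 × 50), a 120-point closed-form grid, and 100 random additive trees of
4–6 leaves; the hotspot scan uses an 8 × 12,000 synthetic plastome
alignment. The whole suite completes in well under a minute.

## Known limitations

* Distance models cover p/JC69/K2P/T3P (+gamma); no ML distances, no
  "+Invariable" correction, no model selection — the model is configuration.
* Topological agreement with trees produced by other software depends on
  their missing-data handling (pairwise vs complete deletion) and tie rules.
* Hotspot region count is threshold-monotone only for well-separated
  blocks (see above).
* The SNP caller requires other-taxon bases to be defined; heavily gapped
  panels will therefore under-call diagnostics rather than over-call them —
  a deliberate conservatism.
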