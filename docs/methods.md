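# Methods

This note records the models, conventions and numerical choices behind
`retrotarget`, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinates and distances

All internal coordinates are 0-based, half-open, stranded. GFF3 is
emitted 1-based inclusive, BED 0-based half-open; tRNAscan-SE tabular
rows with begin > end are read as minus-strand genes. The tRNA gene's
"mature coding sequence" is the annotated begin..end span; predicted
introns stay inside it and are recorded separately. Distances between
an element copy and a tRNA gene count the bases strictly between the
element terminus and the first (upstream) or last (downstream) base of
the mature coding sequence, in the gene's own transcriptional
orientation. The element terminus is the detected alignment bound; no
target-site-duplication correction is applied. Whether distances
should instead be measured to transcription start sites is a genuinely
open convention; the mature-boundary convention is used throughout.

## Synthetic genomes

The generator emulates the geometry of a compact amoebozoan genome
without modelling its gene content: i.i.d. background bases at a
configurable GC fraction (default 0.28, mimicking A/T-rich dictyostelid
DNA), `n_trna` tRNA genes of 70–90 bp on random strands placed near the
centres of equal slots, and element copies planted per family profile.
tRNA gene sequences are arbitrary tagged sequences, not fold-valid
tRNAs — the pipeline consumes annotations, not tRNA structure.

Per profile: the copy's tRNA-proximal terminus is placed exactly
`gap_bp` outside the mature boundary on the requested side, with
`gap_bp` drawn uniformly on `[gap_min, gap_max]`; when `n_copies ≥ 2`
the first two draws are pinned to the bounds so the planted window is
exactly recoverable ground truth (with 18 uniform draws over a 21-value
window the probability of attaining both bounds by chance is only
~0.33, which would make window recovery untestable). Structural
composition uses round-half-up on the full-length and solo-LTR
fractions and assigns the remainder to 5′-truncated partials
(truncation uniform between 60 bp and 50% of the element, keeping
partials distinguishable from solo LTRs). Copies are mutated at
per-base substitution and indel rates (indels 1–3 bp); a planted
full-length copy is recorded as intact only if, after mutation, every
ORF still translates without internal stops or net frame disruption.
Randomly placed copies are uniform over unoccupied space with no
spacing pad — deliberately the same process as the permutation null,
so the null-calibration experiments are exchangeable. One RNG stream
per profile is derived from `(seed, crc32(family))`, so adding a
profile does not perturb the others; identical inputs give
byte-identical outputs.

Not modelled: target-site duplications (the literature on these
elements does not establish them), realistic codon usage,
recombination between copies. Consequently, passing tests demonstrate
correctness of the measurement and inference machinery on known
geometry — not robustness to assembly artefacts, nested repeat
landscapes or diverged real-world families beyond ~15% divergence.

## Homology scanning

The scanner is DNA-level (real translated searches are served by the
BLAST-import path, which applies the conventional e < 1e-15 cutoff to
tabular input). Exact 12-mer seeds are matched on both strands after a
complexity filter (k-mers with > 8 copies of one base or < 3 distinct
bases never seed — in A/T-rich DNA homopolymeric k-mers match
everywhere); a two-hit rule (a partner seed within 500 bp on a
diagonal within ±32) and a minimum cluster size of 5 seeds nominate
candidate windows, whose extent comes from the seed diagonals plus a
drift margin. Each window is resolved by a full affine-gap local
alignment (Gotoh; match +1, mismatch −1, gap open −5 including the
first gap column, extend −1), so reported hit scores equal the optimal
dynamic-programming score for the window by construction — the test
suite verifies this against Biopython's independent `PairwiseAligner`
on 100 planted copies. Score-only passes with O(m) memory locate the
alignment end; rerunning the recursion on reversed prefixes locates the
start. After a hit, its span is masked and the window is realigned, so
several nearby copies in one window are all found. Percent identity per
hit comes from an edit-distance (edlib) alignment of the matched
segments.

Chaining merges colinear hits (consistent strand, agreeing genome and
consensus order, gaps ≤ 2 kb on both axes) into per-copy calls;
within a locus the highest-scoring colinear subset wins and
non-overlapping leftovers form further calls. Where related families
share sequence (e.g. near-identical chromo-domain regions), calls from
different families can overlap one locus; the highest-scoring family
keeps it (logged). E-values are not computed by the internal scanner —
Karlin–Altschul calibration is out of scope; scores and the e-cutoff
on imported tables serve instead.

Known limitation: for copies whose alignment ends internal to the
consensus (solo LTRs, truncated partials), the optimal local alignment
may extend a few bases into flanking sequence by chance matches;
full-length copies are immune (the query is exhausted). The
structural-class thresholds absorb this slop.

## Structural classification

LTR pairs are detected as the highest-scoring near-identical terminal
direct repeat (left copy starting within 50 bp of the element start,
right copy ending within 50 bp of the end, ≥ 80 bp, identity ≥ 0.90).
A copy is **solo_LTR** if its consensus coverage lies within one LTR
span ±20 bp and covers ≥ 80% of that LTR, ignoring up to 40 bp of
coverage beyond that window — the score-optimal alignment occasionally
makes a short net-positive chance excursion into flanking DNA, and the
overhang allowance absorbs it without risk of confusing genuine
partials, which exceed the LTR by kilobases; **full_length** if coverage
is ≥ 95% of the consensus with both termini within 10 bp of the ends;
**full_length_intact** additionally requires every ORF, read from the
genomic copy through an edit-distance alignment to the consensus, to
translate without internal stops and without net frame disruption
(indels whose net balance inside the ORF is divisible by 3 are
tolerated — a single in-frame indel does not break intactness);
anything else is **partial**. The coverage and terminus thresholds are
package choices (the source literature states none) set to be robust
to scanner end-trimming, and are pinned in the config.

Junction typing inspects the 40 bp after the left LTR: a TGG within
10 bp is a PBS (the canonical primer-binding signature complementary to
a primer tRNA's CCA 3′ end; the motif reported is the TGG plus 11
following bases), else any 15-base window with ≥ 12 pyrimidines
including ≥ 1 C is a PPy (the C reflects the characteristic cytosine in
these degenerate tracts); the 10-bp offset bound and 12/15 rule are
concrete thresholds for an informally described signature. The
integrase carboxy-terminal extension (IN-CTD) is measured from the
last G-P-[Y/F] tripeptide (at/after an optional IN-core hint) to the
protein's carboxyl end; without the motif the CTD is "n.d.". Chromo
domains are detected in the CTD with a position-specific scoring model
(log-odds against a uniform background, pseudocount 0.5) built from a
packaged **synthetic** chromo-domain alignment — a constructed
fixture, clearly labelled as such, with its three aromatic-cage columns
marked; real-data users should supply a profile built from curated
domains. The detection threshold is the mean + 4 SD of profile scores
over 1000 seeded shuffles of the profile's reference sequence
(empirical false-positive rate on shuffles: 0/1000 in the test suite).
Cage typing: all three cage residues in {F,Y,W} → group I; position 1
non-aromatic → group II; the remaining combination is logged as
I-atypical. Family naming follows chromovirus convention: an LTR
element with a CHD in its IN-CTD is Skipper-like, one without is
DGLT-A-like; non-LTR elements stay provisional (NLTR) until targeting
evidence resolves TRE5-like (upstream) or TRE3-like (downstream).

## Targeting inference

Each copy is assigned to the tRNA gene with the smallest gap within
3000 bp (ties: smaller gap, then upstream, then lower coordinate); a
copy is nested when another call lies wholly between its proximal
terminus and the target gene. The element-centric assignment and the
tRNA-centric flank listing are mutually consistent by construction and
by test. The verbal notion of "several copies at a similar distance" is
formalised as: ≥ 3 associated copies (gap ≤ 500 bp — all credible
windows in this element class fall within ~0–450 bp), ≥ 70% side
consistency, and permutation p ≤ 0.01. The null re-places the family's
copies (same lengths) uniformly at non-overlapping positions, excluding
existing copy spans and re-drawing placements that overlap tRNA genes,
with tRNA positions fixed; the statistic is the association count on
the observed majority side, and p uses the add-one estimator. Under
random planting this p is approximately uniform (measured fraction of
p ≤ 0.05 ≈ 0.045–0.065 across independent 200-seed batches); the
statistic is integer-valued, so p is mildly lumpy at small copy
numbers. Setting `n_permutations: 0` gives the heuristic-only decision.
Nested copies count toward totals and association but never toward the
reported window. When more than 5 families are tested in one run, the
per-family alpha is Bonferroni-divided by the number of families;
solo LTRs and partials count toward association like any other
structural class (configurable in principle via the class table).

Genome summaries use the union of copy spans for retroelement content
(overlaps counted once) and report the fraction of tRNA genes with ≥ 1
associated copy (overall and per family) and the fraction flanked on
both sides by upstream- and downstream-targeting families.

## Phylogenetics

Distances are amino-acid p-distances after complete gap deletion
(every column containing `-`, `X`, `?` or `.` removed first; the
retained-site count is reported). No Poisson or substitution-model
correction is applied — the upstream tooling this mirrors does not
state its distance model, and p-distance is the explicit, documented
assumption here. Neighbor joining is the Saitou–Nei agglomeration with
the standard Q-criterion; Q-ties resolve to the lexicographically
smallest cluster pair (clusters named by their smallest leaf label),
and negative branch lengths are clamped to zero with the clamped
amount logged. Bootstrap resamples retained columns with replacement,
rebuilds the NJ tree per replicate, and reports the percentage of
replicates containing each internal bipartition of the point tree as
internal node labels. Rooting is on an outgroup (bisecting the edge to
its MRCA; a non-monophyletic outgroup draws a warning and roots on the
edge best separating it) or at the midpoint of the longest path.
Maximum-likelihood trees are deliberately out of scope: NJ is exactly
testable at desk scale against enumeration oracles, and the test suite
verifies exact topology and branch-length recovery on additive 4–6
taxon matrices, cross-checked against scikit-bio's independent NJ.

## Pipeline, determinism, problem sizes

A single nested config pins every stage parameter; unknown keys are
rejected before any work. Every report file carries a header with the
tool version, seed and config hash, and a rerun with the same config
and seed is byte-identical (verified by test). All randomness flows
from the global seed through named child streams.

Problem sizes used in the shipped experiments are the package's own
choices for a desk-scale study: 500-kb genomes with 40 tRNA genes for
the targeting experiments (18-copy planted family, 1000 permutations),
400 kb / 30 tRNAs for structural accounting (20 copies: 5 intact, 4
partial, 11 solo), 100 planted copies at ~9% divergence for the
scanner-oracle comparison, 100–200 seeds at 200 permutations for null
calibration, and 1000 bootstrap replicates on a 230-residue synthetic
domain alignment for the phylogeny script.
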