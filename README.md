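# retrotarget

Annotation and statistical analysis of tRNA-gene-targeting
retrotransposons in compact genomes.

In gene-dense haploid genomes — the social amoebae are the canonical
case — mobile elements face strong selection against inserting into
genes, and several retrotransposon lineages have independently evolved
position-specific integration next to tRNA genes, which act as
dispersed "safe sites". Characterising this behaviour from a genome
assembly requires a chain of steps: finding the copies of each element
family, deciding what is structurally left of each copy (an intact
full-length element, a truncated fragment, or a solo LTR left behind by
recombination between the two LTRs), reading the family's diagnostic
features (primer-binding site vs polypyrimidine junction after the left
LTR, the GPY/F motif that ends the integrase core and anchors its
carboxy-terminal extension, the chromo-domain group), and finally
measuring where each copy sits relative to tRNA genes and deciding
whether the family *actively targets* them.

`retrotarget` implements that chain as a tested pipeline, exercised
end-to-end on seeded synthetic genomes with planted insertions whose
geometry is exact ground truth.

## What it computes

For a copy at $[a,b)$ and a tRNA gene whose mature coding sequence
occupies $[s,e)$ on the plus strand, the distance is counted in bases
strictly between the element terminus and the gene boundary, in the
gene's own orientation: upstream gap $= s-b$, downstream gap $= a-e$
(mirrored for minus-strand genes). A family with copies
$c_1,\dots,c_n$ is called **actively targeting** when

1. at least `min_copies` (default 3) copies lie within `assoc_max_gap`
   (default 500 bp) of their nearest tRNA gene,
2. at least `side_consistency` (default 70%) of those share one side,
   and
3. a permutation test rejects uniform placement: the copies are
   re-placed uniformly at non-overlapping positions `n_permutations`
   times, the statistic is the association count on the observed
   majority side, and $p = (1 + \#\{\text{null} \ge \text{obs}\}) /
   (1 + N) \le \alpha$ (default 0.01).

The family's **integration window** is reported as `min–max (n)` over
the non-nested associated copies — copies separated from their target
gene by another element count toward association but not toward the
window, since their original target distance is indeterminable.

Supporting stages: a seed-and-extend DNA scanner whose hit scores equal
the optimal affine-gap Smith–Waterman score on each candidate window
(match +1, mismatch −1, gap open −5, extend −1); structural-class
rules for solo-LTR/full-length/partial calls; PBS (TGG within 10 bp of
the left LTR) vs PPy (≥12 pyrimidines per 15 with ≥1 C) junction
typing; profile-based chromo-domain detection with aromatic-cage
group I/II classification; and neighbor-joining trees from amino-acid
p-distances under complete gap deletion, with column-bootstrap support.

## Worked example

The four numbered scripts under `analysis/` run the whole study:

```bash
python analysis/01_simulate_genome.py     # build the 500-kb study genome
python analysis/02_scan_and_annotate.py   # find and classify copies
python analysis/03_targeting_analysis.py  # call targeting, summary table
python analysis/04_phylogeny.py           # NJ tree of domain sequences
```

`03_targeting_analysis.py` prints the per-family table (this is the
actual output for the default seed):

```
family          total intact  solo targeting  5-prime     3-prime            p
DGLTA_like         18      0    10       yes  14–32 (17)  –           0.000999
Skipper2_like       6      0     0       yes  –           26–94 (6)   0.000999
Skipper_like       10      0     0        no  –           –                  -
TRE5_like           8      0     0       yes  37–90 (8)   –           0.000999
```

Reading the first row: 18 copies of the DGLT-A-like family were
detected, 10 of them solo LTRs and none with an intact ORF (the copies
were planted at 2% divergence, enough to disrupt a 3-kb reading
frame); the family is called actively targeting with its copies 14–32
bp upstream of tRNA genes (17 of 18 usable for the window; one is
excluded by divergence-induced end-trimming or nesting), at permutation
p ≈ 0.001. The randomly scattered Skipper-like control family is
correctly *not* called targeting, and the same analysis on 40
random-placement genomes yields zero false "yes" verdicts at α = 0.01.

The same machinery is scriptable through a CLI
(`retrotarget run --config cfg.yml --out report/`, plus `simulate`,
`scan`, `target`, `phylo`, `report` subcommands) or directly from
Python via `retrotarget.pipeline.run_pipeline`.

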