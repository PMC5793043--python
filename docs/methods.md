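# Methods

This note documents the models and procedures implemented in `mutrace`,
the defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical conventions that matter for reproducibility.

## Coordinates and variant normal form

All coordinates are 1-based inclusive (VCF/GFF3 convention); BED-style
0-based half-open intervals appear only at serialization boundaries
(`hotspots.bed`). Variants are stored in VCF normal form: parsimony-trimmed
and left-aligned, insertions anchored on the reference base to their left.
Left-alignment (the `vt` algorithm) makes any placement of an indel inside
a repeat collapse to one canonical record, so call sets can be compared by
exact `(pos, ref, alt)` identity. Protein-level naming of in-frame
deletions follows the HGVS 3'-rule instead (right-shifted within repeats,
e.g. `L68_A69del`); the conversion happens during annotation, not in the
variant model.

## Collinear variant calling

The caller assumes assembled, near-identical (≲ 1 % divergence),
rearrangement-free genomes — the situation of sibling isolates of one
strain. k-mers (default k = 21) unique in both genomes are collected, the
longest chain increasing in both coordinates is kept, same-diagonal
overlapping anchors merge into blocks, and anchors that straddle an indel
(overlap on a shifted diagonal) are dropped so the difference stays inside
an alignable gap. Inter-anchor gaps are aligned with match +1,
mismatch −2, gap open −4, gap extend −1 (Biopython's `PairwiseAligner`).
If fewer than half of the shared anchors fit one collinear chain, a
`NonCollinearError` is raised rather than returning a silently truncated
call set; a swapped-halves genome or an unrelated sequence both trigger it.

Calls from assemblies carry no read support, so the coverage/quality
filter (keep iff relative coverage > 0.5 **and** absolute coverage > 10
**and** Q ≥ 23; note the strict vs inclusive boundaries) passes
metadata-free variants with a logged warning. The filter acts on VCF
`DP`/`AF`/`QUAL` fields when present and is monotone in its thresholds.

## Mutational spectra and signature calls

Substitutions collapse onto six strand-symmetric base-pair classes.
Signature rules, all configurable (`SignatureConfig`):

| flag | rule | default |
|---|---|---|
| `MMR` | indel/SNP ratio ≥ r **and** transition fraction ≥ f | r = 0.2, f = 0.4 |
| `MutT_like` | A:T>C:G fraction ≥ f | f = 0.15 |
| `oxidative_GT` | G:C>T:A fraction ≥ f | f = 0.15 |

Profiles with fewer than 30 events return "insufficient data" and no
flags. Each flag carries a one-sided binomial p-value of its class count
against a configurable null spectrum (default: uniform over the six
classes). The thresholds encode the qualitative spectra of the pathways:
mismatch-repair loss elevates slippage indels and transitions; MutT loss
lets 8-oxo-dGTP mispair with A, producing A:T>C:G transversions; unrepaired
oxidative damage on the template strand produces G:C>T:A. They are
deliberately permissive cutoffs for flagging, not calibrated classifiers —
the binomial evidence is reported so users can apply their own stringency.

The hotspot scan bins variant positions into fixed windows (default
10 kb), pools adjacent windows until each bin expects ≥ 1 variant, and
tests the counts against a bin-size-proportional uniform expectation by
chi-square. A single variant is uninformative and returns p = 1 by
convention.

## Ka/Ks by site enumeration

Expected counts come from enumerating every coding site (each CDS
separately, so each frame of an overlapping pair contributes; initiator
codon included, terminal stop codons and internal stops excluded) and each
site's three alternative bases. With transition fraction *f*<sub>ts</sub>
estimated from the isolate's own SNPs (CDS + intergenic — the composition
is genome-wide, so restricting it would only add noise), the transition
alternative gets weight *f*<sub>ts</sub> and each transversion
(1 − *f*<sub>ts</sub>)/2; per-site weights sum to 1. Weights accumulate
into `na_exp` (missense) and `ns_exp` (synonymous); nonsense and stop-loss
alternatives are excluded from both, mirroring the exclusion of observed
nonsense SNPs. The two-class (ts/tv) weighting is the primary mode; a
six-class mode (`class_weights=`) renormalizes the three classes available
at each site and is provided for sensitivity analysis. Translation uses
the bacterial code (table 11).

Degenerate inputs return explicit statuses instead of numbers: no SNPs at
all, no synonymous SNP observed (the indel-only-isolate case), or a
degenerate expectation. An optional percentile bootstrap over variants
(`n_boot`) gives a CI on the ratio.

Hand-enumerated anchor: for the toy gene `ATG AAA TAA`, the 18 non-stop
alternatives split 16 missense : 1 synonymous (AAA→AAG) : 1 excluded
nonsense (AAA→TAA) under uniform weights, and na_exp = 5.25, ns_exp = 0.5
at *f*<sub>ts</sub> = 0.5. Both are frozen in the tests, alongside an
independent brute-force enumeration oracle.

## cgMLST typing and clustering

The ad hoc scheme keeps every reference CDS except those shorter than
120 bp, containing ambiguity codes, or paralogous (≥ 0.9 identity over
≥ 50 % of the shorter length — both members dropped; identity is computed
on the best local alignment after a shared-15-mer prefilter). These
parameters are declared package defaults — commercial schemes do not
publish theirs — and are all configurable.

Allele calling on a single collinear query projects each target interval
through the called variant set and assigns integer allele ids per target
in order of first observation (reference = 1). Contig-set queries use
exact flank-anchor search (24 bp flanks); targets truncated by contig
borders, hit in their flanks, or containing ambiguity codes are `MISSING`.
Allelic distance counts targets where both profiles are non-MISSING and
differ (pairwise deletion; the raw count is reported, not rescaled, and
the number of mutually comparable targets is recorded per pair). Note the
distance saturates: a target contributes at most 1 however many mutations
it carries.

UPGMA and the SNP/indel presence-absence tree share one agglomeration
routine: average linkage with the size-weighted Lance–Williams update,
merge height d/2, ties broken by the lexicographic label order of the
merged pair (each cluster labelled by its smallest leaf). The
presence/absence tree uses Manhattan (L1) distances over the 0/1 variant
matrix. The implementation is cross-checked in the tests against
exhaustive re-agglomeration from the raw matrix and against
`scipy.cluster.hierarchy.average`.

Set-specific gene content ("present in every isolate of group A, absent
from every isolate of group B") uses seed-and-extend presence testing:
11-mer seeds vote for a diagonal, the best candidate window is aligned
locally, and a gene counts as present iff identity ≥ 0.8 over ≥ 0.8 of its
length (both thresholds configurable). This reproduces the
plasmid-contig logic of comparing collection isolates that did or did not
retain a plasmid.

## Squatter convergence screening

Candidate resistance variants of a squatter colony are the normalized set
difference squatter − parent, retaining only CDS-overlapping indels and
missense/nonsense SNPs (synonymous and intergenic changes never qualify).
Convergence counts, per gene, the number of squatter isolates carrying a
qualifying change; the default threshold is n − 1 of n isolates
("all or nearly all"). Genes are counted separately by default;
user-defined `gene_groups` can merge loci (e.g. the sensor and regulator
of one two-component system) before counting, since whether such a pair
constitutes one locus is a biological judgement the package does not make.

## The simulator

`generate_ancestor` packs non-overlapping ORF-valid CDS (ATG start, one
terminal stop, no internal stops, codon usage matched to the GC target) on
both strands of an iid background at the same GC; realized GC lands within
±2 % of target for ≥ 100 kb genomes. `evolve` applies a
`MutatorRegime`: a mutation is an indel with probability `indel_fraction`,
else a substitution whose class is drawn from the six class weights and
whose site is drawn uniformly among bases of the matching pair — class
first, then site, so realized class proportions converge to the weights
regardless of genome composition. Indels are ±1–6 bp with 1 bp dominant;
with probability `indel_homopolymer_bias` an indel is a ±1 bp slippage
event at a homopolymer run ≥ 3 (reproducing the mutT-style C-insertion-in-
a-C-tract fixture).

Preset regimes (class order A:T>G:C, G:C>A:T, A:T>C:G, A:T>T:A, G:C>T:A,
G:C>C:G):

| preset | weights | indel fraction | homopolymer bias |
|---|---|---|---|
| MMR | .42 .42 .04 .04 .04 .04 | 0.45 | 0.8 |
| MutT | .08 .08 .72 .03 .06 .03 | 0.03 | 0.5 |
| oxidative | .15 .20 .05 .05 .50 .05 | 0.05 | 0.5 |
| wildtype | .32 .38 .05 .08 .08 .09 | 0.05 | 0.5 |

MMR reflects the indel- and transition-rich spectrum of mismatch-repair
loss; MutT the A:T>C:G dominance of 8-oxo-dGTP mispairing; "wildtype" is a
transition-biased, low-indel spectrum of a repair-proficient enteric
bacterium, used as the no-signature control.

Mutations within one lineage hit distinct sites of the root chromosome
(no multi-hit, no back-mutation), so ancestor-relative truth sets nest
exactly along every root-to-leaf path and applying an isolate's truth set
to the ancestor reproduces its genome byte-for-byte. Sites are reserved
with a buffer: ±2 bases around substitutions, and an asymmetric window
around indels (3 left / 16 right of the left-aligned record, plus the
whole homopolymer run for slippage events). The wide 3' margin matters:
two indels close together in quasi-periodic sequence can admit more than
one minimal normalized decomposition of the same sequence change, which
would make exact truth/call comparison ill-posed; the margin makes the
decomposition unique with overwhelming probability. The simulator counts
mutations per edge, not generations — storage durations and per-generation
rates are deliberately out of scope.

What the simulator does **not** emulate: recombination and horizontal
transfer, rearrangements, selection during growth, multi-hit sites,
sequencing error and coverage structure (truth variants carry no
read-support metadata), and trinucleotide context beyond homopolymer runs.
Passing tests therefore demonstrate correctness of the analysis logic on
clean collinear assemblies, not robustness to assembly artefacts or
recombination — on real data those enter through the upstream assembler
and the non-collinearity guard.

## Scales used in the shipped checks

The test suite and `scripts/acceptance.py` run on 30–50 kb genomes with
25–40 genes — large enough that every code path (multi-gene schemes,
paralog screens, both strands, homopolymer runs) is exercised and binomial
tolerances are tight, small enough that the whole suite runs in about a
minute. Calling round-trips use 200 mutations per 50 kb genome (0.4 %
divergence, the upper end of the intended regime); spectrum recovery uses
n = 1000 with ±3 binomial-SD tolerances; Ka/Ks calibration uses 50
replicates of 1000 coding SNPs (neutral mean within [0.9, 1.1]; rejecting
half of missense draws yields 0.5 ± 0.1); topology recovery uses a
two-branch, six-edge transfer tree with ≥ 40 mutations per edge, 20 seeds.
The `odyssey` CLI preset scales the collection scenario to ~0.5–1× of the
historical mutation counts.

## Known limitations

- The caller requires collinearity; genuinely rearranged isolates must be
  split at rearrangement breakpoints upstream.
- MNPs are split into SNPs for spectra and Ka/Ks; for annotation a joined
  MNP within one codon is handled, multi-codon MNPs are annotated per
  contained SNP.
- Gene presence testing is seed-based; homologs diverged far beyond the
  identity threshold (or lacking any conserved 11-mer) are invisible, which
  is the desired behaviour at the 80 % threshold but makes the method
  unsuitable for remote-homology search.
- Panel genes are matched by `gene_id` in the annotation; orthology search
  beyond exact id is out of scope.
- Allelic distances count MISSING-vs-present as "not comparable", never as
  a difference; with small schemes deep distances saturate at the target
  count.
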