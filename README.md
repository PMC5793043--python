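# mutrace

Comparative genomics of bacterial hypermutator strains maintained in
separate culture collections.

When sibling isolates of one ancestral strain spend a century in different
collections, mutations accumulate independently in each line — rapidly so
if the strain is a mutator (defective mismatch repair and/or oxidized-guanine
sanitation). `mutrace` implements the desk side of that analysis for
microbiologists and bioinformaticians working with assembled genomes:

- **Variant detection** between near-identical collinear genomes
  (unique-k-mer anchoring + optimal gap alignment), with VCF-normalized
  (left-aligned, parsimony-trimmed) output and the classical short-read
  coverage/quality filter (relative coverage > 0.5, absolute coverage > 10,
  Q ≥ 23).
- **Mutational spectra** over the six strand-collapsed substitution classes
  (A:T>G:C, G:C>A:T transitions; A:T>C:G, A:T>T:A, G:C>T:A, G:C>C:G
  transversions), indel/SNP ratios, and rule-based mutator-signature calls:
  MMR loss (indel-rich, transition-dominated), MutT loss (A:T>C:G), and
  oxidative G:C>T:A enrichment — each with binomial evidence statistics.
- **Ka/Ks by site enumeration**: every coding site's three alternatives are
  weighted by the isolate's own transition/transversion composition
  (the transition gets *f*<sub>ts</sub>, each transversion
  (1 − *f*<sub>ts</sub>)/2), giving expected nonsynonymous/synonymous
  totals; `Ka/Ks = (na_obs/ns_obs)/(na_exp/ns_exp)`, with nonsense changes
  excluded on both sides. A ratio near 1 indicates neutral accumulation,
  as expected for mutations fixed during dormant storage.
- **cgMLST-style phylogeography**: an ad hoc scheme from the reference CDS,
  gene-by-gene allele calling (new alleles numbered in order of first
  observation, `MISSING` for border-truncated targets), pairwise allelic
  distances with pairwise deletion, UPGMA dendrograms, plus average-linkage
  Manhattan clustering of SNP/indel presence/absence and export of the
  concatenated segregating-SNP alignment (FASTA/PHYLIP) for external ML
  inference.
- **Screening**: antimutator gene panels with HGVS-like protein naming
  (`R190C`, `L68_A69del`, `fs`), squatter-colony resistance-variant
  filtering (CDS indels + missense/nonsense SNPs absent from the parent),
  gene-level convergence counting, and set-specific gene content at
  ≥ 80 % identity / ≥ 80 % coverage (plasmid-contig logic).
- **A forward simulator** of mutator evolution along a collection-transfer
  tree, with exact ground-truth variant sets for every isolate — the test
  bed for everything above.

## Worked example

Simulate five isolates along a transfer chain (an English pair derived
from the reference, then a French → American → German lineage) and run the
full analysis:

```sh
printf 'genome_length: 50000\nn_genes: 40\nplan_scale: 0.5\n' > demo.yaml
mutrace simulate --config demo.yaml --seed 1 --out demo
mutrace analyze --in demo --out demo_out
```

`demo_out/signatures.tsv` recovers the mutagenesis regimes of the
simulation — mismatch-repair loss in the early English isolates, MutT-type
mutagenesis in the later lineage:

```
isolate     status  flags
ENG_Meric   ok      MMR
ENG_NCTC    ok      MMR
FRA_CIP     ok      MutT_like
GER_DSM     ok      MutT_like
USA_ATCC    ok      MutT_like
```

`demo_out/kaks.tsv` shows ratios drifting toward 1 as SNP counts grow,
the neutral-accumulation signal (isolates with few synonymous events have
noisy ratios; an isolate with no synonymous SNPs is reported as undefined):

```
isolate     na_obs  ns_obs  na_exp    ns_exp    ratio   n_excluded_nonsense  status
ENG_Meric   8       6       23457.07  11422.50  0.6493  0                    ok
FRA_CIP     44      17      25760.92  8713.17   0.8754  3                    ok
GER_DSM     190     63      26023.16  8404.78   0.9740  7                    ok
USA_ATCC    160     55      26042.48  8382.06   0.9363  7                    ok
```

`demo_out/cgmlst_upgma.nwk` groups the English/French isolates against the
American/German pair (with only 40 scheme targets the deepest distances
saturate at 40 — every target can differ at most once):

```
(((ENG_Meric:12.5,ENG_NCTC:12.5):2.25,FRA_CIP:14.75):5.25,(GER_DSM:13.5,USA_ATCC:13.5):6.5);
```

The spectra table (`spectra.tsv`) carries the per-class counts and
indel/SNP ratios behind the signature calls, `hotspots.bed` the per-window
variant counts with a chi-square uniformity p-value, and
`snp_alignment.fasta` / `.phy` the concatenated SNP columns.

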