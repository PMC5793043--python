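"""Forward simulation of mutator evolution along a culture-collection history.

The generator builds an annotated ancestral chromosome (random intergenic
sequence at a target GC content, packed with non-overlapping ORF-valid CDS
on both strands) and evolves derived isolates along a transfer tree.  Each
edge applies a configurable :class:`MutatorRegime`: a six-class substitution
bias, an indel fraction, and a homopolymer bias that concentrates +-1 bp
indels inside mononucleotide runs — the hallmarks of mismatch-repair and
MutT-type hypermutators.

All mutations within one lineage hit distinct, non-adjacent sites of the
root chromosome, so the per-isolate truth sets are exact, stay normalized,
and nest along every root-to-leaf path (no back-mutation, no multi-hit).
Applying an isolate's truth set to the ancestor reproduces its genome
byte-for-byte; this is the invariant every caller test leans on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import (
    AnnotatedGenome,
    CdsFeature,
    Variant,
    VariantSet,
    apply_variants,
    normalize_variant,
    revcomp,
)
from .spectrum_stats import SUBSTITUTION_CLASSES, classify_substitution

# alt base implied by (class, ref base); ref base must belong to the class pair
_ALT_FOR = {
    ("A:T>G:C", "A"): "G", ("A:T>G:C", "T"): "C",
    ("G:C>A:T", "G"): "A", ("G:C>A:T", "C"): "T",
    ("A:T>C:G", "A"): "C", ("A:T>C:G", "T"): "G",
    ("A:T>T:A", "A"): "T", ("A:T>T:A", "T"): "A",
    ("G:C>T:A", "G"): "T", ("G:C>T:A", "C"): "A",
    ("G:C>C:G", "G"): "C", ("G:C>C:G", "C"): "G",
}

_STOPS = ("TAA", "TGA", "TAG")


class SiteExhaustionError(RuntimeError):
    """Raised when no unused site compatible with the drawn mutation remains."""


@dataclass(frozen=True)
class MutatorRegime:
    """Mutation-process parameters for one evolutionary edge.

    ``class_weights`` are the relative rates of the six strand-collapsed
    substitution classes; ``indel_fraction`` is the fraction of mutation
    events that are indels; ``indel_homopolymer_bias`` is the probability
    that an indel is a +-1 bp slippage event inside a homopolymer run >= 3.
    """

    name: str
    class_weights: tuple[float, ...]
    indel_fraction: float = 0.1
    indel_homopolymer_bias: float = 0.5

    def __post_init__(self) -> None:
        if len(self.class_weights) != 6:
            raise ValueError("class_weights must have 6 entries")
        if any(w < 0 for w in self.class_weights) or sum(self.class_weights) <= 0:
            raise ValueError("class_weights must be nonnegative and normalizable")
        if not 0 <= self.indel_fraction < 1:
            raise ValueError("indel_fraction must lie in [0, 1)")
        if not 0 <= self.indel_homopolymer_bias <= 1:
            raise ValueError("indel_homopolymer_bias must lie in [0, 1]")

    @property
    def weights(self) -> np.ndarray:
        w = np.asarray(self.class_weights, dtype=float)
        return w / w.sum()


# Preset regimes.  Class order: A:T>G:C, G:C>A:T, A:T>C:G, A:T>T:A, G:C>T:A,
# G:C>C:G.  "MMR": mismatch-repair loss, transition-dominated with abundant
# slippage indels.  "MutT": 8-oxo-dGTP sanitation loss, A:T>C:G dominated.
# "oxidative": G:C>T:A enrichment from unrepaired 8-oxo-G in the template.
# "wildtype": transition-biased low-indel spectrum of a repair-proficient
# strain, used as the no-signature control.
REGIMES: dict[str, MutatorRegime] = {
    "MMR": MutatorRegime("MMR", (0.42, 0.42, 0.04, 0.04, 0.04, 0.04),
                         indel_fraction=0.45, indel_homopolymer_bias=0.8),
    "MutT": MutatorRegime("MutT", (0.08, 0.08, 0.72, 0.03, 0.06, 0.03),
                          indel_fraction=0.03, indel_homopolymer_bias=0.5),
    "oxidative": MutatorRegime("oxidative", (0.15, 0.20, 0.05, 0.05, 0.50, 0.05),
                               indel_fraction=0.05, indel_homopolymer_bias=0.5),
    "wildtype": MutatorRegime("wildtype", (0.32, 0.38, 0.05, 0.08, 0.08, 0.09),
                              indel_fraction=0.05, indel_homopolymer_bias=0.5),
}


@dataclass(frozen=True)
class LineagePlan:
    """A rooted transfer tree: edges (parent, child, n_mutations, regime)."""

    root_label: str
    edges: tuple[tuple[str, str, int, MutatorRegime], ...]

    def __post_init__(self) -> None:
        known = {self.root_label}
        for parent, child, n, regime in self.edges:
            if parent not in known:
                raise ValueError(f"edge parent {parent!r} unknown (edges must be "
                                 "listed parent-first)")
            if child in known:
                raise ValueError(f"duplicate node {child!r}")
            if n < 0:
                raise ValueError("n_mutations must be >= 0")
            known.add(child)

    @property
    def labels(self) -> list[str]:
        return [self.root_label] + [child for _, child, _, _ in self.edges]


@dataclass
class TruthRecord:
    variant: Variant
    mclass: str          # substitution class, "INS" or "DEL"
    edge: tuple[str, str]


@dataclass
class TruthSet:
    """Ground-truth variant sets (vs the root genome) for every isolate."""

    root_id: str
    sets: dict[str, VariantSet] = field(default_factory=dict)
    records: dict[str, list[TruthRecord]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Ancestor construction
# ---------------------------------------------------------------------------

def _codon_weights(gc: float, rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
    base_p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    codons = ["".join((a, b, c))
              for a in "ACGT" for b in "ACGT" for c in "ACGT"]
    codons = [c for c in codons if c not in _STOPS]
    w = np.array([base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in codons])
    return codons, w / w.sum()


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def generate_ancestor(length: int, gc: float, n_genes: int, mean_gene_len: int,
                      seed: int, min_spacer: int = 50) -> AnnotatedGenome:
    """Build a random annotated ancestral chromosome.

    CDS are non-overlapping, placed on alternating random strands, each an
    ORF-valid gene (ATG start, single terminal stop, no internal stops) whose
    codon usage matches the target GC.  Intergenic spacers are iid bases at
    the same GC.  Raises ``ValueError`` when the genes cannot be packed or
    the GC target leaves no usable codons.
    """
    if not 0.2 <= gc <= 0.8:
        raise ValueError("gc must lie in [0.2, 0.8] for valid codon sampling")
    rng = np.random.default_rng(seed)
    codons, codon_p = _codon_weights(gc, rng)

    # gene lengths in codons (incl. start, excl. stop), >= 30 codons
    mean_codons = max(31, mean_gene_len // 3)
    n_codons = np.maximum(30, rng.normal(mean_codons, mean_codons / 8, n_genes)
                          .round().astype(int))
    gene_lens = (n_codons + 1) * 3          # + terminal stop
    total_genes = int(gene_lens.sum())
    slack = length - total_genes - min_spacer * (n_genes + 1)
    if slack < 0:
        raise ValueError("infeasible packing: genome too short for requested genes")

    # distribute the slack over the n_genes+1 spacers
    extra = rng.multinomial(slack, np.full(n_genes + 1, 1 / (n_genes + 1)))
    spacers = extra + min_spacer

    parts: list[str] = []
    features: list[CdsFeature] = []
    pos = 0
    for i in range(n_genes):
        parts.append(_random_bases(int(spacers[i]), gc, rng))
        pos += int(spacers[i])
        body = "".join(rng.choice(codons, size=int(n_codons[i]) - 1, p=codon_p))
        coding = "ATG" + body + str(rng.choice(_STOPS))
        strand = "+" if rng.random() < 0.5 else "-"
        placed = coding if strand == "+" else revcomp(coding)
        start = pos + 1
        parts.append(placed)
        pos += len(placed)
        features.append(CdsFeature(gene_id=f"gene{i + 1:04d}", start=start,
                                   end=pos, strand=strand, phase=0,
                                   product="hypothetical protein"))
    parts.append(_random_bases(int(spacers[-1]), gc, rng))
    sequence = "".join(parts)
    assert len(sequence) == length
    return AnnotatedGenome(id=f"ancestor_seed{seed}", sequence=sequence,
                           circular=True, features=features)


# ---------------------------------------------------------------------------
# Mutation drawing
# ---------------------------------------------------------------------------

_INDEL_LEN_P = np.array([0.55, 0.20, 0.10, 0.07, 0.05, 0.03])  # lengths 1..6


class _MutationDrawer:
    """Draws normalized root-coordinate mutations on distinct, buffered sites."""

    def __init__(self, root: AnnotatedGenome):
        self.root = root
        self.seq = root.sequence
        arr = np.frombuffer(self.seq.encode(), dtype="S1")
        self.positions_by_pair = {
            "A:T": np.flatnonzero((arr == b"A") | (arr == b"T")) + 1,
            "G:C": np.flatnonzero((arr == b"G") | (arr == b"C")) + 1,
        }
        self.runs = self._homopolymer_runs(self.seq)

    @staticmethod
    def _homopolymer_runs(seq: str, min_len: int = 3) -> list[tuple[int, int, str]]:
        runs = []
        i, n = 0, len(seq)
        while i < n:
            j = i
            while j < n and seq[j] == seq[i]:
                j += 1
            if j - i >= min_len and 0 < i:  # need a left anchor base
                runs.append((i + 1, j - i, seq[i]))  # 1-based start
            i = j
        return runs

    def _free(self, used: set[int], lo: int, hi: int) -> bool:
        return all(p not in used for p in range(lo, hi + 1))

    def _reserve(self, used: set[int], lo: int, hi: int) -> None:
        used.update(range(lo, hi + 1))

    def draw(self, regime: MutatorRegime, n: int, rng: np.random.Generator,
             used: set[int]) -> list[tuple[Variant, str]]:
        out: list[tuple[Variant, str]] = []
        w = regime.weights
        for _ in range(n):
            if rng.random() < regime.indel_fraction:
                out.append(self._draw_indel(regime, rng, used))
            else:
                out.append(self._draw_snp(w, rng, used))
        return out

    def _draw_snp(self, w: np.ndarray, rng: np.random.Generator,
                  used: set[int]) -> tuple[Variant, str]:
        for _ in range(10_000):
            cls = SUBSTITUTION_CLASSES[rng.choice(6, p=w)]
            pair = cls.split(">")[0]
            candidates = self.positions_by_pair[pair]
            pos = int(candidates[rng.integers(len(candidates))])
            if not self._free(used, pos - 2, pos + 2):
                continue
            ref = self.seq[pos - 1]
            v = Variant(chrom=self.root.id, pos=pos, ref=ref,
                        alt=_ALT_FOR[(cls, ref)])
            self._reserve(used, pos - 2, pos + 2)
            return v, cls
        raise SiteExhaustionError("no free site for substitution")

    # Exclusion margin around indels.  Two indels (or an indel plus nearby
    # substitutions) closer than the local repeat structure allows admit
    # more than one minimal normalized decomposition of the same sequence
    # change, which would break exact truth/call set comparison.  A wide
    # one-sided margin on the 3' side (where a left-aligned indel can
    # migrate) makes the decomposition unique with overwhelming probability.
    INDEL_MARGIN_LEFT = 3
    INDEL_MARGIN_RIGHT = 16

    def _draw_indel(self, regime: MutatorRegime, rng: np.random.Generator,
                    used: set[int]) -> tuple[Variant, str]:
        for _ in range(10_000):
            if self.runs and rng.random() < regime.indel_homopolymer_bias:
                start, run_len, base = self.runs[rng.integers(len(self.runs))]
                anchor = start - 1
                lo = anchor - self.INDEL_MARGIN_LEFT
                hi = start + run_len + self.INDEL_MARGIN_RIGHT
                if not self._free(used, lo, hi):
                    continue
                a = self.seq[anchor - 1]
                if rng.random() < 0.5:  # +1 slippage insertion
                    v = Variant(chrom=self.root.id, pos=anchor, ref=a, alt=a + base)
                    mclass = "INS"
                else:                   # -1 slippage deletion
                    v = Variant(chrom=self.root.id, pos=anchor,
                                ref=a + base, alt=a)
                    mclass = "DEL"
                self._reserve(used, lo, hi)
                return v, mclass
            # unbiased indel, length 1-6, length 1 dominant
            length = int(rng.choice(6, p=_INDEL_LEN_P)) + 1
            pos = int(rng.integers(2, len(self.seq) - length - 1))
            a = self.seq[pos - 1]
            if rng.random() < 0.5:
                ins = _random_bases(length, 0.5, rng)
                v = Variant(chrom=self.root.id, pos=pos, ref=a, alt=a + ins)
                mclass = "INS"
            else:
                v = Variant(chrom=self.root.id, pos=pos,
                            ref=self.seq[pos - 1: pos + length], alt=a)
                mclass = "DEL"
            v = normalize_variant(v, self.seq)
            lo = v.pos - self.INDEL_MARGIN_LEFT
            hi = v.end + self.INDEL_MARGIN_RIGHT
            if not self._free(used, lo, hi):
                continue
            self._reserve(used, lo, hi)
            return v, mclass
        raise SiteExhaustionError("no free site for indel")


def _project_features(features: list[CdsFeature],
                      variants: list[Variant]) -> list[CdsFeature]:
    """Shift feature coordinates through a variant set; frameshifted CDS
    are flagged pseudo.  Assumes variants do not cross feature boundaries
    ambiguously (guaranteed by the buffered drawing scheme)."""
    indels = [v for v in variants if v.is_indel]
    out = []
    for f in features:
        start, end = f.start, f.end
        pseudo = f.pseudo
        for v in indels:
            delta = len(v.alt) - len(v.ref)
            if v.end < f.start:
                start += delta
                end += delta
            elif v.pos >= f.start and v.end <= f.end:
                end += delta
                if delta % 3 != 0:
                    pseudo = True
            elif v.pos < f.start <= v.end or v.pos <= f.end < v.end:
                pseudo = True  # indel straddles a boundary; coordinates kept
        out.append(replace(f, start=start, end=end, pseudo=pseudo))
    return out


def evolve(genome: AnnotatedGenome, regime: MutatorRegime, n_mutations: int,
           seed: int | np.random.Generator,
           derived_id: str | None = None) -> tuple[AnnotatedGenome, VariantSet]:
    """Evolve one derived genome: exactly ``n_mutations`` distinct-site
    mutations drawn under ``regime``; returns the derived genome and the
    normalized truth set against ``genome``."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    drawer = _MutationDrawer(genome)
    used: set[int] = set()
    drawn = drawer.draw(regime, n_mutations, rng, used)
    variants = [v for v, _ in drawn]
    truth = VariantSet(reference_id=genome.id,
                       isolate_id=derived_id or f"{genome.id}_derived",
                       variants=variants)
    derived_seq = apply_variants(truth, genome.sequence)
    derived = AnnotatedGenome(id=truth.isolate_id, sequence=derived_seq,
                              circular=genome.circular,
                              features=_project_features(genome.features,
                                                         truth.variants))
    return derived, truth


def simulate_collection_history(ancestor: AnnotatedGenome, plan: LineagePlan,
                                seed: int) -> tuple[dict[str, AnnotatedGenome], TruthSet]:
    """Evolve isolates along a transfer tree.

    Mutations accumulate on distinct root-genome sites along each lineage
    path, so ancestor-relative truth sets are nested root-to-leaf.  Every
    edge consumes its own seeded substream; identical (ancestor, plan, seed)
    inputs give byte-identical outputs.
    """
    drawer = _MutationDrawer(ancestor)
    acc: dict[str, list[tuple[Variant, str, tuple[str, str]]]] = {
        plan.root_label: []}
    used_by_node: dict[str, set[int]] = {plan.root_label: set()}
    for i, (parent, child, n, regime) in enumerate(plan.edges):
        rng = np.random.default_rng([seed, i])
        used = set(used_by_node[parent])
        drawn = drawer.draw(regime, n, rng, used)
        acc[child] = acc[parent] + [(v, c, (parent, child)) for v, c in drawn]
        used_by_node[child] = used

    genomes: dict[str, AnnotatedGenome] = {}
    truth = TruthSet(root_id=ancestor.id)
    for label in plan.labels:
        records = sorted(acc[label], key=lambda t: t[0].pos)
        vset = VariantSet(reference_id=ancestor.id, isolate_id=label,
                          variants=[v for v, _, _ in records])
        seq = apply_variants(vset, ancestor.sequence)
        if label == plan.root_label:
            genomes[label] = AnnotatedGenome(
                id=label, sequence=ancestor.sequence, circular=ancestor.circular,
                features=list(ancestor.features))
        else:
            genomes[label] = AnnotatedGenome(
                id=label, sequence=seq, circular=ancestor.circular,
                features=_project_features(ancestor.features, vset.variants))
        truth.sets[label] = vset
        truth.records[label] = [TruthRecord(v, c, e) for v, c, e in records]
    return genomes, truth


# ---------------------------------------------------------------------------
# Squatter fixtures and targeted coding mutations
# ---------------------------------------------------------------------------

def _codon_info(genome: AnnotatedGenome, feat: CdsFeature, codon_index: int
                ) -> tuple[str, list[int]]:
    """Codon string (coding strand) and its genomic positions, 5'->3' on the
    coding strand, for 1-based ``codon_index``."""
    off = (codon_index - 1) * 3
    if feat.strand == "+":
        gpos = [feat.start + feat.phase + off + k for k in range(3)]
        codon = "".join(genome.sequence[p - 1] for p in gpos)
    else:
        gpos = [feat.end - feat.phase - off - k for k in range(3)]
        codon = "".join(revcomp(genome.sequence[p - 1]) for p in gpos)
    return codon, gpos


def _genomic_snp(genome: AnnotatedGenome, feat: CdsFeature, gpos: int,
                 coding_alt: str) -> Variant:
    alt = coding_alt if feat.strand == "+" else revcomp(coding_alt)
    return Variant(chrom=genome.id, pos=gpos,
                   ref=genome.sequence[gpos - 1], alt=alt)


from .selection_kaks import CODON_TO_AA  # noqa: E402  (leaf import, no cycle)


def draw_coding_snp(genome: AnnotatedGenome, feat: CdsFeature,
                    rng: np.random.Generator,
                    want: str) -> Variant | None:
    """Draw one SNP of effect ``want`` ('missense' | 'synonymous') in a CDS."""
    n_codons = feat.n_codons - 1  # exclude terminal stop
    for _ in range(500):
        ci = int(rng.integers(2, max(3, n_codons)))  # skip initiator codon
        codon, gpos = _codon_info(genome, feat, ci)
        if CODON_TO_AA.get(codon, "*") == "*":
            continue
        k = int(rng.integers(3))
        old = codon[k]
        new = "ACGT"[int(rng.integers(4))]
        if new == old:
            continue
        alt_codon = codon[:k] + new + codon[k + 1:]
        aa0, aa1 = CODON_TO_AA[codon], CODON_TO_AA[alt_codon]
        effect = ("synonymous" if aa0 == aa1
                  else "nonsense" if aa1 == "*" else "missense")
        if effect == want:
            return _genomic_snp(genome, feat, gpos[k], new)
    return None


def make_squatter_fixture(parent: AnnotatedGenome, target_gene: str,
                          change_kind: str, seed: int,
                          n_background: int = 6,
                          derived_id: str | None = None
                          ) -> tuple[AnnotatedGenome, VariantSet]:
    """Derive a squatter-like genome from ``parent``: exactly one CDS-altering
    change of ``change_kind`` ('missense' | 'frameshift') in ``target_gene``
    plus ``n_background`` background mutations (synonymous in other genes and
    intergenic SNPs) that must not pass the resistance-variant filter."""
    if change_kind not in ("missense", "frameshift"):
        raise ValueError("change_kind must be 'missense' or 'frameshift'")
    rng = np.random.default_rng(seed)
    feat = parent.feature_by_id(target_gene)
    variants: list[Variant] = []

    if change_kind == "missense":
        v = draw_coding_snp(parent, feat, rng, "missense")
        if v is None:
            raise RuntimeError(f"could not place a missense SNP in {target_gene}")
        variants.append(v)
    else:
        # +1 insertion in the middle third of the CDS -> guaranteed frameshift
        lo = feat.start + feat.length // 3
        hi = feat.end - feat.length // 3
        pos = int(rng.integers(lo, hi))
        a = parent.sequence[pos - 1]
        ins = "ACGT"[int(rng.integers(4))]
        variants.append(normalize_variant(
            Variant(chrom=parent.id, pos=pos, ref=a, alt=a + ins), parent))

    other = [f for f in parent.features if f.gene_id != target_gene and not f.pseudo]
    covered = {p for v in variants for p in range(v.pos - 1, v.end + 2)}
    in_cds = np.zeros(len(parent) + 2, dtype=bool)
    for f in parent.features:
        in_cds[f.start:f.end + 1] = True
    n_syn = n_background // 2
    for _ in range(n_syn):
        for _ in range(200):
            f = other[int(rng.integers(len(other)))]
            v = draw_coding_snp(parent, f, rng, "synonymous")
            if v is not None and not ({v.pos - 1, v.pos, v.pos + 1} & covered):
                variants.append(v)
                covered.update((v.pos - 1, v.pos, v.pos + 1))
                break
    for _ in range(n_background - n_syn):
        for _ in range(200):
            pos = int(rng.integers(2, len(parent)))
            if in_cds[pos] or ({pos - 1, pos, pos + 1} & covered):
                continue
            ref = parent.sequence[pos - 1]
            alt = rng.permutation([b for b in "ACGT" if b != ref])[0]
            variants.append(Variant(chrom=parent.id, pos=pos, ref=ref, alt=str(alt)))
            covered.update((pos - 1, pos, pos + 1))
            break

    truth = VariantSet(reference_id=parent.id,
                       isolate_id=derived_id or f"{parent.id}_squatter",
                       variants=variants)
    derived = AnnotatedGenome(id=truth.isolate_id,
                              sequence=apply_variants(truth, parent.sequence),
                              circular=parent.circular,
                              features=_project_features(parent.features,
                                                         truth.variants))
    return derived, truth


def simulate_coding_snps(genome: AnnotatedGenome, n: int, ts_fraction: float,
                         seed: int | np.random.Generator,
                         missense_retention: float = 1.0,
                         isolate_id: str = "sim") -> VariantSet:
    """Draw ``n`` coding SNPs with a fixed transition fraction.

    Sites are uniform over coding positions; the alternative base is the
    transition with probability ``ts_fraction``, else one of the two
    transversions.  With ``missense_retention`` < 1, missense draws are
    rejected (redrawn) with probability 1 - retention, emulating purifying
    selection; synonymous and nonsense draws are always kept.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    transition_of = {"A": "G", "G": "A", "C": "T", "T": "C"}
    sites = []  # (feature, codon_index, within_codon)
    for f in genome.features:
        if f.pseudo:
            continue
        for ci in range(2, f.n_codons):          # skip initiator & stop
            for k in range(3):
                sites.append((f, ci, k))
    if not sites:
        raise ValueError("genome has no usable coding sites")
    used: set[int] = set()
    variants: list[Variant] = []
    attempts = 0
    while len(variants) < n:
        attempts += 1
        if attempts > 200 * n:
            raise SiteExhaustionError("could not place requested coding SNPs")
        f, ci, k = sites[int(rng.integers(len(sites)))]
        codon, gpos = _codon_info(genome, f, ci)
        if CODON_TO_AA.get(codon, "*") == "*":
            continue
        if gpos[k] in used:
            continue
        old = codon[k]
        if rng.random() < ts_fraction:
            new = transition_of[old]
        else:
            tv = [b for b in "ACGT" if b != old and b != transition_of[old]]
            new = tv[int(rng.integers(2))]
        alt_codon = codon[:k] + new + codon[k + 1:]
        aa0, aa1 = CODON_TO_AA[codon], CODON_TO_AA[alt_codon]
        if aa0 != aa1 and aa1 != "*" and rng.random() > missense_retention:
            continue
        variants.append(_genomic_snp(genome, f, gpos[k], new))
        used.add(gpos[k])
    return VariantSet(reference_id=genome.id, isolate_id=isolate_id,
                      variants=variants)


def odyssey_plan(scale: float = 1.0) -> LineagePlan:
    """The default collection-transfer scenario: an English pair derived
    directly from the reference, then a French -> American -> German chain,
    with mismatch-repair mutagenesis first and MutT / oxidative regimes
    appearing later — mirroring a century of storage in separate collections.
    Mutation counts scale linearly with ``scale``."""
    s = lambda n: max(1, int(round(n * scale)))
    return LineagePlan(
        root_label="REF_Dunne",
        edges=(
            ("REF_Dunne", "ENG_Meric", s(60), REGIMES["MMR"]),
            ("REF_Dunne", "ENG_NCTC", s(80), REGIMES["MMR"]),
            ("ENG_NCTC", "FRA_CIP", s(150), REGIMES["MutT"]),
            ("FRA_CIP", "USA_ATCC", s(420), REGIMES["MutT"]),
            ("USA_ATCC", "GER_DSM", s(120), REGIMES["oxidative"]),
        ),
    )
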