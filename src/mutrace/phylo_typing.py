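"""Core-genome typing and phylogeography.

Reproduces the gene-by-gene view of collection divergence: an ad hoc
core-genome MLST (cgMLST) scheme is built from the reference CDS, alleles
are called per target in each query genome (novel sequences receive new
integer allele ids in order of first observation), and pairwise allelic
distances feed a UPGMA dendrogram.  A complementary whole-genome view
clusters isolates by average-linkage on Manhattan distances over the
presence/absence matrix of SNPs and indels.  The concatenated segregating
SNP columns can be exported (FASTA / relaxed PHYLIP) for external
maximum-likelihood inference, and gene content can be compared across
isolate groups (the plasmid-contig logic: genes present in one collection's
isolates and absent from the others at >=80% identity and coverage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy.spatial.distance import pdist, squareform

from .core_io import (
    AnnotatedGenome,
    ProjectionAmbiguousError,
    VariantSet,
    project_interval,
    revcomp,
)
from .variant_analysis import call_variants_collinear

MISSING = None  # allele sentinel for absent / border-truncated targets


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Rooted ultrametric tree node; leaves carry labels, internal nodes
    carry merge heights (in distance/2 units, the UPGMA convention)."""

    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    height: float = 0.0
    branch_length: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def clades(self) -> set[frozenset[str]]:
        """All non-trivial leaf sets of internal nodes (for topology tests)."""
        out: set[frozenset[str]] = set()

        def walk(node: "TreeNode") -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 1 < len(below):
                out.add(below)
            return below

        walk(self)
        return out

    def to_newick(self) -> str:
        def fmt(node: "TreeNode") -> str:
            bl = "" if node.branch_length is None else f":{node.branch_length:g}"
            if node.is_leaf:
                return f"{node.label}{bl}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){bl}"

        return fmt(self) + ";"


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair comparable-target counts."""

    labels: list[str]
    matrix: np.ndarray
    n_compared: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
            raise ValueError("matrix must be symmetric, nonnegative, zero-diagonal")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def _agglomerate(labels: list[str], dist: np.ndarray) -> TreeNode:
    """Average-linkage agglomeration (UPGMA) with deterministic tie-breaks.

    At each step the minimum-distance cluster pair merges at height d/2;
    ties are broken by the lexicographic order of the merged pair's labels
    (each cluster labelled by its lexicographically smallest leaf).
    Distances update by the size-weighted Lance-Williams rule, which keeps
    average linkage exact with respect to the original matrix.
    """
    n = len(labels)
    if n == 0:
        raise ValueError("empty distance matrix")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(label=labels[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    tags = {i: labels[i] for i in range(n)}  # lexicographically smallest leaf
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if i >= j:
                    continue
                key = d[(i, j)]
                tag = tuple(sorted((tags[i], tags[j])))
                if best is None or (key, tag) < (best[0], best[1]):
                    best = (key, tag, i, j)
        dmin, _, i, j = best
        h = dmin / 2.0
        left, right = nodes[i], nodes[j]
        if tags[j] < tags[i]:
            left, right = right, left
        for c in (left, right):
            c.branch_length = h - c.height
        merged = TreeNode(children=[left, right], height=h)
        nodes[next_id] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        tags[next_id] = min(tags[i], tags[j])
        for k in active:
            if k in (i, j):
                continue
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            d[(min(next_id, k), max(next_id, k))] = dnew
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    root = nodes[active.pop()]
    root.branch_length = None
    return root


def upgma(matrix: DistanceMatrix) -> TreeNode:
    """UPGMA tree of a distance matrix (ultrametric; heights = distance/2)."""
    return _agglomerate(matrix.labels, matrix.matrix)


# ---------------------------------------------------------------------------
# cgMLST scheme and allele calling
# ---------------------------------------------------------------------------

@dataclass
class CgScheme:
    """cgMLST targets: (gene_id, reference allele sequence on coding strand)."""

    provenance: str
    targets: list[tuple[str, str]]

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.targets]


def _identity_over(a: str, b: str, aligner: Align.PairwiseAligner
                   ) -> tuple[float, int]:
    """(identity, aligned columns) of the best local alignment of a vs b."""
    aln = aligner.align(a, b)
    if len(aln) == 0:
        return 0.0, 0
    best = aln[0]
    ablocks, bblocks = best.aligned
    matches = cols = 0
    for (as_, ae), (bs, be) in zip(ablocks, bblocks):
        seg_a, seg_b = a[as_:ae], b[bs:be]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
        cols += ae - as_
    if cols == 0:
        return 0.0, 0
    return matches / cols, cols


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    return aligner


def build_scheme(reference: AnnotatedGenome, min_len: int = 120,
                 max_paralog_identity: float = 0.9) -> CgScheme:
    """Construct an ad hoc cgMLST scheme from the reference CDS.

    Excluded: CDS shorter than ``min_len`` bp, CDS containing ambiguity
    codes, and paralogous pairs (>= ``max_paralog_identity`` identical over
    >= 50% of the shorter length — both members dropped).
    """
    if not reference.features:
        raise ValueError("reference genome carries no CDS annotation")
    candidates = []
    for f in reference.features:
        seq = reference.sequence[f.start - 1: f.end]
        if f.strand == "-":
            seq = revcomp(seq)
        if f.length < min_len or set(seq) - set("ACGT"):
            continue
        candidates.append((f.gene_id, seq))

    # paralog screen with a shared-15-mer prefilter before alignment
    kmer_owners: dict[str, set[int]] = {}
    for idx, (_, seq) in enumerate(candidates):
        for i in range(0, len(seq) - 15 + 1, 5):
            kmer_owners.setdefault(seq[i:i + 15], set()).add(idx)
    suspect_pairs = set()
    for owners in kmer_owners.values():
        if len(owners) > 1:
            olist = sorted(owners)
            for i in range(len(olist)):
                for j in range(i + 1, len(olist)):
                    suspect_pairs.add((olist[i], olist[j]))
    aligner = _local_aligner()
    dropped: set[int] = set()
    for i, j in sorted(suspect_pairs):
        a, b = candidates[i][1], candidates[j][1]
        identity, cols = _identity_over(a, b, aligner)
        if identity >= max_paralog_identity and cols >= 0.5 * min(len(a), len(b)):
            dropped.update((i, j))
    targets = [c for idx, c in enumerate(candidates) if idx not in dropped]
    return CgScheme(provenance=reference.id, targets=targets)


@dataclass
class AlleleProfile:
    """Integer allele id per scheme target (1 = reference), MISSING if absent."""

    isolate_id: str
    alleles: dict[str, int | None]


class AlleleCaller:
    """Gene-by-gene allele calling against one scheme.

    Allele ids are assigned per target in order of first observation across
    all queries passed through one caller instance (reference allele = 1).
    Collinear single-sequence queries are resolved by calling variants once
    and projecting each target interval; contig sets are resolved by exact
    flank-anchor search, with MISSING for targets truncated by contig
    borders or hit by flank mutations.
    """

    def __init__(self, scheme: CgScheme, reference: AnnotatedGenome,
                 flank: int = 24):
        self.scheme = scheme
        self.reference = reference
        self.flank = flank
        self.registry: dict[str, dict[str, int]] = {}
        feats = {f.gene_id: f for f in reference.features}
        self._feats = {g: feats[g] for g, _ in scheme.targets if g in feats}
        for gene_id, ref_allele in scheme.targets:
            self.registry[gene_id] = {ref_allele: 1}

    def _assign(self, gene_id: str, seq: str) -> int:
        reg = self.registry[gene_id]
        if seq not in reg:
            reg[seq] = max(reg.values()) + 1
        return reg[seq]

    def call_collinear(self, query: AnnotatedGenome) -> AlleleProfile:
        vset = call_variants_collinear(self.reference, query)
        return self.call_from_variants(vset, query.sequence,
                                       isolate_id=query.id)

    def call_from_variants(self, vset: VariantSet, query_sequence: str,
                           isolate_id: str) -> AlleleProfile:
        alleles: dict[str, int | None] = {}
        for gene_id, _ in self.scheme.targets:
            f = self._feats[gene_id]
            try:
                qs, qe = project_interval(vset, f.start, f.end)
            except ProjectionAmbiguousError:
                alleles[gene_id] = MISSING
                continue
            seq = query_sequence[qs - 1: qe]
            if f.strand == "-":
                seq = revcomp(seq)
            if set(seq) - set("ACGT"):
                alleles[gene_id] = MISSING
                continue
            alleles[gene_id] = self._assign(gene_id, seq)
        return AlleleProfile(isolate_id=isolate_id, alleles=alleles)

    def call_contigs(self, contigs: list[AnnotatedGenome],
                     isolate_id: str) -> AlleleProfile:
        alleles: dict[str, int | None] = {}
        rseq = self.reference.sequence
        for gene_id, _ in self.scheme.targets:
            f = self._feats[gene_id]
            up = rseq[max(0, f.start - 1 - self.flank): f.start - 1]
            down = rseq[f.end: f.end + self.flank]
            found = MISSING
            if len(up) == self.flank and len(down) == self.flank:
                for contig in contigs:
                    for cseq in (contig.sequence, revcomp(contig.sequence)):
                        i = cseq.find(up)
                        if i < 0 or cseq.find(up, i + 1) >= 0:
                            continue
                        j = cseq.find(down, i + self.flank)
                        if j < 0 or cseq.find(down, j + 1) >= 0:
                            continue
                        seq = cseq[i + self.flank: j]
                        if seq and not set(seq) - set("ACGT"):
                            if f.strand == "-":
                                seq = revcomp(seq)
                            found = self._assign(gene_id, seq)
                        break
                    if found is not MISSING:
                        break
            alleles[gene_id] = found
        return AlleleProfile(isolate_id=isolate_id, alleles=alleles)


def call_allele_profiles(scheme: CgScheme, reference: AnnotatedGenome,
                         queries: list[AnnotatedGenome]) -> list[AlleleProfile]:
    """Convenience wrapper: one collinear profile per query genome."""
    caller = AlleleCaller(scheme, reference)
    return [caller.call_collinear(q) for q in queries]


def allelic_distance(profiles: list[AlleleProfile]) -> DistanceMatrix:
    """Pairwise count of targets with differing alleles (pairwise deletion:
    targets MISSING in either member of a pair are excluded and the number
    of mutually present targets recorded)."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    genes = list(profiles[0].alleles)
    labels = [p.isolate_id for p in profiles]
    n = len(profiles)
    mat = np.zeros((n, n))
    ncmp = np.zeros((n, n), dtype=int)
    for i in range(n):
        ncmp[i, i] = len(genes)
        for j in range(i + 1, n):
            diff = comp = 0
            for g in genes:
                a, b = profiles[i].alleles[g], profiles[j].alleles[g]
                if a is MISSING or b is MISSING:
                    continue
                comp += 1
                if a != b:
                    diff += 1
            mat[i, j] = mat[j, i] = diff
            ncmp[i, j] = ncmp[j, i] = comp
    return DistanceMatrix(labels=labels, matrix=mat, n_compared=ncmp)


# ---------------------------------------------------------------------------
# SNP/indel presence-absence clustering
# ---------------------------------------------------------------------------

def binary_variant_matrix(variant_sets: list[VariantSet]) -> pd.DataFrame:
    """0/1 matrix: isolates x union of distinct (pos, ref, alt) variants."""
    ref_ids = {vs.reference_id for vs in variant_sets}
    if len(ref_ids) != 1:
        raise ValueError("all variant sets must share one reference")
    columns = sorted({v.key for vs in variant_sets for v in vs},
                     key=lambda k: (k[1], k[2], k[3]))
    data = np.zeros((len(variant_sets), len(columns)), dtype=int)
    col_index = {c: i for i, c in enumerate(columns)}
    for r, vs in enumerate(variant_sets):
        for v in vs:
            data[r, col_index[v.key]] = 1
    labels = [f"{k[1]}:{k[2]}>{k[3]}" for k in columns]
    return pd.DataFrame(data, index=[vs.isolate_id for vs in variant_sets],
                        columns=labels)


def average_linkage_manhattan(matrix: pd.DataFrame) -> TreeNode:
    """Average-linkage tree on Manhattan (L1) distances between the rows of
    a presence/absence matrix; tie rule as in :func:`upgma`."""
    labels = list(matrix.index)
    if len(labels) < 2:
        raise ValueError("need at least two isolates")
    dist = squareform(pdist(matrix.values, metric="cityblock"))
    return _agglomerate(labels, dist)


# ---------------------------------------------------------------------------
# SNP-concatenation alignment export
# ---------------------------------------------------------------------------

@dataclass
class SnpAlignment:
    positions: list[int]
    rows: dict[str, str]   # isolate (and reference) -> concatenated bases

    def to_fasta(self) -> str:
        return "".join(f">{name}\n{seq}\n" for name, seq in self.rows.items())

    def to_phylip(self) -> str:
        lines = [f" {len(self.rows)} {len(self.positions)}"]
        for name, seq in self.rows.items():
            lines.append(f"{name}  {seq}")
        return "\n".join(lines) + "\n"


def export_snp_alignment(variant_sets: list[VariantSet],
                         reference: AnnotatedGenome) -> SnpAlignment:
    """Concatenate all positions segregating in >= 1 isolate into a
    multi-sequence alignment (reference included as a row; isolates without
    a call at a position carry the reference base)."""
    snp_by_isolate = {vs.isolate_id: {v.pos: v.alt for v in vs.snps()}
                      for vs in variant_sets}
    positions = sorted({p for calls in snp_by_isolate.values() for p in calls})
    if not positions:
        raise ValueError("no segregating SNP positions to export")
    ref_row = "".join(reference.sequence[p - 1] for p in positions)
    rows = {reference.id: ref_row}
    for isolate, calls in snp_by_isolate.items():
        rows[isolate] = "".join(calls.get(p, reference.sequence[p - 1])
                                for p in positions)
    return SnpAlignment(positions=positions, rows=rows)


# ---------------------------------------------------------------------------
# Set-specific gene content (plasmid-contig logic)
# ---------------------------------------------------------------------------

def _genome_kmer_index(genomes: list[AnnotatedGenome], k: int = 11
                       ) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for gi, g in enumerate(genomes):
        seq = g.sequence
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], []).append((gi, i))
    return index


def _gene_present(gene_seq: str, genomes: list[AnnotatedGenome],
                  index: dict[str, list[tuple[int, int]]],
                  aligner: Align.PairwiseAligner,
                  min_identity: float, min_coverage: float,
                  k: int = 11, max_hits: int = 50) -> bool:
    """Seed-and-extend presence test of a gene in a contig set."""
    for probe in (gene_seq, revcomp(gene_seq)):
        votes: dict[tuple[int, int], int] = {}
        for off in range(0, len(probe) - k + 1, max(1, k // 2)):
            hits = index.get(probe[off:off + k], ())
            if len(hits) > max_hits:
                continue
            for gi, pos in hits:
                diag = (gi, (pos - off) // 32)
                votes[diag] = votes.get(diag, 0) + 1
        if not votes:
            continue
        gi, bucket = max(votes, key=lambda d: votes[d])
        target = genomes[gi].sequence
        lo = max(0, bucket * 32 - 60)
        hi = min(len(target), bucket * 32 + len(probe) + 92)
        window = target[lo:hi]
        aln = aligner.align(probe, window)
        if len(aln) == 0:
            continue
        best = aln[0]
        pblocks, _wblocks = best.aligned
        matches = cols = 0
        for (ps, pe), (ws, we) in zip(pblocks, _wblocks):
            matches += sum(x == y for x, y in zip(probe[ps:pe], window[ws:we]))
            cols += pe - ps
        if cols == 0:
            continue
        span = pblocks[-1][1] - pblocks[0][0]
        identity = matches / cols
        coverage = span / len(probe)
        if identity >= min_identity and coverage >= min_coverage:
            return True
    return False


def set_specific_genes(genomes_a: list[AnnotatedGenome | list[AnnotatedGenome]],
                       genomes_b: list[AnnotatedGenome | list[AnnotatedGenome]],
                       min_identity: float = 0.8,
                       min_coverage: float = 0.8) -> list[str]:
    """Genes present in every isolate of group A and absent from every
    isolate of group B ("present" = an alignment with >= ``min_identity``
    over >= ``min_coverage`` of the gene exists).  Each isolate may be one
    genome or a list of contigs.  Gene candidates come from the annotation
    of group A's isolates (first annotated occurrence wins).
    """
    def contigs_of(iso) -> list[AnnotatedGenome]:
        return iso if isinstance(iso, list) else [iso]

    a_sets = [contigs_of(i) for i in genomes_a]
    b_sets = [contigs_of(i) for i in genomes_b]
    candidates: dict[str, str] = {}
    for contigs in a_sets:
        for g in contigs:
            for f in g.features:
                if f.gene_id not in candidates:
                    seq = g.sequence[f.start - 1: f.end]
                    if f.strand == "-":
                        seq = revcomp(seq)
                    candidates[f.gene_id] = seq

    aligner = _local_aligner()
    a_indexes = [_genome_kmer_index(c) for c in a_sets]
    b_indexes = [_genome_kmer_index(c) for c in b_sets]
    out = []
    for gene_id, seq in candidates.items():
        in_all_a = all(
            _gene_present(seq, c, idx, aligner, min_identity, min_coverage)
            for c, idx in zip(a_sets, a_indexes))
        if not in_all_a:
            continue
        in_any_b = any(
            _gene_present(seq, c, idx, aligner, min_identity, min_coverage)
            for c, idx in zip(b_sets, b_indexes))
        if not in_any_b:
            out.append(gene_id)
    return out


# ---------------------------------------------------------------------------
# TSV serialization helpers
# ---------------------------------------------------------------------------

def scheme_to_tsv(scheme: CgScheme) -> str:
    lines = ["gene_id\tsequence"]
    lines += [f"{g}\t{s}" for g, s in scheme.targets]
    return "\n".join(lines) + "\n"


def profiles_to_tsv(profiles: list[AlleleProfile]) -> str:
    genes = list(profiles[0].alleles)
    lines = ["isolate\t" + "\t".join(genes)]
    for p in profiles:
        vals = ["-" if p.alleles[g] is MISSING else str(p.alleles[g])
                for g in genes]
        lines.append(p.isolate_id + "\t" + "\t".join(vals))
    return "\n".join(lines) + "\n"
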