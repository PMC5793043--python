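"""Variant calling between collinear genomes, filtering, and coding effects.

Calling operates on assembled, near-identical genomes: unique shared k-mers
anchor a collinear chain, the inter-anchor gaps are resolved by optimal
pairwise alignment, and the resulting differences are normalized into a
:class:`~mutrace.core_io.VariantSet`.  A genuinely rearranged query (the
anchor chain collapses) raises :class:`~mutrace.core_io.NonCollinearError`
rather than silently truncating the call set.

Filtering reproduces the coverage/quality rule used for short-read calls:
keep a variant iff relative coverage > 0.5, absolute coverage > 10 and
Phred quality >= 23 (note the strict vs inclusive boundaries).  Variants
without metadata — e.g. assembly-to-assembly calls — pass with a warning.

Annotation recomputes each variant's consequence on the strand-corrected
codon and names it in compact HGVS-like protein notation ("R190C",
"L68_A69del", "fs"), numbering from the initiator methionine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from .core_io import (
    AnnotatedGenome,
    CdsFeature,
    NonCollinearError,
    Variant,
    VariantSet,
    apply_variants,
    normalize_variant,
    revcomp,
)
from .selection_kaks import CODON_TO_AA

log = logging.getLogger("mutrace")

# alignment scores for inter-anchor gap resolution
MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_OPEN = -4       # charged on the first gapped column, on top of GAP_EXTEND
GAP_EXTEND = -1

DEFAULT_ANCHOR_K = 21


@dataclass(frozen=True)
class FilterThresholds:
    """Coverage/quality cutoffs; defaults follow the short-read filter rule
    'relative coverage > 0.5, absolute coverage > 10 bases, Q >= 23'."""

    min_rel_coverage_exclusive: float = 0.5
    min_abs_coverage_exclusive: int = 10
    min_quality_inclusive: float = 23.0

    def __post_init__(self) -> None:
        if (self.min_rel_coverage_exclusive < 0 or self.min_abs_coverage_exclusive < 0
                or self.min_quality_inclusive < 0):
            raise ValueError("thresholds must be nonnegative")


PROTEIN_CHANGE_KINDS = ("synonymous", "missense", "nonsense", "stop_loss",
                        "inframe_del", "inframe_ins", "frameshift", "intergenic")


@dataclass(frozen=True)
class ProteinChange:
    """Protein-level consequence of one variant within one CDS."""

    gene_id: str
    kind: str
    hgvs_like: str = ""
    codon_index: int = 0       # 1-based; 0 for intergenic

    def __post_init__(self) -> None:
        if self.kind not in PROTEIN_CHANGE_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")


INTERGENIC = ProteinChange(gene_id="", kind="intergenic")


# ---------------------------------------------------------------------------
# Collinear variant calling
# ---------------------------------------------------------------------------

def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    """k-mer -> 0-based position, for k-mers occurring exactly once."""
    first: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if km in dup:
            continue
        if km in first:
            del first[km]
            dup.add(km)
        else:
            first[km] = i
    return first


def _chain_anchors(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain of anchors increasing in both genomes (LIS on query pos;
    anchors arrive sorted by reference position)."""
    if not anchors:
        return []
    qs = [q for _, q in anchors]
    import bisect
    tails: list[int] = []          # tails[i] = min possible tail of chain len i+1
    back: list[int] = [0] * len(qs)
    idx_of_tail: list[int] = []
    for i, q in enumerate(qs):
        j = bisect.bisect_left(tails, q)
        if j == len(tails):
            tails.append(q)
            idx_of_tail.append(i)
        else:
            tails[j] = q
            idx_of_tail[j] = i
        back[i] = idx_of_tail[j - 1] if j > 0 else -1
    chain = []
    i = idx_of_tail[len(tails) - 1]
    while i >= 0:
        chain.append(anchors[i])
        i = back[i]
    return chain[::-1]


def _gap_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN + GAP_EXTEND
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _variants_from_gap(ref_seg: str, query_seg: str, ref_offset: int,
                       chrom: str, full_ref: str,
                       aligner: Align.PairwiseAligner) -> list[Variant]:
    """Differences between two gap segments, as anchored raw variants.

    ``ref_offset`` is the 0-based position of ``ref_seg`` in the reference;
    the preceding reference base must exist (anchors guarantee this except
    at position 0, handled by the caller adding a sentinel anchor).
    """
    out: list[Variant] = []
    if ref_seg == query_seg:
        return out
    if not ref_seg or not query_seg:
        # pure insertion / deletion between anchors
        anchor_pos = ref_offset  # 1-based position of base left of the gap
        anchor = full_ref[anchor_pos - 1]
        if not ref_seg:
            out.append(Variant(chrom, anchor_pos, anchor, anchor + query_seg))
        else:
            out.append(Variant(chrom, anchor_pos, anchor + ref_seg, anchor))
        return out
    aln = aligner.align(ref_seg, query_seg)[0]
    rblocks, qblocks = aln.aligned
    prev_r, prev_q = 0, 0
    for (rs, re), (qs, qe) in zip(rblocks, qblocks):
        if rs > prev_r or qs > prev_q:
            rgap = ref_seg[prev_r:rs]
            qgap = query_seg[prev_q:qs]
            anchor_pos = ref_offset + prev_r  # base left of gap, 1-based
            anchor = full_ref[anchor_pos - 1]
            out.append(Variant(chrom, anchor_pos, anchor + rgap, anchor + qgap))
        for k in range(re - rs):
            if ref_seg[rs + k] != query_seg[qs + k]:
                out.append(Variant(chrom, ref_offset + rs + k + 1,
                                   ref_seg[rs + k], query_seg[qs + k]))
        prev_r, prev_q = re, qe
    if prev_r < len(ref_seg) or prev_q < len(query_seg):
        rgap = ref_seg[prev_r:]
        qgap = query_seg[prev_q:]
        anchor_pos = ref_offset + prev_r
        anchor = full_ref[anchor_pos - 1]
        out.append(Variant(chrom, anchor_pos, anchor + rgap, anchor + qgap))
    return out


def call_variants_collinear(reference: AnnotatedGenome, query: AnnotatedGenome,
                            k: int = DEFAULT_ANCHOR_K,
                            min_chain_fraction: float = 0.5) -> VariantSet:
    """Call the normalized variant set turning ``reference`` into ``query``.

    Contract: genomes are near-identical and collinear.  Shared k-mers unique
    in both genomes are chained collinearly (longest increasing chain); the
    inter-anchor gaps are aligned optimally; differences are normalized.
    If fewer than ``min_chain_fraction`` of shared anchors fit one collinear
    chain — the signature of a rearrangement — a
    :class:`~mutrace.core_io.NonCollinearError` is raised.
    """
    rseq, qseq = reference.sequence, query.sequence
    ref_k = _unique_kmers(rseq, k)
    query_k = _unique_kmers(qseq, k)
    shared = sorted((rpos, query_k[km]) for km, rpos in ref_k.items()
                    if km in query_k)
    if not shared:
        raise NonCollinearError("no shared unique anchors; genomes too divergent "
                                "or rearranged")
    chain = _chain_anchors(shared)
    if len(chain) < min_chain_fraction * len(shared):
        raise NonCollinearError(
            f"only {len(chain)}/{len(shared)} anchors form a collinear chain; "
            "likely rearrangement")

    # merge same-diagonal overlapping anchors into maximal collinear blocks;
    # anchors straddling an indel (overlap on a shifted diagonal) are dropped
    # so the difference stays inside an alignable gap
    blocks: list[list[int]] = []  # [rstart, rend, qstart, qend), 0-based half-open
    for rpos, qpos in chain:
        if not blocks:
            blocks.append([rpos, rpos + k, qpos, qpos + k])
            continue
        last = blocks[-1]
        same_diag = qpos - rpos == last[2] - last[0]
        if same_diag and rpos <= last[1]:
            last[1] = rpos + k
            last[3] = qpos + k
        elif rpos >= last[1] and qpos >= last[3]:
            blocks.append([rpos, rpos + k, qpos, qpos + k])
        # else: anchor overlaps the previous block across an indel; skip it

    aligner = _gap_aligner()
    raw: list[Variant] = []
    prev_r, prev_q = 0, 0
    # sentinel handling: a difference before the first anchor lacks a left
    # anchor base; prepend a matching sentinel base by requiring the first
    # divergence to sit at position >= 1 (true when sequences share base 1,
    # which holds for near-identical genomes; otherwise align from pos 0).
    for rs, re, qs, qe in blocks + [[len(rseq), len(rseq), len(qseq), len(qseq)]]:
        ref_seg = rseq[prev_r:rs]
        query_seg = qseq[prev_q:qs]
        if ref_seg != query_seg:
            if prev_r == 0:
                # no left anchor yet: align with a shared virtual anchor
                # base prepended, then shift coordinates back by one
                from dataclasses import replace as _replace
                aln_vars = _variants_from_gap("X" + ref_seg, "X" + query_seg,
                                              0, reference.id, "X" + rseq,
                                              aligner)
                for v in aln_vars:
                    if v.pos <= 1:
                        raise NonCollinearError("divergence at sequence start")
                    raw.append(_replace(v, pos=v.pos - 1))
            else:
                raw.extend(_variants_from_gap(ref_seg, query_seg, prev_r,
                                              reference.id, rseq, aligner))
        prev_r, prev_q = re, qe

    normalized = [normalize_variant(v, rseq) for v in raw]
    vset = VariantSet(reference_id=reference.id, isolate_id=query.id,
                      variants=normalized)
    return vset


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_variants(vset: VariantSet,
                    thresholds: FilterThresholds | None = None) -> VariantSet:
    """Apply the coverage/quality filter; metadata-free variants pass with a
    logged warning (assembly-derived calls carry no read support)."""
    thr = thresholds or FilterThresholds()
    kept = []
    n_no_meta = 0
    for v in vset:
        if v.rel_coverage is None and v.abs_coverage is None and v.quality is None:
            n_no_meta += 1
            kept.append(v)
            continue
        if v.rel_coverage is not None and \
                not v.rel_coverage > thr.min_rel_coverage_exclusive:
            continue
        if v.abs_coverage is not None and \
                not v.abs_coverage > thr.min_abs_coverage_exclusive:
            continue
        if v.quality is not None and \
                not v.quality >= thr.min_quality_inclusive:
            continue
        kept.append(v)
    if n_no_meta:
        log.warning("%s: %d variants without coverage/quality metadata passed "
                    "the filter unexamined", vset.isolate_id, n_no_meta)
    return VariantSet(vset.reference_id, vset.isolate_id, kept)


# ---------------------------------------------------------------------------
# Coding-effect annotation
# ---------------------------------------------------------------------------

def _translate(coding: str) -> str:
    return "".join(CODON_TO_AA.get(coding[i:i + 3], "X")
                   for i in range(0, len(coding) - len(coding) % 3, 3))


def _snp_change(v: Variant, genome: AnnotatedGenome, feat: CdsFeature,
                numbering_offset: int = 0) -> ProteinChange:
    if feat.strand == "+":
        off = v.pos - feat.start - feat.phase
        ref_c, alt_c = v.ref, v.alt
    else:
        off = feat.end - feat.phase - v.pos
        ref_c, alt_c = revcomp(v.ref), revcomp(v.alt)
    if off < 0:
        return INTERGENIC
    ci, k = divmod(off, 3)
    coding = genome.cds_sequence(feat)
    codon = coding[3 * ci: 3 * ci + 3]
    if len(codon) < 3 or codon[k] != ref_c:
        raise ValueError(f"{feat.gene_id}: codon/variant inconsistency at {v.pos}")
    alt_codon = codon[:k] + alt_c + codon[k + 1:]
    aa0 = CODON_TO_AA.get(codon, "X")
    aa1 = CODON_TO_AA.get(alt_codon, "X")
    pos_aa = ci + 1 - numbering_offset
    if aa0 == aa1:
        kind = "synonymous"
    elif aa1 == "*":
        kind = "nonsense"
    elif aa0 == "*":
        kind = "stop_loss"
    else:
        kind = "missense"
    return ProteinChange(gene_id=feat.gene_id, kind=kind,
                         hgvs_like=f"{aa0}{pos_aa}{aa1}", codon_index=pos_aa)


def _inframe_name(before: str, after: str) -> tuple[str, int]:
    """HGVS-style name for an in-frame protein-level deletion or insertion,
    right-shifted within repeats (the 3'-most placement)."""
    if len(before) > len(after):   # deletion
        k = len(before) - len(after)
        p = 0
        while p < len(after) and before[p] == after[p]:
            p += 1
        # p is the longest common prefix -> rightmost placement of the gap
        block = before[p:p + k]
        if before[p + k:] != after[p:]:
            return f"{p + 1}delins", p + 1   # deletion plus junction change
        if k == 1:
            return f"{block}{p + 1}del", p + 1
        return f"{block[0]}{p + 1}_{block[-1]}{p + k}del", p + 1
    else:                           # insertion
        k = len(after) - len(before)
        p = 0
        while p < len(before) and before[p] == after[p]:
            p += 1
        block = after[p:p + k]
        if after[p + k:] != before[p:]:
            return f"{p + 1}delins", p + 1
        return f"{before[p - 1] if p else '?'}{p}_{before[p] if p < len(before) else '?'}{p + 1}ins{block}", max(p, 1)


def _indel_change(v: Variant, genome: AnnotatedGenome,
                  feat: CdsFeature) -> ProteinChange:
    delta = len(v.alt) - len(v.ref)
    # first coding base affected
    first_affected = v.pos + 1 if v.vclass in ("INS", "DEL") else v.pos
    if feat.strand == "+":
        off = first_affected - feat.start - feat.phase
    else:
        off = feat.end - feat.phase - first_affected
    ci = max(0, off) // 3 + 1
    if delta % 3 != 0:
        return ProteinChange(gene_id=feat.gene_id, kind="frameshift",
                             hgvs_like="fs", codon_index=ci)
    # in-frame: recompute the protein with the variant applied to this CDS
    within = v.pos >= feat.start and v.end <= feat.end
    if not within:
        return ProteinChange(gene_id=feat.gene_id, kind="frameshift",
                             hgvs_like="fs", codon_index=ci)
    local = replace_pos = v.pos - feat.start  # 0-based within feature
    seg = genome.sequence[feat.start - 1: feat.end]
    mutated = seg[:local] + v.alt + seg[local + len(v.ref):]
    if feat.strand == "-":
        seg, mutated = revcomp(seg), revcomp(mutated)
    before = _translate(seg[feat.phase:]).rstrip("*")
    after = _translate(mutated[feat.phase:]).rstrip("*")
    kind = "inframe_del" if delta < 0 else "inframe_ins"
    name, codon_index = _inframe_name(before, after)
    return ProteinChange(gene_id=feat.gene_id, kind=kind,
                         hgvs_like=name, codon_index=codon_index)


def annotate_variant(v: Variant, genome: AnnotatedGenome,
                     numbering_offsets: dict[str, int] | None = None
                     ) -> list[ProteinChange]:
    """Protein-level consequence(s) of a normalized variant.

    Returns one :class:`ProteinChange` per overlapping CDS, or a single
    intergenic change when none overlaps.  ``numbering_offsets`` maps
    gene_id -> residues to subtract, reproducing mature-protein numbering
    for genes with a cleaved signal peptide.
    """
    offsets = numbering_offsets or {}
    if v.vclass == "INS":
        feats = genome.features_overlapping(v.pos, v.pos + 1)
        feats = [f for f in feats if f.start <= v.pos < f.end]
    else:
        feats = genome.features_overlapping(v.pos if v.vclass == "SNP" else v.pos + 1,
                                            v.end)
    if not feats:
        return [INTERGENIC]
    out = []
    for f in feats:
        if v.vclass == "SNP":
            out.append(_snp_change(v, genome, f, offsets.get(f.gene_id, 0)))
        elif v.vclass == "MNP":
            # annotate per contained SNP; report the first non-synonymous one,
            # falling back to the first
            changes = [_snp_change(s, genome, f, offsets.get(f.gene_id, 0))
                       for s in v.split_mnp()]
            nonsyn = [c for c in changes if c.kind != "synonymous"]
            out.append(nonsyn[0] if nonsyn else changes[0])
        else:
            out.append(_indel_change(v, genome, f))
    return out


def annotate_variants(vset: VariantSet, genome: AnnotatedGenome,
                      numbering_offsets: dict[str, int] | None = None
                      ) -> list[tuple[Variant, list[ProteinChange]]]:
    return [(v, annotate_variant(v, genome, numbering_offsets)) for v in vset]
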