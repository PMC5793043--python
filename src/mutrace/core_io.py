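"""Domain types and I/O for annotated bacterial genomes and variant sets.

Everything downstream (spectra, Ka/Ks, cgMLST, screening) operates on the
three containers defined here: :class:`AnnotatedGenome` (a chromosome or
contig plus its CDS features), :class:`Variant` (one normalized difference
against a reference) and :class:`VariantSet` (a position-sorted, de-duplicated
collection of variants for one isolate).

Coordinate conventions
----------------------
All coordinates are 1-based inclusive, as in VCF and GFF3.  Insertions are
anchored on the reference base immediately to their left, and indels are
stored left-aligned and parsimony-trimmed (the canonical VCF normal form),
so that two call sets can be compared by exact `(pos, ref, alt)` identity
even when an indel sits inside a repeat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("mutrace")

IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class NonCollinearError(ValueError):
    """Raised when two genomes cannot be related by a collinear alignment."""


class ProjectionAmbiguousError(ValueError):
    """Raised when a reference interval endpoint falls inside a deletion."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature on a genome, 1-based inclusive coordinates."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    phase: int = 0
    product: str = ""
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"{self.gene_id}: invalid interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"{self.gene_id}: phase must be 0, 1 or 2")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_codons(self) -> int:
        """Codons in the phase-adjusted reading frame (including the stop)."""
        return (self.length - self.phase) // 3

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class AnnotatedGenome:
    """A DNA sequence plus CDS annotation; the coordinate frame of every analysis."""

    id: str
    sequence: str
    circular: bool = False
    features: list[CdsFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - IUPAC_CODES
        if bad:
            raise ValueError(f"{self.id}: non-IUPAC characters {sorted(bad)!r}")
        n = len(self.sequence)
        fixed = []
        for f in self.features:
            if f.end > n:
                raise ValueError(f"{self.id}: feature {f.gene_id} ends at {f.end} > length {n}")
            # a CDS whose frame-adjusted length is not a whole number of codons
            # cannot encode a clean ORF; flag rather than reject
            if not f.pseudo and (f.length - f.phase) % 3 != 0:
                f = replace(f, pseudo=True)
            fixed.append(f)
        self.features = sorted(fixed, key=lambda f: (f.start, f.end, f.gene_id))

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_id(self, gene_id: str) -> CdsFeature:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        raise KeyError(gene_id)

    def cds_sequence(self, feat: CdsFeature) -> str:
        """Coding-strand sequence of a feature, phase-trimmed to the frame."""
        s = self.sequence[feat.start - 1: feat.end]
        if feat.strand == "-":
            s = revcomp(s)
        return s[feat.phase:]

    def features_overlapping(self, start: int, end: int) -> list[CdsFeature]:
        return [f for f in self.features if f.start <= end and start <= f.end]


def classify_alleles(ref: str, alt: str) -> str:
    """Variant class from normalized ref/alt alleles: SNP, MNP, INS or DEL."""
    if not ref or not alt:
        raise ValueError("empty allele; variants must carry an anchor base")
    if len(ref) == len(alt) == 1:
        if ref == alt:
            raise ValueError("ref == alt is not a variant")
        return "SNP"
    if len(ref) == len(alt):
        return "MNP"
    if len(alt) > len(ref) and alt.startswith(ref):
        return "INS"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "DEL"
    raise ValueError(f"unsupported allele shape {ref}>{alt}; normalize first")


@dataclass(frozen=True)
class Variant:
    """One normalized difference vs a reference.

    ``pos`` is the 1-based position of the first reference base of ``ref``;
    for insertions this is the base immediately left of the inserted material.
    Coverage/quality metadata are optional (absent on simulated truth).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    quality: float | None = None
    abs_coverage: int | None = None
    rel_coverage: float | None = None

    def __post_init__(self) -> None:
        classify_alleles(self.ref, self.alt)  # validates shape
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.rel_coverage is not None and not 0.0 <= self.rel_coverage <= 1.0:
            raise ValueError("rel_coverage must lie in [0, 1]")

    @property
    def vclass(self) -> str:
        return classify_alleles(self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        """Last reference position touched (== pos for SNPs and insertions)."""
        return self.pos + len(self.ref) - 1

    @property
    def is_indel(self) -> bool:
        return self.vclass in ("INS", "DEL")

    def split_mnp(self) -> list["Variant"]:
        """Decompose an MNP into per-base SNPs; other classes pass through."""
        if self.vclass != "MNP":
            return [self]
        out = []
        for i, (r, a) in enumerate(zip(self.ref, self.alt)):
            if r != a:
                out.append(replace(self, pos=self.pos + i, ref=r, alt=a))
        return out


@dataclass
class VariantSet:
    """Position-sorted, de-duplicated variants of one isolate vs one reference."""

    reference_id: str
    isolate_id: str
    variants: list[Variant] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        uniq = []
        for v in sorted(self.variants, key=lambda v: (v.pos, v.ref, v.alt)):
            if v.key not in seen:
                seen.add(v.key)
                uniq.append(v)
        self.variants = uniq

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.variants}

    def snps(self, split_mnps: bool = True) -> list[Variant]:
        out = []
        for v in self.variants:
            if v.vclass == "SNP":
                out.append(v)
            elif v.vclass == "MNP" and split_mnps:
                out.extend(v.split_mnp())
        return out

    def indels(self) -> list[Variant]:
        return [v for v in self.variants if v.is_indel]

    def difference(self, other: "VariantSet") -> "VariantSet":
        """Variants present here and absent from ``other`` (by (pos, ref, alt))."""
        other_keys = other.keys()
        return VariantSet(
            self.reference_id, self.isolate_id,
            [v for v in self.variants if v.key not in other_keys],
        )


# ---------------------------------------------------------------------------
# Normalization and application
# ---------------------------------------------------------------------------

def normalize_variant(v: Variant, genome: AnnotatedGenome | str) -> Variant:
    """Canonical form: parsimony-trimmed and left-aligned against the reference.

    Indels are shifted left while the base preceding them matches the last
    base of the event (the standard VCF/`vt` algorithm), so any placement of
    an insertion inside a homopolymer run collapses to one record at the
    run's left edge.  SNPs are returned unchanged.  Raises ``ValueError`` if
    ``ref`` disagrees with the reference sequence at ``pos``.
    """
    seq = genome.sequence if isinstance(genome, AnnotatedGenome) else genome
    pos, ref, alt = v.pos, v.ref, v.alt
    if seq[pos - 1: pos - 1 + len(ref)] != ref:
        raise ValueError(
            f"ref allele {ref!r} does not match reference at {pos} "
            f"({seq[pos - 1: pos - 1 + len(ref)]!r})"
        )
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if (len(ref) == 1 or len(alt) == 1) and pos == 1:
                break  # cannot left-extend past the sequence start
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                pos -= 1
                b = seq[pos - 1]
                ref, alt = b + ref, b + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (pos, ref, alt) == (v.pos, v.ref, v.alt):
        return v
    return replace(v, pos=pos, ref=ref, alt=alt)


def apply_variants(variants: Iterable[Variant] | VariantSet, sequence: str) -> str:
    """Apply a non-overlapping, sorted variant set to a reference sequence."""
    if isinstance(variants, VariantSet):
        variants = variants.variants
    variants = sorted(variants, key=lambda v: v.pos)
    out = []
    cursor = 0  # 0-based index into sequence
    for v in variants:
        start = v.pos - 1
        if start < cursor:
            raise ValueError(f"overlapping variants at position {v.pos}")
        if sequence[start: start + len(v.ref)] != v.ref:
            raise ValueError(f"ref mismatch at {v.pos}: expected {v.ref!r}")
        out.append(sequence[cursor:start])
        out.append(v.alt)
        cursor = start + len(v.ref)
    out.append(sequence[cursor:])
    return "".join(out)


def project_interval(
    variants: Iterable[Variant] | VariantSet, start: int, end: int
) -> tuple[int, int]:
    """Map a reference interval [start, end] into derived-genome coordinates.

    The derived genome is ``apply_variants(variants, reference)``.  Raises
    :class:`ProjectionAmbiguousError` when an endpoint falls strictly inside
    a deleted block, in which case the interval has no clean image.
    """
    if isinstance(variants, VariantSet):
        variants = variants.variants

    def image(p: int) -> int:
        q = p
        for v in variants:
            delta = len(v.alt) - len(v.ref)
            if delta == 0:
                continue
            if v.vclass == "INS":
                if v.pos < p:  # inserted bases sit right of the anchor
                    q += delta
            else:  # DEL: bases pos+1..end are removed
                if v.end < p:
                    q += delta
                elif v.pos + 1 <= p <= v.end:
                    raise ProjectionAmbiguousError(
                        f"position {p} lies inside a deletion at {v.pos}")
        return q

    return image(start), image(end)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[AnnotatedGenome]:
    """Read FASTA records as genomes (features empty), preserving file order."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return [AnnotatedGenome(id=r.id, sequence=str(r.seq)) for r in records]


def write_fasta(genomes: Sequence[AnnotatedGenome] | AnnotatedGenome, path: str | Path,
                width: int = 70) -> None:
    if isinstance(genomes, AnnotatedGenome):
        genomes = [genomes]
    records = [SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3 (CDS rows only)
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path, genome: AnnotatedGenome) -> AnnotatedGenome:
    """Attach CDS features from a GFF3 file to ``genome`` (new object).

    Only ``CDS`` rows are kept; ``ID`` (or ``locus_tag``) becomes ``gene_id``.
    Intervals outside the genome or rows lacking an identifier are errors.
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    feats = []
    for f in db.features_of_type("CDS"):
        ids = f.attributes.get("ID") or f.attributes.get("locus_tag")
        if not ids:
            raise ValueError(f"{path}: CDS at {f.start}..{f.end} lacks ID/locus_tag")
        product = (f.attributes.get("product") or [""])[0]
        phase = 0 if f.frame in (None, ".") else int(f.frame)
        feats.append(CdsFeature(gene_id=ids[0], start=f.start, end=f.end,
                                strand=f.strand if f.strand in "+-" else "+",
                                phase=phase, product=product))
    out = AnnotatedGenome(id=genome.id, sequence=genome.sequence,
                          circular=genome.circular, features=feats)
    return out


def write_annotation(genome: AnnotatedGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for f in genome.features:
            attrs = f"ID={f.gene_id}"
            if f.product:
                attrs += f";product={f.product}"
            if f.pseudo:
                attrs += ";pseudo=true"
            fh.write("\t".join([genome.id, "mutrace", "CDS", str(f.start),
                                str(f.end), ".", f.strand, str(f.phase), attrs]) + "\n")


# ---------------------------------------------------------------------------
# VCF 4.x (sites-only; DP = absolute coverage, AF = relative coverage)
# ---------------------------------------------------------------------------

def _vcf_header(reference_id: str, isolate_id: str,
                reference_length: int | None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    if reference_length:
        header.add_line(f"##contig=<ID={reference_id},length={reference_length}>")
    else:
        header.add_line(f"##contig=<ID={reference_id}>")
    header.add_line(f"##isolate={isolate_id}")
    header.info.add("DP", 1, "Integer", "Absolute coverage (supporting bases)")
    header.info.add("AF", "A", "Float", "Relative coverage (supporting fraction)")
    header.info.add("EFF", 1, "String", "Predicted coding effect")
    header.info.add("GENE", 1, "String", "Affected gene")
    header.info.add("AACHG", 1, "String", "Protein-level change")
    return header


def write_vcf(vset: VariantSet, path: str | Path,
              reference_length: int | None = None,
              annotations: dict[tuple, tuple[str, str, str]] | None = None) -> None:
    """Write a sites-only VCF; ``annotations`` maps variant keys to
    (effect kind, gene_id, protein change) triples stored as INFO fields."""
    header = _vcf_header(vset.reference_id, vset.isolate_id, reference_length)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in vset:
            rec = vf.new_record(contig=vset.reference_id, start=v.pos - 1,
                                stop=v.pos - 1 + len(v.ref),
                                alleles=(v.ref, v.alt))
            if v.quality is not None:
                rec.qual = v.quality
            if v.abs_coverage is not None:
                rec.info["DP"] = v.abs_coverage
            if v.rel_coverage is not None:
                rec.info["AF"] = v.rel_coverage
            if annotations and v.key in annotations:
                eff, gene, aachg = annotations[v.key]
                rec.info["EFF"] = eff
                if gene:
                    rec.info["GENE"] = gene
                if aachg:
                    rec.info["AACHG"] = aachg
            vf.write(rec)


def read_vcf(path: str | Path) -> VariantSet:
    """Read a VCF 4.x file into a :class:`VariantSet`.

    Quality comes from QUAL; absolute/relative coverage from INFO ``DP``/``AF``.
    Multi-allelic rows are split into one variant per ALT allele.
    """
    path = Path(path)
    with pysam.VariantFile(str(path)) as vf:
        isolate = path.stem
        for line in str(vf.header).splitlines():
            if line.startswith("##isolate="):
                isolate = line.split("=", 1)[1]
        reference_id = next(iter(vf.header.contigs), None) or "reference"
        variants = []
        for rec in vf:
            if rec.alts is None:
                continue
            af = rec.info.get("AF")
            if isinstance(af, tuple):
                af = af[0]
            dp = rec.info.get("DP")
            for alt in rec.alts:
                if alt is None or set(rec.ref + alt) - IUPAC_CODES:
                    raise ValueError(f"{path}: malformed row at {rec.pos}")
                variants.append(Variant(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    quality=rec.qual,
                    abs_coverage=int(dp) if dp is not None else None,
                    rel_coverage=float(af) if af is not None else None,
                ))
    return VariantSet(reference_id=reference_id, isolate_id=isolate,
                      variants=variants)
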