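"""Genome/variant containers, format round-trips, and indel normalization."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutrace import (
    AnnotatedGenome,
    CdsFeature,
    Variant,
    VariantSet,
    apply_variants,
    normalize_variant,
    read_annotation,
    read_fasta,
    read_vcf,
    write_annotation,
    write_fasta,
    write_vcf,
)
from mutrace.core_io import classify_alleles, project_interval, revcomp


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">g\nACGT\n")
        genomes = read_fasta(p)
        assert len(genomes) == 1
        assert genomes[0].id == "g"
        assert len(genomes[0]) == 4

    def test_roundtrip_preserves_sequences_and_order(self, tmp_path):
        gs = [AnnotatedGenome(id="a", sequence="ACGTACGT" * 30),
              AnnotatedGenome(id="b", sequence="TTTTGGGG")]
        p = tmp_path / "two.fasta"
        write_fasta(gs, p)
        back = read_fasta(p)
        assert [g.id for g in back] == ["a", "b"]
        assert [g.sequence for g in back] == [g.sequence for g in gs]

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            read_fasta(p)

    def test_non_iupac_characters_error(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">x\nACQT\n")
        with pytest.raises(ValueError):
            read_fasta(p)

    def test_lowercase_input_uppercased(self):
        g = AnnotatedGenome(id="x", sequence="acgt")
        assert g.sequence == "ACGT"


class TestAnnotation:
    def _gff(self, tmp_path, rows):
        p = tmp_path / "a.gff3"
        body = "\n".join("\t".join(map(str, r)) for r in rows)
        p.write_text("##gff-version 3\n" + body + "\n")
        return p

    def test_cds_rows_parsed(self, tmp_path):
        g = AnnotatedGenome(id="c", sequence="ATGAAATAA" + "T" * 20)
        p = self._gff(tmp_path, [("c", "src", "CDS", 1, 9, ".", "+", 0, "ID=g1")])
        out = read_annotation(p, g)
        assert len(out.features) == 1
        f = out.features[0]
        assert (f.gene_id, f.n_codons, f.strand) == ("g1", 3, "+")

    def test_only_cds_rows_retained(self, tmp_path):
        g = AnnotatedGenome(id="c", sequence="ATGAAATAA" + "T" * 20)
        p = self._gff(tmp_path, [
            ("c", "src", "gene", 1, 9, ".", "+", ".", "ID=gene1"),
            ("c", "src", "CDS", 1, 9, ".", "+", 0, "ID=g1"),
        ])
        assert [f.gene_id for f in read_annotation(p, g).features] == ["g1"]

    def test_feature_outside_genome_errors(self, tmp_path):
        g = AnnotatedGenome(id="c", sequence="ATGAAATAA")
        p = self._gff(tmp_path, [("c", "src", "CDS", 1, 300, ".", "+", 0, "ID=g1")])
        with pytest.raises(ValueError):
            read_annotation(p, g)

    def test_missing_id_errors(self, tmp_path):
        g = AnnotatedGenome(id="c", sequence="ATGAAATAA")
        p = self._gff(tmp_path, [("c", "src", "CDS", 1, 9, ".", "+", 0, "note=x")])
        with pytest.raises(ValueError):
            read_annotation(p, g)

    def test_reverse_strand_cds_reads_from_reverse_complement(self, tmp_path):
        coding = "ATGCCCAAATAA"
        g = AnnotatedGenome(id="c", sequence="TT" + revcomp(coding) + "GG")
        p = self._gff(tmp_path, [("c", "src", "CDS", 3, 14, ".", "-", 0, "ID=rev")])
        out = read_annotation(p, g)
        assert out.cds_sequence(out.features[0]) == coding

    def test_gff_roundtrip(self, tmp_path, ancestor_30k):
        p = tmp_path / "anc.gff3"
        write_annotation(ancestor_30k, p)
        stripped = AnnotatedGenome(id=ancestor_30k.id,
                                   sequence=ancestor_30k.sequence)
        back = read_annotation(p, stripped)
        assert [(f.gene_id, f.start, f.end, f.strand) for f in back.features] == \
               [(f.gene_id, f.start, f.end, f.strand)
                for f in ancestor_30k.features]

    def test_unframed_cds_flagged_pseudo(self):
        g = AnnotatedGenome(id="c", sequence="ATGAAATAAT",
                            features=[CdsFeature("g1", 1, 10)])
        assert g.features[0].pseudo


class TestVcf:
    def test_snp_and_insertion_conventions(self, tmp_path):
        ref = "ACGTACGTAC"
        vs = VariantSet("chr", "iso", [
            Variant("chr", 5, "A", "G", quality=30, abs_coverage=20,
                    rel_coverage=0.9),
            Variant("chr", 3, "G", "GT"),
        ])
        p = tmp_path / "v.vcf"
        write_vcf(vs, p, reference_length=len(ref))
        back = read_vcf(p)
        assert back.keys() == vs.keys()
        assert back.isolate_id == "iso"
        snp = [v for v in back if v.pos == 5][0]
        assert (snp.quality, snp.abs_coverage) == (30, 20)
        assert snp.rel_coverage == pytest.approx(0.9)  # float32 in VCF
        ins = [v for v in back if v.pos == 3][0]
        assert ins.vclass == "INS"

    def test_roundtrip_identity_on_normalized_sets(self, tmp_path, ancestor_50k):
        from mutrace import REGIMES, evolve
        _, truth = evolve(ancestor_50k, REGIMES["MMR"], 120, seed=7)
        p = tmp_path / "t.vcf"
        write_vcf(truth, p, reference_length=len(ancestor_50k))
        assert read_vcf(p).keys() == truth.keys()


class TestVariantModel:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("A", "G", "SNP"), ("C", "CT", "INS"), ("CTG", "C", "DEL"),
        ("AT", "GC", "MNP"),
    ])
    def test_classification(self, ref, alt, expected):
        assert classify_alleles(ref, alt) == expected

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            Variant("c", 1, "A", "A")

    def test_variant_set_sorts_and_dedupes(self):
        vs = VariantSet("r", "i", [Variant("r", 9, "A", "G"),
                                   Variant("r", 2, "C", "T"),
                                   Variant("r", 9, "A", "G")])
        assert [v.pos for v in vs] == [2, 9]


class TestNormalization:
    def test_snp_unchanged(self):
        seq = "ACGTA"
        v = Variant("c", 3, "G", "T")
        assert normalize_variant(v, seq) == v

    def test_homopolymer_insertion_left_aligned(self):
        # run CCCC at positions 10-13; inserting C after any run base
        # collapses to one canonical record at the run's left edge
        seq = "ATGATGATGCCCCATGATG"
        canonical = None
        for anchor in range(10, 14):
            v = normalize_variant(Variant("c", anchor, "C", "CC"), seq)
            canonical = canonical or v
            assert (v.pos, v.ref, v.alt) == (canonical.pos, canonical.ref,
                                             canonical.alt)
        assert canonical.pos == 9  # base left of the run
        assert canonical.alt == canonical.ref + "C"

    def test_deletion_in_repeat_apply_oracle(self):
        # deleting TGC at offset 4 of CTGCTGC equals the left-aligned record;
        # verified by applying both placements to the sequence
        seq = "CTGCTGC"
        raw = Variant("c", 4, "CTGC", "C")
        norm = normalize_variant(raw, seq)
        assert norm.pos == 1
        assert apply_variants([raw], seq) == apply_variants([norm], seq)

    def test_ref_mismatch_errors(self):
        with pytest.raises(ValueError):
            normalize_variant(Variant("c", 2, "T", "G"), "AAAA")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_idempotent_and_placement_invariant(self, data):
        """Normalization is idempotent and independent of the initial
        placement of a 1-bp indel inside a randomly generated repeat."""
        unit = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=3))
        n_rep = data.draw(st.integers(min_value=2, max_value=5))
        left = data.draw(st.text(alphabet="ACGT", min_size=3, max_size=8))
        right = data.draw(st.text(alphabet="ACGT", min_size=3, max_size=8))
        seq = left + unit * n_rep + right
        results = set()
        for k in range(n_rep):
            pos = len(left) + k * len(unit)  # anchor base before k-th copy
            if pos < 1:
                continue
            ref = seq[pos - 1]
            v = Variant("c", pos, ref, ref + unit)
            n1 = normalize_variant(v, seq)
            n2 = normalize_variant(n1, seq)
            assert n1 == n2
            assert apply_variants([n1], seq) == apply_variants([v], seq)
            results.add((n1.pos, n1.ref, n1.alt))
        assert len(results) == 1


class TestApplyAndProjection:
    def test_apply_respects_anchor_conventions(self):
        seq = "AACCGGTT"
        out = apply_variants([Variant("c", 2, "A", "AT"),      # insertion
                              Variant("c", 5, "GG", "G"),      # deletion
                              Variant("c", 8, "T", "C")], seq)  # SNP
        assert out == "AATCCGTC"

    def test_project_interval_shifts_with_indels(self):
        variants = [Variant("c", 2, "A", "ATT"), Variant("c", 10, "GAA", "G")]
        qs, qe = project_interval(variants, 20, 30)
        assert (qs, qe) == (20, 30)  # +2 insertion, -2 deletion cancel

    def test_project_endpoint_in_deletion_is_ambiguous(self):
        from mutrace.core_io import ProjectionAmbiguousError
        with pytest.raises(ProjectionAmbiguousError):
            project_interval([Variant("c", 10, "GAAA", "G")], 11, 30)
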