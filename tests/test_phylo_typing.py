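"""cgMLST scheme/alleles/distances, clustering oracles, alignment export."""

import numpy as np
import pytest

from mutrace import (
    AnnotatedGenome,
    CdsFeature,
    DistanceMatrix,
    REGIMES,
    Variant,
    VariantSet,
    allelic_distance,
    average_linkage_manhattan,
    binary_variant_matrix,
    build_scheme,
    call_allele_profiles,
    evolve,
    export_snp_alignment,
    generate_ancestor,
    set_specific_genes,
    upgma,
)
from mutrace.core_io import revcomp
from mutrace.phylo_typing import MISSING, AlleleCaller, AlleleProfile


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_force_average_linkage(labels, dist):
    """Exhaustive agglomeration recomputing average linkage from the original
    matrix at every step (no Lance-Williams update); returns merge clades."""
    clusters = [frozenset([l]) for l in labels]
    index = {l: i for i, l in enumerate(labels)}
    clades = set()
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[index[a], index[b]]
                             for a in clusters[i] for b in clusters[j]])
                tag = tuple(sorted((min(clusters[i]), min(clusters[j]))))
                if best is None or (d, tag) < (best[0], best[1]):
                    best = (d, tag, i, j)
        _, _, i, j = best
        merged = clusters[i] | clusters[j]
        clades.add(merged)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return {c for c in clades if len(c) > 1}


def random_distance_matrix(rng, n):
    m = rng.integers(1, 40, size=(n, n)).astype(float)
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


class TestUpgma:
    def test_two_taxa_root_height(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        tree = upgma(dm)
        assert tree.height == 1.0
        assert sorted(tree.leaves()) == ["A", "B"]

    def test_three_taxa_hand_oracle(self):
        # d(A,B)=2, d(A,C)=d(B,C)=6 -> ((A,B) at h=1, C) at h=3
        m = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float)
        tree = upgma(DistanceMatrix(["A", "B", "C"], m))
        assert tree.height == 3.0
        inner = [c for c in tree.children if not c.is_leaf][0]
        assert inner.height == 1.0
        assert sorted(inner.leaves()) == ["A", "B"]

    def test_agrees_with_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 7))
            labels = [f"t{i}" for i in range(n)]
            m = random_distance_matrix(rng, n)
            tree = upgma(DistanceMatrix(labels, m))
            assert tree.clades() == brute_force_average_linkage(labels, m)

    def test_agrees_with_scipy_linkage(self):
        from scipy.cluster.hierarchy import average, fcluster
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(4, 8))
            labels = [f"t{i}" for i in range(n)]
            m = rng.random((n, n)) * 10  # continuous -> ties improbable
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            tree = upgma(DistanceMatrix(labels, m))
            Z = average(squareform(m))
            scipy_clades = set()
            for k in range(2, n):
                assign = fcluster(Z, k, criterion="maxclust")
                for c in np.unique(assign):
                    mem = frozenset(labels[i] for i in np.flatnonzero(assign == c))
                    if len(mem) > 1:
                        scipy_clades.add(mem)
            assert scipy_clades <= tree.clades()

    def test_ultrametric_matrix_reproduces_generating_tree(self):
        # clades ((A,B),(C,D)) with heights 1, 2, 5
        m = np.array([[0, 2, 10, 10], [2, 0, 10, 10],
                      [10, 10, 0, 4], [10, 10, 4, 0]], dtype=float)
        tree = upgma(DistanceMatrix(list("ABCD"), m))
        assert tree.clades() == {frozenset("AB"), frozenset("CD"),
                                 frozenset("ABCD")}

    def test_newick_parses_with_external_reader(self):
        import io
        from Bio import Phylo
        dm = DistanceMatrix(list("ABC"),
                            np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]],
                                     dtype=float))
        nwk = upgma(dm).to_newick()
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["A", "B", "C"]


class TestScheme:
    def test_clean_reference_keeps_all_genes(self, ancestor_30k):
        scheme = build_scheme(ancestor_30k)
        assert len(scheme.targets) == len(ancestor_30k.features)

    def test_duplicated_genes_both_excluded(self, ancestor_30k):
        g = ancestor_30k
        f = g.features[2]
        dup_seq = g.sequence[f.start - 1: f.end]
        seq = g.sequence + "TTTTT" + dup_seq + "TTTTT"
        feats = list(g.features) + [
            CdsFeature("dup", len(g.sequence) + 6,
                       len(g.sequence) + 5 + len(dup_seq), strand=f.strand)]
        g2 = AnnotatedGenome(id="dup", sequence=seq, features=feats)
        scheme = build_scheme(g2)
        assert f.gene_id not in scheme.gene_ids
        assert "dup" not in scheme.gene_ids
        assert len(scheme.targets) == len(g.features) - 1

    def test_short_gene_excluded(self, ancestor_30k):
        g = ancestor_30k
        feats = list(g.features) + [CdsFeature("tiny", 5, 34)]
        g2 = AnnotatedGenome(id="t", sequence=g.sequence, features=feats)
        assert "tiny" not in build_scheme(g2).gene_ids

    def test_ambiguous_gene_excluded(self, ancestor_30k):
        g = ancestor_30k
        f = g.features[0]
        seq = g.sequence[:f.start + 9] + "N" + g.sequence[f.start + 10:]
        g2 = AnnotatedGenome(id="n", sequence=seq, features=list(g.features))
        assert f.gene_id not in build_scheme(g2).gene_ids


class TestAlleleCalling:
    def test_reference_query_all_allele_one(self, ancestor_30k):
        scheme = build_scheme(ancestor_30k)
        prof, = call_allele_profiles(scheme, ancestor_30k, [ancestor_30k])
        assert set(prof.alleles.values()) == {1}

    def test_single_snp_new_allele_distance_one(self, ancestor_30k):
        g = ancestor_30k
        scheme = build_scheme(g)
        f = g.features[7]
        pos = f.start + 30
        alt = "A" if g.sequence[pos - 1] != "A" else "G"
        q = AnnotatedGenome(id="q",
                            sequence=g.sequence[:pos - 1] + alt + g.sequence[pos:])
        ref_prof, q_prof = call_allele_profiles(scheme, g, [g, q])
        assert q_prof.alleles[f.gene_id] == 2
        others = {k: v for k, v in q_prof.alleles.items() if k != f.gene_id}
        assert set(others.values()) == {1}
        dm = allelic_distance([ref_prof, q_prof])
        assert dm.get(g.id, "q") == 1

    def test_contig_border_truncation_missing(self, ancestor_30k):
        g = ancestor_30k
        scheme = build_scheme(g)
        caller = AlleleCaller(scheme, g)
        f = g.features[5]
        cut = (f.start + f.end) // 2
        contigs = [AnnotatedGenome(id="c1", sequence=g.sequence[:cut]),
                   AnnotatedGenome(id="c2", sequence=g.sequence[cut:])]
        prof = caller.call_contigs(contigs, "split")
        assert prof.alleles[f.gene_id] is MISSING
        # targets away from the cut still resolve to the reference allele
        resolved = [v for v in prof.alleles.values() if v is not MISSING]
        assert resolved and set(resolved) == {1}

    def test_missing_excluded_from_pair_distance(self):
        a = AlleleProfile("a", {"g1": 1, "g2": 1, "g3": 1, "g4": 1})
        b = AlleleProfile("b", {"g1": 2, "g2": 2, "g3": MISSING, "g4": 1})
        # g3 differs only by MISSING -> excluded; 2 real differences remain
        dm = allelic_distance([a, b])
        assert dm.get("a", "b") == 2
        assert dm.n_compared[0, 1] == 3

    def test_distance_matrix_symmetric_zero_diagonal(self, ancestor_30k):
        g = ancestor_30k
        scheme = build_scheme(g)
        queries = [evolve(g, REGIMES["wildtype"], 40, seed=s,
                          derived_id=f"q{s}")[0] for s in range(3)]
        profs = call_allele_profiles(scheme, g, [g] + queries)
        dm = allelic_distance(profs)
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)

    def test_allelic_distance_bounded_by_mutation_count(self, ancestor_30k):
        """Each scheme target contributes at most one allelic difference,
        however many mutations it carries."""
        g = ancestor_30k
        scheme = build_scheme(g)
        derived, truth = evolve(g, REGIMES["wildtype"], 80, seed=17,
                                derived_id="d")
        profs = call_allele_profiles(scheme, g, [g, derived])
        dm = allelic_distance(profs)
        assert dm.get(g.id, "d") <= len(truth)


class TestBinaryMatrixClustering:
    def test_matrix_columns_are_variant_union(self, ancestor_50k):
        _, t1 = evolve(ancestor_50k, REGIMES["MMR"], 30, seed=31)
        _, t2 = evolve(ancestor_50k, REGIMES["MMR"], 40, seed=32)
        t1.isolate_id, t2.isolate_id = "x", "y"
        m = binary_variant_matrix([t1, t2])
        assert m.shape[1] == len(t1.keys() | t2.keys())
        assert m.values.sum() == len(t1) + len(t2)

    def test_identical_sets_identical_rows(self, ancestor_50k):
        _, t = evolve(ancestor_50k, REGIMES["MMR"], 25, seed=33)
        t2 = VariantSet(t.reference_id, "copy", list(t.variants))
        m = binary_variant_matrix([t, t2])
        assert (m.iloc[0] == m.iloc[1]).all()

    def test_disjoint_sets_manhattan_distance(self):
        a = VariantSet("r", "a", [Variant("r", i, "A", "G")
                                  for i in (10, 20, 30)])
        b = VariantSet("r", "b", [Variant("r", i, "C", "T")
                                  for i in (40, 50, 60, 70)])
        m = binary_variant_matrix([a, b])
        from scipy.spatial.distance import cityblock
        assert cityblock(m.iloc[0], m.iloc[1]) == 7

    def test_two_rows_merge_at_manhattan_distance(self):
        a = VariantSet("r", "a", [Variant("r", i, "A", "G") for i in (5, 15)])
        b = VariantSet("r", "b", [Variant("r", 5, "A", "G")])
        tree = average_linkage_manhattan(binary_variant_matrix([a, b]))
        assert tree.height == 0.5  # Manhattan distance 1, UPGMA height d/2

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(3)
        from scipy.spatial.distance import pdist, squareform
        for _ in range(30):
            n, m = int(rng.integers(3, 7)), 20
            data = rng.integers(0, 2, size=(n, m))
            import pandas as pd
            frame = pd.DataFrame(data, index=[f"i{k}" for k in range(n)])
            tree = average_linkage_manhattan(frame)
            dist = squareform(pdist(data, metric="cityblock"))
            assert tree.clades() == brute_force_average_linkage(
                list(frame.index), dist)


class TestSnpAlignment:
    def test_no_snps_errors(self, ancestor_30k):
        with pytest.raises(ValueError):
            export_snp_alignment([VariantSet(ancestor_30k.id, "i", [])],
                                 ancestor_30k)

    def test_columns_ordered_and_reference_included(self, ancestor_30k):
        g = ancestor_30k
        seq = g.sequence

        def snp(pos, alt_pref="A"):
            alt = alt_pref if seq[pos - 1] != alt_pref else "G"
            return Variant(g.id, pos, seq[pos - 1], alt)

        sets = [VariantSet(g.id, "i1", [snp(100), snp(300)]),
                VariantSet(g.id, "i2", [snp(200), snp(300), snp(500)]),
                VariantSet(g.id, "i3", [snp(700)])]
        aln = export_snp_alignment(sets, g)
        assert aln.positions == [100, 200, 300, 500, 700]
        assert len(aln.rows) == 4
        assert aln.rows[g.id] == "".join(seq[p - 1] for p in aln.positions)
        # isolates carry the reference base where they have no call
        assert aln.rows["i3"][:4] == aln.rows[g.id][:4]
        assert all(len(r) == 5 for r in aln.rows.values())

    def test_phylip_header(self, ancestor_30k):
        g = ancestor_30k
        v = Variant(g.id, 50, g.sequence[49],
                    "A" if g.sequence[49] != "A" else "C")
        aln = export_snp_alignment([VariantSet(g.id, "i1", [v])], g)
        assert aln.to_phylip().splitlines()[0].split() == ["2", "1"]


class TestSetSpecificGenes:
    def test_identical_groups_empty(self, ancestor_30k):
        assert set_specific_genes([ancestor_30k], [ancestor_30k]) == []

    def test_planted_plasmid_block_recovered(self, ancestor_30k):
        plasmid = generate_ancestor(10_000, 0.5, 8, 800, seed=51)
        feats = [CdsFeature(f"plas{i:02d}", f.start, f.end, f.strand)
                 for i, f in enumerate(plasmid.features)]
        plasmid = AnnotatedGenome(id="plasmid", sequence=plasmid.sequence,
                                  features=feats)
        carriers, free = [], []
        for s in range(4):
            iso, _ = evolve(ancestor_30k, REGIMES["wildtype"], 25,
                            seed=600 + s, derived_id=f"I{s}")
            (carriers if s < 2 else free).append(iso)
        found = set_specific_genes([[c, plasmid] for c in carriers], free)
        assert sorted(found) == sorted(f.gene_id for f in feats)

    def test_gene_below_identity_threshold_absent(self, ancestor_30k):
        """A homolog at ~79% identity does not count as present at the
        80% threshold; at ~95% it does."""
        rng = np.random.default_rng(5)
        f = ancestor_30k.features[1]
        gene = ancestor_30k.sequence[f.start - 1: f.end]

        def degrade(seq, identity):
            n_mut = int(round(len(seq) * (1 - identity)))
            pos = rng.choice(len(seq), size=n_mut, replace=False)
            out = list(seq)
            for p in pos:
                out[p] = rng.permutation([b for b in "ACGT" if b != seq[p]])[0]
            return "".join(out)

        donor = AnnotatedGenome(id="donor", sequence="T" * 30 + gene + "A" * 30,
                                features=[CdsFeature(f.gene_id, 31,
                                                     30 + len(gene), f.strand)])
        far = AnnotatedGenome(id="far",
                              sequence="T" * 30 + degrade(gene, 0.79) + "A" * 30)
        near = AnnotatedGenome(id="near",
                               sequence="T" * 30 + degrade(gene, 0.95) + "A" * 30)
        assert set_specific_genes([donor], [far]) == [f.gene_id]
        assert set_specific_genes([donor], [near]) == []
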