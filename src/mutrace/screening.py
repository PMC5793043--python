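"""Antimutator-gene screening and squatter-colony convergence analysis.

Two questions drive this module.  First: which alleles of the classical
mutator-avoidance genes (mismatch repair: mutL, mutS, mutH, dam, uvrD;
oxidized-guanine repair: mutT, mutY, mutM; and friends) differ between an
isolate and the reference — the comparison that exposes e.g. a MutL
L68_A69del repeat contraction or a +C frameshift in a mutT C-tract?
Second: across independently evolved antibiotic-resistant "squatter"
colonies, which genes are hit again and again by candidate resistance
variants (CDS indels plus missense/nonsense SNPs absent from the parent),
the convergence pattern expected when a mutator strain rediscovers the
same resistance locus repeatedly?
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_io import AnnotatedGenome, VariantSet
from .variant_analysis import ProteinChange, annotate_variant, call_variants_collinear

# default antimutator / stress-response panel, gene_id -> role tag
DEFAULT_PANEL_ROLES = {
    "mutL": "MMR", "mutS": "MMR", "mutH": "MMR", "dam": "MMR", "uvrD": "MMR",
    "mutT": "oxidized-guanine", "mutY": "oxidized-guanine",
    "mutM": "oxidized-guanine",
    "miaA": "other",
    "rpoS": "SPANC", "ompF": "SPANC",
    "acrB": "efflux", "acrE": "efflux", "acrS": "efflux", "rob": "efflux",
    "ompR": "regulator", "envZ": "regulator", "ompC": "regulator",
    "ompA": "regulator",
}


@dataclass
class GenePanel:
    """Gene ids with role tags; ids must resolve in the annotation used."""

    roles: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_ROLES))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.roles)

    @classmethod
    def from_text(cls, text: str) -> "GenePanel":
        """Parse a plain-text panel: one `gene_id<TAB>role` per line."""
        roles = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            roles[parts[0]] = parts[1] if len(parts) > 1 else "unassigned"
        return cls(roles=roles)

    def to_text(self) -> str:
        return "".join(f"{g}\t{r}\n" for g, r in self.roles.items())


@dataclass
class ConvergenceReport:
    """Per-gene recurrence of qualifying changes across squatter isolates."""

    n_total: int
    min_hits: int
    hits: dict[str, list[tuple[str, ProteinChange]]]  # gene -> (isolate, change)

    @property
    def convergent_genes(self) -> list[str]:
        """Genes with qualifying changes in >= min_hits distinct isolates."""
        out = []
        for gene, entries in self.hits.items():
            isolates = {iso for iso, _ in entries}
            if len(isolates) >= self.min_hits:
                out.append(gene)
        return sorted(out)

    def n_isolates_hit(self, gene: str) -> int:
        return len({iso for iso, _ in self.hits.get(gene, [])})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene, entries in sorted(self.hits.items()):
            rows.append({
                "gene_id": gene,
                "n_isolates_hit": len({iso for iso, _ in entries}),
                "n_total": self.n_total,
                "convergent": len({iso for iso, _ in entries}) >= self.min_hits,
                "changes": ";".join(f"{iso}:{c.hgvs_like or c.kind}"
                                    for iso, c in entries),
            })
        return pd.DataFrame(rows)


def _as_variant_set(obj: VariantSet | AnnotatedGenome,
                    reference: AnnotatedGenome) -> VariantSet:
    if isinstance(obj, VariantSet):
        return obj
    return call_variants_collinear(reference, obj)


def screen_gene_panel(reference: AnnotatedGenome,
                      query: VariantSet | AnnotatedGenome,
                      panel: GenePanel | None = None
                      ) -> dict[str, list[tuple]]:
    """All coding changes (including synonymous) per panel gene.

    ``query`` is a collinear genome (variants are called) or a pre-computed
    variant set against ``reference``.  Returns gene_id -> list of
    (Variant, ProteinChange) with protein-level naming.
    """
    panel = panel or GenePanel()
    panel_ids = set(panel.gene_ids)
    known = {f.gene_id for f in reference.features}
    missing = panel_ids - known
    resolved = panel_ids & known
    if not resolved:
        raise ValueError("no panel gene resolves in the reference annotation")
    vset = _as_variant_set(query, reference)
    report: dict[str, list[tuple]] = {g: [] for g in sorted(resolved)}
    for v in vset:
        for change in annotate_variant(v, reference):
            if change.gene_id in resolved:
                report[change.gene_id].append((v, change))
    return report


def squatter_specific_variants(parent: VariantSet | AnnotatedGenome,
                               squatter: VariantSet | AnnotatedGenome,
                               reference: AnnotatedGenome
                               ) -> list[tuple]:
    """Candidate resistance variants of one squatter colony.

    Set difference squatter - parent on normalized (pos, ref, alt) keys,
    retaining only CDS-overlapping indels and missense/nonsense SNPs.
    Returns (Variant, [ProteinChange]) pairs for the retained variants.
    """
    parent_set = _as_variant_set(parent, reference)
    squatter_set = _as_variant_set(squatter, reference)
    specific = squatter_set.difference(parent_set)
    out = []
    for v in specific:
        changes = [c for c in annotate_variant(v, reference)
                   if c.kind != "intergenic"]
        if not changes:
            continue
        if v.is_indel:
            out.append((v, changes))
        else:
            qualifying = [c for c in changes if c.kind in ("missense", "nonsense")]
            if qualifying:
                out.append((v, qualifying))
    return out


def convergence_genes(filtered_sets: dict[str, list[tuple]],
                      min_hits: int | None = None,
                      gene_groups: dict[str, str] | None = None
                      ) -> ConvergenceReport:
    """Recurrently hit genes across squatter isolates.

    ``filtered_sets`` maps isolate id -> output of
    :func:`squatter_specific_variants`.  Default ``min_hits`` is n-1 of n
    isolates (the "all or nearly all" rule).  ``gene_groups`` optionally
    maps gene ids onto a shared locus label before counting (e.g. merging
    a two-component system's sensor and regulator).
    """
    if len(filtered_sets) < 2:
        raise ValueError("need at least two squatter isolates")
    n_total = len(filtered_sets)
    if min_hits is None:
        min_hits = n_total - 1
    groups = gene_groups or {}
    hits: dict[str, list[tuple[str, ProteinChange]]] = {}
    for isolate, entries in filtered_sets.items():
        for _v, changes in entries:
            for c in changes:
                locus = groups.get(c.gene_id, c.gene_id)
                hits.setdefault(locus, []).append((isolate, c))
    return ConvergenceReport(n_total=n_total, min_hits=min_hits, hits=hits)
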