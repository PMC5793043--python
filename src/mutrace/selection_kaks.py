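"""Ka/Ks by exhaustive site enumeration with transition/transversion weighting.

The statistic compares the observed nonsynonymous/synonymous split of CDS
SNPs with the split expected under neutrality for the *same* mutational
composition.  Every coding site of the reference is enumerated with its
three alternative bases; the single transition at a site receives weight
``ts_fraction`` (estimated from the isolate's own SNPs) and each of the two
transversions ``(1 - ts_fraction) / 2``.  Weights accumulate into expected
missense (``na_exp``) and synonymous (``ns_exp``) totals; nonsense and
stop-loss alternatives are excluded from both sums, as are terminal stop
codons, mirroring the exclusion of observed nonsense changes.

    Ka/Ks = (na_obs / ns_obs) / (na_exp / ns_exp)

A ratio near 1 indicates neutral evolution — the expected outcome for
mutations accumulated during dormant storage rather than growth under
selection.  Isolates with no observed synonymous SNPs (e.g. an isolate
carrying only indels) yield an explicitly undefined result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .core_io import AnnotatedGenome, VariantSet

# bacterial/archaeal genetic code (translation table 11); '*' marks stops
_T11 = unambiguous_dna_by_id[11]
CODON_TO_AA: dict[str, str] = dict(_T11.forward_table)
for _stop in _T11.stop_codons:
    CODON_TO_AA[_stop] = "*"

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

# the six strand-collapsed classes, for the optional 6-class weighting mode
_PAIR_OF = {"A": "A:T", "T": "A:T", "G": "G:C", "C": "G:C"}
_CLASS_OF_CHANGE = {
    ("A", "G"): "A:T>G:C", ("T", "C"): "A:T>G:C",
    ("G", "A"): "G:C>A:T", ("C", "T"): "G:C>A:T",
    ("A", "C"): "A:T>C:G", ("T", "G"): "A:T>C:G",
    ("A", "T"): "A:T>T:A", ("T", "A"): "A:T>T:A",
    ("G", "T"): "G:C>T:A", ("C", "A"): "G:C>T:A",
    ("G", "C"): "G:C>C:G", ("C", "G"): "G:C>C:G",
}


@dataclass
class ExpectedWeights:
    """Site-enumeration totals; ``total_weight`` equals the number of
    enumerated sites (per-site weights sum to 1)."""

    na_exp: float
    ns_exp: float
    nonsense_weight: float
    stop_loss_weight: float
    n_sites: int

    @property
    def total_weight(self) -> float:
        return self.na_exp + self.ns_exp + self.nonsense_weight + self.stop_loss_weight


@dataclass
class KaKsResult:
    na_obs: int
    ns_obs: int
    na_exp: float
    ns_exp: float
    ratio: float | None
    n_excluded_nonsense: int
    ts_fraction: float | None = None
    status: str = "ok"
    ci_low: float | None = None
    ci_high: float | None = None


def _alt_weight(ref: str, alt: str, ts_fraction: float,
                class_weights: dict[str, float] | None) -> float:
    """Neutral weight of one alternative base at one site.

    2-class mode: the transition gets ``ts_fraction``, each transversion
    ``(1 - ts_fraction)/2``.  6-class mode: the three alternatives at a site
    share the (renormalized) weights of their substitution classes.
    """
    if class_weights is None:
        if alt == _TRANSITION[ref]:
            return ts_fraction
        return (1.0 - ts_fraction) / 2.0
    pair = _PAIR_OF[ref]
    classes = [c for (r, a), c in _CLASS_OF_CHANGE.items() if r == ref]
    z = sum(class_weights[c] for c in classes)
    if z == 0:
        return 0.0
    return class_weights[_CLASS_OF_CHANGE[(ref, alt)]] / z


def expected_effect_weights(genome: AnnotatedGenome, ts_fraction: float,
                            class_weights: dict[str, float] | None = None
                            ) -> ExpectedWeights:
    """Enumerate every coding site and its three alternatives.

    Per CDS (each frame of an overlapping pair contributes separately),
    terminal stop codons are excluded; internal stops (pseudogenes) are
    skipped.  Raises ``ValueError`` on a genome without CDS.
    """
    if class_weights is None and not 0.0 < ts_fraction < 1.0:
        raise ValueError("ts_fraction must lie strictly between 0 and 1")
    feats = [f for f in genome.features]
    if not feats:
        raise ValueError("genome has no CDS to enumerate")
    na = ns = nonsense = stop_loss = 0.0
    n_sites = 0
    for f in feats:
        coding = genome.cds_sequence(f)
        n_codons = len(coding) // 3
        for ci in range(n_codons):
            codon = coding[3 * ci: 3 * ci + 3]
            aa0 = CODON_TO_AA.get(codon)
            if aa0 is None or aa0 == "*":
                continue  # terminal stop (or internal stop in a pseudogene)
            for k in range(3):
                ref = codon[k]
                n_sites += 1
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    w = _alt_weight(ref, alt, ts_fraction, class_weights)
                    aa1 = CODON_TO_AA[codon[:k] + alt + codon[k + 1:]]
                    if aa1 == aa0:
                        ns += w
                    elif aa1 == "*":
                        nonsense += w
                    else:
                        na += w
    return ExpectedWeights(na_exp=na, ns_exp=ns, nonsense_weight=nonsense,
                           stop_loss_weight=stop_loss, n_sites=n_sites)


def observed_effect_counts(annotated: list[tuple]) -> tuple[int, int, int]:
    """(na_obs, ns_obs, n_nonsense) from annotated SNPs.

    ``annotated`` holds (Variant, [ProteinChange]) pairs as produced by
    :func:`mutrace.variant_analysis.annotate_variants`.  Indels and
    intergenic SNPs contribute nothing; a variant counts once per CDS it
    hits.  Nonsense changes are tallied separately and excluded.
    """
    na = ns = nn = 0
    for v, changes in annotated:
        if v.vclass not in ("SNP", "MNP"):
            continue
        for c in changes:
            if c.kind == "missense":
                na += 1
            elif c.kind == "synonymous":
                ns += 1
            elif c.kind in ("nonsense", "stop_loss"):
                nn += 1
    return na, ns, nn


def estimate_ts_fraction(vset: VariantSet) -> float | None:
    """Transition fraction of all SNPs (CDS + intergenic) in a variant set."""
    snps = vset.snps(split_mnps=True)
    if not snps:
        return None
    ts = sum(1 for v in snps if v.alt == _TRANSITION[v.ref])
    return ts / len(snps)


def kaks(genome: AnnotatedGenome, vset: VariantSet,
         class_weights: dict[str, float] | None = None,
         n_boot: int = 0, seed: int = 0) -> KaKsResult:
    """Ka/Ks of one isolate's variant set against its annotated reference.

    The transition fraction is estimated from the same set's SNPs; expected
    weights come from full site enumeration of the reference CDS.  Returns
    an explicitly undefined result when no synonymous SNP was observed or
    when the expectation degenerates.  ``n_boot`` > 0 adds a percentile
    bootstrap CI over variants.
    """
    from .variant_analysis import annotate_variants  # deferred: avoids cycle

    snps = vset.snps(split_mnps=True)
    if not snps:
        return KaKsResult(0, 0, 0.0, 0.0, None, 0,
                          status="undefined (no SNPs observed)")
    ts_fraction = estimate_ts_fraction(vset)
    eps = 1e-9
    ts_clamped = min(max(ts_fraction, eps), 1 - eps)
    exp = expected_effect_weights(genome, ts_clamped, class_weights)
    snp_set = VariantSet(vset.reference_id, vset.isolate_id, snps)
    annotated = annotate_variants(snp_set, genome)
    na_obs, ns_obs, nn = observed_effect_counts(annotated)

    def ratio_of(na_o: int, ns_o: int) -> float | None:
        if ns_o == 0 or exp.ns_exp <= 0 or exp.na_exp <= 0:
            return None
        return (na_o / ns_o) / (exp.na_exp / exp.ns_exp)

    ratio = ratio_of(na_obs, ns_obs)
    if ratio is None:
        status = ("undefined (no synonymous)" if ns_obs == 0
                  else "undefined (degenerate expectation)")
        return KaKsResult(na_obs, ns_obs, exp.na_exp, exp.ns_exp, None, nn,
                          ts_fraction=ts_fraction, status=status)

    ci_low = ci_high = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        kinds = []
        for v, changes in annotated:
            for c in changes:
                if c.kind in ("missense", "synonymous"):
                    kinds.append(c.kind == "missense")
        kinds_arr = np.array(kinds)
        ratios = []
        for _ in range(n_boot):
            res = kinds_arr[rng.integers(len(kinds_arr), size=len(kinds_arr))]
            r = ratio_of(int(res.sum()), int((~res).sum()))
            if r is not None:
                ratios.append(r)
        if ratios:
            ci_low, ci_high = np.percentile(ratios, [2.5, 97.5]).tolist()

    return KaKsResult(na_obs, ns_obs, exp.na_exp, exp.ns_exp, ratio, nn,
                      ts_fraction=ts_fraction, ci_low=ci_low, ci_high=ci_high)
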