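"""Mutational-spectrum statistics and mutator-signature inference.

Substitutions are collapsed onto the six strand-symmetric base-pair classes
used throughout bacterial mutation-accumulation work:

    transitions:   A:T>G:C, G:C>A:T
    transversions: A:T>C:G, A:T>T:A, G:C>T:A, G:C>C:G

so e.g. an observed T->C change counts with A->G as A:T>G:C.  The module
computes per-isolate spectra and indel/SNP ratios, flags the signatures of
the classical Escherichia coli mutator pathways (mismatch-repair loss:
elevated indels plus transitions; MutT loss: A:T>C:G transversions;
oxidative damage: G:C>T:A transversions), and tests whether variants are
spread uniformly along the chromosome or concentrated in hotspots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import VariantSet

SUBSTITUTION_CLASSES = (
    "A:T>G:C", "G:C>A:T",            # transitions
    "A:T>C:G", "A:T>T:A", "G:C>T:A", "G:C>C:G",  # transversions
)
TRANSITION_CLASSES = frozenset({"A:T>G:C", "G:C>A:T"})

_CLASS_BY_CHANGE = {
    ("A", "G"): "A:T>G:C", ("T", "C"): "A:T>G:C",
    ("G", "A"): "G:C>A:T", ("C", "T"): "G:C>A:T",
    ("A", "C"): "A:T>C:G", ("T", "G"): "A:T>C:G",
    ("A", "T"): "A:T>T:A", ("T", "A"): "A:T>T:A",
    ("G", "T"): "G:C>T:A", ("C", "A"): "G:C>T:A",
    ("G", "C"): "G:C>C:G", ("C", "G"): "G:C>C:G",
}


def classify_substitution(ref_base: str, alt_base: str) -> str:
    """Strand-collapsed base-pair class of a single-nucleotide substitution."""
    try:
        return _CLASS_BY_CHANGE[(ref_base.upper(), alt_base.upper())]
    except KeyError:
        raise ValueError(f"not a substitution: {ref_base}>{alt_base}") from None


def is_transition(ref_base: str, alt_base: str) -> bool:
    return classify_substitution(ref_base, alt_base) in TRANSITION_CLASSES


@dataclass
class SpectrumProfile:
    """Counts per substitution class plus the indel count of one variant set."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in SUBSTITUTION_CLASSES})
    n_indel: int = 0

    @property
    def n_snp(self) -> int:
        return sum(self.counts.values())

    def fraction(self, cls: str) -> float:
        return self.counts[cls] / self.n_snp if self.n_snp else 0.0

    @property
    def transition_fraction(self) -> float:
        if not self.n_snp:
            return 0.0
        return sum(self.counts[c] for c in TRANSITION_CLASSES) / self.n_snp

    def __add__(self, other: "SpectrumProfile") -> "SpectrumProfile":
        merged = {c: self.counts[c] + other.counts[c] for c in SUBSTITUTION_CLASSES}
        return SpectrumProfile(counts=merged, n_indel=self.n_indel + other.n_indel)

    def as_series(self) -> pd.Series:
        data = dict(self.counts)
        data["n_snp"] = self.n_snp
        data["n_indel"] = self.n_indel
        return pd.Series(data)


def compute_spectrum(variant_set: VariantSet) -> SpectrumProfile:
    """Six-class substitution spectrum + indel count (MNPs split per base)."""
    profile = SpectrumProfile()
    for v in variant_set.snps(split_mnps=True):
        profile.counts[classify_substitution(v.ref, v.alt)] += 1
    profile.n_indel = len(variant_set.indels())
    return profile


def indel_snp_ratio(profile: SpectrumProfile) -> float | None:
    """Indels per SNP; ``None`` (undefined) when the isolate carries no SNPs."""
    if profile.n_snp == 0:
        return None
    return profile.n_indel / profile.n_snp


# ---------------------------------------------------------------------------
# Mutator signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureConfig:
    """Thresholds for the rule-based mutator signature calls.

    The flags encode the qualitative spectra of the three classical pathways:
    MMR loss (many indels and transition-dominated SNPs), MutT loss
    (A:T>C:G transversions) and oxidative damage (G:C>T:A transversions).
    ``null_spectrum`` feeds the one-sided binomial evidence statistics and
    defaults to a uniform spectrum over the six classes.
    """

    min_events: int = 30
    r_mmr: float = 0.2          # indel/SNP ratio threshold
    f_ts: float = 0.4           # transition-fraction threshold
    f_mutT: float = 0.15        # A:T>C:G fraction threshold
    f_ox: float = 0.15          # G:C>T:A fraction threshold
    null_spectrum: tuple[float, ...] = (1 / 6,) * 6


@dataclass
class SignatureCall:
    flags: set[str]
    evidence: dict[str, dict[str, float]]
    status: str = "ok"          # or "insufficient data"


def infer_mutator_signatures(profile: SpectrumProfile,
                             config: SignatureConfig | None = None) -> SignatureCall:
    """Flag mutator signatures in a spectrum.

    Rules (all thresholds from ``config``): ``MMR`` iff indel/SNP ratio >=
    ``r_mmr`` and transition fraction >= ``f_ts``; ``MutT_like`` iff the
    A:T>C:G fraction >= ``f_mutT``; ``oxidative_GT`` iff the G:C>T:A fraction
    >= ``f_ox``.  Each flag carries a one-sided binomial p-value of its class
    count against the configured null spectrum.  Profiles with fewer than
    ``min_events`` SNPs+indels return an "insufficient data" call, no flags.
    """
    cfg = config or SignatureConfig()
    n_events = profile.n_snp + profile.n_indel
    if n_events < cfg.min_events:
        return SignatureCall(flags=set(), evidence={}, status="insufficient data")

    null = dict(zip(SUBSTITUTION_CLASSES, cfg.null_spectrum))
    n = profile.n_snp
    ratio = indel_snp_ratio(profile)
    flags: set[str] = set()
    evidence: dict[str, dict[str, float]] = {}

    def binom_p(k: int, p_null: float) -> float:
        if n == 0:
            return 1.0
        return stats.binomtest(k, n, p_null, alternative="greater").pvalue

    ts_count = sum(profile.counts[c] for c in TRANSITION_CLASSES)
    ts_null = sum(null[c] for c in TRANSITION_CLASSES)
    evidence["MMR"] = {
        "indel_snp_ratio": ratio if ratio is not None else float("inf"),
        "ratio_threshold": cfg.r_mmr,
        "transition_fraction": profile.transition_fraction,
        "fraction_threshold": cfg.f_ts,
        "p_transitions": binom_p(ts_count, ts_null),
    }
    if (ratio is None or ratio >= cfg.r_mmr) and \
            (n > 0 and profile.transition_fraction >= cfg.f_ts):
        flags.add("MMR")

    for flag, cls, thr in (("MutT_like", "A:T>C:G", cfg.f_mutT),
                           ("oxidative_GT", "G:C>T:A", cfg.f_ox)):
        frac = profile.fraction(cls)
        evidence[flag] = {
            "fraction": frac,
            "fraction_threshold": thr,
            "p_value": binom_p(profile.counts[cls], null[cls]),
        }
        if n > 0 and frac >= thr:
            flags.add(flag)

    return SignatureCall(flags=flags, evidence=evidence)


# ---------------------------------------------------------------------------
# Physical distribution (hotspot scan)
# ---------------------------------------------------------------------------

@dataclass
class HotspotResult:
    window_counts: pd.DataFrame   # columns: start, end, count (1-based inclusive)
    p_value: float
    max_window: tuple[int, int, int]   # (start, end, count)


def hotspot_scan(variant_set: VariantSet, genome_length: int,
                 window_bp: int = 10_000) -> HotspotResult:
    """Chi-square test of variant positions against a uniform genome-wide rate.

    Positions are binned into fixed windows; adjacent windows are pooled
    until every bin expects at least one variant, then a goodness-of-fit
    test against the (bin-size-proportional) uniform expectation is run.
    A single variant is uninformative and returns p = 1 by convention.
    """
    positions = np.array([v.pos for v in variant_set], dtype=float)
    if positions.size == 0:
        raise ValueError("hotspot_scan requires at least one variant")
    n_windows = int(np.ceil(genome_length / window_bp))
    edges = np.arange(n_windows + 1, dtype=float) * window_bp
    edges[-1] = genome_length
    counts, _ = np.histogram(positions, bins=edges + 0.5)

    starts = (np.arange(n_windows) * window_bp + 1).astype(int)
    ends = np.minimum((np.arange(1, n_windows + 1)) * window_bp, genome_length)
    table = pd.DataFrame({"start": starts, "end": ends, "count": counts})
    imax = int(np.argmax(counts))
    max_window = (int(starts[imax]), int(ends[imax]), int(counts[imax]))

    n = positions.size
    if n < 2:
        return HotspotResult(table, 1.0, max_window)

    # pool adjacent windows so each bin expects >= 1 variant
    per_window = n / n_windows
    group = 1 if per_window >= 1.0 else int(np.ceil(1.0 / per_window))
    sizes = []
    pooled = []
    for i in range(0, n_windows, group):
        chunk = counts[i:i + group]
        pooled.append(chunk.sum())
        sizes.append(len(chunk))
    if len(pooled) < 2:
        return HotspotResult(table, 1.0, max_window)
    pooled_arr = np.array(pooled, dtype=float)
    expected = n * np.array(sizes, dtype=float) / n_windows
    _, p = stats.chisquare(pooled_arr, f_exp=expected)
    return HotspotResult(table, float(p), max_window)


def spectrum_table(profiles: dict[str, SpectrumProfile]) -> pd.DataFrame:
    """Per-isolate spectrum table: one row per isolate, classes + totals + ratio."""
    rows = {}
    for isolate, prof in profiles.items():
        s = prof.as_series()
        r = indel_snp_ratio(prof)
        s["indel_snp_ratio"] = float("nan") if r is None else r
        rows[isolate] = s
    return pd.DataFrame(rows).T


def windows_to_bed(result: HotspotResult, chrom: str) -> str:
    """BED track (0-based half-open on export only) of per-window counts."""
    lines = [f"{chrom}\t{s - 1}\t{e}\t{c}"
             for s, e, c in result.window_counts.itertuples(index=False)]
    return "\n".join(lines) + "\n"
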