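"""Candidate somatic SNV detection from matched tumor/normal evidence.

A site yields a candidate when the normal genotypes as homozygous reference,
the tumor carries enough alternate reads at sufficient allele frequency, and
Fisher's exact test on the tumor-vs-normal ref/alt counts shows a significant
allele-frequency change.  Read counts use only bases at or above a quality
floor; N bases never count toward alleles.  Multi-allelic sites are resolved
to the most frequent non-reference base.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import pandas as pd

from .evidence import EvidenceStore, SiteEvidence
from .stats import fisher_exact_2x2


@dataclass(frozen=True)
class CallerConfig:
    min_depth_each_sample: int = 10
    min_alt_reads_tumor: int = 2
    min_tumor_vaf: float = 0.04
    max_normal_vaf: float = 0.02
    candidate_p_threshold: float = 0.05
    min_count_base_quality: int = 15
    het_band: tuple[float, float] = (0.3, 0.7)
    hom_alt_min: float = 0.95

    def __post_init__(self) -> None:
        if not (0 <= self.max_normal_vaf < self.min_tumor_vaf <= 1):
            raise ValueError("need 0 <= max_normal_vaf < min_tumor_vaf <= 1")
        if not (0 < self.candidate_p_threshold < 1):
            raise ValueError("candidate_p_threshold must be in (0,1)")
        if self.min_depth_each_sample < 1 or self.min_alt_reads_tumor < 0:
            raise ValueError("depth/read thresholds must be positive")


@dataclass(frozen=True)
class CandidateSNV:
    """A putative tumor-specific substitution with its supporting counts."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    tumor_ref_count: int
    tumor_alt_count: int
    normal_ref_count: int
    normal_alt_count: int
    vaf_tumor: float
    vaf_normal: float
    fisher_p: float

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError("alt allele equals reference")
        if min(
            self.tumor_ref_count, self.tumor_alt_count,
            self.normal_ref_count, self.normal_alt_count,
        ) < 0:
            raise ValueError("negative allele count")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def compute_vaf(alt_count: int, total_informative_count: int) -> float:
    """Variant allele fraction alt/total; 0 when no informative reads."""
    if alt_count < 0 or total_informative_count < 0:
        raise ValueError("counts must be non-negative")
    if alt_count > total_informative_count:
        raise ValueError("alt count exceeds total informative count")
    if total_informative_count == 0:
        return 0.0
    return alt_count / total_informative_count


def vaf_percent(vaf: float) -> float:
    """VAF as a percentage rounded to 2 decimals, the reporting convention."""
    return round(100.0 * vaf, 2)


def _site_counts(site: SiteEvidence, min_baseq: int) -> Counter:
    return Counter(
        {base: n for base, n in site.allele_counts(min_base_quality=min_baseq).items()}
    )


def genotype_normal(site: SiteEvidence, config: CallerConfig = CallerConfig()) -> str:
    """Genotype the matched normal at one site: hom_ref / het / hom_alt / ambiguous.

    Sites below the depth floor are ambiguous (and skipped upstream).  The
    classification uses the VAF of the most frequent non-reference allele.
    """
    if site.depth < config.min_depth_each_sample:
        return "ambiguous"
    counts = _site_counts(site, config.min_count_base_quality)
    ref_n = counts.get(site.ref_base, 0)
    alt_counts = {b: n for b, n in counts.items() if b != site.ref_base}
    alt_n = max(alt_counts.values()) if alt_counts else 0
    total = ref_n + alt_n
    if total == 0:
        return "ambiguous"
    vaf = alt_n / total
    if vaf <= config.max_normal_vaf:
        return "hom_ref"
    if config.het_band[0] <= vaf <= config.het_band[1]:
        return "het"
    if vaf >= config.hom_alt_min:
        return "hom_alt"
    return "ambiguous"


def detect_candidates(
    tumor: EvidenceStore,
    normal: EvidenceStore,
    config: CallerConfig = CallerConfig(),
) -> tuple[list[CandidateSNV], dict[str, int]]:
    """Scan all tumor sites and emit candidate somatic SNVs.

    Returns the candidate list (sorted by position) and a counter of skip
    reasons for the sites that did not yield a candidate.
    """
    counters: dict[str, int] = Counter()
    candidates: list[CandidateSNV] = []

    # vectorized per-site allele counts for both samples
    def count_table(store: EvidenceStore) -> dict[tuple[str, int], Counter]:
        f = store.frame
        if f.empty:
            return {}
        ok = (f["baseq"] >= config.min_count_base_quality) & (f["base"] != "N")
        grouped = f[ok].groupby(["chrom", "pos", "base"], sort=False).size()
        out: dict[tuple[str, int], Counter] = {}
        for (chrom, pos, base), n in grouped.items():
            out.setdefault((chrom, int(pos)), Counter())[base] = int(n)
        return out

    def depth_table(store: EvidenceStore) -> dict[tuple[str, int], int]:
        f = store.frame
        if f.empty:
            return {}
        g = f.groupby(["chrom", "pos"], sort=False).size()
        return {(c, int(p)): int(n) for (c, p), n in g.items()}

    def ref_table(store: EvidenceStore) -> dict[tuple[str, int], str]:
        f = store.frame
        if f.empty:
            return {}
        g = f.groupby(["chrom", "pos"], sort=False)["ref"].first()
        return {(c, int(p)): r for (c, p), r in g.items()}

    t_counts = count_table(tumor)
    n_counts = count_table(normal)
    t_depth = depth_table(tumor)
    n_depth = depth_table(normal)
    refs = ref_table(tumor)

    for key in sorted(t_depth):
        chrom, pos = key
        if key not in n_depth:
            counters["no_normal_evidence"] += 1
            continue
        if t_depth[key] < config.min_depth_each_sample or n_depth[key] < config.min_depth_each_sample:
            counters["low_depth"] += 1
            continue
        ref = refs[key]
        tc = t_counts.get(key, Counter())
        nc = n_counts.get(key, Counter())

        alt_candidates = {b: n for b, n in tc.items() if b != ref}
        if not alt_candidates:
            counters["no_alt_reads"] += 1
            continue
        # most frequent non-reference base; deterministic tie-break on base
        alt = sorted(alt_candidates, key=lambda b: (-alt_candidates[b], b))[0]
        t_alt = alt_candidates[alt]
        t_ref = tc.get(ref, 0)
        if t_alt < config.min_alt_reads_tumor:
            counters["few_alt_reads"] += 1
            continue
        vaf_t = compute_vaf(t_alt, t_ref + t_alt)
        if vaf_t < config.min_tumor_vaf:
            counters["low_tumor_vaf"] += 1
            continue

        n_ref = nc.get(ref, 0)
        n_alt = nc.get(alt, 0)
        # normal genotype by top non-ref allele VAF
        n_alt_all = {b: n for b, n in nc.items() if b != ref}
        n_top = max(n_alt_all.values()) if n_alt_all else 0
        n_total = n_ref + n_top
        if n_total == 0:
            counters["normal_uninformative"] += 1
            continue
        n_vaf_top = n_top / n_total
        if n_vaf_top > config.max_normal_vaf:
            counters["normal_not_hom_ref"] += 1
            continue

        result = fisher_exact_2x2(t_alt, t_ref, n_alt, n_ref)
        if result.p_value >= config.candidate_p_threshold:
            counters["fisher_not_significant"] += 1
            continue
        candidates.append(
            CandidateSNV(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                tumor_ref_count=t_ref, tumor_alt_count=t_alt,
                normal_ref_count=n_ref, normal_alt_count=n_alt,
                vaf_tumor=vaf_t,
                vaf_normal=compute_vaf(n_alt, n_ref + n_alt) if (n_ref + n_alt) else 0.0,
                fisher_p=result.p_value,
            )
        )
    return candidates, dict(counters)
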