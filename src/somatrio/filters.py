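"""Seven-criterion statistical false-positive filter cascade for somatic SNVs.

Each candidate is vetted by seven independently testable criteria; every
criterion is always evaluated (no short-circuiting) and the call passes
overall iff all seven pass:

1. ``adj_dist``       -- nearest candidate on the same chromosome at >= 10 bp;
2. ``low_mapq``       -- variant-read mapping qualities not significantly
                         below 30 (Wilcoxon test, p < 0.20 fails);
3. ``low_baseq``      -- variant-read base qualities not significantly below
                         20 (Wilcoxon test, p < 0.05 fails);
4. ``af_fisher``      -- significant tumor-vs-normal allele-frequency change
                         (Fisher's exact test; p >= 0.05 fails);
5. ``gap_region``     -- fewer than 10 gap-flagged reads within a 20 bp flank;
6. ``read_end_bias``  -- variant reads not significantly enriched within 5 bp
                         of a read end (Wilcoxon test, p < 0.05 fails);
7. ``repeat_region``  -- not inside a simple tandem repeat of >= 6 copies.

Criteria 2 and 3 are read as one-sample signed-rank tests of the
variant-supporting reads against the stated constant; a two-sample variant
(variant vs. reference reads) is available through the config.  Criterion 6
compares variant-read against reference-read end distances (the population
named by "enriched"); a hard positional cutoff is available through the
config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .caller import CandidateSNV
from .evidence import EvidenceStore, SiteEvidence
from .repeats import max_tandem_copies
from .stats import fisher_exact_2x2, rank_sum_one_sided, signed_rank_vs_constant

CRITERIA = (
    "adj_dist",
    "low_mapq",
    "low_baseq",
    "af_fisher",
    "gap_region",
    "read_end_bias",
    "repeat_region",
)


@dataclass(frozen=True)
class FilterConfig:
    min_adjacent_distance: int = 10
    mapq_ref_value: int = 30
    mapq_p: float = 0.20
    baseq_ref_value: int = 20
    baseq_p: float = 0.05
    af_p: float = 0.05
    gap_flank: int = 20
    max_gap_flags: int = 10       # exclusive: >= this many fails
    end_window: int = 5
    end_p: float = 0.05
    max_repeat_events: int = 6    # exclusive: >= this many copies fails
    repeat_scan_flank: int = 25
    repeat_max_unit: int = 4
    quality_test_mode: str = "one_sample"   # or "two_sample"
    end_bias_mode: str = "rank_sum"         # or "hard_cutoff"

    def __post_init__(self) -> None:
        for p in (self.mapq_p, self.baseq_p, self.af_p, self.end_p):
            if not (0 < p < 1):
                raise ValueError("p thresholds must be in (0,1)")
        for v in (
            self.min_adjacent_distance, self.gap_flank, self.max_gap_flags,
            self.end_window, self.max_repeat_events, self.repeat_scan_flank,
            self.repeat_max_unit,
        ):
            if v <= 0:
                raise ValueError("all thresholds must be positive")
        if self.quality_test_mode not in ("one_sample", "two_sample"):
            raise ValueError("quality_test_mode must be one_sample or two_sample")
        if self.end_bias_mode not in ("rank_sum", "hard_cutoff"):
            raise ValueError("end_bias_mode must be rank_sum or hard_cutoff")


@dataclass(frozen=True)
class FilterVerdict:
    criterion: str
    passed: bool
    statistic: float | None = None
    p_value: float | None = None
    detail: str = ""


@dataclass
class SomaticCall:
    """A candidate annotated with all seven filter verdicts."""

    candidate: CandidateSNV
    verdicts: dict[str, FilterVerdict] = field(default_factory=dict)

    @property
    def key(self):
        return self.candidate.key

    @property
    def passed(self) -> bool:
        return all(v.passed for v in self.verdicts.values()) and len(self.verdicts) == len(CRITERIA)

    @property
    def failed_criteria(self) -> list[str]:
        return [c for c in CRITERIA if c in self.verdicts and not self.verdicts[c].passed]

    @property
    def filter_field(self) -> str:
        """VCF FILTER column value."""
        failed = self.failed_criteria
        return "PASS" if not failed else ";".join(failed)


def f1_adjacent_distance(
    candidates: Sequence[CandidateSNV], config: FilterConfig = FilterConfig()
) -> dict[tuple, FilterVerdict]:
    """Both members of any pair closer than the minimum distance fail.

    Clustered calls signal one local alignment artifact, not one good and one
    bad call, so the whole cluster is removed.
    """
    ordered = sorted(candidates, key=lambda c: (c.chrom, c.pos))
    verdicts: dict[tuple, FilterVerdict] = {}
    for i, cand in enumerate(ordered):
        nearest = None
        if i > 0 and ordered[i - 1].chrom == cand.chrom:
            nearest = cand.pos - ordered[i - 1].pos
        if i + 1 < len(ordered) and ordered[i + 1].chrom == cand.chrom:
            d = ordered[i + 1].pos - cand.pos
            nearest = d if nearest is None else min(nearest, d)
        if nearest is None:
            verdicts[cand.key] = FilterVerdict("adj_dist", True, detail="single candidate on chromosome")
        else:
            verdicts[cand.key] = FilterVerdict(
                "adj_dist",
                nearest >= config.min_adjacent_distance,
                statistic=float(nearest),
                detail=f"nearest candidate at {nearest} bp",
            )
    return verdicts


def _variant_obs(site: SiteEvidence, alt: str):
    obs = site.variant_observations(alt)
    if not obs:
        raise ValueError(
            f"no variant-supporting reads at {site.chrom}:{site.pos} for alt {alt!r}; "
            "caller contract violated"
        )
    return obs


def f2_mapping_quality(
    candidate: CandidateSNV, tumor_site: SiteEvidence, config: FilterConfig = FilterConfig()
) -> FilterVerdict:
    """Variant-read MAPQs must not be significantly below the phred-30 floor."""
    var_obs = _variant_obs(tumor_site, candidate.alt)
    mapqs = [o.map_quality for o in var_obs]
    if config.quality_test_mode == "one_sample":
        res = signed_rank_vs_constant(mapqs, config.mapq_ref_value, "less")
    else:
        ref_obs = tumor_site.reference_observations()
        if not ref_obs:
            return FilterVerdict("low_mapq", True, detail="untestable: no reference reads")
        res = rank_sum_one_sided(mapqs, [o.map_quality for o in ref_obs], "less")
    return FilterVerdict(
        "low_mapq", res.p_value >= config.mapq_p, statistic=res.statistic, p_value=res.p_value
    )


def f3_base_quality(
    candidate: CandidateSNV, tumor_site: SiteEvidence, config: FilterConfig = FilterConfig()
) -> FilterVerdict:
    """Variant-read base qualities must not be significantly below phred 20."""
    var_obs = _variant_obs(tumor_site, candidate.alt)
    baseqs = [o.base_quality for o in var_obs]
    if config.quality_test_mode == "one_sample":
        res = signed_rank_vs_constant(baseqs, config.baseq_ref_value, "less")
    else:
        ref_obs = tumor_site.reference_observations()
        if not ref_obs:
            return FilterVerdict("low_baseq", True, detail="untestable: no reference reads")
        res = rank_sum_one_sided(baseqs, [o.base_quality for o in ref_obs], "less")
    return FilterVerdict(
        "low_baseq", res.p_value >= config.baseq_p, statistic=res.statistic, p_value=res.p_value
    )


def f4_allele_freq_change(
    candidate: CandidateSNV, config: FilterConfig = FilterConfig()
) -> FilterVerdict:
    """Tumor vs. normal allele counts must differ significantly (Fisher)."""
    t_alt, t_ref = candidate.tumor_alt_count, candidate.tumor_ref_count
    n_alt, n_ref = candidate.normal_alt_count, candidate.normal_ref_count
    if t_alt + t_ref == 0 or n_alt + n_ref == 0:
        return FilterVerdict("af_fisher", False, detail="no data")
    res = fisher_exact_2x2(t_alt, t_ref, n_alt, n_ref)
    return FilterVerdict(
        "af_fisher", res.p_value < config.af_p, statistic=res.statistic, p_value=res.p_value
    )


def f5_gap_region(
    candidate: CandidateSNV, tumor_store: EvidenceStore, config: FilterConfig = FilterConfig()
) -> FilterVerdict:
    """Fewer than ``max_gap_flags`` gap-flagged tumor reads within the flank.

    Gap flags are counted over every tumor read observation at sites within
    +/- ``gap_flank`` bp of the candidate.  The evidence model carries no
    read identifiers, so each observation counts once.
    """
    window = tumor_store.window(candidate.chrom, candidate.pos, config.gap_flank)
    n_gap = sum(1 for site in window for o in site.observations if o.has_gap)
    return FilterVerdict(
        "gap_region",
        n_gap < config.max_gap_flags,
        statistic=float(n_gap),
        detail=f"{n_gap} gap flags within {config.gap_flank} bp",
    )


def f6_read_end_bias(
    candidate: CandidateSNV, tumor_site: SiteEvidence, config: FilterConfig = FilterConfig()
) -> FilterVerdict:
    """Variant reads must not sit significantly closer to read ends than
    reference reads (one-sided rank-sum)."""
    var_obs = _variant_obs(tumor_site, candidate.alt)
    var_ends = [o.end_distance for o in var_obs]
    if config.end_bias_mode == "hard_cutoff":
        frac = sum(1 for e in var_ends if e <= config.end_window) / len(var_ends)
        return FilterVerdict(
            "read_end_bias", frac <= 0.5, statistic=frac,
            detail=f"{frac:.2f} of variant reads within {config.end_window} bp of a read end",
        )
    ref_obs = tumor_site.reference_observations()
    if not ref_obs:
        return FilterVerdict("read_end_bias", True, detail="untestable: no reference reads")
    res = rank_sum_one_sided(var_ends, [o.end_distance for o in ref_obs], "less")
    return FilterVerdict(
        "read_end_bias", res.p_value >= config.end_p,
        statistic=res.statistic, p_value=res.p_value,
        detail=f"window {config.end_window} bp",
    )


def f7_simple_repeat(
    candidate: CandidateSNV, reference: Mapping[str, str], config: FilterConfig = FilterConfig()
) -> FilterVerdict:
    """The site must not lie inside a tandem run of >= 6 unit copies."""
    seq = reference[candidate.chrom]
    copies = max_tandem_copies(
        seq, candidate.pos - 1,
        max_unit=config.repeat_max_unit, flank=config.repeat_scan_flank,
    )
    return FilterVerdict(
        "repeat_region",
        copies < config.max_repeat_events,
        statistic=float(copies),
        detail=f"max tandem run of {copies} copies",
    )


def apply_cascade(
    candidates: Sequence[CandidateSNV],
    tumor_store: EvidenceStore,
    reference: Mapping[str, str],
    config: FilterConfig = FilterConfig(),
) -> list[SomaticCall]:
    """Annotate every candidate with all seven verdicts.

    All criteria are always evaluated; the final PASS requires all seven.
    The result is sorted by (chrom, pos) and independent of input order.
    """
    ordered = sorted(candidates, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    adj = f1_adjacent_distance(ordered, config)
    calls: list[SomaticCall] = []
    for cand in ordered:
        site = tumor_store.get(cand.chrom, cand.pos)
        if site is None:
            raise KeyError(f"no tumor evidence at candidate site {cand.chrom}:{cand.pos}")
        verdicts = {
            "adj_dist": adj[cand.key],
            "low_mapq": f2_mapping_quality(cand, site, config),
            "low_baseq": f3_base_quality(cand, site, config),
            "af_fisher": f4_allele_freq_change(cand, config),
            "gap_region": f5_gap_region(cand, tumor_store, config),
            "read_end_bias": f6_read_end_bias(cand, site, config),
            "repeat_region": f7_simple_repeat(cand, reference, config),
        }
        calls.append(SomaticCall(candidate=cand, verdicts=verdicts))
    return calls
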