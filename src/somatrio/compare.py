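"""Pre- vs. post-treatment call-set comparison and the emergent-mutation report.

Somatic call sets from the two tumor biopsies (each called against the same
matched normal) are partitioned by exact (chrom, pos, ref, alt) key into
shared / pre-only / post-only.  For a private call, the VAF in the other
sample is recomputed from that sample's read evidence at the site rather
than assumed zero.  The emergent-mutation report lists the protein-altering
post-only calls -- the candidates for acquired drug resistance -- with their
baseline and resistance allele frequencies as percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .annotate import AnnotatedVariant
from .caller import compute_vaf, vaf_percent
from .evidence import EvidenceStore
from .filters import SomaticCall

log = logging.getLogger(__name__)

Key = tuple[str, int, str, str]

PROTEIN_ALTERING = frozenset({"nonsynonymous", "stopgain", "splice"})


@dataclass
class CallSet:
    """Passing somatic calls of one sample, keyed by (chrom, pos, ref, alt)."""

    label: str
    calls: dict[Key, SomaticCall] = field(default_factory=dict)

    @classmethod
    def from_calls(
        cls, label: str, calls: Iterable[SomaticCall], include_failed: bool = False
    ) -> "CallSet":
        out: dict[Key, SomaticCall] = {}
        for call in calls:
            if not include_failed and not call.passed:
                continue
            if call.key in out:
                raise ValueError(f"duplicate call key {call.key}")
            out[call.key] = call
        return cls(label=label, calls=out)

    def __len__(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class ComparedSite:
    key: Key
    vaf_pre: float | None
    vaf_post: float | None
    category: str  # shared | pre_only | post_only


@dataclass
class TrioComparison:
    shared: list[ComparedSite] = field(default_factory=list)
    pre_only: list[ComparedSite] = field(default_factory=list)
    post_only: list[ComparedSite] = field(default_factory=list)

    @property
    def totals(self) -> dict[str, int]:
        return {
            "total": len(self.shared) + len(self.pre_only) + len(self.post_only),
            "shared": len(self.shared),
            "pre_only": len(self.pre_only),
            "post_only": len(self.post_only),
        }

    def all_sites(self) -> list[ComparedSite]:
        return sorted(
            [*self.shared, *self.pre_only, *self.post_only], key=lambda s: s.key
        )


def _measured_vaf(
    store: EvidenceStore | None, key: Key, min_base_quality: int = 15
) -> float | None:
    """Recompute a site's VAF from raw evidence; None when evidence is absent."""
    if store is None:
        return None
    chrom, pos, ref, alt = key
    site = store.get(chrom, pos)
    if site is None:
        return None
    counts = site.allele_counts(min_base_quality=min_base_quality)
    alt_n = counts.get(alt, 0)
    ref_n = counts.get(ref, 0)
    total = alt_n + ref_n
    return compute_vaf(alt_n, total) if total else 0.0


def compare_callsets(
    pre: CallSet,
    post: CallSet,
    pre_evidence: EvidenceStore | None = None,
    post_evidence: EvidenceStore | None = None,
) -> TrioComparison:
    """Partition the union of the two call sets by exact key.

    For shared keys the VAF pair comes from the calls themselves; for private
    keys, the VAF in the other tumor is measured from that tumor's evidence
    at the site (it may be 0, but it is measured, not assumed).
    """
    comparison = TrioComparison()
    pre_keys = set(pre.calls)
    post_keys = set(post.calls)
    for key in sorted(pre_keys & post_keys):
        comparison.shared.append(
            ComparedSite(
                key,
                vaf_pre=pre.calls[key].candidate.vaf_tumor,
                vaf_post=post.calls[key].candidate.vaf_tumor,
                category="shared",
            )
        )
    for key in sorted(pre_keys - post_keys):
        vaf_post = _measured_vaf(post_evidence, key)
        if vaf_post is None:
            log.warning("no post-treatment evidence at %s:%s; VAF recorded as missing", key[0], key[1])
        comparison.pre_only.append(
            ComparedSite(key, vaf_pre=pre.calls[key].candidate.vaf_tumor,
                         vaf_post=vaf_post, category="pre_only")
        )
    for key in sorted(post_keys - pre_keys):
        vaf_pre = _measured_vaf(pre_evidence, key)
        if vaf_pre is None:
            log.warning("no pre-treatment evidence at %s:%s; VAF recorded as missing", key[0], key[1])
        comparison.post_only.append(
            ComparedSite(key, vaf_pre=vaf_pre,
                         vaf_post=post.calls[key].candidate.vaf_tumor, category="post_only")
        )
    return comparison


@dataclass(frozen=True)
class EmergentRow:
    gene: str
    genomic_change: str  # "chrN:posR>A"
    aa_change: str | None
    mutation_type: str
    vaf_baseline_pct: float | None
    vaf_resistance_pct: float


@dataclass
class EmergentReport:
    rows: list[EmergentRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": r.gene,
                    "genomic_change": r.genomic_change,
                    "aa_change": r.aa_change,
                    "mutation_type": r.mutation_type,
                    "vaf_baseline_pct": r.vaf_baseline_pct,
                    "vaf_resistance_pct": r.vaf_resistance_pct,
                }
                for r in self.rows
            ]
        )


def emergent_mutations(
    comparison: TrioComparison,
    annotations: Mapping[Key, AnnotatedVariant],
) -> EmergentReport:
    """Protein-altering post-only calls, sorted by gene.

    Post-only sites without an annotation are excluded with a warning;
    synonymous and non-coding post-only sites are excluded by definition.
    """
    rows: list[EmergentRow] = []
    for site in comparison.post_only:
        ann = annotations.get(site.key)
        if ann is None:
            log.warning("post-only variant %s has no annotation; excluded from report", site.key)
            continue
        if ann.effect not in PROTEIN_ALTERING:
            continue
        chrom, pos, ref, alt = site.key
        rows.append(
            EmergentRow(
                gene=ann.gene or ".",
                genomic_change=f"{chrom}:{pos}{ref}>{alt}",
                aa_change=ann.aa_change,
                mutation_type=f"{ann.effect} SNV" if ann.effect != "splice" else "splice",
                vaf_baseline_pct=None if site.vaf_pre is None else vaf_percent(site.vaf_pre),
                vaf_resistance_pct=vaf_percent(site.vaf_post or 0.0),
            )
        )
    rows.sort(key=lambda r: (r.gene, r.genomic_change))
    return EmergentReport(rows=rows)


def scatter_table(comparison: TrioComparison) -> pd.DataFrame:
    """One row per union key: VAF in each tumor plus the category.

    The substrate of the pre- vs. post-treatment allele-frequency scatter.
    """
    rows = []
    for site in comparison.all_sites():
        chrom, pos, ref, alt = site.key
        rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "vaf_pre": site.vaf_pre, "vaf_post": site.vaf_post,
                "category": site.category,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vaf_pre", "vaf_post", "category"])


def scatter_plot(comparison: TrioComparison, path) -> None:
    """Scatter of pre- vs. post-treatment VAFs, colored by category."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = scatter_table(comparison)
    colors = {"shared": "tab:gray", "pre_only": "tab:blue", "post_only": "tab:red"}
    fig, ax = plt.subplots(figsize=(5, 5))
    for cat, sub in table.groupby("category"):
        ax.scatter(sub["vaf_pre"], sub["vaf_post"], s=18, label=cat, color=colors.get(cat))
    ax.set_xlabel("VAF, pre-treatment (sensitive) tumor")
    ax.set_ylabel("VAF, post-treatment (resistant) tumor")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def subtract_germline_events(
    tumor_events: Sequence,
    normal_events: Sequence,
    key: Callable = lambda e: (e.chrom, e.pos, e.ref, e.alt) if hasattr(e, "chrom") else tuple(e),
) -> list:
    """Set difference by key: tumor events not present in the normal.

    Generic over event type (used for the small insertion/deletion path,
    where somatic events are exactly the tumor events absent from the
    matched normal).  Preserves tumor input order.
    """
    normal_keys = {key(e) for e in normal_events}
    return [e for e in tumor_events if key(e) not in normal_keys]
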