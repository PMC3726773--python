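"""End-to-end trio orchestration: call -> filter -> annotate -> compare.

Thin composition of the module-level operations, used by the command-line
``run-all`` subcommand and by the bundled worked example.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .annotate import AnnotatedVariant, TranscriptModel, classify_effect
from .caller import CallerConfig, CandidateSNV, detect_candidates
from .compare import CallSet, EmergentReport, TrioComparison, compare_callsets, emergent_mutations
from .evidence import EvidenceStore
from .filters import FilterConfig, SomaticCall, apply_cascade

log = logging.getLogger(__name__)


@dataclass
class TrioResult:
    candidates: dict[str, list[CandidateSNV]]
    calls: dict[str, list[SomaticCall]]
    callsets: dict[str, CallSet]
    comparison: TrioComparison
    annotations: dict[tuple, AnnotatedVariant]
    emergent: EmergentReport
    counters: dict[str, dict[str, int]] = field(default_factory=dict)


def run_trio(
    reference: Mapping[str, str],
    evidence: pd.DataFrame,
    gene_models: Sequence[TranscriptModel] = (),
    caller_config: CallerConfig = CallerConfig(),
    filter_config: FilterConfig = FilterConfig(),
) -> TrioResult:
    """Run the somatic pipeline on trio evidence (samples normal/pre/post)."""
    normal = EvidenceStore(evidence, "normal")
    stores = {s: EvidenceStore(evidence, s) for s in ("pre", "post")}

    candidates: dict[str, list[CandidateSNV]] = {}
    calls: dict[str, list[SomaticCall]] = {}
    callsets: dict[str, CallSet] = {}
    counters: dict[str, dict[str, int]] = {}
    for sample, store in stores.items():
        cands, skip = detect_candidates(store, normal, caller_config)
        counters[sample] = skip
        log.info("%s: %d candidates (skipped: %s)", sample, len(cands), skip)
        sample_calls = apply_cascade(cands, store, reference, filter_config)
        candidates[sample] = cands
        calls[sample] = sample_calls
        callsets[sample] = CallSet.from_calls(sample, sample_calls)
        log.info("%s: %d calls pass all filters", sample, len(callsets[sample]))

    comparison = compare_callsets(
        callsets["pre"], callsets["post"], stores["pre"], stores["post"]
    )

    annotations: dict[tuple, AnnotatedVariant] = {}
    if gene_models is not None:
        for site in comparison.all_sites():
            chrom, pos, ref, alt = site.key
            annotations[site.key] = classify_effect(
                chrom, pos, ref, alt, gene_models, reference
            )
    emergent = emergent_mutations(comparison, annotations)
    return TrioResult(
        candidates=candidates,
        calls=calls,
        callsets=callsets,
        comparison=comparison,
        annotations=annotations,
        emergent=emergent,
        counters=counters,
    )
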