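"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython; VCF 4.2 written directly (FILTER meta-lines declare the
seven cascade criteria) and read back through pysam; YAML run configs.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .caller import CandidateSNV, vaf_percent
from .filters import CRITERIA, FilterVerdict, SomaticCall
from .compare import CallSet

_FILTER_DESCRIPTIONS = {
    "adj_dist": "Nearest somatic candidate closer than the minimum adjacent distance",
    "low_mapq": "Variant-read mapping quality significantly below 30 (Wilcoxon)",
    "low_baseq": "Variant-read base quality significantly below 20 (Wilcoxon)",
    "af_fisher": "No significant tumor vs normal allele frequency change (Fisher)",
    "gap_region": "Too many gap-flagged reads within the flank region",
    "read_end_bias": "Variant reads significantly enriched near read ends (Wilcoxon)",
    "repeat_region": "Site inside a simple tandem repeat",
}


def write_fasta(reference: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in reference.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _vcf_header(reference: Mapping[str, str] | None, with_filters: bool) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=somatrio",
    ]
    if reference:
        for chrom, seq in reference.items():
            lines.append(f"##contig=<ID={chrom},length={len(seq)}>")
    if with_filters:
        for crit in CRITERIA:
            lines.append(f'##FILTER=<ID={crit},Description="{_FILTER_DESCRIPTIONS[crit]}">')
    lines += [
        '##INFO=<ID=TUMOR_AD,Number=2,Type=Integer,Description="Tumor ref,alt read counts">',
        '##INFO=<ID=NORMAL_AD,Number=2,Type=Integer,Description="Normal ref,alt read counts">',
        '##INFO=<ID=VAF_T,Number=1,Type=Float,Description="Tumor variant allele frequency (percent)">',
        '##INFO=<ID=VAF_N,Number=1,Type=Float,Description="Normal variant allele frequency (percent)">',
        '##INFO=<ID=FISHER_P,Number=1,Type=Float,Description="Fisher exact p, tumor vs normal allele counts">',
        '##INFO=<ID=CRIT_P,Number=.,Type=String,Description="Per-criterion statistic/p as crit:stat:p">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    return "\n".join(lines) + "\n"


def _info_for(cand: CandidateSNV, call: SomaticCall | None = None) -> str:
    fields = [
        f"TUMOR_AD={cand.tumor_ref_count},{cand.tumor_alt_count}",
        f"NORMAL_AD={cand.normal_ref_count},{cand.normal_alt_count}",
        f"VAF_T={vaf_percent(cand.vaf_tumor)}",
        f"VAF_N={vaf_percent(cand.vaf_normal)}",
        f"FISHER_P={cand.fisher_p:.4g}",
    ]
    if call is not None:
        parts = []
        for crit in CRITERIA:
            v = call.verdicts.get(crit)
            if v is None:
                continue
            stat = "." if v.statistic is None else f"{v.statistic:.4g}"
            p = "." if v.p_value is None else f"{v.p_value:.4g}"
            parts.append(f"{crit}:{stat}:{p}")
        fields.append("CRIT_P=" + ",".join(parts))
    return ";".join(fields)


def write_candidates_vcf(
    path, candidates: Sequence[CandidateSNV], reference: Mapping[str, str] | None = None
) -> None:
    """Unfiltered candidates; FILTER is '.' pending the cascade."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_vcf_header(reference, with_filters=False))
        for cand in sorted(candidates, key=lambda c: (c.chrom, c.pos)):
            fh.write(
                f"{cand.chrom}\t{cand.pos}\t.\t{cand.ref}\t{cand.alt}\t.\t.\t{_info_for(cand)}\n"
            )


def write_calls_vcf(
    path, calls: Sequence[SomaticCall], reference: Mapping[str, str] | None = None
) -> None:
    """Filtered calls; FILTER lists the failed criterion ids or PASS."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_vcf_header(reference, with_filters=True))
        for call in sorted(calls, key=lambda c: (c.key[0], c.key[1])):
            cand = call.candidate
            fh.write(
                f"{cand.chrom}\t{cand.pos}\t.\t{cand.ref}\t{cand.alt}\t.\t"
                f"{call.filter_field}\t{_info_for(cand, call)}\n"
            )


def read_callset_vcf(path, label: str, include_failed: bool = False) -> CallSet:
    """Read a filtered VCF back into a CallSet.

    Verdicts are reconstructed from the FILTER column (criteria listed there
    failed; all others passed); per-criterion statistics travel in CRIT_P.
    """
    calls: list[SomaticCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            t_ref, t_alt = info["TUMOR_AD"]
            n_ref, n_alt = info["NORMAL_AD"]
            cand = CandidateSNV(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                tumor_ref_count=t_ref, tumor_alt_count=t_alt,
                normal_ref_count=n_ref, normal_alt_count=n_alt,
                vaf_tumor=round(float(info["VAF_T"]) / 100.0, 6),
                vaf_normal=round(float(info["VAF_N"]) / 100.0, 6),
                fisher_p=float(info["FISHER_P"]),
            )
            failed = {f for f in rec.filter.keys() if f != "PASS"}
            verdicts = {
                crit: FilterVerdict(crit, crit not in failed) for crit in CRITERIA
            }
            calls.append(SomaticCall(candidate=cand, verdicts=verdicts))
    return CallSet.from_calls(label, calls, include_failed=include_failed)


def read_candidates_vcf(path) -> list[CandidateSNV]:
    """Read an unfiltered candidate VCF back into CandidateSNV records."""
    out: list[CandidateSNV] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            t_ref, t_alt = info["TUMOR_AD"]
            n_ref, n_alt = info["NORMAL_AD"]
            out.append(
                CandidateSNV(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                    tumor_ref_count=t_ref, tumor_alt_count=t_alt,
                    normal_ref_count=n_ref, normal_alt_count=n_alt,
                    vaf_tumor=round(float(info["VAF_T"]) / 100.0, 6),
                    vaf_normal=round(float(info["VAF_N"]) / 100.0, 6),
                    fisher_p=float(info["FISHER_P"]),
                )
            )
    return out


def read_segments_bed(path):
    """Read a segments BED (chrom, start, end, mean_log2, state) back."""
    from .cnv import CNASegment

    segments = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, mean_log2, state = line.rstrip("\n").split("\t")
            segments.append(
                CNASegment(chrom, int(start), int(end), float(mean_log2), 0, state)
            )
    return segments


def load_config_yaml(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping of key: value pairs")
    return data
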