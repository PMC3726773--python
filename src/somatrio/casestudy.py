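"""Bundled worked example: an acquired-resistance trio fixture.

This module programmatically constructs a deterministic micro-genome fixture
of a drug-resistance scenario: 46 somatic SNVs across a matched trio, of
which 22 are shared between the pre- and post-treatment tumors, 12 are
private to the pre-treatment tumor, and 12 emerge in the resistant tumor.
Nine of the emergent mutations are protein-altering -- eight nonsynonymous
and one stopgain -- in the genes ACAP2, CARD10 (two sites), KIAA0556, PAQR7,
PPP1R39, SAFB2, STARD9 and ZFYVE9, with resistance VAFs spanning 5.26-46.81%
and baseline VAFs of 0.

Genome-scale coordinates are re-based into a micro-genome: each gene receives
a short CDS whose codon context realizes the reported amino-acid change at
the reported substitution, on a strand chosen so the genomic ref>alt matches
(``position_map`` records original -> micro coordinates).  Read counts behind
each printed VAF are the smallest (alt, total) integer pair that rounds to
the printed percentage while remaining detectable against a 70x clean normal
(Fisher's exact p < 0.05).  All evidence attributes are benign by
construction so every fixture site survives the filter cascade; everything
is deterministic and rebuilt at import time (no data files ship).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotate import TranscriptModel, load_gene_model
from .evidence import EVIDENCE_COLUMNS
from .repeats import overlaps_repeat
from .stats import fisher_exact_2x2

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class CaseVariant:
    gene: str
    orig_chrom: str
    orig_pos: int
    ref: str
    alt: str
    ref_aa: str  # one-letter
    alt_aa: str  # one-letter; '*' = stop gained
    effect: str
    vaf_baseline_pct: float
    vaf_resistance_pct: float


#: the nine emergent protein-altering mutations of the case
CASE_VARIANTS: tuple[CaseVariant, ...] = (
    CaseVariant("ACAP2", "chr3", 195041480, "C", "T", "M", "I", "nonsynonymous", 0.0, 11.36),
    CaseVariant("CARD10", "chr22", 37891880, "C", "G", "E", "D", "nonsynonymous", 0.0, 6.6),
    CaseVariant("CARD10", "chr22", 37891912, "C", "G", "D", "H", "nonsynonymous", 0.0, 6.6),
    CaseVariant("KIAA0556", "chr16", 27788348, "G", "T", "G", "C", "nonsynonymous", 0.0, 5.26),
    CaseVariant("PAQR7", "chr1", 26190151, "G", "T", "F", "L", "nonsynonymous", 0.0, 28.37),
    CaseVariant("PPP1R39", "chr5", 145435750, "G", "A", "R", "Q", "nonsynonymous", 0.0, 8.5),
    CaseVariant("SAFB2", "chr19", 5587776, "C", "T", "G", "S", "nonsynonymous", 0.0, 15.79),
    CaseVariant("STARD9", "chr15", 42984506, "G", "A", "G", "E", "nonsynonymous", 0.0, 46.81),
    CaseVariant("ZFYVE9", "chr1", 52704185, "G", "T", "E", "*", "stopgain", 0.0, 9.89),
)

VENN_STRUCTURE = {"total": 46, "shared": 22, "pre_only": 12, "post_only": 12}

_CODONS = ["".join(c) for c in itertools.product("TCAG", repeat=3)]
_FILLER_CODONS = ("GCT", "GAT", "CTG", "AAC", "GTC", "TGG", "CAT", "AGC")
_DEPTHS = {"normal": 70, "pre": 66, "post": 68}
_BASEQ_CYCLE = (31, 33, 35, 37, 34, 32, 36, 38)


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _codon_solutions(ref_aa: str, alt_aa: str, g_ref: str, g_alt: str, strand: str):
    """All (ref_codon, within) realizing aa change via the genomic ref>alt."""
    coding_ref = g_ref if strand == "+" else g_ref.translate(_COMP)
    coding_alt = g_alt if strand == "+" else g_alt.translate(_COMP)
    out = []
    for codon in _CODONS:
        if _translate(codon) != ref_aa:
            continue
        for within in range(3):
            if codon[within] != coding_ref:
                continue
            alt_codon = codon[:within] + coding_alt + codon[within + 1 :]
            if _translate(alt_codon) == alt_aa:
                out.append((codon, within))
    return out


def _layout_gene(variants: list[CaseVariant]):
    """Choose strand, coding offsets and codons realizing all of a gene's
    variants at the original inter-variant genomic spacings."""
    variants = sorted(variants, key=lambda v: v.orig_pos)
    deltas = [v.orig_pos - variants[0].orig_pos for v in variants]
    for strand in ("+", "-"):
        solution_sets = [
            _codon_solutions(v.ref_aa, v.alt_aa, v.ref, v.alt, strand) for v in variants
        ]
        if any(not s for s in solution_sets):
            continue
        for combo in itertools.product(*solution_sets):
            for c0 in range(3, 90):
                if strand == "+":
                    offsets = [c0 + d for d in deltas]
                else:
                    offsets = [c0 + deltas[-1] - d for d in deltas]
                if any(c < 3 for c in offsets):
                    continue
                if any(c % 3 != combo[i][1] for i, c in enumerate(offsets)):
                    continue
                if len({c // 3 for c in offsets}) != len(offsets):
                    continue
                return strand, variants, offsets, [combo[i][0] for i in range(len(variants))]
    raise RuntimeError(f"no codon layout found for gene {variants[0].gene}")


def _build_cds(offsets: list[int], codons: list[str]) -> str:
    n_codons = max(c // 3 for c in offsets) + 4
    seq = ["ATG"] + [
        _FILLER_CODONS[i % len(_FILLER_CODONS)] for i in range(n_codons - 1)
    ]
    for off, codon in zip(offsets, codons):
        seq[off // 3] = codon
    return "".join(seq)


def _background(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


def _smallest_counts(target_pct: float, normal_depth: int = 70, max_total: int = 600) -> tuple[int, int]:
    """Smallest (alt, total) with round(100*alt/total, 2) == printed percent
    and Fisher p (alt,total-alt vs 0,normal_depth) < 0.05."""
    for total in range(10, max_total + 1):
        for alt in range(2, total):
            pct = round(100.0 * alt / total, 2)
            if abs(pct - round(target_pct, 2)) > 1e-9:
                continue
            p = fisher_exact_2x2(alt, total - alt, 0, normal_depth).p_value
            if p < 0.05:
                return alt, total
            break  # only one alt per total can match an exact rounding
    raise RuntimeError(f"no detectable count pair reproduces {target_pct}%")


@dataclass
class CaseStudy:
    reference: dict[str, str]
    gtf: str
    models: list[TranscriptModel]
    position_map: dict[tuple[str, int], tuple[str, int]]  # original -> micro
    case_keys: list[tuple[str, int, str, str]]  # micro keys of the 9 case variants
    evidence: pd.DataFrame  # all three samples
    truth_categories: dict[tuple[str, int, str, str], str] = field(default_factory=dict)


def _site_rows(chrom, pos, ref, sample, alt, n_alt, depth, rows):
    for i in range(depth):
        is_alt = i < n_alt
        base = alt if is_alt else ref
        end = 44 - (3 * i) % 40 if is_alt else (i * 7) % 45 + 1
        rows.append(
            (
                chrom, pos, ref, sample, base,
                _BASEQ_CYCLE[i % len(_BASEQ_CYCLE)], 60, end, 0,
                "+" if i % 2 == 0 else "-",
            )
        )


def build_case_study() -> CaseStudy:
    """Construct the micro-genome, gene model and trio evidence fixture."""
    rng = np.random.default_rng(973)

    # group case variants by gene, genes by original chromosome
    by_gene: dict[str, list[CaseVariant]] = {}
    for v in CASE_VARIANTS:
        by_gene.setdefault(v.gene, []).append(v)
    by_chrom: dict[str, list[str]] = {}
    for gene, vs in by_gene.items():
        by_chrom.setdefault(vs[0].orig_chrom, []).append(gene)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: min(v.orig_pos for v in by_gene[g]))

    pad = 300
    reference: dict[str, str] = {}
    gtf_lines: list[str] = []
    position_map: dict[tuple[str, int], tuple[str, int]] = {}
    case_keys: list[tuple[str, int, str, str]] = []
    gene_spans: dict[str, list[tuple[int, int]]] = {}

    def chrom_sort_key(c: str):
        return int(c.replace("chr", ""))

    for chrom in sorted(by_chrom, key=chrom_sort_key):
        seq = _background(rng, pad)
        gene_spans[chrom] = []
        for gene in by_chrom[chrom]:
            strand, ordered, offsets, codons = _layout_gene(by_gene[gene])
            cds = _build_cds(offsets, codons)
            genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
            start = len(seq) + 1
            seq += genomic
            end = len(seq)
            seq += _background(rng, pad)
            gene_spans[chrom].append((start, end))
            gtf_lines.append(
                f"{chrom}\tsomatrio\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
                f'gene_name "{gene}"; transcript_id "{gene}.1";'
            )
            for v, off in zip(ordered, offsets):
                pos = start + off if strand == "+" else end - off
                position_map[(v.orig_chrom, v.orig_pos)] = (chrom, pos)
        reference[chrom] = seq

    # keys in CASE_VARIANTS order
    for v in CASE_VARIANTS:
        chrom, pos = position_map[(v.orig_chrom, v.orig_pos)]
        case_keys.append((chrom, pos, v.ref, v.alt))

    # verify the construction against the reference and repeat context
    for v in CASE_VARIANTS:
        chrom, pos = position_map[(v.orig_chrom, v.orig_pos)]
        if reference[chrom][pos - 1] != v.ref:
            raise RuntimeError(f"fixture construction error at {chrom}:{pos}")
        if overlaps_repeat(reference[chrom], pos - 1):
            raise RuntimeError(f"fixture variant at {chrom}:{pos} sits in a repeat")

    gtf = "\n".join(gtf_lines) + "\n"
    models = load_gene_model(gtf)

    # 37 additional somatic sites: 22 shared, 12 pre-only, 3 intergenic post-only
    chroms = sorted(reference, key=chrom_sort_key)
    occupied: dict[str, list[int]] = {c: [] for c in chroms}
    for chrom, pos, _, _ in case_keys:
        occupied[chrom].append(pos)

    def place_site() -> tuple[str, int]:
        for _ in range(10_000):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            seq = reference[chrom]
            pos = int(rng.integers(30, len(seq) - 30))
            if any(abs(pos - q) < 50 for q in occupied[chrom]):
                continue
            if any(s - 10 <= pos <= e + 10 for s, e in gene_spans[chrom]):
                continue
            if overlaps_repeat(seq, pos - 1):
                continue
            occupied[chrom].append(pos)
            return chrom, pos
        raise RuntimeError("could not place fixture site")

    extra_categories = ["shared"] * 22 + ["pre_only"] * 12 + ["post_only"] * 3
    sites = []  # (chrom,pos,ref,alt,vaf_pre,vaf_post,category)
    for category in extra_categories:
        chrom, pos = place_site()
        ref = reference[chrom][pos - 1]
        alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
        vaf_pre = float(rng.uniform(0.12, 0.47)) if category in ("shared", "pre_only") else 0.0
        vaf_post = float(rng.uniform(0.12, 0.47)) if category in ("shared", "post_only") else 0.0
        sites.append((chrom, pos, ref, alt, vaf_pre, vaf_post, category))
    for (chrom, pos, ref, alt), v in zip(case_keys, CASE_VARIANTS):
        sites.append((chrom, pos, ref, alt, 0.0, v.vaf_resistance_pct / 100.0, "post_only"))
    sites.sort(key=lambda s: (chrom_sort_key(s[0]), s[1]))

    # deterministic evidence for the trio at every site
    rows: list[tuple] = []
    truth_categories: dict[tuple[str, int, str, str], str] = {}
    case_key_set = set(case_keys)
    for chrom, pos, ref, alt, vaf_pre, vaf_post, category in sites:
        key = (chrom, pos, ref, alt)
        truth_categories[key] = category
        _site_rows(chrom, pos, ref, "normal", alt, 0, _DEPTHS["normal"], rows)
        for sample, vaf in (("pre", vaf_pre), ("post", vaf_post)):
            if vaf <= 0:
                _site_rows(chrom, pos, ref, sample, alt, 0, _DEPTHS[sample], rows)
            elif key in case_key_set and sample == "post":
                n_alt, total = _smallest_counts(vaf * 100.0)
                _site_rows(chrom, pos, ref, sample, alt, n_alt, total, rows)
            else:
                depth = _DEPTHS[sample]
                n_alt = max(5, round(vaf * depth))
                _site_rows(chrom, pos, ref, sample, alt, n_alt, depth, rows)

    evidence = pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)
    evidence["gap"] = evidence["gap"].astype(bool)
    return CaseStudy(
        reference=reference,
        gtf=gtf,
        models=models,
        position_map=position_map,
        case_keys=case_keys,
        evidence=evidence,
        truth_categories=truth_categories,
    )
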