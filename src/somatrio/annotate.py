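"""Codon-level SNV effect classification against a minimal CDS gene model,
plus mutation-spectrum and per-region tabulation.

The gene model is a GTF subset: CDS features (attributes ``gene_name`` and
``transcript_id``), optionally accompanied by ``transcript`` features whose
span distinguishes UTR from intergenic context.  Effects are classified with
the standard nuclear codon table, strand-aware; positions within 2 bp of a
CDS/intron boundary on the intron side are splice.

The mutation spectrum uses the six strand-collapsed substitution classes
(pyrimidine-first labels); because axis conventions differ between reports,
the purine-first label of each class is carried alongside.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import gffutils
import pandas as pd
from Bio.Seq import Seq

SPLICE_WINDOW = 2

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "",  # stops render as the empty string: "Glu->" means stopgain
}

#: strand-collapsed substitution classes, pyrimidine-first representation
SPECTRUM_CLASSES = (
    "C:G>T:A", "C:G>A:T", "C:G>G:C", "T:A>C:G", "T:A>G:C", "T:A>A:T",
)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass
class TranscriptModel:
    """One transcript's CDS intervals, frame anchored at the annotated start."""

    gene: str
    transcript_id: str
    chrom: str
    strand: str
    cds: list[tuple[int, int]]  # 1-based inclusive, sorted by genomic coordinate
    transcript_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.cds, self.cds[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS intervals in {self.transcript_id}")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length of {self.transcript_id} ({self.cds_length}) not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds[0][0], self.cds[-1][1]

    def cds_sequence(self, reference: Mapping[str, str]) -> str:
        seq = "".join(reference[self.chrom][s - 1 : e] for s, e in self.cds)
        return _revcomp(seq) if self.strand == "-" else seq

    def cds_offset(self, pos: int) -> int | None:
        """0-based coding offset of a genomic position, or None outside CDS."""
        if self.strand == "+":
            acc = 0
            for s, e in self.cds:
                if s <= pos <= e:
                    return acc + (pos - s)
                acc += e - s + 1
            return None
        acc = 0
        for s, e in reversed(self.cds):
            if s <= pos <= e:
                return acc + (e - pos)
            acc += e - s + 1
        return None

    def splice_distance(self, pos: int) -> int | None:
        """Distance to the nearest intron-side CDS boundary, if pos is intronic."""
        for (s1, e1), (s2, e2) in zip(self.cds, self.cds[1:]):
            if e1 < pos < s2:
                return min(pos - e1, s2 - pos)
        return None


@dataclass(frozen=True)
class AnnotatedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None
    effect: str  # synonymous|nonsynonymous|stopgain|stoploss|splice|intronic|utr|intergenic
    aa_change: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def load_gene_model(gtf: str) -> list[TranscriptModel]:
    """Parse a GTF subset (CDS and optional transcript features).

    ``gtf`` is a path or raw GTF text.
    """
    from_file = "\n" not in gtf and os.path.exists(gtf)
    db = gffutils.create_db(
        gtf,
        dbfn=":memory:",
        from_string=not from_file,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    cds_by_tx: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    spans: dict[str, tuple[int, int]] = {}
    for feat in db.all_features():
        tx = feat.attributes.get("transcript_id", [feat.id])[0]
        gene = feat.attributes.get("gene_name", feat.attributes.get("gene_id", [tx]))[0]
        if feat.featuretype == "CDS":
            cds_by_tx.setdefault(tx, []).append((feat.start, feat.end))
            meta[tx] = (gene, feat.seqid, feat.strand)
        elif feat.featuretype == "transcript":
            spans[tx] = (feat.start, feat.end)
    models = []
    for tx, intervals in cds_by_tx.items():
        gene, chrom, strand = meta[tx]
        models.append(
            TranscriptModel(
                gene=gene, transcript_id=tx, chrom=chrom, strand=strand,
                cds=intervals, transcript_span=spans.get(tx),
            )
        )
    return models


def classify_effect(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    models: Sequence[TranscriptModel],
    reference: Mapping[str, str],
) -> AnnotatedVariant:
    """Classify one SNV against the gene model.

    The variant's stated reference base must match the reference sequence.
    When several transcripts overlap the site, the most severe consequence
    wins (coding > splice > utr > intronic).
    """
    if reference[chrom][pos - 1] != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: expected {reference[chrom][pos - 1]}, got {ref}"
        )
    if alt == ref:
        raise ValueError("alt equals ref")

    best: AnnotatedVariant | None = None
    severity = {"intergenic": 0, "intronic": 1, "utr": 2, "splice": 3,
                "synonymous": 4, "nonsynonymous": 5, "stoploss": 6, "stopgain": 7}

    for model in models:
        if model.chrom != chrom:
            continue
        offset = model.cds_offset(pos)
        ann: AnnotatedVariant | None = None
        if offset is not None:
            cds_seq = model.cds_sequence(reference)
            codon_idx = offset // 3
            within = offset % 3
            ref_codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
            coding_ref = ref if model.strand == "+" else _complement(ref)
            coding_alt = alt if model.strand == "+" else _complement(alt)
            if ref_codon[within] != coding_ref:
                raise ValueError(
                    f"gene model inconsistent with reference at {chrom}:{pos} "
                    f"({model.transcript_id})"
                )
            alt_codon = ref_codon[:within] + coding_alt + ref_codon[within + 1 :]
            ref_aa = str(Seq(ref_codon).translate())
            alt_aa = str(Seq(alt_codon).translate())
            if ref_aa == alt_aa:
                effect = "synonymous"
            elif alt_aa == "*":
                effect = "stopgain"
            elif ref_aa == "*":
                effect = "stoploss"
            else:
                effect = "nonsynonymous"
            ann = AnnotatedVariant(
                chrom, pos, ref, alt, model.gene, effect,
                aa_change=f"{_AA3[ref_aa]}->{_AA3[alt_aa]}",
            )
        else:
            lo, hi = model.span
            d = model.splice_distance(pos)
            if d is not None:
                effect = "splice" if d <= SPLICE_WINDOW else "intronic"
                ann = AnnotatedVariant(chrom, pos, ref, alt, model.gene, effect)
            elif model.transcript_span and model.transcript_span[0] <= pos <= model.transcript_span[1] and not (lo <= pos <= hi):
                ann = AnnotatedVariant(chrom, pos, ref, alt, model.gene, "utr")
        if ann and (best is None or severity[ann.effect] > severity[best.effect]):
            best = ann
    if best is None:
        return AnnotatedVariant(chrom, pos, ref, alt, None, "intergenic")
    return best


def spectrum_class(ref: str, alt: str) -> str:
    """Strand-collapsed substitution class (pyrimidine-first label)."""
    if ref == alt:
        raise ValueError("ref equals alt")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if ref in "AG":  # collapse to the pyrimidine strand
        ref, alt = _complement(ref), _complement(alt)
    return f"{ref}:{_complement(ref)}>{alt}:{_complement(alt)}"


def purine_first_label(pyrimidine_label: str) -> str:
    """The same class written purine-first (e.g. 'C:G>A:T' <-> 'G:C>T:A')."""
    left, right = pyrimidine_label.split(">")
    p, q = left.split(":")
    a, b = right.split(":")
    return f"{q}:{p}>{b}:{a}"


def spectrum_counts(variants: Sequence[tuple[str, int, str, str]]) -> dict[str, int]:
    """Counts over the six strand-collapsed classes; sums to the input size."""
    counts = {cls: 0 for cls in SPECTRUM_CLASSES}
    for _, _, ref, alt in variants:
        counts[spectrum_class(ref, alt)] += 1
    return counts


def spectrum_table(variants: Sequence[tuple[str, int, str, str]]) -> pd.DataFrame:
    """Spectrum with both label conventions side by side."""
    counts = spectrum_counts(variants)
    return pd.DataFrame(
        {
            "class_pyrimidine_first": list(SPECTRUM_CLASSES),
            "class_purine_first": [purine_first_label(c) for c in SPECTRUM_CLASSES],
            "count": [counts[c] for c in SPECTRUM_CLASSES],
        }
    )


REGION_CATEGORIES = (
    "synonymous", "nonsynonymous", "stopgain", "stoploss",
    "splice", "intronic", "utr", "intergenic",
)


def region_summary(annotated: Sequence[AnnotatedVariant]) -> dict[str, int]:
    """Per-region variant counts (CDS split by effect); sums to input size."""
    counts = {cat: 0 for cat in REGION_CATEGORIES}
    for v in annotated:
        counts[v.effect] += 1
    return counts
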