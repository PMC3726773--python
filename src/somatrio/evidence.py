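"""Per-read / per-site sequencing evidence model and its readers and writers.

The whole pipeline consumes a pileup-like substrate: at each reference site,
for each sample, an ordered list of read observations carrying the per-read
attributes the downstream filters interrogate (base, phred base quality,
phred mapping quality, distance to the nearest read end, a gap flag marking
reads whose alignment contains an insertion or deletion, and strand).

Coordinates are 1-based inclusive everywhere internally and in the evidence
TSV; BED output elsewhere is 0-based half-open and VCF 1-based, matching
each format's convention.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGTN")
VALID_REF = frozenset("ACGT")

#: column order of the evidence TSV (one row per read observation)
EVIDENCE_COLUMNS = [
    "chrom", "pos", "ref", "sample", "base",
    "baseq", "mapq", "end_dist", "gap", "strand",
]


class EvidenceParseError(ValueError):
    """Malformed evidence file; message names the offending line."""


@dataclass(frozen=True)
class ReadObservation:
    """One read's contribution to one site."""

    base: str
    base_quality: int
    map_quality: int
    end_distance: int
    has_gap: bool
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.base not in VALID_BASES:
            raise ValueError(f"invalid base {self.base!r}")
        if self.base_quality < 0 or self.map_quality < 0 or self.end_distance < 0:
            raise ValueError("qualities and end distance must be non-negative")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class SiteEvidence:
    """All read observations for one sample at one reference site."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    sample_id: str
    observations: list[ReadObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ref_base not in VALID_REF:
            raise ValueError(f"invalid reference base {self.ref_base!r}")
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")

    @property
    def depth(self) -> int:
        return len(self.observations)

    def allele_counts(self, min_base_quality: int = 0) -> dict[str, int]:
        """Counts per base among observations passing the quality floor.

        N bases contribute to depth but never to allele counts.
        """
        counts: dict[str, int] = {}
        for obs in self.observations:
            if obs.base == "N" or obs.base_quality < min_base_quality:
                continue
            counts[obs.base] = counts.get(obs.base, 0) + 1
        return counts

    def variant_observations(self, alt: str) -> list[ReadObservation]:
        return [o for o in self.observations if o.base == alt]

    def reference_observations(self) -> list[ReadObservation]:
        return [o for o in self.observations if o.base == self.ref_base]


class EvidenceStore:
    """Indexed, single-sample collection of site evidence.

    Backed by column arrays of the evidence table; ``SiteEvidence`` objects
    are materialized on demand, so iterating candidate sites stays cheap even
    when the table holds millions of read observations.
    """

    def __init__(self, frame: pd.DataFrame, sample_id: str):
        sub = frame[frame["sample"] == sample_id]
        if sub.empty and not frame.empty:
            raise KeyError(f"sample {sample_id!r} not present in evidence")
        sub = sub.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.sample_id = sample_id
        self.frame = sub
        self._index: dict[str, tuple[list[int], list[int], list[int]]] = {}
        self._build_index()

    def _build_index(self) -> None:
        if self.frame.empty:
            return
        chroms = self.frame["chrom"].to_numpy()
        pos = self.frame["pos"].to_numpy()
        for chrom in pd.unique(chroms):
            mask = chroms == chrom
            idx = np.flatnonzero(mask)
            p = pos[idx]
            uniq, starts = np.unique(p, return_index=True)
            ends = np.append(starts[1:], p.size)
            base = idx[0]
            self._index[str(chrom)] = (
                uniq.tolist(),
                (starts + base).tolist(),
                (ends + base).tolist(),
            )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sample_id: str) -> "EvidenceStore":
        return cls(frame, sample_id)

    def sites(self) -> Iterator[tuple[str, int]]:
        for chrom, (positions, _, _) in self._index.items():
            for p in positions:
                yield chrom, int(p)

    def _materialize(self, chrom: str, lo: int, hi: int, pos: int) -> SiteEvidence:
        rows = self.frame.iloc[lo:hi]
        obs = [
            ReadObservation(
                base=r.base,
                base_quality=int(r.baseq),
                map_quality=int(r.mapq),
                end_distance=int(r.end_dist),
                has_gap=bool(r.gap),
                strand=r.strand,
            )
            for r in rows.itertuples(index=False)
        ]
        return SiteEvidence(
            chrom=chrom,
            pos=pos,
            ref_base=str(rows["ref"].iloc[0]),
            sample_id=self.sample_id,
            observations=obs,
        )

    def get(self, chrom: str, pos: int) -> SiteEvidence | None:
        entry = self._index.get(chrom)
        if entry is None:
            return None
        positions, starts, ends = entry
        i = bisect.bisect_left(positions, pos)
        if i == len(positions) or positions[i] != pos:
            return None
        return self._materialize(chrom, starts[i], ends[i], pos)

    def window(self, chrom: str, center: int, flank: int) -> list[SiteEvidence]:
        """All sites with |pos - center| <= flank, sorted by position."""
        entry = self._index.get(chrom)
        if entry is None:
            return []
        positions, starts, ends = entry
        lo = bisect.bisect_left(positions, center - flank)
        hi = bisect.bisect_right(positions, center + flank)
        return [
            self._materialize(chrom, starts[i], ends[i], int(positions[i]))
            for i in range(lo, hi)
        ]


def fetch_window(store: EvidenceStore, chrom: str, center: int, flank: int) -> list[SiteEvidence]:
    """Functional alias for :meth:`EvidenceStore.window`."""
    return store.window(chrom, center, flank)


def sites_to_frame(sites: Iterable[SiteEvidence]) -> pd.DataFrame:
    rows = []
    for site in sites:
        for obs in site.observations:
            rows.append(
                (
                    site.chrom, site.pos, site.ref_base, site.sample_id,
                    obs.base, obs.base_quality, obs.map_quality,
                    obs.end_distance, int(obs.has_gap), obs.strand,
                )
            )
    return pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)


def write_evidence(path, frame_or_sites) -> None:
    """Write an evidence table as a '#'-headed, tab-separated file.

    Accepts either a DataFrame in evidence column order or an iterable of
    ``SiteEvidence``.  Compression is inferred from the file extension
    (``.gz`` transparently supported).
    """
    if isinstance(frame_or_sites, pd.DataFrame):
        frame = frame_or_sites[EVIDENCE_COLUMNS].copy()
    else:
        frame = sites_to_frame(frame_or_sites)
    frame = frame.copy()
    frame["gap"] = frame["gap"].astype(int)
    header = "#" + "\t".join(EVIDENCE_COLUMNS) + "\n"
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt", encoding="utf-8") as fh:
        fh.write(header)
        frame.to_csv(fh, sep="\t", header=False, index=False)


def read_evidence(path) -> pd.DataFrame:
    """Read an evidence TSV back into a validated DataFrame.

    Raises :class:`EvidenceParseError` naming the 1-based file line of the
    first malformed row (positions must be 1-based, bases A/C/G/T/N, strand
    + or -).
    """
    try:
        frame = pd.read_csv(
            path, sep="\t", compression="infer", dtype={"chrom": str, "sample": str}
        )
    except pd.errors.ParserError as exc:
        raise EvidenceParseError(f"malformed evidence file {path}: {exc}") from exc
    if frame.columns[0].startswith("#"):
        frame = frame.rename(columns={frame.columns[0]: frame.columns[0].lstrip("#")})
    missing = [c for c in EVIDENCE_COLUMNS if c not in frame.columns]
    if missing:
        raise EvidenceParseError(f"{path}: missing columns {missing}")
    frame = frame[EVIDENCE_COLUMNS]

    def _bad(mask: pd.Series, why: str) -> None:
        if mask.any():
            line = int(frame.index[mask][0]) + 2  # +1 header, +1 one-based
            raise EvidenceParseError(f"{path}: line {line}: {why}")

    _bad(frame["pos"] < 1, "pos must be >= 1 (1-based convention)")
    _bad(~frame["ref"].isin(list(VALID_REF)), "invalid reference base")
    _bad(~frame["base"].isin(list(VALID_BASES)), "invalid read base")
    _bad((frame["baseq"] < 0) | (frame["mapq"] < 0), "negative quality")
    _bad(frame["end_dist"] < 0, "negative end distance")
    _bad(~frame["strand"].isin(["+", "-"]), "invalid strand")
    frame["gap"] = frame["gap"].astype(bool)
    return frame


@dataclass
class IngestResult:
    frame: pd.DataFrame
    n_unmapped: int = 0
    n_duplicate: int = 0


def ingest_alignments(
    alignments: Iterable, reference: Mapping[str, str], sample_id: str
) -> IngestResult:
    """Convert SAM-style alignment records into per-site evidence rows.

    ``alignments`` is an iterable of :class:`pysam.AlignedSegment` (e.g. a
    ``pysam.AlignmentFile``).  Unmapped records are skipped (counted);
    duplicate-flagged records are skipped (counted); records without base
    qualities raise.  ``end_distance`` is the distance, in aligned read
    bases, to the nearest read end -- soft-clipped bases do not count.
    ``has_gap`` is true iff the alignment contains any insertion or deletion
    operation.
    """
    rows = []
    n_unmapped = 0
    n_duplicate = 0
    for read in alignments:
        if read.is_unmapped:
            n_unmapped += 1
            continue
        if read.is_duplicate:
            n_duplicate += 1
            continue
        quals = read.query_qualities
        if quals is None:
            raise ValueError(f"read {read.query_name!r} has no base qualities")
        seq = read.query_sequence
        has_gap = any(op in (1, 2) for op, _ in (read.cigartuples or []))
        strand = "-" if read.is_reverse else "+"
        pairs = read.get_aligned_pairs(matches_only=True)
        n_aligned = len(pairs)
        chrom = read.reference_name
        ref_seq = reference[chrom]
        for i, (qpos, rpos) in enumerate(pairs):
            ref_base = ref_seq[rpos].upper()
            if ref_base not in VALID_REF:
                continue
            rows.append(
                (
                    chrom, rpos + 1, ref_base, sample_id,
                    seq[qpos].upper(), int(quals[qpos]), int(read.mapping_quality),
                    min(i, n_aligned - 1 - i), int(has_gap), strand,
                )
            )
    frame = pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)
    if not frame.empty:
        frame = frame.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    frame["gap"] = frame["gap"].astype(bool)
    return IngestResult(frame=frame, n_unmapped=n_unmapped, n_duplicate=n_duplicate)
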