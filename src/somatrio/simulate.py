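"""Synthetic tumor-trio simulator with a machine-readable truth set.

Generates a reference micro-genome and per-site read evidence for a matched
trio -- normal, pre-treatment tumor, post-treatment tumor -- with known
germline heterozygous SNPs (shared by all three samples), clonal somatic SNVs
partitioned into shared / pre-only / post-only categories, copy-number
segments, and injected artifact classes that each target one downstream
filter criterion:

* ``end_biased``       -- variant-supporting reads concentrated within 5 bp
                          of a read end (read-end bias filter),
* ``gap_proximal``     -- >= 10 gap-flagged reads within the 20 bp flank
                          (gap-region filter),
* ``low_mapq_cluster`` -- variant-supporting reads with mapping quality well
                          below 30 (mapping-quality filter),
* ``repeat_hotspot``   -- spurious variant inside a >= 6-copy tandem repeat
                          (simple-repeat filter),
* ``adjacent_cluster`` -- two spurious sites < 10 bp apart (adjacent-distance
                          filter).

The simulation is pileup-level: the filters consume per-read attributes only,
so reads are represented by the minimal sufficient statistics (base, phred
base quality, phred mapping quality, distance to nearest read end, gap flag,
strand) rather than full sequences.  Per-site depth is Poisson with mean
``mean_depth x local copy ratio``; the default depths are 69.70x / 66.55x /
68.26x for normal / pre / post and the default somatic structure is
22 shared + 12 pre-only + 12 post-only sites with VAFs spanning 5-47%.

Identical configuration (including seed) yields byte-identical outputs.  Each
stage draws from its own seeded substream so that the reference, the truth
set, and the evidence are individually reproducible regardless of which
stages a caller re-runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evidence import EVIDENCE_COLUMNS
from .repeats import overlaps_repeat

SAMPLES = ("normal", "pre", "post")
ARTIFACT_CLASSES = (
    "end_biased",
    "gap_proximal",
    "low_mapq_cluster",
    "repeat_hotspot",
    "adjacent_cluster",
)

_BASES = np.array(list("ACGT"))
# per-stage RNG substream tags (stage, seed)
_STAGE_REFERENCE, _STAGE_VARIANTS, _STAGE_EVIDENCE, _STAGE_DEPTH = 1, 2, 3, 4


class SimConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


@dataclass(frozen=True)
class RepeatTrack:
    """A tandem repeat embedded verbatim in the reference."""

    chrom: str
    start: int  # 1-based
    unit: str
    copies: int

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive (start, end)."""
        return self.start, self.start + len(self.unit) * self.copies - 1


@dataclass(frozen=True)
class CNVTruthSegment:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    copy_number: int
    samples: tuple[str, ...] = ("pre", "post")


@dataclass
class SimConfig:
    """Study conditions for one synthetic trio.

    Defaults reproduce the structure of a deeply sequenced tumor trio:
    ~65-70x Poisson depth per sample, germline heterozygous SNPs at ~1/kb,
    a 22/12/12 shared/pre-only/post-only somatic structure with VAFs in
    5-47%, zero variant reads in the normal, and copy-number segments shared
    by the two tumors.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 50_000
    gc_fraction: float = 0.41
    germline_rate: float = 1e-3
    n_somatic_shared: int = 22
    n_somatic_pre_only: int = 12
    n_somatic_post_only: int = 12
    vaf_range: tuple[float, float] = (0.05, 0.47)
    mean_depth_normal: float = 69.70
    mean_depth_pre: float = 66.55
    mean_depth_post: float = 68.26
    read_length: int = 90
    base_error_rate: float = 0.001
    gap_rate: float = 0.005
    baseq_mean: float = 32.0
    baseq_sd: float = 4.0
    baseq_clip: tuple[int, int] = (2, 40)
    mapq_high: int = 60
    mapq_low_fraction: float = 0.05
    artifact_rates: dict = field(
        default_factory=lambda: {cls: 2 for cls in ARTIFACT_CLASSES}
    )
    artifact_vaf: float = 0.20
    repeat_tracks: list = field(
        default_factory=lambda: [RepeatTrack("chr1", 30_001, "CAG", 8)]
    )
    cnv_segments: list = field(default_factory=list)
    n_neutral_sites: int = 300
    min_somatic_spacing: int = 50
    edge_margin: int = 100

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def mean_depth(self, sample: str) -> float:
        return {
            "normal": self.mean_depth_normal,
            "pre": self.mean_depth_pre,
            "post": self.mean_depth_post,
        }[sample]

    def validate(self) -> None:
        if self.chrom_length <= 0 or self.n_chroms <= 0:
            raise SimConfigError("chromosome count and length must be positive")
        if not (0.0 < self.gc_fraction < 1.0):
            raise SimConfigError("gc_fraction must be in (0,1)")
        lo, hi = self.vaf_range
        if not (0.0 < lo <= hi <= 1.0):
            raise SimConfigError("vaf_range must satisfy 0 < lo <= hi <= 1")
        for count in (
            self.n_somatic_shared,
            self.n_somatic_pre_only,
            self.n_somatic_post_only,
            self.n_neutral_sites,
        ):
            if count < 0:
                raise SimConfigError("counts must be non-negative")
        for d in (self.mean_depth_normal, self.mean_depth_pre, self.mean_depth_post):
            if d <= 0:
                raise SimConfigError("mean depths must be positive")
        if self.read_length <= 0:
            raise SimConfigError("read_length must be positive")
        for cls, rate in self.artifact_rates.items():
            if cls not in ARTIFACT_CLASSES:
                raise SimConfigError(f"unknown artifact class {cls!r}")
            if rate < 0:
                raise SimConfigError("artifact rates must be non-negative")
        chroms = set(self.chrom_names())
        tracks = [t if isinstance(t, RepeatTrack) else RepeatTrack(*t) for t in self.repeat_tracks]
        for track in tracks:
            if track.chrom not in chroms:
                raise SimConfigError(f"repeat track on unknown chromosome {track.chrom!r}")
            _, end = track.span
            if track.start < 1 or end > self.chrom_length:
                raise SimConfigError(
                    f"repeat track {track.unit}x{track.copies} at "
                    f"{track.chrom}:{track.start} exceeds chromosome bounds"
                )
        segs = self.cnv_truth()
        by_chrom: dict[str, list[CNVTruthSegment]] = {}
        for seg in segs:
            if seg.chrom not in chroms:
                raise SimConfigError(f"CNV segment on unknown chromosome {seg.chrom!r}")
            if not (1 <= seg.start <= seg.end <= self.chrom_length):
                raise SimConfigError("CNV segment out of chromosome bounds")
            if seg.copy_number < 0:
                raise SimConfigError("copy number must be non-negative")
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom_segs in by_chrom.values():
            chrom_segs.sort(key=lambda s: s.start)
            for prev, cur in zip(chrom_segs, chrom_segs[1:]):
                if cur.start <= prev.end:
                    raise SimConfigError("CNV segments overlap on one chromosome")

    def repeat_track_objs(self) -> list[RepeatTrack]:
        return [t if isinstance(t, RepeatTrack) else RepeatTrack(*t) for t in self.repeat_tracks]

    def cnv_truth(self) -> list[CNVTruthSegment]:
        return [s if isinstance(s, CNVTruthSegment) else CNVTruthSegment(*s) for s in self.cnv_segments]


@dataclass(frozen=True)
class GermlineSite:
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class SomaticSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf_pre: float
    vaf_post: float
    category: str  # shared | pre_only | post_only


@dataclass(frozen=True)
class ArtifactSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    artifact_class: str


@dataclass
class TruthSet:
    """Ground truth emitted alongside the evidence, for recovery testing."""

    germline_sites: list[GermlineSite] = field(default_factory=list)
    somatic_sites: list[SomaticSite] = field(default_factory=list)
    artifact_sites: list[ArtifactSite] = field(default_factory=list)
    cnv_truth: list[CNVTruthSegment] = field(default_factory=list)

    def validate(self, reference: dict[str, str]) -> None:
        germ = {(s.chrom, s.pos) for s in self.germline_sites}
        som = {(s.chrom, s.pos) for s in self.somatic_sites}
        if germ & som:
            raise ValueError("somatic site coincides with a germline site")
        for site in (*self.germline_sites, *self.somatic_sites, *self.artifact_sites):
            seq = reference.get(site.chrom)
            if seq is None or not (1 <= site.pos <= len(seq)):
                raise ValueError(f"site {site.chrom}:{site.pos} outside reference bounds")
            if seq[site.pos - 1] != site.ref:
                raise ValueError(f"truth ref mismatch at {site.chrom}:{site.pos}")
        cats = {s.category for s in self.somatic_sites}
        if not cats <= {"shared", "pre_only", "post_only"}:
            raise ValueError(f"unknown somatic category in {cats}")

    def vaf_in(self, site: SomaticSite, sample: str) -> float:
        if sample == "normal":
            return 0.0
        return site.vaf_pre if sample == "pre" else site.vaf_post


def generate_reference(config: SimConfig) -> tuple[dict[str, str], list[RepeatTrack]]:
    """Draw a GC-controlled random reference and embed repeat tracks verbatim."""
    config.validate()
    rng = np.random.default_rng([_STAGE_REFERENCE, config.seed])
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    reference: dict[str, str] = {}
    for chrom in config.chrom_names():
        seq = rng.choice(_BASES, size=config.chrom_length, p=probs)
        reference[chrom] = "".join(seq)
    tracks = config.repeat_track_objs()
    for track in tracks:
        start0 = track.start - 1
        insert = track.unit * track.copies
        seq = reference[track.chrom]
        reference[track.chrom] = seq[:start0] + insert + seq[start0 + len(insert):]
    return reference, tracks


def _draw_alt(rng: np.random.Generator, ref: str) -> str:
    others = [b for b in "ACGT" if b != ref]
    return others[int(rng.integers(0, 3))]


class _PositionSampler:
    """Rejection sampler for site positions under spacing/context constraints."""

    def __init__(self, rng: np.random.Generator, reference: dict[str, str], config: SimConfig):
        self.rng = rng
        self.reference = reference
        self.config = config
        self.chroms = config.chrom_names()
        lengths = np.array([len(reference[c]) for c in self.chroms], dtype=float)
        self.weights = lengths / lengths.sum()
        self.occupied: dict[str, list[int]] = {c: [] for c in self.chroms}

    def mark(self, chrom: str, pos: int) -> None:
        self.occupied[chrom].append(pos)

    def sample(
        self,
        spacing: int,
        avoid_repeats: bool = True,
        in_repeat_track: bool = False,
        max_tries: int = 20_000,
    ) -> tuple[str, int]:
        cfg = self.config
        for _ in range(max_tries):
            if in_repeat_track:
                tracks = [t for t in cfg.repeat_track_objs() if t.copies >= 6]
                if not tracks:
                    raise SimConfigError(
                        "repeat_hotspot artifacts need a repeat track with >= 6 copies"
                    )
                track = tracks[int(self.rng.integers(0, len(tracks)))]
                lo, hi = track.span
                chrom = track.chrom
                pos = int(self.rng.integers(lo, hi + 1))
            else:
                chrom = self.chroms[int(self.rng.choice(len(self.chroms), p=self.weights))]
                length = len(self.reference[chrom])
                lo = cfg.edge_margin + 1
                hi = length - cfg.edge_margin
                if hi <= lo:
                    raise SimConfigError("chromosome too short for edge margin")
                pos = int(self.rng.integers(lo, hi + 1))
            if any(abs(pos - q) < spacing for q in self.occupied[chrom]):
                continue
            if avoid_repeats and overlaps_repeat(self.reference[chrom], pos - 1):
                continue
            self.mark(chrom, pos)
            return chrom, pos
        raise SimConfigError(
            "could not place a site under the configured spacing; "
            "reduce counts or spacing, or enlarge the genome"
        )


def implant_variants(reference: dict[str, str], config: SimConfig) -> TruthSet:
    """Choose germline, somatic, and artifact sites and their true VAFs.

    Somatic and artifact sites keep ``min_somatic_spacing`` between one
    another (so adjacent-distance behavior is fully controlled by the
    ``adjacent_cluster`` artifact class) and avoid simple-repeat context
    (controlled by ``repeat_hotspot``).  Germline sites are heterozygous in
    all three samples.
    """
    config.validate()
    rng = np.random.default_rng([_STAGE_VARIANTS, config.seed])
    sampler = _PositionSampler(rng, reference, config)
    truth = TruthSet(cnv_truth=config.cnv_truth())

    lo, hi = config.vaf_range

    def draw_vaf() -> float:
        return float(rng.uniform(lo, hi))

    # somatic sites first: they carry the strictest placement constraints
    categories = (
        ["shared"] * config.n_somatic_shared
        + ["pre_only"] * config.n_somatic_pre_only
        + ["post_only"] * config.n_somatic_post_only
    )
    for category in categories:
        chrom, pos = sampler.sample(spacing=config.min_somatic_spacing)
        ref = reference[chrom][pos - 1]
        alt = _draw_alt(rng, ref)
        vaf_pre = draw_vaf() if category in ("shared", "pre_only") else 0.0
        vaf_post = draw_vaf() if category in ("shared", "post_only") else 0.0
        truth.somatic_sites.append(
            SomaticSite(chrom, pos, ref, alt, vaf_pre, vaf_post, category)
        )

    # artifact sites
    for cls in ARTIFACT_CLASSES:
        count = int(config.artifact_rates.get(cls, 0))
        for _ in range(count):
            if cls == "adjacent_cluster":
                chrom, pos = sampler.sample(spacing=config.min_somatic_spacing)
                offset = int(rng.integers(2, 10))  # strictly inside the 10 bp gate
                pos2 = pos + offset
                sampler.mark(chrom, pos2)
                for p in (pos, pos2):
                    ref = reference[chrom][p - 1]
                    truth.artifact_sites.append(
                        ArtifactSite(chrom, p, ref, _draw_alt(rng, ref), cls)
                    )
            elif cls == "repeat_hotspot":
                # spacing 12 bp: clears the 10 bp adjacency gate while fitting
                # several hotspots inside one short repeat track
                chrom, pos = sampler.sample(
                    spacing=12,
                    avoid_repeats=False,
                    in_repeat_track=True,
                )
                ref = reference[chrom][pos - 1]
                truth.artifact_sites.append(
                    ArtifactSite(chrom, pos, ref, _draw_alt(rng, ref), cls)
                )
            else:
                chrom, pos = sampler.sample(spacing=config.min_somatic_spacing)
                ref = reference[chrom][pos - 1]
                truth.artifact_sites.append(
                    ArtifactSite(chrom, pos, ref, _draw_alt(rng, ref), cls)
                )

    # germline heterozygous SNPs: density germline_rate per bp
    for chrom in config.chrom_names():
        length = len(reference[chrom])
        n_germ = int(rng.binomial(length, config.germline_rate))
        taken = set(sampler.occupied[chrom])
        placed = 0
        tries = 0
        while placed < n_germ and tries < 50 * n_germ + 100:
            tries += 1
            pos = int(rng.integers(config.edge_margin + 1, length - config.edge_margin + 1))
            if pos in taken:
                continue
            taken.add(pos)
            ref = reference[chrom][pos - 1]
            truth.germline_sites.append(
                GermlineSite(chrom, pos, ref, _draw_alt(rng, ref))
            )
            placed += 1

    truth.validate(reference)
    return truth


def _copy_ratio(truth: TruthSet, chrom: str, pos: int, sample: str) -> float:
    if sample == "normal":
        return 1.0
    for seg in truth.cnv_truth:
        if seg.chrom == chrom and seg.start <= pos <= seg.end and sample in seg.samples:
            return seg.copy_number / 2.0
    return 1.0


def simulate_evidence(
    reference: dict[str, str],
    truth: TruthSet,
    config: SimConfig,
) -> pd.DataFrame:
    """Simulate per-read evidence for all three samples at every truth site
    plus ``n_neutral_sites`` variant-free background sites.

    Returns an evidence table in :data:`~somatrio.evidence.EVIDENCE_COLUMNS`
    order covering samples ``normal``, ``pre`` and ``post``.
    """
    config.validate()
    rng = np.random.default_rng([_STAGE_EVIDENCE, config.seed])

    # assemble the site catalogue in deterministic order
    sites: list[tuple[str, int, str, str | None, dict[str, float], str | None]] = []
    for s in truth.germline_sites:
        sites.append((s.chrom, s.pos, s.ref, s.alt, {"normal": 0.5, "pre": 0.5, "post": 0.5}, None))
    for s in truth.somatic_sites:
        sites.append(
            (s.chrom, s.pos, s.ref, s.alt,
             {"normal": 0.0, "pre": s.vaf_pre, "post": s.vaf_post}, None)
        )
    for s in truth.artifact_sites:
        sites.append(
            (s.chrom, s.pos, s.ref, s.alt,
             {"normal": 0.0, "pre": config.artifact_vaf, "post": config.artifact_vaf},
             s.artifact_class)
        )
    # neutral background sites
    occupied = {(c, p) for c, p, *_ in sites}
    chroms = config.chrom_names()
    lengths = np.array([len(reference[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    placed = 0
    while placed < config.n_neutral_sites:
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        pos = int(rng.integers(1, len(reference[chrom]) + 1))
        if (chrom, pos) in occupied:
            continue
        occupied.add((chrom, pos))
        sites.append((chrom, pos, reference[chrom][pos - 1], None, {}, None))
        placed += 1
    sites.sort(key=lambda t: (t[0], t[1]))

    qlo, qhi = config.baseq_clip
    # distance to nearest end of an L bp read spans 0..(L-1)//2
    max_end_dist = (config.read_length - 1) // 2
    base_order = {b: i for i, b in enumerate("ACGT")}
    # per-block scalars (chrom, pos, ref, sample, depth) expanded once at the
    # end with np.repeat; per-read arrays accumulated and concatenated once
    meta: list[tuple[str, int, str, str, int]] = []
    cols: dict[str, list] = {c: [] for c in ("base", "baseq", "mapq", "end_dist", "gap", "strand")}

    for chrom, pos, ref, alt, vaf_by_sample, artifact in sites:
        for sample in SAMPLES:
            depth = int(rng.poisson(config.mean_depth(sample) * _copy_ratio(truth, chrom, pos, sample)))
            if depth == 0:
                continue
            vaf = vaf_by_sample.get(sample, 0.0)
            n_alt = int(rng.binomial(depth, vaf)) if (alt and vaf > 0) else 0
            bases = np.full(depth, ref, dtype="<U1")
            if n_alt:
                bases[:n_alt] = alt
            # sequencing errors replace the observed base with a random other base
            err = rng.random(depth) < config.base_error_rate
            if err.any():
                idx = np.flatnonzero(err)
                cur = bases[idx]
                shift = rng.integers(1, 4, idx.size)
                newb = [_BASES[(base_order[c] + s) % 4] for c, s in zip(cur, shift)]
                bases[idx] = newb
            baseq = np.clip(np.rint(rng.normal(config.baseq_mean, config.baseq_sd, depth)), qlo, qhi).astype(int)
            low_mapq = rng.random(depth) < config.mapq_low_fraction
            mapq = np.where(low_mapq, rng.integers(0, 31, depth), config.mapq_high)
            end_dist = rng.integers(0, max_end_dist + 1, depth)
            gap = rng.random(depth) < config.gap_rate
            strand = np.where(rng.random(depth) < 0.5, "+", "-")

            if artifact and sample in ("pre", "post"):
                is_alt = bases == alt
                if artifact == "end_biased":
                    end_dist = np.where(is_alt, rng.integers(0, 6, depth), end_dist)
                elif artifact == "low_mapq_cluster":
                    mapq = np.where(is_alt, rng.integers(0, 21, depth), mapq)
                elif artifact == "gap_proximal":
                    k = min(12, depth)
                    gap = gap.copy()
                    gap[:k] = True

            meta.append((chrom, pos, ref, sample, depth))
            cols["base"].append(bases)
            cols["baseq"].append(baseq.astype(np.int16))
            cols["mapq"].append(mapq.astype(np.int16))
            cols["end_dist"].append(end_dist.astype(np.int16))
            cols["gap"].append(gap)
            cols["strand"].append(strand)

    if not meta:
        return pd.DataFrame(columns=EVIDENCE_COLUMNS)
    counts = np.array([m[4] for m in meta])

    def expand(i, dtype=object):
        return np.repeat(np.array([m[i] for m in meta], dtype=dtype), counts)

    frame = pd.DataFrame(
        {
            "chrom": expand(0),
            "pos": expand(1, np.int64),
            "ref": expand(2),
            "sample": expand(3),
            "base": np.concatenate(cols["base"]).astype(object),
            "baseq": np.concatenate(cols["baseq"]),
            "mapq": np.concatenate(cols["mapq"]),
            "end_dist": np.concatenate(cols["end_dist"]),
            "gap": np.concatenate(cols["gap"]).astype(bool),
            "strand": np.concatenate(cols["strand"]).astype(object),
        },
        columns=EVIDENCE_COLUMNS,
    )
    return frame


def simulate_trio(config: SimConfig) -> tuple[dict[str, str], TruthSet, pd.DataFrame]:
    """Convenience wrapper: reference -> truth -> evidence in one call."""
    reference, _ = generate_reference(config)
    truth = implant_variants(reference, config)
    evidence = simulate_evidence(reference, truth, config)
    return reference, truth, evidence


def simulate_depth_windows(config: SimConfig, window_size: int = 1000) -> pd.DataFrame:
    """Simulate per-window read counts for all three samples.

    Window counts are Poisson with mean ``mean_depth x window/read_length x
    local copy ratio`` -- the read-count analogue of the per-base Poisson
    depth model.  Returns columns chrom, start, end (0-based half-open),
    count_normal, count_pre, count_post.
    """
    config.validate()
    if window_size < 100:
        raise SimConfigError("window_size must be >= 100")
    rng = np.random.default_rng([_STAGE_DEPTH, config.seed])
    truth = TruthSet(cnv_truth=config.cnv_truth())
    rows = []
    for chrom in config.chrom_names():
        n_win = config.chrom_length // window_size
        for w in range(n_win):
            start = w * window_size
            end = start + window_size
            mid = start + window_size // 2 + 1
            counts = {}
            for sample in SAMPLES:
                lam = (
                    config.mean_depth(sample)
                    * window_size
                    / config.read_length
                    * _copy_ratio(truth, chrom, mid, sample)
                )
                counts[sample] = int(rng.poisson(lam))
            rows.append((chrom, start, end, counts["normal"], counts["pre"], counts["post"]))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "count_normal", "count_pre", "count_post"]
    )


# ---------------------------------------------------------------------------
# truth-set IO (tab-separated, '#'-headed)

def write_truth_variants(path, truth: TruthSet, seed: int | None = None) -> None:
    lines = ["# synthetic trio truth set"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    lines.append("#kind\tchrom\tpos\tref\talt\tvaf_pre\tvaf_post\tcategory")
    for s in truth.germline_sites:
        lines.append(f"germline\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t0.5\t0.5\t.")
    for s in truth.somatic_sites:
        lines.append(
            f"somatic\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.vaf_pre!r}\t{s.vaf_post!r}\t{s.category}"
        )
    for s in truth.artifact_sites:
        lines.append(f"artifact\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t.\t.\t{s.artifact_class}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_truth_variants(path) -> TruthSet:
    truth = TruthSet()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            kind, chrom, pos, ref, alt, vpre, vpost, cat = line.rstrip("\n").split("\t")
            pos = int(pos)
            if kind == "germline":
                truth.germline_sites.append(GermlineSite(chrom, pos, ref, alt))
            elif kind == "somatic":
                truth.somatic_sites.append(
                    SomaticSite(chrom, pos, ref, alt, float(vpre), float(vpost), cat)
                )
            elif kind == "artifact":
                truth.artifact_sites.append(ArtifactSite(chrom, pos, ref, alt, cat))
            else:
                raise ValueError(f"unknown truth record kind {kind!r}")
    return truth


def write_cnv_truth(path, truth: TruthSet) -> None:
    """BED3+copy-number (+samples) of the implanted copy-number segments."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#chrom\tstart\tend\tcopy_number\tsamples\n")
        for seg in truth.cnv_truth:
            fh.write(
                f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\t{seg.copy_number}\t{','.join(seg.samples)}\n"
            )
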