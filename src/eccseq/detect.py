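"""Two-track eccDNA detection and the high-confidence filter.

Track 1 classifies read pairs: a pair is circle evidence when the mates map
in opposite orientations on the same scaffold with a negative insert size
of at least the read length plus five bases, and both mates have MAPQ >= 10.
Qualifying pairs define candidate regions (the pair's aligned extent),
merged with distance-0 (bookended-merge) semantics.

Track 2 re-anchors soft-clipped reads: a read clipped at one side of a
putative junction whose clipped sequence matches the reference on the other
side (same scaffold, within the maximum circle size, at most one mismatch
by default) defines a junction interval.

Candidates from both tracks are merged and kept as high-confidence eccDNA
when (1) at least 80% of the region is read-covered, (2) the region is
supported by both tracks or by at least two discordant pairs, and (3) at
least 10% of the region is covered by uniquely mapping reads (MAPQ >= 10).
All thresholds are inclusive.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alignments import AlignmentSet, ReadPair
from .intervals import merge_tagged

logger = logging.getLogger(__name__)

CIRCLE_DISCORDANT = "circle_discordant"
CONCORDANT = "concordant"
UNUSABLE = "unusable"

SIZE_CLASS_SPLIT = 1000  # small (<1 kb) vs larger (>=1 kb) elements


@dataclass
class CandidateRegion:
    scaffold: str
    start: int
    end: int
    n_discordant_pairs: int = 0
    n_split_reads: int = 0
    evidence_sources: frozenset = frozenset()
    coverage_fraction: float | None = None
    unique_fraction: float | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("region must have positive length")
        if self.n_discordant_pairs < 0 or self.n_split_reads < 0:
            raise ValueError("support counts must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class EccDNARecord:
    scaffold: str
    start: int
    end: int
    n_discordant_pairs: int
    n_split_reads: int
    evidence_sources: frozenset
    coverage_fraction: float
    unique_fraction: float
    sample_id: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def size_class(self) -> str:
        return "lt1kb" if self.length < SIZE_CLASS_SPLIT else "ge1kb"

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Junction:
    scaffold: str
    left: int
    right: int
    support: int


# ---------------------------------------------------------------------------
# track 1: discordant pairs


def classify_pair(
    pair: ReadPair, min_mapq: int = 10, min_nonoverlap: int = 5
) -> str:
    """Classify a pair as circle evidence, concordant, or unusable.

    Circle evidence requires ALL of: opposite orientations with a negative
    insert size; both mates on the same scaffold; both MAPQ >= ``min_mapq``;
    and |insert| >= read length + ``min_nonoverlap``.
    """
    if not pair.same_scaffold:
        return UNUSABLE
    if pair.mate1.mapq < min_mapq or pair.mate2.mapq < min_mapq:
        return UNUSABLE
    if pair.mate1.strand == pair.mate2.strand:
        return UNUSABLE
    ins = pair.insert_size
    if ins < 0:
        if -ins >= pair.read_len + min_nonoverlap:
            return CIRCLE_DISCORDANT
        return UNUSABLE
    if ins > 0:
        return CONCORDANT
    return UNUSABLE


def build_regions(discordant_pairs: Iterable[ReadPair]) -> list[CandidateRegion]:
    """Merge the aligned extents of circle-supporting pairs into regions.

    Overlapping or bookended pair extents merge (distance-0 semantics);
    each merged region counts its contributing pairs.
    """
    by_scaffold: dict[str, list[tuple[int, int, str]]] = {}
    for p in discordant_pairs:
        scaf, s, e = p.span
        by_scaffold.setdefault(scaf, []).append((s, e, p.qname))
    regions = []
    for scaf in sorted(by_scaffold):
        for s, e, tags in merge_tagged(by_scaffold[scaf]):
            regions.append(
                CandidateRegion(
                    scaf, s, e,
                    n_discordant_pairs=len(tags),
                    evidence_sources=frozenset({"discordant"}),
                )
            )
    return regions


# ---------------------------------------------------------------------------
# track 2: soft-clip junctions


def _find_approx(pattern: str, text: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (mismatches, offset) occurrences of pattern in text, exact first."""
    hits = []
    start = 0
    while True:
        i = text.find(pattern, start)
        if i == -1:
            break
        hits.append((0, i))
        start = i + 1
    if hits or max_mismatch <= 0:
        return hits
    p = np.frombuffer(pattern.encode(), np.uint8)
    t = np.frombuffer(text.encode(), np.uint8)
    if len(t) < len(p):
        return []
    windows = np.lib.stride_tricks.sliding_window_view(t, len(p))
    mm = (windows != p).sum(axis=1)
    idx = np.nonzero(mm <= max_mismatch)[0]
    return [(int(mm[i]), int(i)) for i in idx]


def detect_split_junctions(
    source: AlignmentSet | Iterable[ReadPair],
    sequences: dict[str, str],
    min_clip: int = 15,
    max_mismatch: int = 1,
    max_span: int = 50_000,
) -> list[Junction]:
    """Re-anchor soft-clipped reads to call circle junctions.

    A junction ``(a, b)`` with ``a < b`` is reported when a read clipped on
    the left at position ``a`` has its clipped prefix matching the reference
    ending at ``b``, or a read clipped on the right at ``b`` has its clipped
    suffix matching the reference starting at ``a`` (clip >= ``min_clip``,
    at most ``max_mismatch`` mismatches, same scaffold, span <= ``max_span``).
    Support counts distinct reads.
    """
    pairs = source.pairs if isinstance(source, AlignmentSet) else list(source)
    votes: dict[tuple[str, int, int], set[str]] = {}
    for pair in pairs:
        for mate in (pair.mate1, pair.mate2):
            if mate.scaffold not in sequences:
                continue
            seq = sequences[mate.scaffold]
            if mate.clip_left >= min_clip:
                if mate.clip_left_seq is None:
                    logger.warning("clipped sequence missing for %s; skipped", pair.qname)
                else:
                    j = _anchor_left_clip(
                        seq, mate.start, mate.clip_left_seq, max_mismatch, max_span
                    )
                    if j is not None:
                        votes.setdefault((mate.scaffold, *j), set()).add(pair.qname)
            if mate.clip_right >= min_clip:
                if mate.clip_right_seq is None:
                    logger.warning("clipped sequence missing for %s; skipped", pair.qname)
                else:
                    j = _anchor_right_clip(
                        seq, mate.end, mate.clip_right_seq, max_mismatch, max_span
                    )
                    if j is not None:
                        votes.setdefault((mate.scaffold, *j), set()).add(pair.qname)
    return [
        Junction(scaf, a, b, len(qnames))
        for (scaf, a, b), qnames in sorted(votes.items())
    ]


def _anchor_left_clip(seq, a, clip_seq, max_mismatch, max_span):
    """Left-clipped read starting at ``a``: clip matches ref ending at some b > a."""
    c = len(clip_seq)
    win_lo = max(0, a - c + 1)
    win_hi = min(len(seq), a + max_span)
    hits = _find_approx(clip_seq, seq[win_lo:win_hi], max_mismatch)
    best = None
    for mm, off in hits:
        b = win_lo + off + c
        if b <= a or b - a > max_span:
            continue
        key = (mm, b - a)
        if best is None or key < best[0]:
            best = (key, (a, b))
    return best[1] if best else None


def _anchor_right_clip(seq, b, clip_seq, max_mismatch, max_span):
    """Right-clipped read ending at ``b``: clip matches ref starting at some a < b."""
    c = len(clip_seq)
    win_lo = max(0, b - max_span)
    win_hi = min(len(seq), b + c - 1)
    hits = _find_approx(clip_seq, seq[win_lo:win_hi], max_mismatch)
    best = None
    for mm, off in hits:
        a = win_lo + off
        if a >= b or b - a > max_span:
            continue
        key = (mm, b - a)
        if best is None or key < best[0]:
            best = (key, (a, b))
    return best[1] if best else None


# ---------------------------------------------------------------------------
# merge, score, filter


def assemble_candidates(
    regions: Iterable[CandidateRegion], junctions: Iterable[Junction]
) -> list[CandidateRegion]:
    """Distance-0 union of discordant regions and junction intervals.

    Evidence sources record which track(s) contributed to each merged
    candidate; support counts are carried through additively.
    """
    by_scaffold: dict[str, list[tuple[int, int, tuple]]] = {}
    for r in regions:
        by_scaffold.setdefault(r.scaffold, []).append(
            (r.start, r.end, ("discordant", r.n_discordant_pairs, 0))
        )
    for j in junctions:
        by_scaffold.setdefault(j.scaffold, []).append(
            (j.left, j.right, ("split", 0, j.support))
        )
    out = []
    for scaf in sorted(by_scaffold):
        for s, e, tags in merge_tagged(by_scaffold[scaf]):
            out.append(
                CandidateRegion(
                    scaf, s, e,
                    n_discordant_pairs=sum(t[1] for t in tags),
                    n_split_reads=sum(t[2] for t in tags),
                    evidence_sources=frozenset(t[0] for t in tags),
                )
            )
    return out


class CoverageIndex:
    """Per-base covered / uniquely-covered masks built from the alignment stream."""

    def __init__(
        self,
        source: AlignmentSet | Iterable[ReadPair],
        scaffold_lengths: dict[str, int] | None = None,
        unique_mapq: int = 10,
    ):
        pairs = source.pairs if isinstance(source, AlignmentSet) else list(source)
        if scaffold_lengths is None:
            if not isinstance(source, AlignmentSet):
                raise ValueError("scaffold_lengths required for bare pair lists")
            scaffold_lengths = source.scaffold_lengths
        self.covered = {
            s: np.zeros(ln, dtype=bool) for s, ln in scaffold_lengths.items()
        }
        self.unique = {
            s: np.zeros(ln, dtype=bool) for s, ln in scaffold_lengths.items()
        }
        for p in pairs:
            for m in (p.mate1, p.mate2):
                cov = self.covered.get(m.scaffold)
                if cov is None:
                    continue
                cov[m.start:m.end] = True
                if m.mapq >= unique_mapq:
                    self.unique[m.scaffold][m.start:m.end] = True

    def fractions(self, scaffold: str, start: int, end: int) -> tuple[float, float]:
        if end <= start:
            raise ValueError("zero-length region")
        n = end - start
        return (
            float(self.covered[scaffold][start:end].sum()) / n,
            float(self.unique[scaffold][start:end].sum()) / n,
        )


def score_candidate(
    candidate: CandidateRegion,
    source: AlignmentSet | CoverageIndex,
    unique_mapq: int = 10,
) -> CandidateRegion:
    """Recompute coverage and unique-coverage fractions from the alignments."""
    cov = source if isinstance(source, CoverageIndex) else CoverageIndex(
        source, unique_mapq=unique_mapq
    )
    cf, uf = cov.fractions(candidate.scaffold, candidate.start, candidate.end)
    return replace(candidate, coverage_fraction=cf, unique_fraction=uf)


def filter_high_confidence(
    candidates: Iterable[CandidateRegion],
    min_coverage: float = 0.80,
    min_discordant: int = 2,
    min_unique: float = 0.10,
    sample_id: str | None = None,
) -> list[EccDNARecord]:
    """Apply the three-criterion high-confidence filter (all thresholds inclusive).

    Keep a candidate iff its read coverage is >= ``min_coverage``, it is
    supported by both evidence tracks or by >= ``min_discordant`` discordant
    pairs, and >= ``min_unique`` of the region maps uniquely.
    """
    out = []
    for c in candidates:
        if c.coverage_fraction is None or c.unique_fraction is None:
            raise ValueError("candidates must be scored before filtering")
        both_tracks = {"discordant", "split"} <= c.evidence_sources
        if (
            c.coverage_fraction >= min_coverage
            and (both_tracks or c.n_discordant_pairs >= min_discordant)
            and c.unique_fraction >= min_unique
        ):
            out.append(
                EccDNARecord(
                    c.scaffold, c.start, c.end,
                    c.n_discordant_pairs, c.n_split_reads, c.evidence_sources,
                    c.coverage_fraction, c.unique_fraction, sample_id,
                )
            )
    return out


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class DetectionResult:
    records: list[EccDNARecord]
    candidates: list[CandidateRegion]
    junctions: list[Junction]
    n_discordant_pairs: int
    n_concordant_pairs: int


def detect_eccdna(
    aset: AlignmentSet,
    sequences: dict[str, str],
    *,
    min_mapq: int = 10,
    min_nonoverlap: int = 5,
    min_clip: int = 15,
    max_mismatch: int = 1,
    max_span: int = 50_000,
    min_coverage: float = 0.80,
    min_discordant: int = 2,
    min_unique: float = 0.10,
    unique_mapq: int = 10,
) -> DetectionResult:
    """Run both evidence tracks, merge, score and filter one sample.

    Output is independent of input record order (pairs are sorted internally).
    """
    pairs = sorted(
        aset.pairs, key=lambda p: (p.mate1.scaffold, p.span[1], p.span[2], p.qname)
    )
    discordant, n_conc = [], 0
    for p in pairs:
        cls = classify_pair(p, min_mapq=min_mapq, min_nonoverlap=min_nonoverlap)
        if cls == CIRCLE_DISCORDANT:
            discordant.append(p)
        elif cls == CONCORDANT:
            n_conc += 1
    regions = build_regions(discordant)
    junctions = detect_split_junctions(
        pairs, sequences, min_clip=min_clip,
        max_mismatch=max_mismatch, max_span=max_span,
    )
    candidates = assemble_candidates(regions, junctions)
    cov = CoverageIndex(pairs, aset.scaffold_lengths, unique_mapq=unique_mapq)
    scored = [score_candidate(c, cov) for c in candidates]
    records = filter_high_confidence(
        scored, min_coverage=min_coverage, min_discordant=min_discordant,
        min_unique=min_unique, sample_id=aset.sample_id,
    )
    return DetectionResult(
        records=records,
        candidates=scored,
        junctions=junctions,
        n_discordant_pairs=len(discordant),
        n_concordant_pairs=n_conc,
    )


@dataclass(frozen=True)
class MergedRecord:
    scaffold: str
    start: int
    end: int
    sample_ids: tuple
    n_records: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def pool_and_merge(
    samples: Sequence[Sequence[EccDNARecord]],
    scaffolds: Iterable[str] | None = None,
) -> list[MergedRecord]:
    """Pool per-sample calls into a nonredundant set (distance-0 union).

    Contributing sample ids are retained per merged record.  If ``scaffolds``
    is given, records on unknown scaffolds raise (mixed references).
    """
    known = set(scaffolds) if scaffolds is not None else None
    by_scaffold: dict[str, list[tuple[int, int, str | None]]] = {}
    for recs in samples:
        for r in recs:
            if known is not None and r.scaffold not in known:
                raise ValueError(f"record on unknown reference {r.scaffold!r}")
            by_scaffold.setdefault(r.scaffold, []).append(
                (r.start, r.end, r.sample_id)
            )
    out = []
    for scaf in sorted(by_scaffold):
        for s, e, tags in merge_tagged(by_scaffold[scaf]):
            ids = tuple(dict.fromkeys(t for t in tags if t is not None))
            out.append(MergedRecord(scaf, s, e, ids, len(tags)))
    return out


# ---------------------------------------------------------------------------
# output


def write_ecc_bed(records: Iterable[EccDNARecord], path: str | Path) -> None:
    """Calls as BED6+ with support counts and filter metrics in extra columns."""
    with open(path, "w") as fh:
        for i, r in enumerate(
            sorted(records, key=lambda r: (r.scaffold, r.start)), 1
        ):
            fh.write(
                "\t".join([
                    r.scaffold, str(r.start), str(r.end), f"ecc_{i:05d}",
                    str(r.n_discordant_pairs), ".",
                    str(r.n_split_reads),
                    f"{r.coverage_fraction:.4f}", f"{r.unique_fraction:.4f}",
                    ",".join(sorted(r.evidence_sources)),
                ]) + "\n"
            )
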