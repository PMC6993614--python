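"""Minimal paired-end alignment records and the per-sample container.

The detector consumes :class:`AlignmentSet` objects, normally built from a
SAM/BAM file with :meth:`AlignmentSet.from_sam`.  Only the fields the
pipeline needs are retained: aligned span, strand, MAPQ, soft-clip
structure (side, length and clipped sequence) and the pairing.

Insert-size convention
----------------------
For an opposite-strand pair the signed insert size is the distance between
the 5'-most positions of the two reads, oriented as::

    insert = pos5(reverse mate) - pos5(forward mate)

A proper inward-facing pair (forward mate left of reverse mate) is
positive; an outward-facing pair straddling a circle junction is negative.
Same-strand pairs get ``pos5(mate2) - pos5(mate1)``; the sign is not
interpreted for them.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MateAlignment:
    """One aligned mate.  ``start``/``end`` delimit the aligned reference span
    (soft-clipped bases excluded), 0-based half-open."""

    scaffold: str
    start: int
    end: int
    strand: str  # '+' or '-'
    mapq: int
    read_len: int
    clip_left: int = 0
    clip_right: int = 0
    clip_left_seq: str | None = None
    clip_right_seq: str | None = None

    def __post_init__(self):
        if not (0 <= self.mapq <= 60):
            raise ValueError("MAPQ must be in [0, 60]")
        if self.end <= self.start:
            raise ValueError("aligned span must be non-empty")

    @property
    def pos5(self) -> int:
        """5'-most aligned reference position (rightmost base for '-' reads)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class ReadPair:
    qname: str
    mate1: MateAlignment
    mate2: MateAlignment

    @property
    def same_scaffold(self) -> bool:
        return self.mate1.scaffold == self.mate2.scaffold

    @property
    def read_len(self) -> int:
        return max(self.mate1.read_len, self.mate2.read_len)

    @property
    def insert_size(self) -> int:
        """Signed 5'-to-5' distance (see module docstring for the convention)."""
        m1, m2 = self.mate1, self.mate2
        if m1.strand != m2.strand:
            fwd, rev = (m1, m2) if m1.strand == "+" else (m2, m1)
            return rev.pos5 - fwd.pos5
        return m2.pos5 - m1.pos5

    @property
    def span(self) -> tuple[str, int, int]:
        """Aligned extent of the pair: [min aligned start, max aligned end)."""
        m1, m2 = self.mate1, self.mate2
        return (
            m1.scaffold,
            min(m1.start, m2.start),
            max(m1.end, m2.end),
        )


@dataclass
class AlignmentSet:
    """All usable read pairs of one sample plus library-level counts.

    ``pairs`` holds nuclear pairs only; reads mapping to references named in
    ``excluded_refs`` (spike-in plasmids, mitochondrion) are excluded from
    detection but counted in ``ref_read_counts`` / ``total_mapped_reads``.
    """

    pairs: list[ReadPair]
    scaffold_lengths: dict[str, int]
    total_mapped_reads: int = 0
    ref_read_counts: dict[str, int] = field(default_factory=dict)
    excluded_refs: tuple[str, ...] = ()
    sample_id: str | None = None

    @property
    def nuclear_mapped_reads(self) -> int:
        return sum(
            n for ref, n in self.ref_read_counts.items()
            if ref not in self.excluded_refs
        )

    def reads_on(self, refs) -> int:
        return sum(self.ref_read_counts.get(r, 0) for r in refs)

    @classmethod
    def from_sam(
        cls,
        path: str | Path,
        exclude_refs: tuple[str, ...] = (),
        sample_id: str | None = None,
    ) -> "AlignmentSet":
        """Load primary alignments from SAM/BAM and pair mates by name."""
        import pysam

        mode = "rb" if str(path).endswith(".bam") else "r"
        pending: dict[str, MateAlignment] = {}
        pairs: list[ReadPair] = []
        counts: dict[str, int] = {}
        total = 0
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
            lengths = dict(zip(fh.references, fh.lengths))
            for rec in fh.fetch(until_eof=True):
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                ref = rec.reference_name
                counts[ref] = counts.get(ref, 0) + 1
                total += 1
                if ref in exclude_refs:
                    continue
                mate = _mate_from_pysam(rec)
                if rec.query_name in pending:
                    pairs.append(ReadPair(rec.query_name, pending.pop(rec.query_name), mate))
                else:
                    pending[rec.query_name] = mate
        if pending:
            logger.warning("%d reads had no mapped mate; skipped", len(pending))
        return cls(
            pairs=pairs,
            scaffold_lengths=lengths,
            total_mapped_reads=total,
            ref_read_counts=counts,
            excluded_refs=tuple(exclude_refs),
            sample_id=sample_id,
        )

    def subsample_pairs(self, n_pairs: int, seed: int) -> "AlignmentSet":
        """Seeded without-replacement subsample keeping mates together.

        Uses a prefix of one seeded permutation so deeper subsamples nest.
        """
        if n_pairs >= len(self.pairs):
            kept = list(self.pairs)
        else:
            perm = np.random.default_rng(seed).permutation(len(self.pairs))
            kept = [self.pairs[i] for i in perm[:n_pairs]]
        return replace(self, pairs=kept)


def _mate_from_pysam(rec) -> MateAlignment:
    cig = rec.cigartuples or []
    clip_left = cig[0][1] if cig and cig[0][0] == 4 else 0
    clip_right = cig[-1][1] if cig and cig[-1][0] == 4 else 0
    seq = rec.query_sequence
    cl_seq = seq[:clip_left] if (clip_left and seq) else None
    cr_seq = seq[-clip_right:] if (clip_right and seq) else None
    read_len = rec.infer_read_length() or (len(seq) if seq else 0)
    return MateAlignment(
        scaffold=rec.reference_name,
        start=rec.reference_start,
        end=rec.reference_end,
        strand="-" if rec.is_reverse else "+",
        mapq=min(rec.mapping_quality, 60),
        read_len=read_len,
        clip_left=clip_left,
        clip_right=clip_right,
        clip_left_seq=cl_seq,
        clip_right_seq=cr_seq,
    )
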