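"""Synthesize Circle-Seq paired-end alignments for planted circles.

Alignments are written directly as SAM records (position, flags, CIGAR,
MAPQ, sequence) rather than via sequence-level read mapping: the detection
pipeline consumes alignments, and synthesizing them keeps the test bed
mapper-independent and fast.

Evidence model per circle ``[s, e)`` of length ``L``:

* concordant pairs tile the interior at the requested fold coverage;
* a Poisson number of junction-spanning pairs are emitted as discordant
  records: the fragment wraps across the circle junction, so the leftmost
  read maps on the reverse strand near the circle start and the rightmost
  on the forward strand near the circle end, giving a negative insert size
  under the 5'-most-position convention.  When the wrapped fragment arm is
  shorter than the read, the read is emitted with a soft clip whose
  sequence is the reference on the other side of the junction (the
  signature a local aligner produces for small circles);
* additional junction-crossing reads with soft clips are emitted at
  ``softclip_rate`` to feed the split-read track independently;
* spike-in plasmids receive concordant pairs proportional to
  ``copies x length``; the linear background emits concordant pairs only.

Reads overlapping a repeat interval get a low MAPQ (two-point model: 42
unique / 3 repeat-derived) so the unique-anchoring filter is exercised.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GenomeModel, PlantedCircle, _random_sequence
from .intervals import IntervalIndex

MAPQ_UNIQUE = 42
MAPQ_REPEAT = 3


@dataclass(frozen=True)
class SpikeInConfig:
    """A known-copy-number circular spike-in control."""

    name: str
    length_bp: int
    copies: int = 10_000

    def __post_init__(self):
        if self.length_bp <= 0 or self.copies < 0:
            raise ValueError("length and copies must be positive")

    @property
    def expected_mass_ng(self) -> float:
        from .quantify import spikein_mass_ng

        return spikein_mass_ng(self.length_bp, self.copies)


#: the two plasmid controls added to every Circle-Seq sample
PBR322 = SpikeInConfig("pBR322", 4361, 10_000)
PUG72 = SpikeInConfig("pUG72", 3988, 10_000)
DEFAULT_SPIKEINS = (PBR322, PUG72)


@dataclass
class SimulationStats:
    """Exact bookkeeping of emitted read pairs."""

    per_circle: dict[str, dict[str, int]] = field(default_factory=dict)
    background_pairs: int = 0
    spikein_pairs: dict[str, int] = field(default_factory=dict)

    @property
    def circle_pairs(self) -> int:
        return sum(sum(d.values()) for d in self.per_circle.values())

    @property
    def nuclear_pairs(self) -> int:
        return self.circle_pairs + self.background_pairs

    @property
    def total_pairs(self) -> int:
        return self.nuclear_pairs + sum(self.spikein_pairs.values())


class _SamBuffer:
    """Accumulates records, then writes a coordinate-sorted SAM."""

    def __init__(self, ref_names: list[str], ref_lengths: list[int]):
        self.ref_names = ref_names
        self.ref_lengths = ref_lengths
        self.tid = {n: i for i, n in enumerate(ref_names)}
        self.records: list[tuple] = []

    def add(self, qname, flag, ref, pos, mapq, cigar, mref, mpos, tlen, seq):
        self.records.append(
            (self.tid[ref], pos, qname, flag, mapq, cigar, self.tid[mref], mpos, tlen, seq)
        )

    def add_pair(
        self, qname, ref,
        fwd_pos, fwd_cigar, fwd_seq, fwd_mapq,
        rev_pos, rev_cigar, rev_seq, rev_mapq,
        proper: bool, tlen: int,
    ):
        base = 0x1 | (0x2 if proper else 0)
        self.add(qname, base | 0x20 | 0x40, ref, fwd_pos, fwd_mapq, fwd_cigar,
                 ref, rev_pos, tlen, fwd_seq)
        self.add(qname, base | 0x10 | 0x80, ref, rev_pos, rev_mapq, rev_cigar,
                 ref, fwd_pos, -tlen, rev_seq)

    def write(self, path: str | Path) -> None:
        import pysam

        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [
                    {"SN": n, "LN": ln}
                    for n, ln in zip(self.ref_names, self.ref_lengths)
                ],
            }
        )
        self.records.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for tid, pos, qname, flag, mapq, cigar, mtid, mpos, tlen, seq in self.records:
                a = pysam.AlignedSegment(header)
                a.query_name = qname
                a.flag = flag
                a.reference_id = tid
                a.reference_start = pos
                a.mapping_quality = mapq
                a.cigarstring = cigar
                a.next_reference_id = mtid
                a.next_reference_start = mpos
                a.template_length = tlen
                a.query_sequence = seq
                out.write(a)


def _frag_len(rng, frag_mean, frag_sd, lo, hi):
    f = int(round(rng.normal(frag_mean, frag_sd)))
    return int(min(max(f, lo), hi))


def simulate_alignments(
    genome: GenomeModel,
    circles: list[PlantedCircle],
    spikeins: tuple[SpikeInConfig, ...] = DEFAULT_SPIKEINS,
    *,
    depth: float = 30.0,
    read_len: int = 75,
    frag_mean: float = 300.0,
    frag_sd: float = 30.0,
    junction_pair_rate: float = 0.05,
    softclip_rate: float = 0.2,
    linear_background_depth: float = 1.0,
    min_junction_pairs: int = 0,
    min_nonoverlap: int = 5,
    spikein_depth_per_10k_copies: float = 20.0,
    seed: int = 0,
    out_sam: str | Path,
) -> SimulationStats:
    """Write a SAM file with the evidence signatures of the planted circles.

    ``depth`` is the interior fold coverage per circle (scaled by each
    circle's ``copies_per_cell``); ``junction_pair_rate`` sets the expected
    junction-spanning pairs as a fraction of interior pairs (Poisson drawn,
    floored at ``min_junction_pairs``); ``softclip_rate`` likewise controls
    extra soft-clipped junction reads.  Returns exact pair bookkeeping.
    """
    if read_len >= frag_mean:
        raise ValueError("read_len must be below frag_mean")
    if depth < 0 or linear_background_depth < 0:
        raise ValueError("depths must be >= 0")
    rng = np.random.default_rng(seed)
    lens = genome.lengths
    ref_names = list(lens) + [sp.name for sp in spikeins]
    ref_lengths = list(lens.values()) + [sp.length_bp for sp in spikeins]
    buf = _SamBuffer(ref_names, ref_lengths)
    repeat_idx = {
        scaf: IntervalIndex(genome.merged_repeats(scaf)) for scaf in lens
    }

    def mapq_for(scaf: str, start: int, end: int) -> int:
        return MAPQ_REPEAT if repeat_idx[scaf].overlaps(start, end) else MAPQ_UNIQUE

    stats = SimulationStats()
    serial = 0

    def next_name(tag: str) -> str:
        nonlocal serial
        serial += 1
        return f"{tag}.{serial:08d}"

    # ---- circles ---------------------------------------------------------
    for c in circles:
        seq = genome.sequences[c.scaffold]
        s, e, L = c.start, c.end, c.length
        eff_depth = depth * c.copies_per_cell
        n_interior = int(round(eff_depth * L / (2 * read_len))) if eff_depth > 0 else 0
        n_junction = int(rng.poisson(junction_pair_rate * n_interior))
        n_junction = max(n_junction, min_junction_pairs if eff_depth > 0 else 0)
        n_clip = int(rng.poisson(softclip_rate * n_interior))
        stats.per_circle[c.label] = {
            "interior": n_interior, "junction": n_junction, "softclip": n_clip
        }

        for _ in range(n_interior):
            f = _frag_len(rng, frag_mean, frag_sd, read_len, L)
            u = s + int(rng.integers(0, L - f + 1))
            fwd = (u, u + read_len)
            rev = (u + f - read_len, u + f)
            buf.add_pair(
                next_name("int"), c.scaffold,
                fwd[0], f"{read_len}M", seq[fwd[0]:fwd[1]], mapq_for(c.scaffold, *fwd),
                rev[0], f"{read_len}M", seq[rev[0]:rev[1]], mapq_for(c.scaffold, *rev),
                proper=True, tlen=f,
            )

        max_eff = L - (read_len + min_nonoverlap)  # keep |insert| >= read_len + 5 + 1
        for _ in range(n_junction):
            f_eff = _frag_len(rng, frag_mean, frag_sd, 2, 10**9) % L
            if not (2 <= f_eff <= max_eff):
                f_eff = int(rng.integers(2, max_eff + 1))
            a = int(rng.integers(1, f_eff))
            la_f = min(read_len, a)
            clip_f = read_len - la_f
            fwd_pos = e - a
            fwd_cigar = f"{la_f}M" + (f"{clip_f}S" if clip_f else "")
            fwd_seq = seq[fwd_pos:fwd_pos + la_f] + seq[s:s + clip_f]
            la_r = min(read_len, f_eff - a)
            clip_r = read_len - la_r
            rev_pos = s + (f_eff - a) - la_r
            rev_cigar = (f"{clip_r}S" if clip_r else "") + f"{la_r}M"
            rev_seq = seq[e - clip_r:e] + seq[rev_pos:rev_pos + la_r]
            insert = (f_eff - 1) - L  # pos5(rev) - pos5(fwd), always negative
            buf.add_pair(
                next_name("jct"), c.scaffold,
                fwd_pos, fwd_cigar, fwd_seq, mapq_for(c.scaffold, fwd_pos, fwd_pos + la_f),
                rev_pos, rev_cigar, rev_seq, mapq_for(c.scaffold, rev_pos, rev_pos + la_r),
                proper=False, tlen=insert,
            )

        for _ in range(n_clip):
            cclip = int(rng.integers(20, 41))
            la = read_len - cclip
            if rng.random() < 0.5:
                # suffix clip: alignment ends exactly at the circle end
                rd = (e - la, e)
                rd_cigar = f"{la}M{cclip}S"
                rd_seq = seq[rd[0]:rd[1]] + seq[s:s + cclip]
                mate = (max(s, e - read_len), min(e, max(s, e - read_len) + read_len))
                buf.add_pair(
                    next_name("clp"), c.scaffold,
                    rd[0], rd_cigar, rd_seq, mapq_for(c.scaffold, *rd),
                    mate[0], f"{mate[1] - mate[0]}M", seq[mate[0]:mate[1]],
                    mapq_for(c.scaffold, *mate),
                    proper=True, tlen=max(rd[1], mate[1]) - min(rd[0], mate[0]),
                )
            else:
                # prefix clip: alignment starts exactly at the circle start
                rd = (s, s + la)
                rd_cigar = f"{cclip}S{la}M"
                rd_seq = seq[e - cclip:e] + seq[rd[0]:rd[1]]
                mate = (s, min(e, s + read_len))
                # clipped read is the reverse mate here, mate forward at the start
                buf.add_pair(
                    next_name("clp"), c.scaffold,
                    mate[0], f"{mate[1] - mate[0]}M", seq[mate[0]:mate[1]],
                    mapq_for(c.scaffold, *mate),
                    rd[0], rd_cigar, rd_seq, mapq_for(c.scaffold, *rd),
                    proper=True, tlen=max(rd[1], mate[1]) - min(rd[0], mate[0]),
                )

    # ---- linear background ----------------------------------------------
    for scaf, L in lens.items():
        seq = genome.sequences[scaf]
        n_bg = int(round(linear_background_depth * L / (2 * read_len)))
        stats.background_pairs += n_bg
        for _ in range(n_bg):
            f = _frag_len(rng, frag_mean, frag_sd, 2 * read_len, L)
            u = int(rng.integers(0, L - f + 1))
            fwd = (u, u + read_len)
            rev = (u + f - read_len, u + f)
            buf.add_pair(
                next_name("bg"), scaf,
                fwd[0], f"{read_len}M", seq[fwd[0]:fwd[1]], mapq_for(scaf, *fwd),
                rev[0], f"{read_len}M", seq[rev[0]:rev[1]], mapq_for(scaf, *rev),
                proper=True, tlen=f,
            )

    # ---- spike-in plasmids ----------------------------------------------
    for sp in spikeins:
        pseq = _random_sequence(rng, sp.length_bp, 0.5)
        pdepth = spikein_depth_per_10k_copies * sp.copies / 10_000
        n_sp = int(round(pdepth * sp.length_bp / (2 * read_len)))
        stats.spikein_pairs[sp.name] = n_sp
        for _ in range(n_sp):
            f = _frag_len(rng, frag_mean, frag_sd, 2 * read_len, sp.length_bp)
            u = int(rng.integers(0, sp.length_bp - f + 1))
            buf.add_pair(
                next_name("spk"), sp.name,
                u, f"{read_len}M", pseq[u:u + read_len], MAPQ_UNIQUE,
                u + f - read_len, f"{read_len}M", pseq[u + f - read_len:u + f],
                MAPQ_UNIQUE,
                proper=True, tlen=f,
            )

    buf.write(out_sam)
    return stats
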