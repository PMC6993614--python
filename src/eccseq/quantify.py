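"""Spike-in normalization, genome counting, length histograms, saturation.

Normalization rests on two known-copy-number plasmid controls added before
rolling-circle amplification: abundant eccDNA competes with the plasmids
for polymerase, so the share of reads landing on the plasmids inversely
reflects eccDNA abundance.  The two printed formulas::

    % reads/plasmid        = plasmid-mapped reads x 100 / all mapped reads
    relative eccDNAs/sample = detected eccDNAs / (% reads/plasmid)

make per-sample counts comparable across library depths.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

AVOGADRO = 6.022e23
MOLAR_MASS_PER_BP = 650.0  # g/mol per base pair of double-stranded DNA


@dataclass
class SampleProfile:
    """Raw and derived per-sample quantities for cohort comparison."""

    sample_id: str
    total_mapped_reads: int
    plasmid_mapped_reads: int
    n_ecc_detected: int
    nuclei_count: float | None = None

    def __post_init__(self):
        if self.plasmid_mapped_reads > self.total_mapped_reads:
            raise ValueError("plasmid reads cannot exceed total reads")

    @property
    def pct_reads_per_plasmid(self) -> float:
        return plasmid_read_pct(self)

    @property
    def normalized_ecc(self) -> float:
        return normalize_ecc(self)


@dataclass(frozen=True)
class QpcrConstants:
    """Constants of the qPCR genome-counting arithmetic.

    ``ng_per_diploid_cell`` is stored as the literal published constant; it
    is *not* recomputed from ``genome_length`` x 650 g/mol (which would give
    2.374e-3 ng) — see docs/methods.md.
    """

    copies_per_genome: int = 2       # EFNB2 copies per diploid genome
    molar_mass_per_bp: float = MOLAR_MASS_PER_BP
    genome_length: float = 1.1e9     # bp, haploid
    ng_per_diploid_cell: float = 2.257e-3

    def __post_init__(self):
        if min(self.copies_per_genome, self.molar_mass_per_bp,
               self.genome_length, self.ng_per_diploid_cell) <= 0:
            raise ValueError("all constants must be strictly positive")


def plasmid_read_pct(profile: SampleProfile) -> float:
    """Percent of all mapped reads that map to the spike-in plasmids."""
    if profile.total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    return profile.plasmid_mapped_reads * 100.0 / profile.total_mapped_reads


def normalize_ecc(profile: SampleProfile) -> float:
    """Relative eccDNAs per sample: detected count / (% reads per plasmid)."""
    pct = plasmid_read_pct(profile)
    if pct <= 0:
        raise ValueError(
            "no plasmid reads: spike-in failed, sample cannot be normalized"
        )
    return profile.n_ecc_detected / pct


def spikein_mass_ng(length_bp: int, copies: int, sig_figs: int = 2) -> float:
    """Mass in ng of ``copies`` circles of ``length_bp``, to 2 significant figures."""
    if length_bp <= 0 or copies < 0:
        raise ValueError("length must be > 0 and copies >= 0")
    mass = copies * length_bp * MOLAR_MASS_PER_BP / AVOGADRO * 1e9
    if mass == 0.0:
        return 0.0
    return round(mass, -int(math.floor(math.log10(abs(mass)))) + (sig_figs - 1))


def genomes_from_mass(ng_dna: float, constants: QpcrConstants = QpcrConstants()) -> float:
    """Diploid genome equivalents in ``ng_dna`` nanograms of DNA."""
    if ng_dna < 0:
        raise ValueError("mass must be >= 0")
    return ng_dna / constants.ng_per_diploid_cell


def genomes_from_marker_copies(
    copies: float, constants: QpcrConstants = QpcrConstants()
) -> float:
    """Convert single-locus marker (EFNB2) copy counts to genome counts."""
    if copies < 0:
        raise ValueError("copies must be >= 0")
    return copies / constants.copies_per_genome


# ---------------------------------------------------------------------------
# length histogram

#: bin edges: 50-bp bins to 500 bp, 100-bp bins to 3 kb, 1-kb bins to 50 kb
LENGTH_BIN_EDGES = np.concatenate([
    np.arange(0, 500, 50),
    np.arange(500, 3000, 100),
    np.arange(3000, 50_001, 1000),
]).astype(int)


@dataclass
class BinnedLengths:
    edges: np.ndarray     # len(counts) + 1 edges; bins are [edge[i], edge[i+1])
    counts: np.ndarray
    overflow: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.overflow


def length_histogram(lengths_or_records: Iterable) -> BinnedLengths:
    """Histogram of element lengths in the standard eccDNA size bins.

    Bins are left-closed right-open; an element of exactly 50,000 bp falls
    in the last bin.  Out-of-range lengths go to an overflow bucket and are
    logged.
    """
    lengths = np.array(
        [x if isinstance(x, (int, float, np.integer)) else x.length
         for x in lengths_or_records],
        dtype=float,
    )
    edges = LENGTH_BIN_EDGES
    counts = np.zeros(len(edges) - 1, dtype=int)
    overflow = 0
    for ln in lengths:
        if ln <= 0 or ln > edges[-1]:
            overflow += 1
            continue
        if ln == edges[-1]:
            counts[-1] += 1
            continue
        counts[int(np.searchsorted(edges, ln, side="right")) - 1] += 1
    if overflow:
        logger.warning("%d lengths outside (0, %d] counted as overflow",
                       overflow, edges[-1])
    return BinnedLengths(edges=edges.copy(), counts=counts, overflow=overflow)


# ---------------------------------------------------------------------------
# saturation / decimation

#: read depths sampled for saturation analysis of a full-scale library
DEFAULT_DECIMATION_DEPTHS = tuple(
    int(m * 1e6) for m in (0.25, 0.5, 1, 2.5, 5, 7.5, 10, 12.5, 15)
)


def decimate(
    aset,
    sequences: dict[str, str],
    depths: Sequence[int],
    seed: int = 0,
    **detect_params,
) -> list[tuple[int, int]]:
    """Detected eccDNA count as a function of subsampled read depth.

    ``depths`` are mapped-read counts (ascending); pairs are subsampled
    jointly (both mates kept or dropped) using a prefix of one seeded
    permutation, and the full detection pipeline is re-run per depth.
    Depths exceeding the available reads are skipped with a warning.
    """
    from .detect import detect_eccdna

    if list(depths) != sorted(depths):
        raise ValueError("depths must be sorted ascending")
    n_avail_reads = 2 * len(aset.pairs)
    curve = []
    for depth in depths:
        if depth > n_avail_reads:
            logger.warning("depth %d exceeds available %d reads; skipped",
                           depth, n_avail_reads)
            continue
        sub = aset.subsample_pairs(depth // 2, seed=seed)
        result = detect_eccdna(sub, sequences, **detect_params)
        curve.append((depth, len(result.records)))
    return curve
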