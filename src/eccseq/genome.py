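"""Synthetic reference genomes for Circle-Seq pipeline testing.

Builds a small multi-scaffold genome with gene models (exons and UTRs),
repeat intervals of several RepeatMasker-style classes at a requested
genomic fraction, and planted circular DNA elements whose coordinates act
as the ground truth for the detector.  Everything is deterministic for a
fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .intervals import merge_intervals, union_length

# RepeatMasker-style classes with rough length ranges (bp) and default
# abundance weights; weights loosely follow an avian genome where LINEs
# dominate the (small) repetitive fraction.
REPEAT_CLASSES: dict[str, tuple[int, int]] = {
    "LINE": (500, 4000),
    "SINE": (100, 300),
    "LTR": (300, 2000),
    "DNA": (200, 1500),
    "Simple_repeat": (50, 300),
    "Low_complexity": (50, 300),
    "Satellite": (200, 1000),
}
REPEAT_CLASS_WEIGHTS: dict[str, float] = {
    "LINE": 0.45,
    "SINE": 0.05,
    "LTR": 0.20,
    "DNA": 0.10,
    "Simple_repeat": 0.08,
    "Low_complexity": 0.06,
    "Satellite": 0.06,
}

_BASES = np.frombuffer(b"ATGC", dtype=np.uint8)


@dataclass(frozen=True)
class RepeatInterval:
    scaffold: str
    start: int
    end: int
    repeat_class: str


@dataclass(frozen=True)
class Gene:
    name: str
    scaffold: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None


@dataclass(frozen=True)
class PlantedCircle:
    """Ground-truth circular element planted on the synthetic genome."""

    scaffold: str
    start: int
    end: int
    copies_per_cell: float = 1.0
    label: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("circle must have positive length")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeModel:
    """Scaffold sequences plus gene and repeat annotation."""

    sequences: dict[str, str]
    genes: list[Gene] = field(default_factory=list)
    repeats: list[RepeatInterval] = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("scaffold names must be unique")
        for g in self.genes:
            if not (0 <= g.start < g.end <= self.lengths[g.scaffold]):
                raise ValueError(f"gene {g.name} outside scaffold bounds")
        for r in self.repeats:
            if not (0 <= r.start < r.end <= self.lengths[r.scaffold]):
                raise ValueError("repeat interval outside scaffold bounds")

    # -- basic accessors ---------------------------------------------------
    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def fetch(self, scaffold: str, start: int, end: int) -> str:
        return self.sequences[scaffold][start:end]

    # -- derived annotation ------------------------------------------------
    def repeat_fraction(self) -> float:
        """Masked bases / total bases (overlaps counted once)."""
        masked = 0
        for scaf in self.sequences:
            ivs = [(r.start, r.end) for r in self.repeats if r.scaffold == scaf]
            masked += union_length(ivs)
        return masked / self.total_length

    def repeat_fraction_by_class(self) -> dict[str, float]:
        """Per-class masked fraction of the genome (class overlaps counted once)."""
        out: dict[str, float] = {}
        classes = {r.repeat_class for r in self.repeats}
        for cls in sorted(classes):
            masked = 0
            for scaf in self.sequences:
                ivs = [
                    (r.start, r.end)
                    for r in self.repeats
                    if r.scaffold == scaf and r.repeat_class == cls
                ]
                masked += union_length(ivs)
            out[cls] = masked / self.total_length
        return out

    def merged_repeats(self, scaffold: str) -> list[tuple[int, int]]:
        return merge_intervals(
            [(r.start, r.end) for r in self.repeats if r.scaffold == scaffold]
        )

    def gc_content(self, scaffold: str, start: int, end: int) -> float:
        """GC fraction of a slice; N bases are excluded from the denominator."""
        seq = self.fetch(scaffold, start, end).upper()
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt == 0:
            return math.nan
        return (seq.count("G") + seq.count("C")) / acgt

    def gc_track(self, window: int = 1000) -> dict[str, np.ndarray]:
        """Per-window GC fraction along each scaffold."""
        out = {}
        for scaf, seq in self.sequences.items():
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            is_gc = (arr == ord("G")) | (arr == ord("C"))
            n = len(arr)
            nwin = max(1, math.ceil(n / window))
            vals = np.empty(nwin)
            for i in range(nwin):
                chunk = is_gc[i * window : (i + 1) * window]
                vals[i] = chunk.mean() if len(chunk) else math.nan
            out[scaf] = vals
        return out

    # -- writers -----------------------------------------------------------
    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        """Genes, exons and UTRs as GFF3 (1-based inclusive at the writer)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.sequences.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for g in self.genes:
                cols = [g.scaffold, "eccseq", "gene", str(g.start + 1), str(g.end),
                        ".", g.strand, ".", f"ID={g.name}"]
                fh.write("\t".join(cols) + "\n")
                for i, (es, ee) in enumerate(g.exons):
                    fh.write(
                        "\t".join([g.scaffold, "eccseq", "exon", str(es + 1),
                                   str(ee), ".", g.strand, ".",
                                   f"ID={g.name}.exon{i + 1};Parent={g.name}"])
                        + "\n"
                    )
                for feat, iv in (("five_prime_UTR", g.utr5), ("three_prime_UTR", g.utr3)):
                    if iv is not None:
                        fh.write(
                            "\t".join([g.scaffold, "eccseq", feat, str(iv[0] + 1),
                                       str(iv[1]), ".", g.strand, ".",
                                       f"Parent={g.name}"])
                            + "\n"
                        )

    def write_repeats_bed(self, path: str | Path) -> None:
        """Repeat intervals as BED6 with the class label in column 4."""
        with open(path, "w") as fh:
            for r in sorted(self.repeats, key=lambda r: (r.scaffold, r.start)):
                fh.write(
                    f"{r.scaffold}\t{r.start}\t{r.end}\t{r.repeat_class}\t0\t+\n"
                )

    def feature_intervals(self) -> dict[str, dict[str, list[tuple[int, int]]]]:
        """Per-feature, per-scaffold interval lists for enrichment analyses.

        Features: ``gene``, ``exon``, ``five_prime_UTR``, ``three_prime_UTR``,
        ``repeat``.
        """
        feats: dict[str, dict[str, list[tuple[int, int]]]] = {
            k: {} for k in ("gene", "exon", "five_prime_UTR", "three_prime_UTR", "repeat")
        }
        for g in self.genes:
            feats["gene"].setdefault(g.scaffold, []).append((g.start, g.end))
            for iv in g.exons:
                feats["exon"].setdefault(g.scaffold, []).append(iv)
            if g.utr5:
                feats["five_prime_UTR"].setdefault(g.scaffold, []).append(g.utr5)
            if g.utr3:
                feats["three_prime_UTR"].setdefault(g.scaffold, []).append(g.utr3)
        for r in self.repeats:
            feats["repeat"].setdefault(r.scaffold, []).append((r.start, r.end))
        return feats


# ---------------------------------------------------------------------------
# generation


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]  # A, T, G, C
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def generate_genome(
    n_scaffolds: int,
    scaffold_length: int,
    repeat_fraction: float,
    gene_density: float,
    seed: int,
    *,
    gc: float = 0.42,
    mean_gene_length: int = 4500,
) -> GenomeModel:
    """Generate a toy annotated genome.

    Parameters
    ----------
    n_scaffolds, scaffold_length
        Number of scaffolds and length (bp) of each; lengths below 10 kb are
        rejected.
    repeat_fraction
        Requested masked fraction in [0, 1); realized fraction lands within
        +-20% relative of the request (asserted).
    gene_density
        Genes per megabase.
    seed
        Seed for all randomness.
    """
    if not (0 <= repeat_fraction < 1):
        raise ValueError("repeat_fraction must be in [0, 1)")
    if scaffold_length < 10_000:
        raise ValueError("scaffold_length must be >= 10 kb")
    if n_scaffolds < 1:
        raise ValueError("need at least one scaffold")
    rng = np.random.default_rng(seed)

    names = [f"scaffold_{i + 1}" for i in range(n_scaffolds)]
    sequences = {name: _random_sequence(rng, scaffold_length, gc) for name in names}
    total = n_scaffolds * scaffold_length

    # ---- repeats: place until the masked-base target is met --------------
    repeats: list[RepeatInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    target = repeat_fraction * total
    masked = 0
    classes = list(REPEAT_CLASSES)
    weights = np.array([REPEAT_CLASS_WEIGHTS[c] for c in classes])
    weights = weights / weights.sum()
    attempts, max_attempts = 0, 200 * max(1, int(target / 300) + 1)
    while masked < target and attempts < max_attempts:
        attempts += 1
        cls = classes[int(rng.choice(len(classes), p=weights))]
        lo, hi = REPEAT_CLASSES[cls]
        length = int(rng.integers(lo, hi + 1))
        # trim the last interval so we do not overshoot the target
        remaining = int(target - masked)
        length = max(50, min(length, remaining + 50))
        scaf = names[int(rng.integers(n_scaffolds))]
        if length >= scaffold_length:
            continue
        start = int(rng.integers(0, scaffold_length - length))
        end = start + length
        if any(s < end and start < e for s, e in occupied[scaf]):
            continue
        occupied[scaf].append((start, end))
        repeats.append(RepeatInterval(scaf, start, end, cls))
        masked += length
    if repeat_fraction > 0:
        realized = masked / total
        if abs(realized - repeat_fraction) / repeat_fraction > 0.2:
            raise RuntimeError(
                f"could not realize repeat fraction {repeat_fraction:.3f} "
                f"(got {realized:.3f})"
            )

    # ---- genes -----------------------------------------------------------
    n_genes = int(round(gene_density * total / 1e6))
    genes: list[Gene] = []
    if n_genes > 0:
        max_gene_len = 2 * mean_gene_length
        if n_genes * mean_gene_length > 0.85 * total:
            raise ValueError(
                "impossible packing: gene_density x mean gene length exceeds "
                "scaffold capacity"
            )
        placed: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
        per_scaffold = np.full(n_scaffolds, scaffold_length, dtype=float)
        per_scaffold /= per_scaffold.sum()
        gi = 0
        tries = 0
        while gi < n_genes:
            tries += 1
            if tries > 200 * n_genes:
                raise RuntimeError("gene placement failed; density too high")
            length = int(
                np.clip(rng.normal(mean_gene_length, mean_gene_length / 3),
                        1000, max_gene_len)
            )
            scaf = names[int(rng.choice(n_scaffolds, p=per_scaffold))]
            if length >= scaffold_length:
                continue
            start = int(rng.integers(0, scaffold_length - length))
            end = start + length
            if any(s < end and start < e for s, e in placed[scaf]):
                continue
            placed[scaf].append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                _build_gene(rng, f"gene_{gi + 1:04d}", scaf, start, end, strand)
            )
            gi += 1
        genes.sort(key=lambda g: (g.scaffold, g.start))

    return GenomeModel(sequences=sequences, genes=genes, repeats=repeats)


def _build_gene(
    rng: np.random.Generator, name: str, scaf: str, start: int, end: int, strand: str
) -> Gene:
    """Lay out exons inside [start, end) with UTRs at the transcript ends."""
    length = end - start
    n_ex = int(rng.integers(2, 7))
    exon_lens = rng.integers(100, 401, size=n_ex)
    while exon_lens.sum() > 0.8 * length and n_ex > 1:
        n_ex -= 1
        exon_lens = exon_lens[:n_ex]
    slack = length - int(exon_lens.sum())
    # distribute the intron slack; first exon starts at `start`, last ends at `end`
    if n_ex > 1:
        cuts = np.sort(rng.integers(0, slack + 1, size=n_ex - 1))
        gaps = np.diff(np.concatenate([[0], cuts]))
        tail = slack - int(cuts[-1])
    else:
        gaps = np.array([], dtype=int)
        tail = slack
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        if i < n_ex - 1:
            pos += int(el) + int(gaps[i])
    # stretch the last exon to close the gene
    last_s, last_e = exons[-1]
    exons[-1] = (last_s, last_e + tail) if n_ex == 1 else (last_s + 0, end)
    exons[-1] = (exons[-1][0], end)
    utr_a = (start, min(start + int(rng.integers(50, 201)), exons[0][1]))
    utr_b = (max(exons[-1][0], end - int(rng.integers(50, 201))), end)
    utr5, utr3 = (utr_a, utr_b) if strand == "+" else (utr_b, utr_a)
    return Gene(name, scaf, start, end, strand, tuple(exons), utr5, utr3)


# ---------------------------------------------------------------------------
# circle planting

SizeSampler = "callable | tuple"


def resolve_size_sampler(spec) -> "callable":
    """Turn a distribution spec into ``f(rng) -> int``.

    Accepted specs: a callable, ``("fixed", size)``, ``("uniform", lo, hi)``,
    or ``("lognormal", mode, sigma)`` where the mode is in bp.
    """
    if callable(spec):
        return spec
    kind = spec[0]
    if kind == "fixed":
        size = int(spec[1])
        return lambda rng: size
    if kind == "uniform":
        lo, hi = int(spec[1]), int(spec[2])
        return lambda rng: int(rng.integers(lo, hi + 1))
    if kind == "lognormal":
        mode, sigma = float(spec[1]), float(spec[2])
        mu = math.log(mode) + sigma**2  # mode = exp(mu - sigma^2)
        return lambda rng: int(round(rng.lognormal(mu, sigma)))
    raise ValueError(f"unknown size sampler spec: {spec!r}")


#: default size distribution: log-normal with mode ~200 bp, the typical
#: eccDNA size observed in somatic tissues (tail thinner than real data;
#: pass an explicit sampler to study multi-kb elements)
DEFAULT_SIZE_SAMPLER = ("lognormal", 200, 0.6)


def plant_circles(
    genome: GenomeModel,
    n: int,
    size_sampler=DEFAULT_SIZE_SAMPLER,
    seed: int = 0,
    *,
    min_size: int = 100,
    max_size: int = 50_000,
    avoid_repeats: bool = False,
    edge_margin: int = 500,
) -> list[PlantedCircle]:
    """Place ``n`` non-overlapping circular elements on the genome.

    Sizes come from ``size_sampler`` clipped to ``[min_size, max_size]``;
    placement is uniform over valid positions, weighted by scaffold length.
    ``avoid_repeats`` rejects placements overlapping repeat intervals (used to
    benchmark detection in uniquely mappable space).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    sampler = resolve_size_sampler(size_sampler)
    names = list(genome.sequences)
    lens = genome.lengths
    weights = np.array([lens[s] for s in names], dtype=float)
    weights /= weights.sum()
    repeat_ivs = {s: genome.merged_repeats(s) for s in names}
    placed: dict[str, list[tuple[int, int]]] = {s: [] for s in names}
    circles: list[PlantedCircle] = []
    attempts = 0
    while len(circles) < n:
        attempts += 1
        if attempts > 500 * n:
            raise RuntimeError(
                f"could not place {n} circles (placed {len(circles)}); "
                "genome too small or constraints too tight"
            )
        # out-of-range sizes are rejected (not clipped) so the realized
        # distribution keeps its shape without boundary atoms
        size = int(sampler(rng))
        if not (min_size <= size <= max_size):
            continue
        scaf = names[int(rng.choice(len(names), p=weights))]
        lo, hi = edge_margin, lens[scaf] - size - edge_margin
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        end = start + size
        if any(s < end and start < e for s, e in placed[scaf]):
            continue
        if avoid_repeats and any(s < end and start < e for s, e in repeat_ivs[scaf]):
            continue
        placed[scaf].append((start, end))
        circles.append(
            PlantedCircle(scaf, start, end, 1.0, f"circle_{len(circles) + 1:04d}")
        )
    circles.sort(key=lambda c: (c.scaffold, c.start))
    return circles


def write_truth_bed(circles: list[PlantedCircle], path: str | Path) -> None:
    """Ground-truth circles as BED6 (label in column 4, copies in column 5)."""
    with open(path, "w") as fh:
        for c in circles:
            fh.write(
                f"{c.scaffold}\t{c.start}\t{c.end}\t{c.label}\t"
                f"{c.copies_per_cell:g}\t+\n"
            )


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Minimal BED3+ reader returning (scaffold, start, end) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out
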