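"""Genomic-feature annotation, enrichment and repeat-class quantification.

Enrichment compares detected circles against random region sets drawn with
the same size multiset (ten sets by default).  Overlap with an annotated
feature requires a minimum of 10 bp with a single annotated element, and
results are split into small (<1 kb) and larger (>=1 kb) size classes.
Significance uses a Pearson chi-square on the 2x2 table of overlapping vs
non-overlapping regions, observed vs (pooled) random.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import Gene, GenomeModel
from .intervals import IntervalIndex, overlap_length, reciprocal_overlap

Region = tuple[str, int, int]


def _as_region(x) -> Region:
    if isinstance(x, tuple):
        return x[:3]
    return (x.scaffold, x.start, x.end)


class FeatureCategory(Enum):
    """Mutually exclusive gene-context categories of an eccDNA element."""

    CONTAINS_ONE_GENE = "contains_one_gene"
    CONTAINS_COMPLETE_GENE_OR_MANY = "contains_complete_gene_or_many"
    PARTIAL_GENE_OVERLAP = "partial_gene_overlap"
    INTERGENIC = "intergenic"


def categorize(
    record, genes: Sequence[Gene] | Sequence[Region], min_reciprocal: float = 0.10
) -> FeatureCategory:
    """Assign one gene-context category to a record.

    Decision order: full containment of exactly one gene -> category 1; of
    two or more genes -> category 2; otherwise any gene with >= 10%
    reciprocal overlap -> category 3; else intergenic.
    """
    scaf, start, end = _as_region(record)
    contained = 0
    partial = False
    for g in genes:
        gs = _as_region(g) if not isinstance(g, Gene) else (g.scaffold, g.start, g.end)
        if gs[0] != scaf:
            continue
        if start <= gs[1] and gs[2] <= end:
            contained += 1
        elif overlap_length((start, end), gs[1:]) > 0:
            if reciprocal_overlap((start, end), gs[1:]) >= min_reciprocal:
                partial = True
    if contained == 1:
        return FeatureCategory.CONTAINS_ONE_GENE
    if contained >= 2:
        return FeatureCategory.CONTAINS_COMPLETE_GENE_OR_MANY
    if partial:
        return FeatureCategory.PARTIAL_GENE_OVERLAP
    return FeatureCategory.INTERGENIC


def categorize_all(records, genes) -> dict[FeatureCategory, int]:
    """Category counts over a record set (a partition: counts sum to n)."""
    out = {cat: 0 for cat in FeatureCategory}
    for r in records:
        out[categorize(r, genes)] += 1
    return out


# ---------------------------------------------------------------------------
# random region sets


def sample_random_regions(
    genome: GenomeModel | Mapping[str, int],
    sizes: Sequence[int],
    n_sets: int = 10,
    seed: int = 0,
) -> list[list[Region]]:
    """Draw ``n_sets`` random region sets with exactly the given size multiset.

    Placement is uniform over valid start positions, scaffolds weighted by
    the number of valid positions for each size.  Regions may overlap each
    other (placement with replacement).
    """
    lengths = genome.lengths if isinstance(genome, GenomeModel) else dict(genome)
    names = list(lengths)
    lens = np.array([lengths[n] for n in names], dtype=np.int64)
    rng = np.random.default_rng(seed)
    sets: list[list[Region]] = []
    for _ in range(n_sets):
        regions: list[Region] = []
        for size in sizes:
            valid = lens - size + 1
            valid = np.where(valid > 0, valid, 0)
            if valid.sum() == 0:
                raise ValueError(f"size {size} exceeds every scaffold")
            p = valid / valid.sum()
            si = int(rng.choice(len(names), p=p))
            start = int(rng.integers(0, valid[si]))
            regions.append((names[si], start, start + size))
        sets.append(regions)
    return sets


# ---------------------------------------------------------------------------
# feature enrichment


@dataclass
class EnrichmentResult:
    feature: str
    size_class: str
    n_observed: int
    observed_count: int
    expected_counts: list[int]      # one per random set
    fold: float
    chi2_stat: float
    p_value: float
    per_set_p: list[float]


def _feature_indexes(annotation) -> dict[str, dict[str, IntervalIndex]]:
    out = {}
    for feat, per_scaf in annotation.items():
        out[feat] = {scaf: IntervalIndex(ivs) for scaf, ivs in per_scaf.items()}
    return out


def _count_hits(regions: Sequence[Region], idx: dict[str, IntervalIndex],
                min_overlap: int) -> int:
    n = 0
    for scaf, s, e in regions:
        ii = idx.get(scaf)
        if ii is not None and ii.max_overlap(s, e) >= min_overlap:
            n += 1
    return n


def _chi2_2x2(a_hit, a_n, b_hit, b_n) -> tuple[float, float]:
    table = np.array([[a_hit, a_n - a_hit], [b_hit, b_n - b_hit]], dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 0.0, 1.0
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def feature_enrichment(
    observed: Sequence,
    random_sets: Sequence[Sequence[Region]],
    annotation: Mapping[str, Mapping[str, list[tuple[int, int]]]],
    min_overlap: int = 10,
    size_split: int = 1000,
) -> list[EnrichmentResult]:
    """Observed-vs-random feature overlap per feature and size class.

    ``annotation`` maps feature name -> scaffold -> interval list (as from
    :meth:`GenomeModel.feature_intervals`).  The headline p-value compares
    observed against the pooled random sets; per-set p-values are also
    emitted.  Fold is the observed overlap proportion over the mean random
    proportion.
    """
    obs = [_as_region(r) for r in observed]
    if not obs:
        raise ValueError("empty observed set")
    if not random_sets:
        raise ValueError("need at least one random set")
    idx = _feature_indexes(annotation)

    def split(regions):
        small = [r for r in regions if r[2] - r[1] < size_split]
        large = [r for r in regions if r[2] - r[1] >= size_split]
        return {"lt1kb": small, "ge1kb": large}

    obs_by_class = split(obs)
    rand_by_class = [split(rs) for rs in random_sets]
    results = []
    for feat in annotation:
        for size_class in ("lt1kb", "ge1kb"):
            obs_regions = obs_by_class[size_class]
            if not obs_regions:
                continue
            n_obs = len(obs_regions)
            obs_hit = _count_hits(obs_regions, idx[feat], min_overlap)
            set_hits, set_ns, per_set_p = [], [], []
            for rc in rand_by_class:
                regions = rc[size_class]
                hit = _count_hits(regions, idx[feat], min_overlap)
                set_hits.append(hit)
                set_ns.append(len(regions))
                _, p = _chi2_2x2(obs_hit, n_obs, hit, max(len(regions), 1))
                per_set_p.append(p)
            pooled_hit, pooled_n = sum(set_hits), sum(set_ns)
            chi2, p = _chi2_2x2(obs_hit, n_obs, pooled_hit, max(pooled_n, 1))
            props = [h / n for h, n in zip(set_hits, set_ns) if n > 0]
            mean_rand = float(np.mean(props)) if props else math.nan
            fold = (obs_hit / n_obs) / mean_rand if mean_rand > 0 else math.inf
            results.append(
                EnrichmentResult(
                    feature=feat, size_class=size_class, n_observed=n_obs,
                    observed_count=obs_hit, expected_counts=set_hits,
                    fold=fold, chi2_stat=chi2, p_value=p, per_set_p=per_set_p,
                )
            )
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "feature": r.feature, "size_class": r.size_class,
            "n_observed": r.n_observed, "observed": r.observed_count,
            "fold": r.fold, "chi2": r.chi2_stat, "p": r.p_value,
        }
        for i, c in enumerate(r.expected_counts, 1):
            row[f"expected_{i}"] = c
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GC comparison


def gc_comparison(
    observed: Sequence,
    random_sets: Sequence[Sequence[Region]],
    genome: GenomeModel,
) -> tuple[float, float]:
    """Two-sided Student's t-test of per-region GC, observed vs pooled random.

    Regions without defined sequence (all N) are excluded.
    """
    def gcs(regions):
        vals = []
        for scaf, s, e in (_as_region(r) for r in regions):
            gc = genome.gc_content(scaf, s, e)
            if not math.isnan(gc):
                vals.append(gc)
        return vals

    obs_gc = gcs(observed)
    rand_gc = []
    for rs in random_sets:
        rand_gc.extend(gcs(rs))
    t, p = sps.ttest_ind(obs_gc, rand_gc, equal_var=True)
    return float(t), float(p)


def gc_of_sequence(seq: str) -> float:
    """GC fraction of a sequence (N excluded from the denominator)."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    return (seq.count("G") + seq.count("C")) / acgt if acgt else math.nan


# ---------------------------------------------------------------------------
# repeat-class profile


@dataclass
class RepeatClassProfile:
    """Per-class read counts with library-size and genome-fraction normalization."""

    reads_on_class: dict[str, int]
    library_norm: dict[str, float]       # reads on class / total nuclear reads
    obs_exp_ratio: dict[str, float]      # library_norm / genomic class fraction
    total_reads: int
    overall_repeat_share: float          # fraction of reads on any repeat
    overall_expected: float              # genomic repeat fraction


def repeat_profile(
    read_intervals: Iterable[Region],
    repeats_by_class: Mapping[str, Mapping[str, list[tuple[int, int]]]],
    genome_repeat_fractions: Mapping[str, float],
    overall_fraction: float | None = None,
) -> RepeatClassProfile:
    """Count reads on each repeat class and normalize twice.

    A read is assigned to a class when its aligned interval overlaps any
    interval of that class by >= 1 bp; reads overlapping several classes
    count once per class.  First normalization divides by the total nuclear
    read count (library size); second divides by the genomic fraction of
    the class.  ``genome_repeat_fractions`` are proportions in [0, 1].
    """
    reads = [_as_region(r) for r in read_intervals]
    classes = sorted(repeats_by_class)
    for cls in classes:
        if cls not in genome_repeat_fractions:
            raise KeyError(f"class {cls!r} missing from the fraction table")
    idx = {
        cls: {scaf: IntervalIndex(ivs) for scaf, ivs in per_scaf.items()}
        for cls, per_scaf in repeats_by_class.items()
    }
    any_idx: dict[str, IntervalIndex] = {}
    all_by_scaf: dict[str, list[tuple[int, int]]] = {}
    for per_scaf in repeats_by_class.values():
        for scaf, ivs in per_scaf.items():
            all_by_scaf.setdefault(scaf, []).extend(ivs)
    any_idx = {scaf: IntervalIndex(ivs) for scaf, ivs in all_by_scaf.items()}

    counts = {cls: 0 for cls in classes}
    on_any = 0
    for scaf, s, e in reads:
        ai = any_idx.get(scaf)
        if ai is None or not ai.overlaps(s, e):
            continue
        on_any += 1
        for cls in classes:
            ii = idx[cls].get(scaf)
            if ii is not None and ii.overlaps(s, e):
                counts[cls] += 1
    total = len(reads)
    lib = {cls: counts[cls] / total if total else math.nan for cls in classes}
    ratio = {}
    for cls in classes:
        frac = genome_repeat_fractions[cls]
        ratio[cls] = lib[cls] / frac if frac > 0 else math.inf if lib[cls] > 0 else math.nan
    if overall_fraction is None:
        overall_fraction = float(sum(genome_repeat_fractions[c] for c in classes))
    return RepeatClassProfile(
        reads_on_class=counts,
        library_norm=lib,
        obs_exp_ratio=ratio,
        total_reads=total,
        overall_repeat_share=on_any / total if total else math.nan,
        overall_expected=overall_fraction,
    )


def repeats_by_class_from_intervals(
    repeats,
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """Group RepeatInterval records (or (scaf, start, end, class) rows) by class."""
    out: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for r in repeats:
        scaf, s, e, cls = (
            (r.scaffold, r.start, r.end, r.repeat_class)
            if hasattr(r, "repeat_class") else (r[0], r[1], r[2], r[3])
        )
        out.setdefault(cls, {}).setdefault(scaf, []).append((s, e))
    return out


# ---------------------------------------------------------------------------
# per-gene recurrence and replicate overlap


def ecc_per_gene(
    records_by_sample: Mapping[str, Sequence],
    genes: Sequence[Gene],
    groups: Mapping[str, str] | None = None,
    min_overlap: int = 10,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Distinct eccDNA records overlapping each gene, per sample and per group.

    Returns a per-gene table (one row per gene: length, per-sample counts,
    total, per-group means) and the Pearson correlation (r, p) of total
    count vs gene length.
    """
    samples = list(records_by_sample)
    rows = []
    for g in genes:
        row: dict = {"gene": g.name, "scaffold": g.scaffold,
                     "length": g.end - g.start}
        total = 0
        for sid in samples:
            n = 0
            for r in records_by_sample[sid]:
                scaf, s, e = _as_region(r)
                if scaf == g.scaffold and overlap_length((s, e), (g.start, g.end)) >= min_overlap:
                    n += 1
            row[sid] = n
            total += n
        row["total"] = total
        rows.append(row)
    df = pd.DataFrame(rows)
    if groups:
        for grp in sorted(set(groups.values())):
            cols = [s for s in samples if groups.get(s) == grp]
            df[f"mean_{grp}"] = df[cols].mean(axis=1) if cols else math.nan
    if len(df) >= 3 and df["total"].nunique() > 1 and df["length"].nunique() > 1:
        r, p = sps.pearsonr(df["length"], df["total"])
        corr = (float(r), float(p))
    else:
        corr = (math.nan, math.nan)
    return df, corr


def set_overlap(
    a: Sequence, b: Sequence, min_reciprocal: float = 0.0
) -> tuple[float, float]:
    """Percent of records in ``a`` overlapped by ``b`` and vice versa.

    A record is shared when any record of the other set overlaps it by at
    least 1 bp (or at ``min_reciprocal`` reciprocal overlap if set).
    """
    ra = [_as_region(x) for x in a]
    rb = [_as_region(x) for x in b]
    if not ra or not rb:
        raise ValueError("both sets must be non-empty")

    def pct_shared(xs, ys):
        by_scaf: dict[str, list[tuple[int, int]]] = {}
        for scaf, s, e in ys:
            by_scaf.setdefault(scaf, []).append((s, e))
        idx = {scaf: IntervalIndex(ivs) for scaf, ivs in by_scaf.items()}
        shared = 0
        for scaf, s, e in xs:
            ii = idx.get(scaf)
            if ii is None:
                continue
            if min_reciprocal <= 0:
                if ii.overlaps(s, e):
                    shared += 1
            else:
                hit = any(
                    reciprocal_overlap((s, e), (int(ys_s), int(ys_e))) >= min_reciprocal
                    for ys_s, ys_e in zip(ii.starts, ii.ends)
                    if min(int(ys_e), e) > max(int(ys_s), s)
                )
                if hit:
                    shared += 1
        return shared / len(xs) * 100.0

    return pct_shared(ra, rb), pct_shared(rb, ra)
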