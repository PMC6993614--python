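"""Detection: pair classification, region building, split junctions, filter."""
from __future__ import annotations

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eccseq.alignments import AlignmentSet, MateAlignment, ReadPair
from eccseq.detect import (
    CIRCLE_DISCORDANT,
    CONCORDANT,
    UNUSABLE,
    CandidateRegion,
    CoverageIndex,
    EccDNARecord,
    assemble_candidates,
    build_regions,
    classify_pair,
    detect_eccdna,
    detect_split_junctions,
    filter_high_confidence,
    pool_and_merge,
    score_candidate,
)
from eccseq.genome import _random_sequence
from eccseq.intervals import merge_intervals, reciprocal_overlap

READ = 75


def mate(scaf, start, strand, mapq=42, read_len=READ, **kw):
    return MateAlignment(scaf, start, start + read_len, strand, mapq, read_len, **kw)


def outward_pair(scaf, s, e, mapq=42, qname="q"):
    """Junction-signature pair spanning [s, e): reverse mate left, forward right."""
    return ReadPair(qname, mate(scaf, e - READ, "+", mapq), mate(scaf, s, "-", mapq))


class TestClassifyPair:
    def test_orientation_sign_truth_table(self):
        """Enumerate strand combinations x geometric order: only the
        outward opposite-strand pair with a long negative insert is circle
        evidence; inward opposite-strand pairs are concordant."""
        cases = []
        for strands in ("++", "--", "+-", "-+"):
            for left_first in (True, False):
                a = mate("s", 1000, strands[0])
                b = mate("s", 1500, strands[1])
                pair = ReadPair("q", a, b) if left_first else ReadPair("q", b, a)
                cases.append((strands, pair))
        for strands, pair in cases:
            got = classify_pair(pair)
            if strands in ("++", "--"):
                assert got == UNUSABLE
            else:
                # the reverse mate sitting left means outward -> negative insert
                rev_mate = pair.mate1 if pair.mate1.strand == "-" else pair.mate2
                fwd_mate = pair.mate2 if pair.mate1.strand == "-" else pair.mate1
                expected = (
                    CIRCLE_DISCORDANT if rev_mate.pos5 < fwd_mate.pos5 else CONCORDANT
                )
                assert got == expected, (strands, pair)
        # exactly one geometry passes, regardless of mate order in the record
        assert sum(
            classify_pair(p) == CIRCLE_DISCORDANT for _, p in cases
        ) == 2

    def test_insert_magnitude_threshold_is_read_len_plus_five(self):
        def with_gap(gap):
            # reverse mate 5' at x, forward mate 5' at x + gap
            rev = mate("s", 1000 - READ + 1, "-")   # pos5 = 1000
            fwd = mate("s", 1000 + gap, "+")        # pos5 = 1000 + gap
            return ReadPair("q", fwd, rev)

        assert with_gap(80).insert_size == -80
        assert classify_pair(with_gap(79)) == UNUSABLE   # 79 < 75 + 5
        assert classify_pair(with_gap(80)) == CIRCLE_DISCORDANT

    def test_mapq_below_threshold_is_unusable(self):
        good = outward_pair("s", 1000, 1500)
        assert classify_pair(good) == CIRCLE_DISCORDANT
        bad = ReadPair("q", good.mate1,
                       mate("s", 1000, "-", mapq=9))
        assert classify_pair(bad) == UNUSABLE
        assert classify_pair(bad, min_mapq=9) == CIRCLE_DISCORDANT

    def test_cross_scaffold_pair_never_circle_evidence(self):
        pair = ReadPair("q", mate("s1", 100, "+"), mate("s2", 900, "-"))
        assert classify_pair(pair) == UNUSABLE


class TestBuildRegions:
    def test_overlapping_pairs_merge_with_counts(self):
        pairs = [outward_pair("s", 1000, 1600, qname="a"),
                 outward_pair("s", 1100, 1700, qname="b")]
        regions = build_regions(pairs)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.n_discordant_pairs) == (1000, 1700, 2)
        assert r.evidence_sources == {"discordant"}

    def test_disjoint_pairs_stay_separate(self):
        pairs = [outward_pair("s", 0, 500, qname="a"),
                 outward_pair("s", 600, 900, qname="b")]
        assert len(build_regions(pairs)) == 2

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(
        st.tuples(st.integers(0, 5000), st.integers(300, 900)),
        min_size=1, max_size=10,
    ))
    def test_matches_interval_union_oracle(self, raw):
        spans = [(s, s + ln) for s, ln in raw]
        pairs = [outward_pair("s", s, e, qname=f"q{i}")
                 for i, (s, e) in enumerate(spans)]
        regions = build_regions(pairs)
        assert [(r.start, r.end) for r in regions] == merge_intervals(spans)
        assert sum(r.n_discordant_pairs for r in regions) == len(pairs)

    def test_empty_input_gives_empty_list(self):
        assert build_regions([]) == []


@pytest.fixture(scope="module")
def seq():
    return _random_sequence(np.random.default_rng(17), 10_000, 0.5)


class TestSplitJunctions:
    def _clipped_pair(self, seq, side, junction=(2000, 2800), clip=20, mutate=0):
        a, b = junction
        clip_seq = seq[a:a + clip] if side == "right" else seq[b - clip:b]
        if mutate:
            alt = {"A": "C", "C": "G", "G": "T", "T": "A"}
            clip_seq = "".join(
                alt[c] if i < mutate else c for i, c in enumerate(clip_seq)
            )
        la = READ - clip
        if side == "right":
            clipped = MateAlignment("s", b - la, b, "+", 42, READ,
                                    clip_right=clip, clip_right_seq=clip_seq)
        else:
            clipped = MateAlignment("s", a, a + la, "-", 42, READ,
                                    clip_left=clip, clip_left_seq=clip_seq)
        other = mate("s", (a + b) // 2, "-" if side == "right" else "+")
        return ReadPair("q", clipped, other)

    @pytest.mark.parametrize("side", ["right", "left"])
    def test_junction_recovered_exactly(self, seq, side):
        pair = self._clipped_pair(seq, side)
        juncs = detect_split_junctions([pair], {"s": seq})
        assert [(j.left, j.right, j.support) for j in juncs] == [(2000, 2800, 1)]

    def test_support_counts_distinct_reads(self, seq):
        pairs = [self._clipped_pair(seq, "right"), self._clipped_pair(seq, "left")]
        pairs = [ReadPair(f"q{i}", p.mate1, p.mate2) for i, p in enumerate(pairs)]
        juncs = detect_split_junctions(pairs, {"s": seq})
        assert [(j.left, j.right, j.support) for j in juncs] == [(2000, 2800, 2)]

    def test_one_mismatch_tolerated_two_rejected(self, seq):
        one = self._clipped_pair(seq, "right", mutate=1)
        two = self._clipped_pair(seq, "right", mutate=2)
        assert detect_split_junctions([one], {"s": seq}) != []
        assert detect_split_junctions([two], {"s": seq}) == []

    def test_clip_below_min_clip_not_reported(self, seq):
        short = self._clipped_pair(seq, "right", clip=10)
        assert detect_split_junctions([short], {"s": seq}, min_clip=15) == []

    def test_linear_only_simulation_yields_no_junctions(self, linear_bundle):
        juncs = detect_split_junctions(
            linear_bundle.aset, linear_bundle.genome.sequences
        )
        assert juncs == []


class TestAssembleCandidates:
    def region(self, s, e, n=2):
        return CandidateRegion("s", s, e, n_discordant_pairs=n,
                               evidence_sources=frozenset({"discordant"}))

    def test_region_and_junction_merge_with_both_sources(self):
        from eccseq.detect import Junction

        cands = assemble_candidates(
            [self.region(1000, 1700)], [Junction("s", 1005, 1695, 3)]
        )
        assert len(cands) == 1
        c = cands[0]
        assert c.evidence_sources == {"discordant", "split"}
        assert (c.n_discordant_pairs, c.n_split_reads) == (2, 3)

    def test_junction_only_candidate(self):
        from eccseq.detect import Junction

        cands = assemble_candidates([], [Junction("s", 100, 400, 1)])
        assert [(c.start, c.end) for c in cands] == [(100, 400)]
        assert cands[0].evidence_sources == {"split"}

    def test_disjoint_region_and_junction_stay_separate(self):
        from eccseq.detect import Junction

        cands = assemble_candidates(
            [self.region(0, 500)], [Junction("s", 600, 900, 1)]
        )
        assert [(c.start, c.end) for c in cands] == [(0, 500), (600, 900)]


class TestScoring:
    def test_fractions_match_per_base_pileup_oracle(self):
        rng = np.random.default_rng(23)
        pairs = []
        for i in range(40):
            start = int(rng.integers(0, 1900))
            mapq = int(rng.choice([3, 42]))
            pairs.append(ReadPair(
                f"q{i}",
                mate("s", start, "+", mapq=mapq, read_len=50),
                mate("s", min(start + 120, 1950), "-", mapq=mapq, read_len=50),
            ))
        cov = CoverageIndex(pairs, {"s": 2000})
        covered = np.zeros(2000, bool)
        unique = np.zeros(2000, bool)
        for p in pairs:
            for m in (p.mate1, p.mate2):
                covered[m.start:m.end] = True
                if m.mapq >= 10:
                    unique[m.start:m.end] = True
        for qs, qe in [(0, 100), (500, 900), (1234, 1357), (0, 2000)]:
            c = CandidateRegion("s", qs, qe, evidence_sources=frozenset({"discordant"}))
            scored = score_candidate(c, cov)
            assert scored.coverage_fraction == covered[qs:qe].mean()
            assert scored.unique_fraction == unique[qs:qe].mean()

    def test_region_of_all_repeat_reads_has_zero_unique_fraction(self):
        pairs = [ReadPair("q", mate("s", 100, "+", mapq=3),
                          mate("s", 150, "-", mapq=3))]
        c = CandidateRegion("s", 100, 225, evidence_sources=frozenset({"discordant"}))
        scored = score_candidate(c, CoverageIndex(pairs, {"s": 1000}))
        assert scored.coverage_fraction == 1.0
        assert scored.unique_fraction == 0.0

    def test_zero_length_region_rejected(self):
        with pytest.raises(ValueError):
            CandidateRegion("s", 100, 100)


class TestHighConfidenceFilter:
    def cand(self, coverage, n_disc, unique, sources=("discordant",)):
        return CandidateRegion(
            "s", 0, 1000, n_discordant_pairs=n_disc,
            evidence_sources=frozenset(sources),
            coverage_fraction=coverage, unique_fraction=unique,
        )

    @pytest.mark.parametrize(
        "coverage,n_disc,unique,sources,kept",
        [
            (0.85, 2, 0.50, ("discordant",), True),
            (0.79, 9, 0.90, ("discordant",), False),   # coverage boundary
            (0.80, 2, 0.10, ("discordant",), True),    # all inclusive
            (0.95, 1, 0.50, ("discordant",), False),   # one pair, one track
            (0.95, 1, 0.50, ("discordant", "split"), True),  # two approaches
            (0.90, 0, 0.50, ("split",), False),        # split alone
            (0.90, 2, 0.09, ("discordant",), False),   # unique boundary
            (0.80, 2, 0.10, ("discordant", "split"), True),
        ],
    )
    def test_threshold_sides(self, coverage, n_disc, unique, sources, kept):
        out = filter_high_confidence([self.cand(coverage, n_disc, unique, sources)])
        assert (len(out) == 1) == kept

    def test_unscored_candidate_raises(self):
        c = CandidateRegion("s", 0, 100, evidence_sources=frozenset({"split"}))
        with pytest.raises(ValueError):
            filter_high_confidence([c])

    def test_size_class_boundary_at_1kb(self):
        def rec(length):
            return EccDNARecord("s", 0, length, 2, 0,
                                frozenset({"discordant"}), 1.0, 1.0)

        assert rec(999).size_class == "lt1kb"
        assert rec(1000).size_class == "ge1kb"


class TestPipeline:
    def test_recall_and_reciprocal_overlap_on_simulation(self, sim_bundle):
        res = detect_eccdna(sim_bundle.aset, sim_bundle.genome.sequences)
        for c in sim_bundle.circles:
            assert any(
                r.scaffold == c.scaffold
                and reciprocal_overlap(r.interval, (c.start, c.end)) >= 0.8
                for r in res.records
            ), c.label
        truth = [(c.scaffold, c.start, c.end) for c in sim_bundle.circles]
        for r in res.records:
            assert any(
                t[0] == r.scaffold and t[1] < r.end and r.start < t[2]
                for t in truth
            )

    def test_no_calls_on_linear_only_library(self, linear_bundle):
        res = detect_eccdna(linear_bundle.aset, linear_bundle.genome.sequences)
        assert res.records == []

    def test_output_independent_of_record_order(self, sim_bundle):
        res_a = detect_eccdna(sim_bundle.aset, sim_bundle.genome.sequences)
        shuffled = list(sim_bundle.aset.pairs)
        random.Random(99).shuffle(shuffled)
        aset_b = AlignmentSet(
            pairs=shuffled,
            scaffold_lengths=sim_bundle.aset.scaffold_lengths,
            sample_id=sim_bundle.aset.sample_id,
        )
        res_b = detect_eccdna(aset_b, sim_bundle.genome.sequences)
        assert res_a.records == res_b.records

    def test_raising_any_threshold_never_adds_calls(self, sim_bundle):
        res = detect_eccdna(sim_bundle.aset, sim_bundle.genome.sequences)
        base = len(filter_high_confidence(res.candidates))
        for kwargs in (
            {"min_coverage": 0.9}, {"min_coverage": 0.999},
            {"min_discordant": 5}, {"min_discordant": 100},
            {"min_unique": 0.5}, {"min_unique": 0.99},
        ):
            stricter = len(filter_high_confidence(res.candidates, **kwargs))
            assert stricter <= base


class TestPoolAndMerge:
    def rec(self, scaf, s, e, sample):
        return EccDNARecord(scaf, s, e, 2, 0, frozenset({"discordant"}),
                            1.0, 1.0, sample)

    def test_same_interval_across_samples_collapses(self):
        samples = [[self.rec("s", 100, 400, f"p{i}")] for i in range(3)]
        merged = pool_and_merge(samples)
        assert len(merged) == 1
        assert merged[0].sample_ids == ("p0", "p1", "p2")
        assert merged[0].n_records == 3

    def test_touching_intervals_merge(self):
        merged = pool_and_merge([[self.rec("s", 0, 100, "a")],
                                 [self.rec("s", 100, 200, "b")]])
        assert [(m.start, m.end) for m in merged] == [(0, 200)]

    def test_empty_input(self):
        assert pool_and_merge([]) == []
        assert pool_and_merge([[], []]) == []

    def test_unknown_reference_raises(self):
        with pytest.raises(ValueError):
            pool_and_merge([[self.rec("weird", 0, 10, "a")]],
                           scaffolds=["scaffold_1"])

    @settings(derandomize=True, max_examples=20)
    @given(st.lists(
        st.lists(st.tuples(st.integers(0, 2000), st.integers(1, 400)),
                 min_size=0, max_size=10),
        min_size=1, max_size=4,
    ))
    def test_matches_union_oracle_across_samples(self, raw_samples):
        samples = [
            [self.rec("s", s, s + ln, f"p{i}") for s, ln in sample]
            for i, sample in enumerate(raw_samples)
        ]
        merged = pool_and_merge(samples)
        all_ivs = [(s, s + ln) for sample in raw_samples for s, ln in sample]
        assert [(m.start, m.end) for m in merged] == merge_intervals(all_ivs)
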