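"""Shared fixtures: a small annotated genome and a seeded Circle-Seq simulation."""
from __future__ import annotations

from dataclasses import dataclass

import pytest

from eccseq import genome as G
from eccseq import simulate as S
from eccseq.alignments import AlignmentSet

EXCLUDE = tuple(sp.name for sp in S.DEFAULT_SPIKEINS)


@dataclass
class SimBundle:
    genome: G.GenomeModel
    circles: list
    stats: S.SimulationStats
    aset: AlignmentSet
    sam_path: str


@pytest.fixture(scope="session")
def small_genome() -> G.GenomeModel:
    """Two 60-kb scaffolds, 10% repeats, ~6 genes."""
    return G.generate_genome(2, 60_000, 0.10, 50.0, seed=3)


def _simulate(tmp_path_factory, genome, circles, name, **kwargs):
    params = dict(
        depth=30.0, read_len=75, frag_mean=300.0, frag_sd=30.0,
        junction_pair_rate=0.05, softclip_rate=0.2,
        linear_background_depth=2.0, min_junction_pairs=2, seed=13,
    )
    params.update(kwargs)
    sam = str(tmp_path_factory.mktemp("sim") / f"{name}.sam")
    stats = S.simulate_alignments(genome, circles, S.DEFAULT_SPIKEINS,
                                  out_sam=sam, **params)
    aset = AlignmentSet.from_sam(sam, exclude_refs=EXCLUDE, sample_id=name)
    return SimBundle(genome, circles, stats, aset, sam)


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory) -> SimBundle:
    """12 planted circles on a 2x120-kb genome, >=2 junction pairs each."""
    gm = G.generate_genome(2, 120_000, 0.055, 50.0, seed=7)
    circles = G.plant_circles(gm, 12, seed=11, avoid_repeats=True)
    return _simulate(tmp_path_factory, gm, circles, "circles")


@pytest.fixture(scope="session")
def linear_bundle(tmp_path_factory, sim_bundle) -> SimBundle:
    """Matched linear-only library on the same genome (no circles)."""
    return _simulate(
        tmp_path_factory, sim_bundle.genome, [], "linear",
        linear_background_depth=5.0, min_junction_pairs=0,
    )
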