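import networkx as nx
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from cnmod.segments import GenomicInterval, SampleProfile, SegmentCall
from cnmod.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def tiny_cfg() -> SyntheticConfig:
    return SyntheticConfig(
        n_genes=100, n_samples=12, n_modules=5, module_size=8,
        n_chromosomes=4, seed=7,
    )


@pytest.fixture(scope="session")
def barbell() -> nx.Graph:
    """Two triangles joined by one bridge edge (7 edges total)."""
    g = nx.Graph()
    g.add_edges_from(
        [("a", "b"), ("a", "c"), ("b", "c"),
         ("d", "e"), ("d", "f"), ("e", "f"),
         ("c", "d")]
    )
    return g


@pytest.fixture(scope="session")
def genome_map_10() -> pd.DataFrame:
    """Ten 1 kb genes tiled on chr1: gene i spans [1000*i, 1000*i+1000)."""
    return pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(10)],
            "chrom": ["chr1"] * 10,
            "start": [1000 * i for i in range(10)],
            "end": [1000 * i + 1000 for i in range(10)],
        }
    )


def _profile(sample, ploidy, segs):
    return SampleProfile(
        sample_id=sample, ploidy=ploidy, aberrant_cell_fraction=0.7,
        segments=[
            SegmentCall(sample, GenomicInterval("chr1", s, e), mk, cn)
            for s, e, mk, cn in segs
        ],
    )


@pytest.fixture(scope="session")
def handcrafted_profiles() -> list[SampleProfile]:
    """Three samples over the 10-gene map, exercising every calling rule.

    With the chr1:[0,2000) mask applied at >50% overlap and the default
    delta 0.9 / 10-marker thresholds, the expected call matrix is the golden
    table in HANDCRAFTED_CALLS: the strict >0.9 boundary (SA's 2.9 at ploidy
    2.0 is neutral), a 9-marker segment that cannot
    be called, a segment at exactly 50% mask overlap that is kept, one at
    67% that is removed, and uncovered genes defaulting to ploidy.
    """
    sa = _profile(
        "SA", 2.0,
        [(0, 4000, 12, 3.1),      # 50% masked: kept; dev 1.1 -> +1 (g0-g3)
         (4000, 5000, 12, 2.9),   # dev exactly 0.9 -> neutral (g4)
         (5000, 7000, 9, 0.5),    # 9 markers -> neutral (g5, g6)
         (7000, 9000, 30, 0.8)],  # dev -1.2 -> -1 (g7, g8); g9 uncovered
    )
    sb = _profile(
        "SB", 3.0,
        [(0, 3000, 50, 5.0),      # 67% masked: removed (g0-g2 -> ploidy)
         (3000, 6500, 15, 4.2),   # dev 1.2 -> +1 (g3-g5)
         (6500, 10000, 10, 1.9)], # exactly 10 markers; dev -1.1 -> -1 (g6-g9)
    )
    sc = _profile(
        "SC", 2.8,
        [(2000, 4000, 20, 4.0),   # dev 1.2 -> +1 (g2, g3)
         (4000, 8000, 40, 3.6),   # dev 0.8 < 0.9 -> neutral (g4-g7)
         (8000, 10000, 15, 1.0)], # dev -1.8 -> -1 (g8, g9); g0, g1 uncovered
    )
    return [sa, sb, sc]


@pytest.fixture(scope="session")
def handcrafted_mask() -> list[GenomicInterval]:
    return [GenomicInterval("chr1", 0, 2000)]


# hand-computed golden call matrix for the handcrafted fixture (genes x SA,SB,SC)
HANDCRAFTED_CALLS = pd.DataFrame(
    [
        [1, 0, 0],   # g0
        [1, 0, 0],   # g1
        [1, 0, 1],   # g2
        [1, 1, 1],   # g3
        [0, 1, 0],   # g4
        [0, 1, 0],   # g5
        [0, -1, 0],  # g6
        [-1, -1, 0], # g7
        [-1, -1, -1],# g8
        [0, -1, -1], # g9
    ],
    index=[f"g{i}" for i in range(10)],
    columns=["SA", "SB", "SC"],
)

HANDCRAFTED_CN = pd.DataFrame(
    [
        [3.1, 3.0, 2.8],
        [3.1, 3.0, 2.8],
        [3.1, 3.0, 4.0],
        [3.1, 4.2, 4.0],
        [2.9, 4.2, 3.6],
        [0.5, 4.2, 3.6],
        [0.5, 1.9, 3.6],
        [0.8, 1.9, 3.6],
        [0.8, 1.9, 1.0],
        [2.0, 1.9, 1.0],
    ],
    index=[f"g{i}" for i in range(10)],
    columns=["SA", "SB", "SC"],
)
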