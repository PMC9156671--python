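import pytest

from pansv.graph_io import PangenomeGraph, Segment
from pansv.synthetic import SimConfig, simulate_pangenome

#: small but fully featured study conditions shared across test modules
SMALL_CONFIG = dict(n_chroms=2, chrom_length=1_000_000, sv_rate=3e-6,
                    n_genes=40, cnv_length=60_000, seed=11)


@pytest.fixture(scope="session")
def small_truth():
    return simulate_pangenome(SimConfig(**SMALL_CONFIG))


@pytest.fixture
def diamond_graph():
    """s1 -> {s2 (rank 0), s3 (rank 1)} -> s4: one canonical bubble."""
    g = PangenomeGraph()
    g.add_segment("s1", Segment(100, origin_sample="c1", origin_offset=0, origin_rank=0))
    g.add_segment("s2", Segment(60, origin_sample="c1", origin_offset=100, origin_rank=0))
    g.add_segment("s4", Segment(80, origin_sample="c1", origin_offset=160, origin_rank=0))
    g.add_segment("s3", Segment(725, origin_sample="B", origin_rank=1))
    g.add_link("s1", "+", "s2", "+")
    g.add_link("s2", "+", "s4", "+")
    g.add_link("s1", "+", "s3", "+")
    g.add_link("s3", "+", "s4", "+")
    return g
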