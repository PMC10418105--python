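import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from leakforensics.containers import CountMatrix
from leakforensics.simulate import contaminate_draft, simulate_genome, simulate_reads

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_genomes():
    """Two bacteria in distinct genera plus a eukaryotic host."""
    g1 = simulate_genome(
        2000, gc=0.5, seed=11, id="g1", taxon_path=("root", "Bacteria", "G1", "g1")
    )
    g2 = simulate_genome(
        2000, gc=0.5, seed=12, id="g2", taxon_path=("root", "Bacteria", "G2", "g2")
    )
    host = simulate_genome(
        5000, gc=0.41, seed=13, id="host", taxon_path=("root", "Eukaryota", "Homo", "host")
    )
    return g1, g2, host


@pytest.fixture(scope="session")
def contaminated_scenario(tiny_genomes):
    """Small host-contamination setup: draft g1 carries a 1 kb host contig."""
    g1, g2, host = tiny_genomes
    draft = contaminate_draft(g1, host, 1000, seed=21)
    reads = simulate_reads(
        [(host, 600), (g1, 30)], read_length=100, error_rate=0.0, seed=22
    )
    return draft, g2, host, reads


@pytest.fixture()
def small_count_matrix():
    counts = pd.DataFrame(
        [[5, 0, 0], [9, 0, 0], [0, 3, 0], [2, 0, 0]],
        index=["s1", "s2", "s3", "s4"],
        columns=["gA", "gB", "gC"],
    )
    meta = pd.DataFrame(
        {
            "class_label": ["X", "X", "Y", "Y"],
            "sample_type": ["tumor", "tumor", "tumor", "normal"],
            "library_size": [100, 200, 150, 120],
        },
        index=counts.index,
    )
    return CountMatrix(counts, meta)
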