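import pytest

from editscan.pileup import PileupColumn
from editscan.simdata import SimConfig, build_genome
from editscan.pipeline import run_simulation_study


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=3, n_edited_sites=10, n_snvs=6)


@pytest.fixture(scope="session")
def small_bundle_truth(small_cfg):
    return build_genome(small_cfg)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    """One full simulate->call->annotate run shared by several tests."""
    return run_simulation_study(small_cfg)


def make_column(
    pos, ref, fwd=None, rev=None, n_starts=None, n_ends=None
) -> PileupColumn:
    """Hand-built pileup column; unique start/end sets sized per base."""
    col = PileupColumn(pos, ref)
    for base, n in (fwd or {}).items():
        col.counts["fwd"][base] = n
    for base, n in (rev or {}).items():
        col.counts["rev"][base] = n
    for base in "ACGT":
        total = col.counts["fwd"][base] + col.counts["rev"][base]
        ns = (n_starts or {}).get(base, min(total, 99))
        ne = (n_ends or {}).get(base, min(total, 99))
        col.start_sets[base] = {pos - 50 - k for k in range(ns)}
        col.end_sets[base] = {pos + 50 + k for k in range(ne)}
    return col
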