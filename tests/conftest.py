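import numpy as np
import pytest

from omegascan import SpeciesTree, standard_code
from omegascan.divergence import estimate_divergence
from omegascan.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def tree():
    return SpeciesTree.default()


@pytest.fixture(scope="session")
def small_study():
    """A small null study (no category effects) shared across tests."""
    cfg = SimulationConfig(
        n_genes=120,
        n_codons_range=(150, 350),
        category_sizes={},
        branch_multipliers={},
        saturation_fraction=0.0,
        seed=17,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_study_records(small_study):
    return estimate_divergence(small_study.alignments, small_study.tree)


@pytest.fixture(scope="session")
def category_study():
    """A study with one elevated category on the arawakana branch only."""
    cfg = SimulationConfig(
        n_genes=400,
        n_codons_range=(150, 350),
        category_sizes={"fast": 30},
        branch_multipliers={"fast": {"arawakana": 10.0}},
        saturation_fraction=0.0,
        seed=23,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def category_study_records(category_study):
    return estimate_divergence(category_study.alignments, category_study.tree)


def make_records(omegas, ds=None, scope="tree", gene_prefix="g"):
    """DivergenceRecords with prescribed omega/dS, for scan/filter tests."""
    from omegascan.divergence import DivergenceRecord, SiteCounts

    n = len(omegas)
    if ds is None:
        ds = [0.1] * n
    return [
        DivergenceRecord(
            gene_id=f"{gene_prefix}{i:05d}",
            scope=scope,
            Nd=0.0,
            Sd=0.0,
            dN=float(o) * float(d) if not np.isnan(o) else float("nan"),
            dS=float(d),
            omega=float(o),
            site_counts=SiteCounts(S=100.0, N=200.0, usable_codons=100),
        )
        for i, (o, d) in enumerate(zip(omegas, ds))
    ]
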