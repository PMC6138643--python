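import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from protodyn.io_preprocess import MinuteGrid
from protodyn.synthetic import SyntheticGene, sinusoid_mrna

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def sinus_gene() -> SyntheticGene:
    """Canonical oscillating gene: m0=10, A=5, T=60, half-life 22 min, k_trans=2."""
    return SyntheticGene(
        gene_id="SIN1",
        true_k_trans=2.0,
        true_halflife=22.0,
        m0=10.0,
        amplitude=5.0,
        period_T=60.0,
        phase=0.3,
    )


@pytest.fixture
def sinus_grid(sinus_gene) -> MinuteGrid:
    return sinusoid_mrna(sinus_gene, dt=1.0)


@pytest.fixture
def random_grid_factory():
    """Uniform-random positive mRNA grids with a periodic endpoint."""

    def make(seed: int, T: float = 60.0, dt: float = 1.0) -> MinuteGrid:
        rng = np.random.default_rng(seed)
        n = round(T / dt)
        values = rng.uniform(0.5, 20.0, n + 1)
        values[-1] = values[0]
        return MinuteGrid(f"RND{seed}", T, dt, values)

    return make


@pytest.fixture
def expression_tsv(tmp_path):
    """Small 3-gene expression table with one missing cell."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene\t0\t7\t14\n"
        "GENE1\t0.0\t0.5\t-0.5\n"
        "GENE2\t1.0\t\t-1.0\n"
        "GENE3\t0.2\t0.1\t0.0\n"
    )
    return path
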