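import numpy as np
import pytest

from ogscreen.coxcore import SurvivalDataset
from ogscreen.pathways import PathwayCollection
from ogscreen.simulate import SimConfig


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """Scaled-down design: 3 chained groups over 8 genes, one effective
    group, one effective interaction, 5 environments."""
    return SimConfig(
        n_train=150,
        n_test=80,
        alpha=(1.0, -1.0, 0.5, 0.0, 0.0),
        group_sizes=(3, 3, 4),
        group_overlaps=(1, 1),
        effective_groups=(("1", 1.5),),
        interaction_effects=(("E1", "G2", 1.0, "1"),),
        censor_target=0.30,
    )


def make_survival_data(
    rng: np.random.Generator,
    n: int = 120,
    q: int = 2,
    p: int = 6,
    alpha=None,
    beta=None,
    censor_scale: float = 3.0,
) -> SurvivalDataset:
    """Simple independent-covariate cohort for unit tests."""
    E = rng.standard_normal((n, q))
    X = rng.standard_normal((n, p))
    lp = np.zeros(n)
    if alpha is not None:
        lp += E @ np.asarray(alpha, float)
    if beta is not None:
        lp += X @ np.asarray(beta, float)
    T = rng.exponential(1.0, n) / np.exp(lp)
    C = rng.uniform(0, censor_scale, n)
    t = np.clip(np.minimum(T, C), 1e-12, None)
    d = (T <= C).astype(int)
    return SurvivalDataset(
        time=t,
        event=d,
        E=E,
        X=X,
        env_names=tuple(f"E{i + 1}" for i in range(q)),
        gene_names=tuple(f"g{i + 1}" for i in range(p)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_overlapping_pathways() -> PathwayCollection:
    return PathwayCollection(
        group_names=("a", "b"),
        members=(("g1", "g2"), ("g2", "g3")),
    )
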