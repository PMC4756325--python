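import numpy as np
import pytest

from rcgsim import (
    InteractionGraph,
    ModelParams,
    PopulationState,
    make_square_lattice,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def lattice5():
    return make_square_lattice(5)


@pytest.fixture
def default_params():
    return ModelParams()


@pytest.fixture
def make_pop():
    """Factory for hand-built populations from explicit trait lists.

    The graph defaults to a path over the players (any connected graph
    works for operations that do not walk neighbourhoods).
    """

    def _make(gammas, alphas, betas, graph=None, seed=0, params=None):
        gammas = np.asarray(gammas, dtype=float)
        n = len(gammas)
        if graph is None:
            if n == 1:
                graph = InteractionGraph(
                    indptr=np.array([0, 0], dtype=np.int64),
                    indices=np.array([], dtype=np.int64),
                )
            else:
                graph = InteractionGraph.from_edges(
                    n, [(i, i + 1) for i in range(n - 1)]
                )
        return PopulationState(
            gamma=gammas,
            alpha=np.asarray(alphas, dtype=float),
            beta=np.asarray(betas, dtype=float),
            graph=graph,
            rng=np.random.default_rng(seed),
            params=params,
        )

    return _make
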