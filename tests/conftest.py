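import numpy as np
import pytest

from fanoreg.chains import BirthDeathChain, NetworkChain


def make_monotone_chain(rng: np.random.Generator, direction: str) -> BirthDeathChain:
    """Random chain with monotone h_n, bounded so the mass converges fast."""
    n = int(rng.integers(20, 200))
    h0 = rng.uniform(0.5, 5.0)
    steps = rng.exponential(0.3, size=n - 1) * (rng.random(n - 1) < 0.4)
    h = h0 + np.concatenate([[0.0], np.cumsum(steps)])
    h = np.minimum(h, 40.0)
    if direction == "down":
        h = h[::-1].copy()
    g = rng.uniform(0.5, 2.0)
    return BirthDeathChain.from_arrays(f=h * g, g=np.full(n, g))


def make_acyclic_network(rng: np.random.Generator, m: int) -> NetworkChain:
    """Random DAG-coupled network: constant degradation, no self-dependence.

    Gene i's synthesis rate depends only on lower-numbered parents through a
    saturating response, so every gene satisfies the no-autoregulation,
    constant-degradation, acyclic premises.
    """
    parents: list[list[int]] = [[] for _ in range(m)]
    for j in range(m):
        for i in range(j):
            if rng.random() < 0.7:
                parents[j].append(i)
    if not any(parents):
        parents[m - 1].append(0)
    base = rng.uniform(0.3, 1.2, size=m)
    g = rng.uniform(0.8, 2.0, size=m)
    weights = [rng.uniform(0.1, 0.4, size=len(parents[j])) for j in range(m)]

    def make_f(j):
        pj = parents[j]
        wj = weights[j]
        bj = base[j]

        def f(n):
            return bj + sum(w * min(n[p], 3) for w, p in zip(wj, pj))

        return f

    fs = [make_f(j) for j in range(m)]
    gs = [(lambda v: (lambda n: v))(float(g[j])) for j in range(m)]
    lam = np.array([(base[j] + 3 * weights[j].sum()) / g[j] for j in range(m)])
    box = tuple(int(np.ceil(l + 8 * np.sqrt(l) + 8)) for l in lam)
    return NetworkChain(m=m, f=fs, g=gs, box=box, initial_state=(0,) * m)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def example2_chain():
    gate1 = lambda n: 1.0 if n[1] == 2 else 0.0  # noqa: E731
    gate2 = lambda n: 1.0 if n[0] == 2 else 0.0  # noqa: E731
    return NetworkChain(
        m=2, f=[gate1, gate2], g=[gate1, gate2], box=(40, 40), initial_state=(2, 2)
    )
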