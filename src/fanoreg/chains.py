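"""Exact continuous-time Markov chain models of stochastic gene expression.

Two model classes are supported:

* :class:`BirthDeathChain` -- a single species on the nonnegative integers
  with synthesis rate ``f_n`` (transition ``n-1 -> n``) and per-molecule
  degradation rate ``g_n`` (total rate ``n * g_n`` for ``n -> n-1``).  Its
  stationary law has the product form ``P_n = P_0 * prod(h_i) / n!`` with
  ``h_n = f_n / g_n``, which is evaluated here in log space with adaptive
  truncation.

* :class:`NetworkChain` -- ``m`` species with state-dependent rate functions
  where every transition changes exactly one coordinate by one.  The
  stationary distribution is obtained by solving ``pi Q = 0`` on the closed
  communicating class reachable from a designated initial state, inside a
  finite box, with a sparse direct solve.  No approximation is involved
  beyond the (reported and bounded) truncation.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve
from scipy.special import logsumexp

__all__ = [
    "ModelError",
    "TruncationError",
    "AmbiguousClassError",
    "BirthDeathChain",
    "StationaryDistribution",
    "NetworkChain",
    "JointStationaryDistribution",
    "relative_growth_rates",
    "classify_rate_autoregulation",
    "stationary_birth_death",
    "distribution_moments",
    "stationary_network",
    "marginal_vmr",
    "marginal_distribution",
]

DEFAULT_TAIL_TOL = 1e-12
#: hard cap on states for the single-species recursion
HARD_CAP_SINGLE = 100_000
#: hard cap on enumerated joint states for the network solver
HARD_CAP_JOINT = 1_000_000


class ModelError(ValueError):
    """A rate specification violates the model invariants."""


class TruncationError(RuntimeError):
    """Probability mass did not converge inside the truncation bound."""


class AmbiguousClassError(RuntimeError):
    """More than one closed communicating class is reachable."""


# ---------------------------------------------------------------------------
# single-species birth-death chain
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BirthDeathChain:
    """Single-species chain with synthesis ``f_n`` and per-molecule decay ``g_n``.

    Parameters
    ----------
    f : callable
        ``f(n)`` is the rate of the transition ``n-1 -> n`` for ``n >= 1``.
        Must be nonnegative.
    g : callable
        ``g(n)`` is the per-molecule degradation rate at copy number ``n``;
        the total rate of ``n -> n-1`` is ``n * g(n)``.  Must be positive
        wherever ``f(n) > 0``.
    n_max : int
        Truncation/safety bound on the state space (number of molecules).
    """

    f: Callable[[int], float]
    g: Callable[[int], float]
    n_max: int = 1000

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ModelError("n_max must be at least 1")

    def h(self, n: int) -> float:
        """Relative growth rate ``h_n = f_n / g_n``; 0/0 is read as 0."""
        fn = float(self.f(n))
        gn = float(self.g(n))
        if fn < 0.0:
            raise ModelError(f"f({n}) = {fn} is negative")
        if gn <= 0.0:
            if fn == 0.0 and gn == 0.0:
                warnings.warn(
                    f"f({n}) = g({n}) = 0: treating h_{n} as 0 (support ends)",
                    RuntimeWarning,
                    stacklevel=2,
                )
                return 0.0
            raise ModelError(f"g({n}) = {gn} must be positive")
        return fn / gn

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_arrays(cls, f: Sequence[float], g: Sequence[float]) -> "BirthDeathChain":
        """Build a chain from explicit rate arrays ``f_1..f_N``, ``g_1..g_N``."""
        fa = np.asarray(f, dtype=float)
        ga = np.asarray(g, dtype=float)
        if fa.shape != ga.shape or fa.ndim != 1 or fa.size == 0:
            raise ModelError("f and g must be 1-d arrays of equal positive length")
        if np.any(fa < 0):
            raise ModelError("synthesis rates must be nonnegative")
        n_max = int(fa.size)
        return cls(
            f=lambda n: float(fa[n - 1]) if 1 <= n <= n_max else 0.0,
            g=lambda n: float(ga[n - 1]) if 1 <= n <= n_max else float(ga[-1]),
            n_max=n_max,
        )

    @classmethod
    def constant(cls, f: float, g: float, n_max: int | None = None) -> "BirthDeathChain":
        """Constant rates: no autoregulation; stationary law Poisson(f/g)."""
        if f < 0 or g <= 0:
            raise ModelError("need f >= 0 and g > 0")
        if n_max is None:
            h = f / g
            n_max = int(math.ceil(h + 14.0 * math.sqrt(h + 1.0) + 50.0))
        return cls(f=lambda n: float(f), g=lambda n: float(g), n_max=n_max)

    @classmethod
    def linear(cls, k: float, b: float, c: float, n_max: int | None = None) -> "BirthDeathChain":
        """Linear feedback: ``f_n = max(k + b (n-1), 0)``, ``g_n = c``.

        ``b > 0`` is positive autoregulation, ``b < 0`` negative.  Validity
        requires ``c > 0`` and ``c - b > 0``; the stationary VMR is then
        ``1 + b / (c - b)`` (exactly, when ``b <= 0`` additionally requires
        ``k / |b|`` integral so the linear form stays nonnegative on the
        support).
        """
        if c <= 0 or c - b <= 0:
            raise ModelError("linear family needs c > 0 and c - b > 0")
        if k < 0:
            raise ModelError("linear family needs k >= 0")
        if n_max is None:
            if b > 0:
                mean = k / (c - b)
                var = mean * c / (c - b)
                n_max = int(math.ceil(mean + 14.0 * math.sqrt(var + 1.0) + 50.0))
            elif b < 0:
                n_max = int(math.ceil(k / -b)) + 5
            else:
                return cls.constant(k, c)
        return cls(
            f=lambda n: max(k + b * (n - 1), 0.0),
            g=lambda n: float(c),
            n_max=n_max,
        )

    @classmethod
    def hill(
        cls,
        vmax: float,
        K: float,
        coef: float,
        g: float,
        baseline: float = 0.0,
        n_max: int | None = None,
    ) -> "BirthDeathChain":
        """Hill-activated synthesis: ``f_n = baseline + vmax (n-1)^coef / (K^coef + (n-1)^coef)``."""
        if vmax < 0 or K <= 0 or coef <= 0 or g <= 0 or baseline < 0:
            raise ModelError("hill family needs vmax, baseline >= 0 and K, coef, g > 0")
        if n_max is None:
            h = (baseline + vmax) / g
            n_max = int(math.ceil(h + 14.0 * math.sqrt(h + 1.0) + 50.0))

        def f(n: int) -> float:
            x = float(n - 1)
            if x <= 0.0:
                return baseline
            xe = x**coef
            return baseline + vmax * xe / (K**coef + xe)

        return cls(f=f, g=lambda n: float(g), n_max=n_max)


@dataclass(frozen=True)
class StationaryDistribution:
    """Truncated stationary law ``P_0 .. P_{N}`` with a bound on lost tail mass."""

    probabilities: np.ndarray
    tail_mass_bound: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        object.__setattr__(self, "probabilities", p)

    @property
    def support_size(self) -> int:
        return int(self.probabilities.size)


def relative_growth_rates(chain: BirthDeathChain, upto: int | None = None) -> np.ndarray:
    """Return ``h_n = f_n / g_n`` for ``n = 1 .. upto`` (default ``chain.n_max``)."""
    upto = chain.n_max if upto is None else int(upto)
    return np.array([chain.h(n) for n in range(1, upto + 1)], dtype=float)


def classify_rate_autoregulation(chain: BirthDeathChain, upto: int | None = None) -> str:
    """Classify the rate-level autoregulation of a chain.

    Returns one of ``"none"`` (h constant), ``"positive"`` (h somewhere
    increasing, never decreasing), ``"negative"`` (the reverse) or
    ``"mixed"`` (both occur, at different copy numbers).
    """
    h = relative_growth_rates(chain, upto)
    if h.size < 2:
        raise ModelError("need at least two states to classify autoregulation")
    d = np.diff(h)
    up = bool(np.any(d > 0))
    down = bool(np.any(d < 0))
    if up and down:
        return "mixed"
    if up:
        return "positive"
    if down:
        return "negative"
    return "none"


def stationary_birth_death(
    chain: BirthDeathChain, tail_tol: float = DEFAULT_TAIL_TOL
) -> StationaryDistribution:
    """Stationary distribution via the product-form recursion ``P_n = P_{n-1} h_n / n``.

    Weights are accumulated in log space; the support is extended until the
    relative weight falls below ``tail_tol`` in the decaying regime (or the
    support terminates at a state with ``h = 0``), capped at ``chain.n_max``.

    Raises
    ------
    TruncationError
        If the mass has not converged by ``chain.n_max``.
    """
    if tail_tol <= 0 or tail_tol >= 1:
        raise ValueError("tail_tol must be in (0, 1)")
    cap = min(chain.n_max, HARD_CAP_SINGLE)
    log_tol = math.log(tail_tol)

    lw = [0.0]  # log unnormalized weights, lw[0] = log 1
    lw_max = 0.0
    terminated = False  # h hit zero: support is finite, no tail at all
    n = 0
    while n < cap:
        n += 1
        h = chain.h(n)
        if h == 0.0:
            terminated = True
            n -= 1
            break
        lw.append(lw[-1] + math.log(h) - math.log(n))
        lw_max = max(lw_max, lw[-1])
        # stop once weights are decaying and negligible relative to the mode
        if h / (n + 1) < 1.0 and lw[-1] - lw_max < log_tol:
            break

    lw_arr = np.asarray(lw, dtype=float)
    log_z = float(logsumexp(lw_arr))
    probs = np.exp(lw_arr - log_z)

    if terminated:
        tail_bound = 0.0
    else:
        # geometric bound on the discarded tail: ratios h_m/m are
        # decreasing in the Poisson-like regime beyond the stopping point
        r = chain.h(n + 1) / (n + 1)
        if r >= 1.0:
            raise TruncationError(
                f"stationary mass not converged at n_max={cap}: "
                f"weight ratio h/(n+1) = {r:.3g} >= 1 at n = {n + 1}"
            )
        tail_bound = math.exp(lw_arr[-1] - log_z) * r / (1.0 - r)
        if tail_bound > math.sqrt(tail_tol):
            raise TruncationError(
                f"tail mass bound {tail_bound:.3g} exceeds tolerance at n_max={cap}; "
                "increase n_max"
            )
    return StationaryDistribution(probabilities=probs, tail_mass_bound=tail_bound)


def distribution_moments(dist: StationaryDistribution | np.ndarray) -> tuple[float, float, float]:
    """Exact (mean, variance, VMR) of a distribution on ``0..N``.

    A zero mean makes the VMR undefined; ``nan`` is returned as a flagged
    value rather than raising.
    """
    p = dist.probabilities if isinstance(dist, StationaryDistribution) else np.asarray(dist, float)
    n = np.arange(p.size, dtype=float)
    mean = float(p @ n)
    var = float(p @ (n - mean) ** 2)
    vmr = var / mean if mean > 0 else float("nan")
    return mean, var, vmr


# ---------------------------------------------------------------------------
# multi-species one-step network chain
# ---------------------------------------------------------------------------

RateFunction = Callable[[tuple[int, ...]], float]


@dataclass(frozen=True)
class NetworkChain:
    """``m``-species one-step chain with state-dependent rates.

    For species ``i`` at joint state ``n``, the transition ``n_i -> n_i + 1``
    has rate ``f[i](n)`` and ``n_i -> n_i - 1`` has rate ``g[i](n) * n_i``.
    Only one coordinate may change per transition, by exactly one.

    ``box`` gives the inclusive per-species truncation bound and
    ``initial_state`` selects the communicating class the dynamics is
    restricted to (the chain may be reducible, e.g. indicator-gated rates).
    """

    m: int
    f: Sequence[RateFunction]
    g: Sequence[RateFunction]
    box: tuple[int, ...]
    initial_state: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.m < 1 or len(self.f) != self.m or len(self.g) != self.m:
            raise ModelError("need one f and one g per species")
        if len(self.box) != self.m or any(b < 1 for b in self.box):
            raise ModelError("box must give a bound >= 1 per species")
        if len(self.initial_state) != self.m or any(
            not (0 <= s <= b) for s, b in zip(self.initial_state, self.box)
        ):
            raise ModelError("initial_state must lie inside the box")

    def rates(self, state: tuple[int, ...], i: int) -> tuple[float, float]:
        """(birth rate, total death rate) of species ``i`` at ``state``."""
        up = float(self.f[i](state))
        gi = float(self.g[i](state))
        if up < 0:
            raise ModelError(f"f[{i}]{state} = {up} is negative")
        if state[i] > 0 and gi < 0:
            raise ModelError(f"g[{i}]{state} = {gi} is negative")
        return up, gi * state[i]


@dataclass(frozen=True)
class JointStationaryDistribution:
    """Stationary law on the enumerated closed communicating class."""

    states: np.ndarray  # (N, m) int array
    probabilities: np.ndarray  # (N,)
    boundary_mass: float = 0.0


def _enumerate_reachable(net: NetworkChain) -> list[tuple[int, ...]]:
    seen = {net.initial_state}
    queue = deque([net.initial_state])
    out: list[tuple[int, ...]] = []
    while queue:
        s = queue.popleft()
        out.append(s)
        if len(out) > HARD_CAP_JOINT:
            raise TruncationError(f"more than {HARD_CAP_JOINT} reachable joint states")
        for i in range(net.m):
            up, down = net.rates(s, i)
            if up > 0 and s[i] < net.box[i]:
                t = s[:i] + (s[i] + 1,) + s[i + 1 :]
                if t not in seen:
                    seen.add(t)
                    queue.append(t)
            if down > 0:
                t = s[:i] + (s[i] - 1,) + s[i + 1 :]
                if t not in seen:
                    seen.add(t)
                    queue.append(t)
    return out


def stationary_network(
    net: NetworkChain, tail_tol: float = DEFAULT_TAIL_TOL
) -> JointStationaryDistribution:
    """Solve ``pi Q = 0`` on the closed class reachable from ``initial_state``.

    The reachable set inside the box is enumerated breadth-first, its unique
    closed communicating class is extracted via strongly connected
    components, and the stationary system is solved exactly with a sparse
    direct factorization (one balance equation replaced by normalization).

    Raises
    ------
    AmbiguousClassError
        If more than one closed class is reachable (the stationary law would
        depend on absorption probabilities).
    TruncationError
        If stationary mass presses against the box boundary beyond
        ``sqrt(tail_tol)``.
    """
    states = _enumerate_reachable(net)
    index = {s: k for k, s in enumerate(states)}
    n_states = len(states)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    blocked = np.zeros(n_states, dtype=bool)  # birth suppressed by the box
    for k, s in enumerate(states):
        out_rate = 0.0
        for i in range(net.m):
            up, down = net.rates(s, i)
            if up > 0:
                if s[i] < net.box[i]:
                    t = s[:i] + (s[i] + 1,) + s[i + 1 :]
                    rows.append(k)
                    cols.append(index[t])
                    vals.append(up)
                    out_rate += up
                else:
                    blocked[k] = True
            if down > 0:
                t = s[:i] + (s[i] - 1,) + s[i + 1 :]
                rows.append(k)
                cols.append(index[t])
                vals.append(down)
                out_rate += down
        rows.append(k)
        cols.append(k)
        vals.append(-out_rate)

    q = csr_matrix((vals, (rows, cols)), shape=(n_states, n_states))

    # restrict to the closed communicating class(es) among reachable states
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n_states, n_states))
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    # a class is closed iff no transition leaves it
    open_class = np.zeros(n_comp, dtype=bool)
    coo = q.tocoo()
    for r, c, v in zip(coo.row, coo.col, coo.data):
        if v > 0 and labels[r] != labels[c]:
            open_class[labels[r]] = True
    closed = [c for c in range(n_comp) if not open_class[c]]
    if len(closed) != 1:
        raise AmbiguousClassError(
            f"{len(closed)} closed communicating classes reachable from "
            f"{net.initial_state}; the stationary distribution is not unique"
        )
    keep = np.flatnonzero(labels == closed[0])
    sub = q[keep][:, keep].T.tolil()
    sub[0, :] = 1.0
    rhs = np.zeros(keep.size)
    rhs[0] = 1.0
    pi = spsolve(csr_matrix(sub), rhs)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()

    boundary_mass = float(pi[blocked[keep]].sum())
    if boundary_mass > math.sqrt(tail_tol):
        raise TruncationError(
            f"stationary mass {boundary_mass:.3g} rests on box-blocked states; enlarge box"
        )
    kept_states = np.array([states[k] for k in keep], dtype=np.int64)
    return JointStationaryDistribution(
        states=kept_states, probabilities=pi, boundary_mass=boundary_mass
    )


def marginal_distribution(joint: JointStationaryDistribution, species: int) -> np.ndarray:
    """One-dimensional marginal pmf of ``species`` on ``0..max``."""
    if not 0 <= species < joint.states.shape[1]:
        raise IndexError(f"species index {species} out of range")
    vals = joint.states[:, species]
    out = np.zeros(int(vals.max()) + 1)
    np.add.at(out, vals, joint.probabilities)
    return out


def marginal_vmr(joint: JointStationaryDistribution, species: int) -> float:
    """VMR of the marginal of one species at stationarity."""
    _, _, vmr = distribution_moments(marginal_distribution(joint, species))
    return vmr
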