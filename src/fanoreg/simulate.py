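"""Exact stochastic simulation (direct-method Gillespie) of every model class.

All simulators draw endpoint states of independent cells after a burn-in
long compared to the slowest relaxation time, matching the data type the
inference consumes: one measurement per cell at stationarity.  Thinned
within-trajectory sampling is available for the single-species chain as a
cheaper alternative (with an autocorrelation caveat).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from fanoreg import _kernels
from fanoreg.chains import BirthDeathChain, ModelError, NetworkChain

__all__ = [
    "SimulationError",
    "SimulationPlan",
    "MultiStepCycleModel",
    "TelegraphModel",
    "simulate_birth_death",
    "simulate_network",
    "simulate_multistep_cycle",
    "simulate_telegraph",
]

#: default burn-in, in multiples of the slowest relaxation time (1 / min rate)
BURN_IN_RELAXATIONS = 20.0


class SimulationError(RuntimeError):
    """Runaway trajectory or invalid simulation setup."""


@dataclass(frozen=True)
class SimulationPlan:
    """How to sample a model: burn-in, horizon, replicate count, seed.

    ``burn_in=None`` lets each simulator pick ``20 / (slowest rate)``.
    With ``sampling="endpoint"`` (default) each of ``n_cells`` independent
    trajectories is read out once at ``burn_in + horizon``.  With
    ``sampling="thinned"`` a single trajectory is read every ``spacing``
    time units, which is cheaper but autocorrelated.
    """

    n_cells: int = 1000
    burn_in: float | None = None
    horizon: float = 0.0
    sampling: str = "endpoint"
    spacing: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.burn_in is not None and self.burn_in <= 0:
            raise ValueError("burn_in must be positive")
        if self.horizon < 0:
            raise ValueError("horizon must be nonnegative")
        if self.sampling not in ("endpoint", "thinned"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")

    def resolve_t_end(self, relaxation_time: float) -> tuple[float, float]:
        burn = self.burn_in if self.burn_in is not None else BURN_IN_RELAXATIONS * relaxation_time
        return burn, burn + self.horizon


@dataclass(frozen=True)
class MultiStepCycleModel:
    """Cyclic multi-stage gene-state model: k stages, one transcript per cycle.

    With many stages the cycle time becomes nearly deterministic and the
    stationary transcript count concentrates -- a one-step-model violation
    exhibiting VMR < 1 without any autoregulation.
    """

    k: int
    stage_rate: float
    deg_rate: float

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ModelError("k must be >= 1")
        if self.stage_rate <= 0 or self.deg_rate <= 0:
            raise ModelError("stage_rate and deg_rate must be positive")


@dataclass(frozen=True)
class TelegraphModel:
    """Two-state (on/off) transcription with state-dependent rates."""

    k_on: float
    k_off: float
    rho_on: float
    rho_off: float
    deg: float

    def __post_init__(self) -> None:
        if min(self.k_on, self.k_off, self.rho_on, self.rho_off) < 0:
            raise ModelError("switching and transcription rates must be >= 0")
        if self.deg <= 0:
            raise ModelError("deg must be positive")

    def fano_factor(self) -> float:
        """Closed-form stationary Fano factor (used as a simulation oracle).

        ``F = 1 + (rho_on - rho_off)^2 k_on k_off /
        [(k_on + k_off)^2 (k_on + k_off + deg) mean_rate]`` with
        ``mean_rate = (rho_on k_on + rho_off k_off) / (k_on + k_off)``;
        reduces to ``1 + rho_on k_off / [(k_on + k_off)(k_on + k_off + deg)]``
        when ``rho_off = 0``.
        """
        ksum = self.k_on + self.k_off
        if ksum == 0.0:
            return 1.0
        mean_rate = (self.rho_on * self.k_on + self.rho_off * self.k_off) / ksum
        if mean_rate == 0.0:
            return 1.0
        extra = (self.rho_on - self.rho_off) ** 2 * self.k_on * self.k_off / (
            ksum**2 * (ksum + self.deg)
        )
        return 1.0 + extra / mean_rate


def _tabulate_rates(chain: BirthDeathChain) -> tuple[np.ndarray, np.ndarray]:
    cap = chain.n_max
    birth = np.zeros(cap + 1)
    death = np.zeros(cap + 1)
    for n in range(1, cap + 1):
        fn = float(chain.f(n))
        gn = float(chain.g(n))
        if fn < 0:
            raise ModelError(f"f({n}) = {fn} is negative")
        if fn > 0 and gn <= 0:
            raise ModelError(f"g({n}) = {gn} must be positive where f > 0")
        birth[n - 1] = fn
        death[n] = gn * n
    birth[cap] = 0.0  # safety cap: no births beyond the truncation bound
    return birth, death


def simulate_birth_death(
    chain: BirthDeathChain, plan: SimulationPlan, initial_state: int = 0
) -> np.ndarray:
    """Exact SSA endpoint (or thinned) counts for a single-species chain."""
    birth, death = _tabulate_rates(chain)
    positive_g = death[1:][birth[:-1] > 0]
    min_rate = float(np.min(positive_g / np.arange(1, chain.n_max + 1)[birth[:-1] > 0])) if positive_g.size else 1.0
    burn, t_end = plan.resolve_t_end(1.0 / max(min_rate, 1e-300))
    if not 0 <= initial_state <= chain.n_max:
        raise SimulationError("initial_state outside the truncated state space")
    if plan.sampling == "thinned":
        spacing = plan.spacing if plan.spacing is not None else 1.0 / max(min_rate, 1e-300)
        warnings.warn(
            "thinned sampling along one trajectory yields autocorrelated draws",
            RuntimeWarning,
            stacklevel=2,
        )
        out, cap_hits = _kernels.bd_thinned(
            birth, death, initial_state, burn, spacing, plan.n_cells, plan.seed
        )
    else:
        out, cap_hits = _kernels.bd_endpoints(
            birth, death, initial_state, t_end, plan.n_cells, plan.seed
        )
    if cap_hits:
        raise SimulationError(
            f"trajectories reached the safety cap n_max={chain.n_max} "
            f"{cap_hits} times; the model may be divergent or n_max too small"
        )
    return np.asarray(out)


def simulate_network(net: NetworkChain, plan: SimulationPlan) -> np.ndarray:
    """Exact SSA over all 2m one-step channels; returns (cells, species) endpoints."""
    g_floor = math.inf
    for i in range(net.m):
        gi = float(net.g[i](net.initial_state))
        if gi > 0:
            g_floor = min(g_floor, gi)
    if not math.isfinite(g_floor):
        g_floor = 1.0
    burn, t_end = plan.resolve_t_end(1.0 / g_floor)
    if plan.sampling != "endpoint":
        raise SimulationError("network simulation supports endpoint sampling only")

    m = net.m
    box = net.box
    out = np.empty((plan.n_cells, m), dtype=np.int64)
    root = np.random.SeedSequence(plan.seed)
    up_rates = np.empty(m)
    down_rates = np.empty(m)
    for c, child in enumerate(root.spawn(plan.n_cells)):
        rng = np.random.default_rng(child)
        state = list(net.initial_state)
        t = 0.0
        while True:
            tup = tuple(state)
            a_total = 0.0
            for i in range(m):
                up, down = net.rates(tup, i)
                if state[i] >= box[i] and up > 0:
                    raise SimulationError(
                        f"state {tup} reached the box bound for species {i}"
                    )
                up_rates[i] = up
                down_rates[i] = down
                a_total += up + down
            if a_total <= 0.0:
                break
            t += rng.exponential(1.0 / a_total)
            if t >= t_end:
                break
            u = rng.random() * a_total
            acc = 0.0
            for i in range(m):
                acc += up_rates[i]
                if u < acc:
                    state[i] += 1
                    break
                acc += down_rates[i]
                if u < acc:
                    state[i] -= 1
                    break
        out[c] = state
    return out


def simulate_multistep_cycle(model: MultiStepCycleModel, plan: SimulationPlan) -> np.ndarray:
    """Endpoint transcript counts for the k-stage cycle model."""
    burn, t_end = plan.resolve_t_end(1.0 / model.deg_rate)
    if plan.sampling != "endpoint":
        raise SimulationError("multistep simulation supports endpoint sampling only")
    out = _kernels.multistep_endpoints(
        model.k, model.stage_rate, model.deg_rate, t_end, plan.n_cells, plan.seed
    )
    return np.asarray(out)


def simulate_telegraph(model: TelegraphModel, plan: SimulationPlan) -> np.ndarray:
    """Endpoint transcript counts for the on/off telegraph model."""
    switch = model.k_on + model.k_off
    slowest = min(model.deg, switch) if switch > 0 else model.deg
    burn, t_end = plan.resolve_t_end(1.0 / slowest)
    if plan.sampling != "endpoint":
        raise SimulationError("telegraph simulation supports endpoint sampling only")
    out = _kernels.telegraph_endpoints(
        model.k_on, model.k_off, model.rho_on, model.rho_off, model.deg,
        t_end, plan.n_cells, plan.seed,
    )
    return np.asarray(out)
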