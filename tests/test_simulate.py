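import numpy as np
import pytest

from fanoreg.chains import (
    BirthDeathChain,
    NetworkChain,
    distribution_moments,
    marginal_vmr,
    stationary_birth_death,
    stationary_network,
)
from fanoreg.simulate import (
    MultiStepCycleModel,
    SimulationError,
    SimulationPlan,
    TelegraphModel,
    simulate_birth_death,
    simulate_multistep_cycle,
    simulate_network,
    simulate_telegraph,
)


def fano(x):
    return x.var(ddof=1) / x.mean()


def vmr_se(vmr, n):
    # asymptotic Monte-Carlo standard error of a sample VMR near Poisson
    return vmr * np.sqrt(2.0 / n)


class TestBirthDeath:
    def test_seed_determinism(self):
        chain = BirthDeathChain.constant(5.0, 1.0)
        plan = SimulationPlan(n_cells=200, seed=42)
        a = simulate_birth_death(chain, plan)
        b = simulate_birth_death(chain, plan)
        assert np.array_equal(a, b)
        c = simulate_birth_death(chain, SimulationPlan(n_cells=200, seed=43))
        assert not np.array_equal(a, c)

    def test_zero_synthesis_stays_at_zero(self):
        chain = BirthDeathChain.from_arrays([0.0, 0.0], [1.0, 1.0])
        out = simulate_birth_death(chain, SimulationPlan(n_cells=50, seed=0))
        assert np.all(out == 0)

    def test_poisson_vmr_within_null_band(self):
        from fanoreg.vmrstats import vmr_null_interval

        chain = BirthDeathChain.constant(5.0, 1.0)
        out = simulate_birth_death(chain, SimulationPlan(n_cells=10_000, seed=7))
        lo, hi = vmr_null_interval(10_000, 0.01)
        assert lo < fano(out) < hi

    def test_example1_matches_exact_solver(self):
        chain = BirthDeathChain.linear(k=2.0, b=1.0, c=2.0)
        exact_vmr = distribution_moments(stationary_birth_death(chain))[2]
        out = simulate_birth_death(chain, SimulationPlan(n_cells=10_000, seed=11))
        assert fano(out) == pytest.approx(exact_vmr, abs=4 * vmr_se(exact_vmr, 10_000))

    def test_total_variation_vs_exact(self):
        chain = BirthDeathChain.linear(k=6.0, b=-2.0, c=3.0)
        exact = stationary_birth_death(chain).probabilities
        out = simulate_birth_death(chain, SimulationPlan(n_cells=10_000, seed=3))
        emp = np.bincount(out, minlength=exact.size) / out.size
        k = max(emp.size, exact.size)
        emp = np.pad(emp, (0, k - emp.size))
        ex = np.pad(exact, (0, k - exact.size))
        assert 0.5 * np.abs(emp - ex).sum() < 0.03

    def test_burn_in_adequacy(self):
        chain = BirthDeathChain.constant(8.0, 1.0)
        v1 = fano(simulate_birth_death(chain, SimulationPlan(n_cells=8000, seed=5)))
        v2 = fano(
            simulate_birth_death(chain, SimulationPlan(n_cells=8000, burn_in=40.0, seed=5))
        )
        assert abs(v1 - v2) < 2 * vmr_se(1.0, 8000) * np.sqrt(2)

    def test_runaway_raises(self):
        chain = BirthDeathChain(f=lambda n: 200.0, g=lambda n: 1.0, n_max=20)
        with pytest.raises(SimulationError):
            simulate_birth_death(chain, SimulationPlan(n_cells=5, seed=0))

    def test_thinned_sampling(self):
        chain = BirthDeathChain.constant(5.0, 1.0)
        plan = SimulationPlan(n_cells=4000, sampling="thinned", spacing=5.0, seed=9)
        with pytest.warns(RuntimeWarning, match="autocorrelated"):
            out = simulate_birth_death(chain, plan)
        assert out.size == 4000
        assert out.mean() == pytest.approx(5.0, abs=0.3)


class TestNetwork:
    def test_independent_genes_poisson(self):
        net = NetworkChain(
            m=2,
            f=[lambda n: 3.0, lambda n: 3.0],
            g=[lambda n: 1.0, lambda n: 1.0],
            box=(60, 60),
            initial_state=(0, 0),
        )
        out = simulate_network(net, SimulationPlan(n_cells=4000, seed=13))
        for i in (0, 1):
            assert fano(out[:, i]) == pytest.approx(1.0, abs=5 * vmr_se(1.0, 4000))

    def test_example2_sample_vmr(self, example2_chain):
        out = simulate_network(example2_chain, SimulationPlan(n_cells=4000, seed=17))
        expect = 2 * np.e / (4 * np.e - 1)
        for i in (0, 1):
            assert fano(out[:, i]) == pytest.approx(expect, abs=0.06)

    def test_cascade_child_vmr_at_least_one(self):
        # no autoregulation anywhere, acyclic, constant degradation:
        # child VMR >= 1 both in the exact solve and by simulation
        net = NetworkChain(
            m=2,
            f=[lambda n: 4.0, lambda n: 1.0 + 1.0 * n[0]],
            g=[lambda n: 1.0, lambda n: 1.0],
            box=(80, 80),
            initial_state=(0, 0),
        )
        exact = marginal_vmr(stationary_network(net), 1)
        assert exact >= 1.0 - 1e-10
        out = simulate_network(net, SimulationPlan(n_cells=4000, seed=19))
        assert fano(out[:, 1]) == pytest.approx(exact, abs=5 * vmr_se(exact, 4000))

    def test_seed_determinism(self, example2_chain):
        plan = SimulationPlan(n_cells=100, seed=23)
        a = simulate_network(example2_chain, plan)
        b = simulate_network(example2_chain, plan)
        assert np.array_equal(a, b)


class TestMultiStep:
    def test_k1_reduces_to_poisson(self):
        # single exponential stage at rate 1, degradation 0.01 -> Poisson(100)
        model = MultiStepCycleModel(k=1, stage_rate=1.0, deg_rate=0.01)
        out = simulate_multistep_cycle(model, SimulationPlan(n_cells=3000, seed=29))
        assert out.mean() == pytest.approx(100.0, abs=1.0)
        assert fano(out) == pytest.approx(1.0, abs=5 * vmr_se(1.0, 3000))

    def test_deterministic_cycle_underdispersed(self):
        # moderate stage count already pushes the VMR well below 1
        model = MultiStepCycleModel(k=40, stage_rate=40.0, deg_rate=0.05)
        out = simulate_multistep_cycle(model, SimulationPlan(n_cells=2000, seed=31))
        assert out.mean() == pytest.approx(20.0, rel=0.1)
        assert fano(out) < 0.75

    def test_seed_determinism(self):
        model = MultiStepCycleModel(k=10, stage_rate=10.0, deg_rate=0.1)
        plan = SimulationPlan(n_cells=100, seed=37)
        assert np.array_equal(
            simulate_multistep_cycle(model, plan), simulate_multistep_cycle(model, plan)
        )


class TestTelegraph:
    def test_bursting_overdispersed_matches_closed_form(self):
        model = TelegraphModel(k_on=0.1, k_off=0.1, rho_on=20.0, rho_off=0.0, deg=1.0)
        out = simulate_telegraph(model, SimulationPlan(n_cells=6000, seed=41))
        oracle = model.fano_factor()
        assert oracle == pytest.approx(1 + 20 * 0.1 / (0.2 * 1.2))
        assert fano(out) == pytest.approx(oracle, rel=0.12)
        assert fano(out) > 2.0

    def test_state_independent_rates_poisson(self):
        model = TelegraphModel(k_on=1.0, k_off=1.0, rho_on=6.0, rho_off=6.0, deg=1.0)
        out = simulate_telegraph(model, SimulationPlan(n_cells=5000, seed=43))
        assert fano(out) == pytest.approx(1.0, abs=5 * vmr_se(1.0, 5000))

    def test_always_on_poisson(self):
        model = TelegraphModel(k_on=1.0, k_off=0.0, rho_on=8.0, rho_off=0.0, deg=1.0)
        out = simulate_telegraph(model, SimulationPlan(n_cells=5000, seed=47))
        assert out.mean() == pytest.approx(8.0, abs=0.25)
        assert fano(out) == pytest.approx(1.0, abs=5 * vmr_se(1.0, 5000))
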