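import numpy as np
import pytest
from scipy.stats import poisson

from fanoreg.chains import (
    AmbiguousClassError,
    BirthDeathChain,
    ModelError,
    NetworkChain,
    TruncationError,
    classify_rate_autoregulation,
    distribution_moments,
    marginal_distribution,
    marginal_vmr,
    relative_growth_rates,
    stationary_birth_death,
    stationary_network,
)

E2_VMR = 2 * np.e / (4 * np.e - 1)  # closed form for the two-gene gated chain


class TestRelativeGrowthRates:
    def test_constant_ratio(self):
        chain = BirthDeathChain.constant(5.0, 1.0, n_max=10)
        assert np.allclose(relative_growth_rates(chain), 5.0)

    def test_linear_family_values(self):
        # f_n = 2 + (n-1), g_n = 2  ->  h = (1, 1.5, 2, ...)
        chain = BirthDeathChain.linear(k=2.0, b=1.0, c=2.0)
        h = relative_growth_rates(chain, upto=3)
        assert np.allclose(h, [1.0, 1.5, 2.0])

    def test_zero_synthesis(self):
        chain = BirthDeathChain.from_arrays([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert np.allclose(relative_growth_rates(chain), 0.0)

    def test_nonpositive_g_rejected(self):
        chain = BirthDeathChain(f=lambda n: 1.0, g=lambda n: 0.0, n_max=5)
        with pytest.raises(ModelError):
            relative_growth_rates(chain)

    def test_zero_over_zero_warns_and_reads_zero(self):
        chain = BirthDeathChain(
            f=lambda n: 1.0 if n < 3 else 0.0,
            g=lambda n: 1.0 if n < 3 else 0.0,
            n_max=4,
        )
        with pytest.warns(RuntimeWarning):
            h = relative_growth_rates(chain)
        assert h[2] == 0.0


class TestClassify:
    def test_constant_is_none(self):
        assert classify_rate_autoregulation(BirthDeathChain.constant(3.0, 1.0)) == "none"

    def test_linear_positive(self):
        assert classify_rate_autoregulation(BirthDeathChain.linear(2.0, 1.0, 2.0)) == "positive"

    def test_linear_negative(self):
        assert classify_rate_autoregulation(BirthDeathChain.linear(6.0, -2.0, 3.0)) == "negative"

    def test_mixed(self):
        chain = BirthDeathChain.from_arrays([1.0, 2.0, 1.0], [1.0, 1.0, 1.0])
        assert classify_rate_autoregulation(chain) == "mixed"

    def test_single_state_error(self):
        chain = BirthDeathChain.from_arrays([1.0], [1.0])
        with pytest.raises(ModelError):
            classify_rate_autoregulation(chain)


class TestStationaryBirthDeath:
    def test_constant_h_is_poisson(self):
        dist = stationary_birth_death(BirthDeathChain.constant(5.0, 1.0))
        n = np.arange(dist.probabilities.size)
        assert np.allclose(dist.probabilities, poisson.pmf(n, 5.0), atol=1e-12)
        mean, var, vmr = distribution_moments(dist)
        assert abs(vmr - 1.0) < 1e-8
        assert dist.tail_mass_bound < 1e-10

    def test_all_zero_f_point_mass_at_zero(self):
        dist = stationary_birth_death(BirthDeathChain.from_arrays([0.0, 0.0], [1.0, 1.0]))
        assert dist.probabilities.tolist() == [1.0]
        mean, var, vmr = distribution_moments(dist)
        assert (mean, var) == (0.0, 0.0)
        assert np.isnan(vmr)  # undefined VMR is flagged, not raised

    def test_example1_closed_form(self):
        # oracle re-derivation: direct recursion + moment summation gives
        # VMR = 1 + b/(c-b); with b=1, c=2 that is 2
        dist = stationary_birth_death(BirthDeathChain.linear(k=2.0, b=1.0, c=2.0))
        assert distribution_moments(dist)[2] == pytest.approx(2.0, abs=1e-6)

    def test_detailed_balance(self, rng):
        from conftest import make_monotone_chain

        chain = make_monotone_chain(rng, "up")
        dist = stationary_birth_death(chain)
        p = dist.probabilities
        for n in range(1, p.size):
            assert p[n - 1] * chain.f(n) == pytest.approx(p[n] * chain.g(n) * n, rel=1e-9)

    def test_normalization(self):
        for chain in [
            BirthDeathChain.constant(20.0, 2.0),
            BirthDeathChain.linear(3.0, -1.5, 2.0),
            BirthDeathChain.hill(vmax=8.0, K=4.0, coef=2.0, g=1.0, baseline=2.0),
        ]:
            dist = stationary_birth_death(chain)
            assert abs(dist.probabilities.sum() - 1.0) < 1e-10

    def test_truncation_error_when_mass_diverges(self):
        # h_n = 2n grows so fast the recursion never decays
        chain = BirthDeathChain(f=lambda n: 2.0 * n, g=lambda n: 1.0, n_max=50)
        with pytest.raises(TruncationError):
            stationary_birth_death(chain)


class TestMoments:
    def test_point_mass(self):
        p = np.zeros(5)
        p[3] = 1.0
        assert distribution_moments(p) == (3.0, 0.0, 0.0)

    def test_poisson_identity(self):
        p = poisson.pmf(np.arange(60), 5.0)
        mean, var, vmr = distribution_moments(p / p.sum())
        assert mean == pytest.approx(5.0, abs=1e-9)
        assert vmr == pytest.approx(1.0, abs=1e-9)


class TestStationaryNetwork:
    def test_single_species_matches_birth_death(self):
        net = NetworkChain(
            m=1, f=[lambda n: 4.0], g=[lambda n: 1.0], box=(60,), initial_state=(0,)
        )
        joint = stationary_network(net)
        bd = stationary_birth_death(BirthDeathChain.constant(4.0, 1.0, n_max=60))
        marg = marginal_distribution(joint, 0)
        k = min(marg.size, bd.probabilities.size)
        assert np.allclose(marg[:k], bd.probabilities[:k], atol=1e-10)

    def test_example2_closed_form(self, example2_chain):
        joint = stationary_network(example2_chain)
        assert marginal_vmr(joint, 0) == pytest.approx(E2_VMR, abs=1e-6)
        # model is symmetric in the two genes
        assert marginal_vmr(joint, 1) == pytest.approx(marginal_vmr(joint, 0), abs=1e-9)

    def test_example2_reachable_class_is_a_cross(self, example2_chain):
        joint = stationary_network(example2_chain)
        assert all(s[0] == 2 or s[1] == 2 for s in joint.states)

    def test_two_independent_genes_product_poisson(self):
        net = NetworkChain(
            m=2,
            f=[lambda n: 3.0, lambda n: 3.0],
            g=[lambda n: 1.0, lambda n: 1.0],
            box=(50, 50),
            initial_state=(0, 0),
        )
        joint = stationary_network(net)
        for i in (0, 1):
            assert marginal_vmr(joint, i) == pytest.approx(1.0, abs=1e-8)

    def test_species_index_out_of_range(self, example2_chain):
        joint = stationary_network(example2_chain)
        with pytest.raises(IndexError):
            marginal_vmr(joint, 2)

    def test_transient_states_trimmed(self):
        # from 1 the only move is down to the absorbing empty state
        net = NetworkChain(
            m=1, f=[lambda n: 0.0], g=[lambda n: 1.0], box=(3,), initial_state=(1,)
        )
        joint = stationary_network(net)
        assert joint.states.tolist() == [[0]]
        assert joint.probabilities.tolist() == [1.0]

    def test_multiple_closed_classes_rejected(self):
        # from 1 the chain can fall to 0 (absorbing) or jump to 2 (absorbing)
        net = NetworkChain(
            m=1,
            f=[lambda n: 1.0 if n[0] == 1 else 0.0],
            g=[lambda n: 1.0 if n[0] == 1 else 0.0],
            box=(3,),
            initial_state=(1,),
        )
        with pytest.raises(AmbiguousClassError):
            stationary_network(net)

    def test_box_pressure_raises(self):
        net = NetworkChain(
            m=1, f=[lambda n: 50.0], g=[lambda n: 1.0], box=(10,), initial_state=(0,)
        )
        with pytest.raises(TruncationError):
            stationary_network(net)
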