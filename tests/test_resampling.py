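"""Wild multipliers, the xi process, Hadamard-derivative realizations and
Efron's bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgrfs.counting import build_counting
from cgrfs.data import CENSORED, MultistateDataset, map_prog6_to_idm3
from cgrfs.estimators import (
    KM_COMPONENTS,
    AalenJohansenCGRFS,
    KaplanMeierCombination,
    nelson_aalen,
)
from cgrfs.model import IDM3, PROG6
from cgrfs.resampling import (
    WildMultipliers,
    bootstrap_ensemble,
    draw_multipliers,
    efron_resample,
    wild_aje_realization,
    wild_km_realization,
    xi_process,
)

from conftest import pure_survival_dataset, random_prog6_dataset


class TestMultipliers:
    def test_one_draw_per_individual_jump(self, toy):
        m = draw_multipliers(build_counting(toy), seed=1)
        assert m.values.shape == (5,)

    def test_reproducible(self, toy):
        c = build_counting(toy)
        np.testing.assert_array_equal(
            draw_multipliers(c, 7).values, draw_multipliers(c, 7).values
        )

    def test_recurrent_episodes_get_independent_draws(self, toy):
        # individual 2 contributes two separate 0 -> 1 jumps after mapping
        c3 = build_counting(map_prog6_to_idm3(toy))
        m = draw_multipliers(c3, seed=1)
        assert m.values.shape == (5,)
        jumps01 = (c3.jump_from == 0) & (c3.jump_to == 1)
        assert jumps01.sum() == 3  # ind2 twice, ind3 once


class TestXiProcess:
    def test_zero_multipliers_zero_process(self, toy):
        c = build_counting(toy)
        xi = xi_process(c, WildMultipliers(np.zeros(c.n_jumps)))
        assert np.abs(xi.values).max() == 0.0

    def test_single_death_full_risk_set(self):
        # three individuals, one dies at t=2 with Y_0(2-) = 3 = n
        ds = MultistateDataset.from_records(
            PROG6, [(1, 0, 5, 2.0), (2, 0, CENSORED, 3.0), (3, 0, CENSORED, 4.0)]
        )
        c = build_counting(ds)
        g = 1.7
        xi = xi_process(c, WildMultipliers(np.array([g])))
        assert xi.entry(0, 5)(2.0) == pytest.approx(g / np.sqrt(3))
        assert xi.entry(0, 5)(10.0) == pytest.approx(g / np.sqrt(3))

    def test_rows_sum_to_zero(self, rng):
        ds = random_prog6_dataset(rng, 25)
        c = build_counting(ds)
        xi = xi_process(c, draw_multipliers(c, 5))
        assert np.abs(xi.values.sum(axis=2)).max() < 1e-12

    def test_monte_carlo_variance_closed_form(self, rng):
        """var xi_gh(t) = n * sum_{s<=t} dN_gh(s) / Y_g(s-)^2."""
        ds = random_prog6_dataset(rng, 40)
        c = build_counting(ds)
        t = float(np.median(c.times))
        draws = []
        gen = np.random.default_rng(123)
        for _ in range(4000):
            xi = xi_process(c, WildMultipliers(gen.standard_normal(c.n_jumps)))
            draws.append(xi.entry(0, 1)(t))
        j01 = (c.jump_from == 0) & (c.jump_to == 1)
        mask = j01 & (c.times[c.jump_time_idx] <= t)
        yv = c.Y[0, c.jump_time_idx[mask]].astype(float)
        expect = c.n * np.sum(1.0 / yv**2)
        assert np.var(draws) == pytest.approx(expect, rel=0.1)


class TestWildKMRealization:
    def test_zero_multipliers_zero_realization(self, toy):
        c = build_counting(toy)
        km = KaplanMeierCombination().fit(toy)
        xi = xi_process(c, WildMultipliers(np.zeros(c.n_jumps)))
        r = wild_km_realization(c, km.components_, xi)
        assert np.abs(r.y).max() == 0.0

    def test_pure_survival_collapses_to_km_wild(self, rng):
        """With only 0 -> 5 jumps the five terms collapse with net coefficient
        one: B^(t) = -S^(t) xi_05(t) exactly, per draw."""
        ds = pure_survival_dataset(rng, 60)
        c = build_counting(ds)
        km = KaplanMeierCombination().fit(ds)
        gen = np.random.default_rng(9)
        for _ in range(5):
            xi = xi_process(c, WildMultipliers(gen.standard_normal(c.n_jumps)))
            r = wild_km_realization(c, km.components_, xi)
            expect = -km.survival_function_.y * xi.values[:, 0, 5]
            np.testing.assert_allclose(r.y, expect, atol=1e-10)

    def test_linear_in_multipliers_with_enumerated_coefficients(self, toy):
        """On the example data the realization is a linear map of the five
        draws; its coefficient matrix is recovered by injecting unit vectors
        and reproduces arbitrary draws (hence the induced covariance is the
        explicit 5x5 quadratic form)."""
        c = build_counting(toy)
        km = KaplanMeierCombination().fit(toy)
        coef = np.empty((5, len(c.times)))
        for e in range(5):
            unit = np.zeros(5)
            unit[e] = 1.0
            xi = xi_process(c, WildMultipliers(unit))
            coef[e] = wild_km_realization(c, km.components_, xi).y
        gen = np.random.default_rng(4)
        for _ in range(10):
            g = gen.standard_normal(5)
            xi = xi_process(c, WildMultipliers(g))
            r = wild_km_realization(c, km.components_, xi)
            np.testing.assert_allclose(r.y, g @ coef, atol=1e-12)
        ens = bootstrap_ensemble(toy, "km_comb", "wild", 4000, seed=2)
        np.testing.assert_allclose(
            np.cov(ens.realizations, rowvar=False), coef.T @ coef, atol=0.35
        )


class TestWildAJERealization:
    def test_zero_multipliers_zero(self, toy):
        c = build_counting(toy)
        probs = AalenJohansenCGRFS("prog6").fit(toy).transition_probabilities_
        xi = xi_process(c, WildMultipliers(np.zeros(c.n_jumps)))
        r = wild_aje_realization(c, probs, xi, [0, 2, 4])
        assert np.abs(r.y).max() == 0.0

    def test_functional_over_all_states_is_zero(self, rng):
        # xi rows sum to zero and P^ rows to one, so D rows sum to zero
        ds = random_prog6_dataset(rng, 20)
        c = build_counting(ds)
        probs = AalenJohansenCGRFS("prog6").fit(ds).transition_probabilities_
        xi = xi_process(c, draw_multipliers(c, 3))
        r = wild_aje_realization(c, probs, xi, range(6))
        assert np.abs(r.y).max() < 1e-10

    def test_pure_survival_closed_form(self, rng):
        """In the survival reduction the AJ realization for state 0 equals
        -S^(t) sum_{s<=t} {S^(s-)/S^(s)} dxi_05(s) wherever S^(s) > 0."""
        ds = pure_survival_dataset(rng, 40, cens_rate=0.02)
        c = build_counting(ds)
        aje = AalenJohansenCGRFS("prog6").fit(ds)
        probs = aje.transition_probabilities_
        surv = aje.survival_function_
        xi = xi_process(c, draw_multipliers(c, 11))
        r = wild_aje_realization(c, probs, xi, [0])
        dxi = xi.increments[:, 0, 5]
        s = surv.y
        s_prev = np.concatenate([[1.0], s[:-1]])
        alive = s > 0
        expect = np.where(
            alive, -s * np.cumsum(np.where(alive, s_prev / np.where(alive, s, 1.0), 0.0) * dxi), 0.0
        )
        np.testing.assert_allclose(r.y[alive], expect[alive], atol=1e-10)

    def test_rejects_bad_functional(self, toy):
        c = build_counting(toy)
        probs = AalenJohansenCGRFS("prog6").fit(toy).transition_probabilities_
        xi = xi_process(c, WildMultipliers(np.zeros(c.n_jumps)))
        with pytest.raises(ValueError):
            wild_aje_realization(c, probs, xi, [7])


class TestEfronResample:
    def test_paths_are_copies_of_originals(self, toy):
        rs = efron_resample(toy, seed=3)
        assert rs.n_individuals == 3
        originals = [
            toy.records_of(i)[["from", "to", "time"]].to_numpy().tolist()
            for i in toy.ids
        ]
        for i in rs.ids:
            path = rs.records_of(i)[["from", "to", "time"]].to_numpy().tolist()
            assert path in originals

    def test_reproducible(self, toy):
        assert efron_resample(toy, 5) == efron_resample(toy, 5)

    def test_omission_probability(self, rng):
        """A fixed individual is left out of a resample with probability
        (1 - 1/n)^n."""
        ds = random_prog6_dataset(rng, 40)
        from cgrfs.counting import record_arrays

        rec = record_arrays(ds)
        gen = np.random.default_rng(17)
        omitted = 0
        trials = 3000
        for _ in range(trials):
            idx = gen.integers(0, rec.n, rec.n)
            omitted += 0 not in idx
        expect = (1 - 1 / rec.n) ** rec.n
        se = np.sqrt(expect * (1 - expect) / trials)
        assert omitted / trials == pytest.approx(expect, abs=4 * se)


class TestEnsembles:
    def test_injected_zero_multipliers(self, toy):
        c = build_counting(toy)
        ens = bootstrap_ensemble(
            toy, "km_comb", "wild", 1, seed=0, multipliers=np.zeros((1, c.n_jumps))
        )
        assert np.abs(ens.realizations).max() == 0.0

    def test_efron_toy_smoke(self, toy):
        ens = bootstrap_ensemble(toy, "km_comb", "efron", 25, seed=1)
        assert ens.realizations.shape == (25, 5)
        assert np.isfinite(ens.realizations).all()

    def test_invalid_combinations_rejected(self, toy):
        with pytest.raises(ValueError):
            bootstrap_ensemble(toy, "km_comb", "wild", 0, seed=1)
        with pytest.raises(ValueError):
            bootstrap_ensemble(toy, "nope", "wild", 5, seed=1)
        idm = map_prog6_to_idm3(toy)
        with pytest.raises(ValueError):
            bootstrap_ensemble(idm, "km_comb", "wild", 5, seed=1)

    def test_wild_ensemble_mean_vanishes(self, rng):
        """CLT check: the ensemble mean shrinks at the 1/sqrt(B) rate."""
        ds = random_prog6_dataset(rng, 50)
        ens = bootstrap_ensemble(ds, "km_comb", "wild", 2000, seed=8)
        t = float(np.median(ens.grid))
        vals = ens.at(t)
        assert abs(vals.mean()) <= 4 * vals.std(ddof=1) / np.sqrt(ens.B)

    def test_wild_and_efron_variances_agree_for_aje(self):
        """On a large simulated dataset the two resampling schemes target the
        same limit variance of the Aalen-Johansen CGRFS estimator."""
        from cgrfs.simulate import SimulationConfig, simulate_prog6

        ds = simulate_prog6(SimulationConfig(n=1000), seed=21)
        vw = bootstrap_ensemble(ds, "aje_prog6", "wild", 500, seed=1).at(500.0).var()
        ve = bootstrap_ensemble(ds, "aje_prog6", "efron", 500, seed=2).at(500.0).var()
        assert vw / ve == pytest.approx(1.0, abs=0.3)


@settings(max_examples=10, deadline=None)
@given(seed=st.integers(0, 1000))
def test_xi_row_sums_property(seed):
    rng = np.random.default_rng(seed)
    ds = random_prog6_dataset(rng, int(rng.integers(2, 20)))
    c = build_counting(ds)
    if c.n_jumps == 0:
        return
    xi = xi_process(c, draw_multipliers(c, seed))
    assert np.abs(xi.values.sum(axis=2)).max() < 1e-12
    assert np.array_equal(xi.x, c.times)
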