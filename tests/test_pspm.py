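"""Cohort model: within-season ODEs, maturation and reproduction maps."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from seasonpop import (
    Cohort,
    PSPMState,
    ResourceParams,
    SpeciesParams,
    aggregate_biomasses,
    apply_maturation,
    apply_reproduction_pspm,
    cull_and_compact,
    expected_adult_contribution,
    maturation_event_fn,
    net_production,
    pspm_rhs,
)


def _total_biomass(state):
    return float(np.sum(state.c * (state.s + state.g)))


class TestRHS:
    def test_empty_population_recovers_semichemostat(self, sp50):
        rp = ResourceParams(Rmax=20.0, delta=0.1)
        st = PSPMState.empty(R=10.0)
        _, _, _, dR = pspm_rhs(st, sp50, rp)
        assert dR == pytest.approx(1.0)

    def test_starving_juvenile_stops_growing(self, sp50, rp):
        R = 0.5  # intake below maintenance for q = 1
        nu = net_production(R, "juvenile", sp50)
        assert nu < 0
        st = PSPMState.from_cohorts([Cohort(c=0.2, s=10.0)], R=R)
        dc, ds, dg, _ = pspm_rhs(st, sp50, rp)
        assert ds[0] == 0.0
        assert dc[0] == pytest.approx(-(sp50.rates.mu - nu) * 0.2)
        assert dg[0] == 0.0

    def test_adult_stores_at_saturating_resource(self, sp50):
        rp = ResourceParams(Rmax=1e12, delta=0.1)
        st = PSPMState.from_cohorts([Cohort(c=0.01, s=50.0, adult=True)], R=1e12)
        dc, ds, dg, _ = pspm_rhs(st, sp50, rp)
        assert ds[0] == 0.0
        assert dg[0] == pytest.approx(0.0150424 * 50.0, rel=1e-4)

    def test_storage_does_not_graze(self, sp50, rp):
        lean = PSPMState.from_cohorts([Cohort(c=0.1, s=50.0, g=0.0, adult=True)], R=5.0)
        fat = PSPMState.from_cohorts([Cohort(c=0.1, s=50.0, g=30.0, adult=True)], R=5.0)
        assert pspm_rhs(lean, sp50, rp)[3] == pspm_rhs(fat, sp50, rp)[3]


class TestMaturation:
    def test_event_indicator(self, sp50):
        st = PSPMState.from_cohorts(
            [Cohort(c=1.0, s=50.0, adult=True), Cohort(c=1.0, s=49.9)], R=5.0
        )
        assert maturation_event_fn(st, 50.0) == pytest.approx(-0.1)
        st2 = PSPMState.from_cohorts([Cohort(c=1.0, s=50.0)], R=5.0)
        assert maturation_event_fn(st2, 50.0) == 0.0

    def test_no_juveniles_gives_sentinel(self):
        st = PSPMState.from_cohorts([Cohort(c=1.0, s=50.0, adult=True)], R=5.0)
        assert maturation_event_fn(st, 50.0) == -np.inf

    def test_identity_map_on_cohort(self, sp50):
        st = PSPMState.from_cohorts([Cohort(c=0.2, s=50.0, g=0.0)], R=7.0)
        out = apply_maturation(st, sp50)
        assert out.adult[0]
        assert (out.c[0], out.s[0], out.g[0]) == (0.2, 50.0, 0.0)
        assert out.R == st.R
        assert _total_biomass(out) == pytest.approx(_total_biomass(st), rel=1e-12)

    def test_rejects_cohort_away_from_maturation_size(self, sp50):
        st = PSPMState.from_cohorts([Cohort(c=0.2, s=30.0)], R=7.0)
        with pytest.raises(RuntimeError):
            apply_maturation(st, sp50)


class TestReproduction:
    def test_newborn_density_from_storage(self):
        # two adult cohorts spending (0.5 + 0.5) storage biomass at Sb = 5
        p = SpeciesParams.from_adult_mass(50.0)
        st = PSPMState.from_cohorts(
            [
                Cohort(c=1.0, s=50.0, g=0.5, adult=True),
                Cohort(c=2.0, s=50.0, g=0.25, adult=True),
            ],
            R=5.0,
        )
        out = apply_reproduction_pspm(st, p)
        assert out.n_cohorts == 3
        assert out.c[-1] == pytest.approx(0.2)
        assert out.s[-1] == 5.0
        assert np.all(out.g == 0.0)
        assert out.R == st.R

    def test_no_storage_is_identity(self, sp50):
        st = PSPMState.from_cohorts([Cohort(c=1.0, s=20.0)], R=5.0)
        out = apply_reproduction_pspm(st, sp50)
        assert out.n_cohorts == 1
        np.testing.assert_array_equal(out.c, st.c)

    def test_biomass_conserved_across_pulse(self, sp50):
        st = PSPMState.from_cohorts(
            [
                Cohort(c=0.3, s=50.0, g=12.0, adult=True),
                Cohort(c=0.7, s=8.0),
            ],
            R=5.0,
        )
        out = apply_reproduction_pspm(st, sp50)
        assert _total_biomass(out) == pytest.approx(_total_biomass(st), rel=1e-12)
        # newborn biomass equals the storage spent
        assert out.c[-1] * sp50.Sb == pytest.approx(0.3 * 12.0, rel=1e-12)


class TestCulling:
    def test_zero_threshold_keeps_everything(self, sp50):
        st = PSPMState.from_cohorts([Cohort(c=1e-30, s=5.0)], R=5.0)
        out, removed = cull_and_compact(st, eps_c=0.0)
        assert out.n_cohorts == 1 and removed == 0.0

    def test_tiny_cohort_removed_and_logged(self):
        st = PSPMState.from_cohorts(
            [Cohort(c=1.0, s=50.0, adult=True), Cohort(c=1e-20, s=5.0)], R=5.0
        )
        out, removed = cull_and_compact(st, eps_c=1e-15)
        assert out.n_cohorts == 1
        assert removed == pytest.approx(5e-20)

    def test_relative_biomass_rule(self):
        st = PSPMState.from_cohorts(
            [Cohort(c=1.0, s=50.0, adult=True), Cohort(c=1e-16, s=5.0)], R=5.0
        )
        out, _ = cull_and_compact(st, rel_biomass=1e-12)
        assert out.n_cohorts == 1


class TestAggregation:
    def test_empty(self):
        agg = aggregate_biomasses(PSPMState.empty(R=0.0))
        assert agg == {"J": 0.0, "A": 0.0, "B": 0.0, "total": 0.0, "R": 0.0}

    def test_stage_sums(self):
        st = PSPMState.from_cohorts(
            [Cohort(c=0.1, s=5.0), Cohort(c=0.01, s=50.0, g=10.0, adult=True)], R=2.0
        )
        agg = aggregate_biomasses(st)
        assert agg["J"] == pytest.approx(0.5)
        assert agg["A"] == pytest.approx(0.5)
        assert agg["B"] == pytest.approx(0.1)
        assert agg["total"] == pytest.approx(1.1)


class TestBiomassBalance:
    def test_rhs_matches_production_minus_mortality(self, sp50, rp, rng):
        """Between events d(total)/dt must equal production on structural
        biomass minus mortality on structural plus stored biomass."""
        from seasonpop import net_production, positive_part, stage_mortality

        for _ in range(25):
            R = rng.uniform(0.0, 20.0)
            st = PSPMState.from_cohorts(
                [
                    Cohort(c=rng.uniform(0, 1), s=50.0, g=rng.uniform(0, 20), adult=True),
                    Cohort(c=rng.uniform(0, 1), s=rng.uniform(5, 49)),
                    Cohort(c=rng.uniform(0, 1), s=rng.uniform(5, 49)),
                ],
                R=R,
            )
            dc, ds, dg, _ = pspm_rhs(st, sp50, rp)
            d_total = float(np.sum(dc * (st.s + st.g) + st.c * (ds + dg)))
            expected = 0.0
            for ci, si, gi, ad in zip(st.c, st.s, st.g, st.adult):
                stage = "adult" if ad else "juvenile"
                nu = net_production(R, stage, sp50)
                d = stage_mortality(nu, sp50.rates.mu)
                expected += positive_part(nu) * ci * si - d * ci * (si + gi)
            assert d_total == pytest.approx(expected, rel=1e-12, abs=1e-15)


class TestConstantEnvironment:
    def test_cohort_matures_at_predicted_age_with_predicted_biomass(self, sp50, rp):
        """With the resource frozen, a newborn cohort reaches Sm at age
        -ln(z)/nu carrying exactly the expected adult contribution."""
        R = 1e12  # saturating: nu_J = sigma*M - T
        nu = net_production(R, "juvenile", sp50)
        mu = sp50.rates.mu
        st = PSPMState.from_cohorts([Cohort(c=1.0, s=sp50.Sb)], R=R)

        def rhs(t, y):
            s = PSPMState(
                c=y[:1], s=y[1:2], g=y[2:3], adult=np.array([False]), R=R, t=t
            )
            dc, ds, dg, _ = pspm_rhs(s, sp50, rp)
            return [dc[0], ds[0], dg[0], 0.0]  # resource dynamics frozen

        def hit_Sm(t, y):
            return y[1] - sp50.Sm

        hit_Sm.terminal = True
        sol = solve_ivp(
            rhs, (0.0, 1000.0), [1.0, sp50.Sb, 0.0, R],
            events=hit_Sm, rtol=1e-10, atol=1e-12,
        )
        a_m = sol.t_events[0][0]
        assert a_m == pytest.approx(-np.log(sp50.z) / nu, rel=1e-6)
        delivered = sol.y_events[0][0, 0] * sp50.Sm  # c(a_m) * Sm per newborn
        assert delivered == pytest.approx(
            expected_adult_contribution(nu, mu, sp50.z, sp50.Sm), rel=1e-6
        )

    def test_size_ordering_preserved_under_growth(self, sp50, rp):
        # identical mass-specific growth cannot reorder cohorts
        st = PSPMState.from_cohorts(
            [Cohort(c=1.0, s=s0) for s0 in (40.0, 20.0, 10.0, 5.0)], R=10.0
        )

        def rhs(t, y):
            s = PSPMState(
                c=y[:4], s=y[4:8], g=y[8:12], adult=np.zeros(4, bool), R=y[12], t=t
            )
            dc, ds, dg, dR = pspm_rhs(s, sp50, rp)
            return np.concatenate([dc, ds, dg, [dR]])

        y0 = np.concatenate([st.c, st.s, st.g, [st.R]])
        sol = solve_ivp(rhs, (0.0, 200.0), y0, rtol=1e-8, atol=1e-10)
        sizes = sol.y[4:8]
        assert np.all(np.diff(sizes, axis=0) < 0)
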