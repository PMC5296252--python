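"""Equilibrium model and dataset generator."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from phosphocycle.simulate import (
    CdkCurve,
    SimulationConfig,
    UndefinedStateError,
    cdk_activity,
    generate_site_panel,
    half_activation_threshold,
    simulate_silac_mixture,
    simulate_timecourse,
    steady_state_occupancy,
    study_site_table,
)

rates = st.floats(min_value=1e-3, max_value=1e3)


class TestCdkActivity:
    def test_midpoint_and_asymptotes(self):
        curve = CdkCurve(c0=0.2, cmax=1.4, t_half=40.0, tau=5.0)
        assert cdk_activity(40.0, curve) == pytest.approx((0.2 + 1.4) / 2)
        assert cdk_activity(-1e4, curve) == pytest.approx(0.2, abs=1e-6)
        assert cdk_activity(1e4, curve) == pytest.approx(1.4, abs=1e-6)

    def test_logistic_value(self):
        # independent high-precision evaluation of 1/(1+e^-1)
        curve = CdkCurve(c0=0.0, cmax=1.0, t_half=50.0, tau=10.0)
        assert cdk_activity(60.0, curve) == pytest.approx(0.7310585786300049, rel=1e-12)

    def test_monotone_in_time(self):
        curve = CdkCurve()
        t = np.linspace(-50, 200, 400)
        values = cdk_activity(t, curve)
        assert np.all(np.diff(values) > 0)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            CdkCurve(tau=0.0)


class TestOccupancy:
    @pytest.mark.parametrize(
        "k,c,d,p,expected",
        [
            (1.0, 0.0, 1.0, 1.0, 0.0),  # no kinase activity
            (3.0, 2.0, 2.0, 3.0, 0.5),  # kC == dP balance point
            (2.0, 1.0, 1.0, 1.0, 2.0 / 3.0),
        ],
    )
    def test_known_values(self, k, c, d, p, expected):
        assert steady_state_occupancy(k, c, d, p) == pytest.approx(expected)

    def test_undefined_state(self):
        with pytest.raises(UndefinedStateError):
            steady_state_occupancy(1.0, 0.0, 1.0, 0.0)

    @given(k=rates, d=rates, p=rates, c1=rates, c2=rates)
    @settings(max_examples=150, deadline=None)
    def test_bounds_and_monotonicity_in_activity(self, k, d, p, c1, c2):
        lo, hi = sorted([c1, c2])
        o_lo = steady_state_occupancy(k, lo, d, p)
        o_hi = steady_state_occupancy(k, hi, d, p)
        assert 0.0 <= o_lo <= 1.0 and 0.0 <= o_hi <= 1.0
        if hi > lo:
            assert o_hi > o_lo

    @given(k=rates, d=rates, c=rates, p1=rates, p2=rates)
    @settings(max_examples=150, deadline=None)
    def test_monotone_decreasing_in_phosphatase(self, k, d, c, p1, p2):
        lo, hi = sorted([p1, p2])
        if hi > lo:
            assert steady_state_occupancy(k, c, d, hi) < steady_state_occupancy(k, c, d, lo)


class TestThreshold:
    @pytest.mark.parametrize(
        "k,d,p,expected", [(1, 1, 1, 1.0), (1, 1, 0, 0.0), (2, 3, 2, 3.0)]
    )
    def test_known_values(self, k, d, p, expected):
        assert half_activation_threshold(k, d, p) == pytest.approx(expected)

    @given(k=rates, d=rates, p=rates)
    @settings(max_examples=100, deadline=None)
    def test_threshold_gives_half_occupancy(self, k, d, p):
        c_star = half_activation_threshold(k, d, p)
        if c_star > 0:
            assert steady_state_occupancy(k, c_star, d, p) == pytest.approx(0.5)


class TestPanel:
    def test_no_threonine_when_fraction_zero(self):
        config = SimulationConfig(n_sites=50, fraction_threonine=0.0, seed=1)
        assert all(s.acceptor == "S" for s in generate_site_panel(config))

    def test_threonine_fraction_within_binomial_bound(self):
        config = SimulationConfig(n_sites=1000, fraction_threonine=0.2, seed=11)
        panel = generate_site_panel(config)
        n_t = sum(s.acceptor == "T" for s in panel)
        sd = math.sqrt(1000 * 0.2 * 0.8)
        assert abs(n_t - 200) <= 3 * sd

    def test_deterministic_under_seed(self, fast_config, fast_panel):
        again = generate_site_panel(dataclasses.replace(fast_config))
        assert again == fast_panel

    def test_windows_consistent_with_proteins(self, fast_panel_with_proteins):
        from phosphocycle.site_tables import extract_window

        panel, proteins = fast_panel_with_proteins
        for site in panel:
            assert extract_window(proteins[site.protein_id], site.position) == site.window

    def test_sensitivity_biased_to_threonine_cdk_sites(self, fast_panel):
        for site in fast_panel:
            if site.acceptor == "T" and "minimal_cdk" in site.motif_labels:
                assert site.cdc55_sensitivity >= 1.0
            else:
                assert site.cdc55_sensitivity == 1.0

    def test_empty_panel_valid(self):
        assert generate_site_panel(SimulationConfig(n_sites=0)) == []

    def test_invalid_proportion_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(fraction_threonine=1.5)


class TestSilacMixture:
    def test_control_noise_free_is_exactly_one(self, fast_panel):
        config = SimulationConfig(n_sites=300, seed=7, noise_sd_log2=0.0, missing_rate=0.0)
        mixture = simulate_silac_mixture(fast_panel, "wildtype", "wildtype", "G1", config)
        assert mixture.direction == "control"
        assert (mixture.ratios == 1.0).all()

    def test_forward_raises_sensitive_site_ratio(self, fast_panel):
        config = SimulationConfig(n_sites=300, seed=7, noise_sd_log2=0.0, missing_rate=0.0)
        mixture = simulate_silac_mixture(fast_panel, "phosphatase_null", "wildtype", "G2", config)
        assert mixture.direction == "forward"
        sensitive = [s for s in fast_panel if s.cdc55_sensitivity > 1.5]
        assert sensitive, "panel should contain phosphatase-sensitive sites"
        for site in sensitive:
            assert mixture.ratios[site.site_id] > 1.0

    def test_reverse_direction_label(self, fast_panel, fast_config):
        mixture = simulate_silac_mixture(fast_panel, "wildtype", "phosphatase_null", "S", fast_config)
        assert mixture.direction == "reverse"

    def test_seeded_run_reproducible(self, fast_panel, fast_config):
        a = simulate_silac_mixture(fast_panel, "phosphatase_null", "wildtype", "G1", fast_config)
        b = simulate_silac_mixture(fast_panel, "phosphatase_null", "wildtype", "G1", fast_config)
        pd.testing.assert_series_equal(a.ratios, b.ratios)

    def test_unknown_phase_rejected(self, fast_panel, fast_config):
        with pytest.raises(ValueError, match="phase"):
            simulate_silac_mixture(fast_panel, "wildtype", "wildtype", "M-phase", fast_config)


def _half_max_crossing(site, config) -> float:
    """Numerical root-finding oracle: time at which the noise-free
    metaphase-referenced trajectory crosses half of its final value."""
    d = site.effective_d("wildtype")
    ref = steady_state_occupancy(site.k_kin, cdk_activity(90.0, config.cdk_curve), d)

    def f(t):
        return steady_state_occupancy(site.k_kin, cdk_activity(t, config.cdk_curve), d) / ref - 0.5

    return brentq(f, -500.0, 90.0)


class TestTimecourse:
    def test_noise_free_equals_closed_form(self, fast_panel):
        config = SimulationConfig(n_sites=300, seed=7, noise_sd_log2=0.0, missing_rate=0.0)
        table = simulate_timecourse(fast_panel, config)
        site = fast_panel[0]
        d = site.effective_d("wildtype")
        for t in config.timepoints:
            occ = steady_state_occupancy(site.k_kin, cdk_activity(t, config.cdk_curve), d)
            ref = steady_state_occupancy(site.k_kin, cdk_activity(90.0, config.cdk_curve), d)
            assert table.loc[site.site_id, int(t)] == pytest.approx(occ / ref)

    def test_higher_sensitivity_crosses_half_max_later(self, fast_config):
        base = dict(
            site_id="a", protein_id="p", position=7, acceptor="T",
            window="AAAAAATPAKAAA", motif_labels=frozenset({"minimal_cdk", "pTP"}),
            k_kin=50.0, d_phos=1.0, abundance=1.0,
        )
        from phosphocycle.simulate import SiteKineticSpec

        lo = SiteKineticSpec(cdc55_sensitivity=1.0, **base)
        hi = SiteKineticSpec(cdc55_sensitivity=5.0, **{**base, "site_id": "b"})
        assert _half_max_crossing(hi, fast_config) > _half_max_crossing(lo, fast_config)

    def test_half_max_ordering_matches_threshold_ordering(self, fast_panel, fast_config):
        # threshold ordering oracle on a spread of sites
        sites = fast_panel[::40]
        crossings = [_half_max_crossing(s, fast_config) for s in sites]
        thresholds = [s.d_phos * s.cdc55_sensitivity / s.k_kin for s in sites]
        assert np.array_equal(np.argsort(crossings), np.argsort(thresholds))

    def test_constitutive_site_flat_profile(self):
        from phosphocycle.simulate import SiteKineticSpec

        config = SimulationConfig(n_sites=1, seed=0, noise_sd_log2=0.0, missing_rate=0.0)
        site = SiteKineticSpec(
            site_id="c", protein_id="p", position=7, acceptor="S",
            window="AAAAAASPAKAAA", motif_labels=frozenset({"minimal_cdk", "pSP"}),
            k_kin=1e9, d_phos=1.0, cdc55_sensitivity=1.0, abundance=1.0,
        )
        table = simulate_timecourse([site], config)
        assert np.allclose(table.to_numpy(), 1.0, atol=1e-3)


def test_study_table_deterministic_under_seed(fast_config, fast_panel):
    from phosphocycle.simulate import simulate_silac_study

    t1 = study_site_table(fast_panel, simulate_silac_study(fast_panel, fast_config),
                          simulate_timecourse(fast_panel, fast_config))
    t2 = study_site_table(fast_panel, simulate_silac_study(fast_panel, fast_config),
                          simulate_timecourse(fast_panel, fast_config))
    assert t1.to_csv() == t2.to_csv()
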