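"""Reconvolution fitting, intensity-weighted lifetimes and phasor analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guvchol.flim import (
    DecayHistogram,
    denoise_phasor,
    fit_reconvolution,
    phasor_transform,
    phasor_transform_pixels,
    run_flim_pipeline,
    select_phasor_cloud,
    tau_m_int,
)
from guvchol.phantoms import (
    DecayPhantomSpec,
    expected_decay,
    simulate_decay,
    simulate_two_domain_vesicle,
)

OMEGA = 2.0 * np.pi / 50.0


def noise_free_hist(spec: DecayPhantomSpec) -> DecayHistogram:
    edges, expected, irf = expected_decay(spec)
    return DecayHistogram(bin_edges=edges, counts=expected, irf_counts=irf,
                          rep_period=spec.rep_period)


def mono_phasor(tau: float) -> tuple[float, float]:
    wt = OMEGA * tau
    return 1.0 / (1.0 + wt**2), wt / (1.0 + wt**2)


class TestHistogram:
    def test_validation(self):
        edges = np.linspace(0, 50, 11)
        with pytest.raises(ValueError, match="one more"):
            DecayHistogram(bin_edges=edges, counts=np.ones(11))
        with pytest.raises(ValueError, match="nonnegative"):
            DecayHistogram(bin_edges=edges, counts=-np.ones(10))
        with pytest.raises(ValueError, match="IRF"):
            DecayHistogram(bin_edges=edges, counts=np.ones(10), irf_counts=np.zeros(10))


class TestTauMInt:
    @pytest.mark.parametrize(
        "intensities,lifetimes,expected",
        [
            ([1.0, 0.0], [3.5, 7.0], 3.5),
            ([0.5, 0.5], [2.0, 4.0], 3.0),
            ([0.7, 0.3], [1.5, 5.0], 2.55),
        ],
    )
    def test_tabulated_examples(self, intensities, lifetimes, expected):
        assert tau_m_int(intensities, lifetimes) == pytest.approx(expected)

    def test_zero_total_intensity_errors(self):
        with pytest.raises(ValueError, match="zero"):
            tau_m_int([0.0, 0.0], [2.0, 4.0])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.01, 100.0), min_size=1, max_size=4),
        st.lists(st.floats(0.1, 20.0), min_size=4, max_size=4),
    )
    def test_bounded_by_component_lifetimes(self, intensities, lifetimes):
        k = len(intensities)
        tm = tau_m_int(intensities, lifetimes[:k])
        assert min(lifetimes[:k]) - 1e-9 <= tm <= max(lifetimes[:k]) + 1e-9


class TestReconvolutionFit:
    def test_noise_free_biexponential_recovery(self):
        """Deterministic input: parameters back to < 0.1% relative error
        (fine binning keeps the binned IRF fully resolved)."""
        spec = DecayPhantomSpec(component_fractions=(0.6, 0.4),
                                component_lifetimes=(2.0, 5.0),
                                photon_budget=1e6, n_bins=2048)
        fit = fit_reconvolution(noise_free_hist(spec))
        assert np.allclose(fit.lifetimes, [2.0, 5.0], rtol=1e-3)
        assert np.allclose(fit.intensities / fit.intensities.sum(), [0.6, 0.4], rtol=1e-3)
        assert fit.tau_m_int == pytest.approx(3.2, rel=1e-3)

    def test_monoexponential_data_degenerates_gracefully(self):
        spec = DecayPhantomSpec(component_fractions=(1.0,), component_lifetimes=(3.5,),
                                photon_budget=1e5, seed=21)
        hist, _ = simulate_decay(spec)
        fit = fit_reconvolution(hist, n_components=2)
        assert fit.tau_m_int == pytest.approx(3.5, rel=0.01)
        degenerate = (fit.lifetimes.size == 1) or np.isclose(*fit.lifetimes, rtol=0.2) \
            or fit.intensities.min() < 0.05 * fit.intensities.sum()
        assert degenerate

    def test_pure_background_has_no_decay_signal(self):
        rng = np.random.default_rng(3)
        edges = np.linspace(0, 50, 257)
        irf = np.diff(np.clip((edges - 1.9) / 0.2, 0, 1))
        counts = rng.poisson(40.0, 256)
        hist = DecayHistogram(bin_edges=edges, counts=counts, irf_counts=irf)
        fit = fit_reconvolution(hist)
        assert fit.background > 0.8 * hist.total_counts
        assert fit.redchi == pytest.approx(1.0, abs=0.3)

    def test_too_few_photons_rejected(self):
        spec = DecayPhantomSpec(component_fractions=(1.0,), component_lifetimes=(3.0,),
                                photon_budget=300.0, seed=1)
        hist, _ = simulate_decay(spec)
        with pytest.raises(ValueError, match="photons"):
            fit_reconvolution(hist)

    def test_window_invariance_on_noise_free_data(self):
        spec = DecayPhantomSpec(component_fractions=(0.6, 0.4),
                                component_lifetimes=(2.0, 5.0), photon_budget=1e6)
        hist = noise_free_hist(spec)
        t1 = fit_reconvolution(hist, window=(0.2, 45.0)).tau_m_int
        t2 = fit_reconvolution(hist, window=(0.0, 50.0)).tau_m_int
        assert abs(t1 / t2 - 1.0) < 0.005

    def test_components_sorted_ascending(self):
        spec = DecayPhantomSpec(component_fractions=(0.3, 0.7),
                                component_lifetimes=(1.5, 4.5), photon_budget=1e5, seed=8)
        hist, _ = simulate_decay(spec)
        fit = fit_reconvolution(hist)
        assert np.all(np.diff(fit.lifetimes) >= 0)
        assert min(fit.lifetimes) <= fit.tau_m_int <= max(fit.lifetimes)

    def test_summary_mentions_key_quantities(self):
        spec = DecayPhantomSpec(component_fractions=(0.6, 0.4),
                                component_lifetimes=(2.0, 5.0), photon_budget=1e5, seed=4)
        hist, _ = simulate_decay(spec)
        text = fit_reconvolution(hist).summary()
        assert "tau_m,int" in text and "chi-square" in text


class TestPhasor:
    def test_known_point_at_omega_tau_half(self):
        """omega*tau = 0.5 maps to (0.8, 0.4) exactly."""
        tau = 0.5 / OMEGA
        spec = DecayPhantomSpec(component_fractions=(1.0,), component_lifetimes=(tau,),
                                photon_budget=1e6, n_bins=4096)
        p = phasor_transform(noise_free_hist(spec))
        assert p.g == pytest.approx(0.8, abs=1e-4)
        assert p.s == pytest.approx(0.4, abs=1e-4)
        assert p.phase_lifetime == pytest.approx(tau, rel=1e-4)

    @pytest.mark.parametrize("tau", [0.5, 1.0, 3.979, 7.0])
    def test_monoexponentials_on_universal_semicircle(self, tau):
        spec = DecayPhantomSpec(component_fractions=(1.0,), component_lifetimes=(tau,),
                                photon_budget=1e6, n_bins=4096)
        p = phasor_transform(noise_free_hist(spec))
        assert abs(p.g**2 + p.s**2 - p.g) < 1e-6

    def test_semicircle_endpoints(self):
        fast = DecayPhantomSpec(component_fractions=(1.0,), component_lifetimes=(0.01,),
                                photon_budget=1e6, n_bins=4096)
        slow = DecayPhantomSpec(component_fractions=(1.0,), component_lifetimes=(400.0,),
                                photon_budget=1e6, n_bins=4096)
        p_fast = phasor_transform(noise_free_hist(fast))
        assert (p_fast.g, p_fast.s) == pytest.approx((1.0, 0.0), abs=2e-3)
        p_slow = phasor_transform(noise_free_hist(slow))
        assert np.hypot(p_slow.g, p_slow.s) < 0.15

    def test_mixture_is_midpoint_of_component_phasors(self):
        spec = DecayPhantomSpec(component_fractions=(0.5, 0.5),
                                component_lifetimes=(2.0, 5.0),
                                photon_budget=1e6, n_bins=4096)
        p = phasor_transform(noise_free_hist(spec))
        g1, s1 = mono_phasor(2.0)
        g2, s2 = mono_phasor(5.0)
        assert p.g == pytest.approx((g1 + g2) / 2, abs=1e-6)
        assert p.s == pytest.approx((s1 + s2) / 2, abs=1e-6)
        # mixtures fall strictly inside the semicircle
        assert p.g**2 + p.s**2 < p.g

    def test_empty_histogram_errors(self):
        edges = np.linspace(0, 50, 257)
        hist = DecayHistogram(bin_edges=edges, counts=np.zeros(256))
        with pytest.raises(ValueError, match="empty"):
            phasor_transform(hist)

    def test_phasor_of_fit_matches_phasor_of_data(self):
        """Noise-free biexponential: the fitted model and the data agree in
        phasor space to 1e-4."""
        spec = DecayPhantomSpec(component_fractions=(0.6, 0.4),
                                component_lifetimes=(2.0, 5.0), photon_budget=1e6,
                                n_bins=2048)
        hist = noise_free_hist(spec)
        fit = fit_reconvolution(hist)
        model_hist = DecayHistogram(bin_edges=hist.bin_edges, counts=fit.model_counts,
                                    irf_counts=hist.irf_counts, rep_period=hist.rep_period)
        pd_, pm = phasor_transform(hist), phasor_transform(model_hist)
        assert (pm.g, pm.s) == pytest.approx((pd_.g, pd_.s), abs=1e-4)


class TestPhasorClouds:
    def test_identical_monoexponential_points_recover_tau(self):
        g, s = mono_phasor(4.0)
        from guvchol.flim import PhasorPoint

        pts = [PhasorPoint(g=g, s=s, omega=OMEGA, photons=1000.0) for _ in range(5)]
        sel = select_phasor_cloud(pts, center=(g, s), radius=0.02)
        assert sel.cloud_lifetime == pytest.approx(4.0, rel=1e-9)
        assert sel.member_ids.size == 5

    def test_far_center_is_empty_selection(self):
        from guvchol.flim import PhasorPoint

        pts = [PhasorPoint(g=0.8, s=0.4, omega=OMEGA, photons=10.0)]
        with pytest.raises(ValueError, match="no phasor points"):
            select_phasor_cloud(pts, center=(0.1, 0.1), radius=0.02)

    def test_two_domain_phantom_separates_into_ordered_clouds(self):
        """Phase-separated vesicle: two clouds, ordered-domain lifetime above
        the disordered one, both near their true values."""
        ph = simulate_two_domain_vesicle(4.87, 3.9, n_pixels_per_domain=100,
                                         photons_per_pixel=4000, seed=6)
        pts = phasor_transform_pixels(ph.counts, ph.bin_edges, ph.rep_period, ph.irf_counts)
        g = np.array([p.g for p in pts])
        split = np.median(g)
        taus = []
        for side in (g <= split, g > split):  # low g = long lifetime
            idx = np.flatnonzero(side)
            cg = np.average(g[idx], weights=[pts[i].photons for i in idx])
            cs = np.average([pts[i].s for i in idx], weights=[pts[i].photons for i in idx])
            sel = select_phasor_cloud([pts[i] for i in idx], center=(cg, cs), radius=0.05)
            taus.append(sel.cloud_lifetime)
        tau_long, tau_short = taus
        assert tau_long > tau_short
        assert tau_long == pytest.approx(4.87, abs=0.1)
        assert tau_short == pytest.approx(3.9, abs=0.1)


class TestDenoise:
    def test_constant_field_unchanged(self):
        g = np.full((8, 8), 0.7)
        s = np.full((8, 8), 0.3)
        g2, s2 = denoise_phasor(g, s, strength=3)
        assert np.array_equal(g, g2) and np.array_equal(s, s2)

    def test_single_outlier_removed(self):
        g = np.full((9, 9), 0.7)
        g[4, 4] = 0.1
        g2, _ = denoise_phasor(g, np.zeros_like(g), strength=3)
        assert g2[4, 4] == 0.7

    def test_filtering_increases_cloud_separation(self):
        ph = simulate_two_domain_vesicle(4.87, 3.9, n_pixels_per_domain=128,
                                         photons_per_pixel=800, seed=13)
        pts = phasor_transform_pixels(ph.counts, ph.bin_edges, ph.rep_period, ph.irf_counts)
        g = np.array([p.g for p in pts])
        s = np.array([p.s for p in pts])
        # arrange each domain as a block so the filter works on neighbours
        g_img = g.reshape(16, 16)
        s_img = s.reshape(16, 16)
        labels = ph.labels.reshape(16, 16)

        def separation(gi, si):
            d0 = np.hypot(gi[labels == 0].mean() - gi[labels == 1].mean(),
                          si[labels == 0].mean() - si[labels == 1].mean())
            pooled = 0.5 * (np.hypot(gi[labels == 0].std(), si[labels == 0].std())
                            + np.hypot(gi[labels == 1].std(), si[labels == 1].std()))
            return d0 / pooled

        gf, sf = denoise_phasor(g_img, s_img, strength=3)
        assert separation(gf, sf) > separation(g_img, s_img)


class TestFlimPipeline:
    def test_low_photon_vesicles_flagged(self):
        rich = simulate_decay(DecayPhantomSpec(component_fractions=(1.0,),
                                               component_lifetimes=(3.0,),
                                               photon_budget=5e4, seed=1))[0]
        poor = simulate_decay(DecayPhantomSpec(component_fractions=(1.0,),
                                               component_lifetimes=(3.0,),
                                               photon_budget=100.0, seed=2))[0]
        records, fits, flagged = run_flim_pipeline([("a", rich), ("b", poor)])
        assert [r.vesicle_id for r in records] == ["a"]
        assert flagged == ["b"]

    def test_deterministic_records(self):
        spec = DecayPhantomSpec(component_fractions=(0.25, 0.75),
                                component_lifetimes=(1.5, 3.5),
                                photon_budget=1e5, seed=33)
        h1, _ = simulate_decay(spec)
        h2, _ = simulate_decay(spec)
        r1, _, _ = run_flim_pipeline([h1])
        r2, _, _ = run_flim_pipeline([h2])
        assert r1[0].value == r2[0].value
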