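"""Simulators: determinism, unbiased densities, and agreement with the models."""

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

import gelstruct as gs
from gelstruct import InvalidParameterError
from conftest import band_coverage


@pytest.fixture(scope="module")
def small_domain():
    return gs.Domain(width=400, height=400, pixel_size=0.42)


class TestDomain:
    def test_extent(self):
        d = gs.Domain(width=100, height=50, pixel_size=0.5)
        assert d.width_um == 50.0 and d.height_um == 25.0 and d.shape == (50, 100)

    def test_invalid(self):
        with pytest.raises(InvalidParameterError):
            gs.Domain(width=0, height=10, pixel_size=0.5)


class TestFibres:
    def test_zero_density_gives_empty_image(self, small_domain):
        im = gs.simulate_fibres(small_domain, 0.0, 2.0, 40.0, seed=0)
        assert im.counts.sum() == 0

    def test_determinism(self, small_domain):
        a = gs.simulate_fibres(small_domain, 0.01, 2.0, 40.0, seed=5)
        b = gs.simulate_fibres(small_domain, 0.01, 2.0, 40.0, seed=5)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_area_fraction_matches_boolean_density(self, small_domain):
        # eta = 0.8 -> phi_F = 1 - e^{-0.8}
        f = gs.FibreParams(eta=0.8, D_F=2.0, L_F=40.0)
        fr = [
            gs.simulate_fibres(small_domain, f.theta, f.D_F, f.L_F, s).binary.mean()
            for s in range(15)
        ]
        sem = np.std(fr, ddof=1) / np.sqrt(len(fr))
        assert abs(np.mean(fr) - f.phi_F) < 3 * sem + 1e-12

    def test_covariance_matches_model(self, small_domain):
        f = gs.FibreParams(eta=0.8, D_F=2.0, L_F=40.0)
        curves = []
        for child in np.random.SeedSequence(10).spawn(15):
            im = gs.simulate_fibres(small_domain, f.theta, f.D_F, f.L_F, np.random.default_rng(child))
            cm = gs.autocorrelation_2d(im.binary.astype(float))
            curves.append(gs.radial_profile(cm, small_domain.pixel_size))
        mc = gs.aggregate_replicates(curves)
        model = gs.boolean_covariance(mc.r, f)
        z = (mc.C - model) / mc.sem
        assert band_coverage(z) >= 0.99

    def test_infinite_length_rejected(self, small_domain):
        with pytest.raises(InvalidParameterError):
            gs.simulate_fibres(small_domain, 0.01, 2.0, np.inf, seed=0)


class TestAggregates:
    def test_symmetric_fraction_at_half(self, small_domain):
        a = gs.AggregateParams(phi_A=0.5, L_A=8.0)
        fr = [gs.simulate_aggregates(small_domain, a, s).mean() for s in range(15)]
        sem = np.std(fr, ddof=1) / np.sqrt(len(fr))
        assert abs(np.mean(fr) - 0.5) < 3 * sem

    def test_covariance_matches_model(self, small_domain):
        a = gs.AggregateParams(phi_A=0.6, L_A=6.0)
        curves = []
        for child in np.random.SeedSequence(11).spawn(15):
            m = gs.simulate_aggregates(small_domain, a, np.random.default_rng(child))
            cm = gs.autocorrelation_2d(m.astype(float))
            curves.append(gs.radial_profile(cm, small_domain.pixel_size))
        mc = gs.aggregate_replicates(curves)
        model = gs.clipped_gf_covariance(mc.r, a)
        z = (mc.C - model) / mc.sem
        assert band_coverage(z) >= 0.99

    def test_determinism(self, small_domain):
        a = gs.AggregateParams(phi_A=0.4, L_A=5.0)
        np.testing.assert_array_equal(
            gs.simulate_aggregates(small_domain, a, 3),
            gs.simulate_aggregates(small_domain, a, 3),
        )

    def test_domain_too_small_for_correlation_length(self):
        d = gs.Domain(width=40, height=40, pixel_size=0.5)  # 20 um side
        with pytest.raises(InvalidParameterError):
            gs.simulate_aggregates(d, gs.AggregateParams(phi_A=0.5, L_A=8.0), 0)


class TestGreyTone:
    def test_structureless_image_is_background(self, small_domain):
        # no fibres, no noise: the image is the constant background
        p = gs.GreyToneParams(
            fibre=gs.FibreParams(eta=0.0, D_F=2.0, L_F=40.0),
            aggregate=gs.AggregateParams(phi_A=0.5, L_A=8.0),
            b=17.0, Delta=15.0, sigma=0.0,
        )
        img = gs.simulate_greytone(small_domain, p, 0, quantize=True)
        assert img.dtype == np.uint8
        assert np.all(img == 17)

    def test_mean_matches_model(self, small_domain):
        p = gs.GreyToneParams(
            fibre=gs.FibreParams(eta=1.2, D_F=2.0, L_F=40.0),
            aggregate=gs.AggregateParams(phi_A=0.6, L_A=8.0),
            b=9.0, Delta=15.0, sigma=5.0,
        )
        means = [
            gs.simulate_greytone(small_domain, p, s, quantize=False).mean() for s in range(15)
        ]
        sem = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - gs.mean_intensity(p)) < 3 * sem

    def test_histogram_matches_intensity_distribution(self):
        # chi-square GOF on pixels subsampled beyond the correlation range, so
        # counts are approximately independent; unclipped regime at both ends.
        d = gs.Domain(width=512, height=512, pixel_size=0.5)
        p = gs.GreyToneParams(
            fibre=gs.FibreParams(eta=1.0, D_F=1.5, L_F=8.0),
            aggregate=gs.AggregateParams(phi_A=0.5, L_A=4.0),
            b=30.0, Delta=12.0, sigma=4.0,
        )
        step = int(np.ceil(16.0 / d.pixel_size))  # beyond L_F and ~4 L_A
        vals = np.concatenate(
            [gs.simulate_greytone(d, p, s, quantize=True)[::step, ::step].ravel() for s in range(15)]
        )
        obs = np.bincount(vals, minlength=256).astype(float)
        exp = gs.quantized_intensity_probabilities(p) * vals.size
        # pool adjacent levels to expected counts >= 5
        po, pe, co, ce = [], [], 0.0, 0.0
        for o, e in zip(obs, exp):
            co, ce = co + o, ce + e
            if ce >= 5:
                po.append(co)
                pe.append(ce)
                co = ce = 0.0
        po[-1] += co
        pe[-1] += ce
        po, pe = np.array(po), np.array(pe)
        stat = ((po - pe) ** 2 / pe).sum()
        pval = chi2_dist.sf(stat, len(po) - 1)
        assert pval > 0.01

    def test_determinism(self, small_domain):
        p = gs.GreyToneParams(
            fibre=gs.FibreParams(eta=1.0, D_F=2.0, L_F=40.0),
            aggregate=gs.AggregateParams(phi_A=0.5, L_A=8.0),
            b=9.0, Delta=15.0, sigma=5.0,
        )
        np.testing.assert_array_equal(
            gs.simulate_greytone(small_domain, p, 7), gs.simulate_greytone(small_domain, p, 7)
        )


@pytest.fixture(scope="module")
def spheroid_cfg():
    ramp = np.linspace(0, 1, 3)
    return gs.SpheroidSeriesConfig(
        domain=gs.Domain(width=256, height=256, pixel_size=0.59),
        times_min=(0.0, 360.0, 720.0),
        band_edges_um=(0.0, 30.0, 60.0),
        phi_A=tuple((0.8, 0.6) for _ in range(3)),
        phi_F=tuple((0.5 + 0.3 * t, 0.5) for t in ramp),
        L_A=6.0,
        spheroid_radius_um=20.0,
        radius_growth_um_per_min=0.005,
        n_sprouts=4,
        sprout_speed_um_per_min=0.05,
        sprout_width_um=6.0,
    )


class TestSpheroidSeries:
    def test_determinism(self, spheroid_cfg):
        s1 = gs.simulate_spheroid_series(spheroid_cfg, 21)
        s2 = gs.simulate_spheroid_series(spheroid_cfg, 21)
        for a, b in zip(s1.gel_images, s2.gel_images):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(s1.cell_masks, s2.cell_masks):
            np.testing.assert_array_equal(a, b)

    def test_mask_grows_monotonically(self, spheroid_cfg):
        s = gs.simulate_spheroid_series(spheroid_cfg, 21)
        for m0, m1 in zip(s.cell_masks, s.cell_masks[1:]):
            assert np.all(m1[m0])  # earlier cells stay covered

    def test_step_surface_raises_intensity_only_in_stepped_band(self, spheroid_cfg):
        # phi_F ramps only in band 1: that band's mean intensity rises with
        # time while band 2 stays statistically flat.
        s = gs.simulate_spheroid_series(spheroid_cfg, 21)
        band_means = {1: [], 2: []}
        for img, mask in zip(s.gel_images, s.cell_masks):
            lm = gs.distance_layers(mask, 0.59, spheroid_cfg.band_edges_um)
            for k in band_means:
                band_means[k].append(img[lm.band_mask(k)].mean())
        rise1 = band_means[1][-1] - band_means[1][0]
        rise2 = abs(band_means[2][-1] - band_means[2][0])
        assert rise1 > 2.0  # eta rise of ~0.6 at Delta=15, phi_A=0.8 -> ~+7 levels
        assert rise2 < 2.0

    def test_surface_shape_validation(self, spheroid_cfg):
        with pytest.raises(InvalidParameterError):
            gs.SpheroidSeriesConfig(
                domain=spheroid_cfg.domain,
                times_min=(0.0, 1.0),
                band_edges_um=(0.0, 30.0),
                phi_A=((0.5,),),  # wrong number of rows
                phi_F=((0.5,), (0.5,)),
            )
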