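import numpy as np
import pytest
from scipy import integrate, stats

from conftest import constant_tf, homogeneous_medium, two_layer_medium
from voxtrace.camera import Ray, ThinLensCamera
from voxtrace.fixtures import make_scene
from voxtrace.lights import AreaLight, BackgroundLight
from voxtrace.scattering import MODE_BRDF, MODE_PHASE, HybridParams
from voxtrace.scene import Scene
from voxtrace.transfer import OpticalProperties, optical_properties
from voxtrace.transport import (
    Medium,
    estimate_direct,
    make_scatter_event,
    power_heuristic,
    render_frame,
    render_sample,
    shadow_visible,
    woodcock_track,
)
from voxtrace.volume import GradientSample, Volume
import voxtrace.scattering as sc


def z_rays(n, origin=(0.0, 0.0, 0.0)):
    o = np.tile(origin, (n, 1))
    d = np.tile([0.0, 0.0, 1.0], (n, 1))
    return Ray(o, d, np.zeros(n), np.full(n, np.inf))


class TestWoodcock:
    def test_vacuum_never_scatters(self, rng):
        med = homogeneous_medium(0.0)
        res = woodcock_track(z_rays(1000), 0.0, 100.0, med, rng)
        assert not res.scattered.any()

    def test_homogeneous_free_path_is_exponential(self, rng):
        # sigma_t = sigma_max = 2/mm: free paths ~ Exponential(2)
        med = homogeneous_medium(2.0, extent=4000.0)
        n = 100_000
        res = woodcock_track(z_rays(n, origin=(0, 0, -1500)), 0.0, 3000.0, med, rng)
        assert res.scattered.all()
        t = res.t_scatter
        se = 0.5 / np.sqrt(n)
        assert abs(t.mean() - 0.5) < 3 * se
        # chi-square against the analytic exponential pdf
        edges = np.concatenate([np.linspace(0, 2.0, 21), [np.inf]])
        counts, _ = np.histogram(t, bins=edges)
        probs = np.diff(1.0 - np.exp(-2.0 * edges))
        _, p = stats.chisquare(counts, n * probs)
        assert p > 0.01

    def test_finite_slab_scatter_probability(self, rng):
        # sigma_t * d = 1: P(scatter) = 1 - e^-1
        med = homogeneous_medium(1.0, extent=4000.0)
        n = 100_000
        res = woodcock_track(z_rays(n), 0.0, 1.0, med, rng)
        frac = res.scattered.mean()
        expect = 1.0 - np.exp(-1.0)
        assert abs(frac - expect) < 3 * np.sqrt(expect * (1 - expect) / n)

    def test_heterogeneous_two_layer_depth_distribution(self, rng):
        # majorant rejection in a two-layer medium must reproduce the
        # analytic pdf sigma(t) exp(-int sigma)
        sig_lo, sig_hi = 0.002, 0.006  # mean free paths of 500 / 167 mm
        med, z_eff = two_layer_medium(sig_lo, sig_hi, boundary_voxel=32, extent=1000.0)
        n = 100_000
        res = woodcock_track(z_rays(n, origin=(500.0, 500.0, 0.0)), 0.0, 990.0, med, rng)
        t = res.t_scatter[res.scattered]

        def cdf(x):
            x = np.asarray(x, dtype=float)
            tau = np.where(x < z_eff, sig_lo * x, sig_lo * z_eff + sig_hi * (x - z_eff))
            return 1.0 - np.exp(-tau)

        edges = np.concatenate(
            [np.linspace(0, z_eff, 12)[:-1], [z_eff], np.linspace(z_eff, 990.0, 13)[1:]]
        )
        counts, _ = np.histogram(t, bins=edges)
        probs = np.diff(cdf(edges))
        # include the no-scatter outcome as its own category so observed and
        # expected totals agree exactly
        total = cdf(990.0)
        counts = np.append(counts, n - res.scattered.sum())
        probs = np.append(probs, 1.0 - total)
        _, p = stats.chisquare(counts, n * probs)
        assert res.scattered.mean() == pytest.approx(total, abs=3 * np.sqrt(total * (1 - total) / n))
        assert p > 0.01

    def test_scatter_point_within_clip_range(self, rng):
        med = homogeneous_medium(0.5)
        res = woodcock_track(z_rays(10_000), 2.0, 7.0, med, rng)
        t = res.t_scatter[res.scattered]
        assert t.min() >= 2.0 and t.max() <= 7.0


class TestShadowVisibility:
    def test_vacuum_always_visible(self, rng):
        med = homogeneous_medium(0.0)
        vis = shadow_visible(np.zeros((1000, 3)), np.tile([0, 0, 1.0], (1000, 1)), 50.0, med, rng)
        assert vis.all()

    def test_ln2_slab_transmits_half(self, rng):
        med = homogeneous_medium(np.log(2.0), extent=4000.0)
        n = 100_000
        vis = shadow_visible(
            np.zeros((n, 3)), np.tile([0, 0, 1.0], (n, 1)), 1.0, med, rng
        )
        assert abs(vis.mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_opaque_wall_blocks(self, rng):
        med = homogeneous_medium(1.0, extent=4000.0)
        n = 100_000
        vis = shadow_visible(np.zeros((n, 3)), np.tile([0, 0, 1.0], (n, 1)), 20.0, med, rng)
        assert vis.mean() < 1e-4

    def test_two_layer_transmittance_unbiased(self, rng):
        sig_lo, sig_hi = 0.001, 0.004
        med, z_eff = two_layer_medium(sig_lo, sig_hi, boundary_voxel=32, extent=1000.0)
        span = 40.0
        expect = np.exp(-(sig_lo * z_eff + sig_hi * span))
        n = 100_000
        vis = shadow_visible(
            np.tile([500.0, 500.0, 0.0], (n, 1)),
            np.tile([0, 0, 1.0], (n, 1)),
            z_eff + span,
            med,
            rng,
        )
        assert abs(vis.mean() - expect) < 3 * np.sqrt(expect * (1 - expect) / n)


class TestPowerHeuristic:
    @pytest.mark.parametrize(
        "pa,pb,expect", [(3.0, 3.0, 0.5), (3.0, 0.0, 1.0), (1.0, 2.0, 0.2), (0.0, 0.0, 0.0)]
    )
    def test_spot_values(self, pa, pb, expect):
        assert power_heuristic(pa, pb) == pytest.approx(expect)

    def test_partition_of_unity(self, rng):
        pa, pb = rng.uniform(0, 10, 1000), rng.uniform(0, 10, 1000)
        np.testing.assert_allclose(power_heuristic(pa, pb) + power_heuristic(pb, pa), 1.0)


def phase_event_at(points, medium, wo=None):
    """Build a forced phase-mode event batch at given world points."""
    n = len(points)
    wo = np.tile([0, 0, 1.0], (n, 1)) if wo is None else wo
    ev = make_scatter_event(
        medium, HybridParams(gradient_factor=0.0), np.asarray(points, dtype=float),
        np.ones(n), wo, np.random.default_rng(0),
    )
    return ev


def lambert_style_event_at(points, normal, wo_world, diffuse=0.7):
    """Forced-BRDF event with a fixed shading normal and diffuse-only material."""
    n = len(points)
    normal = np.tile(normal, (n, 1)).astype(float)
    from voxtrace.scattering import make_shading_frame

    nrm, tan, bit = make_shading_frame(normal, np.atleast_2d(wo_world))
    mat = OpticalProperties(
        sigma_t=np.ones(n),
        diffuse=np.full((n, 3), diffuse),
        specular=np.zeros((n, 3)),
        blinn_exponent=np.full(n, 30.0),
        ior=np.ones(n),
        emission=np.zeros((n, 3)),
    )
    return sc.ScatterEvent(
        position=np.asarray(points, dtype=float),
        intensity=np.ones(n),
        opacity=np.ones(n),
        gradient=GradientSample(normal, np.ones(n), np.ones(n)),
        mode=np.full(n, MODE_BRDF),
        normal=nrm, tangent=tan, bitangent=bit,
        material=mat,
        wo_world=np.broadcast_to(wo_world, (n, 3)).copy(),
    )


class TestEstimateDirect:
    def test_background_phase_event_recovers_radiance(self, rng):
        # isotropic event in vacuum under a constant background: the MIS
        # estimate equals L exactly in expectation (value/pdf cancel)
        med = homogeneous_medium(0.0)
        scene = Scene(
            med.volume, med.tf,
            ThinLensCamera((0, 0, -5), (0, 0, 0), (0, 1, 0), 45.0, (4, 4)),
            background=BackgroundLight((0.8, 0.4, 0.2)),
            density_scale=med.density_scale,
        )
        n = 10_000
        ev = phase_event_at(np.zeros((n, 3)), med)
        est = estimate_direct(ev, scene, rng)
        np.testing.assert_allclose(est.mean(axis=0), [0.8, 0.4, 0.2], rtol=0.01)

    def test_fully_occluded_light_contributes_nothing(self, rng):
        # opaque medium everywhere: both strategies shadowed out
        med = homogeneous_medium(5.0, extent=400.0)
        light = AreaLight((0, 0, 150.0), (0, 0, -1.0), (20.0, 20.0), (50.0, 50.0, 50.0))
        scene = Scene(
            med.volume, med.tf,
            ThinLensCamera((0, 0, -5), (0, 0, 1), (0, 1, 0), 45.0, (4, 4)),
            lights=[light], density_scale=med.density_scale,
        )
        n = 2000
        ev = phase_event_at(np.zeros((n, 3)), med)
        est = estimate_direct(ev, scene, rng)
        # unoccluded value would be ~ L * A cos / d^2 / 4pi = O(1)
        assert est.mean() < 1e-3

    @staticmethod
    def quad_light_oracle(scene, event):
        """Quadrature of the direct-light integrand over the quad's area."""
        light = scene.lights[0]
        x0 = event.position[0]
        nrm = event.normal[0]
        wo_l = event.to_local(event.wo_world)[:1]
        mat = event.material.take(slice(0, 1))

        def integrand(v, u):
            pt = light.center + u * light.u_axis + v * light.v_axis
            d = pt - x0
            dist = np.linalg.norm(d)
            wi = d / dist
            cos_l = float(-wi @ light.normal)
            cos_r = float(wi @ nrm)
            if cos_l <= 0 or cos_r <= 0:
                return 0.0
            wi_l = event.to_local(wi[None, :])[:1]
            f = sc.brdf_eval(wi_l, wo_l, mat)[0, 0]
            return f * cos_r * cos_l / dist**2

        hx, hy = light.half_extents
        val, _ = integrate.dblquad(integrand, -hy, hy, -hx, hx, epsabs=1e-10)
        return val * light.radiance[0] if light.radiance.ndim == 1 else val

    def test_mis_matches_quadrature_and_beats_single_strategies(self, rng):
        scene = make_scene("quad_lambert_mis")
        light = scene.lights[0]
        p0 = np.array([14.0, 14.0, 14.0])
        wo = np.array([0.0, 0.0, -1.0])  # toward the camera
        ev1 = lambert_style_event_at(p0[None, :], light.normal * -1, wo)
        oracle = self.quad_light_oracle(scene, ev1)

        n = 20_000
        ev = lambert_style_event_at(np.tile(p0, (n, 1)), light.normal * -1, wo)
        est = estimate_direct(ev, scene, rng)[:, 0]
        se = est.std() / np.sqrt(n)
        assert abs(est.mean() - oracle) < 3 * se

        # variance comparison over independent runs
        runs = 40
        m = 400
        means = {"mis": [], "light": [], "scatter": []}
        for r in range(runs):
            evr = lambert_style_event_at(np.tile(p0, (m, 1)), light.normal * -1, wo)
            for strat in means:
                means[strat].append(
                    estimate_direct(evr, scene, rng, strategy=strat)[:, 0].mean()
                )
        var = {k: np.var(v, ddof=1) for k, v in means.items()}
        assert var["mis"] <= var["light"]
        assert var["mis"] <= var["scatter"]
        # single strategies stay unbiased too
        for strat in ("light", "scatter"):
            assert abs(np.mean(means[strat]) - oracle) < 5 * np.std(means[strat]) / np.sqrt(runs)


class TestRenderSample:
    def test_zero_opacity_volume_passes_background_through(self, rng):
        med = homogeneous_medium(0.0)
        cam = ThinLensCamera((0, 0, -2000), (0, 0, 0), (0, 1, 0), 30.0, (8, 8))
        scene = Scene(med.volume, med.tf, cam,
                      background=BackgroundLight((0.5, 0.5, 0.5)),
                      density_scale=med.density_scale)
        for px in [(0, 0), (4, 4), (7, 3)]:
            L = render_sample(px, scene, rng)
            np.testing.assert_allclose(L, 0.5)

    def test_emissive_homogeneous_medium_matches_closed_form(self, rng):
        # single-scatter emission: pixel mean -> (1 - e^{-sigma d}) E
        scene = make_scene("emissive_cube", film=(8, 8))
        n = 10_000
        samples = np.empty(n)
        px = np.tile([4, 4], (n, 1))
        from voxtrace.transport import render_pixels

        vals = render_pixels(px, scene, rng)
        # all rays from one pixel: mean over samples
        # chord for the center pixel, computed from the camera geometry
        from voxtrace.volume import intersect_box
        from voxtrace.camera import generate_rays

        r = generate_rays(scene.camera, np.array([[4, 4]]), rng,
                          film_uv=np.array([[0.5, 0.5]]))
        _, t0, t1 = intersect_box(scene.volume, r)
        expect = 1.0 - np.exp(-scene.density_scale * (t1[0] - t0[0]))
        assert vals[:, 0].mean() == pytest.approx(expect, rel=0.01)

    def test_occluder_casts_soft_shadow(self, rng):
        # pixels behind the dense slab receive less light than unoccluded
        scene = make_scene("quad_shadow", film=(16, 16))
        acc = np.zeros((16, 16, 3))
        frames = 96
        for i in range(frames):
            acc += render_frame(scene, i, np.random.default_rng([7, i]))
        acc /= frames
        img = acc[..., 0]
        # light is overhead at the volume center; the slab shadows the body
        # beneath it (center columns) relative to the outer columns
        center = img[7:10, 6:10].mean()
        outer = np.concatenate([img[7:10, 1:5].ravel(), img[7:10, 11:15].ravel()]).mean()
        assert center < 0.6 * outer

    def test_all_fixture_scenes_produce_finite_nonnegative_radiance(self):
        for name in ("emissive_cube", "quad_shadow", "env_plus_two_area"):
            scene = make_scene(name, film=(12, 12))
            frame = render_frame(scene, 0, np.random.default_rng(3))
            assert np.all(np.isfinite(frame))
            assert np.all(frame >= 0)


class TestHybridIntegration:
    def test_modes_follow_gradient(self, rng):
        # nested-shells: events on a shell have strong gradients -> brdf
        # events appear when the gradient factor is on, never when off
        scene = make_scene("env_plus_two_area", film=(8, 8))
        med = scene.medium
        shell_pts = np.tile([31.5, 31.5, 31.5 + 0.42 * 63], (200, 1))
        wo = np.tile([0, -1.0, 0], (200, 1))
        ev_on = make_scatter_event(med, HybridParams(gradient_factor=1.0),
                                   shell_pts, np.full(200, 0.8), wo, rng)
        ev_off = make_scatter_event(med, HybridParams(gradient_factor=0.0),
                                    shell_pts, np.full(200, 0.8), wo, rng)
        assert (ev_on.mode == MODE_BRDF).mean() > 0.5
        assert np.all(ev_off.mode == MODE_PHASE)

    def test_flat_region_always_phase(self, rng):
        med = homogeneous_medium(1.0)
        ev = make_scatter_event(med, HybridParams(gradient_factor=1.0),
                                np.zeros((100, 3)), np.ones(100),
                                np.tile([0, 0, 1.0], (100, 1)), rng)
        assert np.all(ev.mode == MODE_PHASE)
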