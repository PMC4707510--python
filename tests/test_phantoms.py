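"""Phantom generator: analytic volumes, rasterization, rendering, plates."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from spheromorph.phantoms import (
    Appearance,
    PhantomError,
    PhantomSpec,
    ellipsoid_volume,
    lens_volume,
    make_phantom,
    make_plate_fixture,
    make_planted_plate,
    render_brightfield,
    sphere_volume,
)

QUIET = Appearance(noise_sd=0.0)
FLAT = Appearance(noise_sd=0.0, halo_gain=0.0, core_fraction=0.0)


def union_of_spheres_volume_numeric(r1, r2, d):
    """1D integration oracle: coaxial spheres, disk cross-sections."""

    def area(x):
        s1 = max(0.0, r1 * r1 - x * x)
        s2 = max(0.0, r2 * r2 - (x - d) ** 2)
        return math.pi * max(s1, s2)

    v, _ = integrate.quad(area, -r1, d + r2, limit=500)
    return v


class TestAnalyticVolumes:
    def test_sphere_closed_form(self):
        spec = PhantomSpec(kind="sphere", radius=100.0, pixel_size=1.0, side=256, appearance=QUIET)
        assert make_phantom(spec).truth_volume == pytest.approx(4.18879e6, rel=1e-5)

    def test_ellipsoid_closed_form(self):
        spec = PhantomSpec(
            kind="ellipsoid", semi_major=60.0, semi_minor=30.0, pixel_size=1.0, side=160,
            appearance=QUIET,
        )
        assert make_phantom(spec).truth_volume == pytest.approx(226_194.671, rel=1e-6)

    @pytest.mark.parametrize("r1,r2,d", [(100, 100, 100), (100, 100, 190), (80, 50, 100)])
    def test_twolobe_matches_integration_oracle(self, r1, r2, d):
        analytic = sphere_volume(r1) + sphere_volume(r2) - lens_volume(r1, r2, d)
        assert analytic == pytest.approx(union_of_spheres_volume_numeric(r1, r2, d), rel=1e-8)

    def test_budding_matches_integration_oracle(self):
        R, rb = 100.0, 30.0
        analytic = sphere_volume(R) + sphere_volume(rb) - lens_volume(R, rb, R)
        assert analytic == pytest.approx(union_of_spheres_volume_numeric(R, rb, R), rel=1e-8)

    def test_lens_limits(self):
        assert lens_volume(10, 5, 15) == 0.0  # tangent
        assert lens_volume(10, 5, 2) == pytest.approx(sphere_volume(5))  # contained


class TestRasterization:
    def test_pixel_center_rule_small_disk(self):
        # radius 2.5 μm at 1 μm/px on a 21-px frame: centers at distance
        # <= 2.5 from the image center are exactly the pixels with
        # (dr² + dc²) <= 6.25.
        spec = PhantomSpec(kind="sphere", radius=2.5, pixel_size=1.0, side=21, appearance=QUIET)
        mask = spec.rasterize()
        yy, xx = np.mgrid[:21, :21]
        expected = (yy - 10) ** 2 + (xx - 10) ** 2 <= 6.25
        assert np.array_equal(mask, expected)

    @pytest.mark.parametrize(
        "kind,kwargs",
        [
            ("sphere", {"radius": 40.0}),
            ("ellipsoid", {"semi_major": 45.0, "semi_minor": 22.0, "angle": 0.4}),
            ("twolobe", {"r1": 30.0, "r2": 30.0, "center_distance": 57.0}),
            ("budding", {"body_radius": 35.0, "bud_radius": 10.0}),
        ],
    )
    def test_voxelized_truth_matches_analytic_volume(self, kind, kwargs):
        # Voxelizing the true 3D geometry at the phantom's voxel size must
        # agree with the closed form within 2% at these feature sizes.
        spec = PhantomSpec(kind=kind, pixel_size=1.0, side=150, appearance=QUIET, **kwargs)
        spec.validate()
        n = 121
        c = (n - 1) / 2.0
        zz, yy, xx = np.mgrid[:n, :n, :n].astype(float) - c
        if kind == "sphere":
            occ = xx**2 + yy**2 + zz**2 <= kwargs["radius"] ** 2
        elif kind == "ellipsoid":
            a, b = kwargs["semi_major"], kwargs["semi_minor"]
            ca, sa = math.cos(kwargs["angle"]), math.sin(kwargs["angle"])
            u = (xx * ca + yy * sa) / a
            v = (-xx * sa + yy * ca) / b
            occ = u * u + v * v + (zz / b) ** 2 <= 1.0
        elif kind == "twolobe":
            d = kwargs["center_distance"]
            occ = (xx + d / 2) ** 2 + yy**2 + zz**2 <= kwargs["r1"] ** 2
            occ |= (xx - d / 2) ** 2 + yy**2 + zz**2 <= kwargs["r2"] ** 2
        else:
            R, rb = kwargs["body_radius"], kwargs["bud_radius"]
            occ = xx**2 + yy**2 + zz**2 <= R * R
            occ |= (xx - R) ** 2 + yy**2 + zz**2 <= rb * rb
        assert occ.sum() == pytest.approx(spec.analytic_volume(), rel=0.02)

    def test_frame_overflow(self):
        with pytest.raises(PhantomError, match="frame overflow"):
            make_phantom(PhantomSpec(kind="sphere", radius=100.0, pixel_size=1.0, side=128))

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            ({"kind": "blob", "radius": 10.0}, "unknown kind"),
            ({"kind": "sphere", "radius": -5.0}, "positive"),
            ({"kind": "twolobe", "r1": 10.0, "r2": 10.0, "center_distance": 25.0}, "center_distance"),
            ({"kind": "budding", "body_radius": 20.0, "bud_radius": 10.0}, "bud_radius"),
            ({"kind": "ellipsoid", "semi_major": 10.0, "semi_minor": 20.0}, "semi_major"),
        ],
    )
    def test_invalid_specs(self, kwargs, msg):
        with pytest.raises(PhantomError, match=msg):
            make_phantom(PhantomSpec(pixel_size=1.0, side=256, **kwargs))


class TestRendering:
    def test_two_level_image_thresholds_to_truth(self):
        spec = PhantomSpec(kind="sphere", radius=40.0, pixel_size=1.0, side=120, appearance=FLAT)
        ph = make_phantom(spec)
        mid = (FLAT.background + FLAT.body) / 2.0
        assert np.array_equal(ph.image.pixels < mid, ph.truth_mask.pixels)

    def test_determinism_same_seed(self):
        spec = PhantomSpec(kind="sphere", radius=40.0, pixel_size=1.0, side=120, seed=7)
        a, b = make_phantom(spec), make_phantom(spec)
        assert a.image.pixels.tobytes() == b.image.pixels.tobytes()

    def test_different_seeds_differ_only_in_noise(self):
        base = dict(kind="sphere", radius=40.0, pixel_size=1.0, side=120)
        a = make_phantom(PhantomSpec(seed=7, **base))
        b = make_phantom(PhantomSpec(seed=8, **base))
        diff = np.abs(a.image.pixels - b.image.pixels)
        assert diff.max() > 0
        assert diff.mean() <= 3 * Appearance().noise_sd

    def test_level_ordering_enforced(self):
        bad = Appearance(core=120.0, body=110.0)
        with pytest.raises(PhantomError, match="levels"):
            render_brightfield(np.ones((10, 10), bool), bad, 0, 1.0)

    def test_halo_is_brighter_than_background(self):
        spec = PhantomSpec(kind="sphere", radius=40.0, pixel_size=1.0, side=120, appearance=QUIET)
        ph = make_phantom(spec)
        img = ph.image.pixels
        assert img.max() > QUIET.background
        assert img[ph.truth_mask.pixels].max() <= QUIET.body


class TestPlateFixture:
    def test_fixed_volume_spheres_identical(self):
        phantoms, truth = make_plate_fixture(
            n_wells=4, class_mix={"sphere": 1.0}, volume_distribution=("fixed", 0.1), seed=1
        )
        assert list(truth["well"]) == ["A1", "A2", "A3", "A4"]
        assert truth["volume_um3"].nunique() == 1
        assert truth["volume_um3"].iloc[0] == pytest.approx(0.1e9)

    def test_class_counts_deterministic_split(self):
        _, truth = make_plate_fixture(
            n_wells=20, class_mix={"sphere": 0.5, "twolobe": 0.5},
            volume_distribution=("fixed", 0.1), seed=5,
        )
        counts = truth["class"].value_counts()
        assert counts["spherical"] == 10 and counts["figure8"] == 10

    def test_lognormal_volume_mean(self):
        mu, sigma = math.log(0.1), 0.25
        _, truth = make_plate_fixture(
            n_wells=96, class_mix={"sphere": 1.0},
            volume_distribution=("lognormal", mu, sigma), seed=11,
        )
        v = truth["volume_um3"].to_numpy() * 1e-9
        dist_mean = math.exp(mu + sigma**2 / 2)
        se = v.std(ddof=1) / math.sqrt(len(v))
        assert abs(v.mean() - dist_mean) <= 3 * se

    def test_plate_overflow(self):
        with pytest.raises(PhantomError, match="plate overflow"):
            make_plate_fixture(n_wells=97)

    def test_wells_reproducible_across_calls(self):
        a, _ = make_plate_fixture(n_wells=3, seed=9)
        b, _ = make_plate_fixture(n_wells=3, seed=9)
        for w in a:
            assert a[w].image.pixels.tobytes() == b[w].image.pixels.tobytes()

    def test_planted_plate_roles(self):
        phantoms, truth = make_planted_plate(
            seed=2, n_in_band=5, n_out_band=3, n_nonspherical=4
        )
        assert len(phantoms) == 12
        assert truth["planted_in_band"].sum() == 5
        in_v = truth.loc[truth["planted_in_band"], "volume_um3"] * 1e-9
        assert ((in_v > 0.112 * 0.95) & (in_v < 0.112 * 1.05)).all()
        out_v = truth.loc[
            ~truth["planted_in_band"] & (truth["class"] == "spherical"), "volume_um3"
        ] * 1e-9
        assert ((out_v < 0.112 * 0.85) | (out_v > 0.112 * 1.15)).all()
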