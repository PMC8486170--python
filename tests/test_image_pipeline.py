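"""Colony-image pipeline on generated colonies with closed-form truth."""

import numpy as np
import pytest

from colonypattern import (
    ColonyImage,
    SyntheticColonySpec,
    analyze_colony_image,
    boundary_profile,
    colony_wavelength,
    detect_colony_edge,
    estimate_center,
    generate_colony_image,
    polar_transform,
)


@pytest.fixture(scope="module")
def disk_image():
    return generate_colony_image(SyntheticColonySpec(n_lobes=0))


@pytest.fixture(scope="module")
def lobed_image():
    return generate_colony_image(SyntheticColonySpec(n_lobes=12))


class TestEstimateCenter:
    def test_centered_disk(self, disk_image):
        r, c = estimate_center(disk_image, 100.0)
        assert r == pytest.approx(255.5, abs=0.5)
        assert c == pytest.approx(255.5, abs=0.5)

    def test_translation_equivariance(self):
        shifted = generate_colony_image(
            SyntheticColonySpec(n_lobes=0, center_px=(265.5, 259.5))
        )
        r, c = estimate_center(shifted, 100.0)
        assert r == pytest.approx(265.5, abs=0.5)
        assert c == pytest.approx(259.5, abs=0.5)

    def test_lobed_colony_within_one_pixel(self, lobed_image):
        r, c = estimate_center(lobed_image, 100.0)
        assert np.hypot(r - 255.5, c - 255.5) < 1.0

    def test_no_pixels_above_threshold(self, disk_image):
        with pytest.raises(ValueError):
            estimate_center(disk_image, 1e9)


class TestPolarTransform:
    def test_uniform_disk_rows_constant_inside(self, disk_image):
        polar = polar_transform(disk_image, (255.5, 255.5), 256, 256)
        inside = polar[30]  # radius well inside the disk
        assert inside.std() < 1e-9
        assert inside.mean() == pytest.approx(200.0)

    def test_single_bright_pixel_lands_at_matching_bin(self):
        px = np.zeros((101, 101))
        px[50, 70] = 100.0  # 20 px east of centre -> theta = 0
        img = ColonyImage(px, 0.01)
        polar = polar_transform(img, (50.0, 50.0), 101, 64)
        r_idx, a_idx = np.unravel_index(np.argmax(polar), polar.shape)
        assert a_idx == 0
        assert r_idx == pytest.approx(40, abs=1)  # 20 px of 50 -> row 40 of 101

    def test_lobed_row_has_lobe_count_maxima(self, lobed_image):
        polar = polar_transform(lobed_image, (255.5, 255.5), 512, 1024)
        # row at the base radius: inside the lobes, outside the troughs
        row = polar[int(round(0.4 / 0.0025 / 255.5 * 511))]
        binary = row > 100.0
        crossings = np.sum(binary & ~np.roll(binary, 1))
        assert crossings == 12

    def test_center_outside_rejected(self, disk_image):
        with pytest.raises(ValueError):
            polar_transform(disk_image, (-3.0, 10.0), 64, 64)


class TestBoundaryProfile:
    def test_uniform_disk_constant(self, disk_image):
        polar = polar_transform(disk_image, (255.5, 255.5))
        prof = boundary_profile(polar, 0.9, disk_image.pixel_size_cm)
        assert prof.intensity.std() < 1e-6

    def test_twelve_lobes_twelve_cycles(self, lobed_image):
        prof, _ = analyze_colony_image(lobed_image, radius_fraction=0.95)
        binary = prof.intensity > 100.0
        crossings = np.sum(binary & ~np.roll(binary, 1))
        assert crossings == 12

    def test_degenerate_center_fraction(self, disk_image):
        polar = polar_transform(disk_image, (255.5, 255.5))
        prof = boundary_profile(polar, 1e-6, disk_image.pixel_size_cm)
        assert prof.intensity.std() < 1e-9

    def test_invalid_fraction(self, disk_image):
        polar = polar_transform(disk_image, (255.5, 255.5))
        with pytest.raises(ValueError):
            boundary_profile(polar, 0.0, disk_image.pixel_size_cm)


class TestColonyWavelength:
    @pytest.mark.parametrize("m", [4, 6, 8, 12, 16])
    def test_closed_form_arc_length(self, m):
        spec = SyntheticColonySpec(n_lobes=m)
        prof, wl = analyze_colony_image(
            generate_colony_image(spec), radius_fraction=0.95
        )
        expected = 2 * np.pi * prof.radius_cm / m
        assert wl == pytest.approx(expected, rel=1e-9)
        # and against the generator's nominal radius
        nominal = 2 * np.pi * 0.95 * spec.base_radius_cm / m
        assert wl == pytest.approx(nominal, rel=0.05)

    def test_six_lobes_at_smaller_radius(self):
        spec = SyntheticColonySpec(
            n_lobes=6, base_radius_cm=0.3, lobe_amplitude_cm=0.03
        )
        prof, wl = analyze_colony_image(generate_colony_image(spec), radius_fraction=0.95)
        assert wl == pytest.approx(np.pi * 0.3 * 0.95 / 3, rel=0.05)

    def test_uniform_disk_none(self, disk_image):
        _, wl = analyze_colony_image(disk_image)
        assert wl is None

    def test_noise_robustness(self):
        # noise SD at 10% of the lobe modulation amplitude
        for m in (6, 12):
            for seed in range(3):
                spec = SyntheticColonySpec(n_lobes=m, noise_sd=17.0, seed=seed)
                prof, wl = analyze_colony_image(
                    generate_colony_image(spec), radius_fraction=0.95
                )
                assert wl == pytest.approx(
                    2 * np.pi * 0.95 * spec.base_radius_cm / m, rel=0.05
                )

    def test_rotation_consistency(self):
        spec = SyntheticColonySpec(n_lobes=12, noise_sd=5.0, seed=4)
        img = generate_colony_image(spec)
        rot = ColonyImage(np.rot90(img.pixels).copy(), img.pixel_size_cm)
        _, w1 = analyze_colony_image(img)
        _, w2 = analyze_colony_image(rot)
        assert w1 == pytest.approx(w2, rel=0.02)


class TestDetectColonyEdge:
    def test_disk_contour_radius(self, disk_image):
        contour = detect_colony_edge(disk_image, 100.0)
        r = np.hypot(contour[:, 0] - 255.5, contour[:, 1] - 255.5)
        assert np.all(np.abs(r - 160.0) <= 1.0)

    def test_counterclockwise(self, disk_image):
        contour = detect_colony_edge(disk_image, 100.0)
        c = contour[:, 1]
        r = -contour[:, 0]
        area = 0.5 * np.sum(c * np.roll(r, -1) - np.roll(c, -1) * r)
        assert area > 0

    def test_lobed_contour_has_lobe_count_maxima(self, lobed_image):
        contour = detect_colony_edge(lobed_image, 100.0)
        r = np.hypot(contour[:, 0] - 255.5, contour[:, 1] - 255.5)
        theta = np.arctan2(255.5 - contour[:, 0], contour[:, 1] - 255.5)
        bins = np.linspace(-np.pi, np.pi, 361)
        digitized = np.digitize(theta, bins)
        radial = np.array(
            [r[digitized == k].mean() for k in range(1, 361) if (digitized == k).any()]
        )
        above = radial > 160.0
        crossings = np.sum(above & ~np.roll(above, 1))
        assert crossings == 12

    def test_all_background_rejected(self):
        img = ColonyImage(np.zeros((64, 64)), 0.01)
        with pytest.raises(ValueError):
            detect_colony_edge(img, 0.5)


class TestGrowthSeries:
    def test_trough_angles_stable_across_days(self):
        """On a growth series with persistent lobes the angular trough
        positions drift by less than one angular bin."""
        trough_sets = []
        for day, radius in enumerate((0.30, 0.35, 0.40)):
            spec = SyntheticColonySpec(
                n_lobes=12, base_radius_cm=radius, lobe_amplitude_cm=0.03
            )
            prof, _ = analyze_colony_image(
                generate_colony_image(spec), radius_fraction=0.95
            )
            binary = prof.intensity > 100.0
            # trough centres: midpoints of below-threshold arcs
            edges_down = np.flatnonzero(~binary & np.roll(binary, 1))
            edges_up = np.flatnonzero(binary & ~np.roll(binary, 1))
            centres = []
            for d in edges_down:
                u = edges_up[edges_up > d]
                u = u[0] if u.size else edges_up[0] + binary.size
                centres.append(((d + u) / 2) % binary.size)
            trough_sets.append(np.sort(np.array(centres)))
        bin_width = 2 * np.pi / 1024
        for later in trough_sets[1:]:
            assert later.size == trough_sets[0].size == 12
            drift = np.abs(later - trough_sets[0]) * bin_width
            assert np.all(drift <= bin_width * 1.5)


class TestColonyImageType:
    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            ColonyImage(np.zeros((4, 4, 3)), 0.01)
        with pytest.raises(ValueError):
            ColonyImage(np.zeros((4, 4)), -1.0)
        bad = np.zeros((8, 8))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            ColonyImage(bad, 0.01)

    def test_png_roundtrip(self, tmp_path, lobed_image):
        from colonypattern.synthetic_data import save_colony_png

        spec = SyntheticColonySpec(n_lobes=12)
        path = tmp_path / "colony.png"
        save_colony_png(lobed_image, spec, path)
        back = ColonyImage.from_file(path, spec.pixel_size_cm)
        assert back.pixels.shape == lobed_image.pixels.shape
        _, wl = analyze_colony_image(back)
        assert wl == pytest.approx(2 * np.pi * 0.95 * 0.4 / 12, rel=0.05)
        assert path.with_suffix(".truth.yaml").exists()
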